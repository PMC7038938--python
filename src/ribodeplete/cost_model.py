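"""Reagent-cost arithmetic for the two probe strategies, plus the bench
hybridization sheet.

Synthesized oligo pools have a high up-front cost amortized over many
reactions; amplicon probes cost more per reaction but nothing up front.
Defaults are typical US list prices: $450 per synthesized probe set good for
12,000+ reactions, $4.98 of amplicon consumables per reaction, and $12.90 of
shared depletion reagents per reaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CostInputs",
    "PerReactionCosts",
    "BreakevenResult",
    "per_reaction_costs",
    "breakeven_reactions",
    "hybridization_sheet",
    "DEFAULT_PROBE_TO_RNA_RATIO",
]

DEFAULT_PROBE_TO_RNA_RATIO = 5.0


@dataclass(frozen=True)
class CostInputs:
    oligo_upfront: float = 450.0
    oligo_yield_reactions: int = 12_000
    amplicon_per_reaction: float = 4.98
    shared_reagents_per_reaction: float = 12.90

    def __post_init__(self) -> None:
        if min(self.oligo_upfront, self.amplicon_per_reaction,
               self.shared_reagents_per_reaction) < 0:
            raise ValueError("costs must be non-negative")
        if self.oligo_yield_reactions < 1:
            raise ValueError("oligo_yield_reactions must be >= 1")

    @property
    def oligo_probe_per_reaction(self) -> float:
        return self.oligo_upfront / self.oligo_yield_reactions


@dataclass(frozen=True)
class PerReactionCosts:
    oligo_probe: float
    amplicon_probe: float
    oligo_total: float
    amplicon_total: float


@dataclass(frozen=True)
class BreakevenResult:
    """Smallest reaction count at which the synthesized pool is cheaper.

    ``n_exact`` accounts for the oligo per-reaction probe cost;
    ``n_upfront_only`` ignores it (upfront / amplicon cost); ``n_rounded``
    presents the exact value to the nearest ten.
    """

    n_exact: int | None
    n_rounded: int | None
    n_upfront_only: int | None


def per_reaction_costs(inputs: CostInputs = CostInputs()) -> PerReactionCosts:
    """Per-reaction probe and total costs for both strategies.

    The oligo probe cost is the up-front synthesis amortized over the yield;
    totals add the shared depletion reagents.
    """
    oligo = inputs.oligo_probe_per_reaction
    return PerReactionCosts(
        oligo_probe=oligo,
        amplicon_probe=inputs.amplicon_per_reaction,
        oligo_total=oligo + inputs.shared_reagents_per_reaction,
        amplicon_total=inputs.amplicon_per_reaction + inputs.shared_reagents_per_reaction,
    )


def breakeven_reactions(inputs: CostInputs = CostInputs()) -> BreakevenResult:
    """Smallest n with upfront + n*oligo_per_reaction <= n*amplicon_per_reaction.

    Shared reagents cancel.  When amplicon probes are not more expensive per
    reaction than oligo probes there is no break-even.
    """
    gap = inputs.amplicon_per_reaction - inputs.oligo_probe_per_reaction
    if gap <= 0:
        return BreakevenResult(None, None, None)
    n_exact = max(1, math.ceil(inputs.oligo_upfront / gap))
    n_upfront_only = (
        max(1, math.ceil(inputs.oligo_upfront / inputs.amplicon_per_reaction))
        if inputs.amplicon_per_reaction > 0
        else None
    )
    return BreakevenResult(
        n_exact=n_exact,
        n_rounded=int(round(n_exact / 10.0) * 10),
        n_upfront_only=n_upfront_only,
    )


def hybridization_sheet(
    rna_input_ng: float, probe_to_rna_ratio: float = DEFAULT_PROBE_TO_RNA_RATIO
) -> float:
    """Probe mass (ng) to add for a given RNA input at the given mass ratio
    (default 5:1, e.g. 2500 ng probe for 500 ng fragmented RNA)."""
    if rna_input_ng <= 0:
        raise ValueError("rna_input_ng must be positive")
    if probe_to_rna_ratio <= 0:
        raise ValueError("probe_to_rna_ratio must be positive")
    return probe_to_rna_ratio * rna_input_ng
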