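"""Synthetic community generator and in-silico probe-directed depletion.

Builds toy bacterial "organisms" (one 16S-like and one 23S-like gene plus
annotated CDSs), simulates a fragmented total-RNA pool dominated by rRNA
(~90-95% of fragments, as in undepleted bacterial total RNA), applies a
probabilistic model of RNase H depletion directed by a probe library, and
emits labeled reads so every downstream metric can be checked against truth.

The depletion model is a step function: a fragment overlapping a probe tile
by at least ``min_overlap`` nt is removed with probability ``p_max`` when
that probe's tile mismatch percent is under ``local_threshold`` (default 25%,
the level below which a probe still depletes its local region), otherwise
with the background probability.  Everything is deterministic under a seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .core_io import CdsFeature, SeqRecord, write_fasta, write_gff3

__all__ = [
    "CommunityConfig",
    "DepletionModel",
    "Fragment",
    "TruthRow",
    "ToyOrganism",
    "make_toy_organism",
    "mutate_target",
    "simulate_pool",
    "apply_depletion",
    "emit_reads",
]

_BASES = np.array(list("ACGT"))


@dataclass
class CommunityConfig:
    """Composition of the simulated fragmented total-RNA pool.

    Defaults follow undepleted bacterial total RNA: ~94% of mapped reads are
    rRNA; fragment lengths ~60 +/- 15 nt (truncated at 25) mimic a
    fragmentation-based library prep.
    """

    rrna_fraction: float = 0.94
    n_fragments: int = 100_000
    fragment_len_mean: float = 60.0
    fragment_len_sd: float = 15.0
    fragment_len_min: int = 25
    divergence: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rrna_fraction <= 1.0:
            raise ValueError("rrna_fraction must be in [0, 1]")
        if self.n_fragments < 1:
            raise ValueError("n_fragments must be >= 1")


@dataclass
class DepletionModel:
    """Step-function removal probabilities for probe-directed depletion."""

    p_max: float = 0.98
    local_threshold: float = 25.0
    p_background: float = 0.0
    min_overlap: int = 20

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_background <= self.p_max <= 1.0:
            raise ValueError("need 0 <= p_background <= p_max <= 1")


@dataclass(frozen=True)
class Fragment:
    """One RNA fragment with its recorded origin (0-based half-open)."""

    fragment_id: str
    origin_class: str  # rRNA_16S | rRNA_23S | mRNA
    origin_feature: str
    start: int
    end: int
    seq: str


@dataclass(frozen=True)
class TruthRow:
    read_id: str
    origin_class: str
    origin_feature: str
    survived_depletion: bool


@dataclass
class ToyOrganism:
    """A toy genome: concatenated rRNA genes and CDSs with spacers."""

    name: str
    genome: SeqRecord
    rrna_16s: SeqRecord
    rrna_23s: SeqRecord
    cds_features: list[CdsFeature]
    cds_seqs: dict[str, str] = field(default_factory=dict)
    rrna_offsets: dict[str, int] = field(default_factory=dict)  # gene -> genome offset (0-based)

    @property
    def rrnas(self) -> list[SeqRecord]:
        return [self.rrna_16s, self.rrna_23s]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def make_toy_organism(
    seed: int,
    n_cds: int = 20,
    cds_len_range: tuple[int, int] = (300, 1500),
    name: str = "toy",
) -> ToyOrganism:
    """Generate a deterministic toy organism.

    The 16S-like gene is 1400-1600 nt, the 23S-like gene 2800-3000 nt,
    followed by ``n_cds`` CDSs with lengths drawn from ``cds_len_range``,
    all separated by 100 nt spacers on a single contig.
    """
    if n_cds < 1:
        raise ValueError("n_cds must be >= 1")
    rng = np.random.default_rng(seed)
    len16 = int(rng.integers(1400, 1601))
    len23 = int(rng.integers(2800, 3001))
    spacer = 100
    parts: list[str] = []
    pos = 0

    def push(seq: str) -> int:
        nonlocal pos
        start = pos
        parts.append(seq)
        pos += len(seq)
        return start

    push(_random_seq(rng, spacer))
    seq16 = _random_seq(rng, len16)
    off16 = push(seq16)
    push(_random_seq(rng, spacer))
    seq23 = _random_seq(rng, len23)
    off23 = push(seq23)

    features: list[CdsFeature] = []
    cds_seqs: dict[str, str] = {}
    contig = f"{name}_contig1"
    for i in range(1, n_cds + 1):
        push(_random_seq(rng, spacer))
        length = int(rng.integers(cds_len_range[0], cds_len_range[1] + 1))
        cds_seq = _random_seq(rng, length)
        start0 = push(cds_seq)
        fid = f"{name}_cds_{i:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(
            CdsFeature(seq_id=contig, start=start0 + 1, end=start0 + length,
                       strand=strand, feature_id=fid)
        )
        cds_seqs[fid] = cds_seq
    push(_random_seq(rng, spacer))

    genome = SeqRecord(id=contig, seq="".join(parts))
    return ToyOrganism(
        name=name,
        genome=genome,
        rrna_16s=SeqRecord(id=f"{name}_16S_rRNA", seq=seq16),
        rrna_23s=SeqRecord(id=f"{name}_23S_rRNA", seq=seq23),
        cds_features=features,
        cds_seqs=cds_seqs,
        rrna_offsets={"16S": off16, "23S": off23},
    )


def mutate_target(rrna: SeqRecord, divergence: float, seed: int) -> SeqRecord:
    """Substitute each base independently (to a different base) with
    probability ``divergence`` — a stand-in for a related species' rRNA."""
    if not 0.0 <= divergence <= 0.5:
        raise ValueError("divergence must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    chars = np.array(list(rrna.seq))
    mask = rng.random(len(chars)) < divergence
    for i in np.flatnonzero(mask):
        alternatives = [b for b in "ACGT" if b != chars[i]]
        chars[i] = alternatives[rng.integers(0, 3)]
    return SeqRecord(
        id=f"{rrna.id}_div{divergence:g}", seq="".join(chars),
        description=f"mutated copy, per-base divergence {divergence:g}",
    )


def simulate_pool(
    config: CommunityConfig,
    organism: ToyOrganism,
    target_rrnas: dict[str, SeqRecord] | None = None,
) -> list[Fragment]:
    """Draw a fragmented total-RNA pool.

    Each fragment is rRNA with probability ``rrna_fraction`` (16S vs 23S
    proportional to gene length, i.e. ~1:2), otherwise mRNA from a CDS chosen
    proportional to length.  Start positions are uniform; lengths are
    truncated-normal, clipped to the source.  ``target_rrnas`` substitutes
    diverged rRNA sequences (e.g. from :func:`mutate_target`) while keeping
    probe-source coordinates.
    """
    rng = np.random.default_rng(config.seed)
    r16 = (target_rrnas or {}).get("16S", organism.rrna_16s)
    r23 = (target_rrnas or {}).get("23S", organism.rrna_23s)
    len16, len23 = len(r16), len(r23)
    p16 = len16 / (len16 + len23)

    cds_ids = [f.feature_id for f in organism.cds_features]
    cds_lens = np.array([f.length for f in organism.cds_features], dtype=float)
    cds_probs = cds_lens / cds_lens.sum()

    fragments: list[Fragment] = []
    for i in range(config.n_fragments):
        if rng.random() < config.rrna_fraction:
            if rng.random() < p16:
                cls, feat, src = "rRNA_16S", r16.id, r16.seq
            else:
                cls, feat, src = "rRNA_23S", r23.id, r23.seq
        else:
            j = rng.choice(len(cds_ids), p=cds_probs)
            cls, feat = "mRNA", cds_ids[j]
            src = organism.cds_seqs[feat]
        length = int(round(rng.normal(config.fragment_len_mean, config.fragment_len_sd)))
        length = max(config.fragment_len_min, length)
        length = min(length, len(src))
        start = int(rng.integers(0, len(src) - length + 1))
        fragments.append(
            Fragment(
                fragment_id=f"frag_{i:07d}",
                origin_class=cls,
                origin_feature=feat,
                start=start,
                end=start + length,
                seq=src[start : start + length],
            )
        )
    return fragments


def apply_depletion(
    fragments: list[Fragment],
    library,
    similarity: dict[str, float],
    model: DepletionModel,
    seed: int,
) -> tuple[list[Fragment], list[TruthRow]]:
    """Remove probe-targetable rRNA fragments stochastically.

    ``similarity`` maps probe_id -> tile mismatch percent (0 for the cognate
    species).  An rRNA fragment overlapping >= ``min_overlap`` nt of any
    effective probe tile (mismatch < ``local_threshold``) is removed with
    probability ``p_max``; all other fragments with ``p_background``.
    Returns the survivors and a truth table covering every input fragment.
    """
    for p in library.probes:
        if p.probe_id not in similarity:
            raise ValueError(f"similarity missing probe {p.probe_id}")
    # Abutting effective tiles form contiguous probe-covered regions: RNase H
    # sees an uninterrupted duplex across tile boundaries, so a fragment
    # straddling two effective tiles is as targetable as one inside a tile.
    effective: dict[str, list[tuple[int, int]]] = {}
    for gene in ("16S", "23S"):
        tiles = sorted(
            (p.tile_start, p.tile_end) for p in library.probes
            if p.source_gene == gene and similarity[p.probe_id] < model.local_threshold
        )
        merged: list[tuple[int, int]] = []
        for start, end in tiles:
            if merged and start <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], end))
            else:
                merged.append((start, end))
        effective[gene] = merged
    rng = np.random.default_rng(seed)
    survivors: list[Fragment] = []
    truth: list[TruthRow] = []
    for frag in fragments:
        p_remove = model.p_background
        if frag.origin_class.startswith("rRNA"):
            gene = frag.origin_class.split("_")[1]
            for ts, te in effective[gene]:
                overlap = min(frag.end, te) - max(frag.start, ts)
                if overlap >= model.min_overlap:
                    p_remove = model.p_max
                    break
        survived = rng.random() >= p_remove
        truth.append(TruthRow(frag.fragment_id, frag.origin_class,
                              frag.origin_feature, survived))
        if survived:
            survivors.append(frag)
    return survivors, truth


def emit_reads(
    fragments: list[Fragment],
    truth: list[TruthRow],
    out_prefix: str | os.PathLike,
    organism: ToyOrganism | None = None,
    write_sam: bool = False,
) -> dict[str, str]:
    """Write reads.fastq (one read per surviving fragment, fixed quality),
    truth.tsv (every fragment), and optionally reads.sam with the known
    origin as the alignment (rRNA reads against the rRNA references, mRNA
    reads against the toy genome)."""
    if not fragments:
        raise ValueError("no surviving fragments to emit")
    prefix = os.fspath(out_prefix)
    paths = {"fastq": prefix + ".fastq", "truth": prefix + ".truth.tsv"}
    with open(paths["fastq"], "w") as fq:
        for frag in fragments:
            fq.write(f"@{frag.fragment_id}\n{frag.seq}\n+\n{'I' * len(frag.seq)}\n")
    with open(paths["truth"], "w") as tsv:
        tsv.write("read_id\torigin_class\torigin_feature\tsurvived_depletion\n")
        for row in truth:
            tsv.write(f"{row.read_id}\t{row.origin_class}\t{row.origin_feature}\t"
                      f"{'true' if row.survived_depletion else 'false'}\n")
    if write_sam:
        if organism is None:
            raise ValueError("write_sam requires the organism for references")
        paths["sam"] = prefix + ".sam"
        feature_pos = {f.feature_id: f.start for f in organism.cds_features}
        with open(paths["sam"], "w") as sam:
            sam.write("@HD\tVN:1.6\tSO:unknown\n")
            for rec in (organism.rrna_16s, organism.rrna_23s, organism.genome):
                sam.write(f"@SQ\tSN:{rec.id}\tLN:{len(rec)}\n")
            for frag in fragments:
                if frag.origin_class == "mRNA":
                    ref = organism.genome.id
                    pos = feature_pos[frag.origin_feature] + frag.start
                else:
                    ref = frag.origin_feature
                    pos = frag.start + 1
                L = frag.end - frag.start
                sam.write(
                    f"{frag.fragment_id}\t0\t{ref}\t{pos}\t42\t{L}M\t*\t0\t0\t"
                    f"{frag.seq}\t{'I' * L}\n"
                )
    return paths
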