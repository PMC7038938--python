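"""Probe-to-target sequence similarity and cross-species applicability.

A probe library designed on one organism's rRNA can deplete a related
species when the sequences are close enough for probe:rRNA duplexes to form.
We quantify closeness by a global pairwise alignment of the two rRNAs and
the fraction of alignment columns that mismatch (gap columns count as
mismatches).  Empirically, libraries work when the 16S/23S average mismatch
fraction is below ~10%, and an individual ~50 nt probe still depletes its
local region below ~25% tile mismatches; both thresholds are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from .core_io import SeqRecord
from .probe_design import ProbeLibrary

__all__ = [
    "PairwiseAlignment",
    "SimilarityReport",
    "ApplicabilityVerdict",
    "GAP",
    "align",
    "overall_mismatch_pct",
    "per_probe_mismatch",
    "evaluate_gene",
    "predict_applicability",
    "OVERALL_THRESHOLD_PCT",
    "LOCAL_THRESHOLD_PCT",
]

GAP = -1  # column maps use -1 where a sequence has a gap

# Default decision thresholds (percent mismatches).
OVERALL_THRESHOLD_PCT = 10.0
LOCAL_THRESHOLD_PCT = 25.0

# Near-identity rRNA alignments are insensitive to the aligner; these NW
# affine-gap parameters keep gaps rare and deterministic.
MATCH_SCORE = 1.0
MISMATCH_SCORE = -1.0
GAP_OPEN = -4.0
GAP_EXTEND = -1.0


@dataclass
class PairwiseAlignment:
    """A global alignment of two sequences with per-column source positions.

    ``col_to_a[i]`` / ``col_to_b[i]`` give the 0-based source position of
    column ``i`` or :data:`GAP`.
    """

    a_aligned: str
    b_aligned: str
    col_to_a: list[int]
    col_to_b: list[int]
    score: float

    def __post_init__(self) -> None:
        if len(self.a_aligned) != len(self.b_aligned):
            raise ValueError("aligned strings differ in length")

    def __len__(self) -> int:
        return len(self.a_aligned)


@dataclass
class SimilarityReport:
    gene: str
    overall_mismatch_pct: float
    per_probe: list[tuple[str, float]]


@dataclass
class ApplicabilityVerdict:
    applicable: bool
    mean_overall_mismatch_pct: float
    locally_effective_fraction: float
    rationale: str


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=MATCH_SCORE,
        mismatch_score=MISMATCH_SCORE,
        open_gap_score=GAP_OPEN,
        extend_gap_score=GAP_EXTEND,
    )
    return aligner


def align(a: SeqRecord | str, b: SeqRecord | str) -> PairwiseAlignment:
    """Global (end-to-end) affine-gap alignment of two nucleotide sequences.

    Scoring: match +1, mismatch -1, gap open -4, gap extend -1 (a gap of
    length g costs 4 + (g-1)).
    """
    seq_a = a.seq if isinstance(a, SeqRecord) else a
    seq_b = b.seq if isinstance(b, SeqRecord) else b
    if not seq_a or not seq_b:
        raise ValueError("cannot align empty sequences")
    aln = _make_aligner().align(seq_a, seq_b)[0]
    a_aligned, b_aligned = aln[0], aln[1]
    col_to_a, col_to_b = [], []
    ia = ib = 0
    for ca, cb in zip(a_aligned, b_aligned):
        if ca == "-":
            col_to_a.append(GAP)
        else:
            col_to_a.append(ia)
            ia += 1
        if cb == "-":
            col_to_b.append(GAP)
        else:
            col_to_b.append(ib)
            ib += 1
    return PairwiseAlignment(a_aligned, b_aligned, col_to_a, col_to_b, float(aln.score))


def overall_mismatch_pct(aln: PairwiseAlignment) -> float:
    """Percent of alignment columns that mismatch, counting every gap column
    as one mismatch."""
    mismatches = sum(
        1 for ca, cb in zip(aln.a_aligned, aln.b_aligned) if ca == "-" or cb == "-" or ca != cb
    )
    return 100.0 * mismatches / len(aln)


def _tile_of(pos_a: int, boundaries: list[tuple[int, int]]) -> int | None:
    for i, (s, e) in enumerate(boundaries):
        if s <= pos_a < e:
            return i
    return None


def per_probe_mismatch(
    aln: PairwiseAlignment, library: ProbeLibrary, gene: str | None = None
) -> list[tuple[str, float]]:
    """Mismatch percent of each probe's tile, walked over alignment columns.

    Each column with a base of sequence ``a`` belongs to the tile containing
    that base; gap-in-``a`` columns are assigned to the tile of the preceding
    ``a`` base (5' tile), so the column blocks partition the alignment.
    """
    probes = library.gene_probes(gene) if gene else library.probes
    if not probes:
        return []
    a_len = max(aln.col_to_a, default=-1) + 1
    for p in probes:
        if p.tile_end > a_len:
            raise ValueError(
                f"probe {p.probe_id} tile {p.tile_start}:{p.tile_end} outside "
                f"aligned sequence of length {a_len}")
    boundaries = [(p.tile_start, p.tile_end) for p in probes]
    lengths = [0] * len(probes)
    mismatches = [0] * len(probes)
    current = None  # tile of the last consumed a-base
    for col, (ca, cb) in enumerate(zip(aln.a_aligned, aln.b_aligned)):
        pos_a = aln.col_to_a[col]
        if pos_a != GAP:
            current = _tile_of(pos_a, boundaries)
        tile = current if pos_a == GAP else _tile_of(pos_a, boundaries)
        if tile is None:
            continue
        lengths[tile] += 1
        if ca == "-" or cb == "-" or ca != cb:
            mismatches[tile] += 1
    return [
        (p.probe_id, 100.0 * mismatches[i] / lengths[i] if lengths[i] else 0.0)
        for i, p in enumerate(probes)
    ]


def evaluate_gene(
    source_rrna: SeqRecord, target_rrna: SeqRecord, library: ProbeLibrary, gene: str
) -> SimilarityReport:
    """Align one gene pair and report overall and per-probe mismatch percents."""
    aln = align(source_rrna, target_rrna)
    return SimilarityReport(
        gene=gene,
        overall_mismatch_pct=overall_mismatch_pct(aln),
        per_probe=per_probe_mismatch(aln, library, gene=gene),
    )


def predict_applicability(
    report_16s: SimilarityReport,
    report_23s: SimilarityReport,
    overall_threshold: float = OVERALL_THRESHOLD_PCT,
    local_threshold: float = LOCAL_THRESHOLD_PCT,
) -> ApplicabilityVerdict:
    """Predict whether the library will deplete the target species' rRNA.

    Applicable iff the mean of the two genes' overall mismatch percents is
    below ``overall_threshold``; also reports the fraction of probes below
    ``local_threshold`` tile mismatches (probes still locally effective).
    """
    mean_pct = (report_16s.overall_mismatch_pct + report_23s.overall_mismatch_pct) / 2.0
    all_probes = report_16s.per_probe + report_23s.per_probe
    if all_probes:
        effective = sum(1 for _, pct in all_probes if pct < local_threshold)
        frac = effective / len(all_probes)
    else:
        frac = 0.0
    applicable = mean_pct < overall_threshold
    rationale = (
        f"mean 16S/23S mismatch {mean_pct:.2f}% "
        f"{'<' if applicable else '>='} {overall_threshold:.0f}% threshold; "
        f"{frac:.0%} of probes under {local_threshold:.0f}% tile mismatches"
    )
    return ApplicabilityVerdict(applicable, mean_pct, frac, rationale)
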