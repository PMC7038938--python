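"""Depletion-performance and transcriptome-consistency statistics.

Read-level metrics follow a two-pass classification (reads are assigned to
rRNA references first; the remainder maps to the genome): the rRNA fraction
is rRNA-mapped / total mapped, and the fold enrichment of non-rRNA reads is
(1 - p_after) / (1 - p_before) for before/after rRNA proportions p.

Gene-level consistency compares per-CDS expression between a depleted and an
undepleted library of the same RNA: counts of uniquely mapped reads are
length-normalized to TPM, and correlations (Pearson, Spearman, R^2), Q-Q
order statistics and the Mann-Whitney rank-biserial effect size are computed
on log10(TPM + 0.1).  Sample ordination uses classical (Torgerson) MDS on
the distance d = sqrt(2 - 2 r_s) between per-sample TPM profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .core_io import CdsFeature, ReadAlignmentRecord

__all__ = [
    "DepletionReport",
    "ExpressionProfile",
    "ConsistencyReport",
    "OrdinationResult",
    "ReadClassification",
    "MetricsError",
    "classify_truth",
    "classify_sam",
    "rrna_fraction",
    "fold_enrichment",
    "cds_counts",
    "tpm",
    "make_expression_profile",
    "consistency",
    "mds_ordination",
    "per_tile_depletion_efficiency",
    "mappability_stats",
    "depletion_report",
]

LOG_PSEUDO = 0.1  # added to TPM before log10
COVERAGE_PSEUDO = 0.5  # added to raw per-base coverage before normalizing


class MetricsError(ValueError):
    """A metric is undefined for the given inputs (e.g. zero denominator)."""


@dataclass
class ReadClassification:
    """Per-sample read-level tallies feeding the depletion metrics."""

    n_rrna: int
    n_genome_mapped: int  # non-rRNA reads mapped to the genome
    n_unmapped: int  # non-rRNA reads mapping nowhere
    n_cds: int  # genome-mapped reads overlapping a CDS

    @property
    def n_mapped(self) -> int:
        return self.n_rrna + self.n_genome_mapped

    @property
    def n_non_rrna(self) -> int:
        return self.n_genome_mapped + self.n_unmapped


@dataclass
class DepletionReport:
    sample_id: str
    rrna_reads_pct: float
    fold_enrichment: float | None
    mappability_pct: float | None
    cds_reads_pct: float | None


@dataclass
class ExpressionProfile:
    """Per-CDS unique counts, lengths and TPM for one sample."""

    sample_id: str
    feature_ids: list[str]
    counts: np.ndarray
    lengths: np.ndarray
    tpm: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.tpm is None:
            self.tpm = tpm(self.counts, self.lengths)
        else:
            self.tpm = np.asarray(self.tpm, dtype=float)


@dataclass
class ConsistencyReport:
    pearson_r: float
    spearman_rs: float
    r_squared: float
    qq_pairs: list[tuple[float, float]]
    mwu_effect_size: float  # rank-biserial, in [-1, 1]
    mwu_common_language: float  # U / (n_a * n_b), in [0, 1]


@dataclass
class OrdinationResult:
    sample_ids: list[str]
    distances: np.ndarray  # d_ij = sqrt(2 - 2 rs_ij)
    coordinates: np.ndarray  # (n_samples, n_dims), n_dims in {1, 2}
    n_dims: int


# ---------------------------------------------------------------------------
# read-level classification and metrics

def classify_truth(rows, cds_feature_ids: set[str] | None = None) -> ReadClassification:
    """Tally truth-table rows for surviving reads.

    Simulated reads always map to their origin, so genome-mapped equals all
    non-rRNA reads and the CDS tally is every mRNA read (fragments are drawn
    from within CDSs).
    """
    n_rrna = n_mrna = 0
    for row in rows:
        if not row.survived_depletion:
            continue
        if row.origin_class.startswith("rRNA"):
            n_rrna += 1
        else:
            n_mrna += 1
    return ReadClassification(n_rrna=n_rrna, n_genome_mapped=n_mrna,
                              n_unmapped=0, n_cds=n_mrna)


def classify_sam(
    records: list[ReadAlignmentRecord],
    rrna_ids: set[str],
    features: list[CdsFeature] | None = None,
) -> ReadClassification:
    """Classify primary alignments: rRNA references first, remainder genome.

    When ``features`` is given, genome-mapped reads are checked for >= 1 bp
    CDS overlap (any strand) for the CDS tally.
    """
    trees = _feature_trees(features) if features else {}
    n_rrna = n_gen = n_unmapped = n_cds = 0
    for rec in records:
        if not rec.mapped:
            n_unmapped += 1
        elif rec.ref_id in rrna_ids:
            n_rrna += 1
        else:
            n_gen += 1
            if trees:
                tree = trees.get(rec.ref_id)
                if tree is not None and tree.overlap(rec.pos - 1, rec.pos - 1 + rec.aln_len):
                    n_cds += 1
    return ReadClassification(n_rrna=n_rrna, n_genome_mapped=n_gen,
                              n_unmapped=n_unmapped, n_cds=n_cds)


def rrna_fraction(classification: ReadClassification) -> float:
    """Percent of total mapped reads that map to rRNA."""
    if classification.n_mapped < 1:
        raise MetricsError("rRNA fraction undefined: zero mapped reads")
    return 100.0 * classification.n_rrna / classification.n_mapped


def fold_enrichment(p_before: float, p_after: float) -> float:
    """Fold change of the non-rRNA proportion, (1 - p_after)/(1 - p_before),
    with both percents on the 0-100 scale."""
    if p_before >= 100.0:
        raise MetricsError("fold enrichment undefined: p_before is 100%")
    return (1.0 - p_after / 100.0) / (1.0 - p_before / 100.0)


def mappability_stats(classification: ReadClassification) -> tuple[float, float]:
    """(mappability %, CDS %) of non-rRNA reads.

    Mappability is genome-mapped / all non-rRNA reads; the CDS percent is
    CDS-overlapping / genome-mapped non-rRNA reads.
    """
    if classification.n_non_rrna < 1:
        raise MetricsError("mappability undefined: no non-rRNA reads")
    mappability = 100.0 * classification.n_genome_mapped / classification.n_non_rrna
    if classification.n_genome_mapped < 1:
        raise MetricsError("CDS percent undefined: no genome-mapped reads")
    cds_pct = 100.0 * classification.n_cds / classification.n_genome_mapped
    return mappability, cds_pct


def depletion_report(
    sample_id: str,
    classification: ReadClassification,
    p_before: float | None = None,
) -> DepletionReport:
    p = rrna_fraction(classification)
    fe = fold_enrichment(p_before, p) if p_before is not None else None
    try:
        mapp, cds = mappability_stats(classification)
    except MetricsError:
        mapp = cds = None
    return DepletionReport(sample_id, p, fe, mapp, cds)


# ---------------------------------------------------------------------------
# CDS counting and TPM

def _feature_trees(features: list[CdsFeature]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for f in features:
        trees.setdefault(f.seq_id, IntervalTree())[f.start - 1 : f.end] = f.feature_id
    return trees


def cds_counts(
    alignments: list[ReadAlignmentRecord], features: list[CdsFeature]
) -> dict[str, int]:
    """Count uniquely mapped reads per CDS (>= 1 bp overlap, either strand).

    Multi-mapped reads are excluded; a read overlapping two or more CDSs is
    ambiguous and counts for none (featureCounts default behaviour).
    """
    trees = _feature_trees(features)
    counts = {f.feature_id: 0 for f in features}
    for rec in alignments:
        if not rec.mapped or rec.multi_mapped:
            continue
        tree = trees.get(rec.ref_id)
        if tree is None:
            continue
        overlaps = {iv.data for iv in tree.overlap(rec.pos - 1, rec.pos - 1 + rec.aln_len)}
        if len(overlaps) == 1:
            counts[overlaps.pop()] += 1
    return counts


def tpm(counts, lengths) -> np.ndarray:
    """Transcripts per million: length-normalized rates rescaled to sum 1e6.

    All-zero counts yield all-zero TPM.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths < 1):
        raise MetricsError("CDS lengths must be >= 1")
    rates = counts / lengths
    total = rates.sum()
    if total == 0:
        return np.zeros_like(rates)
    return 1e6 * rates / total


def make_expression_profile(
    sample_id: str,
    alignments: list[ReadAlignmentRecord],
    features: list[CdsFeature],
) -> ExpressionProfile:
    counts = cds_counts(alignments, features)
    fids = [f.feature_id for f in features]
    return ExpressionProfile(
        sample_id=sample_id,
        feature_ids=fids,
        counts=np.array([counts[f] for f in fids], dtype=float),
        lengths=np.array([f.length for f in features], dtype=float),
    )


# ---------------------------------------------------------------------------
# consistency between depleted and undepleted samples

def _log_tpm(profile: ExpressionProfile) -> np.ndarray:
    return np.log10(profile.tpm + LOG_PSEUDO)


def consistency(profile_a: ExpressionProfile, profile_b: ExpressionProfile) -> ConsistencyReport:
    """Compare two expression profiles on log10(TPM + 0.1).

    Reports Pearson r, Spearman r_s (average ranks on ties), R^2 = r^2, the
    matched order statistics for a Q-Q plot, and the Mann-Whitney effect size
    of sample a vs b, both as rank-biserial r = 2U/(n_a n_b) - 1 and as the
    common-language U/(n_a n_b).
    """
    if profile_a.feature_ids != profile_b.feature_ids:
        raise MetricsError("profiles cover different CDS universes")
    if len(profile_a.feature_ids) < 3:
        raise MetricsError("need >= 3 CDSs for consistency statistics")
    x, y = _log_tpm(profile_a), _log_tpm(profile_b)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise MetricsError("constant expression vector: correlations undefined")
    r = float(stats.pearsonr(x, y).statistic)
    rs = float(stats.spearmanr(x, y).statistic)
    qq = list(zip(np.sort(x).tolist(), np.sort(y).tolist()))
    u = float(stats.mannwhitneyu(x, y, alternative="two-sided").statistic)
    n_ab = len(x) * len(y)
    return ConsistencyReport(
        pearson_r=r,
        spearman_rs=rs,
        r_squared=r * r,
        qq_pairs=qq,
        mwu_effect_size=2.0 * u / n_ab - 1.0,
        mwu_common_language=u / n_ab,
    )


def mds_ordination(profiles: list[ExpressionProfile]) -> OrdinationResult:
    """Classical (Torgerson) MDS of samples on d = sqrt(2 - 2 r_s) distances.

    r_s is the pairwise Spearman correlation of log10(TPM + 0.1) profiles.
    Coordinates are the top-2 scaled eigenvectors of the double-centered
    squared-distance matrix, sign-canonicalized so the first sample has
    non-negative coordinates; when the second eigenvalue is not positive a
    1-D embedding is returned.
    """
    n = len(profiles)
    if n < 3:
        raise MetricsError("need >= 3 profiles for ordination")
    logs = np.array([_log_tpm(p) for p in profiles])
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            rs = float(stats.spearmanr(logs[i], logs[j]).statistic)
            d[i, j] = d[j, i] = np.sqrt(max(0.0, 2.0 - 2.0 * rs))
    d2 = d**2
    j_mat = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j_mat @ d2 @ j_mat
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    n_dims = 2 if eigvals[1] > 1e-12 else 1
    coords = eigvecs[:, :n_dims] * np.sqrt(np.maximum(eigvals[:n_dims], 0.0))
    for axis in range(n_dims):
        pivot = next((i for i in range(n) if abs(coords[i, axis]) > 1e-12), 0)
        if coords[pivot, axis] < 0:
            coords[:, axis] *= -1
    return OrdinationResult(
        sample_ids=[p.sample_id for p in profiles],
        distances=d,
        coordinates=coords,
        n_dims=n_dims,
    )


# ---------------------------------------------------------------------------
# per-tile depletion efficiency

def per_tile_depletion_efficiency(
    cov_undepleted,
    cov_depleted,
    norm_undepleted: float,
    norm_depleted: float,
    tiles: list[tuple[int, int]],
    pseudocount: float = COVERAGE_PSEUDO,
) -> list[float]:
    """Per-tile rRNA fold change between undepleted and depleted coverage.

    Per-base coverage gets ``pseudocount`` added, is normalized by each
    sample's non-rRNA mapped total, and the per-base fold change
    (undepleted / depleted) is averaged within each probe tile.  Larger
    values mean stronger local depletion.
    """
    cov_u = np.asarray(cov_undepleted, dtype=float)
    cov_d = np.asarray(cov_depleted, dtype=float)
    if cov_u.shape != cov_d.shape:
        raise MetricsError("coverage vectors differ in length")
    if norm_undepleted <= 0 or norm_depleted <= 0:
        raise MetricsError("normalization totals must be positive")
    c_u = (cov_u + pseudocount) / norm_undepleted
    c_d = (cov_d + pseudocount) / norm_depleted
    fold = c_u / c_d
    out = []
    for start, end in tiles:
        if not (0 <= start < end <= len(fold)):
            raise MetricsError(f"tile {start}:{end} outside coverage of length {len(fold)}")
        out.append(float(fold[start:end].mean()))
    return out
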