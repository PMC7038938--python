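# Methods

This note documents the models, conventions and numerical choices behind
`ribodeplete`, and what the bundled simulator does and does not establish
about real sequencing data.

## Probe design

**Tiling.** For a gene of length *L* and a target probe length *t*
(default 50 nt, the length with a good efficiency/synthesis-cost trade-off
for RNase H depletion probes), the tiler produces *k* = ⌈*L*/*t*⌉ abutting
tiles covering [0, *L*) exactly, each of length ⌊*L*/*k*⌋ or ⌊*L*/*k*⌋ + 1
with the longer tiles placed 5′-first. This guarantees full coverage with no
tile more than one base away from equal length and no tile shorter than
⌊*L*/*k*⌋. Other tools may place boundaries slightly differently; the probe
*count* for given gene lengths is identical for any convention with
*k* = ⌈*L*/*t*⌉, which is why a 16S of 1520 nt plus a 23S of 2780 nt always
yields 31 + 56 = 87 probes at *t* = 50. Probes are named
`{organism}_{gene}_{index}_{start}-{end}` (1-based inclusive) and pooled
equimolar by default.

**Oligo length ceiling.** Probes of provenance `oligo` are capped at 60 nt
(synthesis practicality); amplicon-derived probes are full-length ssDNA and
exempt from the cap, so the two provenances share the `Probe` container but
not the length invariant.

**In-silico PCR.** Primers are matched with IUPAC degeneracy semantics; up
to 2 internal mismatches are tolerated by default but the 3′-terminal base
must match exactly (polymerase extension requires a paired 3′ end). The
product spans the leftmost forward site through the nearest downstream
reverse site. PCR stringency in the wet protocol is not knowable from
sequence alone, so these parameters are configurable; the defaults model a
permissive universal-primer amplification. Lambda digestion then removes the
5′-phosphorylated (fwd-synthesized, sense) strand, leaving the antisense
strand — by construction identical to the reverse complement of the
inter-primer region, which is verified against a brute-force enumeration
oracle in the tests.

**Multiple rRNA operons.** The designer expects one representative 16S and
one 23S per organism; operon copies within a genome are near-identical, so a
single representative suffices and keeps the pool size minimal.

## Cross-species applicability

Sequence similarity between the probe-source rRNA and a candidate target is
measured on a global pairwise alignment. We use Needleman–Wunsch with affine
gaps (match +1, mismatch −1, gap open −4, gap extend −1, via Biopython's
`PairwiseAligner`) rather than a progressive multiple aligner: at the
divergences that matter for the decision (< 25%), the mismatch fraction of a
near-identity global alignment is insensitive to aligner choice, and a
deterministic pairwise DP keeps the metric reproducible. The mismatch
percent counts every substitution column and every gap column, so a gap run
of length *g* contributes *g* mismatches.

Per-probe mismatch percents walk the alignment columns: a column carrying a
source base belongs to the tile containing that base; a gap-in-source column
is assigned to the tile of the preceding source base (the 5′ tile), which
makes the tile blocks a deterministic partition of the alignment.

Decision thresholds: a library is predicted applicable when the mean of the
16S and 23S overall mismatch percents is below 10%; probes below 25% tile
mismatches are counted as locally effective. Both thresholds are empirical
operating points, exposed as configuration.

## Off-target screening

The published criterion — any transcript a probe maps to with at most eight
mismatches is a potential off-target — is implemented as an exhaustive
banded semi-global alignment (edlib) of the probe, in both orientations,
against every non-cognate transcript; mismatches are substitutions plus gap
columns, i.e. edit distance. A k-mer seed index (default k = 12) is provided
as a prefilter, but it is applied only when the pigeonhole bound
(probe length ≥ k·(max_mismatches + 1)) guarantees that every qualifying hit
shares an exact k-mer; for 50 nt probes at 8 mismatches that bound fails
(a substitution every 6 bases destroys all 12-mers), so the default path is
the full scan, which is exhaustive within the threshold by construction.
Hits are annotated by orientation: only probes antisense to a transcript
("sense" hits) can form the RNA:DNA duplex RNase H cleaves; same-orientation
matches are reported with a flag.

## The depletion simulator

The simulator exists so that every metric can be validated end-to-end with
known truth, without any sequencing data.

* **Toy organisms**: a single contig with one 16S-like gene (1400–1600 nt),
  one 23S-like gene (2800–3000 nt) and *n* random CDSs (default lengths
  300–1500 nt), fully deterministic under a seed.
* **Pool composition**: fragments are rRNA with probability
  `rrna_fraction` (default 0.94, matching undepleted bacterial total RNA),
  split 16S:23S by gene-length share (~1:2, consistent with uniform
  fragmentation of equimolar transcripts); mRNA fragments come from CDSs
  weighted by length. Fragment lengths are truncated-normal, 60 ± 15 nt with
  a 25 nt floor — a generic fragmentation profile, since real protocols do
  not publish their fragment-length distribution.
* **Depletion model**: a step function. A fragment overlapping at least
  `min_overlap` (20) nt of probe-covered sequence whose tile mismatch is
  under `local_threshold` (25%) is removed with probability `p_max`
  (default 0.98); everything else is removed with `p_background` (0).
  Abutting effective tiles are merged before the overlap test: the pool
  tiles the rRNA seamlessly, so RNase H sees a contiguous duplex across tile
  boundaries and a boundary-straddling fragment is as targetable as an
  interior one. The step form is a declared approximation — the real
  mismatch-to-efficiency relationship is a noisy dose-response, and only its
  two operating thresholds are modeled.
* **Analytic anchor**: with pool rRNA fraction *p* and retention
  *q* = 1 − p_max under full cognate coverage, the post-depletion rRNA
  fraction is *pq*/(*pq* + 1 − *p*) and the fold enrichment
  (1 − post)/(1 − *p*). At *p* = 0.94, *q* = 0.023 this gives 26.5% and
  12.25×, the regime the defaults target; the acceptance pipeline checks the
  simulated values against these closed forms within three binomial standard
  errors at 100,000 fragments (a size chosen to make the binomial error
  small while keeping the full pipeline run in seconds).

**What the simulator does not model**: sequencing errors, PCR duplication,
coverage biases along transcripts, partial RNase H cleavage of imperfect
duplexes, adapter chemistry, or multi-mapping reads. Passing tests therefore
demonstrate that the metrics and the depletion bookkeeping are correct, not
that any particular wet-lab depletion will hit these numbers.

## Metrics conventions

* Read-level metrics include multi-mapped reads in "total mapped"; CDS
  counting excludes them, and a read overlapping two CDSs counts for
  neither (featureCounts-style ambiguity handling). Classification mirrors
  the two-pass mapping order: rRNA references first, remainder to the
  genome.
* TPM: rateᵢ = countᵢ/lengthᵢ, rescaled to sum to 10⁶; all-zero counts give
  all-zero TPM rather than NaN.
* Consistency statistics operate on log₁₀(TPM + 0.1); the 0.1 pseudocount
  keeps zero-TPM CDSs finite and compresses their influence. *R*² is the
  square of Pearson *r* on that scale (not a regression-through-origin
  *R*²). For the Mann-Whitney effect size we report the rank-biserial form
  2*U*/(n₁n₂) − 1 and also the common-language form *U*/(n₁n₂), since
  different references prescribe different variants.
* Per-tile depletion efficiency adds a 0.5 pseudocount to raw per-base
  coverage before normalizing by each sample's non-rRNA mapped total, so
  zero-coverage bases give finite fold changes; the reported fold is
  undepleted/depleted (larger = more depleted).
* Ordination is classical (Torgerson) MDS — double-centering of squared
  distances and the top-2 eigenvectors — on d = √(2 − 2 *r*ₛ), with axis
  signs canonicalized (first non-zero coordinate per axis ≥ 0). Non-metric
  MDS is out of scope. When the second eigenvalue is non-positive the
  embedding degrades to 1-D with a warning rather than fabricating an axis.

## Cost model

Oligo probe cost per reaction is the up-front synthesis price amortized over
the yield (defaults $450 / 12,000 reactions = $0.0375 ≈ $0.04); totals add
shared reagents ($12.90). The break-even count is the smallest *n* with
upfront + *n*·oligo ≤ *n*·amplicon (defaults give *n* = 92, ~90 to the
nearest ten); a variant ignoring the amortized oligo cost
(upfront/amplicon = 91) is also exposed because either computation rounds to
~90. The hybridization sheet scales probe mass linearly with RNA input at a
default 5:1 probe-to-RNA mass ratio (2500 ng probe per 500 ng RNA).

## Known limitations

* The aligner is pairwise-global only; libraries evaluated against targets
  with large structural differences (insertions of whole helices) will show
  inflated gap-column mismatch counts.
* The off-target screen reports the best locus per (probe, transcript,
  orientation); multiple distinct loci on one transcript are collapsed to
  the best one, which is sufficient for the transcript-level criterion.
* The depletion simulator's step model cannot reproduce intermediate
  per-tile efficiencies; it is designed for threshold behaviour and
  closed-form recovery, not dose-response fitting.
* SAM input is text-mode only and single-end; paired-end bookkeeping
  (mate flags, proper pairs) is not interpreted.
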