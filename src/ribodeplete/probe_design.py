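"""Antisense ssDNA probe library design for bacterial 16S/23S rRNA depletion.

Two routes produce probes that RNase H can use to direct rRNA cleavage:

* **oligo** — the rRNA sense sequence is split into ~50 nt abutting tiles and
  each tile's reverse complement becomes one synthesizable oligo, so the pool
  covers the entire rRNA;
* **amplicon** — an in-silico PCR with universal primers (forward primer
  5'-phosphorylated) followed by lambda-exonuclease strand selection yields a
  single full-length antisense ssDNA probe per gene.

Tiling convention: k = ceil(L / target_len) tiles of as-equal-as-possible
length (floor(L/k) or floor(L/k)+1), longer tiles placed 5'-first, abutting
with no gaps or overlaps.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import pandas as pd

from .core_io import IUPAC_BASES, SeqRecord, reverse_complement, write_fasta

__all__ = [
    "Probe",
    "ProbeLibrary",
    "PrimerPair",
    "Amplicon",
    "DesignError",
    "AmplificationError",
    "tile_sequence",
    "design_oligo_library",
    "in_silico_pcr",
    "lambda_digest",
    "design_amplicon_library",
    "write_probe_sheet",
    "read_probe_sheet",
    "write_probe_fasta",
]

MAX_OLIGO_LEN = 60  # synthesis-practical ceiling for one oligo tile


class DesignError(ValueError):
    """Inputs cannot yield a valid probe design."""


class AmplificationError(RuntimeError):
    """In-silico PCR found no valid primer placement."""

    def __init__(self, message: str, failed_primer: str | None = None):
        super().__init__(message)
        self.failed_primer = failed_primer


@dataclass(frozen=True)
class Probe:
    """One antisense ssDNA probe with its source tile on the rRNA sense strand.

    ``tile_start``/``tile_end`` are 0-based half-open on the source rRNA;
    ``seq`` is the reverse complement of that tile.
    """

    probe_id: str
    organism: str
    source_gene: str  # "16S" or "23S"
    tile_start: int
    tile_end: int
    seq: str

    def __post_init__(self) -> None:
        if self.tile_end - self.tile_start != len(self.seq):
            raise DesignError(f"probe {self.probe_id}: tile span != sequence length")
        if len(self.seq) < 1:
            raise DesignError(f"probe {self.probe_id}: empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ProbeLibrary:
    """Ordered probe set for one organism's 16S+23S, with molar pool fractions."""

    organism: str
    probes: list[Probe]
    provenance: str = "oligo"  # "oligo" | "amplicon"
    pool_fractions: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pool_fractions:
            n = len(self.probes)
            self.pool_fractions = [1.0 / n] * n if n else []
        if self.probes:
            total = sum(self.pool_fractions)
            if abs(total - 1.0) > 1e-9:
                raise DesignError(f"pool fractions sum to {total}, expected 1")
        if self.provenance == "oligo":
            for p in self.probes:
                if len(p) > MAX_OLIGO_LEN:
                    raise DesignError(
                        f"oligo probe {p.probe_id} length {len(p)} exceeds {MAX_OLIGO_LEN}"
                    )

    def __len__(self) -> int:
        return len(self.probes)

    def gene_probes(self, gene: str) -> list[Probe]:
        return [p for p in self.probes if p.source_gene == gene]


@dataclass(frozen=True)
class PrimerPair:
    """A universal primer pair, both given 5'->3'; the forward primer is
    5'-phosphorylated so lambda exonuclease later removes the sense strand."""

    name: str
    fwd: str
    rev: str
    max_primer_mismatches: int = 2

    def __post_init__(self) -> None:
        if len(self.fwd) < 10 or len(self.rev) < 10:
            raise DesignError(f"primer pair {self.name}: both primers must be >= 10 nt")
        if self.max_primer_mismatches < 0:
            raise DesignError("max_primer_mismatches must be >= 0")


@dataclass(frozen=True)
class Amplicon:
    """A double-stranded PCR product; ``sense`` is the fwd-synthesized strand
    (tagged phosphorylated), 0-based half-open coordinates on the template."""

    name: str
    sense: str
    template_start: int
    template_end: int
    phosphorylated_strand: str = "sense"


def tile_sequence(rrna: SeqRecord | str, target_len: int) -> list[tuple[int, int]]:
    """Split ``rrna`` into k = ceil(L/target_len) abutting tiles covering [0, L).

    Tile lengths are floor(L/k) or floor(L/k)+1, with the longer tiles first
    (5'-most).  Raises :class:`DesignError` when the sequence is shorter than
    ``target_len`` or ``target_len`` < 20.
    """
    seq = rrna.seq if isinstance(rrna, SeqRecord) else rrna
    L = len(seq)
    if target_len < 20:
        raise DesignError(f"target_len {target_len} < 20")
    if L < target_len:
        raise DesignError(f"sequence length {L} shorter than target_len {target_len}")
    k = math.ceil(L / target_len)
    base, extra = divmod(L, k)
    tiles = []
    pos = 0
    for i in range(k):
        length = base + 1 if i < extra else base
        tiles.append((pos, pos + length))
        pos += length
    return tiles


_GENE_TAGS = ("16S", "23S")


def _gene_of(rec: SeqRecord) -> str | None:
    text = f"{rec.id} {rec.description}".upper()
    for tag in _GENE_TAGS:
        if tag in text:
            return tag
    return None


def design_oligo_library(
    rrnas: list[SeqRecord], target_len: int = 50, organism: str = "organism"
) -> ProbeLibrary:
    """Design an equimolar oligo probe library tiling one 16S and one 23S.

    ``rrnas`` must contain exactly one record tagged 16S and one tagged 23S
    (tag looked up in id/description).  Probes are ordered 16S then 23S,
    5'->3' along each gene, each the reverse complement of its tile, and named
    ``{organism}_{gene}_{index}_{start}-{end}`` (1-based inclusive).
    """
    by_gene: dict[str, SeqRecord] = {}
    for rec in rrnas:
        gene = _gene_of(rec)
        if gene is None:
            raise DesignError(f"record {rec.id!r} has no 16S/23S tag in id or description")
        if gene in by_gene:
            raise DesignError(f"more than one {gene} record supplied")
        by_gene[gene] = rec
    missing = [g for g in _GENE_TAGS if g not in by_gene]
    if missing:
        raise DesignError(f"missing rRNA gene(s): {missing}")

    probes: list[Probe] = []
    for gene in _GENE_TAGS:
        rec = by_gene[gene]
        for idx, (start, end) in enumerate(tile_sequence(rec, target_len), 1):
            probes.append(
                Probe(
                    probe_id=f"{organism}_{gene}_{idx}_{start + 1}-{end}",
                    organism=organism,
                    source_gene=gene,
                    tile_start=start,
                    tile_end=end,
                    seq=reverse_complement(rec.seq[start:end]),
                )
            )
    return ProbeLibrary(organism=organism, probes=probes, provenance="oligo")


def _iupac_match(primer_char: str, template_char: str) -> bool:
    return template_char in IUPAC_BASES.get(primer_char, "")


def _primer_sites(template: str, primer: str, max_mm: int, three_prime_index: int) -> list[int]:
    """All template offsets where ``primer`` (plus-strand orientation) matches
    with <= max_mm mismatches and an exact match at ``three_prime_index``
    (offset of the primer's 3'-terminal base within the given orientation)."""
    m, n = len(primer), len(template)
    sites = []
    for start in range(n - m + 1):
        window = template[start : start + m]
        if not _iupac_match(primer[three_prime_index], window[three_prime_index]):
            continue
        mm = sum(1 for pc, tc in zip(primer, window) if not _iupac_match(pc, tc))
        if mm <= max_mm:
            sites.append(start)
    return sites


def in_silico_pcr(template: SeqRecord, primers: PrimerPair) -> Amplicon:
    """Predict the PCR product of a primer pair on ``template``.

    The forward primer anneals to the template as given; the reverse primer
    anneals to the plus strand as its reverse complement.  IUPAC degeneracy in
    primers matches any compatible base; up to ``max_primer_mismatches``
    internal mismatches are allowed but the 3'-terminal base of each primer
    must match exactly.  The leftmost forward site and its nearest downstream
    reverse site define the amplicon.  The fwd-synthesized (sense) strand is
    tagged 5'-phosphorylated.
    """
    seq = template.seq
    fwd_sites = _primer_sites(seq, primers.fwd, primers.max_primer_mismatches,
                              three_prime_index=len(primers.fwd) - 1)
    if not fwd_sites:
        raise AmplificationError(
            f"{primers.name}: no forward-primer site on {template.id}", "fwd")
    fwd_start = fwd_sites[0]
    # The reverse primer's plus-strand footprint is revcomp(rev); the primer's
    # 3' end maps to the leftmost base of that footprint.
    rev_motif = reverse_complement(primers.rev)
    rev_sites = _primer_sites(seq, rev_motif, primers.max_primer_mismatches,
                              three_prime_index=0)
    min_rev_start = fwd_start + len(primers.fwd)
    downstream = [s for s in rev_sites if s >= min_rev_start]
    if not downstream:
        which = "rev" if rev_sites else "rev"
        raise AmplificationError(
            f"{primers.name}: no reverse-primer site downstream of forward site "
            f"on {template.id}", which)
    rev_start = downstream[0]
    end = rev_start + len(rev_motif)
    return Amplicon(
        name=f"{template.id}_{primers.name}_amplicon",
        sense=seq[fwd_start:end],
        template_start=fwd_start,
        template_end=end,
    )


def lambda_digest(amplicon: Amplicon) -> SeqRecord:
    """Digest the 5'-phosphorylated strand, returning the surviving ssDNA.

    With a phosphorylated sense strand the survivor is the antisense strand —
    the reverse complement of the rRNA segment, i.e. the probe.
    """
    if amplicon.phosphorylated_strand not in {"sense", "antisense"}:
        raise DesignError(
            f"amplicon {amplicon.name}: phosphorylated strand must be exactly one "
            f"of sense/antisense, got {amplicon.phosphorylated_strand!r}")
    if amplicon.phosphorylated_strand == "sense":
        probe_seq = reverse_complement(amplicon.sense)
    else:
        probe_seq = amplicon.sense
    return SeqRecord(id=f"{amplicon.name}_ssDNA", seq=probe_seq,
                     description="lambda-exonuclease selected strand")


def design_amplicon_library(
    rrnas: list[SeqRecord],
    primer_pairs: dict[str, PrimerPair],
    organism: str = "organism",
) -> ProbeLibrary:
    """Amplify 16S and 23S with their primer pairs, digest, and pool equimolar.

    Each gene contributes one full-length antisense probe; provenance is
    ``amplicon`` (the oligo length ceiling does not apply).
    """
    probes: list[Probe] = []
    for gene in _GENE_TAGS:
        recs = [r for r in rrnas if _gene_of(r) == gene]
        if len(recs) != 1:
            raise DesignError(f"need exactly one {gene} record, got {len(recs)}")
        rec = recs[0]
        if gene not in primer_pairs:
            raise DesignError(f"no primer pair configured for {gene}")
        amp = in_silico_pcr(rec, primer_pairs[gene])
        ss = lambda_digest(amp)
        probes.append(
            Probe(
                probe_id=f"{organism}_{gene}_amplicon_{amp.template_start + 1}-{amp.template_end}",
                organism=organism,
                source_gene=gene,
                tile_start=amp.template_start,
                tile_end=amp.template_end,
                seq=ss.seq,
            )
        )
    return ProbeLibrary(organism=organism, probes=probes, provenance="amplicon")


_SHEET_COLUMNS = ["probe_id", "organism", "gene", "start", "end", "length", "sequence"]


def write_probe_sheet(library: ProbeLibrary, path: str | os.PathLike) -> None:
    """Write the probe sheet TSV (1-based inclusive coordinates)."""
    rows = [
        {
            "probe_id": p.probe_id,
            "organism": p.organism,
            "gene": p.source_gene,
            "start": p.tile_start + 1,
            "end": p.tile_end,
            "length": len(p),
            "sequence": p.seq,
        }
        for p in library.probes
    ]
    pd.DataFrame(rows, columns=_SHEET_COLUMNS).to_csv(path, sep="\t", index=False)


def read_probe_sheet(path: str | os.PathLike, provenance: str = "oligo") -> ProbeLibrary:
    df = pd.read_csv(path, sep="\t", comment="#",
                     dtype={"probe_id": str, "organism": str, "gene": str})
    missing = set(_SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise DesignError(f"{path}: probe sheet missing columns {sorted(missing)}")
    probes = [
        Probe(
            probe_id=row.probe_id,
            organism=row.organism,
            source_gene=row.gene,
            tile_start=int(row.start) - 1,
            tile_end=int(row.end),
            seq=row.sequence,
        )
        for row in df.itertuples()
    ]
    organism = probes[0].organism if probes else "organism"
    return ProbeLibrary(organism=organism, probes=probes, provenance=provenance)


def write_probe_fasta(library: ProbeLibrary, path: str | os.PathLike) -> None:
    write_fasta(
        [SeqRecord(id=p.probe_id, seq=p.seq) for p in library.probes], path
    )
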