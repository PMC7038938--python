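"""Sequence, annotation and alignment I/O shared by the whole toolkit.

File interfaces use the native conventions of each format (1-based inclusive
coordinates for FASTA/GFF3/SAM); everything held in memory is 0-based
half-open.  RNA input (U) is canonicalized to T at parse time so that DNA
probes and RNA targets compare directly; the original alphabet is remembered
per record and restored on write.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

import pysam
from Bio import SeqIO

__all__ = [
    "SeqRecord",
    "CdsFeature",
    "ReadAlignmentRecord",
    "FormatError",
    "AlphabetError",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "read_gff3",
    "write_gff3",
    "read_sam",
]


class FormatError(ValueError):
    """A file violates its format contract (malformed row, bad coordinates...)."""


class AlphabetError(ValueError):
    """A sequence contains a character outside the IUPAC nucleotide alphabet."""


# IUPAC nucleotide complement table (T canonical; U accepted on input only).
_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

IUPAC_CODES = frozenset(_COMPLEMENT) | {"U"}

# Which bases each degeneracy code stands for, used by primer matching.
IUPAC_BASES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class SeqRecord:
    """One nucleotide sequence with its header.

    ``seq`` is always uppercase with U canonicalized to T; ``is_rna`` records
    whether the source spelled the sequence with U so writers can restore it.
    """

    id: str
    seq: str
    description: str = ""
    is_rna: bool = False

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise FormatError(f"record id {self.id!r} must be a non-empty token")
        if len(self.seq) < 1:
            raise FormatError(f"record {self.id!r} has an empty sequence")
        bad = set(self.seq) - IUPAC_CODES
        if bad:
            raise AlphabetError(
                f"record {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class CdsFeature:
    """A CDS interval on a reference sequence, 1-based inclusive as in GFF3."""

    seq_id: str
    start: int
    end: int
    strand: str
    feature_id: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise FormatError(
                f"CDS {self.feature_id!r}: invalid span {self.start}..{self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise FormatError(f"CDS {self.feature_id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ReadAlignmentRecord:
    """Minimal view of one primary alignment (or unmapped read)."""

    read_id: str
    ref_id: str | None  # None when unmapped
    pos: int = 0  # 1-based leftmost reference position when mapped
    aln_len: int = 0  # reference bases consumed (CIGAR M/=/X/D)
    multi_mapped: bool = False

    @property
    def mapped(self) -> bool:
        return self.ref_id is not None


def _normalize_seq(raw: str, where: str) -> tuple[str, bool]:
    seq = raw.upper()
    is_rna = "U" in seq
    seq = seq.replace("U", "T")
    bad = set(seq) - set(_COMPLEMENT)
    if bad:
        raise AlphabetError(f"{where}: non-IUPAC characters {sorted(bad)}")
    return seq, is_rna


def read_fasta(path: str | os.PathLike) -> list[SeqRecord]:
    """Read a multi-record FASTA.

    Sequences are uppercased and U is canonicalized to T (the ``is_rna`` flag
    preserves the original alphabet).  Raises :class:`FormatError` for an
    empty sequence or a duplicate id.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        seq, is_rna = _normalize_seq(str(rec.seq), f"{path}:{rec.id}")
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SeqRecord(id=rec.id, seq=seq, description=desc, is_rna=is_rna))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | os.PathLike, width: int = 80) -> None:
    """Write records wrapped at ``width`` columns; restores U for RNA records."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            seq = rec.seq.replace("T", "U") if rec.is_rna else rec.seq
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    """Reverse complement with full IUPAC degeneracy support.

    U on input is treated as T. Raises :class:`AlphabetError` on any other
    character outside the IUPAC nucleotide codes.
    """
    out = []
    for c in reversed(seq.upper().replace("U", "T")):
        try:
            out.append(_COMPLEMENT[c])
        except KeyError:
            raise AlphabetError(f"non-IUPAC character {c!r} in sequence") from None
    return "".join(out)


def read_gff3(path: str | os.PathLike) -> list[CdsFeature]:
    """Read CDS rows from a GFF3 file (Prokka-style), 1-based inclusive.

    Non-CDS rows are ignored.  Raises :class:`FormatError` on end < start or
    a duplicate feature ID.
    """
    feats: list[CdsFeature] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(parts)}")
            seq_id, _src, ftype, start_s, end_s, _score, strand, _frame, attrs = parts
            if ftype != "CDS":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if end < start:
                raise FormatError(f"{path}:{lineno}: end {end} < start {start}")
            fid = None
            for kv in attrs.split(";"):
                if kv.startswith("ID="):
                    fid = kv[3:]
                    break
            if fid is None:
                fid = f"cds_{lineno}"
            if fid in seen:
                raise FormatError(f"{path}:{lineno}: duplicate feature ID {fid!r}")
            seen.add(fid)
            feats.append(CdsFeature(seq_id=seq_id, start=start, end=end,
                                    strand=strand, feature_id=fid))
    return feats


def write_gff3(features: Iterable[CdsFeature], path: str | os.PathLike,
               source: str = "ribodeplete") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                f"{f.seq_id}\t{source}\tCDS\t{f.start}\t{f.end}\t.\t{f.strand}\t0\t"
                f"ID={f.feature_id}\n"
            )


def read_sam(path: str | os.PathLike) -> list[ReadAlignmentRecord]:
    """Read a text SAM file into one record per primary alignment line.

    Unmapped status comes from FLAG 0x4; ``multi_mapped`` is set when a
    secondary alignment (FLAG 0x100) exists for the read or an NH tag exceeds
    1.  References must be declared in @SQ headers (consistency error
    otherwise).  CIGAR M/=/X/D advance the reference.
    """
    primaries: dict[str, ReadAlignmentRecord] = {}
    order: list[str] = []
    secondary_reads: set[str] = set()
    try:
        with pysam.AlignmentFile(os.fspath(path), "r", check_sq=True) as sam:
            for aln in sam:
                name = aln.query_name
                if aln.is_secondary or aln.is_supplementary:
                    secondary_reads.add(name)
                    continue
                if name in primaries:
                    raise FormatError(f"{path}: multiple primary lines for read {name!r}")
                if aln.is_unmapped and (aln.reference_start >= 0 or aln.cigarstring):
                    # htslib downgrades an RNAME missing from @SQ to unmapped
                    # but keeps POS/CIGAR; a genuinely unmapped line has neither
                    raise FormatError(
                        f"{path}: read {name!r} references a name absent from @SQ")
                if aln.is_unmapped:
                    rec = ReadAlignmentRecord(read_id=name, ref_id=None)
                else:
                    nh = aln.get_tag("NH") if aln.has_tag("NH") else 1
                    rec = ReadAlignmentRecord(
                        read_id=name,
                        ref_id=aln.reference_name,
                        pos=aln.reference_start + 1,
                        aln_len=aln.reference_length or 0,
                        multi_mapped=nh > 1,
                    )
                primaries[name] = rec
                order.append(name)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    out = []
    for name in order:
        rec = primaries[name]
        if name in secondary_reads and rec.mapped and not rec.multi_mapped:
            rec = ReadAlignmentRecord(rec.read_id, rec.ref_id, rec.pos, rec.aln_len, True)
        out.append(rec)
    return out
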