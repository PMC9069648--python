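"""Coordinate conventions, sequence access, and flat-file readers/writers.

All coordinates are 0-based, half-open (BED convention). Promoters are
derived from transcription start sites as the window covering 1000 bp
upstream to 100 bp downstream of the TSS, mirrored on the minus strand so
that "upstream" is biological upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

logger = logging.getLogger(__name__)

PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 100

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic region on one chromosome, 0-based half-open.

    Attributes
    ----------
    chrom : str
        Chromosome name; non-empty.
    start, end : int
        0-based inclusive start, exclusive end; ``0 <= start < end``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    name : str
        Optional feature name (BED column 4); empty string when absent.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one base pair."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence over the alphabet {A, C, G, T, N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"empty sequence for record {self.id!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TSSRecord:
    """A transcription start site: gene, chromosome, 0-based position, strand."""

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"negative TSS for {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"TSS strand must be + or -, got {self.strand!r}")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str, context: str = "") -> str:
    """Uppercase and map characters outside {A,C,G,T,N} to N."""
    seq = seq.upper()
    if not _VALID_BASES.issuperset(seq):
        n_bad = sum(c not in _VALID_BASES for c in seq)
        logger.warning(
            "%s: %d non-ACGTN characters mapped to N", context or "sequence", n_bad
        )
        seq = "".join(c if c in _VALID_BASES else "N" for c in seq)
    return seq


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into normalized sequence records.

    Sequences are uppercased; ambiguity characters other than N become N.
    Duplicate record IDs are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA record ID: {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, normalize_sequence(str(rec.seq), rec.id)))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def make_promoter(tss_record: TSSRecord, ignore_strand: bool = False) -> GenomicInterval:
    """Promoter window around a TSS: 1000 bp upstream, 100 bp downstream.

    On the minus strand the window is mirrored so that the 1000-bp side is
    biological upstream. ``ignore_strand=True`` applies the plus-strand
    window regardless of strand. The left edge is clipped at 0.
    """
    tss = tss_record.tss
    if tss_record.strand == "+" or ignore_strand:
        start, end = tss - PROMOTER_UPSTREAM, tss + PROMOTER_DOWNSTREAM
    else:
        start, end = tss - PROMOTER_DOWNSTREAM, tss + PROMOTER_UPSTREAM
    return GenomicInterval(
        tss_record.chrom, max(0, start), end, tss_record.strand, tss_record.gene_id
    )


def extract_sequence(
    genome: dict[str, str] | list[SequenceRecord], interval: GenomicInterval
) -> SequenceRecord:
    """Extract the sequence of an interval; minus-strand intervals are
    reverse-complemented. The record ID encodes ``chrom:start-end(strand)``."""
    if not isinstance(genome, dict):
        genome = {rec.id: rec.seq for rec in genome}
    if interval.chrom not in genome:
        raise KeyError(f"unknown chromosome: {interval.chrom!r}")
    chrom_seq = genome[interval.chrom]
    sub = chrom_seq[interval.start : min(interval.end, len(chrom_seq))]
    if interval.strand == "-":
        sub = reverse_complement(sub)
    return SequenceRecord(
        f"{interval.chrom}:{interval.start}-{interval.end}({interval.strand})", sub
    )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ intervals; strand defaults to '.' when absent."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            intervals.append(GenomicInterval(chrom, start, end, strand, name))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )


def read_tss_table(path: str | Path) -> list[TSSRecord]:
    """Read a TSS table: BED6 where start is the TSS position and end = start + 1."""
    records = []
    for iv in read_bed(path):
        if iv.strand not in ("+", "-"):
            raise ValueError(f"TSS record {iv.name!r} lacks a strand")
        records.append(TSSRecord(iv.name or f"{iv.chrom}:{iv.start}", iv.chrom, iv.start, iv.strand))
    return records
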