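"""Enhancer-promoter pair construction from a binned contact matrix.

Candidate pairs of genomic bins are called interacting when the normalized
contact value strictly exceeds a cutoff (default 30; a deeper-sequenced
library warrants 150), and non-interacting when the value is strictly below
5 (absent entries count as zero). Active enhancer and promoter annotations
are then overlapped with the selected bin pairs, keeping pairs whose
enhancer-to-TSS distance lies within [2.5 kb, 2 Mb].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .genome_io import GenomicInterval

logger = logging.getLogger(__name__)

INTERACTION_CUTOFF = 30.0
INTERACTION_CUTOFF_DEEP = 150.0
NONINTERACTION_CUTOFF = 5.0
MIN_DISTANCE = 2_500
MAX_DISTANCE = 2_000_000

#: bin pair key: (chrom, bin_a_start, bin_b_start) with bin_a <= bin_b
BinPair = tuple[str, int, int]


@dataclass(frozen=True)
class ContactRecord:
    """One intra-chromosomal entry of a normalized contact matrix.

    ``bin_a`` and ``bin_b`` are bin start coordinates (bp), canonicalized so
    that ``bin_a <= bin_b``.
    """

    chrom: str
    bin_a: int
    bin_b: int
    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"negative contact value {self.value}")


@dataclass(frozen=True)
class EPPair:
    """An enhancer-promoter candidate pair with its contact evidence.

    ``distance`` is the absolute distance from the enhancer midpoint to the
    TSS. ``label`` is ``positive`` (high contact) or ``negative3``
    (low contact).
    """

    enhancer: GenomicInterval
    promoter: GenomicInterval
    gene_id: str
    contact_value: float
    distance: int
    label: str

    @property
    def ep_id(self) -> str:
        return (
            f"{self.enhancer.chrom}:{self.enhancer.start}-{self.enhancer.end}"
            f"|{self.promoter.chrom}:{self.promoter.start}-{self.promoter.end}"
            f"|{self.gene_id}"
        )


def load_contacts(path: str | Path, resolution: int) -> list[ContactRecord]:
    """Load a sparse contact dump (TSV: chrom, bin_a, bin_b, value).

    Bin starts must be multiples of ``resolution``; mirror duplicates are
    canonicalized to ``bin_a <= bin_b`` and repeated entries summed with a
    warning.
    """
    merged: dict[BinPair, float] = {}
    dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            chrom, a, b, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
            if a % resolution or b % resolution:
                raise ValueError(
                    f"{path}:{lineno}: bin start not a multiple of resolution {resolution}"
                )
            key = (chrom, min(a, b), max(a, b))
            if key in merged:
                dup += 1
            merged[key] = merged.get(key, 0.0) + value
    if dup:
        logger.warning("load_contacts: summed %d duplicate bin-pair entries", dup)
    return [ContactRecord(c, a, b, v) for (c, a, b), v in sorted(merged.items())]


def call_interacting_bins(
    contacts: Iterable[ContactRecord], cutoff: float = INTERACTION_CUTOFF
) -> set[BinPair]:
    """Bin pairs whose normalized contact value is strictly greater than ``cutoff``."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    return {(r.chrom, r.bin_a, r.bin_b) for r in contacts if r.value > cutoff}


def call_noninteracting_bins(
    contacts: Iterable[ContactRecord],
    all_bins: Iterable[BinPair],
    cutoff: float = NONINTERACTION_CUTOFF,
) -> set[BinPair]:
    """Bin pairs with contact strictly below ``cutoff`` among the candidates.

    ``all_bins`` enumerates the candidate bin pairs under consideration;
    pairs absent from ``contacts`` count as zero.
    """
    values = {(r.chrom, r.bin_a, r.bin_b): r.value for r in contacts}
    out = set()
    for key in all_bins:
        chrom, a, b = key
        key = (chrom, min(a, b), max(a, b))
        if values.get(key, 0.0) < cutoff:
            out.add(key)
    return out


def _overlapping_bins(iv: GenomicInterval, resolution: int) -> range:
    """Start coordinates of all bins intersecting the interval by >= 1 bp."""
    first = (iv.start // resolution) * resolution
    last = ((iv.end - 1) // resolution) * resolution
    return range(first, last + resolution, resolution)


def _tss_position(promoter: GenomicInterval) -> int:
    # promoter windows are 1000 bp upstream / 100 bp downstream of the TSS,
    # mirrored by strand (genome_io.make_promoter); clamp for clipped or
    # non-standard promoter intervals
    pos = promoter.end - 1000 if promoter.strand == "-" else promoter.start + 1000
    return min(max(pos, promoter.start), promoter.end - 1)


def pair_distance(
    enhancer: GenomicInterval, promoter: GenomicInterval, mode: str = "midpoint_tss"
) -> int:
    """Enhancer-promoter distance: enhancer midpoint to TSS (default), or
    edge-to-edge gap (``mode='edge'``, 0 when touching/overlapping)."""
    if mode == "edge":
        if enhancer.end <= promoter.start:
            return promoter.start - enhancer.end
        if promoter.end <= enhancer.start:
            return enhancer.start - promoter.end
        return 0
    return abs(enhancer.midpoint - _tss_position(promoter))


def build_ep_pairs(
    bin_pairs: set[BinPair],
    active_enhancers: Sequence[GenomicInterval],
    active_promoters: Sequence[GenomicInterval],
    resolution: int,
    label: str,
    contact_values: dict[BinPair, float] | None = None,
    distance_mode: str = "midpoint_tss",
    min_distance: int = MIN_DISTANCE,
    max_distance: int = MAX_DISTANCE,
) -> list[EPPair]:
    """Overlap selected bin pairs with active annotations to form EP pairs.

    A pair is emitted when the enhancer overlaps one bin and the promoter
    the other bin of a selected bin pair (>= 1 bp each side, either
    assignment of bins), and the distance is within the window. Pairs are
    deduplicated on (enhancer, promoter); the contact value is the maximum
    over supporting bin pairs.
    """
    if contact_values is None:
        contact_values = {}
    # index annotations by the bins they touch
    enh_by_bin: dict[tuple[str, int], list[GenomicInterval]] = {}
    prom_by_bin: dict[tuple[str, int], list[GenomicInterval]] = {}
    for iv in active_enhancers:
        for b in _overlapping_bins(iv, resolution):
            enh_by_bin.setdefault((iv.chrom, b), []).append(iv)
    for iv in active_promoters:
        for b in _overlapping_bins(iv, resolution):
            prom_by_bin.setdefault((iv.chrom, b), []).append(iv)

    best: dict[tuple[GenomicInterval, GenomicInterval], EPPair] = {}
    for chrom, bin_a, bin_b in bin_pairs:
        value = contact_values.get((chrom, bin_a, bin_b), 0.0)
        for e_bin, p_bin in ((bin_a, bin_b), (bin_b, bin_a)):
            for enh in enh_by_bin.get((chrom, e_bin), ()):
                for prom in prom_by_bin.get((chrom, p_bin), ()):
                    dist = pair_distance(enh, prom, distance_mode)
                    if not (min_distance <= dist <= max_distance):
                        continue
                    key = (enh, prom)
                    prev = best.get(key)
                    if prev is None or value > prev.contact_value:
                        best[key] = EPPair(
                            enh, prom, prom.name or "", value, dist, label
                        )
    pairs = sorted(
        best.values(),
        key=lambda p: (p.enhancer.chrom, p.enhancer.start, p.promoter.start, p.gene_id),
    )
    logger.info(
        "build_ep_pairs: %d bin pairs -> %d %s EP pairs", len(bin_pairs), len(pairs), label
    )
    return pairs


def write_ep_pairs(pairs: Iterable[EPPair], path: str | Path) -> None:
    """Write EP pairs as a 10-column TSV (header line starts with '#')."""
    with open(path, "w") as fh:
        fh.write(
            "#enh_chrom\tenh_start\tenh_end\tprom_chrom\tprom_start\tprom_end"
            "\tgene_id\tdistance\tcontact_value\tlabel\n"
        )
        for p in pairs:
            fh.write(
                f"{p.enhancer.chrom}\t{p.enhancer.start}\t{p.enhancer.end}"
                f"\t{p.promoter.chrom}\t{p.promoter.start}\t{p.promoter.end}"
                f"\t{p.gene_id}\t{p.distance}\t{p.contact_value:g}\t{p.label}\n"
            )


def read_ep_pairs(path: str | Path) -> list[EPPair]:
    pairs = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            enh = GenomicInterval(f[0], int(f[1]), int(f[2]))
            prom = GenomicInterval(f[3], int(f[4]), int(f[5]), name=f[6])
            pairs.append(EPPair(enh, prom, f[6], float(f[8]), int(f[7]), f[9]))
    return pairs
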