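"""Three classes of negative EP-pair controls.

* Type 1 — permuted sequences: each positive pair's enhancer and promoter
  sequences are independently nucleotide-shuffled, preserving composition.
* Type 2 — random regions: each enhancer is replaced by a random genomic
  region of identical length whose distance to the promoter's TSS is drawn
  from the empirical positive distance distribution, avoiding overlap with
  excluded regions (by default the active annotations themselves).
* Type 3 — low-contact pairs: annotated enhancer/promoter pairs whose bins
  show a normalized contact value strictly below 5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import ep_pairs as ep
from .genome_io import GenomicInterval, SequenceRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SequencedPair:
    """An EP pair together with its extracted sequences."""

    pair: ep.EPPair
    enh_seq: SequenceRecord
    prom_seq: SequenceRecord


@dataclass
class NegativeSet:
    """A labelled collection of negative EP pairs with provenance."""

    kind: str  # type1_permuted | type2_random_region | type3_low_contact
    pairs: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def _shuffle_seq(seq: str, rng: np.random.Generator, dinucleotide: bool = False) -> str:
    if not dinucleotide:
        chars = np.array(list(seq))
        rng.shuffle(chars)
        return "".join(chars)
    # dinucleotide-preserving: random Eulerian walk on the transition graph
    # (Altschul-Erickson style via repeated edge shuffling with end fixed)
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    for a in edges:
        rng.shuffle(edges[a])  # type: ignore[arg-type]
    # walk greedily; restart if stuck before consuming all edges
    for _ in range(100):
        trial = {a: list(v) for a, v in edges.items()}
        out = [seq[0]]
        node = seq[0]
        ok = True
        for _ in range(len(seq) - 1):
            nxt = trial.get(node)
            if not nxt:
                ok = False
                break
            node = nxt.pop(rng.integers(len(nxt)))
            out.append(node)
        if ok:
            return "".join(out)
        for a in edges:
            rng.shuffle(edges[a])  # type: ignore[arg-type]
    logger.warning("dinucleotide shuffle failed to converge; falling back to mononucleotide")
    chars = np.array(list(seq))
    rng.shuffle(chars)
    return "".join(chars)


def make_type1(
    positives: Sequence[SequencedPair], seed: int, dinucleotide: bool = False
) -> NegativeSet:
    """Permuted-sequence negatives, 1:1 with the positives.

    Each sequence is shuffled independently with the seeded generator;
    nucleotide composition is preserved exactly (and dinucleotide
    composition too when ``dinucleotide=True``).
    """
    rng = np.random.default_rng(seed)
    out = []
    for i, sp in enumerate(positives):
        enh = SequenceRecord(f"type1_{i}_enh", _shuffle_seq(sp.enh_seq.seq, rng, dinucleotide))
        prom = SequenceRecord(f"type1_{i}_prom", _shuffle_seq(sp.prom_seq.seq, rng, dinucleotide))
        out.append(SequencedPair(sp.pair, enh, prom))
    return NegativeSet(
        "type1_permuted", out, {"seed": seed, "dinucleotide": dinucleotide}
    )


def make_type2(
    positives: Sequence[SequencedPair],
    genome: dict[str, str],
    excluded_regions: Sequence[GenomicInterval],
    seed: int,
    max_attempts: int = 100,
) -> NegativeSet:
    """Random-region negatives: promoters kept, enhancers replaced.

    The replacement region has exactly the original enhancer's length; its
    distance to the TSS is resampled (with replacement) from the empirical
    positive distance distribution, placed on a random side of the TSS,
    clipped into the valid distance window and chromosome bounds, and
    rejected while it overlaps any excluded region. Pairs that fail
    ``max_attempts`` draws are skipped with a warning; more than 10%
    failures is an error.
    """
    rng = np.random.default_rng(seed)
    distances = np.array([sp.pair.distance for sp in positives])
    excl_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in excluded_regions:
        excl_by_chrom.setdefault(iv.chrom, []).append(iv)

    out = []
    skipped = 0
    for i, sp in enumerate(positives):
        chrom = sp.pair.promoter.chrom
        chrom_len = len(genome[chrom])
        length = len(sp.pair.enhancer)
        tss_pos = ep._tss_position(sp.pair.promoter)
        placed = None
        for _ in range(max_attempts):
            d = int(np.clip(distances[rng.integers(len(distances))], ep.MIN_DISTANCE, ep.MAX_DISTANCE))
            side = 1 if rng.random() < 0.5 else -1
            mid = tss_pos + side * d
            start = mid - length // 2
            if start < 0 or start + length > chrom_len:
                # try the other side before giving up on this draw
                mid = tss_pos - side * d
                start = mid - length // 2
                if start < 0 or start + length > chrom_len:
                    continue
            cand = GenomicInterval(chrom, start, start + length, ".", f"type2_{i}")
            if any(cand.overlaps(x) for x in excl_by_chrom.get(chrom, ())):
                continue
            placed = cand
            break
        if placed is None:
            skipped += 1
            logger.warning("make_type2: no placement for pair %d after %d attempts", i, max_attempts)
            continue
        seq = genome[chrom][placed.start : placed.end]
        dist = ep.pair_distance(placed, sp.pair.promoter)
        new_pair = ep.EPPair(placed, sp.pair.promoter, sp.pair.gene_id, 0.0, dist, "negative2")
        out.append(SequencedPair(new_pair, SequenceRecord(f"type2_{i}_enh", seq), sp.prom_seq))
    if positives and skipped > 0.1 * len(positives):
        raise RuntimeError(
            f"make_type2: {skipped}/{len(positives)} pairs could not be placed; "
            "genome too short or excluded regions too dense"
        )
    return NegativeSet("type2_random_region", out, {"seed": seed, "skipped": skipped})


def make_type3(
    contacts: Sequence[ep.ContactRecord],
    all_bins: Sequence[ep.BinPair],
    active_enhancers: Sequence[GenomicInterval],
    active_promoters: Sequence[GenomicInterval],
    resolution: int,
    cutoff: float = ep.NONINTERACTION_CUTOFF,
) -> NegativeSet:
    """Low-contact negatives: annotated pairs in bins with contact < 5."""
    low = ep.call_noninteracting_bins(contacts, all_bins, cutoff)
    values = {(r.chrom, r.bin_a, r.bin_b): r.value for r in contacts}
    pairs = ep.build_ep_pairs(
        low, active_enhancers, active_promoters, resolution, "negative3", values
    )
    return NegativeSet("type3_low_contact", pairs, {"cutoff": cutoff})
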