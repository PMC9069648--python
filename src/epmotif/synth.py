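"""Synthetic input bundles with planted enhancer-promoter motif-pair signal.

The generator emulates every input the pipeline consumes: a random genome
(FASTA), enhancer intervals (BED), a TSS table, a sparse normalized contact
matrix (TSV), a motif library (MEME format), and a TF-TF interaction table
(TSV). The genome is tiled into blocks of three contact-matrix bins; each
block hosts one enhancer (bin 0) and one promoter (bin 1), so every
annotated EP candidate maps to exactly one bin pair. Interacting blocks
receive a contact value well above the calling cutoff of 30, non-interacting
blocks a value below 5, and all other bin pairs are absent (zero), so the
two cutoffs separate the classes by construction.

Signal is planted at the sequence level: with probability ``q_joint`` an
interacting EP pair receives an exact-consensus site of the enhancer-side
motif in its enhancer and of the promoter-side motif in its promoter;
independently, every region acquires a site of each library motif with a
small background probability. A manifest records the ground truth so
recovery can be scored.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from . import ep_pairs as ep
from .genome_io import (
    GenomicInterval,
    SequenceRecord,
    TSSRecord,
    extract_sequence,
    make_promoter,
    write_bed,
    write_fasta,
)
from .motifs import PWM, write_meme
from .pair_discovery import MotifPair

logger = logging.getLogger(__name__)

BLOCK_BINS = 3  # bins per EP block: enhancer bin, promoter bin, spacer


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the conditions of the discovery experiments: 500 EP
    pairs, 300-bp enhancers (so promoters, at 1100 bp, are roughly three
    times longer), background motif presence 0.05 per region, one planted
    oriented motif pair at joint probability 0.4, and contact values that
    the 30/5 cutoffs separate cleanly.
    """

    n_ep_pairs: int = 500
    n_negative_blocks: int = 500
    resolution: int = 5_000
    enhancer_length: int = 300
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    motif_library_size: int = 8
    motif_width: int = 8
    planted_pairs: list[tuple[str, str, float]] = field(
        default_factory=lambda: [("M000", "M001", 0.4)]
    )
    background_presence: float = 0.05
    contact_high: tuple[float, float] = (40.0, 100.0)
    contact_low: tuple[float, float] = (0.5, 4.5)
    chrom_name: str = "chrS"
    seed: int = 0

    def __post_init__(self) -> None:
        for _, _, q in self.planted_pairs:
            if not 0 <= q <= 1:
                raise ValueError(f"q_joint must be in [0, 1], got {q}")
        if not self.contact_high[0] > ep.INTERACTION_CUTOFF:
            raise ValueError("contact_high must exceed the interaction cutoff 30")
        if not self.contact_low[1] < ep.NONINTERACTION_CUTOFF:
            raise ValueError("contact_low must stay below the non-interaction cutoff 5")

    @property
    def block_size(self) -> int:
        return BLOCK_BINS * self.resolution

    @property
    def genome_length(self) -> int:
        return (self.n_ep_pairs + self.n_negative_blocks) * self.block_size


@dataclass
class Bundle:
    """In-memory synthetic bundle; ``write`` serializes it to a directory."""

    config: SimConfig
    genome: dict[str, str]
    enhancers: list[GenomicInterval]
    tss_records: list[TSSRecord]
    promoters: list[GenomicInterval]
    contacts: list[ep.ContactRecord]
    all_bin_pairs: list[ep.BinPair]
    pwms: list[PWM]
    tf_pairs: list[tuple[str, str, str]]
    manifest: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "enhancers": outdir / "enhancers.bed",
            "tss": outdir / "tss.bed",
            "contacts": outdir / "contacts.tsv",
            "motifs": outdir / "motifs.meme",
            "interactions": outdir / "tf_interactions.tsv",
            "manifest": outdir / "manifest.json",
        }
        write_fasta(
            [SequenceRecord(c, s) for c, s in sorted(self.genome.items())],
            paths["genome"],
        )
        write_bed(self.enhancers, paths["enhancers"])
        with open(paths["tss"], "w") as fh:
            for t in self.tss_records:
                fh.write(f"{t.chrom}\t{t.tss}\t{t.tss + 1}\t{t.gene_id}\t0\t{t.strand}\n")
        with open(paths["contacts"], "w") as fh:
            fh.write("#chrom\tbin_a\tbin_b\tvalue\n")
            for r in self.contacts:
                fh.write(f"{r.chrom}\t{r.bin_a}\t{r.bin_b}\t{r.value:.4f}\n")
        write_meme(self.pwms, paths["motifs"], self.config.background)
        with open(paths["interactions"], "w") as fh:
            fh.write("#tf_a\ttf_b\ttype\n")
            for a, b, kind in self.tf_pairs:
                fh.write(f"{a}\t{b}\t{kind}\n")
        with open(paths["manifest"], "w") as fh:
            json.dump(self.manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return paths


def _random_pwm(name: str, width: int, rng: np.random.Generator) -> PWM:
    """An information-rich PWM: one dominant base (p=0.91) per position."""
    consensus = rng.integers(0, 4, size=width)
    probs = np.full((width, 4), 0.03)
    probs[np.arange(width), consensus] = 0.91
    return PWM(name, probs, pseudocount=0.0)


def _plant(site: str, region: GenomicInterval, genome_arr, used: list[tuple[int, int]],
           rng: np.random.Generator, max_attempts: int = 50) -> bool:
    """Overwrite a random non-overlapping stretch of the region with a site."""
    lo, hi = region.start, region.end - len(site)
    if hi < lo:
        return False
    for _ in range(max_attempts):
        pos = int(rng.integers(lo, hi + 1))
        if all(pos + len(site) <= s or pos >= e for s, e in used):
            genome_arr[pos : pos + len(site)] = np.frombuffer(site.encode(), dtype=np.uint8)
            used.append((pos, pos + len(site)))
            return True
    return False


def simulate(config: SimConfig, outdir: str | Path | None = None) -> Bundle:
    """Generate a complete synthetic input bundle.

    Deterministic in ``config.seed``; when ``outdir`` is given the bundle
    is also written to disk in the standard formats.
    """
    rng = np.random.default_rng(config.seed)
    res = config.resolution
    chrom = config.chrom_name
    bg = np.asarray(config.background, dtype=float)
    bg = bg / bg.sum()

    # genome as a mutable byte array of i.i.d. bases
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome_arr = rng.choice(bases, size=config.genome_length, p=bg)

    # motif library: planted motifs are the first entries
    planted_names = sorted({m for pair in config.planted_pairs for m in pair[:2]})
    n_extra = max(config.motif_library_size - len(planted_names), 0)
    names = [f"M{i:03d}" for i in range(len(planted_names) + n_extra)]
    if planted_names != names[: len(planted_names)]:
        raise ValueError(
            f"planted motif names must be the first library names {names[:len(planted_names)]}"
        )
    pwms = [_random_pwm(n, config.motif_width, rng) for n in names]
    consensus = {p.name: p.consensus() for p in pwms}

    n_blocks = config.n_ep_pairs + config.n_negative_blocks
    # interleave interacting and non-interacting blocks deterministically
    kinds = np.array([1] * config.n_ep_pairs + [0] * config.n_negative_blocks)
    rng.shuffle(kinds)

    enhancers: list[GenomicInterval] = []
    tss_records: list[TSSRecord] = []
    promoters: list[GenomicInterval] = []
    contacts: list[ep.ContactRecord] = []
    all_bin_pairs: list[ep.BinPair] = []
    planted_carriers: dict[str, list[int]] = {
        f"{a}|{b}": [] for a, b, _ in config.planted_pairs
    }
    interacting_bins: list[list] = []

    e_len = config.enhancer_length
    for i in range(n_blocks):
        block = i * config.block_size
        strand = "+" if rng.random() < 0.5 else "-"
        # enhancer inside bin 0, promoter window inside bin 1; resample
        # until the midpoint-to-TSS distance clears the 2.5 kb floor
        for _ in range(200):
            e_start = block + int(rng.integers(100, res - e_len - 100))
            if strand == "+":
                tss = block + res + int(rng.integers(1000, res - 100))
            else:
                tss = block + res + int(rng.integers(100, res - 1000))
            if abs((e_start + e_len // 2) - tss) >= ep.MIN_DISTANCE:
                break
        else:
            raise RuntimeError("could not satisfy the distance floor; widen the bins")
        enhancer = GenomicInterval(chrom, e_start, e_start + e_len, ".", f"enh{i:05d}")
        tss_rec = TSSRecord(f"gene{i:05d}", chrom, tss, strand)
        promoter = make_promoter(tss_rec)
        enhancers.append(enhancer)
        tss_records.append(tss_rec)
        promoters.append(promoter)

        bin_pair = (chrom, block, block + res)
        all_bin_pairs.append(bin_pair)
        if kinds[i]:
            value = float(rng.uniform(*config.contact_high))
            interacting_bins.append([chrom, block, block + res])
        else:
            value = float(rng.uniform(*config.contact_low))
        contacts.append(ep.ContactRecord(chrom, block, block + res, value))

        # plant motif sites
        used_e: list[tuple[int, int]] = []
        used_p: list[tuple[int, int]] = []
        if kinds[i]:
            for m_e, m_p, q in config.planted_pairs:
                if rng.random() < q:
                    ok_e = _plant(consensus[m_e], enhancer, genome_arr, used_e, rng)
                    ok_p = _plant(consensus[m_p], promoter, genome_arr, used_p, rng)
                    if ok_e and ok_p:
                        planted_carriers[f"{m_e}|{m_p}"].append(i)
        for name in names:
            if rng.random() < config.background_presence:
                _plant(consensus[name], enhancer, genome_arr, used_e, rng)
            if rng.random() < config.background_presence:
                _plant(consensus[name], promoter, genome_arr, used_p, rng)

    genome = {chrom: genome_arr.tobytes().decode()}

    # TF interaction table: planted pairs' TFs interact directly, plus a
    # few random direct/indirect decoy pairs among the remaining TFs
    tf_of = {n: f"TF_{n}" for n in names}
    tf_pairs: list[tuple[str, str, str]] = []
    seen_tf = set()
    for m_e, m_p, _ in config.planted_pairs:
        key = frozenset((tf_of[m_e], tf_of[m_p]))
        if key not in seen_tf:
            tf_pairs.append((tf_of[m_e], tf_of[m_p], "direct"))
            seen_tf.add(key)
    others = [n for n in names if n not in planted_names]
    for _ in range(max(len(others), 2)):
        if len(others) < 2:
            break
        a, b = rng.choice(len(others), size=2, replace=False)
        key = frozenset((tf_of[others[a]], tf_of[others[b]]))
        if key not in seen_tf:
            kind = "direct" if rng.random() < 0.5 else "indirect"
            tf_pairs.append((tf_of[others[a]], tf_of[others[b]], kind))
            seen_tf.add(key)

    manifest = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "planted_pairs": [
            {"motif_E": a, "motif_P": b, "q_joint": q, "carriers": planted_carriers[f"{a}|{b}"]}
            for a, b, q in config.planted_pairs
        ],
        "interacting_bin_pairs": interacting_bins,
        "motif_names": names,
        "motif_consensus": consensus,
        "tf_of_motif": tf_of,
        "n_blocks": n_blocks,
        "block_kinds": kinds.tolist(),
    }
    bundle = Bundle(
        config, genome, enhancers, tss_records, promoters, contacts,
        all_bin_pairs, pwms, tf_pairs, manifest,
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle


def positive_pairs(bundle: Bundle) -> list[ep.EPPair]:
    """Positive EP pairs of a bundle via the standard calling route."""
    high = ep.call_interacting_bins(bundle.contacts, ep.INTERACTION_CUTOFF)
    values = {(r.chrom, r.bin_a, r.bin_b): r.value for r in bundle.contacts}
    return ep.build_ep_pairs(
        high, bundle.enhancers, bundle.promoters, bundle.config.resolution,
        "positive", values,
    )


def pair_sequences(bundle: Bundle, pairs: Sequence[ep.EPPair]):
    """Extract (enhancer, promoter) sequences for EP pairs from the bundle genome."""
    from .negatives import SequencedPair

    out = []
    for p in pairs:
        out.append(
            SequencedPair(
                p,
                extract_sequence(bundle.genome, p.enhancer),
                extract_sequence(bundle.genome, p.promoter),
            )
        )
    return out


def evaluate_recovery(
    discovered_pairs: Sequence[MotifPair], manifest: dict
) -> dict:
    """Score discovery output against the manifest's planted ground truth.

    A planted pair is recovered when a significant discovered pair matches
    it in the correct orientation; every other significant pair counts as a
    false discovery.
    """
    significant = {
        (p.motif_E, p.motif_P) for p in discovered_pairs if p.significant
    }
    planted = {(d["motif_E"], d["motif_P"]) for d in manifest["planted_pairs"]}
    per_pair = [
        {
            "motif_E": a,
            "motif_P": b,
            "recovered": (a, b) in significant,
        }
        for a, b in sorted(planted)
    ]
    return {
        "planted": per_pair,
        "n_recovered": sum(d["recovered"] for d in per_pair),
        "n_planted": len(per_pair),
        "false_discoveries": len(significant - planted),
    }
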