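"""End-to-end orchestration: inputs -> EP pairs -> scan -> discovery -> stats -> CV.

Each stage is a pure function of its inputs plus the run seed, so a rerun
with identical inputs and seed reproduces every output byte for byte. The
log records counts at every filtering step (bin pairs kept, EP pairs kept,
motifs kept, motif pairs kept) so users can assemble their own accounting
tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import classify as clf
from . import ep_pairs as ep
from . import negatives as neg
from . import pair_discovery as disc
from . import pair_stats as ps
from .genome_io import extract_sequence, make_promoter, read_bed, read_fasta, read_tss_table
from .motifs import read_motifs, scan_library, write_occurrences

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All paths and thresholds of one pipeline run.

    The thresholds default to the calling conventions used throughout:
    contact cutoffs 30 (interacting, strict greater) and 5 (non-interacting,
    strict less), EP distance within [2.5 kb, 2 Mb], scan p-value 1e-4,
    motif-similarity E-values 1e-5 (dedup/annotation) and 1e-8
    (cross-condition sharing), discovery alpha 0.01 with Bonferroni
    correction, module support >= 30 and size 2-5.
    """

    genome: str = ""
    enhancers: str = ""
    tss: str = ""
    contacts: str = ""
    motifs: str = ""
    interactions: str = ""
    outdir: str = "epmotif_run"
    resolution: int = 5_000
    interaction_cutoff: float = ep.INTERACTION_CUTOFF
    noninteraction_cutoff: float = ep.NONINTERACTION_CUTOFF
    min_distance: int = ep.MIN_DISTANCE
    max_distance: int = ep.MAX_DISTANCE
    scan_pvalue: float = 1e-4
    similarity_evalue: float = 1e-5
    sharing_evalue: float = 1e-8
    alpha: float = 0.01
    min_support: int = 30
    max_module_size: int = 5
    correction: str = "bonferroni"
    negative_type: int = 1
    with_stats: bool = True
    with_classification: bool = True
    seed: int = 0
    promoter_ignore_strand: bool = False
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)


def _seq_id(iv) -> str:
    return f"{iv.chrom}:{iv.start}-{iv.end}({iv.strand})"


def _write_motif_stats(stats_rows, path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#motif\thom_v1_n\thom_v1_p\thom_v1_sig\thom_v2_n\thom_v2_p\thom_v2_sig"
            "\tpref_count_enh_p\tpref_count_prom_p\tpref_len_enh_p\tpref_len_prom_p\n"
        )
        for name, v1, v2, pc, pl in stats_rows:
            fh.write(
                f"{name}\t{v1.n}\t{v1.pvalue:.6g}\t{int(v1.significant)}"
                f"\t{v2.n}\t{v2.pvalue:.6g}\t{int(v2.significant)}"
                f"\t{pc.pvalue_enh:.6g}\t{pc.pvalue_prom:.6g}"
                f"\t{pl.pvalue_enh:.6g}\t{pl.pvalue_prom:.6g}\n"
            )


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages in dependency order; returns a result summary dict.

    Outputs are written under ``config.outdir``: the serialized config,
    EP-pair TSVs, motif occurrences, discovered motif pairs and modules,
    per-motif statistics, enrichment, and the cross-validation report.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)

    # --- inputs -----------------------------------------------------------
    genome = {r.id: r.seq for r in read_fasta(config.genome)}
    enhancers = read_bed(config.enhancers)
    tss_records = read_tss_table(config.tss)
    promoters = [make_promoter(t, config.promoter_ignore_strand) for t in tss_records]
    contacts = ep.load_contacts(config.contacts, config.resolution)
    pwms = read_motifs(config.motifs)
    logger.info(
        "inputs: %d enhancers, %d promoters, %d contact records, %d motifs",
        len(enhancers), len(promoters), len(contacts), len(pwms),
    )

    # --- EP pairs ---------------------------------------------------------
    values = {(r.chrom, r.bin_a, r.bin_b): r.value for r in contacts}
    high = ep.call_interacting_bins(contacts, config.interaction_cutoff)
    positives = ep.build_ep_pairs(
        high, enhancers, promoters, config.resolution, "positive", values,
        min_distance=config.min_distance, max_distance=config.max_distance,
    )
    all_bins = sorted(values)
    neg3 = neg.make_type3(
        contacts, all_bins, enhancers, promoters, config.resolution,
        config.noninteraction_cutoff,
    )
    ep.write_ep_pairs(positives, out / "ep_pairs_positive.tsv")
    ep.write_ep_pairs(neg3.pairs, out / "ep_pairs_negative3.tsv")
    logger.info(
        "EP pairs: %d bin pairs > %g -> %d positive; %d negative3",
        len(high), config.interaction_cutoff, len(positives), len(neg3.pairs),
    )
    if not positives:
        raise RuntimeError("stage ep_pairs: no positive EP pairs called")

    # --- scanning ---------------------------------------------------------
    pos_seq = []
    for p in positives:
        pos_seq.append(extract_sequence(genome, p.enhancer))
        pos_seq.append(extract_sequence(genome, p.promoter))
    occurrences = scan_library(pwms, pos_seq, p_threshold=config.scan_pvalue)
    widths = {p.name: p.width for p in pwms}
    write_occurrences(
        (o for occs in occurrences.values() for o in occs),
        out / "occurrences_positive.tsv", widths,
    )

    # --- discovery --------------------------------------------------------
    profiles = disc.build_profiles(positives, occurrences)
    modules = disc.find_modules(
        profiles, config.min_support, config.max_module_size, config.alpha
    )
    pairs = disc.extract_pairs(modules, profiles, config.min_support)
    pairs = disc.correct_pvalues(pairs, config.correction, config.alpha)
    disc.write_modules(modules, out / "modules.tsv")
    disc.write_pairs(pairs, out / "motif_pairs.tsv")
    significant = [p for p in pairs if p.significant]
    logger.info(
        "discovery: %d modules, %d oriented pairs, %d significant",
        len(modules), len(pairs), len(significant),
    )

    # --- per-motif statistics --------------------------------------------
    l1 = sum(len(p.promoter) for p in positives) / len(positives)
    l2 = sum(len(p.enhancer) for p in positives) / len(positives)
    scanned = sorted({o.motif_name for occs in occurrences.values() for o in occs})
    K = max(len(scanned), 1)
    stats_rows = []
    for name in scanned if config.with_stats else []:
        v1 = ps.homogeneous_test_v1(name, profiles, occurrences, K, l1, l2)
        v2 = ps.homogeneous_test_v2(name, profiles, K)
        e_hits = sum(
            1
            for p in positives
            for o in occurrences[_seq_id(p.enhancer)]
            if o.motif_name == name
        )
        p_hits = sum(
            1
            for p in positives
            for o in occurrences[_seq_id(p.promoter)]
            if o.motif_name == name
        )
        pref_c = ps.preference_test(name, e_hits, p_hits)
        pref_l = ps.preference_test(name, e_hits, p_hits, (l1, l2))
        stats_rows.append((name, v1, v2, pref_c, pref_l))
    stats_path = out / "motif_stats.tsv"
    if config.with_stats:
        _write_motif_stats(stats_rows, stats_path)

    # --- enrichment -------------------------------------------------------
    enrichment = None
    if config.with_stats and config.interactions:
        db_pairs, db_tfs = ps.load_interaction_db(config.interactions, "direct")
        # motifs in this run are library motifs: identity mapping to their TFs
        tf_of = {name: f"TF_{name}".upper() for name in widths}
        predicted = {
            frozenset((tf_of[p.motif_E], tf_of[p.motif_P]))
            for p in significant
            if tf_of[p.motif_E] != tf_of[p.motif_P]
        }
        if predicted:
            enrichment = ps.hypergeom_enrichment(predicted, db_pairs, db_tfs, "direct")
            with open(out / "enrichment.json", "w") as fh:
                json.dump(asdict(enrichment), fh, indent=1, sort_keys=True)
                fh.write("\n")

    # --- classification ---------------------------------------------------
    cv_report = None
    if config.with_classification and significant:
        pos_sp = [
            neg.SequencedPair(
                p, extract_sequence(genome, p.enhancer), extract_sequence(genome, p.promoter)
            )
            for p in positives
        ]
        if config.negative_type == 1:
            negset = neg.make_type1(pos_sp, config.seed)
        elif config.negative_type == 2:
            negset = neg.make_type2(
                pos_sp, genome, enhancers + promoters, config.seed
            )
        else:
            sp3 = [
                neg.SequencedPair(
                    p, extract_sequence(genome, p.enhancer), extract_sequence(genome, p.promoter)
                )
                for p in neg3.pairs
            ]
            negset = neg.NegativeSet("type3_low_contact", sp3, {})
        neg_seqs = [s for sp in negset.pairs for s in (sp.enh_seq, sp.prom_seq)]
        occ_all = dict(occurrences)
        occ_all.update(scan_library(pwms, neg_seqs, p_threshold=config.scan_pvalue))
        items = [
            (p.ep_id, _seq_id(p.enhancer), _seq_id(p.promoter), 1) for p in positives
        ] + [
            (f"{sp.pair.ep_id}#neg", sp.enh_seq.id, sp.prom_seq.id, 0)
            for sp in negset.pairs
        ]
        features = clf.build_features(items, significant, occ_all)
        cv_report = clf.cross_validate(features, seed=config.seed)
        with open(out / "cv_report.json", "w") as fh:
            json.dump(
                {k: v for k, v in asdict(cv_report).items()},
                fh, indent=1, sort_keys=True,
            )
            fh.write("\n")
        logger.info(
            "classification (type %d negatives): mean F1 %.3f, %d pairs selected",
            config.negative_type, cv_report.mean_f1, cv_report.n_selected,
        )

    summary = {
        "n_positive_pairs": len(positives),
        "n_negative3_pairs": len(neg3.pairs),
        "n_motifs_scanned": len(scanned),
        "n_modules": len(modules),
        "n_motif_pairs": len(pairs),
        "n_significant_pairs": len(significant),
        "mean_f1": cv_report.mean_f1 if cv_report else None,
        "enrichment_pvalue": enrichment.pvalue if enrichment else None,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary
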