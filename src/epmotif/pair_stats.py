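"""Binomial and hypergeometric tests on discovered motifs and motif pairs.

Three test families:

* **Homogeneous pairs** — the same motif present in both the enhancer and
  the promoter of interacting EP pairs (the CTCF-CTCF / YY1-YY1 pattern).
  The number of EP pairs with the motif on both sides is compared with a
  binomial null. Variant 1 is length-aware: the per-pair success
  probability is ``x / (N * (l1 + l2))`` where ``x`` is the total
  occurrence count over all N pairs and ``l1``/``l2`` are the mean promoter
  and enhancer lengths. Variant 2 is presence-based:
  ``p = (x * y) / N^2`` with ``x`` enhancers and ``y`` promoters containing
  the motif. Significance requires p < 0.01/K for K motifs tested.
* **Region preference** — whether a motif's hits favour enhancers or
  promoters, by a binomial test on hit counts with success probability 0.5
  (count-only) or proportional to region length (length-aware).
* **Interaction-database enrichment** — whether predicted motif pairs,
  mapped to transcription factors, are enriched for known interacting TF
  pairs, by the upper hypergeometric tail over all unordered TF pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .motifs import MotifOccurrence, SimilarityResult
from .pair_discovery import EPOccurrenceProfile

logger = logging.getLogger(__name__)

HOMOGENEOUS_ALPHA = 0.01
TF_MAPPING_EVALUE = 1e-5


@dataclass(frozen=True)
class HomogeneousResult:
    """Outcome of one homogeneous-pair test for a single motif.

    ``n`` of the ``N`` EP pairs carry the motif in both regions. Variant
    ``length_aware`` uses total occurrence count ``x`` and mean lengths
    ``l1`` (promoter) / ``l2`` (enhancer); variant ``presence_based`` uses
    ``x`` enhancers and ``y`` promoters containing the motif.
    """

    motif: str
    variant: str
    N: int
    n: int
    x: int
    y: int
    l1: float
    l2: float
    K: int
    p_success: float
    pvalue: float
    significant: bool


@dataclass(frozen=True)
class PreferenceResult:
    """Enhancer-vs-promoter preference of one motif's hits."""

    motif: str
    variant: str  # count_only | length_aware
    e_hits: int
    p_hits: int
    p_success: float  # null probability that a hit falls in the enhancer
    pvalue_enh: float
    pvalue_prom: float


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment of predicted TF pairs in an interaction database."""

    N_tfs: int
    M_pairs: int
    n_tfs: int
    m_pairs: int
    pvalue: float
    mode: str  # direct | direct_plus_indirect

    def __post_init__(self) -> None:
        limit = self.n_tfs * (self.n_tfs - 1) // 2
        if self.m_pairs > min(self.M_pairs, limit):
            raise ValueError(
                f"m_pairs={self.m_pairs} exceeds min(M={self.M_pairs}, "
                f"n(n-1)/2={limit})"
            )


# ---------------------------------------------------------------------------
# tail primitives

def binom_upper_tail(n: int, N: int, p: float) -> float:
    """Exact binomial upper tail P(X >= n) for X ~ Binomial(N, p).

    Includes the ``i = n`` term; returns exactly 1 at ``n = 0``.
    """
    if not (0 <= n <= N):
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not (0 < p < 1):
        raise ValueError(f"p must be in (0, 1), got {p}")
    if n == 0:
        return 1.0
    return float(stats.binom.sf(n - 1, N, p))


def hypergeom_upper_tail(m: int, draws: int, M: int, universe: int) -> float:
    """P(X >= m) drawing ``draws`` from ``universe`` items with ``M`` successes."""
    if m == 0:
        return 1.0
    return float(stats.hypergeom.sf(m - 1, universe, M, draws))


# ---------------------------------------------------------------------------
# homogeneous motif pairs

def _both_sides_count(motif: str, profiles: Sequence[EPOccurrenceProfile]) -> int:
    return sum(1 for p in profiles if motif in p.enh_motifs and motif in p.prom_motifs)


def homogeneous_test_v1(
    motif: str,
    profiles: Sequence[EPOccurrenceProfile],
    occurrences: Mapping[str, Iterable[MotifOccurrence]],
    K: int,
    l1: float,
    l2: float,
) -> HomogeneousResult:
    """Length-aware homogeneous test.

    ``x`` is the motif's total occurrence count across all sequences of the
    N EP pairs (both regions, both strands); the per-pair success
    probability is ``x / (N * (l1 + l2))``, i.e. the per-base hit density
    scaled by the combined mean length. A density >= 1 is a degenerate
    input and an error, not clipped.
    """
    N = len(profiles)
    if N < 1:
        raise ValueError("no profiles")
    if l1 + l2 <= 0:
        raise ValueError("mean lengths must be positive")
    x = sum(
        1 for occs in occurrences.values() for o in occs if o.motif_name == motif
    )
    if x < 1:
        raise ValueError(f"motif {motif!r} has no occurrences")
    p_success = x / (N * (l1 + l2))
    if p_success >= 1:
        raise ValueError(f"degenerate success probability {p_success} for {motif!r}")
    n = _both_sides_count(motif, profiles)
    pvalue = binom_upper_tail(n, N, p_success)
    return HomogeneousResult(
        motif, "length_aware", N, n, x, 0, l1, l2, K, p_success,
        pvalue, pvalue < HOMOGENEOUS_ALPHA / K,
    )


def homogeneous_test_v2(
    motif: str, profiles: Sequence[EPOccurrenceProfile], K: int
) -> HomogeneousResult:
    """Presence-based homogeneous test: p = (x * y) / N^2."""
    N = len(profiles)
    if N < 1:
        raise ValueError("no profiles")
    x = sum(1 for p in profiles if motif in p.enh_motifs)
    y = sum(1 for p in profiles if motif in p.prom_motifs)
    n = _both_sides_count(motif, profiles)
    if (x == 0 or y == 0) and n > 0:
        raise ValueError(f"inconsistent counts for {motif!r}: n={n} but x={x}, y={y}")
    p_success = (x * y) / (N * N)
    if p_success >= 1:
        raise ValueError(f"degenerate success probability 1 for {motif!r}")
    if p_success == 0:
        pvalue = 1.0
    else:
        pvalue = binom_upper_tail(n, N, p_success)
    return HomogeneousResult(
        motif, "presence_based", N, n, x, y, 0.0, 0.0, K, p_success,
        pvalue, pvalue < HOMOGENEOUS_ALPHA / K,
    )


# ---------------------------------------------------------------------------
# region preference

def preference_test(
    motif: str,
    e_hits: int,
    p_hits: int,
    mean_lengths: tuple[float, float] | None = None,
) -> PreferenceResult:
    """Does a motif prefer enhancers or promoters?

    ``e_hits``/``p_hits`` are total hit counts in enhancers and promoters.
    Without ``mean_lengths`` the null places a hit in either region with
    probability 0.5 (count-only); with ``mean_lengths = (l1, l2)`` — mean
    promoter and enhancer lengths — the enhancer success probability is
    ``l2 / (l1 + l2)``, so longer regions absorb proportionally more hits.
    ``pvalue_enh`` is the upper tail for enhancer excess, ``pvalue_prom``
    for promoter excess.
    """
    total = e_hits + p_hits
    if total < 1:
        raise ValueError("no hits to test")
    if mean_lengths is None:
        variant, p_enh = "count_only", 0.5
    else:
        l1, l2 = mean_lengths
        variant, p_enh = "length_aware", l2 / (l1 + l2)
    return PreferenceResult(
        motif, variant, e_hits, p_hits, p_enh,
        binom_upper_tail(e_hits, total, p_enh),
        binom_upper_tail(p_hits, total, 1 - p_enh),
    )


# ---------------------------------------------------------------------------
# interaction-database enrichment

def load_interaction_db(path: str | Path, mode: str = "direct") -> tuple[set[frozenset[str]], set[str]]:
    """Load a TF-TF interaction TSV (tf_a, tf_b, type in {direct, indirect}).

    Symmetric duplicates collapse to one unordered pair; names are
    case-normalized to upper case. Returns (pairs, tfs).
    """
    wanted = {"direct"} if mode == "direct" else {"direct", "indirect"}
    pairs: set[frozenset[str]] = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise ValueError(f"interaction DB needs 3 columns, got {f}")
            a, b, kind = f[0].upper(), f[1].upper(), f[2]
            if kind not in ("direct", "indirect"):
                raise ValueError(f"unknown interaction type {kind!r}")
            if a != b and kind in wanted:
                pairs.add(frozenset((a, b)))
    tfs = {t for pair in pairs for t in pair}
    return pairs, tfs


def map_motifs_to_tfs(
    predicted_motifs: Sequence[str],
    similarities: Sequence[SimilarityResult],
    motif_to_tf: Mapping[str, str],
    mode: str = "best",
    evalue_cutoff: float = TF_MAPPING_EVALUE,
) -> dict[str, set[str]]:
    """Map predicted motifs to TF names via motif-library similarity.

    ``similarities`` compares predicted motifs (``motif_a``) against library
    motifs (``motif_b``); ``motif_to_tf`` names the TF behind each library
    motif. ``mode='all'`` keeps every TF with similarity E-value below the
    cutoff; ``mode='best'`` keeps only the single most similar TF
    (E-value argmin, ties broken lexicographically and logged). Motifs with
    no match map to an empty set and drop out of enrichment.
    """
    by_motif: dict[str, list[SimilarityResult]] = {m: [] for m in predicted_motifs}
    for s in similarities:
        if s.motif_a in by_motif and s.evalue < evalue_cutoff:
            by_motif[s.motif_a].append(s)
    mapping: dict[str, set[str]] = {}
    for motif, hits in by_motif.items():
        if not hits:
            mapping[motif] = set()
            continue
        if mode == "all":
            mapping[motif] = {motif_to_tf[h.motif_b].upper() for h in hits}
        elif mode == "best":
            best = min(hits, key=lambda h: (h.evalue, motif_to_tf[h.motif_b].upper()))
            ties = [h for h in hits if h.evalue == best.evalue]
            if len(ties) > 1:
                logger.info(
                    "map_motifs_to_tfs: %s tie among %s, keeping %s",
                    motif, sorted(motif_to_tf[h.motif_b] for h in ties),
                    motif_to_tf[best.motif_b],
                )
            mapping[motif] = {motif_to_tf[best.motif_b].upper()}
        else:
            raise ValueError(f"unknown mapping mode {mode!r}")
    return mapping


def hypergeom_enrichment(
    predicted_tf_pairs: Iterable[frozenset[str]],
    db_pairs: set[frozenset[str]],
    db_tfs: set[str],
    mode: str = "direct",
) -> EnrichmentResult:
    """Enrichment of known interacting TF pairs among predicted TF pairs.

    With ``N`` TFs in the database the universe holds ``N(N-1)/2``
    unordered pairs, of which ``M`` interact. The ``n`` distinct database
    TFs among the predictions define ``n(n-1)/2`` drawn pairs, ``m`` of
    which are database pairs; the p-value is the upper hypergeometric tail
    P(X >= m). Predicted pairs with a TF absent from the database are
    dropped (logged).
    """
    N = len(db_tfs)
    M = len(db_pairs)
    kept: set[frozenset[str]] = set()
    dropped = 0
    for pair in predicted_tf_pairs:
        if len(pair) == 2 and pair <= db_tfs:
            kept.add(pair)
        else:
            dropped += 1
    if dropped:
        logger.info("hypergeom_enrichment: dropped %d unmappable pairs", dropped)
    n = len({t for pair in kept for t in pair})
    m = len(kept & db_pairs)
    draws = n * (n - 1) // 2
    if m > min(M, draws):
        raise ValueError(f"inconsistent counts: m={m}, M={M}, draws={draws}")
    universe = N * (N - 1) // 2
    pvalue = hypergeom_upper_tail(m, draws, M, universe)
    return EnrichmentResult(N, M, n, m, pvalue, mode)
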