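"""Motif-module and enhancer-promoter motif-pair discovery.

Each EP pair contributes a presence/absence profile: the set of motifs with
at least one hit in its enhancer and the set with a hit in its promoter.
Motif modules (sets of 2-5 motifs jointly present in many EP pairs) are
enumerated level-wise with anti-monotone support pruning. From each module,
oriented motif pairs (one motif on the enhancer side, the other on the
promoter side) are extracted and scored against a Poisson-clumping null:
the number of EP pairs carrying the oriented pattern is compared with the
expectation ``a*b/N`` under independence of the two region-wise presences,
using the upper Poisson tail. Pairs surviving multiple-testing correction
at 0.01 are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .ep_pairs import EPPair
from .motifs import MotifOccurrence

logger = logging.getLogger(__name__)

MIN_SUPPORT = 30
MAX_MODULE_SIZE = 5
ALPHA = 0.01


@dataclass(frozen=True)
class EPOccurrenceProfile:
    """Motif presence sets for one EP pair (>= 1 hit counts as present)."""

    ep_id: str
    enh_motifs: frozenset[str]
    prom_motifs: frozenset[str]

    @property
    def all_motifs(self) -> frozenset[str]:
        return self.enh_motifs | self.prom_motifs


@dataclass(frozen=True)
class MotifModule:
    """A set of 2-5 motifs jointly present (in either region) in many EP pairs."""

    motifs: frozenset[str]
    support: int
    pvalue: float
    pvalue_corrected: float = 1.0


@dataclass(frozen=True)
class MotifPair:
    """An oriented enhancer-side/promoter-side motif pair with its statistics.

    ``support_k`` counts EP pairs with ``motif_E`` in the enhancer AND
    ``motif_P`` in the promoter; ``a_count``/``b_count`` are the marginal
    presence counts; ``lam = a_count * b_count / N`` is the expected support
    under independence.
    """

    motif_E: str
    motif_P: str
    support_k: int
    a_count: int
    b_count: int
    N: int
    lam: float
    pvalue: float
    pvalue_corrected: float = 1.0
    significant: bool = False

    def __post_init__(self) -> None:
        if not (self.support_k <= min(self.a_count, self.b_count) <= self.N):
            raise ValueError(
                f"inconsistent counts for {self.motif_E}/{self.motif_P}: "
                f"k={self.support_k} a={self.a_count} b={self.b_count} N={self.N}"
            )


def poisson_tail(k: int, lam: float) -> float:
    """Upper Poisson tail P(X >= k); exactly 1 when k = 0."""
    if k < 0 or k != int(k):
        raise ValueError(f"k must be a non-negative integer, got {k}")
    if lam <= 0:
        raise ValueError(f"lam must be positive, got {lam}")
    if k == 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, lam))


def build_profiles(
    ep_pairs: Sequence[EPPair],
    occurrences: Mapping[str, Iterable[MotifOccurrence]],
    enh_seq_id=None,
    prom_seq_id=None,
) -> list[EPOccurrenceProfile]:
    """Collapse scanner occurrences into per-EP-pair presence profiles.

    ``occurrences`` is keyed by sequence ID. By default the enhancer and
    promoter sequence IDs are those produced by ``genome_io.extract_sequence``;
    custom key functions may be supplied. An EP pair whose sequences are
    missing from ``occurrences`` is an error: it was never scanned.
    """
    if enh_seq_id is None:
        enh_seq_id = lambda p: (
            f"{p.enhancer.chrom}:{p.enhancer.start}-{p.enhancer.end}({p.enhancer.strand})"
        )
    if prom_seq_id is None:
        prom_seq_id = lambda p: (
            f"{p.promoter.chrom}:{p.promoter.start}-{p.promoter.end}({p.promoter.strand})"
        )
    profiles = []
    for p in ep_pairs:
        e_key, p_key = enh_seq_id(p), prom_seq_id(p)
        if e_key not in occurrences or p_key not in occurrences:
            raise KeyError(f"EP pair {p.ep_id} has unscanned sequences ({e_key}, {p_key})")
        enh = frozenset(o.motif_name for o in occurrences[e_key])
        prom = frozenset(o.motif_name for o in occurrences[p_key])
        profiles.append(EPOccurrenceProfile(p.ep_id, enh, prom))
    return profiles


def find_modules(
    profiles: Sequence[EPOccurrenceProfile],
    min_support: int = MIN_SUPPORT,
    max_size: int = MAX_MODULE_SIZE,
    alpha: float = ALPHA,
) -> list[MotifModule]:
    """Level-wise (Apriori) enumeration of motif modules of size 2..max_size.

    A profile supports a candidate set when all members are present in the
    EP pair (either region). Support is anti-monotone in the set, so each
    level extends only frequent sets from the previous level. Each module's
    p-value is the upper Poisson tail of its support against
    ``lam = N * prod(member marginal frequencies)``; modules are kept at
    Bonferroni-corrected p < alpha.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    N = len(profiles)
    item_sets = [p.all_motifs for p in profiles]
    # level 1: frequent single motifs
    counts: dict[str, int] = {}
    for s in item_sets:
        for m in s:
            counts[m] = counts.get(m, 0) + 1
    frequent1 = sorted(m for m, c in counts.items() if c >= min_support)
    marginal = {m: counts.get(m, 0) / N for m in counts} if N else {}

    candidates: list[MotifModule] = []
    prev_level: list[frozenset[str]] = [frozenset([m]) for m in frequent1]
    for size in range(2, max_size + 1):
        # join step: extend each frequent (size-1)-set by a larger single item
        seen: set[frozenset[str]] = set()
        level: list[frozenset[str]] = []
        for base in prev_level:
            top = max(base)
            for m in frequent1:
                if m <= top:
                    continue
                cand = base | {m}
                if cand in seen:
                    continue
                seen.add(cand)
                support = sum(1 for s in item_sets if cand <= s)
                if support >= min_support:
                    level.append(cand)
                    lam = N
                    for member in cand:
                        lam *= marginal[member]
                    pv = poisson_tail(support, lam) if lam > 0 else 1.0
                    candidates.append(MotifModule(cand, support, pv))
        if not level:
            break
        prev_level = level

    n_tests = len(candidates)
    modules = []
    for mod in candidates:
        corrected = min(1.0, mod.pvalue * max(n_tests, 1))
        if corrected < alpha:
            modules.append(replace(mod, pvalue_corrected=corrected))
    modules.sort(key=lambda m: (m.pvalue, sorted(m.motifs)))
    logger.info(
        "find_modules: %d profiles, %d candidate modules, %d significant",
        N, n_tests, len(modules),
    )
    return modules


def extract_pairs(
    modules: Sequence[MotifModule],
    profiles: Sequence[EPOccurrenceProfile],
    min_support: int = MIN_SUPPORT,
) -> list[MotifPair]:
    """Oriented enhancer/promoter motif pairs from significant modules.

    For each unordered pair within a module, both orientations (X in
    enhancer with Y in promoter, and the flip) are evaluated separately; an
    orientation is kept only when its cross-region support reaches
    ``min_support``. Pairs co-occurring only within one region class are
    thereby dropped. Counts and the independence expectation are computed
    from the profiles; p-values are raw (see ``correct_pvalues``).
    """
    N = len(profiles)
    if N == 0:
        return []
    enh_count: dict[str, int] = {}
    prom_count: dict[str, int] = {}
    for p in profiles:
        for m in p.enh_motifs:
            enh_count[m] = enh_count.get(m, 0) + 1
        for m in p.prom_motifs:
            prom_count[m] = prom_count.get(m, 0) + 1

    seen: set[tuple[str, str]] = set()
    out: list[MotifPair] = []
    for mod in modules:
        for x, y in combinations(sorted(mod.motifs), 2):
            for me, mp in ((x, y), (y, x)):
                if (me, mp) in seen:
                    continue
                seen.add((me, mp))
                a = enh_count.get(me, 0)
                b = prom_count.get(mp, 0)
                k = sum(
                    1 for p in profiles if me in p.enh_motifs and mp in p.prom_motifs
                )
                if k < min_support or a == 0 or b == 0:
                    continue
                lam = a * b / N
                out.append(MotifPair(me, mp, k, a, b, N, lam, poisson_tail(k, lam)))
    out.sort(key=lambda p: (p.pvalue, p.motif_E, p.motif_P))
    return out


def correct_pvalues(
    pairs: Sequence[MotifPair], method: str = "bonferroni", alpha: float = ALPHA
) -> list[MotifPair]:
    """Multiple-testing correction over the oriented pairs actually tested.

    Bonferroni (default) multiplies each raw p-value by the number of
    oriented pairs; Benjamini-Hochberg step-up is available as
    ``method='bh'``. The ``significant`` flag marks corrected p < alpha.
    """
    n = len(pairs)
    if n == 0:
        return []
    if method == "bonferroni":
        corrected = [min(1.0, p.pvalue * n) for p in pairs]
    elif method == "bh":
        order = sorted(range(n), key=lambda i: pairs[i].pvalue)
        corrected = [1.0] * n
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, pairs[i].pvalue * n / rank)
            corrected[i] = running
    else:
        raise ValueError(f"unknown correction method {method!r}")
    return [
        replace(p, pvalue_corrected=c, significant=c < alpha)
        for p, c in zip(pairs, corrected)
    ]


def discover_pairs(
    profiles: Sequence[EPOccurrenceProfile],
    min_support: int = MIN_SUPPORT,
    max_size: int = MAX_MODULE_SIZE,
    alpha: float = ALPHA,
    method: str = "bonferroni",
) -> list[MotifPair]:
    """Full discovery: modules -> oriented pairs -> corrected p-values."""
    modules = find_modules(profiles, min_support, max_size, alpha)
    pairs = extract_pairs(modules, profiles, min_support)
    return correct_pvalues(pairs, method, alpha)


def shared_motif_pairs(
    pairs_a: Sequence[MotifPair],
    pairs_b: Sequence[MotifPair],
    pwms_a: Mapping[str, "object"],
    pwms_b: Mapping[str, "object"],
    evalue_cutoff: float | None = None,
    n_shuffles: int = 500,
    seed: int = 0,
) -> list[tuple[MotifPair, MotifPair]]:
    """Motif pairs shared between two conditions, by motif similarity.

    A pair from condition A is shared with a pair from condition B when the
    two enhancer-side motifs are similar and the two promoter-side motifs
    are similar (orientation respected), both at the strict cross-condition
    similarity cutoff (default 1e-8; identical library names short-circuit
    as shared). ``pwms_a``/``pwms_b`` map motif names to their PWMs.
    """
    from .motifs import SHARING_EVALUE, similarity

    if evalue_cutoff is None:
        evalue_cutoff = SHARING_EVALUE
    cache: dict[tuple[str, str], bool] = {}

    def similar(name_a: str, name_b: str) -> bool:
        if name_a == name_b:
            return True
        key = (name_a, name_b)
        if key not in cache:
            res = similarity(pwms_a[name_a], pwms_b[name_b], n_shuffles, seed)
            cache[key] = res.evalue < evalue_cutoff
        return cache[key]

    shared = []
    for pa in pairs_a:
        for pb in pairs_b:
            if similar(pa.motif_E, pb.motif_E) and similar(pa.motif_P, pb.motif_P):
                shared.append((pa, pb))
    return shared


def write_pairs(pairs: Iterable[MotifPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#motif_E\tmotif_P\tsupport_k\ta_count\tb_count\tN\tlambda\tpvalue"
            "\tpvalue_corrected\tsignificant\n"
        )
        for p in pairs:
            fh.write(
                f"{p.motif_E}\t{p.motif_P}\t{p.support_k}\t{p.a_count}\t{p.b_count}"
                f"\t{p.N}\t{p.lam:.6g}\t{p.pvalue:.6g}\t{p.pvalue_corrected:.6g}"
                f"\t{int(p.significant)}\n"
            )


def write_modules(modules: Iterable[MotifModule], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#members\tsupport\tpvalue\tpvalue_corrected\n")
        for m in modules:
            fh.write(
                f"{','.join(sorted(m.motifs))}\t{m.support}\t{m.pvalue:.6g}"
                f"\t{m.pvalue_corrected:.6g}\n"
            )
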