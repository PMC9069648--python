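"""Module enumeration, oriented pair extraction, and Poisson-tail significance."""

import itertools
from fractions import Fraction

import numpy as np
import pytest
import sympy

from epmotif.ep_pairs import EPPair
from epmotif.genome_io import GenomicInterval
from epmotif.motifs import MotifOccurrence
from epmotif.pair_discovery import (
    EPOccurrenceProfile,
    MotifModule,
    build_profiles,
    correct_pvalues,
    discover_pairs,
    extract_pairs,
    find_modules,
    poisson_tail,
    MotifPair,
)


def profile(i, enh=(), prom=()):
    return EPOccurrenceProfile(f"ep{i}", frozenset(enh), frozenset(prom))


class TestPoissonTail:
    def test_k_zero_is_one(self):
        assert poisson_tail(0, 5.0) == 1.0

    def test_closed_form_k1(self):
        assert poisson_tail(1, 1.0) == pytest.approx(1 - np.exp(-1), abs=1e-12)

    @pytest.mark.parametrize("k,lam", [(12, 3.0), (5, 0.5), (50, 20.0), (1, 19.5)])
    def test_matches_high_precision_summation(self, k, lam):
        """Direct term-by-term summation at 60 decimal digits."""
        lam_s = sympy.Rational(lam)
        tail = 1 - sum(
            sympy.exp(-lam_s) * lam_s**i / sympy.factorial(i) for i in range(k)
        )
        assert poisson_tail(k, lam) == pytest.approx(float(tail.evalf(60)), abs=1e-12)

    def test_invalid_lambda(self):
        with pytest.raises(ValueError):
            poisson_tail(3, 0.0)


class TestBuildProfiles:
    def _pair(self, i):
        enh = GenomicInterval("chr1", 10_000 * (i + 1), 10_000 * (i + 1) + 300, ".", f"e{i}")
        prom = GenomicInterval("chr1", 10_000 * (i + 1) + 5_000, 10_000 * (i + 1) + 6_100, "+", f"g{i}")
        return EPPair(enh, prom, f"g{i}", 40.0, 5_000, "positive")

    def _occ(self, motif, seq_id):
        return MotifOccurrence(motif, seq_id, 0, "+", 10.0, 1e-5)

    def _seq_ids(self, pair):
        e = f"{pair.enhancer.chrom}:{pair.enhancer.start}-{pair.enhancer.end}(.)"
        p = f"{pair.promoter.chrom}:{pair.promoter.start}-{pair.promoter.end}(+)"
        return e, p

    def test_enhancer_only_hit(self):
        pair = self._pair(0)
        e_id, p_id = self._seq_ids(pair)
        occ = {e_id: [self._occ("M1", e_id)], p_id: []}
        (prof,) = build_profiles([pair], occ)
        assert prof.enh_motifs == {"M1"} and prof.prom_motifs == frozenset()

    def test_no_hits_empty_sets(self):
        pair = self._pair(0)
        e_id, p_id = self._seq_ids(pair)
        (prof,) = build_profiles([pair], {e_id: [], p_id: []})
        assert prof.enh_motifs == frozenset() == prof.prom_motifs

    def test_planted_pattern_count(self):
        """M1(enh)+M2(prom) planted in 2 of 3 pairs is seen in exactly 2 profiles."""
        pairs = [self._pair(i) for i in range(3)]
        occ = {}
        for i, pr in enumerate(pairs):
            e_id, p_id = self._seq_ids(pr)
            if i < 2:
                occ[e_id] = [self._occ("M1", e_id)]
                occ[p_id] = [self._occ("M2", p_id)]
            else:
                occ[e_id] = []
                occ[p_id] = []
        profs = build_profiles(pairs, occ)
        n = sum(1 for p in profs if "M1" in p.enh_motifs and "M2" in p.prom_motifs)
        assert n == 2

    def test_unscanned_pair_raises(self):
        pair = self._pair(0)
        with pytest.raises(KeyError, match="EP pair"):
            build_profiles([pair], {})


def brute_force_modules(profiles, min_support, max_size):
    """Oracle: enumerate every motif subset of size 2..max_size directly."""
    universe = sorted({m for p in profiles for m in p.all_motifs})
    out = {}
    for size in range(2, max_size + 1):
        for combo in itertools.combinations(universe, size):
            s = frozenset(combo)
            support = sum(1 for p in profiles if s <= p.all_motifs)
            if support >= min_support:
                out[s] = support
    return out


class TestFindModules:
    def test_apriori_equals_brute_force(self):
        """Level-wise enumeration matches exhaustive subset enumeration."""
        rng = np.random.default_rng(7)
        motifs = [f"M{i}" for i in range(10)]
        profiles = []
        for i in range(150):
            present = [m for m in motifs if rng.random() < 0.25]
            half = len(present) // 2
            profiles.append(profile(i, present[:half], present[half:]))
        got = find_modules(profiles, min_support=8, max_size=5, alpha=1.1)
        want = brute_force_modules(profiles, 8, 5)
        assert {m.motifs: m.support for m in got} == want

    def test_null_profiles_yield_no_modules(self):
        """Independent presence at 0.05 with min_support 30: nothing significant."""
        n_with_modules = 0
        for seed in range(15):
            rng = np.random.default_rng(seed)
            profiles = []
            for i in range(500):
                enh = {f"M{j}" for j in range(8) if rng.random() < 0.05}
                prom = {f"M{j}" for j in range(8) if rng.random() < 0.05}
                profiles.append(profile(i, enh, prom))
            if find_modules(profiles, min_support=30):
                n_with_modules += 1
        assert n_with_modules == 0

    def test_planted_module_reported(self):
        rng = np.random.default_rng(3)
        profiles = []
        for i in range(500):
            enh = {"M1"} if (planted := rng.random() < 0.4) else set()
            prom = {"M2"} if planted else set()
            if rng.random() < 0.05:
                enh = enh | {"M3"}
            profiles.append(profile(i, enh, prom))
        modules = find_modules(profiles, min_support=30)
        assert any(m.motifs == {"M1", "M2"} for m in modules)

    def test_min_support_above_n_empty(self):
        profiles = [profile(i, {"M1"}, {"M2"}) for i in range(10)]
        assert find_modules(profiles, min_support=11) == []


class TestExtractPairs:
    def test_forced_orientation(self):
        """M1 only in enhancers, M2 only in promoters: single oriented pair."""
        profiles = [profile(i, {"M1"}, {"M2"}) for i in range(40)]
        modules = [MotifModule(frozenset({"M1", "M2"}), 40, 1e-9)]
        pairs = extract_pairs(modules, profiles, min_support=30)
        assert [(p.motif_E, p.motif_P) for p in pairs] == [("M1", "M2")]
        assert pairs[0].support_k == 40
        assert pairs[0].lam == pytest.approx(40 * 40 / 40)

    def test_single_region_cooccurrence_dropped(self):
        """Both motifs only in enhancers: no cross-region pair is emitted."""
        profiles = [profile(i, {"M1", "M2"}, set()) for i in range(40)]
        modules = [MotifModule(frozenset({"M1", "M2"}), 40, 1e-9)]
        assert extract_pairs(modules, profiles, min_support=30) == []

    def test_support_matches_hand_count(self):
        profiles = (
            [profile(i, {"M1"}, {"M2"}) for i in range(35)]
            + [profile(100 + i, {"M1"}, set()) for i in range(10)]
            + [profile(200 + i, set(), {"M2"}) for i in range(5)]
        )
        modules = [MotifModule(frozenset({"M1", "M2"}), 35, 1e-9)]
        (pair,) = extract_pairs(modules, profiles, min_support=30)
        assert (pair.support_k, pair.a_count, pair.b_count, pair.N) == (35, 45, 40, 50)


class TestCorrectPvalues:
    def _pairs(self, pvals):
        return [
            MotifPair(f"E{i}", f"P{i}", 30, 30, 30, 100, 9.0, p)
            for i, p in enumerate(pvals)
        ]

    def test_bonferroni_arithmetic(self):
        out = correct_pvalues(self._pairs([1e-4] * 10), "bonferroni", alpha=0.01)
        assert all(p.pvalue_corrected == pytest.approx(1e-3) for p in out)
        assert all(p.significant for p in out)

    def test_single_pair_unchanged(self):
        (out,) = correct_pvalues(self._pairs([0.004]))
        assert out.pvalue_corrected == pytest.approx(0.004)

    def test_bh_matches_statsmodels(self):
        """BH step-up agrees with the statsmodels reference implementation."""
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        for _ in range(20):
            pvals = rng.uniform(size=rng.integers(2, 15)) ** 2
            ours = [p.pvalue_corrected for p in correct_pvalues(self._pairs(pvals), "bh")]
            _, ref, _, _ = multipletests(pvals, method="fdr_bh")
            assert np.allclose(ours, ref)


class TestNullCalibration:
    def test_raw_pvalues_not_anticonservative(self):
        """Under region-wise independence the fraction of oriented pairs with
        raw p < alpha stays within the Poisson-approximation band (<= 2*alpha)."""
        rng = np.random.default_rng(123)
        n_tests = 0
        n_sig = {0.01: 0, 0.05: 0}
        for _ in range(40):
            profiles = []
            for i in range(300):
                enh = {m for m in ("A", "B") if rng.random() < 0.4}
                prom = {m for m in ("A", "B") if rng.random() < 0.4}
                profiles.append(profile(i, enh, prom))
            modules = [MotifModule(frozenset({"A", "B"}), 1, 1.0)]
            for p in extract_pairs(modules, profiles, min_support=1):
                n_tests += 1
                for alpha in n_sig:
                    if p.pvalue < alpha:
                        n_sig[alpha] += 1
        assert n_tests > 0
        for alpha, count in n_sig.items():
            assert count / n_tests <= 2 * alpha + 0.02


def test_discover_pairs_recovers_planted_orientation():
    rng = np.random.default_rng(9)
    profiles = []
    for i in range(500):
        enh, prom = set(), set()
        if rng.random() < 0.4:
            enh.add("M1")
            prom.add("M2")
        for m in ("M1", "M2", "M3"):
            if rng.random() < 0.05:
                enh.add(m)
            if rng.random() < 0.05:
                prom.add(m)
        profiles.append(profile(i, enh, prom))
    pairs = discover_pairs(profiles)
    sig = {(p.motif_E, p.motif_P) for p in pairs if p.significant}
    assert ("M1", "M2") in sig
    assert ("M2", "M1") not in sig


class TestSharedMotifPairs:
    def _pair(self, me, mp):
        return MotifPair(me, mp, 40, 50, 50, 100, 25.0, 1e-9, 1e-8, True)

    def test_identical_names_shared_and_disjoint_not(self):
        from conftest import one_hot_pwm
        from epmotif.pair_discovery import shared_motif_pairs

        pwms = {
            "A": one_hot_pwm("A", "ACGTTGCAAC"),
            "B": one_hot_pwm("B", "AAAACCGGTT"),
            "C": one_hot_pwm("C", "GTGTGTACAC"),
            "D": one_hot_pwm("D", "CCCTTTAAAG"),
        }
        shared = shared_motif_pairs(
            [self._pair("A", "B")], [self._pair("A", "B")], pwms, pwms
        )
        assert len(shared) == 1
        disjoint = shared_motif_pairs(
            [self._pair("A", "B")], [self._pair("C", "D")], pwms, pwms,
            n_shuffles=200,
        )
        assert disjoint == []

    def test_similar_copies_shared_across_conditions(self):
        from conftest import one_hot_pwm
        from epmotif.pair_discovery import shared_motif_pairs
        from epmotif.motifs import PWM

        a = one_hot_pwm("mA", "ACGTTGCAAC")
        b = one_hot_pwm("mB", "AAAACCGGTT")
        pwms_a = {"mA": a, "mB": b}
        # condition B rediscovered the same motifs under different names
        pwms_b = {
            "other1": PWM("other1", a.probs, pseudocount=0.0),
            "other2": PWM("other2", b.probs, pseudocount=0.0),
        }
        # width-10 motifs: the calibrated tail bottoms out near 1e-7, so the
        # annotation-level cutoff is the right one to exercise the mechanism
        shared = shared_motif_pairs(
            [self._pair("mA", "mB")], [self._pair("other1", "other2")],
            pwms_a, pwms_b, evalue_cutoff=1e-5, n_shuffles=300,
        )
        assert len(shared) == 1
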