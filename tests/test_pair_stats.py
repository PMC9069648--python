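"""Exact tail primitives against rational oracles; homogeneous, preference,
and interaction-database enrichment tests."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest

from epmotif.pair_discovery import EPOccurrenceProfile
from epmotif.motifs import MotifOccurrence, SimilarityResult
from epmotif.pair_stats import (
    binom_upper_tail,
    homogeneous_test_v1,
    homogeneous_test_v2,
    hypergeom_enrichment,
    hypergeom_upper_tail,
    load_interaction_db,
    map_motifs_to_tfs,
    preference_test,
)


def binom_tail_fraction(n: int, N: int, p: Fraction) -> Fraction:
    """Exact rational oracle for the binomial upper tail."""
    return sum(
        Fraction(comb(N, i)) * p**i * (1 - p) ** (N - i) for i in range(n, N + 1)
    )


def hypergeom_tail_fraction(m: int, draws: int, M: int, universe: int) -> Fraction:
    """Exact rational oracle: P(X >= m) for draws from a finite universe."""
    total = Fraction(comb(universe, draws))
    return sum(
        Fraction(comb(M, k) * comb(universe - M, draws - k)) / total
        for k in range(m, min(draws, M) + 1)
    )


def profile(i, enh=(), prom=()):
    return EPOccurrenceProfile(f"ep{i}", frozenset(enh), frozenset(prom))


class TestBinomUpperTail:
    def test_n_zero_is_one(self):
        assert binom_upper_tail(0, 10, 0.3) == 1.0

    def test_all_successes_closed_form(self):
        assert binom_upper_tail(10, 10, 0.5) == pytest.approx(2**-10, abs=1e-15)

    @pytest.mark.parametrize(
        "n,N,p",
        [(7, 20, Fraction(1, 5)), (3, 12, Fraction(1, 2)), (1, 30, Fraction(1, 100)),
         (15, 30, Fraction(3, 4)), (30, 30, Fraction(9, 10))],
    )
    def test_matches_rational_oracle(self, n, N, p):
        exact = float(binom_tail_fraction(n, N, p))
        assert binom_upper_tail(n, N, float(p)) == pytest.approx(exact, abs=1e-12)

    def test_exhaustive_small_instances(self):
        """Agreement to 1e-12 on every instance with N <= 30 (coarse p grid)."""
        for N in (5, 13, 30):
            for p in (Fraction(1, 10), Fraction(1, 2), Fraction(17, 20)):
                for n in range(N + 1):
                    exact = float(binom_tail_fraction(n, N, p))
                    assert binom_upper_tail(n, N, float(p)) == pytest.approx(
                        exact, abs=1e-12
                    )

    def test_p_out_of_range(self):
        with pytest.raises(ValueError):
            binom_upper_tail(1, 10, 1.0)


class TestHypergeomTail:
    def test_m_zero_is_one(self):
        assert hypergeom_upper_tail(0, 6, 5, 45) == 1.0

    @pytest.mark.parametrize(
        "m,draws,M,universe",
        [(3, 6, 5, 45), (1, 10, 4, 30), (5, 5, 8, 28), (2, 12, 12, 28)],
    )
    def test_matches_rational_oracle(self, m, draws, M, universe):
        exact = float(hypergeom_tail_fraction(m, draws, M, universe))
        assert hypergeom_upper_tail(m, draws, M, universe) == pytest.approx(
            exact, abs=1e-12
        )

    def test_ten_tf_universe_by_enumeration(self):
        """10 TFs -> 45 pairs; M=5 interacting; 4 predicted TFs -> 6 drawn
        pairs with m=3 hits: matches direct enumeration over all C(45,6) draws
        (evaluated with the rational oracle, itself the enumeration identity)."""
        exact = float(hypergeom_tail_fraction(3, 6, 5, 45))
        assert hypergeom_upper_tail(3, 6, 5, 45) == pytest.approx(exact, abs=1e-12)


class TestHomogeneous:
    def _profiles_with_both(self, n_both, N):
        profs = [profile(i, {"M"}, {"M"}) for i in range(n_both)]
        profs += [profile(1000 + i) for i in range(N - n_both)]
        return profs

    def test_v1_example_against_oracle(self):
        """N=100 pairs, mean lengths 1100/300, x=280 occurrences -> p=0.002."""
        N, l1, l2, x, n = 100, 1100.0, 300.0, 280, 9
        profs = self._profiles_with_both(n, N)
        occ = {
            f"s{j}": [MotifOccurrence("M", f"s{j}", 0, "+", 5.0, 1e-5)]
            for j in range(x)
        }
        res = homogeneous_test_v1("M", profs, occ, K=10, l1=l1, l2=l2)
        assert res.p_success == pytest.approx(x / (N * (l1 + l2)))
        exact = float(binom_tail_fraction(n, N, Fraction(x, int(N * (l1 + l2)))))
        assert res.pvalue == pytest.approx(exact, rel=1e-9)
        assert res.significant == (res.pvalue < 0.01 / 10)

    def test_v1_no_carriers_pvalue_one(self):
        profs = self._profiles_with_both(0, 50)
        occ = {"s0": [MotifOccurrence("M", "s0", 0, "+", 5.0, 1e-5)]}
        res = homogeneous_test_v1("M", profs, occ, K=5, l1=1100, l2=300)
        assert res.pvalue == 1.0 and not res.significant

    def test_v1_degenerate_density_raises(self):
        profs = self._profiles_with_both(1, 2)
        occ = {
            f"s{j}": [MotifOccurrence("M", f"s{j}", 0, "+", 5.0, 1e-5)]
            for j in range(3000)
        }
        with pytest.raises(ValueError, match="degenerate"):
            homogeneous_test_v1("M", profs, occ, K=1, l1=1000, l2=200)

    def test_threshold_scales_with_k_not_pvalue(self):
        profs = self._profiles_with_both(9, 100)
        occ = {f"s{j}": [MotifOccurrence("M", f"s{j}", 0, "+", 5.0, 1e-5)] for j in range(280)}
        r1 = homogeneous_test_v1("M", profs, occ, K=1, l1=1100, l2=300)
        r2 = homogeneous_test_v1("M", profs, occ, K=2, l1=1100, l2=300)
        assert r1.pvalue == r2.pvalue
        # doubling K halves the threshold: significance can only be lost
        assert r1.significant or not r2.significant

    def test_v2_example_against_oracle(self):
        """x=50 enhancers, y=40 promoters of N=100; n=30 carriers vs null 20."""
        profs = (
            [profile(i, {"M"}, {"M"}) for i in range(30)]
            + [profile(100 + i, {"M"}, ()) for i in range(20)]
            + [profile(200 + i, (), {"M"}) for i in range(10)]
            + [profile(300 + i) for i in range(40)]
        )
        res = homogeneous_test_v2("M", profs, K=5)
        assert (res.x, res.y, res.n, res.N) == (50, 40, 30, 100)
        assert res.p_success == pytest.approx(0.2)
        exact = float(binom_tail_fraction(30, 100, Fraction(1, 5)))
        assert res.pvalue == pytest.approx(exact, rel=1e-9)

    def test_v2_everywhere_degenerate(self):
        profs = [profile(i, {"M"}, {"M"}) for i in range(10)]
        with pytest.raises(ValueError, match="degenerate"):
            homogeneous_test_v2("M", profs, K=1)

    def test_v2_at_null_expectation_midrange_pvalue(self):
        """n equal to the null mean x*y/N gives an unremarkable p-value."""
        n = 25  # x=y=50, N=100 -> expectation 25
        profs = (
            [profile(i, {"M"}, {"M"}) for i in range(n)]
            + [profile(100 + i, {"M"}, ()) for i in range(25)]
            + [profile(200 + i, (), {"M"}) for i in range(25)]
            + [profile(300 + i) for i in range(25)]
        )
        res = homogeneous_test_v2("M", profs, K=1)
        assert 0.3 < res.pvalue < 0.7

    def test_v2_null_calibration_superuniform(self):
        """Raw v2 p-values under i.i.d. presence: P(p < a) <= a + 0.02."""
        rng = np.random.default_rng(77)
        N, reps = 200, 1000
        pvals = []
        for _ in range(reps):
            enh = rng.random(N) < 0.3
            prom = rng.random(N) < 0.3
            profs = [
                profile(i, {"M"} if enh[i] else (), {"M"} if prom[i] else ())
                for i in range(N)
            ]
            pvals.append(homogeneous_test_v2("M", profs, K=1).pvalue)
        pvals = np.array(pvals)
        for alpha in (0.01, 0.05):
            assert (pvals < alpha).mean() <= alpha + 0.02


class TestPreference:
    def test_balanced_counts_symmetric(self):
        res = preference_test("M", 12, 12)
        assert res.pvalue_enh == pytest.approx(res.pvalue_prom)
        assert res.pvalue_enh >= 0.25

    def test_proportional_hits_with_length_null_not_significant(self):
        """Promoters 3x the enhancer length and hits split 3:1 accordingly."""
        res = preference_test("M", 25, 75, mean_lengths=(900.0, 300.0))
        assert res.p_success == pytest.approx(0.25)
        assert res.pvalue_enh > 0.05 and res.pvalue_prom > 0.05

    def test_all_hits_one_side_closed_form(self):
        e, p = 0, 12
        res = preference_test("M", e, p)
        assert res.pvalue_prom == pytest.approx(2.0 ** -(e + p), abs=1e-15)
        assert res.pvalue_enh == 1.0

    def test_count_only_matches_oracle(self):
        res = preference_test("M", 18, 7)
        exact = float(binom_tail_fraction(18, 25, Fraction(1, 2)))
        assert res.pvalue_enh == pytest.approx(exact, rel=1e-9)


class TestEnrichment:
    DB = {frozenset(p) for p in
          [("TF1", "TF2"), ("TF1", "TF3"), ("TF2", "TF3"), ("TF4", "TF5"), ("TF5", "TF6")]}
    TFS = {f"TF{i}" for i in range(1, 11)}  # 10 TFs -> universe of 45 pairs

    def test_no_hits_pvalue_one(self):
        res = hypergeom_enrichment([frozenset(("TF7", "TF8"))], self.DB, self.TFS)
        assert res.m_pairs == 0 and res.pvalue == 1.0

    def test_counts_and_oracle(self):
        predicted = [
            frozenset(("TF1", "TF2")), frozenset(("TF1", "TF3")),
            frozenset(("TF2", "TF3")), frozenset(("TF1", "TF4")),
        ]
        res = hypergeom_enrichment(predicted, self.DB, self.TFS)
        assert (res.N_tfs, res.M_pairs, res.n_tfs, res.m_pairs) == (10, 5, 4, 3)
        exact = float(hypergeom_tail_fraction(3, 6, 5, 45))
        assert res.pvalue == pytest.approx(exact, abs=1e-12)

    def test_unmapped_tfs_dropped(self):
        predicted = [frozenset(("TF1", "TF2")), frozenset(("TF1", "UNKNOWN"))]
        res = hypergeom_enrichment(predicted, self.DB, self.TFS)
        assert res.n_tfs == 2 and res.m_pairs == 1


class TestInteractionDb:
    def test_load_and_dedup_symmetric(self, tmp_path):
        f = tmp_path / "db.tsv"
        f.write_text(
            "#tf_a\ttf_b\ttype\n"
            "CTCF\tYY1\tdirect\n"
            "YY1\tCTCF\tdirect\n"     # symmetric duplicate
            "ctcf\tMAX\tindirect\n"   # case-normalized
        )
        direct, tfs_d = load_interaction_db(f, "direct")
        both, tfs_b = load_interaction_db(f, "direct_plus_indirect")
        assert direct == {frozenset(("CTCF", "YY1"))}
        assert both == {frozenset(("CTCF", "YY1")), frozenset(("CTCF", "MAX"))}
        assert tfs_b == {"CTCF", "YY1", "MAX"}

    def test_bad_type_raises(self, tmp_path):
        f = tmp_path / "db.tsv"
        f.write_text("A\tB\tphysical\n")
        with pytest.raises(ValueError, match="physical"):
            load_interaction_db(f)


class TestMapMotifsToTfs:
    SIMS = [
        SimilarityResult("m1", "lib_ctcf", 0, "same", 0.99, 1e-9),
        SimilarityResult("m1", "lib_ctcfl", 0, "same", 0.95, 1e-7),
        SimilarityResult("m2", "lib_yy1", 0, "same", 0.99, 1e-12),
        SimilarityResult("m3", "lib_max", 0, "same", 0.4, 0.2),
    ]
    TF_OF = {"lib_ctcf": "CTCF", "lib_ctcfl": "CTCFL", "lib_yy1": "YY1", "lib_max": "MAX"}

    def test_all_mode(self):
        m = map_motifs_to_tfs(["m1"], self.SIMS, self.TF_OF, mode="all")
        assert m["m1"] == {"CTCF", "CTCFL"}

    def test_best_mode_argmin(self):
        m = map_motifs_to_tfs(["m1"], self.SIMS, self.TF_OF, mode="best")
        assert m["m1"] == {"CTCF"}

    def test_no_match_empty(self):
        m = map_motifs_to_tfs(["m3"], self.SIMS, self.TF_OF, mode="all")
        assert m["m3"] == set()
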