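import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xrer import (
    CountTable2x2,
    fisher_burden,
    homogeneity_test,
    nested_regression_ftest,
    permutation_overlap,
    poisson_rate_test,
    poisson_regression_burden,
    sliding_window_scan,
    transmission_burden,
)


def hypergeom_tail_oracle(a, b, c, d):
    """P(X >= a) for the 2x2 margins, by direct enumeration (upper tail)."""
    r1, c1, n = a + c, a + b, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {x: stats.hypergeom.pmf(x, n, c1, r1) for x in range(lo, hi + 1)}
    return sum(p for x, p in probs.items() if x >= a)


class TestFisherBurden:
    def test_lgd_rer_vs_ner_worked_table(self):
        # 12/4 LGD in RER (cases/controls), 48/24 in NER
        res = fisher_burden(CountTable2x2(12, 48, 4, 24))
        assert res.odds_ratio == pytest.approx(1.49, abs=0.005)
        assert res.p_one_sided == pytest.approx(0.37, abs=0.005)

    def test_transmitted_untransmitted_worked_table(self):
        res = fisher_burden(CountTable2x2(155, 119, 698, 671))
        assert res.odds_ratio == pytest.approx(1.25, abs=0.005)

    def test_small_table_full_enumeration(self):
        # (2,1,1,2): upper tail P(X >= 2) = 0.5 by enumeration
        res = fisher_burden(CountTable2x2(2, 1, 1, 2))
        assert res.p_one_sided == pytest.approx(0.5)
        assert res.p_one_sided == pytest.approx(hypergeom_tail_oracle(2, 1, 1, 2))

    def test_matches_enumeration_on_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(60):
            a, b, c, d = rng.integers(0, 12, 4)
            if (a + b == 0) or (c + d == 0) or (a + b + c + d == 0):
                continue
            res = fisher_burden(CountTable2x2(int(a), int(b), int(c), int(d)))
            assert res.p_one_sided == pytest.approx(
                hypergeom_tail_oracle(a, b, c, d), abs=1e-10
            )

    def test_transposing_groups_inverts_odds_ratio(self):
        t = CountTable2x2(9, 17, 4, 21)
        res = fisher_burden(t)
        res_t = fisher_burden(t.transpose_groups())
        assert res_t.odds_ratio == pytest.approx(1.0 / res.odds_ratio, rel=1e-6)
        # the one-sided alternative maps accordingly: greater <-> less
        assert fisher_burden(t.transpose_groups(), alternative="less").p_one_sided \
            == pytest.approx(res.p_one_sided, abs=1e-10)

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            CountTable2x2(0, 0, 0, 0)

    def test_null_p_values_conservative_vs_uniform(self):
        # binomial-sampled null tables: one-sided p stochastically >= uniform
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(400):
            a = rng.binomial(30, 0.3)
            c = rng.binomial(30, 0.3)
            ps.append(fisher_burden(CountTable2x2(int(a), 30 - int(a),
                                                  int(c), 30 - int(c))).p_one_sided)
        ps = np.sort(ps)
        ecdf = np.arange(1, len(ps) + 1) / len(ps)
        assert np.max(ecdf - ps) < 0.06  # ECDF never far above the diagonal


class TestPoissonRateTest:
    def test_equal_rates(self):
        rr, ci, p = poisson_rate_test(50, 1000, 50, 1000)
        assert rr == pytest.approx(1.0)
        assert p >= 0.5

    def test_rate_ratio_arithmetic(self):
        rr, _, _ = poisson_rate_test(20, 100, 10, 100)
        assert rr == pytest.approx(2.0)

    def test_small_counts_match_conditional_binomial_oracle(self):
        for x1, n1, x2, n2 in [(5, 100, 2, 150), (3, 50, 3, 50), (8, 200, 1, 100)]:
            _, _, p = poisson_rate_test(x1, n1, x2, n2)
            p0 = n1 / (n1 + n2)
            oracle = sum(stats.binom.pmf(k, x1 + x2, p0) for k in range(x1, x1 + x2 + 1))
            assert p == pytest.approx(oracle, abs=1e-10)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            poisson_rate_test(1, 0, 1, 10)


class TestTransmissionBurden:
    def test_equal_transmission_gives_or_one(self):
        res = transmission_burden(50, 50, 200, 200)
        assert res.odds_ratio == pytest.approx(1.0, abs=0.01)

    def test_layout_matches_fisher_example(self):
        # same contrast as the worked transmitted/untransmitted table
        res = transmission_burden(155, 119, 698, 671)
        ref = fisher_burden(CountTable2x2(155, 698, 119, 671))
        assert res.odds_ratio == pytest.approx(ref.odds_ratio)
        assert res.p_one_sided == pytest.approx(ref.p_one_sided)


class TestPoissonRegression:
    def test_identical_rates_give_unit_rate_ratio(self):
        rng = np.random.default_rng(1)
        n = 400
        syn = rng.poisson(2.0, 2 * n) + 1
        dam = rng.poisson(0.5 * syn)
        phen = np.array(["control"] * n + ["case"] * n)
        res, dropped = poisson_regression_burden(dam, phen, syn)
        assert dropped == []
        row = res.iloc[0]
        assert row["ci_low"] < 1.0 < row["ci_high"]
        assert row["rate_ratio"] == pytest.approx(1.0, abs=0.15)

    def test_small_group_dropped(self):
        rng = np.random.default_rng(2)
        phen = np.array(["control"] * 200 + ["case"] * 200 + ["tiny"] * 99)
        syn = rng.poisson(2.0, len(phen)) + 1
        dam = rng.poisson(0.4 * syn)
        res, dropped = poisson_regression_burden(dam, phen, syn)
        assert dropped == ["tiny"]
        assert res["phenotype"].tolist() == ["case"]

    def test_recovers_planted_rate_ratio(self):
        rng = np.random.default_rng(3)
        cover = 0
        reps = 60
        for _ in range(reps):
            n = 1000
            syn = rng.poisson(2.0, 2 * n) + 1
            mult = np.array([1.0] * n + [1.7] * n)
            dam = rng.poisson(0.3 * syn * mult)
            phen = np.array(["control"] * n + ["case"] * n)
            res, _ = poisson_regression_burden(dam, phen, syn)
            row = res.iloc[0]
            if row["ci_low"] <= 1.7 <= row["ci_high"]:
                cover += 1
        assert cover / reps >= 0.9


class TestSlidingWindow:
    @staticmethod
    def _records(pos, transmitted, vclass="Mis3"):
        return pd.DataFrame({
            "pos": pos, "vclass": vclass,
            "transmission": np.where(transmitted, "transmitted", "untransmitted"),
        })

    def test_width_below_step_rejected(self):
        r = self._records([1], [True])
        with pytest.raises(ValueError):
            sliding_window_scan(r, r, (0, 10_000_000), width=10_000, step=20_000)

    def test_implanted_region_produces_flagged_run(self):
        rng = np.random.default_rng(4)
        span = (0, 30_000_000)
        pos_c = rng.uniform(*span, 3000)
        t_c = rng.uniform(size=3000) < np.where(
            (pos_c > 10e6) & (pos_c < 15e6), 0.65, 0.45
        )
        pos_t = rng.uniform(*span, 3000)
        t_t = rng.uniform(size=3000) < 0.45
        out = sliding_window_scan(self._records(pos_c, t_c), self._records(pos_t, t_t),
                                  span, width=5_000_000, step=500_000)
        flagged = out[out["flagged"]]
        assert len(flagged) > 0
        # flagged windows concentrate on the implanted region
        mid = (flagged["start"] + flagged["end"]) / 2
        assert ((mid > 7e6) & (mid < 18e6)).mean() > 0.5

    def test_empty_windows_skipped(self):
        r = self._records([1_000_000], [True])
        out = sliding_window_scan(r, r, (0, 40_000_000), width=5_000_000,
                                  step=5_000_000)
        assert out["start"].max() <= 1_000_000


class TestPermutationOverlap:
    universe = [f"g{i}" for i in range(808)]

    def test_identical_full_sets(self):
        u = set(self.universe)
        fold, p, obs = permutation_overlap(u, u, self.universe, n_perm=200, seed=0)
        assert fold == pytest.approx(1.0)
        assert p == 1.0
        assert obs == 808

    def test_disjoint_sets_below_expectation(self):
        a = set(self.universe[:149])
        b = set(self.universe[-149:])
        fold, _, _ = permutation_overlap(a, b, self.universe, n_perm=500, seed=1)
        assert fold < 1.0

    def test_matches_hypergeometric_tail(self):
        # 149-gene sets in a 808-gene universe with 50 shared
        a = set(self.universe[:149])
        b = set(self.universe[99:248])  # overlap 50
        fold, p, obs = permutation_overlap(a, b, self.universe, n_perm=20_000, seed=2)
        assert obs == 50
        expect_p = stats.hypergeom.sf(49, 808, 149, 149)
        assert p == pytest.approx(expect_p, abs=4 * np.sqrt(expect_p / 20_000) + 1e-4)
        assert fold == pytest.approx(50 / (149 * 149 / 808), rel=0.1)

    def test_sets_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            permutation_overlap({"zz"}, set(), self.universe, n_perm=100)


class TestNestedRegressionFtest:
    def test_duplicate_covariate_adds_nothing(self):
        rng = np.random.default_rng(5)
        sib = rng.poisson(2.0, 300).astype(float)
        y = sib * 0.8 + rng.normal(0, 0.5, 300)
        f, p = nested_regression_ftest(y, sib, np.exp(sib))  # log(exp(sib)) = sib
        assert f == pytest.approx(0.0, abs=1e-8)

    def test_planted_covariate_detected(self):
        rng = np.random.default_rng(6)
        sib = rng.poisson(2.0, 300).astype(float)
        rate = np.exp(rng.normal(0, 1, 300))
        y = sib * 0.5 + 2.0 * np.log(rate) + rng.normal(0, 0.5, 300)
        f, p = nested_regression_ftest(y, sib, rate)
        assert p < 0.01

    def test_null_covariate_p_roughly_uniform(self):
        rng = np.random.default_rng(7)
        ps = []
        for _ in range(60):
            sib = rng.poisson(2.0, 120).astype(float)
            y = sib * 0.5 + rng.normal(0, 1, 120)
            rate = np.exp(rng.normal(0, 1, 120))
            ps.append(nested_regression_ftest(y, sib, rate)[1])
        assert 0.2 < np.mean(ps) < 0.8
        assert np.mean(np.array(ps) < 0.05) < 0.2

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            nested_regression_ftest([1.0, 2.0], [1.0, 2.0], [1.0, 0.0])


class TestHomogeneity:
    def test_identical_tables_homogeneous(self):
        t = CountTable2x2(20, 80, 10, 90)
        chi2, p, df = homogeneity_test([t, t])
        assert p > 0.9
        assert df == 1

    def test_discordant_odds_ratios_detected(self):
        t1 = CountTable2x2(50, 450, 50, 450)    # OR 1
        t2 = CountTable2x2(100, 400, 20, 480)   # OR 6
        _, p, _ = homogeneity_test([t1, t2])
        assert p < 0.001

    def test_matches_statsmodels_on_nondegenerate_strata(self):
        import statsmodels.api as sm

        tables = [CountTable2x2(10, 20, 15, 30), CountTable2x2(12, 18, 7, 25),
                  CountTable2x2(30, 40, 22, 51)]
        chi2, p, _ = homogeneity_test(tables)
        st = sm.stats.StratifiedTable([t.as_array() for t in tables])
        ref = st.test_equal_odds()
        assert chi2 == pytest.approx(ref.statistic, rel=1e-6)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_degenerate_unit_odds_ratio_handled(self):
        # pooled OR exactly 1: some implementations return NaN here
        t = CountTable2x2(10, 20, 15, 30)
        chi2, p, _ = homogeneity_test([t, t])
        assert np.isfinite(chi2) and np.isfinite(p)

    def test_single_stratum_rejected(self):
        with pytest.raises(ValueError):
            homogeneity_test([CountTable2x2(1, 2, 3, 4)])
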