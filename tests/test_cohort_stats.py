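"""Group tests, RBS-R scoring, and predictive mean matching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from longicort.cohort_stats import (
    change_distribution_summary, chi2_2x2, group_comparison_table,
    pmm_impute, score_rbsr, welch_t_from_summary,
)


class TestWelch:
    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_direct_formula(self, seed):
        r = np.random.default_rng(seed)
        m1, m2 = r.normal(0, 10, 2)
        s1, s2 = r.uniform(0.5, 10, 2)
        n1, n2 = r.integers(2, 200, 2)
        res = welch_t_from_summary(m1, s1, int(n1), m2, s2, int(n2))
        t_direct = (m1 - m2) / np.sqrt(s1**2 / n1 + s2**2 / n2)
        v1, v2 = s1**2 / n1, s2**2 / n2
        df_direct = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        assert res.statistic == pytest.approx(t_direct, abs=1e-12)
        assert res.df == pytest.approx(df_direct, abs=1e-9)

    def test_identical_groups(self):
        res = welch_t_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert res.statistic == 0.0 and res.p == pytest.approx(1.0)

    def test_degenerate_variances_rejected(self):
        with pytest.raises(ValueError):
            welch_t_from_summary(1.0, 0.0, 10, 2.0, 0.0, 10)
        with pytest.raises(ValueError):
            welch_t_from_summary(1.0, 1.0, 1, 2.0, 1.0, 10)

    def test_pooled_option_uses_pooled_df(self):
        res = welch_t_from_summary(5.0, 2.0, 10, 4.0, 1.0, 15, pooled=True)
        assert res.df == 23 and res.family == "pooled-t"


class TestChi2:
    def test_yates_not_larger_than_plain(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(1, 40, 4)
            yates = chi2_2x2(a, b, c, d, continuity=True).statistic
            plain = chi2_2x2(a, b, c, d, continuity=False).statistic
            assert yates <= plain + 1e-12

    def test_proportional_rows_give_zero(self):
        assert chi2_2x2(10, 20, 20, 40, continuity=False).statistic == pytest.approx(0.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi2_2x2(0, 0, 5, 5)


class TestPmm:
    def test_complete_matrix_unchanged(self, rng):
        X = rng.integers(0, 4, (10, 5)).astype(float)
        assert np.array_equal(pmm_impute(X, k_donors=3, seed=0), X)

    def test_toy_nearest_donor(self):
        """Hand-checked: item0 = item1/2 exactly on complete cases, so the
        donor nearest to the prediction for (item1=4, item2=6) is subject 2."""
        X = np.array([[1.0, 2.0, 3.0],
                      [2.0, 4.0, 6.0],
                      [3.0, 6.0, 9.0],
                      [np.nan, 4.0, 6.0]])
        out = pmm_impute(X, k_donors=1, seed=0)
        assert out[3, 0] == 2.0
        assert np.array_equal(out[:3], X[:3])

    def test_imputed_values_in_observed_support(self, rng):
        X = rng.integers(0, 4, (30, 8)).astype(float)
        mask = rng.random(X.shape) < 0.05
        Xm = np.where(mask, np.nan, X)
        out = pmm_impute(Xm, k_donors=5, seed=1)
        for j in range(X.shape[1]):
            observed = set(Xm[~np.isnan(Xm[:, j]), j])
            assert set(out[:, j]) <= observed

    def test_seeded_determinism_and_locality(self, rng):
        X = rng.integers(0, 4, (20, 6)).astype(float)
        X[3, 2] = np.nan
        a = pmm_impute(X, seed=7)
        b = pmm_impute(X, seed=7)
        c = pmm_impute(X, seed=8)
        assert np.array_equal(a, b)
        diff = a != c
        assert not diff[~np.isnan(X) & ~np.isnan(c)].any()

    def test_insufficient_donors_named(self):
        X = np.array([[1.0, np.nan], [np.nan, 2.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="donors|complete"):
            pmm_impute(X, k_donors=5, seed=0)


class TestRbsrScoring:
    FACTOR_MAP = {1: "F1", 2: "F1", 3: "F2", 4: "F3", 5: "F4"}

    def test_toy_hand_sum(self):
        scores = score_rbsr([[1, 2, 0, 3, 1]], [[1, 2, 0, 3, 1]], self.FACTOR_MAP)
        assert scores.total_t1[0] == 7
        assert scores.factors_t1["F1"][0] == 3
        assert scores.factors_t1["F2"][0] == 0
        assert scores.factors_t1["F3"][0] == 3
        assert scores.factors_t1["F4"][0] == 1
        assert scores.delta_total[0] == 0

    def test_all_zero(self):
        s = score_rbsr(np.zeros((2, 5)), np.zeros((2, 5)), self.FACTOR_MAP)
        assert np.all(s.total_t1 == 0) and np.all(s.delta_total == 0)

    def test_delta_antisymmetric(self, rng):
        a = rng.integers(0, 4, (6, 5)).astype(float)
        b = rng.integers(0, 4, (6, 5)).astype(float)
        fwd = score_rbsr(a, b, self.FACTOR_MAP).delta_total
        rev = score_rbsr(b, a, self.FACTOR_MAP).delta_total
        assert np.array_equal(fwd, -rev)

    def test_incomplete_factor_map_rejected(self):
        with pytest.raises(ValueError, match="factor map"):
            score_rbsr(np.zeros((1, 5)), np.zeros((1, 5)), {1: "F1", 2: "F1"})

    def test_missing_items_rejected(self):
        x = np.zeros((1, 5))
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="impute"):
            score_rbsr(x, np.zeros((1, 5)), self.FACTOR_MAP)


class TestChangeDistribution:
    def test_enumerated_example(self):
        s = change_distribution_summary(np.array([-3.0, 0.0, 2.0]))
        assert s["fraction_decreased"] == pytest.approx(1 / 3)
        assert s["fraction_increased"] == pytest.approx(1 / 3)
        assert s["fraction_unchanged"] == pytest.approx(1 / 3)
        assert s["max_decrease"] == -3 and s["max_increase"] == 2

    def test_all_unchanged(self):
        s = change_distribution_summary(np.zeros(5))
        assert s["fraction_unchanged"] == 1.0

    def test_permutation_invariance(self, rng):
        d = rng.normal(size=20)
        assert change_distribution_summary(d) == change_distribution_summary(d[::-1])

    def test_fractions_sum_to_one(self, rng):
        s = change_distribution_summary(rng.integers(-5, 5, 50).astype(float))
        assert (s["fraction_decreased"] + s["fraction_increased"]
                + s["fraction_unchanged"]) == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            change_distribution_summary(np.array([]))


def test_group_comparison_table_runs_on_synthetic_cohort(small_mesh):
    from longicort import SimulationConfig, simulate_cohort
    from longicort.synthetic import DEFAULT_FACTOR_MAP

    co = simulate_cohort(SimulationConfig(seed=11, mesh_subdivisions=2), small_mesh)
    table = group_comparison_table(co.subjects, DEFAULT_FACTOR_MAP, seed=0)
    assert {"age_t1", "fsiq", "rbsr_total_t1"} <= set(table["measure"])
    rbsr = table.set_index("measure").loc["rbsr_total_t1"]
    assert rbsr["statistic"] > 3 and rbsr["p"] < 0.01
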