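import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

import specmammo as sm


def rank_with_mean_ties(values):
    """Independent mean-rank computation by explicit sorting (test oracle)."""
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def kruskal_oracle(groups):
    """Brute-force H: explicit joint ranking and the printed rank-sum formula."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    ranks = rank_with_mean_ties(pooled)
    n = len(pooled)
    h = 0.0
    start = 0
    for g in groups:
        t = ranks[start:start + len(g)].sum()
        h += t * t / len(g)
        start += len(g)
    return 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(10.0)
        assert sm.spearman_r(x, np.exp(x)) == pytest.approx(1.0)
        assert sm.spearman_r(x, -x**3) == pytest.approx(-1.0)

    def test_hand_ranked_example(self):
        assert sm.spearman_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            sm.spearman_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(st.permutations(list(range(8))))
    def test_invariant_under_monotone_transforms(self, perm):
        x = np.arange(8.0)
        y = np.asarray(perm, dtype=float)
        base = sm.spearman_r(x, y)
        assert sm.spearman_r(np.exp(x / 4), y) == pytest.approx(base, abs=1e-12)
        assert sm.spearman_r(x, 3.0 * y + 7.0) == pytest.approx(base, abs=1e-12)


class TestTFromR:
    def test_zero_correlation_gives_zero(self):
        assert sm.t_from_r(0.0, 20) == 0.0

    @pytest.mark.parametrize("r,n,expected", [(0.93, 23, 11.58), (0.89, 11, 5.87)])
    def test_tabulated_correlation_significance(self, r, n, expected):
        """t = r sqrt(n-2)/sqrt(1-r^2) reproduces the study's printed t values."""
        assert sm.t_from_r(r, n) == pytest.approx(expected, abs=0.05)

    def test_perfect_correlation_signals_infinity(self):
        assert math.isinf(sm.t_from_r(1.0, 10))
        assert sm.t_from_r(-1.0, 10) == -math.inf

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sm.t_from_r(0.5, 2)
        with pytest.raises(ValueError):
            sm.t_from_r(1.5, 10)

    @given(r=st.floats(-0.99, 0.99), n=st.integers(3, 200))
    def test_squared_identity(self, r, n):
        t = sm.t_from_r(r, n)
        assert t * t == pytest.approx((n - 2) * r * r / (1 - r * r), rel=1e-9)


class TestCriticalValues:
    @pytest.mark.parametrize("dist,alpha,df,expected", [
        ("t", 0.05, 21, 2.080),
        ("t", 0.05, 6, 2.447),
        ("t", 0.05, 9, 2.262),
        ("chi2", 0.05, 1, 3.84),
        ("chi2", 0.05, 2, 5.99),
    ])
    def test_tabulated_values(self, dist, alpha, df, expected):
        assert sm.critical_value(dist, alpha, df) == pytest.approx(expected, abs=5e-3)

    def test_t_decreases_towards_normal_limit(self):
        vals = [sm.critical_value("t", 0.05, df) for df in (5, 10, 50, 500, 5000)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(1.96, abs=0.005)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sm.critical_value("t", 1.5, 5)
        with pytest.raises(ValueError):
            sm.critical_value("normal", 0.05, 5)
        with pytest.raises(ValueError):
            sm.critical_value("chi2", 0.05, 0)


class TestKruskalWallis:
    def test_two_group_hand_example(self):
        assert sm.kruskal_wallis([[1, 2], [3, 4]]) == pytest.approx(2.4)

    def test_identical_groups_give_zero(self):
        assert sm.kruskal_wallis([[3, 1, 2], [2, 3, 1]]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle_on_random_groups(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            groups = [rng.integers(0, 8, size=rng.integers(3, 7)).astype(float)
                      for _ in range(rng.integers(2, 5))]
            assert sm.kruskal_wallis(groups) == pytest.approx(kruskal_oracle(groups), abs=1e-12)

    def test_tie_corrected_variant_matches_scipy(self):
        rng = np.random.default_rng(2)
        groups = [rng.integers(0, 5, 8).astype(float) for _ in range(3)]
        h = sm.kruskal_wallis(groups, tie_correction=True)
        assert h == pytest.approx(sps.kruskal(*groups).statistic, abs=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            sm.kruskal_wallis([[1, 2, 3]])


class TestRootFit:
    def test_exact_root_data(self):
        d = np.array([0.25, 1.0, 2.25, 4.0])
        series = sm.DoseCnrSeries("m", d, 2.0 * np.sqrt(d))
        assert sm.fit_root(series) == pytest.approx(2.0, rel=1e-12)

    def test_scale_equivariance(self):
        d = np.array([0.5, 1.0, 2.0, 3.0])
        c = np.array([3.0, 4.5, 6.0, 7.0])
        a1 = sm.fit_root(sm.DoseCnrSeries("m", d, c))
        a2 = sm.fit_root(sm.DoseCnrSeries("m", d, 2 * c))
        assert a2 == pytest.approx(2 * a1, rel=1e-12)

    def test_parameter_recovery_from_noisy_series(self):
        """a_true = 30, sigma = 1, 10 doses in [0.2, 4]: mean estimate within 30 +/- 0.5."""
        rng = np.random.default_rng(8)
        doses = np.linspace(0.2, 4.0, 10)
        est = []
        for _ in range(200):
            cnr = 30.0 * np.sqrt(doses) + rng.normal(0, 1, doses.size)
            est.append(sm.fit_root(sm.DoseCnrSeries("m", doses, cnr)))
        assert np.mean(est) == pytest.approx(30.0, abs=0.5)

    def test_intercept_variant_and_power_fit(self):
        d = np.array([0.5, 1.0, 2.0, 4.0])
        series = sm.DoseCnrSeries("m", d, 3.0 * np.sqrt(d) + 1.0)
        a, c = sm.fit_root_with_intercept(series)
        assert a == pytest.approx(3.0, rel=1e-9)
        assert c == pytest.approx(1.0, rel=1e-9)
        a_p, b_p = sm.fit_power(sm.DoseCnrSeries("m", d, 3.0 * d**0.5))
        assert (a_p, b_p) == (pytest.approx(3.0, rel=1e-9), pytest.approx(0.5, abs=1e-9))

    def test_degenerate_series_rejected(self):
        with pytest.raises(ValueError):
            sm.DoseCnrSeries("m", np.array([0.0, 1.0, 2.0]), np.ones(3))
        with pytest.raises(ValueError):
            sm.fit_root(sm.DoseCnrSeries("m", np.array([1.0, 2.0]), np.ones(2)))


class TestDoseAtCnr:
    def test_basic_intersection(self):
        assert sm.dose_at_cnr(2.0, 2.0) == pytest.approx(1.0)

    def test_matched_cnr_dose_ratio_is_target_independent(self):
        a1, a2 = 3.0, 3.0 * np.sqrt(2.5)
        for target in (5.0, 10.0, 40.0):
            ratio = sm.dose_at_cnr(a1, target) / sm.dose_at_cnr(a2, target)
            assert ratio == pytest.approx(2.5, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sm.dose_at_cnr(0.0, 5.0)
        with pytest.raises(ValueError):
            sm.dose_at_cnr(2.0, -1.0)


def test_analyze_series_decisions_are_consistent():
    rng = np.random.default_rng(3)
    doses = np.linspace(0.3, 3.0, 12)
    series = [
        sm.DoseCnrSeries("a", doses, 20 * np.sqrt(doses) + rng.normal(0, 0.5, 12)),
        sm.DoseCnrSeries("b", doses, 10 * np.sqrt(doses) + rng.normal(0, 0.5, 12)),
    ]
    rep = sm.analyze_series(series)
    for s in rep.series_stats:
        assert s.reject_null == (abs(s.t_calc) > s.t_crit)
        assert -1 <= s.r <= 1 and s.fit_a > 0
    assert rep.h is not None and rep.h >= 0
    assert rep.h_df == 1
    assert rep.h_reject_null == (rep.h > rep.chi2_crit)
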