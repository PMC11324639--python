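"""Repeatability statistics: exact oracles and Monte-Carlo behaviour."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from svperf.errors import (
    DegenerateRegressionError,
    InvalidParameterError,
    UndefinedCorrelationError,
)
from svperf.stats import (
    PairedData,
    analyze_pairs,
    bland_altman,
    paired_regression,
    rmse_rmsd,
    spearman_ci,
    wilcoxon_signed_rank,
)


def pairs(x, y):
    return PairedData(first=np.asarray(x, float), second=np.asarray(y, float))


def brute_force_wilcoxon_p(d):
    """Two-sided signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = d.size
    ws = np.array([sum(r for r, s in zip(ranks, signs) if s)
                   for signs in itertools.product((False, True), repeat=n)])
    cdf = np.mean(ws <= w_obs + 1e-9)
    sf = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(cdf, sf))


class TestPairedRegression:
    def test_identity_line(self):
        x = np.array([0.5, 0.9, 1.2, 1.7, 2.0])
        reg = paired_regression(pairs(x, x))
        assert reg.slope == pytest.approx(1.0, abs=1e-12)
        assert reg.intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_line_through_origin(self):
        reg = paired_regression(pairs([1, 2, 3], [2, 4, 6]))
        assert reg.slope == pytest.approx(2.0)
        assert reg.intercept == pytest.approx(0.0, abs=1e-12)

    def test_cis_match_statsmodels(self, rng):
        import statsmodels.api as sm

        x = rng.uniform(0.4, 2.2, 30)
        y = 0.9 * x + 0.1 + rng.normal(0, 0.2, 30)
        reg = paired_regression(pairs(x, y))
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        ci = ols.conf_int(alpha=0.05)
        assert reg.intercept_ci == pytest.approx(tuple(ci[0]), rel=1e-8)
        assert reg.slope_ci == pytest.approx(tuple(ci[1]), rel=1e-8)

    def test_constant_predictor_rejected(self):
        with pytest.raises(DegenerateRegressionError):
            paired_regression(pairs([1, 1, 1], [1, 2, 3]))

    def test_slope_recovery_simulation(self, rng):
        """Regional-regime sims (slope 0.86, noise 0.29, n=68): unbiased."""
        slopes = []
        for _ in range(300):
            x = rng.uniform(0.4, 2.2, 68)
            y = 0.86 * x + 0.13 + rng.normal(0, 0.29, 68)
            slopes.append(paired_regression(pairs(x, y)).slope)
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes) - 0.86) <= 2 * se


class TestSpearman:
    def test_monotone_sequences(self):
        rho, _ = spearman_ci(pairs([1, 2, 3, 4, 5], [2, 4, 9, 16, 30]))
        assert rho == pytest.approx(1.0)
        rho, _ = spearman_ci(pairs([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]))
        assert rho == pytest.approx(-1.0)

    def test_tied_data_matches_rank_formula(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
        y = np.array([1.5, 1.0, 2.5, 2.5, 4.0])
        rho, _ = spearman_ci(pairs(x, y))
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]  # Pearson on average ranks
        assert rho == pytest.approx(expected, rel=1e-12)

    def test_fisher_ci_brackets_rho(self, rng):
        x = rng.uniform(0, 1, 40)
        y = x + rng.normal(0, 0.3, 40)
        rho, (lo, hi) = spearman_ci(pairs(x, y))
        assert lo < rho < hi
        assert -1 <= lo and hi <= 1

    def test_all_tied_margin_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman_ci(pairs([1, 1, 1, 1], [1, 2, 3, 4]))


class TestRmseRmsd:
    def test_perfect_agreement(self):
        p = pairs([1, 2, 3, 4], [1, 2, 3, 4])
        reg = paired_regression(p)
        rmse, rmsd = rmse_rmsd(p, reg)
        assert rmse == pytest.approx(0.0, abs=1e-12)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_rmsd(self):
        # d = (0,0,0,1): rmsd = sqrt(1/8)
        p = pairs([0, 1, 2, 3], [0, 1, 2, 4])
        _, rmsd = rmse_rmsd(p, paired_regression(p))
        assert rmsd == pytest.approx(np.sqrt(1 / 8))

    def test_rmse_equals_residual_definition(self, rng):
        x = rng.uniform(0, 2, 25)
        y = x + rng.normal(0, 0.3, 25)
        p = pairs(x, y)
        reg = paired_regression(p)
        rmse, _ = rmse_rmsd(p, reg)
        resid = y - (reg.slope * x + reg.intercept)
        assert rmse == pytest.approx(np.sqrt(np.mean(resid ** 2)), rel=1e-12)


class TestBlandAltman:
    def test_identical_pairs(self):
        bias, lo, hi = bland_altman(pairs([1, 2, 3], [1, 2, 3]))
        assert bias == lo == hi == 0.0

    def test_two_point_arithmetic(self):
        # d = (-1, +1, 0): sd = 1, limits at +/-1.96
        bias, lo, hi = bland_altman(pairs([1.0, 2.0, 3.0], [0.0, 3.0, 3.0]))
        assert bias == pytest.approx(0.0)
        assert hi == pytest.approx(1.96)
        assert lo == pytest.approx(-1.96)

    def test_limits_widen_with_noise(self, rng):
        widths = []
        for sd in (0.05, 0.1, 0.2, 0.4):
            x = rng.uniform(0.5, 2, 200)
            y = x + rng.normal(0, sd, 200)
            _, lo, hi = bland_altman(pairs(x, y))
            widths.append(hi - lo)
        assert all(b > a for a, b in zip(widths, widths[1:]))

    def test_loa_coverage_near_95_percent(self, rng):
        """d ~ N(0.05, 0.1^2), n=34: LoA cover ~95% of the population."""
        cover = []
        for _ in range(500):
            d = rng.normal(0.05, 0.1, 34)
            x = rng.uniform(0.5, 2, 34)
            _, lo, hi = bland_altman(pairs(x, x + d))
            cover.append(sps.norm.cdf(hi, 0.05, 0.1) - sps.norm.cdf(lo, 0.05, 0.1))
        assert np.mean(cover) == pytest.approx(0.95, abs=0.02)


class TestWilcoxon:
    def test_all_positive_n6_exact(self):
        p = pairs([0, 0, 0, 0, 0, 0], [1, 2, 3, 4, 5, 6])
        assert wilcoxon_signed_rank(p) == pytest.approx(2 / 64)

    def test_symmetric_differences_give_large_p(self):
        p = pairs([0, 0, 0, 0, 0, 0], [-3, -2, -1, 1, 2, 3])
        assert wilcoxon_signed_rank(p) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_exact_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        d = np.round(rng.normal(0.1, 1.0, n), 2)
        d[d == 0] = 0.01
        p = pairs(np.zeros(n), d)
        assert wilcoxon_signed_rank(p) == pytest.approx(brute_force_wilcoxon_p(d),
                                                        rel=1e-12)

    def test_exact_matches_scipy_without_ties(self, rng):
        d = rng.normal(0.2, 1.0, 15)
        assert np.unique(np.abs(d)).size == d.size
        ours = wilcoxon_signed_rank(pairs(np.zeros(15), d))
        ref = sps.wilcoxon(d, method="exact").pvalue
        assert ours == pytest.approx(ref, rel=1e-10)

    def test_zero_differences_dropped(self):
        d = np.array([0.0, 0.0, 1.0, 2.0, 3.0, -1.5, 2.5])
        ours = wilcoxon_signed_rank(pairs(np.zeros(7), d))
        ref = wilcoxon_signed_rank(pairs(np.zeros(5), d[d != 0]))
        assert ours == ref

    def test_all_zero_differences_warns_p1(self):
        with pytest.warns(RuntimeWarning):
            p = wilcoxon_signed_rank(pairs([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]))
        assert p == 1.0

    def test_too_few_nonzero_rejected(self):
        with pytest.raises(InvalidParameterError):
            wilcoxon_signed_rank(pairs([0, 0, 0], [1, 2, 3]))

    def test_large_n_approximation_close_to_exact(self, rng):
        """Normal approximation at n=26 tracks the exact DP at n=25."""
        d = rng.normal(0.15, 1.0, 26)
        approx_p = wilcoxon_signed_rank(pairs(np.zeros(26), d))
        exact_p = wilcoxon_signed_rank(pairs(np.zeros(26), d), exact_max_n=30)
        assert approx_p == pytest.approx(exact_p, abs=0.02)

    def test_type_one_error_calibrated(self, rng):
        """Symmetric null at n=34: rejection rate at alpha=.05 in [.04, .06]."""
        rejections = 0
        n_rep = 4000
        for _ in range(n_rep):
            d = rng.normal(0.0, 1.0, 34)
            if wilcoxon_signed_rank(pairs(np.zeros(34), d)) < 0.05:
                rejections += 1
        assert 0.04 <= rejections / n_rep <= 0.06


def test_analyze_pairs_composes_all_statistics(rng):
    x = rng.uniform(0.5, 2.0, 40)
    y = 1.01 * x - 0.03 + rng.normal(0, 0.08, 40)
    res = analyze_pairs(pairs(x, y))
    assert res.loa_low <= res.bias <= res.loa_high
    assert -1 <= res.spearman_rho <= 1
    assert res.rmse >= 0 and res.rmsd >= 0
    assert res.n == 40
    d = res.to_dict()
    assert set(d) >= {"slope", "intercept", "spearman_rho", "wilcoxon_p"}
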