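"""Liability-threshold machinery: thresholds, bivariate tails, tetrachorics, ACE."""

import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import multivariate_normal, norm

from twinliab import (bvn_upper_tail, fit_ace, model_concordance,
                      tetrachoric_from_concordance, threshold_from_risk)


def test_threshold_examples():
    assert threshold_from_risk(0.5) == pytest.approx(0.0, abs=1e-12)
    assert threshold_from_risk(0.01) == pytest.approx(2.3263, abs=1e-4)
    # monotone increasing as K -> 0
    ks = [0.2, 0.1, 0.01, 0.001]
    ts = [threshold_from_risk(k) for k in ks]
    assert all(a < b for a, b in zip(ts, ts[1:]))
    with pytest.raises(ValueError):
        threshold_from_risk(1.5)


def test_bvn_independence_factorisation():
    for t1, t2 in [(0.3, -1.2), (2.0, 2.0), (-0.5, 0.9)]:
        assert bvn_upper_tail(t1, t2, 0.0) == \
            pytest.approx(norm.sf(t1) * norm.sf(t2), abs=1e-14)


def test_bvn_orthant_identity():
    for r in np.arange(-0.9, 0.95, 0.1):
        want = 0.25 + math.asin(r) / (2 * math.pi)
        assert bvn_upper_tail(0.0, 0.0, r) == pytest.approx(want, abs=1e-10)


def test_bvn_perfect_correlation_collapses_to_univariate():
    for t in (-1.0, 0.0, 1.5, 2.5):
        assert bvn_upper_tail(t, t, 1.0) == pytest.approx(norm.sf(t), abs=1e-14)
    assert bvn_upper_tail(0.0, 0.0, -1.0) == pytest.approx(0.0, abs=1e-14)


def test_bvn_against_scipy_mvn_cross_check():
    rng = np.random.default_rng(0)
    for _ in range(25):
        t1, t2 = rng.uniform(-2.5, 3.0, 2)
        r = rng.uniform(-0.95, 0.98)
        want = multivariate_normal.cdf([-t1, -t2], cov=[[1, r], [r, 1]],
                                       abseps=1e-12, releps=1e-12)
        assert bvn_upper_tail(t1, t2, r) == pytest.approx(want, abs=5e-9)


def test_bvn_brute_force_quadrature_on_grid():
    """Independent 2-D quadrature oracle agreement to 1e-8 (small grid here;
    the full grid runs in the acceptance suite)."""
    def oracle(t1, t2, r):
        det = 1 - r * r
        f = lambda y, x: math.exp(-(x * x - 2 * r * x * y + y * y) / (2 * det)) \
            / (2 * math.pi * math.sqrt(det))
        val, _ = integrate.dblquad(f, t1, t1 + 12, t2, t2 + 12,
                                   epsabs=1e-12, epsrel=1e-11)
        return val
    for t in (-1.0, 0.5, 2.33):
        for r in (-0.6, 0.0, 0.8):
            assert bvn_upper_tail(t, t, r) == pytest.approx(oracle(t, t, r),
                                                            abs=1e-8)


def test_model_concordance_identity_at_zero_correlation():
    for K in (0.005, 0.05, 0.2):
        assert model_concordance(0.0, K) == pytest.approx(K, abs=1e-12)


def test_model_concordance_strictly_increasing_in_r():
    # full correlation range at a common risk; at rare-disease thresholds the
    # far-negative tail underflows double precision, so start nearer zero
    for K, r_lo in ((0.2, -0.99), (0.01, -0.3)):
        grid = np.linspace(r_lo, 0.999, 34)
        vals = [model_concordance(r, K) for r in grid]
        assert all(a < b for a, b in zip(vals, vals[1:]))


def test_tetrachoric_trivial_cases():
    # co-twin risk equals population risk => independence
    fit = tetrachoric_from_concordance(100, 10000, K=0.01)
    assert abs(fit.r_hat) < 0.02
    # all concordant => boundary at r = 1
    fit = tetrachoric_from_concordance(20, 20, K=0.01)
    assert fit.r_hat == 1.0 and fit.boundary
    with pytest.raises(ValueError):
        tetrachoric_from_concordance(1, 0, K=0.01)


def test_tetrachoric_round_trip_self_inversion():
    K = 0.01
    c = model_concordance(0.8, K)
    n = 10000
    fit = tetrachoric_from_concordance(round(n * c), n, K)
    assert fit.r_hat == pytest.approx(0.8, abs=0.01)


def test_tetrachoric_zero_concordant_lower_limit_not_applicable():
    fit = tetrachoric_from_concordance(0, 8, K=0.03)
    assert fit.ci_low is None
    assert fit.ci_low_label == "not applicable"
    assert fit.r_hat < 0  # likelihood favours negative correlation at 0/8


def test_profile_ci_contains_estimate_and_tightens_with_n():
    K = 0.02
    c = model_concordance(0.5, K)
    widths = []
    for n in (50, 500, 5000):
        fit = tetrachoric_from_concordance(round(n * c), n, K)
        assert fit.ci_low < fit.r_hat < fit.ci_high
        widths.append(fit.ci_high - fit.ci_low)
    assert widths[0] > widths[1] > widths[2]


def _grid_search_ace(mz, dz, K, step=0.005):
    """Independent dense-grid maximiser of the same joint likelihood, with
    the concordance curve computed by scipy's bivariate-normal CDF."""
    t = norm.isf(K)
    rs = np.arange(0.0, 0.9975 + step / 2, step / 2)
    cs = np.array([multivariate_normal.cdf([-t, -t], cov=[[1, r], [r, 1]],
                                           abseps=1e-10, releps=1e-10) / K
                   for r in rs])
    cs = np.clip(cs, 1e-12, 1 - 1e-12)

    def ll_of(ridx, k, n):
        return k * np.log(cs[ridx]) + (n - k) * np.log(1 - cs[ridx])

    best, arg = -np.inf, (0.0, 0.0)
    a_vals = np.arange(0.0, 0.9975 + step / 2, step)
    for i, a in enumerate(a_vals):
        c_vals = np.arange(0.0, 0.9975 - a + step / 2, step)
        for c in c_vals:
            if a + c > 0.9975 + 1e-9:
                continue
            i_mz = round((a + c) / (step / 2))
            i_dz = round((0.5 * a + c) / (step / 2))
            ll = ll_of(i_mz, *mz) + ll_of(i_dz, *dz)
            if ll > best:
                best, arg = ll, (a, c)
    return arg


def test_fit_ace_matches_dense_grid_search():
    rng = np.random.default_rng(5)
    for _ in range(20):
        K = rng.uniform(0.005, 0.2)
        r_mz = rng.uniform(0.1, 0.95)
        r_dz = rng.uniform(0.3, 1.0) * r_mz
        n_mz, n_dz = rng.integers(20, 400, 2)
        k_mz = rng.binomial(n_mz, model_concordance(r_mz, K))
        k_dz = rng.binomial(n_dz, model_concordance(r_dz, K))
        est = fit_ace((k_mz, n_mz), (k_dz, n_dz), K)
        a_grid, c_grid = _grid_search_ace((k_mz, n_mz), (k_dz, n_dz), K)
        assert est.a2 == pytest.approx(a_grid, abs=0.01)
        assert est.c2 == pytest.approx(c_grid, abs=0.01)


def test_ace_boundary_zero_concordant_mz():
    for K in (0.005, 0.02, 0.05):
        est = fit_ace((0, 8), (0, 15), K)
        assert est.a2 == 0.0 and est.c2 == 0.0 and est.e2 == 1.0
        assert est.boundary


def test_ace_no_familial_aggregation():
    # both concordances equal K => no aggregation to explain
    K = 0.05
    c = model_concordance(0.0, K)
    est = fit_ace((round(2000 * c), 2000), (round(2000 * c), 2000), K)
    assert est.a2 == pytest.approx(0.0, abs=1e-3)
    assert est.c2 == pytest.approx(0.0, abs=1e-3)


def test_ace_equal_correlations_attributed_to_shared_environment():
    """When MZ and DZ implied correlations are equal, only c2 explains it."""
    K = 0.05
    c = model_concordance(0.4, K)
    n = 50000
    est = fit_ace((round(n * c), n), (round(n * c), n), K)
    assert est.a2 == pytest.approx(0.0, abs=5e-3)
    assert est.c2 == pytest.approx(0.4, abs=5e-3)


def test_ace_implied_correlation_ordering_and_cis_contain_estimates():
    est = fit_ace((40, 100), (10, 100), 0.01)
    assert est.r_mz_implied >= est.r_dz_implied
    assert est.a2_ci[0] <= est.a2 <= est.a2_ci[1]
    assert est.c2_ci[0] <= est.c2 <= est.c2_ci[1]
    assert est.a2 + est.c2 + est.e2 == pytest.approx(1.0, abs=1e-12)
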