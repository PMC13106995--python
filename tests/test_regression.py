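"""Logistic and mixed logistic regression, and Benjamini-Hochberg FDR."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from statsmodels.stats.multitest import multipletests

from twinliab import SeparationError, bh_fdr, fit_logistic, fit_logistic_glmm
from twinliab.regression import build_concordance_design


def two_by_two(n11, n10, n01, n00):
    """Outcome/predictor data for a saturated 2x2 logistic model."""
    y = np.r_[np.ones(n11), np.zeros(n10), np.ones(n01), np.zeros(n00)]
    x = np.r_[np.ones(n11 + n10), np.zeros(n01 + n00)]
    return y, pd.DataFrame({"intercept": 1.0, "x": x})


def test_saturated_two_by_two_equals_cross_product_ratio():
    y, X = two_by_two(11, 6, 1, 15)
    res = fit_logistic(y, X)
    assert res.odds_ratios[1] == pytest.approx((11 / 6) / (1 / 15), rel=1e-8)


def test_null_association_gives_unit_odds_ratio():
    y, X = two_by_two(30, 70, 30, 70)
    res = fit_logistic(y, X)
    assert res.odds_ratios[1] == pytest.approx(1.0, abs=1e-8)
    assert res.or_ci[1, 0] < 1.0 < res.or_ci[1, 1]


def test_constant_outcome_is_degenerate_error():
    y = np.ones(20)
    X = pd.DataFrame({"intercept": 1.0, "x": np.r_[np.ones(10), np.zeros(10)]})
    with pytest.raises(ValueError, match="degenerate"):
        fit_logistic(y, X)


def test_complete_separation_raises_naming_column():
    import warnings

    x = np.r_[np.ones(15), np.zeros(15)]
    y = x.copy()
    X = pd.DataFrame({"intercept": 1.0, "sep_col": x})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels also flags the divergence
        with pytest.raises(SeparationError, match="sep_col"):
            fit_logistic(y, X)


def test_rank_deficient_design_raises():
    y = np.r_[np.ones(5), np.zeros(5)]
    X = pd.DataFrame({"intercept": 1.0, "a": np.arange(10.0),
                      "b": 2 * np.arange(10.0)})
    with pytest.raises(ValueError, match="rank deficient"):
        fit_logistic(y, X)


def _grid_mle_2param(y, X, span=6.0, step=1e-3):
    """Brute-force likelihood maximisation for intercept+slope models."""
    b0 = np.arange(-span, span, step * 20)
    b1 = np.arange(-span, span, step * 20)
    eta = X.iloc[:, 0].to_numpy()[:, None, None] * b0[None, :, None] + \
        X.iloc[:, 1].to_numpy()[:, None, None] * b1[None, None, :]
    ll = (y[:, None, None] * eta - np.logaddexp(0, eta)).sum(axis=0)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    # refine around the coarse optimum at the requested step
    b0f = np.arange(b0[i] - 0.05, b0[i] + 0.05, step)
    b1f = np.arange(b1[j] - 0.05, b1[j] + 0.05, step)
    eta = X.iloc[:, 0].to_numpy()[:, None, None] * b0f[None, :, None] + \
        X.iloc[:, 1].to_numpy()[:, None, None] * b1f[None, None, :]
    ll = (y[:, None, None] * eta - np.logaddexp(0, eta)).sum(axis=0)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    return np.array([b0f[i], b1f[j]])


def test_irls_matches_grid_search_mle():
    rng = np.random.default_rng(3)
    for _ in range(10):
        n = 60
        x = rng.normal(size=n)
        beta = rng.uniform(-1.5, 1.5, 2)
        y = (rng.random(n) < expit(beta[0] + beta[1] * x)).astype(float)
        if len(np.unique(y)) < 2:
            continue
        X = pd.DataFrame({"intercept": 1.0, "x": x})
        res = fit_logistic(y, X)
        grid = _grid_mle_2param(y, X)
        assert np.abs(res.params - grid).max() < 2e-3


def _paired_dataset(rng, n_pairs=400, sigma=0.0, beta=(-0.5, 1.0)):
    mz = (rng.random(n_pairs) < 0.5).astype(float)
    u = rng.normal(0, sigma, n_pairs)
    eta = beta[0] + beta[1] * mz[:, None] + u[:, None] + np.zeros((n_pairs, 2))
    y = (rng.random((n_pairs, 2)) < expit(eta)).astype(float).ravel()
    X = pd.DataFrame({"intercept": 1.0, "mz": np.repeat(mz, 2)})
    groups = {"pair": np.repeat(np.arange(n_pairs), 2)}
    return y, X, groups


def test_glmm_zero_true_variance_matches_plain_logistic(rng):
    y, X, groups = _paired_dataset(rng, sigma=0.0)
    mixed = fit_logistic_glmm(y, X, groups, nodes=21)
    plain = fit_logistic(y, X)
    assert np.abs(mixed.params - plain.params).max() < 1e-4
    assert mixed.re_var["pair"] < 0.01


def test_glmm_single_group_variance_shrinks_to_boundary(rng):
    y, X, _ = _paired_dataset(rng, sigma=0.0, n_pairs=300)
    res = fit_logistic_glmm(y, X, {"sample": np.zeros(len(y), dtype=int)},
                            nodes=21)
    plain = fit_logistic(y, X)
    assert res.re_var["sample"] < 0.05
    assert np.abs(res.params - plain.params).max() < 1e-2


def test_glmm_parameter_recovery_over_seeds():
    """True zygosity log-OR 2.0 with pair variance 1.0: mean estimate close."""
    estimates = []
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        y, X, groups = _paired_dataset(rng, n_pairs=1000, sigma=1.0,
                                       beta=(-1.0, 2.0))
        res = fit_logistic_glmm(y, X, groups, nodes=21)
        estimates.append(res.params[1])
    assert abs(np.mean(estimates) - 2.0) < 0.25


def test_glmm_quadrature_stability_21_vs_51_nodes(rng):
    y, X, groups = _paired_dataset(rng, n_pairs=200, sigma=0.8)
    a = fit_logistic_glmm(y, X, groups, nodes=21)
    b = fit_logistic_glmm(y, X, groups, nodes=51)
    assert abs(a.loglik - b.loglik) < 1e-4
    assert np.abs(a.params - b.params).max() < 1e-3


def test_glmm_matches_lme4_glmer():
    """Independent cross-check of the adaptive-quadrature fit against lme4."""
    rng = np.random.default_rng(12)
    y, X, groups = _paired_dataset(rng, n_pairs=300, sigma=0.8,
                                   beta=(-0.8, 1.2))
    res = fit_logistic_glmm(y, X, groups, nodes=25)
    df = pd.DataFrame({"y": y, "mz": X["mz"], "pair": groups["pair"]})
    csv = df.to_csv(index=False)
    script = textwrap.dedent("""
        suppressMessages(library(lme4))
        d <- read.csv("stdin")
        m <- glmer(y ~ mz + (1 | pair), data = d, family = binomial, nAGQ = 25)
        cat(fixef(m), sqrt(unlist(VarCorr(m))), logLik(m), sep = "\\n")
    """)
    out = subprocess.run(["Rscript", "-e", script], input=csv, text=True,
                         capture_output=True, check=True)
    vals = [float(v) for v in out.stdout.strip().splitlines()[-4:]]
    assert res.params[0] == pytest.approx(vals[0], abs=2e-3)
    assert res.params[1] == pytest.approx(vals[1], abs=2e-3)
    assert np.sqrt(res.re_var["pair"]) == pytest.approx(vals[2], abs=5e-3)
    assert res.loglik == pytest.approx(vals[3], abs=1e-3)


def test_nested_random_effects_sample_and_pair(rng):
    n_samples, pairs_per = 4, 150
    n_pairs = n_samples * pairs_per
    sample = np.repeat(np.arange(n_samples), pairs_per)
    v = rng.normal(0, 0.6, n_samples)[sample]
    u = rng.normal(0, 0.8, n_pairs)
    mz = (rng.random(n_pairs) < 0.5).astype(float)
    eta = -0.5 + 1.0 * mz[:, None] + (v + u)[:, None] + np.zeros((n_pairs, 2))
    y = (rng.random((n_pairs, 2)) < expit(eta)).astype(float).ravel()
    X = pd.DataFrame({"intercept": 1.0, "mz": np.repeat(mz, 2)})
    groups = {"sample": np.repeat(sample, 2),
              "pair": np.repeat(np.arange(n_pairs), 2)}
    res = fit_logistic_glmm(y, X, groups, nodes=11)
    assert res.converged
    assert abs(res.params[1] - 1.0) < 0.4
    assert 0.0 <= res.re_var["sample"] < 4.0
    assert 0.05 < res.re_var["pair"] < 4.0


def brute_force_bh(p, q):
    """Step-up by explicit rank scan."""
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for rank in range(1, m + 1):
        if p[order[rank - 1]] <= q * rank / m:
            k_star = rank
    rejected = np.zeros(m, dtype=bool)
    rejected[order[:k_star]] = True
    return rejected


def test_bh_fdr_paper_style_four_phenotypes():
    """p = .016 and .043 do not survive FDR over four correlated phenotypes."""
    res = bh_fdr([0.016, 0.043, 0.2, 0.8], q=0.05)
    assert not res.rejected.any()
    assert res.adjusted[0] == pytest.approx(0.064, abs=1e-9)


def test_bh_fdr_trivial_cases():
    assert bh_fdr([0.04], q=0.05).rejected.all()
    assert bh_fdr([0.0, 0.0, 0.0], q=0.05).rejected.all()
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.2])


def test_bh_fdr_matches_brute_force_and_statsmodels(rng):
    for _ in range(300):
        m = int(rng.integers(1, 25))
        p = rng.random(m) ** rng.uniform(0.5, 3.0)
        res = bh_fdr(p, q=0.05)
        assert np.array_equal(res.rejected, brute_force_bh(p, 0.05))
        sm_rej, sm_adj, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.array_equal(res.rejected, sm_rej)
        assert np.allclose(res.adjusted, sm_adj)
        # never rejects a raw p above q; Bonferroni subset of BH
        assert (res.pvalues[res.rejected] <= 0.05).all()
        bonf = p <= 0.05 / m
        assert (~res.rejected[bonf]).sum() == 0
        # adjusted p monotone in raw-p rank order
        order = np.argsort(p)
        assert (np.diff(res.adjusted[order]) >= -1e-15).all()


def test_build_concordance_design_coding():
    units = pd.DataFrame({
        "cotwin_sex": ["M", "F", "M"],
        "cotwin_age_last_info": [30.0, 50.0, 40.0]})
    X = build_concordance_design(units, {"z": np.array([1.0, 0.0, 1.0])})
    assert list(X.columns) == ["intercept", "cotwin_male",
                               "cotwin_age_decades", "z"]
    assert X["cotwin_male"].tolist() == [1.0, 0.0, 1.0]
    assert X["cotwin_age_decades"].tolist() == [-1.0, 1.0, 0.0]
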