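"""Logistic and random-intercept mixed logistic regression, plus BH-FDR.

Concordance regressions model the co-twin's syndrome status (one row per
proband unit) on predictors such as zygosity or the proband's subsyndrome,
adjusted for co-twin sex and age at last information.  Because doubly
ascertained pairs contribute two correlated units, the twin pair enters as
a random intercept; when several samples are pooled, sample is a second
random intercept with pairs nested inside samples (pairs never span
samples).

The mixed-model marginal likelihood integrates the random intercepts out by
adaptive Gauss-Hermite quadrature: each group's integrand is re-centred at
its posterior mode and scaled by the local curvature before applying the
Gauss-Hermite rule, which keeps a modest node count accurate even for
groups with strong data.  One node reproduces the Laplace approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial.hermite import hermgauss
from scipy import optimize
from scipy.special import expit, logsumexp
from scipy.stats import norm

log = logging.getLogger("twinliab")

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: the MLE does not exist."""


@dataclass
class RegressionResult:
    names: list[str]
    params: np.ndarray            # log-odds scale
    se: np.ndarray
    odds_ratios: np.ndarray
    or_ci: np.ndarray             # (p, 2), exp(beta +/- z se)
    pvalues: np.ndarray           # two-tailed Wald
    converged: bool
    n: int
    loglik: float
    re_var: dict[str, float] = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "estimate": self.params, "se": self.se, "OR": self.odds_ratios,
            "OR_ci_low": self.or_ci[:, 0], "OR_ci_high": self.or_ci[:, 1],
            "p": self.pvalues}, index=self.names)


def _as_design(design) -> tuple[np.ndarray, list[str]]:
    if isinstance(design, pd.DataFrame):
        return design.to_numpy(dtype=float), list(design.columns)
    X = np.asarray(design, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def _wald_package(names, beta, se, n, loglik, converged, re_var=None,
                  level=0.95) -> RegressionResult:
    z = norm.ppf(0.5 + level / 2.0)
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    ors = np.exp(beta)
    ci = np.column_stack([np.exp(beta - z * se), np.exp(beta + z * se)])
    with np.errstate(divide="ignore", invalid="ignore"):
        pvals = 2.0 * norm.sf(np.abs(beta) / se)
    return RegressionResult(names=list(names), params=beta, se=se,
                            odds_ratios=ors, or_ci=ci, pvalues=pvals,
                            converged=bool(converged), n=n, loglik=loglik,
                            re_var=dict(re_var or {}))


def fit_logistic(outcome, design, level: float = 0.95,
                 tol: float = 1e-8, maxiter: int = 100) -> RegressionResult:
    """Maximum-likelihood logistic regression (IRLS) with separation checks.

    ``design`` is a named covariate matrix that already includes the
    intercept column if one is wanted.  Raises :class:`SeparationError`
    naming the offending column when the estimates diverge (fitted
    probabilities pinned at 0/1), and ``ValueError`` for a constant outcome
    or a rank-deficient design.
    """
    y = np.asarray(outcome, dtype=float)
    X, names = _as_design(design)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate outcome: all units share one outcome class")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    model = sm.GLM(y, X, family=sm.families.Binomial())
    fit = model.fit(maxiter=maxiter, tol=tol)
    beta = np.asarray(fit.params)
    bse = np.asarray(fit.bse)
    mu = np.asarray(fit.fittedvalues)
    pinned = (mu < 1e-8) | (mu > 1 - 1e-8)
    if np.abs(beta).max() > 12.0 or np.any(bse > 40.0) or \
            (pinned.any() and np.abs(beta).max() > 8.0):
        j = int(np.argmax(np.abs(beta)))
        raise SeparationError(
            f"complete or quasi-complete separation detected "
            f"(column {names[j]!r}, estimate {beta[j]:.2f})")
    return _wald_package(names, beta, bse, len(y), float(fit.llf),
                         fit.converged if fit.converged is not None else True,
                         level=level)


# ---------------------------------------------------------------------------
# adaptive Gauss-Hermite machinery for random-intercept logistic models

def _pad_groups(eta0: np.ndarray, y: np.ndarray, codes: np.ndarray):
    """Reshape unit vectors into padded (group, slot) matrices with a mask."""
    order = np.argsort(codes, kind="stable")
    codes_s, eta_s, y_s = codes[order], eta0[order], y[order]
    uniq, counts = np.unique(codes_s, return_counts=True)
    G, S = len(uniq), int(counts.max())
    eta_m = np.zeros((G, S))
    y_m = np.zeros((G, S))
    mask = np.zeros((G, S), dtype=bool)
    pos = np.concatenate([[0], np.cumsum(counts)])
    for g in range(G):
        s = counts[g]
        eta_m[g, :s] = eta_s[pos[g]:pos[g + 1]]
        y_m[g, :s] = y_s[pos[g]:pos[g + 1]]
        mask[g, :s] = True
    return eta_m, y_m, mask


def _group_loglik_at(eta_m, y_m, mask, u):
    """Conditional log-likelihood of each group at intercepts ``u`` (G,) or (G,K)."""
    if u.ndim == 1:
        eta = eta_m + u[:, None]
        ll = y_m * eta - np.logaddexp(0.0, eta)
        return np.where(mask, ll, 0.0).sum(axis=1)
    eta = eta_m[:, None, :] + u[:, :, None]
    ll = y_m[:, None, :] * eta - np.logaddexp(0.0, eta)
    return np.where(mask[:, None, :], ll, 0.0).sum(axis=2)


def _agq_group_logliks(eta_m, y_m, mask, sigma: float,
                       nodes_x: np.ndarray, nodes_logw: np.ndarray) -> np.ndarray:
    """log marginal likelihood per group, random intercept sigma * u, u~N(0,1).

    Integrates exp(l_g(s u)) phi(u) du by AGQ after a vectorised Newton
    search for each group's posterior mode (the integrand is log-concave,
    so Newton with step capping is globally convergent).
    """
    G = eta_m.shape[0]
    s2 = sigma * sigma
    if s2 == 0.0:
        return _group_loglik_at(eta_m, y_m, mask, np.zeros(G))
    b = np.zeros(G)  # b = sigma * u: Newton on the intercept scale
    for _ in range(60):
        eta = eta_m + b[:, None]
        p = expit(eta)
        grad = np.where(mask, y_m - p, 0.0).sum(axis=1) - b / s2
        hess = -np.where(mask, p * (1.0 - p), 0.0).sum(axis=1) - 1.0 / s2
        step = grad / hess
        np.clip(step, -4.0, 4.0, out=step)
        b -= step
        if np.abs(grad).max() < 1e-11:
            break
    tau = 1.0 / np.sqrt(-hess)          # local curvature scale
    u_nodes = b[:, None] + np.sqrt(2.0) * tau[:, None] * nodes_x[None, :]
    ll_cond = _group_loglik_at(eta_m, y_m, mask, u_nodes)
    log_prior = -0.5 * (u_nodes / sigma) ** 2 - np.log(sigma) - _LOG_SQRT_2PI
    body = nodes_logw[None, :] + nodes_x[None, :] ** 2 + ll_cond + log_prior
    return 0.5 * np.log(2.0) + np.log(tau) + logsumexp(body, axis=1)


def _glmm_loglik_single(beta, sigma, y, X, codes, nodes_x, nodes_logw) -> float:
    eta0 = X @ beta
    eta_m, y_m, mask = _pad_groups(eta0, y, codes)
    return float(_agq_group_logliks(eta_m, y_m, mask, sigma,
                                    nodes_x, nodes_logw).sum())


def _glmm_loglik_nested(beta, sigma_outer, sigma_inner, y, X,
                        outer_codes, inner_codes, nodes_x, nodes_logw) -> float:
    """Nested random intercepts: inner groups (pairs) within outer (samples).

    The outer integral is evaluated adaptively: the outer mode is located by
    a bounded scalar search over the profiled inner-marginalised likelihood,
    then Gauss-Hermite applied around it.
    """
    eta0 = X @ beta
    total = 0.0
    for s in np.unique(outer_codes):
        sel = outer_codes == s
        eta_s, y_s, codes_s = eta0[sel], y[sel], inner_codes[sel]
        eta_m, y_m, mask = _pad_groups(eta_s, y_s, codes_s)

        def h(v: float) -> float:
            # log integrand of the outer integral at outer effect v
            inner = _agq_group_logliks(eta_m + sigma_outer * v, y_m, mask,
                                       sigma_inner, nodes_x, nodes_logw).sum()
            return inner - 0.5 * v * v - _LOG_SQRT_2PI

        if sigma_outer == 0.0:
            total += h(0.0) + _LOG_SQRT_2PI
            continue
        res = optimize.minimize_scalar(lambda v: -h(v), bounds=(-8.0, 8.0),
                                       method="bounded",
                                       options={"xatol": 1e-7})
        v_hat = float(res.x)
        d = 1e-4
        curv = (h(v_hat + d) - 2.0 * h(v_hat) + h(v_hat - d)) / (d * d)
        tau = 1.0 / np.sqrt(max(-curv, 1e-6))
        v_nodes = v_hat + np.sqrt(2.0) * tau * nodes_x
        vals = np.array([h(v) for v in v_nodes])
        total += 0.5 * np.log(2.0) + np.log(tau) + \
            logsumexp(nodes_logw + nodes_x ** 2 + vals)
    return float(total)


def fit_logistic_glmm(outcome, design, groups: dict[str, np.ndarray],
                      nodes: int = 21, level: float = 0.95,
                      tol: float = 1e-8) -> RegressionResult:
    """Random-intercept mixed logistic regression via adaptive quadrature.

    Parameters
    ----------
    groups
        Mapping of grouping-factor name to a code array per unit.  One
        factor gives a single random intercept; two factors are treated as
        nested, the first (e.g. sample) containing the second (e.g. pair).
    nodes
        Odd Gauss-Hermite node count; ``nodes=1`` is the Laplace
        approximation, used as a logged fallback if quadrature fails.
    """
    y = np.asarray(outcome, dtype=float)
    X, names = _as_design(design)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate outcome: all units share one outcome class")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if nodes % 2 != 1 or nodes < 1:
        raise ValueError("quadrature node count must be a positive odd integer")
    factor_names = list(groups)
    if not 1 <= len(factor_names) <= 2:
        raise ValueError("one or two grouping factors supported")
    code_arrays = [np.asarray(pd.factorize(np.asarray(groups[f]))[0])
                   for f in factor_names]
    nodes_x, nodes_w = hermgauss(nodes)
    nodes_logw = np.log(nodes_w)
    p = X.shape[1]
    q = len(factor_names)

    def loglik(theta: np.ndarray) -> float:
        beta, sigmas = theta[:p], np.abs(theta[p:])
        if q == 1:
            return _glmm_loglik_single(beta, sigmas[0], y, X, code_arrays[0],
                                       nodes_x, nodes_logw)
        return _glmm_loglik_nested(beta, sigmas[0], sigmas[1], y, X,
                                   code_arrays[0], code_arrays[1],
                                   nodes_x, nodes_logw)

    start_beta = fit_logistic(y, pd.DataFrame(X, columns=names)).params
    theta0 = np.concatenate([start_beta, np.full(q, 0.5)])
    try:
        res = optimize.minimize(
            lambda th: -loglik(th), theta0, method="L-BFGS-B",
            bounds=[(None, None)] * p + [(0.0, 10.0)] * q,
            options={"ftol": tol, "gtol": 1e-7, "maxiter": 500})
    except (FloatingPointError, np.linalg.LinAlgError):
        log.warning("adaptive quadrature failed; falling back to Laplace")
        return fit_logistic_glmm(outcome, design, groups, nodes=1, level=level)
    theta = res.x
    beta_hat, sigma_hat = theta[:p], np.abs(theta[p:])
    if np.all(sigma_hat < 1e-6):
        # variance at the zero boundary: the model collapses to plain
        # logistic, whose MLE is exact rather than optimizer-terminated
        plain = fit_logistic(y, pd.DataFrame(X, columns=names), level=level)
        sigma_hat = np.zeros(q)
        re_var = {f: 0.0 for f in factor_names}
        return RegressionResult(names=plain.names, params=plain.params,
                                se=plain.se, odds_ratios=plain.odds_ratios,
                                or_ci=plain.or_ci, pvalues=plain.pvalues,
                                converged=plain.converged, n=plain.n,
                                loglik=plain.loglik, re_var=re_var)
    theta = np.concatenate([beta_hat, sigma_hat])
    se = _numeric_wald_se(loglik, theta, p)
    re_var = {f: float(s * s) for f, s in zip(factor_names, sigma_hat)}
    return _wald_package(names, beta_hat, se, len(y), float(-res.fun),
                         res.success, re_var=re_var, level=level)


def _numeric_wald_se(loglik, theta: np.ndarray, p: int) -> np.ndarray:
    """Fixed-effect SEs from a finite-difference Hessian of the log-likelihood.

    Variance components at the zero boundary are profiled out (their rows
    are dropped) since the Hessian is singular there.
    """
    m = len(theta)
    keep = list(range(p)) + [j for j in range(p, m) if theta[j] > 1e-4]
    h = 1e-4 * np.maximum(1.0, np.abs(theta))
    H = np.zeros((len(keep), len(keep)))
    for a, ja in enumerate(keep):
        for b, jb in enumerate(keep[:a + 1]):
            ta = theta.copy(); ta[ja] += h[ja]; ta[jb] += h[jb]
            tb = theta.copy(); tb[ja] += h[ja]; tb[jb] -= h[jb]
            tc = theta.copy(); tc[ja] -= h[ja]; tc[jb] += h[jb]
            td = theta.copy(); td[ja] -= h[ja]; td[jb] -= h[jb]
            H[a, b] = H[b, a] = (loglik(ta) - loglik(tb) - loglik(tc)
                                 + loglik(td)) / (4.0 * h[ja] * h[jb])
    try:
        cov = np.linalg.inv(-H)
        var = np.clip(np.diag(cov)[:p], 0.0, None)
    except np.linalg.LinAlgError:
        var = np.full(p, np.nan)
    return np.sqrt(var)


# ---------------------------------------------------------------------------

@dataclass
class FDRResult:
    pvalues: np.ndarray
    m: int
    q: float
    adjusted: np.ndarray
    rejected: np.ndarray


def bh_fdr(pvalues, q: float = 0.05) -> FDRResult:
    """Benjamini-Hochberg step-up FDR control.

    Rejects hypotheses 1..k* in p-value order, where k* is the largest rank
    with ``p_(k) <= q k / m``; adjusted p-values are the step-up-enforced
    ``min_{j >= rank} m p_(j) / j`` clamped at 1, so rejection is exactly
    ``adjusted <= q``.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("need a non-empty 1-d p-value vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return FDRResult(pvalues=p, m=m, q=q, adjusted=adj, rejected=adj <= q)


def build_concordance_design(units: pd.DataFrame,
                             predictors: dict[str, np.ndarray] | None = None
                             ) -> pd.DataFrame:
    """Design matrix for concordance regressions on a proband-unit frame.

    Intercept, co-twin sex (F=0, M=1) and co-twin age in centred decades
    (odds ratios for age are per decade), plus any extra named predictor
    columns aligned with the units.
    """
    X = pd.DataFrame(index=units.index)
    X["intercept"] = 1.0
    X["cotwin_male"] = (units["cotwin_sex"].astype(str) == "M").astype(float)
    age = units["cotwin_age_last_info"].astype(float)
    X["cotwin_age_decades"] = (age - age.mean()) / 10.0
    for name, values in (predictors or {}).items():
        X[name] = np.asarray(values, dtype=float)
    return X
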