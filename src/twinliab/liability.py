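"""Liability-threshold tetrachoric correlations and ACE variance decomposition.

The model: each individual carries a latent standard-normal liability; the
syndrome is present iff liability exceeds a threshold ``t`` fixed by the
lifetime morbid risk ``K`` through ``t = Phi^-1(1 - K)``.  Twin liabilities
are bivariate normal with correlation ``r`` (the tetrachoric correlation),
so the probandwise concordance implied by the model is

    C(r) = P(L2 > t | L1 > t) = Phi2_upper(t, t; r) / K.

The tetrachoric correlation is estimated by maximising the probandwise
binomial likelihood ``k * log C(r) + (n - k) * log(1 - C(r))`` given ``k``
concordant out of ``n`` proband units, i.e. ascertainment is handled by
conditioning on proband affection — exactly the information a probandwise
concordance table carries.  The ACE decomposition constrains the MZ and DZ
correlations to ``r_MZ = a2 + c2`` and ``r_DZ = a2/2 + c2`` on the simplex
``a2, c2 >= 0, a2 + c2 <= 1`` and maximises the joint likelihood; confidence
intervals are profile-likelihood sets at the chi-square(1) 95% cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize
from scipy.stats import norm

_SQRT2 = math.sqrt(2.0)


def _norm_sf(x: float) -> float:
    return 0.5 * math.erfc(x / _SQRT2)

__all__ = [
    "LiabilityFit",
    "ACEEstimate",
    "threshold_from_risk",
    "bvn_upper_tail",
    "model_concordance",
    "tetrachoric_from_concordance",
    "fit_ace",
]

# chi-square(1) 0.95 quantile: profile-likelihood CI cutoff
_CHI2_95 = 3.8414588206941245
# search domain for the tetrachoric correlation (open at +/-1 to keep the
# binomial log-likelihood finite when 0 < k < n)
_R_LO, _R_HI = -0.99, 0.999
_XTOL = 1e-10
# 96-point Gauss-Legendre rule on [-1, 1] for the bivariate-normal tail
_GL_X, _GL_W = np.polynomial.legendre.leggauss(96)


def threshold_from_risk(K: float) -> float:
    """Liability threshold ``t = Phi^-1(1 - K)`` for morbid risk ``K`` in (0, 1)."""
    if not 0.0 < K < 1.0:
        raise ValueError(f"morbid risk K must lie in (0, 1), got {K}")
    return _cached_threshold(K)


@lru_cache(maxsize=1024)
def _cached_threshold(K: float) -> float:
    return float(norm.isf(K))


def bvn_upper_tail(t1: float, t2: float, r: float) -> float:
    """Upper-tail probability P(X > t1, Y > t2) of a standard bivariate normal.

    Uses the single-integral identity (with the substitution ``rho = sin(theta)``
    which removes the endpoint singularity)::

        P = Q(t1) Q(t2) + (1/2pi) * Int_0^{asin r} exp(-(t1^2 - 2 t1 t2 sin(th)
            + t2^2) / (2 cos^2 th)) dth

    where ``Q`` is the standard-normal survival function.  Absolute accuracy
    is well below 1e-10 across the closed correlation range, including the
    degenerate endpoints ``r = +/-1``.
    """
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation must lie in [-1, 1], got {r}")
    if r == 1.0:
        return _norm_sf(max(t1, t2))
    if r == -1.0:
        return max(0.0, _norm_sf(t1) + _norm_sf(t2) - 1.0)
    base = _norm_sf(t1) * _norm_sf(t2)
    if r == 0.0:
        return base
    # the transformed integrand is analytic on the closed interval, so a
    # fixed-order Gauss-Legendre rule converges to machine precision
    upper = math.asin(r)
    theta = 0.5 * upper * (_GL_X + 1.0)
    s, c2 = np.sin(theta), np.cos(theta) ** 2
    vals = np.exp(-(t1 * t1 - 2.0 * t1 * t2 * s + t2 * t2) / (2.0 * c2))
    val = 0.5 * upper * float(_GL_W @ vals)
    return min(1.0, max(0.0, base + val / (2.0 * math.pi)))


def model_concordance(r: float, K: float) -> float:
    """Model-implied probandwise concordance C(r) = Phi2_upper(t, t; r) / K."""
    t = threshold_from_risk(K)
    return bvn_upper_tail(t, t, r) / K


def _binom_loglik(r: float, k: float, n: float, K: float) -> float:
    """Probandwise binomial log-likelihood at tetrachoric correlation r.

    Accepts real-valued k (pseudo-counts) for inversion at large n.
    """
    c = model_concordance(r, K)
    eps = 1e-300
    ll = 0.0
    if k > 0:
        ll += k * math.log(max(c, eps))
    if n - k > 0:
        ll += (n - k) * math.log(max(1.0 - c, eps))
    return ll


@dataclass
class LiabilityFit:
    """Tetrachoric correlation estimate under the liability-threshold model."""

    K: float
    t: float
    r_hat: float
    ci_low: float | None  # None => "not applicable" (profile set unbounded below)
    ci_high: float | None
    loglik: float
    n: float
    k: float
    boundary: bool = False

    @property
    def ci_low_label(self) -> str:
        return "not applicable" if self.ci_low is None else f"{self.ci_low:.3f}"


def _profile_ci_1d(loglik, r_hat: float, ll_max: float,
                   lo: float, hi: float) -> tuple[float | None, float | None]:
    """Profile-likelihood CI {r : 2(ll_max - loglik(r)) <= chi2_1(0.95)} by bisection."""
    cutoff = ll_max - _CHI2_95 / 2.0

    def deficit(r: float) -> float:
        return loglik(r) - cutoff

    ci_lo: float | None
    ci_hi: float | None
    if deficit(lo) >= 0:
        ci_lo = None  # set extends to the domain edge: lower limit not given
    else:
        a, b = lo, r_hat
        for _ in range(80):
            m = 0.5 * (a + b)
            if deficit(m) < 0:
                a = m
            else:
                b = m
        ci_lo = 0.5 * (a + b)
    if deficit(hi) >= 0:
        ci_hi = hi
    else:
        a, b = r_hat, hi
        for _ in range(80):
            m = 0.5 * (a + b)
            if deficit(m) >= 0:
                a = m
            else:
                b = m
        ci_hi = 0.5 * (a + b)
    return ci_lo, ci_hi


def tetrachoric_from_concordance(k: float, n: float, K: float) -> LiabilityFit:
    """Estimate the tetrachoric twin correlation from probandwise counts.

    Parameters
    ----------
    k, n
        Concordant and total proband units (k may be real-valued when
        inverting an exact concordance with pseudo-counts).
    K
        Lifetime morbid risk of the phenotype, in (0, 0.5).

    Returns
    -------
    LiabilityFit with the MLE over r in [-0.99, 0.999], profile 95% CI, and
    the log-likelihood at the optimum.  When ``k = 0`` the likelihood is
    monotone decreasing in r, the estimate sits at the lower search boundary
    and the CI lower limit is reported as not applicable.
    """
    if n <= 0:
        raise ValueError("n must be >= 1 (not estimable otherwise)")
    if not 0.0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < K < 0.5:
        raise ValueError(f"morbid risk K must lie in (0, 0.5), got {K}")
    t = threshold_from_risk(K)

    def ll(r: float) -> float:
        return _binom_loglik(r, k, n, K)

    boundary = False
    if k == n:
        # C(r) -> 1 only as r -> 1: boundary solution
        r_hat, boundary = 1.0, True
        ll_max = 0.0
    else:
        res = optimize.minimize_scalar(lambda r: -ll(r), bounds=(_R_LO, _R_HI),
                                       method="bounded",
                                       options={"xatol": _XTOL})
        r_hat = float(res.x)
        ll_max = -float(res.fun)
        # snap to the boundary when the optimiser pushes against it
        if r_hat <= _R_LO + 1e-6 and ll(_R_LO) >= ll_max - 1e-12:
            r_hat, ll_max, boundary = _R_LO, ll(_R_LO), True
        if r_hat >= _R_HI - 1e-6 and ll(_R_HI) >= ll_max - 1e-12:
            r_hat, ll_max, boundary = _R_HI, ll(_R_HI), True

    if k == n:
        ci_lo, _ = _profile_ci_1d(ll, _R_HI, ll(_R_HI), _R_LO, _R_HI)
        ci_hi = 1.0
    else:
        ci_lo, ci_hi = _profile_ci_1d(ll, r_hat, ll_max, _R_LO, _R_HI)
    if k == 0:
        ci_lo = None  # no concordant pairs: lower limit not given
    return LiabilityFit(K=K, t=t, r_hat=r_hat, ci_low=ci_lo, ci_high=ci_hi,
                        loglik=ll_max, n=n, k=k, boundary=boundary)


@dataclass
class ACEEstimate:
    """Constrained ACE decomposition of twin liability correlations.

    ``a2`` is the additive-genetic share (heritability h2), ``c2`` the
    shared-environment share, ``e2 = 1 - a2 - c2`` the non-shared remainder.
    """

    a2: float
    c2: float
    e2: float
    a2_ci: tuple[float, float]
    c2_ci: tuple[float, float]
    loglik: float
    r_mz_implied: float = field(init=False)
    r_dz_implied: float = field(init=False)
    boundary: bool = False

    def __post_init__(self) -> None:
        self.r_mz_implied = self.a2 + self.c2
        self.r_dz_implied = 0.5 * self.a2 + self.c2


def _ace_loglik(a2: float, c2: float, mz: tuple[float, float],
                dz: tuple[float, float], K: float) -> float:
    return (_binom_loglik(a2 + c2, mz[0], mz[1], K)
            + _binom_loglik(0.5 * a2 + c2, dz[0], dz[1], K))


def fit_ace(mz: tuple[float, float], dz: tuple[float, float],
            K: float, n_starts: int = 5) -> ACEEstimate:
    """Fit the ACE model to MZ and DZ probandwise counts ``(k, n)``.

    Maximises ``l_MZ(a2 + c2) + l_DZ(a2/2 + c2)`` over the simplex with the
    probandwise binomial likelihood, from ``n_starts`` fixed multi-starts;
    boundary solutions (a2 = 0 or c2 = 0) are permitted, snapped exactly to
    the boundary, and flagged.  Profile-likelihood 95% CIs for a2 and c2
    re-optimise the other share at each profiled value.
    """
    for label, (kk, nn) in (("MZ", mz), ("DZ", dz)):
        if nn <= 0:
            raise ValueError(f"{label} group needs n >= 1")
        if not 0 <= kk <= nn:
            raise ValueError(f"{label} counts invalid: k={kk}, n={nn}")
    if not 0.0 < K < 0.5:
        raise ValueError(f"morbid risk K must lie in (0, 0.5), got {K}")
    cap = _R_HI  # a2 + c2 bounded so both implied correlations stay in-domain

    def neg(theta: np.ndarray) -> float:
        a2, c2 = theta
        if a2 < 0 or c2 < 0 or a2 + c2 > cap:
            return np.inf
        return -_ace_loglik(a2, c2, mz, dz, K)

    starts = [(0.4, 0.1), (0.8, 0.0), (0.0, 0.4), (0.1, 0.01), (0.6, 0.3)]
    best = None
    for x0 in starts[:n_starts]:
        res = optimize.minimize(
            neg, x0=np.array(x0), method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    a2, c2 = (float(v) for v in best.x)
    a2, c2 = max(a2, 0.0), max(c2, 0.0)
    # polish on the simplex, then snap near-zero shares onto the boundary
    boundary = False
    if a2 < 1e-7 and neg((0.0, c2)) <= best.fun + 1e-12:
        a2, boundary = 0.0, True
    if c2 < 1e-7 and neg((a2, 0.0)) <= neg((a2, c2)) + 1e-12:
        c2 = 0.0
        boundary = boundary or a2 == 0.0 or True
        boundary = True
    ll_max = _ace_loglik(a2, c2, mz, dz, K)

    def profile(which: str, value: float) -> float:
        if which == "a2":
            hi = cap - value
            if hi <= 0:
                return _ace_loglik(value, 0.0, mz, dz, K)
            r = optimize.minimize_scalar(
                lambda c: -_ace_loglik(value, c, mz, dz, K),
                bounds=(0.0, hi), method="bounded", options={"xatol": 1e-9})
            out = -r.fun
            return max(out, _ace_loglik(value, 0.0, mz, dz, K))
        hi = cap - value
        if hi <= 0:
            return _ace_loglik(0.0, value, mz, dz, K)
        r = optimize.minimize_scalar(
            lambda a: -_ace_loglik(a, value, mz, dz, K),
            bounds=(0.0, hi), method="bounded", options={"xatol": 1e-9})
        return max(-r.fun, _ace_loglik(0.0, value, mz, dz, K))

    def ci_for(which: str, point: float) -> tuple[float, float]:
        lo, hi = _profile_ci_1d(lambda v: profile(which, v),
                                point, ll_max, 0.0, cap)
        return (0.0 if lo is None else lo, cap if hi is None else min(hi, 1.0))

    a2_ci = ci_for("a2", a2)
    c2_ci = ci_for("c2", c2)
    return ACEEstimate(a2=a2, c2=c2, e2=1.0 - a2 - c2,
                       a2_ci=a2_ci, c2_ci=c2_ci, loglik=ll_max,
                       boundary=boundary)
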