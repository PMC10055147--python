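"""Moments and tail probabilities under the Poisson-log-normal null.

The null model for a UMI count x with expected value mu and gene-noise
coefficient of variation c is: lambda = mu * L with L log-normal of mean 1
and CV c, and x | lambda ~ Poisson(lambda).  For the log-normal mixing
variable, E[L^r] = (1 + c^2)^(r(r-1)/2), so with w = 1 + c^2 the factorial
moments of x are E[x(x-1)...(x-r+1)] = mu^r w^(r(r-1)/2).  Raw moments
follow through Stirling numbers of the second kind, and central moments by
binomial expansion.  All of this algebra is carried out once, exactly, in
integer arithmetic, producing for each order k a polynomial

    E[(x - mu)^k] = sum_{r,s} A[k][(r, s)] mu^r w^s

with integer coefficients; evaluation is then a stable Horner pass over mu
with per-power-of-mu coefficients assembled from w.

Standardized residuals P' = (x - mu) / sqrt(mu (1 + c^2 mu)) inherit their
moments by scaling.  Cumulants of sums of independent per-cell terms add;
tail probabilities are obtained by inverting the fourth-order
Cornish-Fisher quantile polynomial (which uses standardized cumulants up
to kappa_5) to map the observed statistic to an equivalent Gaussian
deviate.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import comb

import numpy as np
from scipy.special import erfc, ndtr

from .exceptions import NumericError, ValidationError

__all__ = [
    "MAX_MOMENT_ORDER",
    "MomentSet",
    "TailProbability",
    "pln_raw_moments",
    "pln_central_moments",
    "residual_central_moments",
    "residual_raw_moment_arrays",
    "squared_residual_raw_moment_arrays",
    "raw_moments_to_cumulants",
    "sum_cumulants",
    "cornish_fisher_pvalue",
    "cornish_fisher_zscores",
    "gaussian_tail_pvalues",
]

MAX_MOMENT_ORDER = 12

P_FLOOR = 1e-320  # underflow guard on returned p-values
FAST_P_THRESHOLD = 1e-12  # below this the quartic inversion may be skipped


# ---------------------------------------------------------------------------
# exact moment tables
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _stirling2(k: int, r: int) -> int:
    if r == 0:
        return 1 if k == 0 else 0
    if r > k:
        return 0
    if r == k:
        return 1
    return r * _stirling2(k - 1, r) + _stirling2(k - 1, r - 1)


@lru_cache(maxsize=None)
def _raw_moment_poly(k: int) -> tuple:
    """E[x^k] as {(r, s): int} meaning coeff * mu^r * w^s (frozen as tuple)."""
    terms = {}
    for r in range(1, k + 1):
        terms[(r, r * (r - 1) // 2)] = _stirling2(k, r)
    if k == 0:
        terms[(0, 0)] = 1
    return tuple(sorted(terms.items()))


@lru_cache(maxsize=None)
def _central_moment_poly(k: int) -> tuple:
    """E[(x - mu)^k] as {(r, s): int}, exact integer coefficients."""
    acc: dict[tuple[int, int], int] = {}
    for j in range(0, k + 1):
        sign = (-1) ** (k - j)
        c_kj = comb(k, j)
        for (r, s), a in _raw_moment_poly(j):
            key = (r + (k - j), s)
            acc[key] = acc.get(key, 0) + sign * c_kj * a
    return tuple(sorted((key, a) for key, a in acc.items() if a != 0))


def _eval_poly(terms: tuple, mu: np.ndarray, w) -> np.ndarray:
    """Evaluate sum a * mu^r * w^s: Horner over mu, w-coefficients first."""
    mu = np.asarray(mu, dtype=float)
    w = np.asarray(w, dtype=float)
    shape = np.broadcast(mu, w).shape
    if terms == ():
        return np.zeros(shape)
    max_r = max(r for (r, _s), _a in terms)
    # per-power-of-mu coefficient, itself a polynomial in w
    coeffs: list = [0.0] * (max_r + 1)
    for (r, s), a in terms:
        coeffs[r] = coeffs[r] + float(a) * w**s
    out = np.zeros(shape) + coeffs[max_r]
    for r in range(max_r - 1, -1, -1):
        out = out * mu + coeffs[r]
    return out


def _check_order(k: int) -> None:
    if not 1 <= k <= MAX_MOMENT_ORDER:
        raise ValidationError(
            f"moment order {k} unsupported (1..{MAX_MOMENT_ORDER})"
        )


def pln_raw_moments(mu, c, k: int) -> np.ndarray:
    """First k raw moments of the Poisson-log-normal distribution.

    Returns an array with the moment order on the first axis, broadcast
    over ``mu`` (which may be scalar or an array of per-cell expectations).
    """
    _check_order(k)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValidationError("pln_raw_moments requires mu > 0")
    if np.any(np.asarray(c) < 0):
        raise ValidationError("c must be non-negative")
    w = 1.0 + np.asarray(c, dtype=float) ** 2
    out = np.stack([_eval_poly(_raw_moment_poly(j), mu, w) for j in range(1, k + 1)])
    if not np.all(np.isfinite(out)):
        raise NumericError("non-finite Poisson-log-normal moment")
    return out


def pln_central_moments(mu, c, k: int) -> np.ndarray:
    """First k central moments E[(x - mu)^j], j = 1..k (j=1 is exactly 0)."""
    _check_order(k)
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise ValidationError("pln_central_moments requires mu > 0")
    w = 1.0 + np.asarray(c, dtype=float) ** 2
    out = np.stack(
        [_eval_poly(_central_moment_poly(j), mu, w) for j in range(1, k + 1)]
    )
    if not np.all(np.isfinite(out)):
        raise NumericError("non-finite Poisson-log-normal central moment")
    return out


# ---------------------------------------------------------------------------
# residual moments
# ---------------------------------------------------------------------------

def _residual_scale_sq(mu, c) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    return mu * (1.0 + np.asarray(c, dtype=float) ** 2 * mu)


def residual_raw_moment_arrays(mu, c, k: int) -> np.ndarray:
    """E[(P')^r] for r = 1..k of the standardized residual, broadcast over mu.

    P' = (x - mu)/sqrt(mu (1 + c^2 mu)); the first moment is exactly 0 and,
    when ``c`` matches the generating process, the second is exactly 1.
    """
    central = pln_central_moments(mu, c, k)
    s = np.sqrt(_residual_scale_sq(mu, c))
    powers = np.stack([s ** r for r in range(1, k + 1)])
    return central / powers


def squared_residual_raw_moment_arrays(mu, c, order: int) -> np.ndarray:
    """E[((P')^2)^m] for m = 1..order, i.e. central count moments 2m scaled."""
    if 2 * order > MAX_MOMENT_ORDER:
        raise ValidationError(
            f"order {order} needs count moments up to {2 * order} > {MAX_MOMENT_ORDER}"
        )
    central = pln_central_moments(mu, c, 2 * order)
    s2 = _residual_scale_sq(mu, c)
    return np.stack([central[2 * m - 1] / s2**m for m in range(1, order + 1)])


def residual_central_moments(mu_ij: float, c: float, k: int):
    """Central moments of P' and of (P')^2 for a single (mu, c).

    Returns ``(p_moments, p2_central)``: the first k central moments of the
    standardized residual (equal to its raw moments, as it is mean-centered)
    and the first k central moments of its square.
    """
    if mu_ij <= 0:
        raise ValidationError("mu_ij must be positive")
    p_moments = np.atleast_1d(residual_raw_moment_arrays(mu_ij, c, k).squeeze())
    p2_raw = np.atleast_1d(squared_residual_raw_moment_arrays(mu_ij, c, k).squeeze())
    mean = p2_raw[0]
    # central moments of (P')^2 about its mean, by binomial expansion
    raw = np.concatenate([[1.0], p2_raw])
    p2_central = np.empty(k)
    for j in range(1, k + 1):
        acc = 0.0
        for i in range(0, j + 1):
            acc += comb(j, i) * raw[i] * (-mean) ** (j - i)
        p2_central[j - 1] = acc
    return p_moments, p2_central


# ---------------------------------------------------------------------------
# cumulants
# ---------------------------------------------------------------------------

@dataclass
class MomentSet:
    """First ``order`` cumulants of a null statistic."""

    order: int
    cumulants: np.ndarray

    def __post_init__(self) -> None:
        self.cumulants = np.asarray(self.cumulants, dtype=float)
        if self.cumulants.shape[0] != self.order:
            raise ValidationError("cumulant vector length must equal order")


def raw_moments_to_cumulants(raw: np.ndarray) -> np.ndarray:
    """Convert raw moments m_1..m_k (first axis = order) to cumulants.

    Uses the standard recursion
    kappa_n = m_n - sum_{j=1}^{n-1} C(n-1, j-1) kappa_j m_{n-j};
    vectorized over any trailing axes.
    """
    raw = np.asarray(raw, dtype=float)
    k = raw.shape[0]
    kappa = np.empty_like(raw)
    for n in range(1, k + 1):
        acc = raw[n - 1].copy()
        for j in range(1, n):
            acc -= comb(n - 1, j - 1) * kappa[j - 1] * raw[n - j - 1]
        kappa[n - 1] = acc
    return kappa


def sum_cumulants(per_cell_moments) -> MomentSet:
    """Cumulants of a sum of independent terms = sum of per-term cumulants."""
    sets = list(per_cell_moments)
    if not sets:
        raise ValidationError("empty moment sequence")
    order = sets[0].order
    if any(ms.order != order for ms in sets):
        raise ValidationError("mixed cumulant orders in sum_cumulants")
    total = np.sum([ms.cumulants for ms in sets], axis=0)
    return MomentSet(order=order, cumulants=total)


# ---------------------------------------------------------------------------
# Cornish-Fisher tail probabilities
# ---------------------------------------------------------------------------

@dataclass
class TailProbability:
    p_two_sided: float
    p_upper: float
    p_lower: float
    method_flag: str  # "cornish_fisher" | "gaussian_fallback" | "gaussian_bound"


def _cf_forward(z, g1, g2, g3):
    """Fourth-order Cornish-Fisher quantile polynomial (standardized scale)."""
    z2 = z * z
    out = (
        z
        + g1 / 6.0 * (z2 - 1.0)
        + g2 / 24.0 * (z2 * z - 3.0 * z)
        - g1 * g1 / 36.0 * (2.0 * z2 * z - 5.0 * z)
    )
    out += (
        g3 / 120.0 * (z2 * z2 - 6.0 * z2 + 3.0)
        - g1 * g2 / 24.0 * (z2 * z2 - 5.0 * z2 + 2.0)
        + g1**3 / 324.0 * (12.0 * z2 * z2 - 53.0 * z2 + 17.0)
    )
    return out


def _cf_derivative(z, g1, g2, g3):
    z2 = z * z
    out = (
        1.0
        + g1 / 3.0 * z
        + g2 / 24.0 * (3.0 * z2 - 3.0)
        - g1 * g1 / 36.0 * (6.0 * z2 - 5.0)
    )
    out += (
        g3 / 120.0 * (4.0 * z2 * z - 12.0 * z)
        - g1 * g2 / 24.0 * (4.0 * z2 * z - 10.0 * z)
        + g1**3 / 324.0 * (48.0 * z2 * z - 106.0 * z)
    )
    return out


def cornish_fisher_zscores(x, g1, g2, g3, max_iter: int = 80, tol: float = 1e-10):
    """Invert the CF quantile polynomial: find z with CF(z) = x.

    ``x`` is the observed statistic standardized by (kappa_1, kappa_2);
    g1..g3 are the standardized cumulants kappa_3/kappa_2^1.5,
    kappa_4/kappa_2^2, kappa_5/kappa_2^2.5.  A damped Newton iteration is
    started at the naive value z = x, converging to the real root of the
    quartic nearest to it.  Returns ``(z, ok)`` where ``ok`` is False where
    the iteration failed or the CF map is non-monotone at the root (callers
    should fall back to the Gaussian tail there).
    """
    x = np.asarray(x, dtype=float)
    g1, g2, g3 = np.broadcast_arrays(
        np.asarray(g1, float), np.asarray(g2, float), np.asarray(g3, float)
    )
    g1 = np.broadcast_to(g1, x.shape).copy()
    g2 = np.broadcast_to(g2, x.shape).copy()
    g3 = np.broadcast_to(g3, x.shape).copy()
    z = x.copy()
    for _ in range(max_iter):
        f = _cf_forward(z, g1, g2, g3) - x
        fp = _cf_derivative(z, g1, g2, g3)
        safe = np.abs(fp) > 1e-12
        step = np.where(safe, f / np.where(safe, fp, 1.0), 0.0)
        step = np.clip(step, -1.0, 1.0)  # damping: CF scale is ~unit
        z = z - step
        if np.all(np.abs(step) < tol):
            break
    resid = np.abs(_cf_forward(z, g1, g2, g3) - x)
    ok = (
        np.isfinite(z)
        & (resid < 1e-6 * (1.0 + np.abs(x)))
        & (_cf_derivative(z, g1, g2, g3) > 0.0)
    )
    return z, ok


def gaussian_tail_pvalues(z):
    """Upper/lower Gaussian tails of a deviate, floored against underflow."""
    z = np.asarray(z, dtype=float)
    upper = 0.5 * erfc(z / np.sqrt(2.0))
    lower = ndtr(z)
    return np.maximum(upper, P_FLOOR), np.maximum(lower, P_FLOOR)


def cornish_fisher_pvalue(
    stat_observed: float,
    ms: MomentSet,
    fast_threshold: float = FAST_P_THRESHOLD,
) -> TailProbability:
    """Two-tailed p-value for an observed statistic given null cumulants.

    Standardizes by kappa_1, kappa_2, inverts the Cornish-Fisher quantile
    polynomial (cumulants up to order 5; missing orders treated as
    Gaussian), and returns Phi-tail probabilities of the equivalent
    Gaussian deviate.  Where the naive Gaussian tail already falls below
    ``fast_threshold`` the slow inversion is skipped and the Gaussian bound
    returned (flagged), per the speed/accuracy contract; the returned p is
    then guaranteed to be at or below the threshold.
    """
    kap = ms.cumulants
    if ms.order < 2 or kap[1] <= 0:
        raise ValidationError("cornish_fisher_pvalue requires kappa_2 > 0")
    k1, k2 = kap[0], kap[1]
    k3 = kap[2] if ms.order >= 3 else 0.0
    k4 = kap[3] if ms.order >= 4 else 0.0
    k5 = kap[4] if ms.order >= 5 else 0.0
    x = (stat_observed - k1) / np.sqrt(k2)
    g1 = k3 / k2**1.5
    g2 = k4 / k2**2
    g3 = k5 / k2**2.5

    p_up_naive, p_lo_naive = gaussian_tail_pvalues(np.asarray(x))
    if min(p_up_naive, p_lo_naive) < fast_threshold:
        p_upper, p_lower = float(p_up_naive), float(p_lo_naive)
        flag = "gaussian_bound"
    else:
        z, ok = cornish_fisher_zscores(np.asarray(x), g1, g2, g3)
        if bool(ok):
            p_upper_a, p_lower_a = gaussian_tail_pvalues(z)
            p_upper, p_lower = float(p_upper_a), float(p_lower_a)
            flag = "cornish_fisher"
        else:
            p_upper, p_lower = float(p_up_naive), float(p_lo_naive)
            flag = "gaussian_fallback"
    p_two = min(1.0, 2.0 * min(p_upper, p_lower))
    return TailProbability(
        p_two_sided=max(p_two, P_FLOOR),
        p_upper=min(max(p_upper, P_FLOOR), 1.0),
        p_lower=min(max(p_lower, P_FLOOR), 1.0),
        method_flag=flag,
    )


def cornish_fisher_pvalue_arrays(stats, k1, k2, k3, k4, k5, fast_threshold=FAST_P_THRESHOLD):
    """Vectorized two-tail CF p-values.

    Returns ``(p_upper, p_lower, flags)`` with flags 0 = cornish_fisher,
    1 = gaussian_fallback, 2 = gaussian_bound (fast path).
    """
    stats, k1, k2, k3, k4, k5 = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(a, float)) for a in (stats, k1, k2, k3, k4, k5))
    )
    if np.any(k2 <= 0):
        raise ValidationError("kappa_2 must be positive")
    x = (stats - k1) / np.sqrt(k2)
    g1 = k3 / k2**1.5
    g2 = k4 / k2**2
    g3 = k5 / k2**2.5

    p_up, p_lo = gaussian_tail_pvalues(x)
    flags = np.full(x.shape, 2, dtype=np.int8)
    slow = np.minimum(p_up, p_lo) >= fast_threshold
    if np.any(slow):
        z, ok = cornish_fisher_zscores(x[slow], g1[slow], g2[slow], g3[slow])
        pu, pl = gaussian_tail_pvalues(z)
        # where inversion failed keep the naive Gaussian values
        pu = np.where(ok, pu, p_up[slow])
        pl = np.where(ok, pl, p_lo[slow])
        p_up = p_up.copy()
        p_lo = p_lo.copy()
        p_up[slow] = pu
        p_lo[slow] = pl
        fl = np.where(ok, 0, 1).astype(np.int8)
        flags[slow] = fl
    return p_up, p_lo, flags


def cf_quartic_roots(x: float, g1: float, g2: float, g3: float) -> np.ndarray:
    """All real roots of CF(z) - x = 0 via the companion matrix (reference).

    Used as an independent cross-check of the Newton-based inversion.
    """
    coeffs = np.zeros(5)  # coeffs[d] multiplies z^d
    coeffs[4] = g3 / 120.0 - g1 * g2 / 24.0 + 12.0 * g1**3 / 324.0
    coeffs[3] = g2 / 24.0 - 2.0 * g1**2 / 36.0
    coeffs[2] = g1 / 6.0 - 6.0 * g3 / 120.0 + 5.0 * g1 * g2 / 24.0 - 53.0 * g1**3 / 324.0
    coeffs[1] = 1.0 - 3.0 * g2 / 24.0 + 5.0 * g1**2 / 36.0
    coeffs[0] = -g1 / 6.0 + 3.0 * g3 / 120.0 - 2.0 * g1 * g2 / 24.0 + 17.0 * g1**3 / 324.0
    coeffs[0] -= x
    # highest-degree first for np.roots; drop negligible leading terms
    poly = coeffs[::-1]
    lead = np.max(np.abs(poly))
    while len(poly) > 1 and abs(poly[0]) < 1e-14 * lead:
        poly = poly[1:]
    roots = np.roots(poly)
    real = roots[np.abs(roots.imag) < 1e-8].real
    return np.sort(real)
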