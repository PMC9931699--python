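"""Rank-based companion tests and distribution checks.

The Mann-Whitney U statistic is built from the pairwise score

    S(x, y) = 0 if x > y,  1/2 if x = y,  1 if x < y,
    U = sum_i sum_j S(X_i, Y_j),

so U counts wins of the second sample (ties count half). With X the first
group (e.g. reproducible) and Y the second, U(X, Y) + U(Y, X) = n1 * n2.
The two-sided p-value comes from full permutation enumeration for small
pooled samples and otherwise from the normal approximation with tie
correction and optional continuity correction.

Also here: the Shapiro-Wilk normality gate that motivates the rank test,
and a goodness-of-fit check of the location-scale t ("NCT") distribution
family via probability-plot (QQ) least-squares fitting followed by a
two-sided Kolmogorov-Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations

import numpy as np
from scipy import optimize, stats

__all__ = [
    "PValueMethod",
    "FrequentistResult",
    "NormalityResult",
    "DistributionFitResult",
    "mann_whitney_u",
    "mwu_pvalue",
    "normality_gate",
    "nct_fit_check",
]

EXACT_POOLED_N = 12  # full enumeration up to this pooled sample size


class PValueMethod(str, Enum):
    EXACT = "EXACT"
    NORMAL_APPROX = "NORMAL_APPROX"


@dataclass(frozen=True)
class FrequentistResult:
    u_statistic: float
    p_value: float
    method: PValueMethod
    n1: int
    n2: int

    def to_dict(self) -> dict:
        return {
            "U": self.u_statistic,
            "p_value": self.p_value,
            "method": self.method.value,
            "n1": self.n1,
            "n2": self.n2,
        }


def _as_vector(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).ravel()
    if v.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} contains non-finite values")
    return v


def mann_whitney_u(X, Y) -> float:
    """U = #{pairs with X < Y} + 1/2 #{tied pairs}, over all n1*n2 pairs."""
    x = _as_vector(X, "X")
    y = _as_vector(Y, "Y")
    diff = y[None, :] - x[:, None]
    return float(np.sum(diff > 0) + 0.5 * np.sum(diff == 0))


def _u_from_mask(pooled: np.ndarray, x_idx: tuple[int, ...]) -> float:
    mask = np.zeros(pooled.size, dtype=bool)
    mask[list(x_idx)] = True
    return mann_whitney_u(pooled[mask], pooled[~mask])


def _exact_pvalue(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided p by enumerating all C(n1+n2, n1) group labelings."""
    pooled = np.concatenate([x, y])
    n1 = x.size
    center = n1 * y.size / 2.0
    dev = abs(u_obs - center) - 1e-12  # guard float noise on half-integers
    total = 0
    extreme = 0
    for idx in combinations(range(pooled.size), n1):
        total += 1
        if abs(_u_from_mask(pooled, idx) - center) >= dev:
            extreme += 1
    return extreme / total


def _normal_pvalue(
    x: np.ndarray, y: np.ndarray, u_obs: float, continuity: bool
) -> float:
    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:  # all pooled values identical
        return 1.0
    mean = n1 * n2 / 2.0
    dev = abs(u_obs - mean)
    if continuity:
        dev = max(dev - 0.5, 0.0)
    z = dev / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def mwu_pvalue(
    X,
    Y,
    exact_threshold: int = EXACT_POOLED_N,
    continuity: bool = True,
) -> FrequentistResult:
    """Two-sided Mann-Whitney U test.

    Exact permutation enumeration when the pooled size is at most
    ``exact_threshold``; otherwise the tie-corrected normal approximation
    (continuity correction on by default).
    """
    x = _as_vector(X, "X")
    y = _as_vector(Y, "Y")
    u = mann_whitney_u(x, y)
    if x.size + y.size <= exact_threshold:
        return FrequentistResult(u, _exact_pvalue(x, y, u), PValueMethod.EXACT,
                                 x.size, y.size)
    return FrequentistResult(u, _normal_pvalue(x, y, u, continuity),
                             PValueMethod.NORMAL_APPROX, x.size, y.size)


@dataclass(frozen=True)
class NormalityResult:
    statistic: float
    p_value: float
    is_normal: bool

    def to_dict(self) -> dict:
        return {"W": self.statistic, "p_value": self.p_value, "is_normal": self.is_normal}


def normality_gate(samples, alpha: float = 0.05) -> NormalityResult:
    """Shapiro-Wilk test; is_normal = (p >= alpha)."""
    x = _as_vector(samples, "samples")
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs n >= 3")
    w, p = stats.shapiro(x)
    return NormalityResult(statistic=float(w), p_value=float(p), is_normal=bool(p >= alpha))


@dataclass(frozen=True)
class DistributionFitResult:
    mu: float
    sigma: float
    nu: float
    r_squared: float
    ks_statistic: float
    ks_p: float

    def to_dict(self) -> dict:
        return {
            "mu": self.mu,
            "sigma": self.sigma,
            "nu": self.nu,
            "r_squared": self.r_squared,
            "ks_statistic": self.ks_statistic,
            "ks_p": self.ks_p,
        }


def nct_fit_check(samples) -> DistributionFitResult:
    """Fit a location-scale t by QQ least squares, then KS-test the fit.

    The shape nu is found by a 1-D search maximizing the probability-plot
    correlation; at each candidate nu, (mu, sigma) are the intercept/slope
    of the order statistics regressed on theoretical t quantiles. The KS
    test treats the fitted parameters as fixed, which makes its p-value
    conservative.
    """
    x = _as_vector(samples, "samples")
    if x.size < 20:
        raise ValueError("need n >= 20 to fit the distribution")
    if np.std(x) == 0:
        raise ValueError("zero-variance data cannot be fitted")

    def neg_r2(log_nu: float) -> float:
        (_, _), (_, _, r) = stats.probplot(x, sparams=(np.exp(log_nu),), dist="t")
        return -r * r

    res = optimize.minimize_scalar(neg_r2, bounds=(np.log(0.5), np.log(200.0)),
                                   method="bounded")
    nu = float(np.exp(res.x))
    (osm, osr), (slope, intercept, r) = stats.probplot(x, sparams=(nu,), dist="t")
    sigma, mu = float(slope), float(intercept)
    if sigma <= 0:
        raise ValueError("degenerate QQ fit (non-positive scale)")
    ks_stat, ks_p = stats.kstest(x, "t", args=(nu, mu, sigma))
    return DistributionFitResult(mu=mu, sigma=sigma, nu=nu, r_squared=float(r * r),
                                 ks_statistic=float(ks_stat), ks_p=float(ks_p))
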