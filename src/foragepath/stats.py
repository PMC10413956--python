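"""Two-group comparison statistics, implemented from their definitions.

Mann-Whitney U (normal approximation with tie correction and continuity
correction), two-sample Kolmogorov-Smirnov (exact sup over the pooled
ECDF grid, asymptotic Kolmogorov p at the effective sample size),
R x C chi-square contingency tests, the pooled two-proportion z test, and
Pearson product-moment correlation with its t-based p.

The statistics themselves are computed from first principles; only the
reference distributions (normal, chi-square, t, Kolmogorov) come from
scipy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special, stats as spstats

__all__ = [
    "RankTestResult",
    "KSResult",
    "ChiSquareResult",
    "TwoProportionResult",
    "CorrelationResult",
    "mann_whitney_u",
    "ks_two_sample",
    "chi_square_rxc",
    "two_proportion_z",
    "pearson_correlation",
]


@dataclass
class RankTestResult:
    U1: float
    U2: float
    U_reported: float  # U of the first-named sample (unreduced convention)
    z: float
    p: float
    median1: float
    median2: float
    n1: int
    n2: int


@dataclass
class KSResult:
    D: float
    p: float
    n1: int
    n2: int


@dataclass
class ChiSquareResult:
    chi2: float
    df: int
    p: float
    expected: np.ndarray
    low_expected_warning: bool = False


@dataclass
class TwoProportionResult:
    z: float
    p: float
    p1_hat: float
    p2_hat: float
    n1: int
    n2: int


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> RankTestResult:
    """Mann-Whitney rank test of two independent samples.

    U1 counts pairs (x_i, y_j) with x_i > y_j, ties counting one half.
    The two-sided p uses the normal approximation with tie-corrected
    variance and a 0.5 continuity correction, adequate at the pooled
    sample sizes this pipeline produces.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = spstats.rankdata(pooled)  # midranks for ties
    R1 = ranks[:n1].sum()
    U1 = R1 - n1 * (n1 + 1) / 2.0
    U2 = n1 * n2 - U1
    mu = n1 * n2 / 2.0
    # tie correction to the variance
    _, counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        warnings.warn("all values tied across both samples", stacklevel=2)
        z, p = 0.0, 1.0
    else:
        diff = U1 - mu
        cc = 0.5 if diff != 0 else 0.0
        z = (diff - math.copysign(cc, diff)) / math.sqrt(var)
        p = min(1.0, 2.0 * float(spstats.norm.sf(abs(z))))
    return RankTestResult(
        U1=float(U1), U2=float(U2), U_reported=float(U1), z=float(z), p=p,
        median1=float(np.median(x)), median2=float(np.median(y)), n1=n1, n2=n2,
    )


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the exact supremum of |ECDF1 - ECDF2| over the pooled sample
    points; p comes from the asymptotic Kolmogorov distribution at the
    effective size n1*n2/(n1+n2), with the Stephens finite-n correction
    factor.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    grid = np.concatenate([x, y])
    cdf1 = np.searchsorted(x, grid, side="right") / n1
    cdf2 = np.searchsorted(y, grid, side="right") / n2
    D = float(np.max(np.abs(cdf1 - cdf2)))
    ne = n1 * n2 / (n1 + n2)
    lam = (math.sqrt(ne) + 0.12 + 0.11 / math.sqrt(ne)) * D
    p = float(special.kolmogorov(lam))
    return KSResult(D=D, p=min(1.0, max(0.0, p)), n1=n1, n2=n2)


def chi_square_rxc(table) -> ChiSquareResult:
    """Pearson chi-square test of independence on an R x C count table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("need an R x C table with R, C >= 2")
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if np.any(row == 0):
        raise ValueError(f"zero marginal row(s): {np.where(row == 0)[0].tolist()}")
    if np.any(col == 0):
        raise ValueError(f"zero marginal column(s): {np.where(col == 0)[0].tolist()}")
    total = obs.sum()
    expected = np.outer(row, col) / total
    chi2 = float(np.sum((obs - expected) ** 2 / expected))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    low = bool(np.any(expected < 5))
    if low:
        warnings.warn("some expected counts < 5; chi-square approximation weak",
                      stacklevel=2)
    p = float(spstats.chi2.sf(chi2, df))
    return ChiSquareResult(chi2=chi2, df=df, p=p, expected=expected,
                           low_expected_warning=low)


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> TwoProportionResult:
    """Pooled-variance two-proportion z test (two-sided)."""
    for k, n in ((k1, n1), (k2, n2)):
        if not (0 <= k <= n) or n < 1:
            raise ValueError("need 0 <= k <= n with n >= 1 in both groups")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        warnings.warn("degenerate pooled proportion; z undefined, reported 0",
                      stacklevel=2)
        return TwoProportionResult(z=0.0, p=1.0, p1_hat=p1, p2_hat=p2, n1=n1, n2=n2)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    p = min(1.0, 2.0 * float(spstats.norm.sf(abs(z))))
    return TwoProportionResult(z=float(z), p=p, p1_hat=p1, p2_hat=p2, n1=n1, n2=n2)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with t-distributed p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must be paired")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3")
    xd, yd = x - x.mean(), y - y.mean()
    sx = math.sqrt(float(np.dot(xd, xd)))
    sy = math.sqrt(float(np.dot(yd, yd)))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance in one of the variables")
    r = float(np.dot(xd, yd)) / (sx * sy)
    r = min(1.0, max(-1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt((n - 2) / (1 - r * r))
        p = min(1.0, 2.0 * float(spstats.t.sf(abs(t), n - 2)))
    return CorrelationResult(r=r, p=p, n=n)
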