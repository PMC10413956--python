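"""Circular statistics for turn angles.

Descriptive summaries (mean direction, mean resultant length R), the
Rayleigh test of circular uniformity (z = n R**2 with the standard series
approximation for p), and a von Mises conformity check: maximum-likelihood
fit of (mu, kappa) followed by a Watson U-squared goodness-of-fit test
against the fitted distribution, reported as a p-value *range* read from a
critical-value table for the estimated-parameters case.

Angles are degrees at the module boundary and radians internally.  Signed
turn angles live in (-180, 180]; folded (absolute) angles in [0, 180].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import special, stats

__all__ = [
    "CircularSummary",
    "RayleighResult",
    "VonMisesFit",
    "circular_mean_R",
    "rayleigh_test",
    "vonmises_fit_and_gof",
    "fold_angles",
    "bessel_ratio",
    "invert_bessel_ratio",
    "watson_u2",
]

KAPPA_CAP = 1e3


@dataclass
class CircularSummary:
    n: int
    mean_angle: Optional[float]   # degrees; undefined when R == 0
    resultant_length_R: float


@dataclass
class RayleighResult:
    z: float
    n: int
    p: float

    @property
    def df_convention_note(self) -> str:
        return f"z uses n = {self.n}; n - 1 = {self.n - 1}"


@dataclass
class VonMisesFit:
    mu: float                     # degrees
    kappa: float
    gof_statistic: float          # Watson U^2 against the fitted von Mises
    gof_p_range: tuple[float, float]
    n: int
    capped: bool = False


def bessel_ratio(kappa) -> np.ndarray | float:
    """A(kappa) = I1(kappa) / I0(kappa), computed with scaled Bessels."""
    kappa = np.asarray(kappa, dtype=float)
    out = special.i1e(kappa) / special.i0e(kappa)
    return float(out) if out.ndim == 0 else out


def invert_bessel_ratio(R: float, tol: float = 1e-10) -> float:
    """Solve A(kappa) = R for kappa by bisection.

    kappa grows without bound as R -> 1, so it is capped at 1e3 (with a
    warning) which corresponds to R ~ 0.9995.
    """
    if not 0.0 <= R < 1.0 + 1e-12:
        raise ValueError(f"R must be in [0, 1], got {R}")
    if R <= 0.0:
        return 0.0
    if bessel_ratio(KAPPA_CAP) <= R:
        warnings.warn("R too close to 1; kappa capped at 1e3", stacklevel=2)
        return KAPPA_CAP
    lo, hi = 0.0, KAPPA_CAP
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        a = bessel_ratio(mid)
        if abs(a - R) < tol:
            return mid
        if a < R:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _to_rad(angles: Sequence[float]) -> np.ndarray:
    return np.deg2rad(np.asarray(angles, dtype=float))


def circular_mean_R(angles: Sequence[float]) -> CircularSummary:
    """Mean direction and mean resultant length of a sample of angles."""
    th = _to_rad(angles)
    if th.size == 0:
        raise ValueError("empty angle sample")
    c, s = np.mean(np.cos(th)), np.mean(np.sin(th))
    R = float(np.hypot(c, s))
    mean = float(np.rad2deg(np.arctan2(s, c))) if R > 1e-15 else None
    return CircularSummary(n=int(th.size), mean_angle=mean, resultant_length_R=R)


def rayleigh_test(angles: Sequence[float]) -> RayleighResult:
    """Rayleigh test of uniformity: z = n R^2.

    p uses the standard fourth-order series approximation
    p ~ exp(-z) [1 + (2z - z^2)/(4n) - (24z - 132z^2 + 76z^3 - 9z^4)/(288 n^2)],
    clamped to [0, 1].  Below n = 5 the approximation is unreliable and a
    warning is attached.
    """
    summ = circular_mean_R(angles)
    n, R = summ.n, summ.resultant_length_R
    if n < 5:
        warnings.warn("Rayleigh p approximation unreliable for n < 5", stacklevel=2)
    z = n * R * R
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z * z) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n * n)
    )
    return RayleighResult(z=float(z), n=n, p=float(min(1.0, max(0.0, p))))


def fold_angles(signed: Sequence[float]) -> np.ndarray:
    """Fold signed angles in (-180, 180] onto [0, 180] by absolute value."""
    return np.abs(np.asarray(signed, dtype=float))


def watson_u2(angles: Sequence[float], mu_deg: float, kappa: float) -> float:
    """Watson U^2 statistic of the sample against von Mises(mu, kappa)."""
    th = _to_rad(angles)
    n = th.size
    if kappa <= 0:
        # fitted distribution degenerates to circular uniform
        u = np.mod(th - np.deg2rad(mu_deg), 2 * np.pi) / (2 * np.pi)
    else:
        centered = np.remainder(th - np.deg2rad(mu_deg) + np.pi, 2 * np.pi) - np.pi
        u = stats.vonmises.cdf(centered, kappa)
    u = np.sort(u)
    i = np.arange(1, n + 1)
    u2 = np.sum((u - (2 * i - 1) / (2 * n)) ** 2) + 1 / (12 * n) - n * (u.mean() - 0.5) ** 2
    return float(u2)


# Upper-tail critical values of Watson U^2 for a von Mises fit with BOTH
# parameters estimated from the data, as a function of the estimated kappa.
# Generated once by parametric bootstrap (20000 replicates per kappa row,
# n = 200, seed 20170620); see scripts/gen_watson_table.py.  Rows: kappa;
# columns: alpha = 0.10, 0.05, 0.025, 0.01.
_WATSON_ALPHAS = (0.10, 0.05, 0.025, 0.01)
_WATSON_KAPPAS = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)
_WATSON_CRIT = (
    (0.0520, 0.0615, 0.0702, 0.0821),  # kappa = 0.0
    (0.0569, 0.0667, 0.0772, 0.0918),  # kappa = 0.5
    (0.0672, 0.0803, 0.0945, 0.1098),  # kappa = 1.0
    (0.0841, 0.1012, 0.1177, 0.1397),  # kappa = 2.0
    (0.0932, 0.1130, 0.1324, 0.1564),  # kappa = 4.0
    (0.0955, 0.1144, 0.1331, 0.1589),  # kappa = 8.0
)


def _watson_critical(kappa: float) -> np.ndarray:
    """Critical values at the table alphas, linearly interpolated in kappa."""
    ks = np.asarray(_WATSON_KAPPAS)
    table = np.asarray(_WATSON_CRIT)
    k = min(max(kappa, ks[0]), ks[-1])
    return np.array([np.interp(k, ks, table[:, j]) for j in range(table.shape[1])])


def vonmises_fit_and_gof(angles: Sequence[float]) -> VonMisesFit:
    """Fit a von Mises distribution and test conformity.

    mu-hat is the circular mean; kappa-hat inverts the Bessel ratio
    A(kappa) = R.  Conformity is assessed with Watson U^2 against the
    fitted distribution; since both parameters are estimated, p is
    reported as a range bracketed by tabulated critical values.
    """
    th = np.asarray(angles, dtype=float)
    if th.size < 10:
        raise ValueError("need n >= 10 for a von Mises fit")
    summ = circular_mean_R(th)
    R = summ.resultant_length_R
    capped = False
    if R >= bessel_ratio(KAPPA_CAP):
        capped = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kappa = invert_bessel_ratio(min(R, 1.0))
    mu = summ.mean_angle if summ.mean_angle is not None else 0.0
    u2 = watson_u2(th, mu, kappa)
    crit = _watson_critical(kappa)
    # bracket the p-value between neighbouring tabulated levels
    if u2 < crit[0]:
        lo, hi = _WATSON_ALPHAS[0], 1.0
    elif u2 >= crit[-1]:
        lo, hi = 0.0, _WATSON_ALPHAS[-1]
    else:
        j = int(np.searchsorted(crit, u2, side="right")) - 1
        lo, hi = _WATSON_ALPHAS[j + 1], _WATSON_ALPHAS[j]
    return VonMisesFit(
        mu=mu, kappa=kappa, gof_statistic=u2, gof_p_range=(lo, hi),
        n=int(th.size), capped=capped,
    )
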