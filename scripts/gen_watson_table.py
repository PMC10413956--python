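"""Regenerate the Watson U^2 critical-value table in foragepath.circular.

Parametric bootstrap for the estimated-parameters case: for each true
kappa, draw von Mises samples, refit (mu, kappa) on each, compute the
Watson U^2 statistic against the *fitted* distribution, and take the
upper-tail empirical quantiles.  20000 replicates of n = 200 per kappa
row; the critical values depend only weakly on n at this size.

Run from the repository root:  python scripts/gen_watson_table.py
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from foragepath.circular import bessel_ratio

SEED = 20170620
N = 200
REPS = 20000
KAPPAS = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)
ALPHAS = (0.10, 0.05, 0.025, 0.01)

# Bessel-ratio inversion by interpolation on a fine grid (plenty accurate
# for generating quantiles)
_kgrid = np.concatenate([[0.0], np.logspace(-3, 3.5, 4000)])
_agrid = bessel_ratio(_kgrid)


def invert_R(R: np.ndarray) -> np.ndarray:
    return np.interp(R, _agrid, _kgrid)


def watson_u2_rows(theta: np.ndarray, kappa_hat: np.ndarray,
                   mu_hat: np.ndarray) -> np.ndarray:
    n = theta.shape[1]
    centered = np.remainder(theta - mu_hat[:, None] + np.pi, 2 * np.pi) - np.pi
    u = np.where(
        kappa_hat[:, None] > 0,
        stats.vonmises.cdf(centered, np.maximum(kappa_hat, 1e-12)[:, None]),
        (centered + np.pi) / (2 * np.pi),
    )
    u = np.sort(u, axis=1)
    i = np.arange(1, n + 1)
    return (
        np.sum((u - (2 * i - 1) / (2 * n)) ** 2, axis=1)
        + 1 / (12 * n)
        - n * (u.mean(axis=1) - 0.5) ** 2
    )


def main() -> None:
    rng = np.random.default_rng(SEED)
    print("_WATSON_ALPHAS =", ALPHAS)
    print("_WATSON_KAPPAS =", KAPPAS)
    print("_WATSON_CRIT = (")
    for kappa in KAPPAS:
        if kappa == 0.0:
            theta = rng.uniform(-np.pi, np.pi, size=(REPS, N))
        else:
            theta = rng.vonmises(0.0, kappa, size=(REPS, N))
        C = np.cos(theta).mean(axis=1)
        S = np.sin(theta).mean(axis=1)
        R = np.hypot(C, S)
        mu_hat = np.arctan2(S, C)
        kappa_hat = invert_R(R)
        u2 = watson_u2_rows(theta, kappa_hat, mu_hat)
        q = np.quantile(u2, [1 - a for a in ALPHAS])
        print("    (" + ", ".join(f"{v:.4f}" for v in q) + f"),  # kappa = {kappa}")
    print(")")


if __name__ == "__main__":
    main()
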