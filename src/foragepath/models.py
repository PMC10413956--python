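"""Regression stages: step-length mixed model and observer-effect trend.

Within-species variation in step length is modelled with a linear mixed
model: random intercept per individual lizard, fixed effects sex, body
size (SVL) and the weather covariates (air temperature, wind speed) at
the minute of the step.  The model is fitted by restricted maximum
likelihood, profiled down to a single variance-ratio parameter
lambda = sigma_individual^2 / sigma_residual^2; for a random-intercept
model every REML quantity is then available in closed form given lambda,
so the fit reduces to a bounded scalar search.

Fixed-effect F tests (numerator df 1) use the containment method for the
denominator df: effects constant within individuals are tested against
(number of individuals - number of between-individual columns), effects
varying within individuals against (records - individuals - number of
within-individual columns).

The observer-effect check regresses a pooled per-minute response (step
length or absolute turn angle) on time in the observation; a trend would
indicate that the observers' presence altered behaviour over the follow.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as spstats

from .data import Dataset
from .paths import compute_steps, turn_angles

__all__ = [
    "StepRecord",
    "FixedEffect",
    "MixedModelResult",
    "TrendTestResult",
    "build_step_records",
    "fit_step_length_lmm",
    "observer_effect_trend",
]

logger = logging.getLogger(__name__)


@dataclass
class StepRecord:
    lizard_id: str
    step_length: float
    t: int                   # minute index of the destination fix
    sex: str
    svl_mm: float
    air_temp_c: float
    wind_speed_ms: float


@dataclass
class FixedEffect:
    estimate: float
    std_error: float
    F: float
    df_num: int
    df_den: int
    p: float


@dataclass
class MixedModelResult:
    fixed_effects: dict[str, FixedEffect]
    variance_individual: float
    variance_residual: float
    n_records: int
    n_individuals: int
    singular: bool
    var_ratio: float
    reml_objective: float
    objective_trace: list[float] = field(default_factory=list)
    df_method: str = "containment"
    response_transform: str = "identity"


@dataclass
class TrendTestResult:
    slope: float
    F: float
    df: tuple[int, int]
    p: float
    n: int


def build_step_records(dataset: Dataset, species: str,
                       move_epsilon: float = 0.0) -> list[StepRecord]:
    """One record per moving interval, covariates joined by minute.

    Records with any absent covariate (sex unknown, missing SVL or
    weather) are dropped listwise; the number dropped is logged.
    """
    observations = dataset.by_species(species)
    if not observations:
        raise ValueError(f"species {species!r} not present in dataset")
    records: list[StepRecord] = []
    dropped = 0
    for obs in observations:
        fixes_by_t = {fx.t: fx for fx in obs.fixes}
        for step in compute_steps(obs, move_epsilon):
            if not step.moved:
                continue
            fx = fixes_by_t[step.to_t]
            if (
                obs.sex in ("M", "F")
                and obs.svl_mm is not None
                and fx.air_temp_c is not None
                and fx.wind_speed_ms is not None
            ):
                records.append(
                    StepRecord(
                        lizard_id=obs.lizard_id,
                        step_length=step.length,
                        t=step.to_t,
                        sex=obs.sex,
                        svl_mm=obs.svl_mm,
                        air_temp_c=fx.air_temp_c,
                        wind_speed_ms=fx.wind_speed_ms,
                    )
                )
            else:
                dropped += 1
    if dropped:
        logger.info("build_step_records(%s): dropped %d record(s) with absent covariates",
                    species, dropped)
    return records


def _design(records: Sequence[StepRecord], response_transform: str):
    y = np.array([r.step_length for r in records], dtype=float)
    if response_transform == "log":
        y = np.log(y)
    elif response_transform != "identity":
        raise ValueError(f"unknown response_transform {response_transform!r}")
    cols = {"intercept": np.ones(len(records))}
    sexes = sorted({r.sex for r in records})
    if len(sexes) > 1:
        # treatment coding against the alphabetically first level
        cols[f"sex[{sexes[1]}]"] = np.array(
            [1.0 if r.sex == sexes[1] else 0.0 for r in records])
    cols["svl_mm"] = np.array([r.svl_mm for r in records])
    cols["air_temp_c"] = np.array([r.air_temp_c for r in records])
    cols["wind_speed_ms"] = np.array([r.wind_speed_ms for r in records])
    names = list(cols)
    X = np.column_stack([cols[c] for c in names])
    groups = np.array([r.lizard_id for r in records])
    return y, X, names, groups


class _ProfiledREML:
    """Closed-form REML pieces for a random-intercept model, given lambda.

    With V_i = I + lambda * J (block per group), V_i^{-1} = I - c_i J with
    c_i = lambda / (1 + lambda n_i), so X'V^{-1}X, X'V^{-1}y and y'V^{-1}y
    only need per-group column sums.
    """

    def __init__(self, y, X, groups):
        self.n, self.p = X.shape
        uniq, idx = np.unique(groups, return_inverse=True)
        self.g = uniq.size
        self.sizes = np.bincount(idx).astype(float)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        # per-group sums of columns and of y
        self.S = np.zeros((self.g, self.p))
        np.add.at(self.S, idx, X)
        self.T = np.bincount(idx, weights=y)

    def pieces(self, lam: float):
        c = lam / (1.0 + lam * self.sizes)
        A = self.XtX - (self.S * c[:, None]).T @ self.S
        b = self.Xty - self.S.T @ (c * self.T)
        q = self.yty - float(c @ (self.T**2))
        beta = np.linalg.solve(A, b)
        rss = q - float(beta @ b)
        return A, beta, rss

    def objective(self, lam: float) -> float:
        """-2 REML log-likelihood up to an additive constant."""
        A, _, rss = self.pieces(lam)
        if rss <= 0:
            return np.inf
        nmp = self.n - self.p
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        logdetV = float(np.sum(np.log1p(lam * self.sizes)))
        return nmp * math.log(rss) + logdetV + logdetA


def _minimize_lambda(prof: _ProfiledREML, tol: float = 1e-8):
    """Grid scan plus golden-section refinement over the variance ratio.

    Returns (lambda_hat, objective, trace) where trace is the best-so-far
    objective sequence (non-increasing by construction).
    """
    grid = np.concatenate([[0.0], np.logspace(-6, 4, 41)])
    trace: list[float] = []
    best = np.inf
    best_i = 0
    vals = []
    for i, lam in enumerate(grid):
        v = prof.objective(lam)
        vals.append(v)
        if v < best:
            best, best_i = v, i
        trace.append(best)
    lo = grid[max(best_i - 1, 0)]
    hi = grid[min(best_i + 1, len(grid) - 1)]
    phi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    x1 = b - phi * (b - a)
    x2 = a + phi * (b - a)
    f1, f2 = prof.objective(x1), prof.objective(x2)
    for _ in range(200):
        if b - a < tol * (1.0 + a):
            break
        if f1 <= f2:
            b, x2, f2 = x2, x1, f1
            x1 = b - phi * (b - a)
            f1 = prof.objective(x1)
        else:
            a, x1, f1 = x1, x2, f2
            x2 = a + phi * (b - a)
            f2 = prof.objective(x2)
        best = min(best, f1, f2)
        trace.append(best)
    lam = x1 if f1 <= f2 else x2
    obj = min(f1, f2)
    if prof.objective(0.0) <= obj:
        lam, obj = 0.0, prof.objective(0.0)
    trace.append(min(best, obj))
    return float(lam), float(obj), trace


def fit_step_length_lmm(records: Sequence[StepRecord],
                        response_transform: str = "identity",
                        var_ratio: Optional[float] = None) -> MixedModelResult:
    """Random-intercept REML fit of step length on sex, SVL and weather.

    ``var_ratio`` fixes lambda = sigma_ind^2 / sigma_res^2 instead of
    estimating it (0 reduces the fit to ordinary least squares).
    """
    records = list(records)
    individuals = {r.lizard_id for r in records}
    if len(individuals) < 2:
        raise ValueError("need records from at least 2 individuals")
    if len(records) < 10:
        raise ValueError("need at least 10 records")
    y, X, names, groups = _design(records, response_transform)
    prof = _ProfiledREML(y, X, groups)
    if var_ratio is None:
        lam, obj, trace = _minimize_lambda(prof)
    else:
        if var_ratio < 0:
            raise ValueError("var_ratio must be >= 0")
        lam = float(var_ratio)
        obj = prof.objective(lam)
        trace = [obj]
    A, beta, rss = prof.pieces(lam)
    nmp = prof.n - prof.p
    sigma2 = rss / nmp
    cov = sigma2 * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov))

    # containment denominator df per column
    uniq, idx = np.unique(groups, return_inverse=True)
    between = []
    for j in range(X.shape[1]):
        col = X[:, j]
        gmin = np.full(uniq.size, np.inf)
        gmax = np.full(uniq.size, -np.inf)
        np.minimum.at(gmin, idx, col)
        np.maximum.at(gmax, idx, col)
        between.append(bool(np.all(gmax - gmin == 0.0)))
    q_between = sum(between)
    q_within = X.shape[1] - q_between
    df_b = max(int(uniq.size - q_between), 1)
    df_w = max(int(prof.n - uniq.size - q_within), 1)

    effects: dict[str, FixedEffect] = {}
    for j, name in enumerate(names):
        F = float((beta[j] / se[j]) ** 2) if se[j] > 0 else np.inf
        df_den = df_b if between[j] else df_w
        p = float(spstats.f.sf(F, 1, df_den))
        effects[name] = FixedEffect(
            estimate=float(beta[j]), std_error=float(se[j]),
            F=F, df_num=1, df_den=df_den, p=p,
        )
    return MixedModelResult(
        fixed_effects=effects,
        variance_individual=float(lam * sigma2),
        variance_residual=float(sigma2),
        n_records=prof.n,
        n_individuals=int(uniq.size),
        singular=lam < 1e-8,
        var_ratio=float(lam),
        reml_objective=float(obj),
        objective_trace=trace,
        response_transform=response_transform,
    )


def observer_effect_trend(dataset: Dataset, species: str,
                          response: str = "step_length",
                          move_epsilon: float = 0.0) -> TrendTestResult:
    """Pooled least-squares trend of a movement response on minute index.

    ``response`` is ``"step_length"`` (length of each moving step at its
    destination minute) or ``"turn_angle_abs"`` (absolute turn angle at
    the minute of its second step).  A significant slope would indicate
    behaviour changing over the course of an observation.
    """
    observations = dataset.by_species(species)
    if not observations:
        raise ValueError(f"species {species!r} not present in dataset")
    ts: list[float] = []
    ys: list[float] = []
    for obs in observations:
        steps = compute_steps(obs, move_epsilon)
        if response == "step_length":
            for s in steps:
                if s.moved:
                    ts.append(s.to_t)
                    ys.append(s.length)
        elif response == "turn_angle_abs":
            moving = [s for s in steps if s.moved]
            signed, folded = turn_angles(steps)
            # angle i sits between moving steps i and i+1
            for ang, s in zip(folded, moving[1:]):
                ts.append(s.to_t)
                ys.append(ang)
        else:
            raise ValueError(f"unknown response {response!r}")
    n = len(ys)
    if n < 10:
        raise ValueError("need at least 10 pooled response values")
    t = np.asarray(ts, dtype=float)
    y = np.asarray(ys, dtype=float)
    td = t - t.mean()
    yd = y - y.mean()
    stt = float(td @ td)
    if stt == 0.0:
        raise ValueError("no variation in minute index")
    slope = float(td @ yd) / stt
    resid = yd - slope * td
    rss = float(resid @ resid)
    if rss <= 0.0 or float(yd @ yd) == 0.0:
        return TrendTestResult(slope=slope, F=0.0, df=(1, n - 2), p=1.0, n=n)
    se2 = rss / (n - 2) / stt
    F = slope * slope / se2
    p = float(spstats.f.sf(F, 1, n - 2))
    return TrendTestResult(slope=slope, F=float(F), df=(1, n - 2), p=p, n=n)
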