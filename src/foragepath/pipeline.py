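"""Full two-species analysis: orchestration, report assembly, export.

``run_full_analysis`` takes a validated dataset with exactly two species
and produces an :class:`AnalysisReport` containing

* per-species median (range) summaries of the five path metrics,
* Mann-Whitney comparisons per metric (pooled fixes by default; a
  per-individual mode aggregates to one value per animal first, since
  pooling repeated measures pseudo-replicates),
* Kolmogorov-Smirnov comparisons of the step-length and turn-angle
  distributions,
* circular statistics per species (mean vector, Rayleigh uniformity,
  von Mises conformity),
* the two-proportion test on the fraction of intervals with movement,
* step-length x turn-angle correlations,
* habitat-use contingency tables (cover, visibility, plant species) with
  chi-square tests,
* the step-length mixed model and observer-effect trend tests.

Incomplete observations contribute step lengths and turn angles but no
whole-path metrics.  No multiple-testing adjustment is applied; the
report records the number of tests performed so readers can judge the
familywise error themselves.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .circular import (
    CircularSummary,
    RayleighResult,
    VonMisesFit,
    circular_mean_R,
    fold_angles,
    rayleigh_test,
    vonmises_fit_and_gof,
)
from .data import Dataset, HABITAT_OPEN, HABITAT_VEGETATION
from .models import (
    MixedModelResult,
    TrendTestResult,
    build_step_records,
    fit_step_length_lmm,
    observer_effect_trend,
)
from .paths import PathSummary, summarize_observation
from .stats import (
    ChiSquareResult,
    CorrelationResult,
    KSResult,
    RankTestResult,
    TwoProportionResult,
    chi_square_rxc,
    ks_two_sample,
    mann_whitney_u,
    pearson_correlation,
    two_proportion_z,
)

__all__ = ["RunConfig", "AnalysisReport", "run_full_analysis", "export_report"]

logger = logging.getLogger(__name__)

METRICS = [
    "step_length",
    "path_length",
    "net_displacement",
    "straightness_index",
    "turn_angle",
]


@dataclass
class RunConfig:
    """Analysis options; every default mirrors the documented field rules."""

    move_epsilon: float = 0.0            # meters; >0 treats tiny shifts as pauses
    carry_across_pauses: bool = True     # turn angles span pauses
    angle_convention: str = "signed"     # circular tests: "signed" or "folded"
    analysis_unit: str = "pooled"        # "pooled" fixes or "per_individual"
    include_models: bool = True
    response_transform: str = "identity"  # step-length LMM response
    alpha: float = 0.05
    step_hist_bin_m: float = 2.0
    turn_hist_bin_deg: float = 45.0

    def __post_init__(self):
        if self.angle_convention not in ("signed", "folded"):
            raise ValueError("angle_convention must be 'signed' or 'folded'")
        if self.analysis_unit not in ("pooled", "per_individual"):
            raise ValueError("analysis_unit must be 'pooled' or 'per_individual'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class MetricSummary:
    median: float
    min: float
    max: float
    n: int


@dataclass
class AnalysisReport:
    species: tuple[str, str]
    per_species_summaries: dict[str, dict[str, MetricSummary]]
    movement_comparisons: dict[str, RankTestResult]
    distribution_tests: dict[str, KSResult]
    circular_results: dict[str, dict]
    proportion_moving_test: dict
    correlation_results: dict[str, CorrelationResult]
    habitat_tables: dict[str, dict]
    model_results: dict[str, object]
    observer_effects: dict[str, object]
    histograms: dict[str, pd.DataFrame]
    n_tests: int
    errors: dict[str, str] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def _pool(summaries: list[PathSummary], attr: str) -> np.ndarray:
    out: list[float] = []
    for s in summaries:
        v = getattr(s, attr)
        if isinstance(v, list):
            out.extend(v)
        elif v is not None:
            out.append(v)
    return np.asarray(out, dtype=float)


def _per_obs_median(summaries: list[PathSummary], attr: str) -> np.ndarray:
    out = [float(np.median(getattr(s, attr))) for s in summaries if getattr(s, attr)]
    return np.asarray(out, dtype=float)


def _metric_summary(values: np.ndarray) -> Optional[MetricSummary]:
    if values.size == 0:
        return None
    return MetricSummary(
        median=float(np.median(values)), min=float(values.min()),
        max=float(values.max()), n=int(values.size),
    )


def run_full_analysis(dataset: Dataset, config: Optional[RunConfig] = None) -> AnalysisReport:
    config = config or RunConfig()
    species = dataset.species_labels()
    if len(species) != 2:
        raise ValueError(f"analysis needs exactly two species, found {species}")
    sp1, sp2 = species

    summaries = {
        sp: [
            summarize_observation(o, config.move_epsilon, config.carry_across_pauses)
            for o in dataset.by_species(sp)
        ]
        for sp in species
    }
    logger.info("summarized observations: %s", {sp: len(v) for sp, v in summaries.items()})

    errors: dict[str, str] = {}
    notes: list[str] = []
    n_tests = 0

    # --- per-species medians and ranges (the five path metrics) ---
    pooled = {
        sp: {
            "step_length": _pool(summaries[sp], "step_lengths"),
            "path_length": _pool(summaries[sp], "path_length"),
            "net_displacement": _pool(summaries[sp], "net_displacement"),
            "straightness_index": _pool(summaries[sp], "straightness_index"),
            "turn_angle": _pool(summaries[sp], "turn_angles_abs"),
            "turn_angle_signed": _pool(summaries[sp], "turn_angles_signed"),
        }
        for sp in species
    }
    per_species = {
        metric: {sp: _metric_summary(pooled[sp][metric]) for sp in species}
        for metric in METRICS
    }

    # --- Mann-Whitney comparisons per metric ---
    per_indiv = config.analysis_unit == "per_individual"
    movement_comparisons: dict[str, RankTestResult] = {}
    mw_samples: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for metric in METRICS:
        if metric in ("step_length", "turn_angle") and per_indiv:
            attr = "step_lengths" if metric == "step_length" else "turn_angles_abs"
            a = _per_obs_median(summaries[sp1], attr)
            b = _per_obs_median(summaries[sp2], attr)
        else:
            a, b = pooled[sp1][metric], pooled[sp2][metric]
        mw_samples[metric] = (a, b)
        try:
            movement_comparisons[metric] = mann_whitney_u(a, b)
            n_tests += 1
        except ValueError as exc:
            errors[f"mann_whitney[{metric}]"] = str(exc)

    # --- KS distribution comparisons (step length, turn angle) ---
    distribution_tests: dict[str, KSResult] = {}
    for metric in ("step_length", "turn_angle"):
        a, b = mw_samples[metric]
        try:
            distribution_tests[metric] = ks_two_sample(a, b)
            n_tests += 1
        except ValueError as exc:
            errors[f"ks[{metric}]"] = str(exc)

    # --- circular statistics per species ---
    circular_results: dict[str, dict] = {}
    for sp in species:
        angles = (
            pooled[sp]["turn_angle_signed"]
            if config.angle_convention == "signed"
            else pooled[sp]["turn_angle"]
        )
        entry: dict = {"convention": config.angle_convention, "n": int(angles.size)}
        try:
            entry["summary"] = circular_mean_R(angles)
            entry["rayleigh"] = rayleigh_test(angles)
            n_tests += 1
        except ValueError as exc:
            errors[f"circular[{sp}]"] = str(exc)
        try:
            entry["vonmises"] = vonmises_fit_and_gof(angles)
            n_tests += 1
        except ValueError as exc:
            entry["vonmises"] = None
            notes.append(f"von Mises fit skipped for {sp}: {exc}")
        circular_results[sp] = entry

    # --- proportion of intervals with movement ---
    def _moving_counts(sp: str) -> tuple[int, int]:
        k = sum(len(s.step_lengths) for s in summaries[sp])
        n = sum(s.n_intervals for s in summaries[sp])
        return k, n

    try:
        if per_indiv:
            a = np.array([s.proportion_moving for s in summaries[sp1]])
            b = np.array([s.proportion_moving for s in summaries[sp2]])
            proportion_test = {"mode": "per_individual", "result": mann_whitney_u(a, b)}
        else:
            k1, n1 = _moving_counts(sp1)
            k2, n2 = _moving_counts(sp2)
            proportion_test = {
                "mode": "pooled",
                "result": two_proportion_z(k1, n1, k2, n2),
            }
        n_tests += 1
    except ValueError as exc:
        proportion_test = {"mode": config.analysis_unit, "result": None}
        errors["proportion_moving"] = str(exc)

    # --- step length x turn angle correlation per species ---
    correlation_results: dict[str, CorrelationResult] = {}
    for sp in species:
        xs: list[float] = []
        ys: list[float] = []
        for s in summaries[sp]:
            # turn angle i sits between moving steps i and i+1; pair it with
            # the length of the outgoing (second) step
            for ang, ln in zip(s.turn_angles_abs, s.step_lengths[1:]):
                xs.append(ang)
                ys.append(ln)
        try:
            correlation_results[sp] = pearson_correlation(xs, ys)
            n_tests += 1
        except ValueError as exc:
            errors[f"correlation[{sp}]"] = str(exc)

    # --- habitat-use contingency tables ---
    habitat_tables: dict[str, dict] = {}

    def _cover_counts(sp: str) -> tuple[int, int]:
        open_n = veg_n = 0
        for obs in dataset.by_species(sp):
            for fx in obs.fixes:
                if fx.habitat == HABITAT_VEGETATION:
                    veg_n += 1
                else:
                    open_n += 1
        return open_n, veg_n

    cover = pd.DataFrame(
        [_cover_counts(sp) for sp in species],
        index=species, columns=[HABITAT_OPEN, HABITAT_VEGETATION],
    )
    habitat_tables["cover"] = {"table": cover}
    try:
        habitat_tables["cover"]["test"] = chi_square_rxc(cover.to_numpy())
        n_tests += 1
    except ValueError as exc:
        errors["chi_square[cover]"] = str(exc)

    def _vis_counts(sp: str) -> tuple[int, int]:
        clear = obstructed = 0
        for obs in dataset.by_species(sp):
            for fx in obs.fixes[1:]:
                if fx.visible_from_previous is True:
                    clear += 1
                elif fx.visible_from_previous is False:
                    obstructed += 1
        return clear, obstructed

    vis = pd.DataFrame(
        [_vis_counts(sp) for sp in species],
        index=species, columns=["clear", "obstructed"],
    )
    habitat_tables["visibility"] = {"table": vis}
    try:
        habitat_tables["visibility"]["test"] = chi_square_rxc(vis.to_numpy())
        n_tests += 1
    except ValueError as exc:
        errors["chi_square[visibility]"] = str(exc)

    plant_counts: dict[str, dict[str, int]] = {sp: {} for sp in species}
    for sp in species:
        for obs in dataset.by_species(sp):
            for fx in obs.fixes:
                if fx.plant_species:
                    plant_counts[sp][fx.plant_species] = (
                        plant_counts[sp].get(fx.plant_species, 0) + 1
                    )
    all_plants = sorted(set(plant_counts[sp1]) | set(plant_counts[sp2]))
    plants = pd.DataFrame(
        [[plant_counts[sp].get(p, 0) for p in all_plants] for sp in species],
        index=species, columns=all_plants,
    )
    habitat_tables["plants"] = {"table": plants}
    if len(all_plants) >= 2:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                habitat_tables["plants"]["test"] = chi_square_rxc(plants.to_numpy())
            n_tests += 1
        except ValueError as exc:
            errors["chi_square[plants]"] = str(exc)
    else:
        notes.append("plant-use chi-square skipped: fewer than two plant species recorded")

    # --- regression stages ---
    model_results: dict[str, object] = {}
    observer_effects: dict[str, object] = {}
    if config.include_models:
        for sp in species:
            try:
                records = build_step_records(dataset, sp, config.move_epsilon)
                model_results[sp] = fit_step_length_lmm(
                    records, response_transform=config.response_transform)
                n_tests += len(model_results[sp].fixed_effects)
            except ValueError as exc:
                errors[f"lmm[{sp}]"] = str(exc)
            for response in ("step_length", "turn_angle_abs"):
                try:
                    observer_effects[f"{sp}:{response}"] = observer_effect_trend(
                        dataset, sp, response, config.move_epsilon)
                    n_tests += 1
                except ValueError as exc:
                    errors[f"observer_effect[{sp}:{response}]"] = str(exc)

    # --- histogram exports (turn angles in 45-degree bins, step lengths) ---
    histograms: dict[str, pd.DataFrame] = {}
    tb = config.turn_hist_bin_deg
    edges = np.arange(0.0, 180.0 + tb, tb)
    histograms["turn_angle"] = pd.DataFrame(
        {
            "bin_left_deg": edges[:-1],
            "bin_right_deg": edges[1:],
            **{
                sp: np.histogram(pooled[sp]["turn_angle"], bins=edges)[0]
                for sp in species
            },
        }
    )
    max_step = max(
        (pooled[sp]["step_length"].max() for sp in species if pooled[sp]["step_length"].size),
        default=0.0,
    )
    sb = config.step_hist_bin_m
    sedges = np.arange(0.0, max_step + sb, sb) if max_step > 0 else np.array([0.0, sb])
    histograms["step_length"] = pd.DataFrame(
        {
            "bin_left_m": sedges[:-1],
            "bin_right_m": sedges[1:],
            **{
                sp: np.histogram(pooled[sp]["step_length"], bins=sedges)[0]
                for sp in species
            },
        }
    )

    notes.append(
        "No multiple-testing adjustment applied; interpret p-values in light "
        f"of the {n_tests} tests performed."
    )
    notes.append(
        "Cover table uses the two recorded habitat classes (open/vegetation)."
    )

    report = AnalysisReport(
        species=(sp1, sp2),
        per_species_summaries=per_species,
        movement_comparisons=movement_comparisons,
        distribution_tests=distribution_tests,
        circular_results=circular_results,
        proportion_moving_test=proportion_test,
        correlation_results=correlation_results,
        habitat_tables=habitat_tables,
        model_results=model_results,
        observer_effects=observer_effects,
        histograms=histograms,
        n_tests=n_tests,
        errors=errors,
        notes=notes,
        provenance={
            "config": config.to_dict(),
            "dataset": dataset.provenance,
            "n_observations": {sp: len(dataset.by_species(sp)) for sp in species},
            "software_version": __version__,
        },
    )
    return report


def _num(x) -> str:
    return repr(float(x))


def export_report(report: AnalysisReport, path) -> None:
    """Write the report as CSV tables plus a markdown summary.

    Numeric fields are written with full precision (repr), so re-imported
    tables agree with the in-memory report to better than 12 significant
    digits.
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    sp1, sp2 = report.species

    # Table-2-layout: five metric rows, median (range) per species, U, p
    rows = []
    for metric in METRICS:
        cells = {}
        for sp in report.species:
            ms = report.per_species_summaries[metric][sp]
            cells[sp] = (
                "NA" if ms is None else f"{ms.median:.3g} ({ms.min:.3g}-{ms.max:.3g})"
            )
        mw = report.movement_comparisons.get(metric)
        rows.append(
            {
                "metric": metric,
                sp1: cells[sp1],
                sp2: cells[sp2],
                "U": "NA" if mw is None else _num(mw.U_reported),
                "p": "NA" if mw is None else _num(mw.p),
            }
        )
    pd.DataFrame(rows).to_csv(out / "movement_metrics.csv", index=False)

    # long-format numeric results for machine consumption
    tests: list[dict] = []

    def add(test: str, unit: str, **kv):
        row = {"test": test, "unit": unit}
        for k, v in kv.items():
            row[k] = _num(v) if isinstance(v, (int, float, np.floating)) else v
        tests.append(row)

    for metric, mw in report.movement_comparisons.items():
        add(f"mann_whitney[{metric}]", "per_obs" if metric not in ("step_length", "turn_angle")
            else report.provenance["config"]["analysis_unit"],
            U1=mw.U1, U2=mw.U2, U=mw.U_reported, z=mw.z, p=mw.p,
            median1=mw.median1, median2=mw.median2, n1=mw.n1, n2=mw.n2)
    for metric, ks in report.distribution_tests.items():
        add(f"ks[{metric}]", report.provenance["config"]["analysis_unit"],
            D=ks.D, p=ks.p, n1=ks.n1, n2=ks.n2)
    for sp, entry in report.circular_results.items():
        if "summary" in entry:
            s: CircularSummary = entry["summary"]
            r: RayleighResult = entry["rayleigh"]
            add(f"rayleigh[{sp}]", entry["convention"],
                z=r.z, p=r.p, n=r.n, n_minus_1=r.n - 1,
                R=s.resultant_length_R,
                mean_angle=s.mean_angle if s.mean_angle is not None else "NA")
        vm: Optional[VonMisesFit] = entry.get("vonmises")
        if vm is not None:
            add(f"vonmises_gof[{sp}]", entry["convention"],
                mu=vm.mu, kappa=vm.kappa, U2=vm.gof_statistic,
                p_low=vm.gof_p_range[0], p_high=vm.gof_p_range[1], n=vm.n)
    pm = report.proportion_moving_test.get("result")
    if pm is not None:
        if isinstance(pm, TwoProportionResult):
            add("proportion_moving", "pooled", z=pm.z, p=pm.p,
                p1_hat=pm.p1_hat, p2_hat=pm.p2_hat, n1=pm.n1, n2=pm.n2)
        else:
            add("proportion_moving", "per_individual", U=pm.U_reported, z=pm.z,
                p=pm.p, median1=pm.median1, median2=pm.median2, n1=pm.n1, n2=pm.n2)
    for sp, cr in report.correlation_results.items():
        add(f"correlation[{sp}]", "pooled", r=cr.r, p=cr.p, n=cr.n)
    for name, entry in report.habitat_tables.items():
        test: Optional[ChiSquareResult] = entry.get("test")
        if test is not None:
            add(f"chi_square[{name}]", "pooled", chi2=test.chi2, df=test.df, p=test.p)
    for sp, mr in report.model_results.items():
        if isinstance(mr, MixedModelResult):
            for eff, fe in mr.fixed_effects.items():
                add(f"lmm[{sp}:{eff}]", "mixed",
                    estimate=fe.estimate, se=fe.std_error, F=fe.F,
                    df_num=fe.df_num, df_den=fe.df_den, p=fe.p)
            add(f"lmm_variance[{sp}]", "mixed",
                individual=mr.variance_individual, residual=mr.variance_residual,
                n=mr.n_records, n_individuals=mr.n_individuals,
                singular=str(mr.singular))
    for key, tr in report.observer_effects.items():
        if isinstance(tr, TrendTestResult):
            add(f"observer_effect[{key}]", "pooled", slope=tr.slope, F=tr.F,
                df1=tr.df[0], df2=tr.df[1], p=tr.p, n=tr.n)
    pd.DataFrame(tests).to_csv(out / "tests.csv", index=False)

    for name, entry in report.habitat_tables.items():
        entry["table"].to_csv(out / f"habitat_{name}.csv")
    for name, df in report.histograms.items():
        df.to_csv(out / f"hist_{name}.csv", index=False)

    with open(out / "provenance.json", "w") as fh:
        json.dump(report.provenance, fh, indent=2, default=str)

    # human-readable summary
    lines = [
        "# Movement and habitat-use analysis",
        "",
        f"Species compared: **{sp1}** vs **{sp2}** "
        f"(n = {report.provenance['n_observations'][sp1]} / "
        f"{report.provenance['n_observations'][sp2]} observations).",
        "",
        "## Movement metrics (median (range))",
        "",
        f"| metric | {sp1} | {sp2} | U | p |",
        "|---|---|---|---|---|",
    ]
    for row in rows:
        u = row["U"] if row["U"] == "NA" else f"{float(row['U']):.4g}"
        p = row["p"] if row["p"] == "NA" else f"{float(row['p']):.3g}"
        lines.append(f"| {row['metric']} | {row[sp1]} | {row[sp2]} | {u} | {p} |")
    pmres = report.proportion_moving_test.get("result")
    if isinstance(pmres, TwoProportionResult):
        lines += [
            "",
            f"Proportion of intervals with movement: {pmres.p1_hat:.1%} ({sp1}) vs "
            f"{pmres.p2_hat:.1%} ({sp2}); z = {pmres.z:.2f}, p = {pmres.p:.3g}.",
        ]
    for sp, entry in report.circular_results.items():
        if "summary" in entry:
            s, r = entry["summary"], entry["rayleigh"]
            lines.append(
                f"Turn angles ({sp}, {entry['convention']}): R = "
                f"{s.resultant_length_R:.3f}, Rayleigh z = {r.z:.2f} "
                f"(n = {r.n}), p = {r.p:.3g}."
            )
    if report.model_results:
        lines += ["", "## Step-length mixed models (containment df)", ""]
        for sp, mr in report.model_results.items():
            if isinstance(mr, MixedModelResult):
                lines.append(
                    f"- {sp}: variance (individual / residual) = "
                    f"{mr.variance_individual:.4g} / {mr.variance_residual:.4g}; "
                    + "; ".join(
                        f"{eff}: F(1,{fe.df_den}) = {fe.F:.3g}, p = {fe.p:.3g}"
                        for eff, fe in mr.fixed_effects.items()
                    )
                )
    if report.errors:
        lines += ["", "## Stage errors", ""]
        lines += [f"- {k}: {v}" for k, v in report.errors.items()]
    if report.notes:
        lines += ["", "## Notes", ""]
        lines += [f"- {n}" for n in report.notes]
    (out / "summary.md").write_text("\n".join(lines) + "\n", encoding="utf-8")
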