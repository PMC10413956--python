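# foragepath

Movement-path and habitat-use analysis for minute-by-minute focal
observations of free-ranging animals, built around a field comparison of
two sympatric Great Basin desert lizards that hunt by different senses:
a visually oriented sit-and-pursue forager (long-nosed leopard lizard,
*Gambelia wislizenii*) and an actively searching chemosensory forager
(western whiptail, *Aspidoscelis tigris*). The two species eat much the
same prey in the same habitat; the question is whether they partition it
by *how they move* — and the package turns that question into a
reproducible analysis chain that runs end to end on synthetic data.

## What it computes

Each observation is a 30-min focal follow sampled at 1-min intervals
(up to 31 fixes). From the fix sequence the package derives the standard
path-segmentation metrics:

- **step length** `l_t` — straight-line distance between consecutive fixes;
- **path length** `L = Σ l_t` over a complete follow;
- **net displacement** `D` — distance from first to last fix;
- **straightness index** `S = D / L ∈ [0, 1]`;
- **turn angle** — change of heading between consecutive *movement*
  steps, signed in (−180°, 180°] or folded to [0°, 180°]; intervals
  without movement are excluded from the series (heading carries across
  pauses) but kept in the denominator of the proportion of intervals
  with movement;
- **visibility index** — the proportion of transitions whose destination
  was visible from the previous fix at ground level.

On top of the per-observation metrics it runs the comparative analysis:
Mann–Whitney U tests per metric, two-sample Kolmogorov–Smirnov tests for
the step-length and turn-angle distributions, circular statistics on
turn angles (mean resultant length `R`, Rayleigh uniformity test
`z = nR²`, maximum-likelihood von Mises fit `κ̂ = A⁻¹(R)` with
`A(κ) = I₁(κ)/I₀(κ)`, and a Watson U² conformity check), a pooled
two-proportion z test on the fraction of intervals with movement,
habitat-use contingency tables (open/vegetation, visibility,
plant species) with chi-square tests, a random-intercept mixed model for
step length (REML, fixed effects sex + SVL + air temperature + wind
speed), and an observer-effect trend test of the responses on time in
the observation.

Because the original field data are archived separately, the package
ships a first-class synthetic generator: a seeded correlated random walk
over a mosaic of circular vegetation patches, with closed-form
line-of-sight visibility and two species presets calibrated to the
published contrasts (movement in 44% vs 75% of intervals, median steps
2.1 m vs 4.2 m, turn-angle resultant lengths 0.34 vs 0.28, straightness
≈0.66 vs ≈0.31, open-ground vs vegetation-seeking habitat use).

## Worked example

```bash
foragepath simulate --n-visual 61 --n-chemo 51 --seed 7 --out fixes.csv
foragepath analyze --in fixes.csv --out report
```

The first command writes 112 observations (3377 fixes) in the fix-table
CSV schema plus a `fixes.mosaic.json` sidecar with the patch geometry.
The second writes `report/` with `summary.md`, `movement_metrics.csv`
(the five-metric median (range) table), `tests.csv` (all statistics at
full precision), habitat contingency tables, and 45°-binned turn-angle
and 2 m-binned step-length histograms. The summary for seed 7 reads:

| metric | visual | chemosensory | U | p |
|---|---|---|---|---|
| step_length | 2.2 (0.0329–43.8) | 3.95 (0.129–139) | 3.224e+05 | 1.33e-29 |
| path_length | 48.1 (18.9–126) | 160 (77.8–331) | 36 | 8.36e-18 |
| net_displacement | 30.4 (9.58–95) | 41.7 (6.19–142) | 954 | 0.00675 |
| straightness_index | 0.673 (0.227–0.9) | 0.314 (0.0661–0.621) | 2516 | 2.89e-13 |
| turn_angle | 54.6 (0.0524–180) | 59.4 (0.0285–180) | 3.808e+05 | 0.0178 |

with movement in 45.5% (visual) vs 76.3% (chemosensory) of intervals
(z = −17.89) and turn-angle resultant lengths R = 0.373 vs 0.282
(Rayleigh z = 101.8 and 88.5, both p ≪ .001). Read: the visual forager
moves less often and less far but along much straighter paths, the
chemosensory forager covers more ground circuitously — the movement
signature of stalking prey by sight versus sampling vegetation by
chemistry. The same numbers are reproduced by the library API
(`generate_dataset` → `run_full_analysis` → `export_report`).

A fix-table CSV of your own can be analyzed the same way; the schema is
one row per fix with columns `observation_id, lizard_id, species, sex,
svl_mm, mass_g, t_min, x_m, y_m, habitat, plant_species,
visible_from_previous, air_temp_c, wind_speed_ms` (empty cell = absent).
An optional YAML config selects, e.g., `analysis_unit: per_individual`
(observation-level aggregation instead of pooled fixes) or
`angle_convention: folded`; see `foragepath.pipeline.RunConfig` for the
full set of keys and defaults.

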