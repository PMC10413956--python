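# Methods

## Data model

A *fix* is one animal location at a known minute; an *observation* is a
focal follow of one individual with strictly increasing minute indices
0–30 (at most 31 fixes; exactly 31 = complete). Coordinates are planar
meters in an arbitrary local frame — follows happen on a gridded study
plot a few hundred meters across, so no geodesy is involved. Each
lizard appears in exactly one observation per dataset, which is what
licenses treating observations as independent sampling units. The CSV
schema is deliberately denormalized (animal covariates repeated on every
row) so a truncated file still carries full context.

Validation is total: `validate_observation`/`validate_dataset` report
violations as data rather than raising, and the reader refuses files
whose minute indices are out of order instead of silently re-sorting —
an out-of-order fix table is evidence of a transcription problem, not a
formatting choice. Missing minutes *inside* a follow are permitted by
the schema (only strictly increasing `t` is enforced); the field
protocol mentions truncated follows but not interior gaps, so gaps are
left to validation flags rather than rejected.

## Path metrics

Step lengths are Euclidean distances between consecutive fixes. A step
counts as movement when its length exceeds `move_epsilon`, default 0 m:
the field data record steps as small as 1 cm, so no coarser threshold
is imposed (configurable). Non-movement intervals are excluded from the
step-length and turn-angle series but retained in the proportion-moving
denominator and contribute zero to path length.

Turn angles are computed between consecutive *moving* steps with the
heading carried across pauses: a pause is not a step, so the turn after
it compares the new heading with the heading of the last moving step.
The alternative (dropping any turn that spans a pause) is available via
`carry_across_pauses=False`; the choice matters little for concentrated
walks but the carry rule uses every moving step. Headings are degrees
counterclockwise from +x; all reported quantities are
convention-independent, which the rotation/reflection invariance tests
enforce.

Whole-path metrics (path length, net displacement, straightness) are
reported only for complete follows; truncated follows still pool their
step lengths and turn angles. A non-mover has path length 0 and its
straightness index is *absent*, not 0 or 1 — a path that goes nowhere
has no shape to rate.

## Circular statistics

Angles are degrees at module boundaries and radians inside. The mean
resultant length is `R = ‖(mean cos θ, mean sin θ)‖`; the Rayleigh
statistic is `z = nR²` with the standard fourth-order series
approximation for p, clamped to [0, 1] and flagged below n = 5. The
series is accurate in its intended regime (moderate n, z not close to
n); at z → n with small n it can wiggle non-monotonically in the
extreme tail, where every p is ≪ 0.001 anyway.

κ estimation inverts the Bessel ratio `A(κ) = I₁(κ)/I₀(κ)` by bisection
(|A(κ̂) − R| < 1e−10), computed with exponentially scaled Bessel
functions for stability and capped at κ = 1e3 (R ≈ 0.9995) with a
warning — beyond that the sample is effectively a point mass.

Von Mises conformity uses the Watson U² statistic of the
probability-integral-transformed sample under the *fitted* (μ̂, κ̂).
Because both parameters are estimated, critical values differ
substantially from the known-parameter case; the table shipped in
`circular.py` was generated by parametric bootstrap (20 000 replicates
per κ row at n = 200, κ ∈ {0, 0.5, 1, 2, 4, 8}, regenerable with
`scripts/gen_watson_table.py`) and the test reports a p-*range*
bracketed by the tabulated levels (0.10, 0.05, 0.025, 0.01), linearly
interpolated in κ̂. The Monte-Carlo acceptance test confirms ≤10%
false rejection at the 0.05 level under the true model.

Circular tests default to *signed* turn angles in (−180°, 180°];
medians, KS comparisons and histograms use *folded* angles in
[0°, 180°], matching how turn angles are conventionally tabulated. A
config switch (`angle_convention: folded`) runs the circular tests on
folded angles instead, since published mean vector lengths do not always
state which convention was used. Rayleigh results report both n and
n − 1 alongside z (which uses n), because published circular results
sometimes print a "df" whose meaning is ambiguous.

## Comparison statistics

The two-group statistics are computed from their definitions, with
scipy supplying only reference distributions: Mann–Whitney U via
midranks (U1 counts pairs with x > y, ties half) with tie-corrected
normal approximation and continuity correction; two-sample KS as the
exact supremum over the pooled sample with the asymptotic Kolmogorov
p at effective size n₁n₂/(n₁+n₂) and the Stephens finite-n factor;
Pearson chi-square on R×C tables with a low-expected-count warning;
pooled two-proportion z; Pearson correlation with the t-based p. All
p-values are two-sided. The reported U is the unreduced U of the
first-named sample (both U1 and U2 are returned). The suite verifies
each statistic against an O(n²) or pooled-grid brute-force oracle and
checks p-uniformity under the null (Kolmogorov distance < 0.05 at 2000
replicates).

Pooled-fix analyses treat fixes as independent, mirroring standard
practice of pooling measurements by species; this pseudo-replicates
(repeated measures per animal), so `analysis_unit: per_individual`
aggregates to one value per animal (observation medians, observation
proportions) before testing, and the null-calibration acceptance test
requires the per-individual tests to hold their nominal size. No
multiple-testing adjustment is applied; the report footer states the
number of tests performed.

## Mixed model and trend test

Within-species step-length variation is modelled as
`y = Xβ + b_individual + ε`, random intercept per lizard, fixed effects
sex, SVL, air temperature and wind speed (no interactions). The REML
criterion is profiled down to the variance ratio
λ = σ²_ind/σ²_res: for a random-intercept model, V = I + λZZᵀ is block
diagonal with closed-form inverse, so each λ evaluation is O(p²·groups)
from per-group sufficient statistics. λ is optimized by a log-spaced
grid scan plus golden-section refinement to 1e−8, with λ = 0 always
compared (the boundary case; fits there are flagged singular). The
implementation agrees with an independent general-purpose REML fitter
to ~1e−4 on estimates and is exercised for parameter recovery and null
p-uniformity in the acceptance suite.

Fixed-effect F tests use numerator df 1 and *containment* denominator
df: effects constant within individuals are tested against
(individuals − between-individual columns), within-individual effects
against (records − individuals − within-individual columns). Published
mixed-model df at this design scale are not derivable from any single
standard rule, so the df method is printed with the results and no
claim is made to match a particular convention. The response is
untransformed by default with a log option, step lengths being strongly
right-skewed.

The observer-effect check pools moving-step responses (step length, or
absolute turn angle at the minute of its second step) across follows of
a species and regresses on minute index; F(1, n−2) on the slope. A
trend would indicate behaviour drifting over the follow — e.g. a
reaction to the observers.

## Synthetic generator

The generator emulates the study conditions: two species, 61 and 51
follows by default, 31 fixes each with a 10% chance of truncation to a
uniform 10–30 fixes; a 150 m square arena with ~15% vegetation cover in
circular patches (radii lognormal, median 1.5 m, σ_log 0.3; species
drawn from a sage/greasewood-dominated weight table); air temperature
and wind speed as slow random walks shared by all follows; sex
Bernoulli(½), SVL normal per species (visual 105 ± 8 mm, chemosensory
78 ± 6 mm), mass allometric in SVL. Everything is a pure function of
the master seed: observation i of species s draws from
`SeedSequence([master_seed, s, i])`, the mosaic from `[master_seed,
991]`, weather from `[master_seed, 992]`.

Movement is a correlated random walk: move with probability `p_move`,
lognormal step length, von Mises(0, κ_turn) turn. Two design points
deserve explanation:

- **Directed mode (visual preset).** A first-order CRW cannot be both
  wiggly and straight: with pooled turn-angle resultant 0.34 and ~13
  moving steps, its straightness is ~0.4, far below the ~0.66 a
  sit-and-pursue forager shows. In directed mode each heading is the
  follow's goal direction plus von Mises noise, so heading errors do
  not accumulate; the observable turn angle is then a *difference* of
  two noise draws with resultant A(κ_noise)², and the noise
  concentration is set to A⁻¹(√A(κ_turn)) so the turn-angle statistics
  are identical across modes while straightness rises to the field
  level. A boundary reflection deflects the goal along with the path.
- **Cover stops, not re-aiming.** Habitat bias is generated by letting
  an open-ground step stop just inside the first vegetation patch its
  segment crosses (probability `cover_bias` per open moving step, patch
  accepted with probability proportional to the animal's preference for
  its plant species). Earlier designs that re-aimed the heading at a
  patch distorted the turn-angle distribution badly enough to break the
  generator's own calibration anchors; truncating a kernel-drawn step
  leaves the turn distribution exactly von Mises and the step-length
  distribution nearly intact, while producing vegetation occupancy,
  lower visibility indices, and plant-use contrasts.

Patches are discs because discs give exact point-in-patch tests and
closed-form segment–disc line-of-sight (a disc blocks a sight line iff
the minimum distance from its centre to the segment is below its
radius; discs containing either endpoint are transparent — a lizard
sees out of its own bush). The arena boundary reflects, which keeps
fixes in-arena without absorbing paths; reflections insert occasional
non-von-Mises turns, depressing the pooled turn-angle resultant by
~0.02 at the default arena size — well inside the ±0.05 recovery band
the acceptance suite enforces. Extreme lognormal tail steps can exceed
the largest steps seen in the field; ranges are extreme-value
statistics and are not calibration targets.

Preset anchors (fixed from the published contrasts): movement
probability 0.44/0.75; log-median step ln 2.1/ln 4.2 m (σ_log
1.10/1.15, chosen so the simulated ranges span the published 0.01–45 m
at field sample sizes); κ_turn = A⁻¹(0.34)/A⁻¹(0.28); cover bias
0.10/0.50; the visual forager starts in the open, walks directed, and
prefers greasewood, while the chemosensory forager is a plain CRW with
near-equal sage/greasewood preference.

What the generator does *not* emulate: irregular shrub outlines,
inter-animal interactions, thermoregulatory schedules, prey fields, or
any real relationship between covariates and movement (sex, SVL and
weather have no effect on simulated step lengths). Passing tests
therefore demonstrate that the analysis chain is correct and calibrated
on data with the assumed structure — not that the biological conclusions
transfer to any particular field system. In the same vein, the shipped
habitat tables have two cover categories (open/vegetation); field
protocols sometimes distinguish more, which is why the contingency code
is generic R×C.

## Problem sizes and tolerances

The acceptance suite runs at the sizes its properties are stated for:
1000 simulated observations for metric identities (relative tolerance
1e−9 on the path-length sum), 5000 uniform samples of n = 30 for
Rayleigh type-I calibration (0.05 ± 0.01), 200 random sample pairs for
exact oracle agreement, 10⁴ random segment–mosaic cases for
line-of-sight vs 1-cm discretization, 100 observations per preset for
parameter recovery (movement probability ±0.03, median step ±10%,
turn-angle resultant ±0.05), 200 seeds / 2000 null replicates for
mixed-model recovery and calibration, and 100 seeded runs (50
observations per species) plus 200 identical-preset replicates for the
end-to-end contrasts and per-individual null calibration. The whole
suite completes in a few minutes on one CPU.
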