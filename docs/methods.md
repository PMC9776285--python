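# Methods

## Scope and data model

One perfusion experiment (`KidneyRecord`) carries a hemodynamic stream
(renal blood flow, arterial pressure, kidney temperature on one time base,
default 0.2 s sampling), arterial and venous blood-gas panels at 0 and
every 20 min to 240 min, urea and GST assays plus cumulative urine volume at
0 and every 60 min, kidney weight, warm/cold ischemia times, a reference
function class (1 nonfunctional, 2 limited, 3 functional; defined by inulin
clearance and treated as an input), and a train/test assignment. Analysis
happens on two grids: 20…240 min for blood-gas and hemodynamic markers
(12 points), 60…240 min for filtration/injury markers (4 points).

## Marker derivation

* Oxygen content uses the Hüfner constant 1.34 mL O2/g Hb and plasma
  solubility 0.0031 mL/(mmHg·dL). The hemoglobin entering every content
  evaluation is the per-kidney median over all panels of the experiment,
  which suppresses panel-level analyzer noise.
* Whole-blood CO2 content follows the Douglas formulation: plasma CO2
  (mmol/L) = s·pCO2·(1 + 10^(pH − pK′)) with
  s = 0.0307 + 0.00057(37 − T) + 0.00002(37 − T)² and
  pK′ = 6.086 + 0.042(7.4 − pH) + (38 − T)(0.00472 + 0.00139(7.4 − pH)),
  scaled to whole blood by 1 − (0.0289·Hb)/((3.352 − 0.456·sO2)(8.142 − pH))
  and converted at 22.26 mL/mmol. The temperature argument is the windowed
  kidney temperature at the same analysis time (the blood-analyzer
  temperature is not separately available). The model is treated as valid
  for pH 6.8–7.8; cells outside that range are left missing.
* CO2 production is computed as flow in L/min times the venoarterial
  content difference in mL/L, yielding mL CO2/min per 100 g. (A literal
  product of mL/min flow with mL/L contents would be dimensionally
  inconsistent; negative values are meaningful and indicate net CO2
  fixation by the tissue.)
* Hemodynamic markers are arithmetic means over analysis time ± 2 min with
  inclusive edges; the operator is sampling-rate agnostic, so coarser test
  streams (1 s) and fine production streams (0.2 s) give the same analysis.
* Urea and GST are expressed as percent of their t = 0 baseline (the
  baseline-relative reading makes the weight normalization moot); urine
  production is the per-interval volume increment per 100 g (mL/h/100 g).
* All flow/oxygen/volume markers are normalized to 100 g kidney weight.
* Missing blood-gas panels leave the oxygen/CO2 cells of that time point
  missing; no imputation happens at derivation time. Downstream, feature
  construction interpolates linearly within each kidney's series (edge gaps
  take the nearest observation) and falls back to the column mean only for
  a marker entirely unobserved in one kidney, so no kidney is dropped from
  the small cohort.

## Critical thresholds

The extraction–delivery elbow is estimated by exhaustive-breakpoint
two-segment ordinary least squares: candidate breakpoints are midpoints of
consecutive distinct x values (each side keeping at least two distinct x),
the candidate minimizing total SSE wins, ties go to the smaller breakpoint,
and data a single line explains equally well are flagged as having no
breakpoint. Input points are class-by-time means (3 classes × 12 times),
the aggregation used to draw such scatter relationships at this cohort
size.

`propagate_critical` reports two chains. The headline values follow printed
precision (one decimal for DO2/VO2, integers for percent, flow and
pressure) and substitute the rounded values stepwise — critical flow from
the RBF~DO2 line at the rounded DO2_crit, critical consumption as
ERO2_crit/100 · DO2_crit, critical pressure as the smaller real root of the
quadratic RBF~AP relation solved at the rounded RBF_crit (the smaller root
lies inside the observed pressure range; the larger does not). The fully
unrounded chain is attached as `.raw`. The critical consumption is defined
through the extraction–delivery identity rather than by evaluating the
VO2~DO2 linear branch at DO2_crit; the two definitions differ and only the
identity is internally consistent with the elbow.

## Significance screening

Normality is assessed per class group (any failing group routes the cell
nonparametric — the conservative reading when group sizes are 3–12);
degenerate (constant) groups count as non-normal. Routing is exhaustive and
mutually exclusive: all groups normal and Levene p > 0.05 → classical ANOVA
with Bonferroni-corrected pairwise t tests; all normal and Levene p ≤ 0.05 →
Welch ANOVA with Games–Howell; otherwise Kruskal–Wallis with Dunn's
rank-based pairwise z tests (tie-corrected) under Šidák adjustment
1 − (1 − p)³. α = 0.05 throughout; no multiplicity correction is applied
across markers or time points, matching the per-cell reporting convention
of this analysis style. Cells where any class has fewer than three
observations are flagged untestable rather than guessed. Downstream feature
eligibility uses contrasts involving the functional class (1v3, 2v3); the
1v2 results are computed and stored but unused by default.

## Multicollinearity and feature variants

VIF is the diagonal of the inverse correlation matrix of the per-kidney
marker summary (time-mean over each marker's grid after per-kidney
interpolation), equivalent to 1/(1 − R²) from regressing each marker on the
rest; perfect collinearity is reported as infinite rather than raising. The
filter removes exactly the current maximum per pass (ties broken by the
canonical marker order do2, vo2, ero2, co2p, rbf, ap, irr, t_kidney,
rel_urea, urine_rate, rel_gst) until all VIF ≤ 10. The summary operates on
the 11-marker matrix, not the full (marker, time) expansion: collinearity
here is a property of markers, and 26 kidneys could not support a
210-column correlation matrix anyway.

Variant A expands every eligible marker (VIF-surviving and significant at
≥ 1 time point) over its full grid to 240 min; variants B–E keep only the
significant cells up to 240/180/120/60 min. Columns are ordered by
(canonical marker order, time). Standardization (z-score) is fit on
training rows only and reapplied — never refit — to validation folds and
the holdout.

## Classifier bench

Five fixed-hyperparameter families: linear-kernel SVM (one-vs-one), random
forest with 20 trees (seeded), k-nearest-neighbour with k = 5, uniform
weights and Euclidean distance, logistic regression (solver iteration cap
raised to 1000 so the fit always converges; this is not a model
hyperparameter), Gaussian naive Bayes. No hyperparameter search is
implemented. Validation is leave-one-out grouped by kidney: each fold holds
out one kidney with all of its features, scaling is refit inside the fold,
and metrics pool the out-of-fold predictions. The final model refits on all
training kidneys and scores the stratified 77/23 holdout (largest-remainder
apportionment per class, never holding out a whole class). Accuracy is
correct/total; precision and recall are macro-averaged over the three
classes, classes absent from the truth being excluded from the macro mean
with a warning ("minor" averaging does not exist in any library; macro is
the only mode consistent with a reported test precision differing from test
accuracy). Scale-sensitive families (SVM, kNN, logistic) see standardized
features; the forest and naive Bayes see raw values; scaling can be
disabled globally.

## Synthetic cohort generator

The generator's defaults are the study conditions: 4/10/12 kidneys per
class, four hours, 0.2 s hemodynamics, 20/60-min sampling grids, 77/23
stratified split, warm ischemia 4–185 min and cold ischemia 94–790 min
drawn uniformly without class dependence (no class-conditional distribution
is reported).

The physiologically primitive latent quantity is the intrarenal resistance
trajectory; flow and pressure follow through the perfusion controller. The
pump targets 100–110 mmHg by commanding flow = AP_set/IRR through a
first-order lag (τ = 45 s), starting from 50 mL/min systemic flow, but
never commands less than an operator flow floor (15 ± 3 mL/min) — unless
the 185 mmHg pressure ceiling forces it lower — so a kidney whose
resistance keeps rising ends up pressure-elevated at the floor instead of
pressure-regulated. Class 3 resistance is low and slowly falling (flow well
above 23 mL/min/100 g at setpoint); class 2 climbs after ~100 min so flow
declines below the critical value and the organ cools after ~120 min;
class 1 is high from the start (flow pinned, pressure near/above 155 mmHg
early, temperature below 33.5 °C throughout). Organ temperature relaxes
(τ = 6 min) from the cold-storage value toward a flow-dependent equilibrium
that falls below normothermia when flow per 100 g drops under ~36.

Oxygen handling is demand-limited with a supply-limited ceiling: each
kidney's end-of-perfusion oxygen demand follows delivery sub-linearly
(demand ∝ DO2^0.75, lognormal spread 9%) and is approached along a
per-kidney recovery profile; extraction is demand/delivery capped at a
per-kidney ceiling (0.655 ± 0.14). This one law reproduces the study's
qualitative regimes in all three classes: supply-adequate kidneys show flat
extraction and rising consumption, supply-limited kidneys saturate
extraction near the ceiling, and the pooled extraction–delivery cloud is
biphasic. Venous panels are constructed from the latent extraction;
arterial saturation never falls below venous. CO2 gaps, urea clearance
(exponential decay toward class asymptotes), GST release
(rise-and-plateau for class 1, rise-then-recovery otherwise) and urine
production complete the panel set.

Heterogeneity is deliberately large, matching the within-class scatter the
published class-3 standard errors imply (coefficients of variation near
40/32/13% for consumption/delivery/extraction): per-kidney lognormal
resistance scale (26%, winsorized; limited-function organs 1.6× wider —
borderline organs are the most heterogeneous group), hemoglobin 6.2 ±
1.8 g/dL, setpoint drawn in 100–110 mmHg, floor/heater/assay/urine spreads,
and a two-factor ischemia severity structure: the warm-ischemia draw shifts
resistance, the cold-ischemia draw shifts urea clearance, GST release and
urine output, so hemodynamic and tubular markers do not collapse onto one
severity axis. Blood-gas panels are dropped at random per class (25/40/15%
for classes 1/2/3), emulating the uneven per-time-point group sizes such
experiments report, and venous saturation carries extra analyzer noise.
Setting `noise_scale = 0` collapses every draw — measurement noise, random
effects, ischemia times, dropout — to its central value, making records
seed-independent.

### Calibration and its limits

At default parameters, a 12-kidney class-3 cohort reproduces final-hour
means near V̇O2 ≈ 2.3 mL/min/100 g, ERO2 ≈ 52%, DO2 ≈ 4.6 mL/min/100 g,
each within two standard errors of the published magnitudes; the exact
triple (2.6, 52%, 4.4) is not jointly reachable pointwise since
2.6/4.4 = 59%. The 11-marker per-kidney summary of a default cohort is
structurally collinear exactly in the derived markers: the filter removes
two of {IRR, DO2, V̇O2} and retains nine for the majority of generator
seeds. This outcome is intrinsically seed-sensitive: with 26 kidneys and 11
markers, each VIF regression carries 8–10 predictors, and the sampling
distribution of the largest third-iteration VIF straddles the threshold 10;
no faithful parameterization pushes it far below while the class-3 flow
(~52 mL/min/100 g) and the pinned classes (~15–25) remain where the
critical-threshold narrative requires them. Single-cohort VIF counts should
therefore be read as one draw from a distribution whose mode is nine.

The generator emulates marginal trajectories and plausible heterogeneity,
not real renal physiology: there is no pulsatile or Windkessel
hemodynamics, no acid–base dynamics beyond the CO2 gap, no coupling of
urine output to filtration pressure, and the classes are cleaner than
biology — margin-based classifiers can separate a default synthetic cohort
almost perfectly, so classification accuracies on synthetic cohorts
overstate what identical pipelines achieve on real organs. The synthetic
extraction–delivery elbow also sits at somewhat higher delivery and lower
extraction than the published one, because class-3 extraction rises with
recovery time in the generator. Passing tests demonstrate the correctness
and statistical behavior of the pipeline machinery, not field performance.

## Numerical choices

* Breakpoint search is exhaustive over midpoints; ties to the smaller
  candidate; a two-segment fit must beat the single line by more than a
  1e-9 relative SSE margin to count as a breakpoint.
* Rounding of reported critical values is half-up at printed precision.
* Parallel lines (relative slope difference < 1e-12) cannot be intersected.
* Constant responses fit as slope 0 with R² = 0.
* The VIF of a singular correlation matrix falls back to per-column
  regression with infinities for perfectly collinear columns.
* Kruskal–Wallis on identical constants is reported as p = 1 on the
  nonparametric route.
* All randomness flows from integer seeds through `numpy.random.default_rng`;
  per-kidney seeds are drawn below 2³¹.

## Pipeline sizes

Unit tests run reduced cohorts (3–8 kidneys per class) at 1 s hemodynamic
sampling; the acceptance script and acceptance tests run the full 4/10/12
cohort and 12-kidney class-3 cohorts at the default 0.2 s sampling. The
pipeline/CLI default is 1 s sampling because the long-format CSV interchange
of a full cohort at 0.2 s would exceed five million rows; derived analyses
are unchanged by the sampling rate.
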