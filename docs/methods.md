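# Methods

## Scope and model

`radsyn` covers the group-level statistics by which preclinical studies
judge whether a drug sensitizes tumors to ionizing radiation. The common
thread is Bliss independence: two independently acting agents should leave
a surviving fraction equal to the product of their single-agent surviving
fractions — equivalently, a combined inhibition of r₁ + r₂ − r₁r₂. Both
endpoints the package analyses are scored against this null:

* **In vitro (clonogenic):** per radiation dose D, the observed combination
  surviving fraction SF_R+C is compared with SF_R(D) × SF_C. Observed below
  the product ⇒ synergism, above ⇒ antagonism, equal ⇒ additivity.
  `classify_bliss` takes a relative tolerance around the product (default
  0, i.e. plain comparison of the stored numbers) because colony-count data
  are discrete: a tolerance at the 1/colonies scale absorbs counting
  granularity when that matters.
* **In vivo (volumes):** group mean tumor volumes at a fixed evaluation day
  give inhibition rates r = 1 − V_treated/V_control; the combination's
  expected rate under Bliss is r_d + r_r − r_d·r_r and the combination
  index CI = (1 − r_observed)/(1 − r_expected) measures the deviation
  (CI < 1 synergy).

Two *different* quantities are both conventionally called "inhibition
rate": the growth-time ratio (treated/control mean time to a threshold
volume) used in delay tables, and the volume-based rate used in
combination-index tables. They are implemented as separately named
operations (`summarize_growth_times` vs `volume_inhibition_rate`) and never
interchanged.

## Key formulas and parameters

| quantity | definition | default |
|---|---|---|
| viability % | 100·(c₁A₁ − c₂A₂)/(c₃N₂ − c₄N₁), c = (117216, 80586, 155677, 14652) | manufacturer's constants |
| surviving fraction | colonies/(plated × PE); PE pooled over untreated dishes | — |
| LQ survival | SF(D) = exp(−αD − βD²) | fit, not assumed |
| doubling time | (t−t₀)·ln2/(lnN−lnN₀) over a user-chosen exponential window | — |
| tumor volume | k·L·W·H | k = 0.523 (4π/24 selectable) |
| growth time | first day volume ≥ threshold, log-linear between measurements | threshold 400 mm³ |
| combination index | (1 − r_obs)/(1 − r_exp) | — |
| significance tiers | two-sided pooled-variance t; glyph repeats per p < 0.05/0.01/0.001 | Student, Welch via flag |

The viability equation is implemented exactly as supplied, including its
asymmetric use of the control channels (N₂ at 600 nm carries the large
coefficient); the package does not second-guess the constants. Viability is
not clipped to [0, 100] — clipping is a display choice, not an analysis
step.

### Printed-precision mode

Published tables in this literature typically compute ratios from
already-rounded intermediates (e.g. an enhancement ratio of 2.78/1.33 =
2.09 where full precision gives 2.08; a CI of 0.22/0.31 = 0.71 where full
precision gives ≈0.72). Every group-level operation takes
`precision_mode`: `"full"` (the default) performs no intermediate
rounding; `"printed"` rounds time-ratio rates to two decimals and
volume-based rates to the whole percent (half away from zero) before they
enter ratios, and rounds outputs to the table's precision. This reproduces
published values exactly while keeping an honest default.

## Estimation choices

* **IC50.** `log_interp` finds the first downward crossing of 50% by
  linear interpolation of viability against log₁₀(dose); dose 0 is excluded
  from log space and serves only as an anchor. `four_pl` fits
  v = bottom + (top−bottom)/(1 + (d/IC50)^h) by bounded least squares with
  top ∈ [80, 120]%, bottom ∈ [0, 50]%, h > 0, initialized from the curve
  extremes and the interpolated crossing — the bounds keep 7-point curves
  away from degenerate optima.
* **LQ fit.** ln SF is regressed on (−D, −D²) through the origin with
  non-negativity enforced by NNLS. Points are weighted by their pooled
  colony count: for Poisson counts C, Var[ln SF] ≈ 1/C, so the weight is
  the inverse log-variance. Zero-SF points are below detection and excluded
  (ln 0 undefined); they remain in tables.
* **Plating efficiency** pools colonies and platings across untreated
  replicates (ratio of totals), the minimum-variance estimator for Poisson
  counts; per-replicate SFs are then averaged within each condition with
  their standard error.
* **t tests** use the pooled-variance Student form because that is what
  the summaries of this field cite; Welch is available via a flag. No
  multiple-testing correction is applied by default, matching field
  practice; annotations are per-comparison.
* **Censoring.** An animal whose tumor never reaches the threshold is
  censored: excluded from mean growth time with a logged warning. No
  survival-analysis treatment of censored times is attempted.

## The synthetic-data generators

`SimulationConfig` fixes the study conditions; one integer seed drives an
independent named stream per assay, so generating one assay never perturbs
another's draws.

* **Clonogenic:** true SF from LQ (α = 0.3 Gy⁻¹, β = 0.03 Gy⁻², a typical
  α/β = 10 tumor line), drug-only SF 0.5, interaction multiplier on the
  combination (1 = Bliss-null). Colonies ~ Poisson(plated × PE × SF) over
  {0, 2, 4, 6, 8} Gy × {0, 75 µM}, triplicate. Plating is dose-escalated
  ({500, 500, 2000, 10⁴, 5·10⁴} cells) — standard practice, and necessary
  for the assay to resolve surviving fractions down to the 10⁻³–10⁻⁴ range
  the design spans with countable colony numbers.
* **Viability:** a 7-dose panel (0–100 µM) with logistic truth
  (top 100%, bottom 0%, midpoint 75 µM, Hill 2). Absorbance pairs are
  built by fixing the negative-control pair (0.05, 0.2) and the test-well
  600 nm baseline (0.1) and inverting the viability equation for the
  570 nm channel; Gaussian noise (sd 0.01 AU) is added per channel. By
  construction the noiseless plate reproduces the logistic exactly.
* **Tumor growth:** Gompertz volumes V(t) = v₀·exp((a/b)(1 − e^(−bt)))
  with v₀ = 100 mm³ (treatment-start size), a = 0.2124 d⁻¹, b = 0.05 d⁻¹ —
  calibrated so the control arm reaches ≈2200 mm³ at day 26 and plateaus
  thereafter. Single-agent arms multiply a by 0.8761 (drug) and 0.7449
  (radiation), giving expected day-26 volumes ≈1500 and ≈1000 mm³; the
  combination multiplier is solved so its expected day-26 volume is the
  control volume times the Bliss product of the single-agent volume
  fractions, times the interaction factor — hence noiseless CI equals the
  interaction exactly. Measurements occur twice weekly (days 0–26) with
  mean-preserving lognormal noise, CV 0.2 (the emulated study publishes no
  variance for volumes; 0.2 is a typical xenograft value and a generator
  choice). Caliper triplets factor each volume at aspect ratios 1 : 0.8 :
  0.6 jittered ±10%.
* **Cohort:** six animals per arm; spleen-index, CD4/CD8 and cytokine
  group means/sds are configurable (defaults use published subset
  percentages where available; spleen-index and cytokine levels are
  generator choices, as the emulated study prints only relative or plotted
  values), drawn from normals truncated at 0.

### What the generators do and do not emulate

They reproduce the designs (dose panels, arm structure, measurement
schedule, count statistics) and the null/alternative structure of the
analyses. They do **not** emulate plate-position effects, caliper operator
bias, inter-animal growth-rate heterogeneity beyond lognormal measurement
noise, attrition/early sacrifice, or correlations between endpoints in the
same animal. Passing calibration tests therefore demonstrates correctness
and unbiasedness of the *computational chain* under idealized noise, not
robustness to every artifact of real assay data.

## Calibration results the suite verifies

All problem sizes are desk-scale, chosen to keep the full suite under a
few seconds: 500 simulated cohorts for Bliss-null CI calibration (median
CI within [0.9, 1.1]), 200 plates for IC50 recovery (median |relative
error| < 5% with log-interpolation), 200 clonogenic assays for α recovery
(within ±20% of truth in ≥ 90% of runs), exact identities (SF(0 Gy) = 1,
RSI(normal) = 1, noiseless CI = interaction), and agreement of the t-test
p-values with an independent hand computation to 1e-10.

## Numerical conventions and degenerate inputs

* Printed-mode rounding is half-away-from-zero (table convention), not
  banker's rounding.
* Growth-time interpolation is log-linear in volume; a zero bracketing
  volume falls back to the day of first attainment.
* A viability denominator within 1e-12 (relative) of zero raises a
  degenerate-control error rather than returning ±inf.
* `classify_bliss` requires all fractions in (0, 1]; zero surviving
  fractions cannot be scored (they are below detection).
* CI is undefined at an expected rate of 100% and raises.
* Group labels form a closed, case-insensitive vocabulary; unknown labels
  are errors so that control/normal anchors can never be silently missing.
* Day 0 is treatment start (irradiation day); growth times and the
  evaluation day count from it.

## Known limitations

Image-derived endpoints (colony counting, densitometry, flow gating,
histology), ELISA standard curves, two-way ANOVA, survival (Kaplan–Meier)
analysis and mixed-effects growth modelling are out of scope. The
drug-only surviving fraction enters Table-style synergy summaries as a
measured input; when only the product column of a published table is
available, `infer_drug_sf` documents the inference product/SF_R rather
than pretending the value was measured.
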