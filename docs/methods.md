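# Methods

## Thermal summation model

Development of each immature stage (egg, L1, L2, L3, pupa) is modelled as
linear in temperature: the stage completes when accumulated effective
degrees above its lower developmental threshold *t* (°C) reach its thermal
constant *k* (degree-hours). At constant temperature the duration is
D = k/(T − t) for T > t, infinite otherwise; the rate is max(T − t, 0)/k
per hour.

**Units.** Durations are hours and *k* is degree-hours everywhere. For a
beetle of this size the magnitudes only make sense on that scale (an egg
constant near 930 interpreted as degree-days would imply five-month eggs at
18 °C); the package states the convention prominently rather than leaving
it implicit, because degree-day conventions dominate the older literature.

**T ≤ t is a valid input, not an error.** The fitted L1 and L2 thresholds
(≈15.4 and ≈15.7 °C) sit above the coldest chamber of the reference design
(15 °C) — linear-threshold extrapolation routinely does this. Prediction
returns an infinite duration and zero rate there; the synthetic generator
skips such chambers with a logged warning, which mirrors chambers in which
beetles fail to develop.

**Per-stage thresholds in sequence.** When an individual is stepped through
its stages over a temperature record, each stage accumulates against its
OWN threshold, consistent with the stages having been fitted separately.
No published convention exists for chaining differently-thresholded stages;
this is the one that preserves each stage's fitted (k, t) pair exactly at
constant temperature.

**Temperature records.** Interpolation between readings is
piecewise-constant left-hold — the simplest convention that makes
accumulation exactly additive and lets stage-completion instants be solved
in closed form inside each constant segment (progression therefore carries
no step-size error of its own). Intervals extending beyond the record hold
the nearest endpoint reading and emit an `ExtrapolationWarning`.

**PMImin.** The minimum post-mortem interval for an observed stage is the
smallest Δ such that development started at collection − Δ reaches that
stage by collection. Reachedness is monotone in Δ (accumulation is
non-negative), so Δ is found by bisection, bracketed to `step_h`
(default 1 h, configurable). An observed egg gives 0 h — it may have just
been laid. A record too short for the stage to be reached at all raises
`InsufficientRecordError` rather than returning a misleading bound.

## Parameter estimation

Observations (D, T) are mapped through the Ikemoto–Takai transform
(x, y) = (D, D·T), on which the model is the line y = k + t·x. Because D
appears in both coordinates, the line is fitted by major-axis regression:
the slope is the principal-axis root
b = (s_yy − s_xx + √((s_yy − s_xx)² + 4 s_xy²)) / (2 s_xy) of the sample
covariance matrix (sign follows s_xy) and the line passes through the
centroid. Degenerate geometry — under three points, a single temperature,
or zero covariance — is a hard error; under three distinct temperatures
the fit proceeds with a warning, since threshold and constant are then
weakly separated.

**Standard errors** are nonparametric case-bootstrap (default B = 2000,
seeded): resample individuals with replacement, refit, take the standard
deviation of the replicate estimates. This was chosen over closed-form
model-II formulas because it is assumption-light and directly testable
(noiseless data must give SEs ≈ 0; fixed seeds must reproduce exactly).
Bootstrap SEs are not expected to match any particular closed-form
published value digit for digit.

**R² and p** are the squared Pearson correlation of the transformed pairs
and the two-sided correlation test on df = n − 2 — the only definitions
that yield a single R²/p for a model-II line. The OLS rate regression
1/D = −t/k + T/k is provided as the classical comparison; both fitters are
exact on noiseless data, and they differ on noisy data (documented, not
asserted in magnitude).

## Instar size models

Each instar's head-capsule widths are summarized by mean, sample sd (n − 1
denominator), observed min/max and n. Classification of a new width uses
plain (untruncated) normal densities weighted by priors — equal by default,
configurable because field stage frequencies differ from rearing
frequencies. Truncation to the observed range is used only when
*generating* widths; a classifier must handle out-of-range widths, so they
are flagged (`out_of_range`) rather than rejected. Exact posterior ties go
to the earlier instar — the conservative direction for PMImin use.

Decision boundaries between adjacent instars solve the quadratic obtained
by equating weighted log-densities, taking the root inside the open
interval between the means and falling back to bisection if root selection
is ambiguous. Two exactly identical models are degenerate (densities equal
everywhere); their common mean is returned as the boundary, which makes the
misclassification matrix the honest "complete confusion" 0.5 everywhere.
The misclassification matrix itself is closed-form normal mass over the
boundary-partitioned axis; rows sum to 1 by construction.

Brooks–Dyar ratios are successive mean ratios; the constancy statistic is
their population coefficient of variation (0 for exactly geometric growth,
and well-defined even with a single ratio).

**Molt detection.** A molt is declared when a daily reading exceeds the
running mean of the current instar's readings by strictly more than the
threshold; the reference then resets to the triggering reading. The running
mean (rather than the previous single reading) keeps one noisy frame from
faking or masking a molt. The classic 0.1 mm default is exposed as a
parameter because it sits above the L1→L2 mean gap of the reference species
(0.421 − 0.329 = 0.092 mm) while the L2→L3 gap (0.101 mm) just clears it:
with the default the first molt of a noiseless mean-plateau trajectory is
invisible, with 0.08 mm both molts are found. Users working with small
larvae should set the threshold below the smallest expected gap.

## Synthetic study generator

The generator emulates a constant-temperature rearing study so that every
fitting and classification path is testable without external data:

- **Durations**: D = k/(T − t)·exp(ε), ε ~ N(0, σ) with σ = √log(1 + CV²)
  so the duration coefficient of variation equals `duration_noise_cv`.
  Multiplicative log-normal noise guarantees positive durations and makes
  tolerance statements scale-free. Default CV 5 % — a modest biological
  spread around the thermal-summation mean; defaults of 50 individuals per
  chamber at {15, 18, 21, 25} °C.
- **Head widths**: normal(mean, sd) truncated to the instar's observed
  [min, max] by rejection; default n per instar are the published
  photograph counts (591/500/640).
- **Trajectories**: per-instar mean plateaus over configurable blocks of
  days plus optional Gaussian measurement noise.
- **Temperature records**: constant chambers or a 24 h sinusoid
  (mean ± amplitude) with optional jitter, for PMI scenarios.

All draws flow through a seeded `numpy.random.Generator`; a fixed seed
gives byte-identical CSVs.

**What the generator does not emulate**: egg-laying time censoring beyond
an optional uniform jitter, temperature-dependent mortality (no usable
rates are published; survival thinning is available but defaults off),
developmental-rate nonlinearity near the optimum (the reference data
themselves hint at a plateau between 21 and 25 °C for late instars), and
between-individual correlation across stages. Passing recovery tests on
this generator therefore demonstrates correctness of the estimators under
the model's own assumptions — not robustness to real-data violations of
linearity.

## Problem sizes and numerical choices

Recovery checks run 20 seeded replicates of 50 individuals per chamber at
CV 5 %, with recovered medians compared against the published per-stage
values within twice their published standard errors; Monte-Carlo cross-checks
of the misclassification matrix use 1e5 draws per instar (agreement within
0.005 per cell). The PMI bisection is checked against the constant-
temperature closed form within one 1 h step. Exact-limit tests require
relative error below 1e-10 on noiseless data for both fitters.

Known limitations: no upper developmental threshold (failures at high
temperature are not modelled); no nonlinear development models; no
mixture-model instar assignment from unlabeled widths (labelled-by-tracking
data are the premise — unlabeled size-based assignment is exactly the bias
the misclassification matrix is meant to expose); summed per-stage
durations at 18 °C (~36 days egg→adult) exceed colony-level total-development
reports (~28 days), a reconciliation the per-stage model does not attempt.
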