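# thermaldev

Thermal summation models, minimum post-mortem interval (PMImin) estimation
and head-capsule-based instar determination for necrophagous beetle
development data — built around the development of *Sciodrepoides watsoni*
(Coleoptera: Leiodidae), one of the most widespread carrion beetles of the
Holarctic, whose published per-stage developmental constants ship with the
package as defaults.

It is aimed at forensic entomologists and developmental biologists who need
to (a) fit developmental constants from constant-temperature rearing data,
(b) turn an observed developmental stage plus a temperature record into a
PMImin, and (c) assign larval instars from head-capsule widths with an
honest account of the misclassification risk.

## The models

**Thermal summation.** Development of each immature stage is assumed linear
in temperature: a stage completes when the accumulated effective degrees
above its lower developmental threshold *t* (°C) reach its thermal constant
*k* (degree-hours),

    D (T − t) = k,     so at constant T > t:   D = k / (T − t),

with zero development rate at or below *t*. Parameters are estimated on the
Ikemoto–Takai transform: each observation (D, T) is mapped to
(x, y) = (D, D·T), on which the model is the straight line **y = k + t·x**.
Because the measurement error in D enters both coordinates, the line is
fitted by **major-axis (model-II) regression** — the principal axis of the
sample covariance matrix, minimizing perpendicular distances — with
case-bootstrap standard errors. The classical OLS rate regression
(1/D = −t/k + T/k) is included as the comparison method.

For a timestamped temperature record T(τ) the package accumulates
ADH(τ₀, τ₁) = ∫ max(T − t, 0) dτ, steps an individual egg → L1 → L2 → L3 →
pupa (each stage against its own threshold), and back-computes PMImin as
the smallest Δ such that development started at collection − Δ reaches the
observed stage by collection.

**Instar determination.** Each larval instar's head-capsule width (mm) is
summarized as a Gaussian (mean, sd) plus its observed range. Widths are
assigned by prior-weighted normal densities, giving posteriors, the
decision boundaries between adjacent instars, a closed-form
misclassification matrix, and Brooks–Dyar growth ratios. Molts are detected
on daily width trajectories as jumps exceeding a threshold (default 0.1 mm)
over the running mean of the current instar.

All durations are hours and all thermal constants degree-hours.

## Worked example

Simulate a rearing study (50 individuals per chamber at 15/18/21/25 °C,
5 % duration noise), refit the constants, and estimate a PMImin:

```sh
thermaldev --seed 1 --out-dir demo simulate --n-per-temp 50
thermaldev --seed 1 --out-dir demo fit-thermal demo/observations.csv
```

```
stage  temp_min_c  temp_max_c       r2  df             p           k      k_se         t     t_se   n
  egg        15.0        25.0 0.997392 198 9.409534e-258  914.860857  6.954472 11.485760 0.040684 200
   L1        18.0        25.0 0.999425 148 1.019115e-241  230.667147  1.718477 15.465258 0.030146 150
   L2        18.0        25.0 0.999578 148 1.337532e-251  244.635485  1.763621 15.708518 0.024476 150
   L3        15.0        25.0 0.984145 198 3.737349e-180 2475.552870 25.134689  9.790750 0.081253 200
 pupa        15.0        25.0 0.998885 198 2.604113e-294 1203.838504  8.058476 12.542133 0.028301 200
```

Each row is a Table-1-style fit: the egg constant is recovered as
k ≈ 915 degree-hours with threshold t ≈ 11.49 °C, close to the generating
values (929.354, 11.400). L1 and L2 have no rows at 15 °C because their
thresholds (≈15.4, 15.7 °C) sit above that chamber — the simulator skips
non-viable chambers just as cold chambers produce no larvae in practice.

With a constant 21 °C record, an L3 larva found on remains gives:

```sh
python -c "import thermaldev as td; \
    td.gen_temperature_series('constant', 21.0, span_h=400).to_csv('demo/temps.csv')"
thermaldev estimate-pmi --stage L3 demo/temps.csv
```

```
PMImin for L3 collected 2015-06-17 16:00:00: 185.2 h (7.71 d)
stage budget over the estimated interval:
  egg: k = 929.4 ADH at t = 11.40 °C (record supplies 1777.5 ADH above this threshold)
  L1: k = 233.7 ADH at t = 15.44 °C (record supplies 1030.0 ADH above this threshold)
  L2: k = 243.9 ADH at t = 15.69 °C (record supplies 983.4 ADH above this threshold)
bounding stage: L3 must have been reached by collection
```

185.2 h is the shortest time since oviposition consistent with a third
instar being present: the sum of egg, L1 and L2 durations at 21 °C
(closed form 184.7 h, matched within the 1 h search resolution).

In Python the same surfaces are importable directly:

```python
import thermaldev as td

egg = td.WATSONI_STAGE_PARAMS[td.Stage.egg]
td.predict_duration(egg, 18.0)          # 140.8 h
models = list(td.WATSONI_HEAD_WIDTHS.values())
td.classify_width(models, 0.40).posterior  # instar posteriors for a 0.40 mm head
td.misclassification_matrix(models)     # risk of erroneous determination
```

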