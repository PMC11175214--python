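# Methods

This note records the models implemented in `fenceline`, the choices
made where the design was genuinely open, and what the synthetic bench
does and does not demonstrate.

## Signal model and compensation

A MOX sensor's resistance in odourless air ("baseline") depends
strongly on the water content of the sampled air.  We work in absolute
humidity, `AH = (RH/100)·Ps(T)/(Rw·T)` in g/m³ with
`Rw = 461.5 J/(kg·K)` and the saturation pressure from the standard
empirical correlation `ln Ps = C1 + C2/T + C3·ln T + C4·T^C5` (default
water coefficients 73.649, −7258.2, −7.3037, 4.1653·10⁻⁶, 2; pressure
in Pa, temperature in K; overridable via `PsychroConstants`).  The
correlation is validated against steam-table anchors (2339 Pa at
293.15 K; 611 Pa at the triple point) in the test suite.

Three pre-treatments of the raw resistance `y` are supported:

* **CA** — none; `y` passes through.
* **CB** — static reference: `y_norm = (y − ȳ)/y` with `ȳ` the mean
  resistance in odourless ambient air.
* **CC** — dynamic reference: `y_ref(AH)` is a least-squares
  polynomial of AH (degree 1–5) fitted per sensor on odourless air;
  `y_norm = (y − y_ref)/y` with `y_ref` evaluated at the window-mean
  AH of the analysis window.

Notes and choices:

* The normalization denominator is the raw signal `y`, exactly as the
  formula is used; `(y − y_ref)/y_ref` is available behind a switch
  for sensitivity studies, default off.
* Polynomial degree is chosen automatically as the lowest degree whose
  RMSE improvement over the next degree falls below 5% relative — a
  reproducible stand-in for choosing the degree by eye.  Evaluation
  outside the fitted AH range (beyond a 20% margin) warns and clamps
  to the range endpoints.
* The polynomial is an empirical interpolation; it claims no physical
  model of water adsorption on the sensing layer.
* Temperature enters only through AH; no separate temperature term is
  compensated.
* **Field re-zeroing:** static and dynamic references describe the
  sensors *as they currently respond*.  Before processing a campaign,
  the pipeline refits the references from that campaign's odourless
  (Air) windows, which absorbs the slow multiplicative drift of MOX
  elements between campaigns; the dynamic model continues to handle
  humidity through its AH input.  Multi-campaign training fits
  references per campaign before pooling features.

## Features and selection

Each valid 5-min window (≥ 80% of its expected records, ≥ 3 records)
yields 43 features: per MOX channel the minimum (A), EMA(α=0.05) area
and minimum (B, C), EMA(α=0.1) area and minimum (D, E), range (F),
minimum first derivative (G), area (H), mean (I) and maximum (J); per
EC/PID channel the maximum reading (L).  Areas use the trapezoidal
rule over actual timestamps; derivatives divide first differences by
actual spacing; the EMA starts at the window's first sample with no
carry-over between windows.  The tenth MOX descriptor (J, the maximum)
completes the nine named shape descriptors to ten per sensor; it is the natural counterpart of the minimum and is
already implicit in the range.  EC/PID maxima are taken from raw
readings: compensation targets MOX resistances only.

Selection is all-relevant, Boruta-style: each iteration joins the
candidate features with permuted ("shadow") copies, fits a Random
Forest, and scores a hit for every candidate beating the best shadow
importance; sequential two-sided binomial tests (Bonferroni-corrected
over features and over the repeated looks) confirm or reject.  Two
implementation choices differ from the common Python implementation:
the shadow pool is rebuilt each iteration from the *full* original
feature set, keeping the best-shadow bar equally demanding as
candidates drop out, and the test threshold is divided by the
iteration count to control the sequential peeking.  Both choices were
validated on planted-feature simulations (signal confirmed, ≥ 90% of
pure-noise features rejected, no false confirmations on all-noise
matrices).

## Chemometrics

Features are autoscaled and projected by PCA.  The operative retention
rule is 90% cumulative explained variance; on this bench that selects
4–5 components (a fixed 3-component projection is available and is
what the quantifier-comparison bench uses).  Outliers are removed once before model fitting using
the influence plot — Hotelling T² over the retained scores (F-based
97.5% limit) against the Q residual (moment-matched scaled-χ²
limit) — computed *within each class*: the training set spans the
concentration range by design, so global leverage flags the designed
extremes rather than anomalies.

Classification is an RBF-SVM on the scores (one-vs-one multiclass),
with C ∈ 10⁻²…10³ and γ around the median heuristic (±2 decades)
chosen by stratified 10-fold CV maximizing the multiclass MCC.
Quantification is RBF-SVR on log₁₀ concentration with the analogous
grid, 10-fold CV minimizing log-RMSE:

* **QA** — one global regressor trained on all samples (including Air
  windows at their assigned olfactometry values).
* **QB** — one regressor per odour class, trained on that class only
  and routed at prediction time by the classifier's output.

Windows classified as Air bypass regression and report a floor of
20 ou_E/m³ (the lower end of the training range), flagged as a
convention.  Regressed predictions are clamped to the concentration
range seen in training: the instrument is calibrated only inside it.

## Evaluation

Multiclass MCC uses the covariance (R_K) form, cross-checked against
the binary closed form and an independent implementation in tests.
Accuracy intervals are exact binomial (Clopper–Pearson).  Bland–Altman
agreement is computed on log₁₀ concentrations: bias (mean difference),
limits of agreement `bias ± 1.96·s`, t-based bias CI (`s/√n`) and
classical LoA CIs (`s·√(3/n)`), each log quantity back-transformed to
a multiplicative factor `10^x`.  A Shapiro–Wilk gate (α = 0.05) checks
the normality assumption.  The olfactometry quality criteria are
`|bias| < 0.217` (accuracy) and `1.96·10^s < 3` (intermediate
precision, with the dispersion expressed as a factor, which keeps
the criterion arithmetic internally consistent).
Agreement pairs require a concentration estimate from both methods, so
windows the instrument classifies as Air are excluded (same mask for
QA and QB to keep the comparison paired).

## The synthetic bench

Field data being unavailable, the generator emulates the phenomena the
pipeline exists to handle.  Per MOX sensor the odourless baseline is
`R0·(1 − h1·AH + h2·AH²)` (decreasing over AH 5–18 g/m³); ambient AH
is a sinusoid (6-h period by default) with temperature in phase so the
derived RH stays physical.  An odour of class c at concentration C
drops sensor i's resistance by `min(k_ic·log₁₀(C/C0), 0.8)` with a
40-s first-order rise; EC channels respond in proportion to the
class's H₂S/NH₃ content and the PID to C with a class-specific
response factor.  Noise is multiplicative on MOX (2% default) and
additive/proportional on EC/PID.

Deliberate design features:

* **Humidity/odour confound.**  The per-sensor AH sensitivities `h1`
  are pattern-correlated with the Biogas response vector, so humidity
  swings mimic a reducing-gas event on raw and statically normalized
  signals — the failure mode that motivates the dynamic reference.
* **Deterministic aging.**  Sensitivity decays with campaign age
  (strongest for the most gas-sensitive MOX elements, ~0.1 log-units
  per month, small per-campaign scatter), so a test campaign months
  after training always faces a material drift that only re-zeroed
  references absorb.  EC cells and PID lamps decay more slowly.
* **Response threshold below the measured range.**  `C0 = 5 ou_E/m³`:
  every presentation in the 20–1000 ou range evokes a pattern, as the
  instruments' field discrimination over that range implies.  (The
  Air *reporting* floor stays at 20 ou_E/m³.)
* **Plateau presentations.**  Each training presentation opens half a
  window before its annotated analysis window and covers it
  end-to-end, so the window sees the settled response; the next slot's
  buffer half-window absorbs the shut-off.
* **EC/PID near detection limits.**  At fenceline concentrations the
  auxiliary channels are weakly informative relative to their noise
  floors, as for real electrochemical cells and PID lamps at tens of
  ppb.
* **Composition jitter.**  Each presentation's MOX/H₂S/NH₃/PID
  responses carry independent lognormal factors (σ = 0.08): two grabs
  from the same source never match exactly.

What passing tests do *not* show about real data: the generator has no
unknown interferents, no rain/wind effects, no sensor failures, no
within-window humidity transients faster than the ambient sinusoid,
and its class patterns are stationary apart from the modelled aging.
Results on the bench demonstrate that the pipeline recovers what the
generator encodes, not that the field instrument achieves the same
numbers.

## Named benches and their sizes

* *Compensation ordering*: one training campaign (3 classes × 40
  windows), one test campaign four months later (3 × 20), AH 5–18
  g/m³, 2% MOX noise.  Expected: test MCC CC ≥ CB ≥ CA with
  CC − CA ≥ 0.1.  Classification only (quantifiers skipped for speed).
* *Quantifier comparison*: a variant scenario with strongly
  class-distinct gains (MOX magnitudes ~3×, PID factors ~6× between
  classes, jitter 0.02), fixed 3-component projection, 60 training and
  40 test windows per class, pooled over 4 independent replicates into
  one Bland–Altman per quantifier.  Expected: QB's LoA width below
  QA's.  Both benches are stochastic; across 18 validation seeds the
  ordering held in all and the quantifier direction in all but
  occasional near-ties (width gap < 0.02 log units).
* *Recovery*: noiseless AH sweeps must return the baseline polynomial
  coefficients to ≤ 10⁻⁶ relative; a low-noise campaign (0.5% noise,
  no jitter) must train to CV MCC ≥ 0.9 and CV log-RMSE ≤ 0.15.
* *Calibration*: clean Gaussian clouds (n = 2000) flagged at ≈ 2.5–5%
  by the influence plot; planted-feature selection over 20 seeds
  (250 × 16 matrices) confirms the signal and rejects ≥ 90% of noise
  features.

These sizes keep a full reproduction run in the minutes range on a
single CPU while leaving each comparison comfortably powered.

## Known limitations

* The closed-world classifier has no reject option; far-out windows
  still receive one of the trained labels (flagged only indirectly via
  the AH-extrapolation warning and the clamped quantifier range).
* Monitoring uses the training-time references; without periodic
  re-zeroing on known-clean air, instrument drift re-enters as odour
  over-detection (visible on the bench when the monitoring stream's
  drift state differs from training).
* The intermediate-precision criterion is evaluated with the
  dispersion mapped to a factor (`10^s`); other readings of the
  dispersion scale exist.
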