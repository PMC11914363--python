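# Methods

`ramanferm` implements a complete chemometric workflow for Raman-based
fermentation monitoring — preprocessing, PLS1 calibration, error assessment,
specificity diagnostics, and calibration-set supplementation — together with a
synthetic-data generator that reproduces the data situation the workflow is
designed for.  This note documents the models, the defaults and why they were
chosen, and what the synthetic results do and do not establish about real
instruments.

## The scientific problem

During a batch fermentation, substrate consumption, product formation and
growth are coupled: glucose falls while ethanol and biomass rise, with pairwise
|Pearson r| typically above 0.98.  A PLS model calibrated on such data
maximizes X–y covariance without knowing chemistry, so a "glucose" model is
free to quantify glucose from ethanol or biomass bands.  On the process it was
calibrated for, this is invisible — validation on an identical batch gives low
errors.  It fails the moment the inter-analyte ratios change, e.g. when the
same organism is run as a fed-batch with substrate boluses.  The remedy
implemented here: append spectra of the target analyte titrated alone in
medium ("single-compound spectra") to the process calibration set and
re-calibrate, which breaks the cross-correlation for that analyte and extends
its calibration range without new process runs.

## Synthetic data generator

### Process kinetics

Monod uptake with growth tied to consumption:

    dS/dt = -q_s(S) X,   q_s = qs_max * S / (Ks + S),   dX/dt = Y_xs * MW * (-dS/dt)

with S glucose (mM), X biomass (g DW/L), MW = 0.18016 g/mmol, and ethanol
stoichiometric, `E = Y_es * (glucose supplied - glucose left)`.  Because X and
E are affine functions of S, the mass balance and the cross-correlation
structure hold *exactly* at every sample; only S is integrated numerically
(`scipy.integrate.solve_ivp`, rtol/atol 1e-10, with a terminal depletion
event).  Defaults: `qs_max = 10.9 mmol/(g·h)`, `Ks = 5.6 mM`,
`Y_xs = 0.16 g/g`, `Y_es = 1.43 mol/mol`, initial charge 111 mM (20 g/L),
inoculum 0.10 g/L, hourly sampling, depletion threshold 0.5 mM.  These put one
batch at ~12.5 h to depletion (13–14 hourly samples; three batches ≈ 40
calibration samples, one validation batch ≈ 13), ethanol ≤ ~165 mM and biomass
≤ ~3.4 g/L — the usual batch calibration ranges for aerobic *S. cerevisiae* on
20 g/L glucose.

Fed-batch operation fires an instantaneous glucose bolus (default 3 × 40 mM;
feed volume ignored) whenever the substrate hits the depletion threshold, the
off-gas-triggered spiking regime.  Fed phases keep the batch yields: the
boluses alone redistribute the substrate-to-product ratios, while ethanol and
biomass keep co-varying as in the batch.  This is deliberate — if the
ethanol:biomass direction itself rotated between modes, no per-target
supplementation could fix the glucose model even in principle, because the
titration constrains only the model's response to its own analyte.  The
default fed-batch reaches ~330 mM ethanol (≈2× the batch ceiling, so a
batch-trained ethanol model must extrapolate) and ~6.8 g/L biomass (beyond the
0–5 g/L biomass titration, so the biomass model keeps extrapolating even after
supplementation — matching the situation where the single-compound biomass
series cannot reach the fed-batch cell densities).

Run-to-run variability (applied when a seed is given): lognormal jitter with
CV 8% on the inoculum, 5% on `qs_max`, 3% on the initial charge, 4% on each
yield.  The yield jitter matters: it shifts the analyte ratios slightly
between nominally identical runs, which is precisely the fragility of implicit
models — without it, base models are unrealistically accurate on the
validation batch.  Pooled three-batch reference correlations stay at
|r| ≈ 0.99, comfortably in the >0.98 regime the analysis presumes.

### Pure-component spectra and the forward model

Each analyte is a set of Gaussian bands (Lorentzian available) at its standard
Raman assignments — glucose 517 (C2-C1-O1 bending), 1060, 1125 (C-O-H
bending), 1365, 1460 cm⁻¹; ethanol 879 (C-C stretch), 1046 (C-O stretch),
1084 (CH₃ rock), 1276, 1455 cm⁻¹ (CH₃ asymmetric deformation); biomass weak
cell markers at 1003, 1450, 1660 cm⁻¹ — on a 100–3400 cm⁻¹ grid at 1 cm⁻¹.
Glucose and ethanol overlap in the 1000–1150 and 1400–1500 cm⁻¹ windows; the
879 cm⁻¹ ethanol band is free of glucose and biomass bands.  Band heights are
per unit concentration (mM, or g/L for biomass) and were set so the three
analytes contribute comparably at their process concentrations.

The noiseless signal is a linear (Beer–Lambert-like) mixture.  Biomass has two
spectral faces, exposed as `biomass_mode` because the mechanism is not settled:

- `suspension_baseline` (single-compound acquisition): the biomass spectrum
  additionally carries a broad ascending baseline over 1200–1600 cm⁻¹
  (logistic ramp, 3 intensity units per g/L);
- `fermentation_extinction` (running process): the ramp is absent and the
  whole mixture is attenuated by `exp(-k_ext · X · w(ν))` with a slowly
  varying `w(ν) ∈ [0.5, 1]` and `k_ext = 0.005 L/g` — non-linear
  Lorenz–Mie-like signal extinction by cells as particles.

On top of the mixture: a deterministic fluorescence background
`A·exp(-(ν-100)/λ)` with `A = 3000`, `λ = 350 cm⁻¹`; a per-spectrum
multiplicative gain `1 + N(0, 0.05)` scaling mixture *and* background
(collection efficiency scales all collected light — this is the term EMSC's
multiplicative coefficient removes); a per-spectrum random polynomial drift
(SDs 2/1/0.5 on a normalized axis); and i.i.d. channel noise with SD 4.  The
background dominates the Raman bands by an order of magnitude and falls off
much faster than a quadratic across the fingerprint window.  Both properties
are load-bearing: they make the EMSC reference fit lock onto the overall
light level (b ≈ gain) rather than onto the analyte signal.  In exploratory
runs with a weak or quadratic-like background, EMSC's division by b rescaled
spectra by their analyte content and destroyed the calibration — a useful
negative result: basic EMSC with a mean reference presumes
fluorescence-dominated spectra.

### Reference assays and titrations

Dataset reference values are simulated assay readings: truth plus independent
error with 2.5% relative SD and floors of 4 mM (glucose, ethanol; HPLC scale)
and 0.06 g/L (biomass dry weight).  One reading covers all replicates of a
titration level (one sample is drawn per level).  Readings near the detection
limit may be slightly negative, as chromatogram integration produces.  The
underlying `ProcessTrajectory` keeps the exact stoichiometric truth.

Titrations follow add-then-sample bookkeeping in a 1 L vessel:
`c ← (cV + c_stock·V_add)/(V + V_add)`, after which the withdrawn assay sample
restores the volume.  Glucose: 20 additions of 10 mL with geometrically
growing increments (ratio 1.08) normalized to end at 247.08 mM — denser at low
concentration, and every step feasible with a ≤50% w/v (≈2776 mM) stock; an
exactly "exponentially increasing" schedule is infeasible late in the series
under that stock cap.  Ethanol: 25 × 20 mM linear steps to 500 mM.  Biomass:
11 × 0.45 g/L steps to ~4.95 g/L using 50 mL additions of a 14.3 g/L washed
cell suspension (10 mL additions cannot reach ~5 g/L from that stock).  Ten
replicate spectra per level, acquired in suspension mode.

## Preprocessing

Fixed, enforced order (`stage` tag on every dataset): fingerprint crop →
EMSC → mean-centering.

- **Crop**: channels with 450 ≤ ν ≤ 1800 cm⁻¹, both bounds inclusive (1351
  channels on the default grid).
- **EMSC**: each spectrum is decomposed by ordinary least squares on
  `[1, ν̃, ν̃², m]`, where ν̃ is the wavenumber axis normalized to [-1, 1]
  (raw cm⁻¹ powers are numerically hostile) and `m` is the mean spectrum of
  the stated fitting set; corrected = `(x - a - d₁ν̃ - d₂ν̃²)/b`.  Spectra with
  |b| below 1e-8 on the reference scale are flagged invalid (NaN) rather than
  aborting the batch.  Unseen data are always corrected against the
  calibration-set reference, never their own mean.
- **Centering**: calibration column means are stored and applied to unseen
  data.

After supplementation, the EMSC reference and the centering means are
recomputed on the combined set (full re-calibration).

## PLS1 calibration

One model per analyte (PLS1 via sequential deflation: `w ∝ X'y`, `t = Xw`,
`p = X't/t't`, `q = y't/t't`, deflate X), regression vector
`b = W(P'W)⁻¹q`.  Equivalence with an independent reference implementation and
the full-rank OLS limit are asserted in the test suite.

Cross-validation is 7-fold venetian blinds over acquisition order (sample i →
fold i mod 7; for supplemented sets, process samples in acquisition order
followed by titration levels in concentration order).  The EMSC reference and
centering means are refit inside every training split — no preprocessing
leakage into held-out folds.  RMSECV pools held-out residuals across folds
(rather than averaging per-fold RMSEs); RMSEC comes from a full-data refit.

The latent-variable count is chosen at the RMSECV elbow: the smallest n whose
relative improvement to n+1 is ≤ τ (default τ = 0.05, non-strict with a 1e-12
float slack so a step of exactly τ counts as the elbow; a flat curve selects
1).  The published workflow selects the elbow visually; this rule is the
package's quantitative stand-in, the full curve is always logged, and a manual
override (logged) wins unconditionally.

## Assessment

RMSE variants are normalized by the interquartile range,
`rRMSE = 100·RMSE/(Q3 - Q1)`, with quartiles by linear interpolation between
closest ranks (the result depends on the quantile convention, so it is fixed
and tested against a sort-and-interpolate oracle).  rRMSEC/rRMSECV use the
calibration set's IQR; rRMSEP uses the application dataset's own IQR.
Supplementation benefit is `improvement = 100·(base - supplemented)/base` on
the fed-batch rRMSEP; negative values (worsening) are reported and logged, not
masked.

Specificity is quantified as the cosine similarity between a model's
regression vector and each mean-centered pure-component spectrum, plus a
per-band table of coefficient signs at 517/879/1046/1084/1125/1455 cm⁻¹.  The
cosine score is a package-level diagnostic of what is usually judged by eye;
it has no literature-standard scale.  Negative regression coefficients are
reported as-is — with overlapping bands they arise from the mathematics of PLS
and need not mean negative correlation.

## Numerical and design choices

- Quantile convention: linear interpolation (numpy default), documented above.
- Venetian-blind tie-break: dataset row order is acquisition order.
- `fit_pls1` raises when the requested components exceed the effective rank;
  inside cross-validation it stops early instead (noise-free folds exhaust the
  rank) and later components predict as the last extractable one.
- Equal weighting of process and single-compound samples in supplemented
  calibrations.
- Non-target reference values of titration rows are carried (their assay
  readings, ≈0) but unused by the PLS1 models.
- Seeds: every stochastic operation takes an explicit seed; no global RNG
  state.  Identical seed + parameters give bitwise-identical datasets.
- Serialization: wide CSV with 17-significant-digit intensities (bit-exact
  float64 round-trip); model bundles as JSON.

## What the synthetic results do and do not show

The generator reproduces the *mechanisms* — cross-correlated calibration data,
ratio redistribution under bolus feeding, range extrapolation, the
suspension/extinction dichotomy for cells — at desk scale (three ~13-sample
batches, one fed-batch, ~20-sample/channel problems, seconds per full study).
Passing tests establish that the pipeline implements these methods correctly
and that supplementation behaves directionally as expected under known ground
truth: base models degrade several-fold when transferred to the fed-batch,
per-target supplementation recovers most of that error for glucose and
ethanol, improves but does not rescue biomass, and leaves validation-batch
performance essentially unchanged (the supplemented/base validation error
ratio is ~1 in the median; on a ~13-sample batch the per-run ratio scatters
roughly between 0.6 and 1.6 from sampling noise alone).

They do not certify numerical error levels on any real instrument: real
spectra add detector saturation and cosmic spikes, wavenumber-axis drift,
media fluorescence with chemistry of its own, non-Gaussian band shapes, and
biology that no fixed-yield Monod model captures.  The exact published error
statistics of the original fed-batch study depend on spectra that are not
public; the worked-example improvements (82.72%, 90.05%, 69.26%) are
recomputed here from the published error pairs, and everything else is
property-based on the synthetic scenario.
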