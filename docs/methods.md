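# Methods

## Optical layer model

A layer is (thickness t, water fraction w, band list). The absorption
coefficient is μₐ(ν) = w·μₐ,water + Σ Gaussian bands; μₐ,water defaults to
817 cm⁻¹, the mid-infrared value for liquid water near 1000 cm⁻¹. Absorbance
is decadic, A = μₐ t / ln 10 — the ln 10 division is what places a 10-μm/10 %
layer at 0.04 Bel and a 20-μm/30 % layer at 0.21 Bel, the stratum-corneum
absorbance window; natural-log absorbance would not. Penetration depth is
defined as 1/μₐ with the wettest hydration (w = 0.3), giving 40.8 μm ≈ 40 μm.
The alternative back-calculation from 0.21 Bel over 20 μm gives 41.4 μm, which
rounds identically; the direct reciprocal is adopted as the cleaner
definition.

Bands are Gaussian with σ as the width parameter — the simplest profile that
makes each center a local extremum, which the model relies on; measured
mid-infrared bands of glucose and skin proteins are broad and smooth enough
that the exact line shape is immaterial at the 2 cm⁻¹ default grid. Band
centers are guaranteed to appear as distinct local extrema only when centers
are separated by more than ~3σ; closer bands merge, which is physical.
Default grid: 930–1200 cm⁻¹ at 2 cm⁻¹ (the source's tuning range; the spacing
is a package choice — fine enough to resolve σ ≥ 8 cm⁻¹ bands, coarse enough
that an 80-record dataset stays small).

No scattering or radiative transfer is modeled: the depth argument in this
regime is purely absorptive. No ATR evanescent-field model is included.

## Photoacoustic forward model

For samples thicker than a few tens of micrometres, essentially all light is
absorbed and the heated volume scales as 1/μₐ, so the thermoelastic signal is
taken as exactly S = k/μₐ (the optically thick regime; a thin-sample mode
S = k·μₐ·t exists but is unused by the generator). No additive offset is
included — the pure reciprocal is the minimal form consistent with the
inverse relation between absorption and signal. A top layer attenuates the
incident light once by 10^(−A): the wave that returns to the detector is
acoustic, not optical, so there is no second optical pass. Laser irradiance
is average power over the 1/e² spot area; 12 mW over a 1-mm spot gives
1.53 ≈ 1.5 W/cm² (peak Gaussian irradiance would be about double, so the
average-power convention is the one that matches the instrument's stated
operating point). Modulation frequency enters only through the acoustic
resonance factor; there is no heat-diffusion PDE.

## Acoustic resonance

Standing waves in a layer of thickness t require t = (2m+1)λ/4, hence
fₘ = (2m+1)v/4t — odd harmonics in exact 1:3:5 ratio. The measured frequency
response is modeled as baseline·(1 + g·Σₘ Lₘ(f)) with Lorentzians
Lₘ = 1/(1 + (2Q(f−fₘ)/fₘ)²) and one shared quality factor: the minimal
damped-resonator description. Defaults Q = 30 and g = 3 make the
on/off-resonance amplitude ratio 4, matching the observed enhancement for a
2-mm polyurethane gel; both are configurable because the gain is specific to
transducer, geometry and coupling. Non-thickness (lateral) resonances can be
injected as extra user-supplied mode frequencies; no lateral geometry is
modeled. Peak detection uses prominence ≥ 0.1 of the sweep's amplitude range
(scipy `find_peaks`), which recovers every analytic resonance to within one
frequency-grid step for Q ≥ 20 and well-separated modes. Interface
reflection uses the scalar normal-incidence coefficient as an upper-bound
diagnostic only; there is no multilayer transfer-matrix solver. Note that a
published 637 kHz observation for a 4-mm gel corresponds to m = 3 at a
compressed-gel sound speed; the formula value at v = 1389 m/s is 607.7 kHz,
and the model reports formula values.

## Synthetic OGTT datasets

The generator emulates a single-subject measurement campaign:

* **Glucose time course.** Baseline 90 mg/dL; after sugar ingestion at t = 0
  the excursion follows baseline + 70·(t/45)·exp(1 − t/45) mg/dL (gamma-like
  rise/decay peaking at 45 min, a plausible OGTT shape for a healthy adult;
  the functional form is a package choice and every parameter is exposed).
  Sampling every 5 min over ±120 min gives 49 records per day; longer
  campaigns roll over to further days. Fingerstick-meter noise: additive
  Gaussian, σ = 2 mg/dL. The reference series is smoothed with a trailing
  3-point moving average (each value with its two predecessors, shortened at
  the start), and class labels threshold the smoothed value at 140 mg/dL
  (exactly 140 → class 0).
* **Spectra.** Each record runs the forward model for a 15-μm, 20 %-water
  stratum-corneum layer with protein bands at 1030/1080 cm⁻¹ (σ = 12,
  amplitude 300 cm⁻¹) over an 80 %-water bulk with glucose bands at
  990/1110 cm⁻¹ (σ = 10). Glucose band amplitude is linear in the record's
  smoothed glucose, 0.142 cm⁻¹ per mg/dL — calibrated so the 90→180 mg/dL
  excursion moves the scaled 1110 cm⁻¹ dip by ~5 % of the spectrum's dynamic
  range, keeping the two-class problem nontrivial. The smoothed value (the
  same quantity the labels threshold) drives the spectra so that a zero-noise
  dataset is separable by construction; the raw reference models only meter
  error.
* **Noise.** Per record: multiplicative gain jitter, per-band amplitude
  jitter, additive white noise (σ = 0.004 a.u. against an off-band signal of
  ~1 a.u.); per day: an additive baseline drift; per dataset: an optional
  band-center shift (an intersubject knob, off by default). Fixed-mode
  defaults are gain 2 % / band 3 %; repositioned mode — the sample removed
  and replaced between measurements on inhomogeneous tissue — uses 8 % /
  10 %. All randomness flows from one seed; identical seeds give
  bit-identical datasets.

What the generator does **not** emulate: blood↔interstitial-fluid lag,
hydration/temperature covariates, contact-pressure effects, drift within a
measurement, or real intersubject spectral diversity. Passing tests
demonstrate that the pipeline recovers a known, linearly encoded glucose
signal under calibrated noise — they say nothing about whether real skin
spectra carry such a signal.

## Preprocessing

Fixed order: laser-power normalization (pointwise quotient) → min–max scaling
→ band selection. Scaling extrema are computed on the closed window
970–1162 cm⁻¹ and the affine map applied to the whole spectrum; the modeling
band 1022–1148 cm⁻¹ is a subset, so its 64 features land in [0, 1]. Window
endpoints are inclusive. A spectrum constant on the scaling window raises
rather than returning zeros, to surface instrument faults. The trailing
moving average belongs to the glucose time series, not to the spectral axis;
record-wise smoothing of spectra over time is available to callers of
`trailing_moving_average` but is not part of the default chain.

## PLS-DA and evaluation

NIPALS PLS1 on column-centered X and centered 0/1 y: per component
w ∝ Xᵀy (unit norm), t = Xw, p = Xᵀt/tᵀt, q = yᵀt/tᵀt, deflate both;
b = W(PᵀW)⁻¹q. Degenerate deflation (‖Xᵀy‖ ≈ 0) stops early with a warning;
requesting more components than the centered rank raises. At full rank the
in-sample fit equals ordinary least squares (tested against a direct solve
and against scikit-learn's PLS with scaling off).

The posterior is the PLS prediction clipped to [0, 1] — the simplest
monotone mapping; the class rule is posterior ≥ 0.5 → class 1 (ties to 1,
documented). The posterior is mapped linearly onto 95–185 mg/dL, whose
midpoint is exactly the 140 mg/dL threshold — an internal-consistency
argument for the linear choice.

Latent-variable selection: leave-one-out Q² = 1 − PRESS/TSS with TSS using
the training-fold mean (strict out-of-sample convention), candidates 1–5,
argmax with ties to the smaller count (parsimony); candidates exceeding a
fold's rank score −∞ and are skipped with a warning. Performance: stratified
seeded fivefold accuracy, reported both fold-averaged and pooled. Clarke
error-grid zones follow the original five-zone piecewise-linear geometry,
evaluated as an ordered rule chain, so every pair in (0, 600]² receives
exactly one zone.

Numerical notes: NIPALS tolerance is 1e−12 relative to the data magnitude;
score orthogonality holds to 1e−8 relative. Cross-validated accuracy on a
zero-noise dataset is not exactly 1: a held-out record arbitrarily close to
the 140 mg/dL threshold has vanishing margin, so tests bound it at 0.95
while asserting exact in-sample separability.

## Problem sizes

Default experiments use 80 records × 64 features, the natural scale of a
single-subject multi-day campaign at 5-min sampling; repeated-seed
statistical checks use 20–50 seeds at this size, and the full suite runs in
a few seconds on one core.
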