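# Methods

## What the package computes

`petquant` quantifies small-animal FDG-PET studies the way a preclinical
imaging lab does when using a clinical scanner: a phantom scan calibrates
image units into dose-per-gram units, static uptake is reported as %ID/g
and SUV_max, ex vivo γ-counting provides the reference standard, and
dynamic scans yield one-tissue-compartment rate constants and Patlak influx
maps. A digital mouse phantom with fully known ground truth closes the
loop: every analysis stage is validated by recovering what the simulator
injected.

## Dose arithmetic and decay

All decay corrections use λ = 0.693/109.8 min⁻¹. The three-digit 0.693 is
deliberate: the package reproduces the published form of the dose formulas
digit-for-digit rather than using ln 2 = 0.693147 (the difference is 2×10⁻⁴
relative per half-life); every decay routine takes `exact_ln2=True` to
switch. Clock times are parsed from strings into integer hour/minute so the
decimal HH.MM log-book encoding (10.05 = five past ten) is exact — floats
like 10.05 have no exact binary representation and would corrupt the
minutes field. The net injected dose subtracts the residual syringe
activity *after* decaying the assayed dose to injection time (the residual
is measured at injection time); other conventions exist, so this is stated
here. Negative time intervals are errors by default, with an opt-in +24 h
midnight wrap.

The conversion factor CF = B1/B2/B3 carries units (μCi/g)/(kBq/ml). For a
scanner that reads true concentration, B3 = B1/B2·37 and CF = 1/37 ≈
0.027027 — the pure μCi↔kBq unit conversion. Any multiplicative scanner
gain applied to both the phantom reading and tissue readings cancels in
%ID/g; this invariance is tested.

## The simulator

**Geometry.** Organs are ellipsoids voxelised at 1 mm isotropic on a
44 × 44 × 84 mm grid (voxel centres at (i+0.5)·1 mm). The default mouse has
brain, heart, liver, one kidney, a ~200 mm³ shoulder tumor and a thigh
muscle region, all pairwise disjoint with ≥5 mm border clearance so
Gaussian blur loses <0.1% of activity off-grid. Organ overlap is a hard
error, never a blend: ground truth must stay unambiguous. The in-plane
reconstructed voxel size of the scanners being emulated is not public;
1 mm is a simulation-grid choice, not a scanner claim.

**Activity.** A static organ with true uptake u (%ID/g) and density ρ
(g/ml, default 1) is painted at the decay-corrected concentration
L = u·ρ·I/(100·CF_ideal) kBq/ml, where I is the dose on board at scan
start — the unique concentration that makes the calibrated quantification
an exact identity. Kinetic organs follow
C(t) = (1−v)·K1·(C_p ⊛ e^(−k2 t)) + v·C_p(t) with vascular fraction v; a
pure blood pool is (K1 = 0, v = 1). Frame values are the *analytic mean*
over the frame interval (Gauss–Legendre order 8 on the closed-form curve),
not a midpoint sample, so the noise-free identity `extract_tac ∘ simulate =
model` holds to float32 precision. Physical decay, when enabled, multiplies
the integrand by e^(−λt) with t = 0 at injection; by default images are
emitted decay-corrected, as reconstructed clinical images are.

**Resolution.** Reconstruction is out of scope; its effect is modelled as
an isotropic Gaussian PSF. Presets: 0 mm (ideal), 1.66 mm (micro-PET
FWHM), 3.3 mm (clinical whole-body without resolution recovery), and
2.0 mm as a stand-in for PSF-based iterative recovery on a clinical
scanner — vendors do not publish an effective width, so 2.0 mm encodes
"between micro-PET and plain clinical" and is used only for direction-of-
effect properties, never for absolute claims.

**Noise.** Additive zero-mean Gaussian with SD = s·√A/√Δ (A voxel activity,
Δ frame duration in minutes, s the `noise_scale` in kBq/ml at 1 kBq/ml·min)
— the variance structure of count statistics without a full sinogram model;
a Poisson mode (counts ~ Poisson(A·Δ/s)) is available. All randomness
derives from one root seed through named substreams (noise, calibration,
biodistribution, cohort), so identical configs are bit-identical and single
stages are independently reproducible.

**Blood input.** The arterial input is a sum-of-exponentials bolus,
C_p(t) = Σᵢ Aᵢ(e^(−aᵢt) − e^(−rt)), two decay terms (fast vascular
clearance 1.5 min⁻¹, slow body clearance 0.02 min⁻¹; amplitudes 80 and
8 kBq/ml) sharing one rise term (6 min⁻¹). It is zero at injection, peaks
(~40 kBq/ml) near 0.6 min — within the bolus-resolving 1-s frames — and
then falls monotonically, fast then slowly. No published functional form
was available for the emulated studies; this shape was chosen once as a
standard bolus model and is configurable. Its convolution with the
one-tissue impulse response and its running integral both have closed
forms, which the simulator and the Patlak oracle exploit.

**γ-counting.** Biodistribution counts invert the %ID/g definition
exactly: counts = u/100 · wet-weight · I(count time) · 37 000 Bq, with
optional multiplicative Gaussian measurement noise of a given CV. Default
wet weights are typical for a 20 g mouse.

## Quantification choices

* ROI SD uses the n−1 (sample) denominator, as do all cohort SDs.
* SUV_max uses the hottest ROI voxel; %ID/g uses the ROI mean. With
  IA taken as the scan-time dose I, SUV = %ID/g·W/100 for unit-density
  tissue — an identity the tests assert on simulated data.
* SNR is computed within the ROI (mean/SD of the same region); whether a
  separate background region should supply the SD is a reporting choice
  we do not make for the user.
* Cohort T/NT is the mean of per-animal tumor/muscle ratios, *not* the
  ratio of cohort means; the two differ under between-animal variability
  and only the former matches how cohort T/NT tables are built.
* `core_mask` erodes an organ mask by a margin (default pipeline uses
  1.5 mm for noisy cohorts): it emulates placing ROIs over the most
  intense part of an organ, which keeps the ROI mean away from
  resolution-blurred edges. With whole-organ masks a 2 mm PSF removes
  15–20% of a heart-sized object's mean by spill-out into cold
  surroundings; hot-core ROIs are how practitioners avoid exactly that.

## Kinetics

**Forward model.** `simulate_1tcm` accepts the blood curve as (a) the
analytic bolus model — closed-form convolution; (b) a sampled TAC — the
curve is treated as piecewise linear and convolved exactly segment by
segment (stable `expm1` forms, k2 = 0 branch), with long late frames
subdivided to ≤20 s for frame averaging; or (c) an arbitrary callable —
ODE integration (`solve_ivp`, rtol 1e-9). Routes are cross-validated
against each other and against quadrature in the tests.

**Fitting.** Nonlinear least squares (`scipy.optimize.least_squares`, TRF,
bounds K1 ∈ [0, 10] mL/min/g, k2 ∈ [0, 2] min⁻¹) from the fixed start grid
{0.01, 0.1, 0.5} × {0.001, 0.01, 0.1} in fixed order; the best converged
start wins, making fits deterministic. Residuals are weighted by frame
duration by default (longer frames carry more counts); uniform weights are
an option. TACs not already decay-corrected are corrected to injection
time before fitting. Non-convergence of every start raises, never returns
silently.

**Accuracy.** With the analytic input function, noise-free round-trips
recover (K1, k2) to machine precision across K1 ∈ [0.05, 0.5],
k2 ∈ [0.001, 0.05]; with 5% multiplicative TAC noise the median bias stays
under 10% over 100 replicates. When the input is known only as its
frame-averaged TAC, piecewise-linear interpolation cannot represent the
fast bolus decay across 2-min frames and leaves a small systematic bias
(≲5% on K1, ≲10% on k2 at the reference tumor parameters); reference
recoveries therefore fit against the continuous input function, and the
sampled route is tested at its own tolerance. This is a real property of
coarsely sampled input functions, not an implementation artifact.

**Patlak.** y = C_t/C_p is regressed on x = ∫C_p/C_p over frames past
t* (default 20 min, configurable; r² of the fitted window is reported so
the linearity assumption can be audited). For k2 = 0 the slope equals K1
exactly; for k2 > 0 it is strictly below K1 — tested as an invariant. The
parametric variant runs the same OLS per voxel with the shared abscissa
vectorised; identically-zero voxel TACs are flagged invalid and mapped to
slope = intercept = 0. Patlak yields influx slope and intercept, not
(K1, k2); the compartment fit is the (K1, k2) source and Patlak is exposed
separately.

## Statistics

Between-source agreement uses unweighted OLS pooled over organ × animal
points and two-sided paired t-tests without multiplicity correction.
Pooled regressions are dominated by the high-uptake organs (heart); the
regression of the six cohort *means* of the reference uptake table gives
slope 0.986, r² 0.9999 — close to, but distinct from, a pooled per-animal
slope, and the tests keep the two separate.

## Validation scales and what passing shows

The test suite and acceptance script run at desk scale: 44 × 44 × 84 grids,
cohorts of 10 mice × 50 seeds for the stochastic regression property,
25-point parameter grids and 100-replicate noise studies — sizes chosen so
the whole suite completes in a few minutes on one CPU while leaving every
statistical check well-powered. The simulator emulates organ-scale uptake,
resolution loss, count-like noise and decay; it does not model sinograms,
scatter/randoms, attenuation, respiratory motion, intra-organ
heterogeneity, or spill-*in* from warm backgrounds (organs sit in cold
surroundings). Recovery tests therefore demonstrate correctness of the
analysis chain — formulas, calibration, convolution, fitting, statistics —
under the stated acquisition model, not scanner-level realism: directional
findings (partial-volume ordering across PSF widths, regression slope
degradation at coarser resolution, blur shrinking fitted K1) transfer to
real data, absolute recovered values do not.

## Known limitations

* The 2.0 mm "resolution-recovery" preset is a stand-in, not a measured
  effective FWHM.
* The heart blood-pool input function is used uncorrected for partial
  volume, as image-derived input functions commonly are in practice.
* k2 is interpreted literally in min⁻¹; at the reference magnitude
  (0.0044 min⁻¹) the 60-min scan constrains it weakly, which is why its
  noisy-fit dispersion is much larger than K1's.
* The Gaussian noise surrogate matches count-statistics variance scaling
  but not its higher moments; use the Poisson mode where that matters.
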