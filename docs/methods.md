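# Methods

This note documents the models implemented in `bbbflow`, the synthetic
phantoms used to validate them, the numerical choices made where the design
was open, and what passing tests do and do not demonstrate.

## DCE-MRI chain

**Signal model.** All dynamic and T1-mapping volumes follow the
steady-state spoiled gradient-echo (SPGR) equation with TR = 4.5 ms and
flip angles 2/8/12° (VFA) and 12° (dynamic), with the achieved flip angle
equal to the nominal angle multiplied by the B1 map. Default acquisition
constants: 60 frames at 17.5 s, gadolinium relaxivity
r1 = 3.5 L·mmol⁻¹·s⁻¹, hematocrit 0.45.

**T1 mapping.** The VFA fit uses the standard linearization:
y = S/sin(α_eff) against x = S/tan(α_eff) is a line with slope
E1 = exp(−TR/T1). Two angles give the closed form, three or more an
ordinary least-squares line per voxel. Voxels with slope outside (0, 1),
constant regressors, zero signal, or signals identical across angles are
flagged invalid and never imputed; ROI averages use valid voxels only.

**Dynamic inversion.** R1(t) is inverted analytically per frame, which is
exact under the fast-water-exchange assumption. The dynamic equilibrium
magnetization is estimated from the mean of the first `n_baseline_frames`
(default 3: with the contrast injection starting ~60 s in at 17.5 s per
frame, the first three frames are guaranteed pre-contrast). Frames whose
inversion falls outside the physical branch (E1 ∉ (0, 1), e.g. zero
signal) are flagged and excluded from fits. Negative concentrations are
preserved — no thresholding or value-based exclusion anywhere — but counted
in the QC report; values within 1e-12 of zero are treated as rounding, not
as negative.

**VIF extraction.** The correlation mask is computed on raw signal curves
(not concentration) against the seed-voxel curve, threshold R ≥ 0.99, with
1e-12 numerical slack so identical curves survive a threshold of exactly
1.0. The mask is thinned (3D skeletonization) and the longest weighted
path through the thinned set is the centerline, ordered by path distance
with lexicographic tie-breaks for determinism. The blood curve averages
the 25 centerline voxels in a contiguous run starting at the point closest
to the seed and extending toward the longer limb — the placement rule is a
package decision (contiguity minimizes partial-volume heterogeneity); only
the count is prescribed by the protocol. Plasma conversion divides by
(1 − HCT). Seed placement is an input; `auto_seed` (global enhancement
argmax) stands in for manual placement in pipelines.

**Patlak fit.** Two-regressor, no-intercept OLS of C_tissue on
[∫C_VIF dt, C_VIF], the integral by cumulative trapezoid on the frame
times converted to minutes so PS is in min⁻¹. No non-negativity
constraint. The injection-peak sensitivity analysis refits with the frames
overlapping the injection (start → end + one frame by default) masked, and
reports the absolute-agreement ICC between full and masked PS across
curves. Masking removes regression rows only; the VIF integral is always
accumulated on the full grid.

## 4D-flow chain

**Preprocessing.** A spatial polynomial (degree ≤ 3, default 1) is fitted
to each velocity component's time-average over static-tissue voxels and
subtracted everywhere, correcting eddy-current/concomitant-field offsets.

**Centerlines.** The CD angiogram is thresholded, thinned to a one-voxel
skeleton, and split into branches at voxels with ≥ 3 skeleton neighbors
(26-connectivity). Vessels only one or two voxels wide can be annihilated
by 3D thinning; any mask component that loses all its skeleton voxels is
recovered by tracing the longest path through the component directly.
Tangents are the principal direction of each voxel and ±3 path neighbors
(±2 for distal vessels), sign-oriented along the path.

**Flow integration.** The cross-section at a centerline point is the voxel
layer within half a voxel of the perpendicular plane, limited to a 6 mm
radius. Lumen voxels are those above 50% of the local CD maximum (the
full-width-half-maximum rule, the standard phase-contrast lumen
criterion). Flow is Σ(v·t̂)·voxel-area converted to ml/min; the
equivalent-circle diameter 2√(area/π) feeds the 1.25 mm large/distal
threshold. Large-vessel waveforms average 15 consecutive sections around
the seed; left and right carotid waveforms can be averaged.

**Classification.** K-means (K = 2) on mean-normalized branch-averaged
waveforms separates arteries from veins; the cluster with the higher mean
pulsatility is arterial (deterministic, and the physiological signature the
separation exploits — veins are heavily damped). Identical waveforms make
clustering degenerate and raise an error advising manual classification.
A prune list excludes contaminated branches a priori. The distal waveform
is the frame-wise median of per-voxel waveforms each normalized by its own
mean (median for robustness to outlier voxels).

**Pulsatility.** Waveforms are interpolated from the 20 acquired cardiac
frames to 2000 with a periodic cubic spline (the cardiac cycle is cyclic,
so the first frame follows the last); PI = (max − min)/mean of the
interpolated curve. tCBF sums the mean inflow of ICA-L, ICA-R and BA and
requires unnormalized waveforms.

## Cohort statistics

Descriptives use sample SD, bias-corrected skewness and *excess* kurtosis
(normal → 0), and a t-based 95% CI of the mean. Simple regression reports
the OLS slope with t-based CI and two-sided p (α = 0.05, no
multiple-comparison correction by default; Bonferroni/FDR is opt-in).
Residualization regresses on [intercept, covariates] and keeps the
residuals; it is an orthogonal projection (idempotent, exactly zero mean
and covariate correlation). Shared variance is the first-eigenvalue share
of the correlation matrix (correlation, not covariance, because regions
differ in scale), reported with the mean ± SD of off-diagonal
correlations. ICC is the two-way random, absolute-agreement, single-measure
form ICC(2,1) from the mean-squares decomposition — the reliability form is
configurable in principle but this default matches interrater absolute
agreement; the unit tests cross-check it against an independent
implementation.

## Synthetic phantoms

The phantoms use analytic geometry — spheres for brain regions, a cylinder
along one axis for the sagittal sinus, cylinders for vessels — because the
ground truth must be exact; no anatomical realism is attempted.

**DCE phantom.** Per-region T1/M0/PS/v_p are constant; the default truth
spans PS ∈ [0.3, 1.0]·10⁻³ min⁻¹ and v_p ∈ [0.7, 1.9]% — the range of
published cohort means for elderly gray and white matter. The ground-truth
plasma input is a 1-minute box-car injection starting at 60 s convolved
with a bi-exponential washout (closed form), giving the broad low peak of
a slow injection without modelling arterial dispersion. Tissue curves
follow the forward Patlak equation with the VIF integral evaluated by
cumulative trapezoid *on the frame grid* — the same discretization the
fitter uses — so noiseless round trips are exact rather than limited by
quadrature error. Noise is Rician (Gaussian on two quadrature channels,
magnitude taken). "Curve SNR" in the Monte-Carlo studies means peak signal
enhancement divided by the channel SD; at SNR 30 this puts the
concentration-curve SNR near 30 as well. The protocol's true noise level
is not prescribed anywhere, so it is a free configuration parameter
(default 0).

**Flow phantom.** Tubes carry sinusoidal waveforms
q(t) = mean·(1 + PI/2·sin 2πt/T), whose amplitude/mean ratio equals the
target PI exactly. Velocity is parallel to the local axis with a parabolic
profile scaled so the cross-sectional integral equals q(t); the
velocity-encoding limit (110 cm/s) is enforced as an amplitude bound only
(no phase wrapping is simulated). The CD angiogram is *flat across each
lumen*, proportional to the tube's time-averaged mean cross-section speed:
real complex-difference contrast saturates across the lumen, and a
parabolic per-voxel-speed CD would make any FWHM lumen rule clip the
profile at r = R/√2 and lose ~25% of flow by construction. Defaults mirror
the reference cohort: large-artery PI 1.14, distal PI 0.99, venous PI 0.2,
total inflow 556 ml/min, 20 cardiac frames, 0.6875 mm isotropic voxels.

**Cohort generator.** Regional PS follows a one-factor model
PS_ij = μ_j + λ f_i + ε_ij with region means from the reference cohort
tables. The default loading/noise split (λ = 0.172, σ = 0.101 in
10⁻³ min⁻¹) is calibrated by the closed-form equicorrelation eigenvalue so
the population first-PC share is 0.76 (equivalently mean between-region
correlation ≈ 0.74) and the total per-region SD matches the published CI
widths. MoCA is linear in whole-brain mean PS (slope −2.9 per
10⁻³ min⁻¹, residual SD 2.1, intercept set so the cohort mean is 26.3).
Pulsatility, tCBF, age and sex are drawn independently of PS — the null
association is true by construction, which is what makes the calibration
tests (uniform p-values, nominal type-I error) meaningful.

## Problem sizes

Default validation sizes: 32³ DCE phantom with 3 regions + sinus and 60
frames; 44³ flow phantom with 8 tubes at 20 cardiac frames; 1000
Monte-Carlo replicates for Patlak accuracy; 10⁴ replicates for type-I
error; 400 replicates of n = 500 cohorts for CI coverage; 10⁴ subjects for
the ICC variance-component oracle. These sizes give Monte-Carlo standard
errors comfortably below the tolerances they are tested against.

## What the phantoms do not show

Passing the phantom suite demonstrates the *estimators* are correct, not
that real acquisitions satisfy their assumptions. Not emulated: k-space
acquisition and reconstruction artifacts, Gibbs ringing, subject motion
and co-registration error (all volumes are assumed aligned, guarded only
by a shape check), B1 estimation error (the true B1 map is supplied),
water-exchange effects, arterial dispersion of the input function,
non-uniform slab excitation (slab-edge regions can be excluded by
configuration instead), and contrast pharmacology beyond the forward
Patlak model. The Patlak model itself underestimates PS when leakage is
reversible — this misspecification is pinned by a regression test rather
than corrected. Hippocampal v_p age-decline on a relative scale is not
reproduced because its baseline convention is underdetermined.
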