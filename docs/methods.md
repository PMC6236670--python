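# Methods

`neuroquant` implements the quantification and statistics chain of a
longitudinal, multimodal small-animal brain imaging study: FDG-PET
standardized uptake values, diffusion-weighted ADC maps, FAIR arterial-spin-
labeling perfusion (K1) maps, atlas-based regional statistics with
hemispheric comparisons, and a mixed-effects model of the time trend. The
intended use case is hemispheric irradiation follow-up — one hemisphere
irradiated at 5 or 20 Gy, imaging at baseline and 3, 7, 30 and 60 days — but
nothing in the code is specific to that intervention.

## Signal models

**Diffusion.** The per-direction DWI signal is modelled as monoexponential,
S(b) = S0·exp(−b·ADC), over b ∈ {0, 100, 200, 400, 600, 800, 1000} s/mm² in
three orthogonal directions. The reported ADC map is the voxel-wise mean of
the three per-direction fits, which removes first-order direction dependence
without estimating a tensor. The default estimator is weighted log-linear
regression of ln S on b with weights ∝ S²; these weights make the linearized
fit agree with nonlinear least squares to first order in the noise, and the
solution is closed-form and exact at zero noise. A vectorized Gauss–Newton
nonlinear mode (`method="nls"`) is available and seeded by the log-linear
solution. Negative fitted ADCs are clamped to 0, values above 4×10⁻³ mm²/s
(above free water) clamped down, both flagged per voxel; voxels with any
non-positive sample are excluded from the output mask rather than fitted.

**Inversion recovery.** Each FAIR series (22 inversion times from 26 ms in
200 ms steps) is fitted voxel-wise with the three-parameter model
S(TI) = c + S0·(1 − 2·exp(−TI·R1)), separately for the slice-selective and
non-selective acquisitions. The fit uses variable projection: for any trial
T1 the model is linear in (c, S0), which are profiled out in closed form,
leaving a one-dimensional least-squares problem in T1. A 60-point
logarithmic grid over T1 ∈ [0.05, 10] s brackets the optimum per voxel and
a vectorized golden-section search (70 iterations on log T1) polishes it.
This returns the exact three-parameter least-squares minimizer
deterministically, with no per-voxel iteration or convergence failures;
residual sums are computed from explicit residuals to avoid cancellation
near perfect fits. Degenerate voxels — constant signal, so S0 ≈ 0 and T1
unidentified — are pinned to the lower bound and flagged `at_bounds`, as is
any voxel whose optimum lands on a bound; flagged voxels are dropped from
the T1/R1 map masks. Recovery curves are treated as signed (real-valued) by
default; `magnitude=True` enables magnitude data with polarity restoration
by exhaustive search over the early-TI sign-flip point.

**Perfusion.** The one-tissue-compartment uptake rate is computed from the
two fitted relaxation-rate maps as

    K1 = V_d · R1,a · (R1,s − R1,ns) / R1,ns

with V_d = 0.95 mL H₂O/mL and arterial T1 = 2 s (R1,a = 0.5 s⁻¹) as fixed
model constants. Under free transcapillary water exchange K1 equals cerebral
blood flow. The algebraic grouping lives in the single function
`k1_from_r1`, so the alternative reading K1 = V_d·(R1,s − R1,ns) can be
swapped in at one place if a different model convention is wanted. Negative
K1 voxels (noise pushing R1,s below R1,ns) are clamped to 0 and flagged.

**SUV.** SUV = A_conc / (A_inj / BW), with concentration in kBq/mL,
injected activity in MBq and body weight in g, giving g/mL. When the PET
sidecar records an injection-to-scan interval, the injected activity is
decay-corrected to scan start with the F-18 half-life (109.77 min); the
correction reference is scan start because the concentration is measured
then.

## Regional and hemispheric statistics

Regional means are taken over atlas-label voxels intersected with each
map's validity mask. Per-modality default region sets reflect what each
acquisition can support: the PET analysis uses thalamus, cortex,
hypothalamus, hippocampus, cerebellum, amygdala and striatum; the ADC
analysis swaps cerebellum (unreliable near the skull base due to shim/EPI
distortion) for the ventricles; the single-slice ASL acquisition covers
only cortex, hippocampus, hypothalamus and thalamus. All sets are
overridable.

The whole-hemisphere value is the *unweighted* mean of the regional means
(not voxel-weighted), and the hemispheric asymmetry is d = (L − R)/L,
referenced to the left (treated) hemisphere, reported per scan and also as
|d| in percent. Interhemispheric coupling is summarized as a region ×
region Pearson matrix: cell (i, j) correlates left-region-i with
right-region-j means pooled over all subjects and time points within one
dose group; cells with fewer than 3 complete pairs are NaN.

## Longitudinal model

The whole-brain value of subject i at time t is modelled as

    y_it = β0 + β_dose·1[dose=20] + β_t·t + β_t²·t² + u0_i + u1_i·t + ε_it

with subject-level random intercept and slope, estimated by REML. Time is
entered as days/60 so t ∈ [0, 1]; this keeps the quadratic term
well-conditioned, and coefficients are reported on both the scaled and the
per-day axes. Dose is a two-level indicator (with two levels, indicator and
continuous codings give the same fit). The quadratic and dose effects are
tested by Wald z-tests without small-sample correction; at 12 subjects the
test is expected to be only approximately calibrated, which the simulation
suite quantifies directly.

Estimation is delegated to statsmodels `MixedLM`, but the contract is the
likelihood, not the optimizer: `reml_loglike` evaluates the restricted
log-likelihood directly (per-subject V_i = Z_i G Z_iᵀ + σ²I, the standard
−½[Σ log|V_i| + log|ΣX_iᵀV_i⁻¹X_i| + rᵀV⁻¹r] − ½(n−p)log 2π) and the test
suite requires the fitted objective to match it to 10⁻⁶ relative. When the
random-slope covariance is singular or the optimizer fails, the model falls
back to a random intercept only (flagged `slope_dropped`); if no
between-subject structure is estimable at all, the zero-variance REML
solution (pooled OLS with residual variance on n−p degrees of freedom) is
returned. Optimizers are tried in a fixed order (L-BFGS, Powell,
Nelder–Mead), so the result is deterministic given the data.

## Synthetic phantom cohort

Because the underlying animal scans are not public, validation rests on a
digital phantom with known ground truth.

* **Geometry.** Eight named regions per hemisphere as ellipsoids on a
  regular 2×4 layout inside the left half of the grid, mirrored exactly
  across the mid-sagittal plane. Mirror symmetry is a construction
  guarantee, so the expected hemispheric difference is identically zero —
  any measured asymmetry is noise, which the hemispheric tests exploit. The
  default grid is 32×32×16 (≈250 voxels per region); 16 voxels per axis is
  the minimum that keeps every region above 50 voxels.
* **Signals.** Noiseless signals follow the fitting models exactly, so
  fit∘simulate is the identity at σ=0 — the basis of the exact-inversion
  tests. MRI magnitude noise is Rician (complex Gaussian channels of scale
  σ), PET concentration noise additive Gaussian; both are standard for
  magnitude MRI and reconstructed PET. Default S0 = 1000 with σ_MRI = 25
  (SNR 40, a typical preclinical EPI value and the level at which estimator
  calibration is tested); default PET noise σ = 20 kBq/mL, about 5% of a
  typical brain concentration at the default 5.05 MBq injected activity and
  20 g body weight.
* **Ground-truth values** are field-realistic for adult mouse brain at 7 T:
  gray-matter ADC 0.70–0.75×10⁻³ mm²/s (CSF 2.2×10⁻³), non-selective T1
  1.75–1.90 s (CSF 3.5 s), FDG SUV 1.3–1.8 (ventricles 0.4). The perfusion
  dial is the selective-vs-non-selective T1 difference (default 50 ms);
  true K1 is always *derived* from the T1 pair through the one-compartment
  formula, never set independently, so the generator cannot contradict the
  model it exercises.
* **Cohort.** The longitudinal generator draws y_it from exactly the mixed
  model above (2 doses × 6 subjects × 5 time points by default) and applies
  it as a common bilateral, multiplicative shift of the regional means —
  left and right hemispheres share the subject×time signal, which produces
  the strong interhemispheric correlations the correlation analysis is
  designed to display. β_dose defaults to 0 (no mean dose effect), the
  quadratic defaults describe a dip-and-recover trajectory; random-effect
  and residual SDs default to 0.03–0.05 on the relative scale.

What the phantom does *not* emulate: realistic anatomy, partial-volume
mixing at region borders, registration error, B0/B1 inhomogeneity, EPI
distortion, PET resolution/scatter, or physiological drift. Passing tests
therefore demonstrate correctness of the estimators and statistics under
the stated noise models, not robustness to those acquisition artifacts;
the cerebellum filter exists precisely because such artifacts are handled
by exclusion, not modelling.

## Numerical choices and edge cases

* T1 search bounds [0.05, 10] s; grid 60 points, golden section 70
  iterations (bracket ≪ 10⁻⁹ relative). ADC clamp range [0, 4×10⁻³] mm²/s.
* Foreground mask: reference signal (b=0 frame, or max |S| over TIs) above
  5% of its in-volume 99th percentile; all fitting masks only ever shrink.
* Series frames are re-sorted by acquisition value on load, making readers
  invariant to on-disk frame order.
* Ties/degeneracies: constant IR signal → T1 pinned at the lower bound and
  flagged; zero left-hemisphere mean → explicit error; correlation cells
  with < 3 pairs or zero variance → NaN.
* All times are seconds internally; TI sidecars are written in seconds.
* Per-scan RNG streams are spawned from one `SeedSequence`, so every
  simulated object is reproducible from a single integer seed.

## Problem sizes in the shipped checks

The test suite and the acceptance script size their simulations as: one
32×32×16 phantom (~4000 in-mask voxels) for exact inversion; 1200–2000
replicate voxels for SNR-40 estimator calibration against brute-force
oracles (per-replicate nonlinear fits for ADC, an exhaustive
17×41×201-point (c, S0, T1) lattice for inversion recovery); 100–200
simulated cohorts for REML bias and Wald type-I error; and one full
image-level 60-scan cohort for the end-to-end demonstration. These sizes
give Monte-Carlo standard errors a factor ≳3 below the effects being
checked while keeping a full run in the minutes range.

## Known limitations

* The Wald z-test on 12 subjects has no Kenward–Roger-type correction; its
  finite-sample size is only approximately nominal (the suite measures it).
* The ADC default estimator is the weighted log-linear fit; at very low SNR
  (≪ 20) its bias diverges from nonlinear least squares, and the `nls` mode
  should be preferred.
* Magnitude-mode IR fitting restores polarity per voxel by exhaustive
  flip-point search, which is robust but assumes a single zero crossing.
* The pipeline assumes pre-registered volumes sharing the atlas grid; no
  registration or resampling is performed.
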