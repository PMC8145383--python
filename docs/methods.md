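# Methods

## Kinetic model

The quantity modelled is the excess H₂¹⁷O concentration *M(t)* of a brain
voxel, in μmol per g of tissue above the natural-abundance baseline
D = 16.07 μmol/g. During inhalation of ¹⁷O-enriched O₂, labeled water is
produced locally by oxidative metabolism (two H₂¹⁷O per O₂, hence the
factor 2), lost from the voxel by perfusion at rate K_L, and gained by
recirculation of labeled water produced elsewhere in the body at rate K_G:

    dM/dt = 2·CMRO₂·A(t) − K_L·M(t) + K_G·B(t),   M(0) = 0.

The two inputs are not measured in an inhalation-only experiment and are
modelled with the simplest forms consistent with the physiology:

* **A(t)** — arterial ¹⁷O₂ enrichment: 0 during baseline, α during the
  inhalation window delayed by the circulation time T_c (blood saturation
  taken as 100%), 0 afterwards. With T_c = 0 and K_G = K_L = 0 this
  reduces exactly to the linear model, which anchors the form.
* **B(t)** — labeled body water: a linear ramp α·(t − t_start) (t in
  minutes) during the delayed window, then a constant plateau
  α·t_inhale(min). The body water pool is large compared to the 15-min
  washout, so depletion of the plateau is neglected. The unknown absolute
  scale of body production is deliberately absorbed into the fitted K_G;
  what matters is that B ∝ α.

Both inputs being proportional to α gives the α-scaling identity: the
curve depends on its parameters only through (α·CMRO₂, α·K_G, K_L).
Consequently, refitting any noiseless curve with an assumed enrichment
α′ = α/c returns exactly (c·CMRO₂, c·K_G, K_L). This identity is what the
acceptance script exercises.

The ODE is linear with piecewise-polynomial forcing and is solved in
closed form phase by phase. During the window (τ minutes since window
start, c = 2·CMRO₂·α, g = K_G·α):

    M(τ) = c·φ₁(τ) + g·φ₂(τ),   φ₁ = (1 − e^(−K_L τ))/K_L,  φ₂ = (τ − φ₁)/K_L,

computed with `expm1` for stability; for K_L below 10⁻¹⁰ min⁻¹ the exact
polynomial limit c·τ + g·τ²/2 is used instead of the 1/K_L forms. After
the window, M relaxes exponentially at rate K_L toward the recirculation
plateau K_G·α·t_inhale(min)/K_L. The solution is continuous at the phase
boundaries by construction and matches an adaptive Runge-Kutta integration
of the ODE to better than 10⁻⁶ relative error across the tested parameter
grid (K_L ∈ {0, 0.05, 0.39, 2} min⁻¹).

**Sampling convention.** Each 18.2-s frame is represented by the model
value at the frame midpoint t_k = (k + ½)·Δt, not the frame-averaged
value; at this frame rate the difference is far below the noise floor.

## Fitting

All fits act on excess (baseline-subtracted) concentration, use all frames
of the relevant phase, and are unweighted — there is no frame-dependent
noise model to justify weights.

* **Linear model**: OLS over frames whose midpoints lie in the nominal
  (undelayed) inhalation window; CMRO₂ = slope/(2α). On curves with
  K_L > 0 it is biased low, monotonically in K_L (verified by test).
* **Three-phase model**: bounded (≥ 0) trust-region least squares
  (`scipy.optimize.least_squares`, trf, tolerances 10⁻¹⁴) over all frames,
  with α and T_c fixed — they are assumptions, not identifiable from one
  voxel curve. Initialization: CMRO₂ from the linear fit, K_L from the
  washout fit, K_G = K_L; three multiplicatively jittered restarts
  (log-normal, SD 0.3, seeded) guard against local minima. Standard errors
  come from the Jacobian at the solution. An all-zero curve returns zeros
  with a degeneracy flag; non-convergence is flagged with the best-so-far
  parameters.
* **Washout model**: k₁·e^(−k_washout·t′) + k₂ with t′ minutes since the
  nominal end of inhalation, initialized at k₂ = mean of the last five
  frames, k₁ = first washout frame − k₂, k_washout = 0.3 min⁻¹. With
  K_G = 0 the three-phase washout is exactly mono-exponential and the fit
  recovers K_L; with recirculation, k₂ converges to the plateau
  K_G·α·t_inhale/K_L as the washout lengthens. A flat curve is flagged
  degenerate (k₁ ≈ 0 leaves k_washout unidentified). The conversion
  k_washout → absolute CBF uses the rat-calibrated factor 1.86 and is
  labelled as such; no calibration for mice is attempted.

T_c is never fitted. The "immediate availability" limit is represented by
T_c = 10⁻⁴ s in the model-comparison grid so that the same code path is
used for all cells.

## Preprocessing

* **Hamming filter**: separable 3D window w[m] = 0.54 + 0.46·cos(2π(m −
  N/2)/N) per axis, centered on the k-space origin at index N/2 and equal
  to 1 there (edge value 0.08), so the DC level — hence the baseline
  normalization — is untouched.
* **Reconstruction**: centered inverse FFT with the orthonormal
  convention (Parseval-exact before the magnitude is taken). Radial
  regridding is out of scope; the entry point is Cartesian complex
  k-space or magnitude images.
* **CSI spectra**: per-voxel exponential line broadening (default
  6000 Hz, against truncation ringing of the 1-ms FID), zero-fill to 256
  points, FFT, zero-order phasing to make the dominant peak absorptive
  (phase taken at the magnitude-spectrum maximum), and integration of the
  real part over 9 points centered on the peak. The 9-point rule is taken
  as operative for the integration width.
* **Concentration conversion**: total(t) = D·S(t)/mean(S over baseline
  frames); excess = total − D. The default baseline window is every frame
  fully inside the 5-min baseline (16 at 18.2 s). Any global coil/gain
  scale cancels. D = 16.07 μmol/g is the operative literature value of
  20.35 μmol/g-water × 0.79 g-water/g-tissue (the raw product, 16.0765,
  differs only in the rounding of the quoted factors).
* **ROI extraction**: unweighted per-frame mean over listed voxels,
  conventionally a 2×2×2 block of 8; adjacency is not enforced.

## Effective volume

The spatial response function (SRF) of the Fourier acquisition is the
transform of the k-space weighting w (apodization window × T2* readout
decay, with readout time mapped linearly to k-space radius as in a
center-out acquisition, default readout 0.88 ms). The effective volume
functional used is

    V_eff = (∫ SRF dV)² / ∫ SRF² dV

over one FOV period. For a trigonometric polynomial both integrals are
exact sums over the weights — V_eff = V_FOV·w(0)²/Σw² — and the
implementation uses that identity; the unit tests verify it against dense
zero-padded-FFT integration of the SRF. A uniform window with no decay
yields exactly the nominal voxel volume; apodization and T2* decay broaden
the PSF and so *increase* V_eff under this functional (Hamming 16³ @ 24 mm
gives 53.8 μL against the 3.375 μL nominal voxel). Published effective
volumes computed under other, unstated conventions can be smaller than the
nominal voxel; this functional is documented here precisely so that the
convention is explicit, and it is kept isolated in `compute_veff` so a
different functional can be swapped in.

## SNR metrics

SNR = (signal/SD(noise))/(V_eff·√(block_time·NR)) for an NR-averaged
image, and tSNR = (temporal mean/temporal SD)/(V_eff·√block_time) across
repetitions (SD with the n−1 denominator). The square root spans the
*total* acquisition time, which is what makes the printed units
min^−1/2·μL^−1 dimensionally consistent. "Signal" is a single pixel value;
the noise SD comes from an ROI outside the object.

## Synthetic data

The generator emulates the study conditions: 5 min baseline / 200 s
inhalation / 15 min washout sampled every 18.2 s (76 frames), α = 0.7,
T_c = 3 s, two groups of 4 animals. Group truths in the shipped preset are
the three-phase (T_c = 3 s) parameter sets of the control
(2.02/0.62/0.39) and transgenic (1.68/0.45/0.36) groups with the reported
between-subject spreads; per-subject parameters are drawn from normals
truncated at zero. Noise is additive gaussian on concentration with a
default per-frame SD of 0.5 μmol/g — the high-SNR magnitude regime; a
rician option exists for low-SNR work. The 0.5 μmol/g default was chosen
once so that (i) per-frame scatter is clearly visible on the ~7 μmol/g
inhalation rise, and (ii) n = 4 group-mean standard errors land at the
±0.07–0.10 μmol/g/min order reported for such cohorts; it is a study
condition, not a tuning knob.

What the generator does **not** emulate: radial spoke acquisition and
regridding artifacts, B0 inhomogeneity, motion, physiological drift,
partial-volume mixing at the brain boundary, or temporally correlated
noise. Passing tests therefore demonstrate correctness of the estimators
under the stated noise model, not robustness to every in-vivo confound.

## Statistics

Cohorts of n = 4 per group make asymptotic tests unreliable, so the exact
paths are primary:

* **Mann-Whitney U**: full enumeration of all C(n₁+n₂, n₁) labelings of
  the pooled mid-ranks for combined n ≤ 12; two-sided p = 2·min(tail
  probabilities) capped at 1 (matches common commercial software for
  untied small samples). Complete separation at 4 vs 4 gives p = 2/70 ≈
  0.029, the floor for that design. Larger samples fall back to the
  tie-corrected normal approximation, flagged `exact=False`.
* **Friedman**: within-subject mid-ranks; exact null distribution for
  k ≤ 4 conditions and n ≤ 6 subjects by convolving the per-subject
  rank-sum distribution over subjects (cost polynomial, not (k!)ⁿ);
  otherwise the χ² approximation. The exact path equals brute-force
  enumeration on 4×3 designs by test.
* **Dunn post hoc**: z = ΔR̄/√(k(k+1)/(6n)) with a Bonferroni-style
  multiplication by the family size. The family is a parameter (default
  all pairs) because published analyses often compare each model variant
  against a reference only; the pipeline uses "each cell vs the first".
* **Pearson correlation** via the t transform (scipy).

## Pipeline

`run_experiment` takes one config (YAML-loadable; `presets/paper.yaml` is
the shipped default design) and produces per-subject fits for every
(model, α, T_c) cell, group summaries, per-cell exact Mann-Whitney tests,
Friedman + Dunn across cells within the reference group, washout fits and
the CMRO₂–k_washout correlation, all written with a manifest (config hash,
seed, version). Every random draw descends from the single config seed, so
reruns are byte-identical.

## Problem sizes and known limitations

Tests and the acceptance script run at the study's native scale (76-frame
curves, 8-subject cohorts, 100-seed Monte-Carlo for the recovery check,
8³–32³ grids for image-domain tests); nothing is scaled up beyond it.
Limitations: the input forms A(t), B(t) are the minimal ones consistent
with the linear-model limit and α-proportionality — other literature forms
would change K_G's meaning but not the α-scaling law; T_c and α are
assumptions, and errors in them propagate multiplicatively into CMRO₂;
the V_eff functional is one documented convention among several; and the
washout CBF conversion factor is rat-calibrated.
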