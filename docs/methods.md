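# Methods

## Signal and tracer-kinetic model

The MR forward chain is the standard one for spoiled-gradient-echo DCE-MRI
at 7 T. The steady-state FLASH signal is

    S = M0 sin(α) (1 − E1) / (1 − E1 cos(α)),   E1 = exp(−TR/T1),

with echo-time decay absorbed into M0 (TE is fixed within each scan, so
T2* weighting is a constant factor that cancels in every ratio the
analysis forms). Pre-contrast T1 is estimated from 7 flip angles
(2, 3, 5, 7, 10, 13, 20°; TR = 20 ms). During the dynamic scan (α = 7°,
TR = 3 ms, 3.5 s temporal resolution, 257 frames = 15 min, bolus at
t0 = 120 s) the longitudinal rate follows the fast-exchange relaxivity
relation R1(t) = R1,pre + r1·C(t), r1 = 3.53 s⁻¹mM⁻¹ (Dotarem).

Tissue uptake follows the standard (two-parameter) Tofts–Kermode model
with a fixed bi-exponential population AIF (A1 = 5.36 mM, A2 = 1.27 mM,
τ1 = 5.36 s, τ2 = 915 s). The convolution has the closed form

    C(t) = Ktrans Σᵢ Aᵢ [e^(−(t−t0)/τᵢ) − e^(−kep(t−t0))] / (kep − 1/τᵢ),

with the analytic limit Aᵢ·Ktrans·(t−t0)·e^(−kep(t−t0)) taken when
|kep − 1/τᵢ| < 1e-8 s⁻¹, which avoids catastrophic cancellation at the
degenerate point. Internally all times are seconds and concentrations mM;
Ktrans is expressed in min⁻¹ at every public surface (field convention)
and divided by 60 inside the formulas.

Assumptions inherited from this model family: fast water exchange,
negligible plasma volume (standard, not extended, Tofts), a
population-fixed AIF with no per-subject bolus-arrival estimation, and
perfect spoiling.

## Parameter estimation

**T1/M0 (VFA).** A linearized DESPOT1 fit (S/sin α vs S/tan α) screens
voxels — a slope E1 outside (0, 1) or an all-zero voxel is flagged
invalid and carried as NaN, never as zero — and the surviving voxels are
refined by bounded nonlinear least squares of the SPGR model. M0 enters
the model linearly, so it is profiled out and the search runs over T1
alone: a 200-point log grid on [0.05, 10] s brackets the minimum, then
golden-section polish (60 iterations) localizes it; the profiled residual
is formed explicitly rather than via the expanded quadratic, keeping the
comparisons meaningful to machine precision. This makes the map fit fully
vectorized and exactly scale-equivariant. T1 bounds [0.05, 10] s exclude
non-tissue solutions.

**Concentration.** An effective M0 is calibrated per voxel from the mean
of all pre-injection frames together with the fitted R1,pre (maximizing
baseline SNR; any gain/TE difference between the VFA and dynamic scans
cancels). Each frame is inverted algebraically to R1(t); signals outside
the invertible range (0, M0 sin α) are carried as NaN and excluded from
downstream medians and SDs. The concentration is referenced to the
baseline rate recovered from the same calibration — algebraically R1,pre,
but bit-exact on the baseline frames, so noiseless pre-injection C(t) is
exactly zero and the zero-SD branch of the classifier behaves correctly.

**Enhancement rule.** A voxel is non-enhanced iff the median of C(t) at
t ≥ t0 is smaller than twice the sample (n−1) SD of the frames at t < t0.
The 5 s injection duration is ignored (the rule names only the injection
time). Degenerate zero baseline SD: non-enhanced iff the post-injection
median is ≤ 0. The SD is computed on concentration units.

**Tofts fit.** Bounded trust-region least squares (Ktrans ∈ [0, 5] min⁻¹,
ve ∈ [1e-3, 1]) against the closed-form curve, on enhanced & valid voxels
only; non-enhanced voxels carry NaN — undefined, deliberately distinct
from Ktrans = 0. The RSS surface is multimodal at low SNR, so
initialization is multi-start on the grid Ktrans ∈ {0.01, 0.1, 0.5} min⁻¹
× ve ∈ {0.1, 0.3, 0.6}: the RSS of all nine starts is evaluated in one
vectorized pass, the best two starts per curve are refined, and the lowest
final RSS wins with ties broken toward the smaller Ktrans (a Ktrans = 0
lower-bound candidate participates in the tie-break, which pins all-zero
curves to exactly zero). kep = Ktrans/ve is derived, never fitted.

**AUC.** Trapezoidal integral of C(t), by default from t0 to the end of
the scan (the acquisition window choice); window endpoints between frames
are handled by linear interpolation so the integral covers the exact
requested window.

## ROI conventions

The tumor mask is a manual-segmentation input. Muscle reference ROIs are
5×5 in-plane blocks in the four central tumor slices — operationalized as
the middle four of the tumor's slice extent, ties toward the smaller
index — each block the one nearest the light-beam axis whose one-pixel
padded bounding box is tumor-free; infeasible slices are skipped with a
warning. Ktrans means are taken over enhanced & converged voxels in both
compartments (the muscle convention mirrors the tumor one).

## Fluorescence and histology quantification

Integrated density over an ROI is corrected in the order dark current →
reference standard → autofluorescence: ID = Σ(pixel − dark), normalized
per 5000 µm², divided by the daily reference gain, then the
autofluorescence (on the same normalized scale) subtracted; negative
results clip to 0 with a flag. The exact arithmetic
(subtract-then-scale) is this package's documented choice; only the
correction order is prescribed by the workflow it implements.

Group values combine as inverse-variance weighted means
(w = 1/SD², wmean = Σwx/Σw). The reported spread is √(1/Σw) — the
uncertainty of the weighted mean — with a weighted sample SD available
behind `wsd_kind="sample"`, since "weighted mean ± SD" is ambiguous.
Zero SDs are capped at the smallest positive SD in the set to avoid
infinite weights. The tumor-to-normal ratio propagates uncertainty to
first order: σ_R = R·√((σ_T/T)² + (σ_N/N)²).

Colocalization is Spearman's rank correlation (average ranks for ties)
after per-channel dark-current subtraction, with no intensity threshold
applied; a constant channel yields NaN (missing), not an exception.

Histology: perfused ⇔ Hoechst ≥ threshold within the tumor mask. The
threshold is a required manual input (an Otsu helper exists but is never
applied automatically). Necrotic fraction and non-perfused fraction are
percentages of the tumor area; their overlap uses the necrotic area as
denominator (the share of necrosis that is non-perfused). Masks are
assumed pre-registered.

## The digital phantom

The phantom emulates the study geometry at desk scale: a 64×64×17 grid
(configurable) with an ellipsoidal tumor whose concentric core has
Ktrans = 0 — modelling the vascular shutdown the therapy produces — set
to 30% of the tumor volume by default, embedded in a muscle ring (2–8
voxels Chebyshev distance in-plane on every tumor-bearing slice, with a
one-voxel empty shell as segmentation margin). Rim Ktrans sweeps
0.05–1.0 min⁻¹ along x and ve 0.1–0.6 along y so that recovery is probed
across the physiological range rather than at one operating point; muscle
is uniform at Ktrans = 0.10 min⁻¹, ve = 0.15 (resting-muscle literature
values); T1 is 1.9 s (tumor) and 1.5 s (muscle), typical 7 T values;
M0 = 1000 in tissue. The DCE baseline is assumed at steady state from
frame 1 (no approach-to-steady-state transient).

Noise is Rician by default (magnitude MRI), with a Gaussian option for
linear-regime checks; `sigma_for_snr` defines SNR on the mean baseline
dynamic signal in the tumor. A single integer seed makes every simulated
series bit-reproducible.

What the phantom does **not** emulate: B1 inhomogeneity, motion, partial
volume, water-exchange effects, per-subject AIF variability, spatially
correlated noise, and k-space/Bloch-level acquisition effects. Passing
recovery tests therefore demonstrates correctness of the inversion chain
under the model's own assumptions, not robustness to these real-data
confounds. The two-channel microscopy generator likewise produces smooth
Gaussian-filtered textures with a tunable monotone-coupling fraction —
enough to probe rank-correlation behavior, not a cell-morphology model.

## Validation problem sizes

The validation suite runs the noiseless recovery chain on the full
64×64×17 phantom (~13k tissue voxels), the closed-form-vs-convolution
check on 100 random parameter draws at dt = 0.01 s, the SNR-20 Monte
Carlo on 500 replicate voxels plus the structured phantom, and the rule-
and statistics-fidelity checks on 1000 random curves / 50-pixel images —
sizes chosen so the whole suite completes in a few minutes on one CPU
while keeping every per-voxel tolerance meaningful.

## Known limitations

- The enhancement rule compares a median against a noise-derived
  threshold; at very low SNR (< ~10) the non-enhanced fraction becomes
  biased upward. The phantom's SNR-20 operating point matches routine
  preclinical DCE quality.
- The Tofts fit inherits the identifiability limits of the model: at
  Ktrans → 0 ve is undefined, and at kep approaching the frame rate the
  two parameters trade off; bounds and multi-start mitigate but cannot
  remove this.
- The muscle reference convention (enhanced-only voxels) slightly biases
  muscle Ktrans upward when muscle enhancement is marginal.
- `place_muscle_rois` assumes the tumor's slice extent is contiguous;
  pathological masks with gaps still use the extent's middle four slices.
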