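# pdtvasc

Quantification of the tumor **vascular response to targeted photodynamic
therapy (PDT)** from three complementary readouts:

1. **DCE-MRI pharmacokinetics** — variable-flip-angle (VFA) T1 mapping,
   conversion of the dynamic signal to gadolinium concentration,
   enhanced/non-enhanced pixel classification, and voxelwise
   **Tofts–Kermode** fitting of Ktrans and ve under a fixed bi-exponential
   population arterial input function (AIF);
2. **intravital fluorescence** — dark-current / reference-standard /
   autofluorescence-corrected integrated densities per 5000 µm²,
   tumor-to-normal ratios with error propagation, inverse-variance weighted
   means, and Spearman-rank colocalization of a probe with the tumor (GFP)
   channel;
3. **histology** — Hoechst-33342 threshold classification of perfused
   vs non-perfused tissue and necrotic/non-perfused fraction statistics.

Because animal image data of this kind are rarely deposited, the package
ships a **digital phantom** (`pdtvasc.phantom`) that pushes known T1, M0,
Ktrans and ve maps — including a non-enhancing tumor core that models
vascular shutdown after PDT — through the exact forward signal chain, so
the whole analysis is validated by parameter recovery rather than by
fixtures. It targets preclinical imaging scientists analysing
vascular-targeted therapies at 7 T.

## The model

Spoiled gradient echo (FLASH) steady-state signal:

    S = M0 · sin α · (1 − E1) / (1 − E1 · cos α),   E1 = exp(−TR/T1)

T1 is fitted voxelwise from 7 flip angles (2–20°, TR = 20 ms); during the
dynamic scan (α = 7°, TR = 3 ms, one frame / 3.5 s, 15 min) the same
equation is inverted per frame to R1(t), and the tracer concentration
follows from the relaxivity relation R1(t) = R1,pre + r1·C(t) with
r1 = 3.53 s⁻¹mM⁻¹ (Dotarem). Pixels are **non-enhanced** when the median
of C(t) after the injection time (t0 = 2 min) is below twice the baseline
SD. Enhanced pixels are fitted with the standard Tofts–Kermode model

    C(t) = Ktrans ∫₀ᵗ Cp(τ) e^(−kep (t−τ)) dτ,   kep = Ktrans / ve

under the population AIF
Cp(t) = A1·e^(−(t−t0)/τ1) + A2·e^(−(t−t0)/τ2) with A1 = 5.36 mM,
A2 = 1.27 mM, τ1 = 5.36 s, τ2 = 915 s, using the closed-form solution of
the convolution.

The two fitting stages are scikit-learn-style estimators
(`VfaT1Fitter`, `ToftsFitter`: `fit` on `(n_voxels, n_series)` arrays,
fitted attributes with trailing underscores), so they compose with sklearn
tooling; the module-level functions (`fit_t1_vfa`, `pk_map`, …) wrap them.

## Worked example

```python
import numpy as np
from pdtvasc import (ScanProtocol, AifParams, NoiseSpec, default_truth,
                     simulate_study, fit_t1_vfa, signal_to_concentration,
                     pk_map, place_muscle_rois, summarize_study)

protocol, aif = ScanProtocol(), AifParams()
truth = default_truth()                       # 64x64x17, 30% necrotic core
vfa, dce = simulate_study(truth, protocol, aif, NoiseSpec("rician", 1.07, 42))

r1map = fit_t1_vfa(vfa)                       # voxelwise VFA T1 fit
maps = signal_to_concentration(dce, r1map)    # C(t) + enhancement mask
fit = pk_map(maps, aif)                       # Tofts Ktrans/ve maps

rois = place_muscle_rois(truth.tumor_mask, beam_axis=(32.0, 25.0))
summary = summarize_study(fit, maps, rois)
print(f"non-enhanced tumor fraction: {summary.nonenhanced_fraction_tumor:.1f}%")
print(f"mean Ktrans (enhanced tumor): {summary.mean_ktrans_tumor_enhanced:.3f} /min")
print(f"mean Ktrans (muscle ROIs): {summary.mean_ktrans_muscle:.3f} /min")
```

prints (noise sigma 1.07 ≈ baseline SNR 20 in the tumor):

```
non-enhanced tumor fraction: 30.2%
mean Ktrans (enhanced tumor): 0.526 /min
mean Ktrans (muscle ROIs): 0.100 /min
```

The 30.2% equals the constructed non-perfused core fraction of this
phantom — every core voxel is flagged non-enhanced, no rim voxel is; the
enhanced-tumor mean matches the ground-truth rim mean (the rim sweeps
Ktrans over 0.05–1.0 /min), and the four 5×5 muscle reference blocks
recover the ground-truth muscle Ktrans of 0.10 /min.

The same pipeline runs from a shell:

```bash
pdtvasc run --config run.yaml        # or: pdtvasc phantom / t1fit / dce2conc /
                                     #     pkfit / summarize / ivm / histo ...
```

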