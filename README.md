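# mitoquant

Quantifying mitochondria in super-resolution time-lapse z-stacks without
photobleaching correction.

## The problem

Fluorescence time-lapse imaging bleaches the fluorophore: by the time a
small cell has gone from metaphase to post-cytokinesis, a mitochondrial
matrix marker imaged once a minute has lost ~20 % of its brightness
(≈ 1.75 %/min). Naively, any intensity-based measure of "how much
mitochondria" a cell has should drift with it — a serious problem for
asking whether organelle content is conserved across a cell division.

The workflow implemented here rests on a histogram observation: global
threshold-based segmentation (Isodata/Ridler–Calvard, ImageJ "Default",
Otsu, and commercial surface renderers built on the same family) computes
its cutoff from each stack's *own* grey-value histogram. Photobleaching is
essentially a multiplicative loss `I → s·I`, which rescales the histogram's
min–max range but leaves its image-specific (relative) frequency profile
unchanged. The threshold therefore scales as `t → s·t` and the set of
foreground voxels — the segmented quantity — is invariant:

```
threshold(s·I) = s · threshold(I)          (exact, no requantisation)
#{v : s·I(v) > threshold(s·I)} = #{v : I(v) > threshold(I)}
```

So raw integrated density decays with bleaching while globally-thresholded
object quantities do not, and no bleach correction is needed before
segmentation.

`mitoquant` is aimed at microscopists and image analysts who want to (a)
run this processing chain — per-slice rigid alignment with transform reuse
across channels, spectral bleedthrough subtraction, Richardson–Lucy
deconvolution with a theoretical PSF, global thresholding, 2D/3D object
quantification — and (b) verify the invariance claim on fully
ground-truthed synthetic data, since raw recordings of this kind are not
publicly deposited.

## What's in the box

| module | contents |
| --- | --- |
| `mitoquant.synthgen` | ground-truthed two-channel scene and timeseries simulator: capsule-shaped mitochondria in an ellipsoidal cell, membrane+chromatin channel, 8 % bleedthrough, linear bleaching with fluctuations, per-slice rigid jitter, PSF blur, shot/read noise, exact cargo-conserving division |
| `mitoquant.optics` | Snell's-law marginal-ray chain (depth-dependent focal shift), Rayleigh radii, scalar paraxial 3-D PSF, Gaussian effective PSF, apparent-size inflation |
| `mitoquant.preprocess` | slice-to-slice rigid registration (+ transform file I/O), bleedthrough subtraction, cropping, flux-conserving RL deconvolution |
| `mitoquant.segmentation` | Isodata / ImageJ-Default / Otsu global thresholds, surface-style chain with background elimination, ROI masking, 2D/3D quantification incl. sphericity |
| `mitoquant.histanalysis` | fixed vs relative 256-class histograms, log–log frequency regression with F-test against slope 1, area-under-curve differences, threshold class positions, threshold–bleach correlation |
| `mitoquant.tseries` | integrated-density traces, decay fitting with CIs, invariance statistics (Shapiro–Wilk-gated t/Wilcoxon, Kruskal–Wallis + BKY correction), threshold-algorithm comparison |
| `mitoquant.pipeline` | end-to-end simulated-division experiments and the invariance battery |
| `mitoquant.stackio` / `cli` | OME-TIFF in/out with TCZYX axis normalisation; `mitoquant` CLI (`simulate`, `preprocess`, `segment`, `hist`, `tseries`, `optics`, `run`) |

## Worked example

```python
import numpy as np
from mitoquant import optics, pipeline, tseries

# Optical geometry: how deep is the cell really?
geom = optics.refraction_chain(optics.OpticalGeometry(rounded=True))
print(f"theta={geom.theta}  theta_r={geom.theta_r}  LS={geom.ls:.3f} um")
print(f"Rayleigh 510nm: {optics.rayleigh_radius_px(510, 1.4, 42.5):.2f} px")

# One simulated division, full pipeline:
m = pipeline.run_division_replicate(seed=2)
print(f"fluorescence post/meta = {m.fluorescence_ratio:.3f}")
print(f"segmented quantity post/meta = {m.quantity_ratio:.3f}")
print(f"threshold post/meta = {m.threshold_ratio:.3f}")

# Photobleaching trace over a 13-frame multi-step series:
series = pipeline.bleach_trace_replicate(seed=2)
fit = tseries.fit_decay(series)
print(f"decay rate = {fit.rate_percent_per_min:.2f} %/min")
```

prints

```
theta=32.63  theta_r=36.81  LS=0.286 um
Rayleigh 510nm: 5.14 px
fluorescence post/meta = 0.764
segmented quantity post/meta = 1.008
threshold post/meta = 0.746
decay rate = 1.62 %/min
```

Read: the focus knob overestimates depth by ~0.29 µm at 2 µm (LS grows
linearly with depth). In this replicate the cell was simulated with
1.75 %/min bleaching plus ±5 % frame-to-frame fluctuations; by
post-cytokinesis the raw fluorescence has dropped to 0.76 of metaphase,
the Isodata threshold has dropped almost in proportion (0.746), and the
segmented mitochondrial quantity is unchanged (1.008 against a
ground-truth ratio of exactly 1.0). The fitted decay rate for this seed's
fluctuating trace is 1.62 %/min; across seeds the fits centre on the
programmed 1.75 %/min.

Across the default 20-replicate battery
(`pipeline.run_invariance_battery`, base seed 1), fluorescence ratios
average 0.78 ± 0.06 (significantly < 1), segmented quantity ratios
1.01 ± 0.10 (not significantly different from 1), two-step acquisition
ratios 0.98 (not significant), the fixed-mode log–log regression slope is
1.15 (significantly > 1) while the relative-mode slope is 1.00 (not
distinguishable from 1), and normalised thresholds correlate with
normalised fluorescence (Pearson r ≈ 0.7).

## CLI

```bash
mitoquant optics --rounded                 # geometry + Rayleigh report
mitoquant simulate --out scene.ome.tif --seed 1 --divide-at 6
mitoquant preprocess scene.ome.tif --out processed.ome.tif --subtract-fraction 0.12
mitoquant segment processed.ome.tif --algorithm isodata --mode 3d --out objects.csv
mitoquant hist processed.ome.tif --mode relative --out hist.csv
mitoquant run --outdir run1                # full simulate-and-analyse run
```

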