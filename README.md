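# condmotion

Quantitative image analysis for membrane-bound signaling condensates in
fluorescence time-lapse movies — built for TIRF data of LAT-scaffolded
condensates on supported lipid bilayers and LAT microclusters at the
immunological synapse, and for anyone asking how phase-separated clusters on a
membrane couple to actin networks.

The package implements, as tested and reusable stages:

* **Detection** — background-subtracted, noise-suppressed per-frame detection
  combining Otsu segmentation (bright, extended condensates) with strict
  local-maxima detection (dim, diffraction-limited ones; disc radius
  3·PSFσ = 222 nm = 1.4 px at 0.16 µm/px), including the peak/valley merge
  rule and seeded-watershed splitting for multi-peak regions, plus
  pixel-level cross-correlation drift correction.
* **Tracking & mobility** — assignment-based linking (search radius 5 px, gap
  closing ≤ 3 frames, merge/split annotations) and moment-scaling-spectrum
  (MSS) analysis: scaling exponents γ_ν of the displacement moments
  μ_ν(τ) = ⟨|Δx(τ)|^ν⟩, the MSS slope S (½ Brownian, →1 directed, →0
  confined) and the effective diffusion coefficient D₂ from μ₂ ≈ 4·D₂·τ^γ₂.
* **Actin enrichment** — mean actin intensity inside condensates over the mean
  outside, averaged over condensates.
* **STICS co-movement** — per-subregion (16×16 px window, 8 px step, temporal
  shift 3 frames) velocity vectors from windowed space–time correlation, and
  paired two-channel speed/angle statistics with a seeded randomization
  control and subsampled KS / rank-sum testing (500-point subsamples, 100
  repeats, mean p).
* **Synapse geometry & composition** — synapse/cSMAC segmentation, the
  normalized radial coordinate r (0 at the cSMAC center, 1 at the synapse
  edge), radial actin profiles, filament-speckle orientation fractions, and
  the full composition pipeline: aggregate-perimeter local background,
  first-three-frame normalization, four track-selection filters, 0.1-wide
  radial bins with median ± notch 95% CI, and rank-sum tests at the
  Bonferroni threshold (0.05/8 → 0.006).
* **Trajectory shape** — transition-point detection (distance/angle ratio,
  top-10% rule with top-25% fallback), cSMAC trimming, and endpoint-zeroed
  signed deviations from a straight path.
* **Binding math** — Hill fits I = I_max·c^n/(K_D^n + c^n) with seeded
  bootstrap CIs, and the co-sedimentation inversion
  K_D = A·(1−f)/f for fraction bound f at accessible F-actin A.
* **Synthetic data** — generators for every stage's input with exact ground
  truth (spot movies with drift and advected actin texture, motion-model
  tracks, synapse movies with known composition decay and photobleaching,
  binding curves, orientation speckles), used throughout the test suite.

## Worked example

```python
import numpy as np
from condmotion import synthio, trackmotion, binding

# 300 Brownian tracks at D = 1e-4 um^2/s, 60 frames, 15 s interval
tracks, truth = synthio.make_tracks(300, 60, "brownian", D=1e-4,
                                    frame_interval_s=15.0, seed=1)
results = [trackmotion.mss(t, frame_interval_s=15.0) for t in tracks]
D2 = np.median([r.D2_um2_s for r in results])
S = np.median([r.slope for r in results])
print(f"median D2 = {D2:.2e} um^2/s   median MSS slope = {S:.2f}")

# Hill fit of a noisy synthetic titration generated at K_D = 280 nM, n = 3.6
curve, _ = synthio.make_binding_curve(280.0, 3.6, 1.0,
                                      np.geomspace(20, 3000, 12),
                                      noise_sd=0.02, seed=1)
fit = binding.fit_hill(curve.concentration, curve.intensity, seed=1)
print(fit.summary())
print(f"cosed K_D: {binding.cosed_kd(0.24, 7.9):.2f} uM")
```

prints

```
median D2 = 1.00e-04 um^2/s   median MSS slope = 0.46
Hill fit: I = I_max * c^n / (K_D^n + c^n)
  K_D   = 281.2  95% CI [274.8, 289.9]
  n     = 3.51  95% CI [3.26, 3.8]
  I_max = 1.009
  residual norm = 0.04035  (bootstrap: 1000 residual resamples, seed 1)
cosed K_D: 25.02 uM
```

The median D₂ recovers the simulated diffusion coefficient; the MSS slope sits
at the Brownian value ½ (slightly low on finite tracks, see
`docs/methods.md`); the Hill fit recovers the generating K_D and cooperativity
within its bootstrap CIs; and 24% of protein bound at 7.9 µM accessible
F-actin inverts to a solution K_D of ≈ 25 µM.

A command-line interface mirrors the library:

```bash
condmotion synth --kind synapse --out-prefix demo --n-frames 40 --seed 1
condmotion detect demo_master.tif --out detections.csv
condmotion track detections.csv --out tracks.csv
condmotion motion tracks.csv --out mobility.csv
condmotion bonferroni --m 8
```

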