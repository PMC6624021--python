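# Methods

`condmotion` quantifies how membrane-bound signaling condensates (LAT-scaffolded
clusters on supported lipid bilayers, and LAT microclusters at the immunological
synapse) move, engage actin networks, and change composition as they travel.
Every stage is validated against synthetic movies with known ground truth; this
note records the models, the parameter choices and their rationale, the
numerical decisions, and what the synthetic validation does and does not show.

## Coordinates and units

Positions are (x, y) with row = y, column = x, 0-based, pixel centers on integer
coordinates. Physical scale attaches to the `ImageStack`: `pixel_size_um`
(default 0.16 µm/px, i.e. 16 px = 2.56 µm) and `frame_interval_s` (default 15 s
for steady-state in-vitro movies; 5 s is typical for contraction and live-cell
movies). Camera background is a single scalar per movie, subtracted on load and
clamped at zero.

## Detection (`detect`)

Per frame: the inhomogeneous background is estimated by a Gaussian blur
(σ = 10 px), subtracted, and the residual clamped at zero; noise is suppressed
with a σ = 1 px blur. Two detectors then combine:

* **Otsu segmentation** finds bright, extended condensates;
* **strict 8-neighbor local maxima** find dim, diffraction-limited ones.

Three scenarios follow. (1) A segmented region with one maximum is one
condensate. (2) A maximum outside any region becomes a disc of radius
3·PSFσ (PSF σ = 74 nm = 0.46 px at 0.16 µm/px, disc radius 222 nm = 1.4 px),
centered on a fixed-σ 2-D Gaussian least-squares fit. (3) A region with
several maxima is resolved by the peak/valley rule: for each pair of maxima,
the mean of their peaks divided by the minimum bilinear intensity on the
straight line between them is compared with the 1st percentile (linear
interpolation between order statistics) of the peak/edge-minimum ratio
distribution of isolated scenario-1 condensates; under-threshold pairs merge by
discarding the dimmer maximum (ascending-ratio order, recomputed after each
discard); the survivors seed a watershed restricted to the region.

Numerical choices that the method description leaves open:

* **Maxima significance.** A maximum (or a segmented region's peak) must
  exceed `median + k·MAD·1.4826` of the *unclamped* smoothed residual,
  `k = 5` by default. The scale is robust to the sparse bright spots, and the
  unclamped residual avoids the halved noise distribution the zero-clamp
  produces. `k = 5` rather than 3 because the test is applied at every pixel
  of the frame: at k = 3 a 128×128 frame is guaranteed several false maxima.
  Otsu regions must clear the same level — Otsu will happily "segment" pure
  noise.
* **Sub-pixel centers.** Segmented condensates use the centroid weighted by
  intensity *above the Otsu threshold*, so dim attached pixels do not drag the
  center at low SNR; diffraction-limited ones use the fixed-σ Gaussian fit.
* **Live-cell detection.** `detect_stack_maxima` applies maxima-only detection
  (all detections treated as diffraction-limited discs); thresholding lacks
  sensitivity for dim cellular microclusters, and the background-subtraction
  residual rim at the synapse edge would otherwise be segmented as an object.

Validated behavior: recall and precision 1.0 at SNR 10 (amplitude = 10× noise
SD, separation ≥ 8 px), exact translation equivariance on noiseless frames,
centers within 0.5 px of ground truth. At SNR 5 detection is still complete but
centroids wander 1–3 px; localization accuracy, not detection, is the limiting
factor there.

## Drift correction

Adjacent raw frames are aligned by the integer offset (within ±10 px)
maximizing their Pearson correlation on the overlap; ties break toward the
smaller shift; offsets accumulate along the movie and the same series applies
to companion channels. Imposed integer drift on synthetic movies is inverted
exactly. All-constant movies return zero shifts with a warning.

## Tracking and mobility (`trackmotion`)

Frame-to-frame linking solves a linear assignment problem (augmented square
cost matrix; alternative cost = search radius², links beyond 5 px forbidden).
Track ends re-join later track starts when the start is ≤ 3 frames after the
end (at least one missing frame) and within the search radius, solved as a
second assignment on squared distances. Merge/split events are annotated only
(an unlinked end/start adjacent to a continuing track) and never alter
positions.

**Moment scaling spectrum.** For lags τ up to ¼ of the track duration (lags
with < 5 displacement samples dropped, the two shortest always kept), the
moments μ_ν(τ) = ⟨|displacement(τ)|^ν⟩, ν = 0..6, give scaling exponents γ_ν
from log–log fits. The MSS slope S is the least-squares slope of γ_ν vs ν
fitted *through the origin* (γ₀ = 0 by construction): a free intercept
inherits the downward Jensen bias of high-order log-moments and biases the
median S on finite Brownian tracks below the theoretical ½. The effective
diffusion coefficient D₂ uses μ₂ ≈ 4·D₂·τ^γ₂ with the fitted line evaluated
*at the shortest lag* — extrapolating the intercept to τ = 1 s inflates the
median ≈ 12% on 60-frame tracks via the slope–intercept correlation, while the
shortest-lag evaluation is accurate to ~2%. On 500 simulated Brownian tracks
(D = 10⁻⁴ µm²/s, Δt = 15 s, 60 frames): median D₂ within 2% of truth, median S
≈ 0.46–0.47; directed tracks give S = 1 and immobile tracks D₂ = 0 exactly.

Track-shape anisotropy is √(λ₁/λ₂) of the position scatter matrix; exactly
collinear tracks report a large sentinel (1e9).

## Actin enrichment (`enrich`)

Per movie (last frame by default): mean background-subtracted actin intensity
inside each condensate mask divided by the mean over all non-condensate pixels,
averaged over condensates. No guard zone is excluded by default (an optional
dilation-exclusion parameter exists for robustness studies). The ratio is
invariant to multiplicative gain only when camera background is removed first —
both behaviors are tested.

## Velocimetry and co-movement (`stics`)

One displacement vector per 16×16 px subregion (8 px step) per analysis
interval. The immobile component is removed by subtracting each pixel's
temporal mean over the interval. For every frame pair (t, t+3), the early
window is compared with displaced copies of the late window at every integer
offset within ±window/4 using normalized (Pearson) correlation, and the
surfaces are averaged over pairs. Sub-pixel refinement maximizes the
interpolated correlation with a coordinate-symmetric pattern search (step
halving from 0.5 px to 10⁻³ px), which makes the recovered field *exactly*
equivariant under 90° rotations of the movie. Frequency-domain correlation of
tapered patches was tried first and rejected: the taper biases the peak toward
zero offset and asymmetric texture autocorrelation biases parabolic
interpolation by up to several pixels.

A vector is valid when (i) its peak correlation exceeds 0.2, (ii) the peak
prominence over the surface's median exceeds 5× the surface's pixel-scale
roughness (1.4826·MAD of first differences — a global MAD is dominated by the
surface's genuine smooth structure), and (iii) the speed exceeds
0.01 px/frame. Uniform 1 px/frame translation is recovered as (3, 0) px at
shift 3 in every interior subregion with error < 0.1 px; radial contraction
vectors point within 10° of the true inward direction beyond 1.5 window-widths
from the aster; static or pure-noise movies yield no valid vectors.

Co-movement pairs speeds and inter-channel angles (degrees, [0, 180]) at
co-valid subregions; the randomized control permutes channel-A vectors across
co-valid positions with a seeded generator. Large-sample distribution
comparisons use the subsampled convention: if either sample exceeds 1000
points, 100 repeats of 500-point subsamples are tested (two-sample KS or
Wilcoxon rank-sum) and the mean p-value is reported.

## Synapse geometry (`synapse`)

Synapse: Gaussian smooth (σ = 2 px), 2-level Otsu, keep the thresholded object
containing (else nearest to) the frame center, fill holes. cSMAC: 3-level
multi-Otsu of the master channel; the largest top-tier region inside the
synapse is the cSMAC *if* it covers < 50% of the synapse and its median
smoothed intensity is ≥ 1.4× the rest of the synapse — without a cSMAC, the
top tier of a 3-level threshold is just the synapse plateau. Frames before the
cSMAC forms use the cSMAC center of the time-averaged movie and area 0.

The normalized radial position r of a point is its distance to the cSMAC
center divided by the center-to-edge distance along the same ray; the edge is
found by marching the ray in 0.25-px steps until it exits the mask. r is scale
invariant and matches the analytic value on circular geometry to 0.01. Points
outside the synapse clamp to r = 1 with a flag (standing in for the published
workflow's manual refinement). Radial actin profiles take 8 rays 45° apart,
bilinear interpolation, per-ray argmax r; flat rays are excluded; the pooled
median peak position on an annulus-at-0.6 phantom is 0.60 ± 0.01, and it
defines the position threshold used by the composition filters.

Filament speckles are classified per 0.1-wide radial bin as perpendicular when
the acute angle between the filament orientation and the local boundary
tangent (5-point central difference on the marching-squares contour) exceeds
45°; a flag rotates dipole-reported orientations by 90° first. Empty bins are
reported as missing.

## Composition analysis (`compo`)

Protein content of a condensate = mean intensity inside its mask minus the
local background, where the background mean and SD come from a 2-px ring
around the condensate's *aggregate* (proximity-connected group: masks dilated
by 2 px touch), the ring excluding all condensate pixels. Measurements are
restricted to the synapse footprint eroded by 3 px and excluding the cSMAC
dilated by 3 px: the smoothed intensity falloff at either boundary would
otherwise leak into the ring and bias the two channels differently (their
background levels differ). A mask that loses more than half its pixels to this
restriction is flagged missing rather than measured from a dim crescent.

Track selection applies four filters in order, with per-filter rejection
counts: (1) duration ≥ 5 frames; (2) scatter anisotropy ≥ 3 (default;
config-exposed — "approximately linear" has no published cutoff); (3) start at
r > 0.6 and end at r < 0.6 (the actin-peak position threshold); (4) mean slave
content over the first three time points greater than the mean background SD
over those points.

Per time point, slave and master contents are each normalized by their own
first-three-frame mean and their ratio pooled by that frame's r into 0.1-wide
bins (outermost bin [0.9, 1.0] closed, others half-open, down to 0.2). Ratio
points with non-positive master content are excluded (the ratio is undefined
there). Bins with n < 10 are suppressed. Each bin is compared with a reference
bin by a two-sided Wilcoxon rank-sum test at the Bonferroni threshold
α_total/m (m = comparisons actually performed; 0.05/8 = 0.00625, displayed
0.006). The notch 95% CI of the median is median ± 1.57·IQR/√n. The reference
bin defaults to 0.9–1.0; when that bin is sparsely populated the 0.8–0.9 bin
is the appropriate reference, and `composition_profile_pooled` pools several
movies (cells) into one profile first. The ratio is computed per time point
and then pooled (not pooled per channel and then divided), which makes it
exactly invariant to per-track multiplicative gain in either channel.

On pooled synthetic movies with a known step decay g(r) = 1 above r = 0.6 and
0.5 below, the binned medians match g within a few percent and rank-sum
significance appears exactly from the 0.5–0.6 bin; with g ≡ 1 no bin is
significant at the Bonferroni threshold.

The photobleaching control is the per-frame mean intensity inside the synapse
but outside the cSMAC and all detected condensates, normalized to frame 0; an
imposed channel-wide exp(−k·t) bleach is recovered to the third decimal in k.

## Trajectory shape (`trajshape`)

The edge-hugging prefix of a track is removed at the transition point: per
interior time point, R(t) = |Δ distance to cSMAC center| / max(turn angle,
10⁻³ rad); the transition is the first point with R at or above the within-
track 90th percentile, falling back to the 75th percentile when that point is
already inside the actin position threshold (the returned r is reported for
audit, not enforced). The suffix after the condensate first enters the cSMAC
mask is trimmed. The remaining segment is rigidly rotated/translated so its
endpoints lie on the x-axis; the y-coordinates are the signed deviations from
the straight path, sign-flipped so positive deviations are the majority (ties
broken toward the larger positive sum; counts ignore float-level dust at
zero). Deviations are invariant to rigid motions of the input; a semicircular
arc's maximum deviation equals its radius exactly. Note that endpoint
anchoring inflates the deviation variance by 1 + (1−t)² + t² along the
segment, so the raw deviation SD overestimates isotropic positional noise by
15–30% unless standardized by that factor.

## Binding math (`binding`)

The Hill model I = I_max·c^n/(K_D^n + c^n) is fitted by bounded least squares
(initialization: I_max₀ = max intensity, K_D₀ = concentration at half-max by
interpolation, n₀ = 2). 95% CIs come from a seeded residual-resampling
bootstrap (percentile method); residuals are centered and inflated by
√(n/(n−3)) so the CIs are near-nominal at titration-sized n (coverage ≈ 93%
over 150 replicates at 5% noise; raw residual resampling undercovers at ~84%).
Noiseless curves at (K_D, n) = (280 nM, 3.6) and (410 nM, 3.2) are recovered
to 0.1%.

The co-sedimentation inversion uses f = K_A·A/(1 + K_A·A) for fraction bound f
at accessible F-actin concentration A, so K_D = 1/K_A = A·(1−f)/f; with
f = 0.24 and A = 7.9 µM this gives 25.02 ≈ 25 µM. `bonferroni(α, m)` returns
α/m with a 3-decimal display helper.

## Synthetic data (`synthio`) — what it emulates, and what it does not

* **In-vitro movies**: integrated-Gaussian spots (exact per-pixel erf
  integration; default σ 0.46 px) or PSF-blurred discs over a smooth
  inhomogeneous background, plus a filamentous texture of random anti-aliased
  line segments (short and sparse, giving the narrow autocorrelation that
  correlation velocimetry needs) advected *exactly* by a uniform or
  radially-contracting velocity field via backward mapping, with optional
  integer stage drift applied to both channels and additive Gaussian noise.
* **Tracks**: Brownian steps with per-axis variance 2·D·Δt, optionally with a
  constant drift velocity (directed), radial reflection at a circular boundary
  (confined), or frozen (immobile).
* **Synapse movies**: a smoothed synapse disc (level 60) with a brighter
  central cSMAC (+90), condensates born near the edge (r ≈ 0.88–0.97) at
  staggered times that move inward over 18–28 frames to r ≈ 0.25–0.45 and then
  dissolve (coalescence into the cSMAC); the slave channel scales each
  condensate by g(r) and the whole channel by exp(−k·t). Staggered births and
  finite lifetimes keep condensate crowding near the center realistic —
  synchronized convergence doubles measured contents through overlapping
  tails. Default noise SD 4 against spot amplitude 150 gives content
  measurements at roughly 5% relative noise.
* **Binding curves and speckles**: Hill-shaped titrations with additive noise;
  filament-orientation point sets with orientations drawn from a rule of r
  relative to the local edge tangent.

All generators are seed-deterministic and, at zero noise, exact functions of
their spec. They do **not** model: photon (Poisson) statistics beyond an
additive Gaussian, camera gain or fixed-pattern artifacts, condensate fusion
and wetting-driven elongation along filaments, polymer mechanics of the actin
network, or non-circular synapse shapes. Passing tests therefore demonstrate
the correctness of the measurement pipeline under its stated statistical
assumptions, not robustness to every real-microscope artifact — in particular,
the composition-profile accuracy shown here assumes detection-quality masks
and local backgrounds that vary smoothly on the scale of the background ring.

## Problem sizes

Validation uses 128 px in-vitro frames (18 frames for velocimetry), 500×60
Brownian tracks for the MSS, three 60-frame synapse movies of 25 tracks each
(pooled) for the composition profile, and 12-point titrations for the binding
fits. These sizes hold every pipeline estimate at its asymptotic value to
within the tolerances quoted above while keeping a full validation run in a
few minutes on one core.
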