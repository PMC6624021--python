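"""Synapse and cSMAC segmentation, the normalized radial coordinate, radial
actin profiles, and filament-speckle orientation classification.

The normalized radial position r of a point is the distance from the cSMAC
center to the point divided by the distance from the cSMAC center to the
synapse edge along the same ray: r = 0 at the cSMAC center, 1 at the edge.
It is unitless, so measurements pool across cells of different sizes and
non-circular synapses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.measure import find_contours, label as sk_label

from .stackio import ImageStack

__all__ = [
    "SynapseGeometry",
    "segment_geometry",
    "normalized_radial_position",
    "radial_profiles",
    "speckle_orientation_fractions",
]

RAY_STEP_PX = 0.25


@dataclass
class SynapseGeometry:
    """Per-frame synapse mask, cSMAC mask (may be empty before the cSMAC
    forms), cSMAC center (x, y) and boundary contour."""

    synapse_masks: list[np.ndarray]
    csmac_masks: list[np.ndarray]
    csmac_centers: list[tuple[float, float]]
    contours: list[np.ndarray] = field(default_factory=list)  # (n, 2) of (y, x)

    @property
    def n_frames(self) -> int:
        return len(self.synapse_masks)

    def csmac_area(self, frame: int) -> int:
        return int(self.csmac_masks[frame].sum())


def _largest_central_object(mask: np.ndarray) -> np.ndarray:
    """Largest connected component among those containing the frame center,
    else the component nearest to it."""
    lab = sk_label(mask, connectivity=2)
    if lab.max() == 0:
        raise ValueError("no thresholded object found")
    h, w = mask.shape
    cy, cx = h // 2, w // 2
    center_lab = lab[cy, cx]
    if center_lab > 0:
        candidates = [center_lab]
    else:
        candidates = list(range(1, lab.max() + 1))
    if len(candidates) > 1:
        # nearest component to the frame center, largest among ties
        best, best_key = None, None
        for c in candidates:
            ys, xs = np.nonzero(lab == c)
            d = np.hypot(ys - cy, xs - cx).min()
            key = (d, -len(ys))
            if best_key is None or key < best_key:
                best, best_key = c, key
        candidates = [best]
    return lab == candidates[0]


def _segment_frame(master_sm: np.ndarray, synapse_sm: np.ndarray,
                   csmac_contrast_min: float = 1.4) -> tuple[np.ndarray, np.ndarray]:
    """(synapse mask, candidate cSMAC mask) from smoothed images.

    A cSMAC candidate counts as formed only when it is genuinely brighter
    than the rest of the synapse (median contrast ≥ ``csmac_contrast_min``):
    a 3-level threshold of a synapse without a cSMAC otherwise just splits
    the synapse plateau in half.
    """
    if synapse_sm.max() == synapse_sm.min():
        raise ValueError("uniform frame: no object to segment")
    thr = threshold_otsu(synapse_sm, nbins=256)
    synapse = _largest_central_object(synapse_sm > thr)
    synapse = ndimage.binary_fill_holes(synapse)

    thr2 = threshold_multiotsu(master_sm, classes=3, nbins=256)
    top = (master_sm > thr2[1]) & synapse
    lab = sk_label(top, connectivity=2)
    if lab.max() == 0:
        return synapse, np.zeros_like(synapse)
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, range(1, lab.max() + 1))
    csmac = lab == (int(np.argmax(sizes)) + 1)
    # a cSMAC is a compact bright feature, not most of the synapse: without
    # one, the top tier of a 3-level threshold is just the synapse plateau
    if csmac.sum() > 0.5 * synapse.sum():
        return synapse, np.zeros_like(synapse)
    rest = synapse & ~csmac
    if rest.any():
        contrast = np.median(master_sm[csmac]) / max(np.median(master_sm[rest]), 1e-12)
        if contrast < csmac_contrast_min:
            return synapse, np.zeros_like(synapse)
    return synapse, csmac


def segment_geometry(
    master: ImageStack,
    actin: ImageStack | None = None,
    smooth_sigma_px: float = 2.0,
    min_csmac_area_px: int = 10,
) -> SynapseGeometry:
    """Segment the synapse (2-level Otsu on the actin channel when available,
    else the master channel) and the cSMAC (largest highest-tier region of a
    3-level multi-Otsu of the master channel, inside the synapse).

    Frames where the cSMAC has not yet formed (largest candidate below
    ``min_csmac_area_px``) get an empty cSMAC mask and, as center, the cSMAC
    center of the time-averaged movie.
    """
    syn_stack = actin if actin is not None else master
    synapse_masks, csmac_masks, centers, contours = [], [], [], []
    pending: list[int] = []
    for t in range(master.n_frames):
        m_sm = ndimage.gaussian_filter(master.frames[t].astype(float), smooth_sigma_px)
        s_sm = ndimage.gaussian_filter(syn_stack.frames[t].astype(float), smooth_sigma_px)
        synapse, csmac = _segment_frame(m_sm, s_sm)
        if csmac.sum() < min_csmac_area_px:
            csmac = np.zeros_like(csmac)
            centers.append(None)
            pending.append(t)
        else:
            ys, xs = np.nonzero(csmac)
            centers.append((float(xs.mean()), float(ys.mean())))
        synapse_masks.append(synapse)
        csmac_masks.append(csmac)
        cont = find_contours(synapse.astype(float), 0.5)
        contours.append(max(cont, key=len) if cont else np.empty((0, 2)))

    if pending:
        avg_m = ndimage.gaussian_filter(
            master.frames.mean(axis=0).astype(float), smooth_sigma_px)
        avg_s = ndimage.gaussian_filter(
            syn_stack.frames.mean(axis=0).astype(float), smooth_sigma_px)
        syn_avg, csmac_avg = _segment_frame(avg_m, avg_s)
        if not csmac_avg.any():
            raise ValueError("cSMAC not found in any frame nor in the time average")
        ys, xs = np.nonzero(csmac_avg)
        fallback = (float(xs.mean()), float(ys.mean()))
        for t in pending:
            centers[t] = fallback

    return SynapseGeometry(synapse_masks, csmac_masks, centers, contours)


def _mask_value(mask: np.ndarray, y: float, x: float) -> bool:
    yi, xi = int(round(y)), int(round(x))
    if yi < 0 or xi < 0 or yi >= mask.shape[0] or xi >= mask.shape[1]:
        return False
    return bool(mask[yi, xi])


def _ray_edge_distance(mask: np.ndarray, center: tuple[float, float],
                       through: tuple[float, float]) -> float:
    """Distance from center to the synapse edge along the ray through a point.

    Marches outward in 0.25-px steps; the edge is the last in-mask position.
    """
    cx, cy = center
    px, py = through
    d = math.hypot(px - cx, py - cy)
    if d == 0:
        raise ValueError("ray direction undefined at the center")
    ux, uy = (px - cx) / d, (py - cy) / d
    if not _mask_value(mask, cy, cx):
        raise ValueError("center lies outside the synapse mask")
    t = 0.0
    limit = math.hypot(*mask.shape) + 1
    last_inside = 0.0
    while t <= limit:
        t += RAY_STEP_PX
        if _mask_value(mask, cy + uy * t, cx + ux * t):
            last_inside = t
        else:
            break
    if last_inside == 0.0:
        raise ValueError("ray exits the mask immediately; degenerate geometry")
    return last_inside


def normalized_radial_position(
    point: tuple[float, float],
    geom: SynapseGeometry,
    frame: int,
) -> tuple[float, bool]:
    """Normalized radial position r ∈ [0, 1] of an (x, y) point.

    Returns (r, outside_flag): points outside the synapse mask are clamped to
    r = 1 and flagged. The center itself maps to r = 0.
    """
    cx, cy = geom.csmac_centers[frame]
    px, py = point
    dist = math.hypot(px - cx, py - cy)
    if dist == 0:
        return 0.0, False
    mask = geom.synapse_masks[frame]
    edge = _ray_edge_distance(mask, (cx, cy), (px, py))
    outside = not _mask_value(mask, py, px)
    r = dist / edge
    if r > 1.0:
        return 1.0, True
    return r, outside


def radial_profiles(
    actin_frame: np.ndarray,
    geom: SynapseGeometry,
    frame: int = 0,
    n_lines: int = 8,
    n_samples: int = 200,
    flat_tol: float = 1e-9,
) -> tuple[pd.DataFrame, list[float]]:
    """Intensity profiles along ``n_lines`` rays (45° apart for the default 8)
    from the cSMAC center to the synapse edge.

    Returns (long-form profile table with columns line, r, intensity; list of
    per-line argmax r). Lines with flat intensity (max − min ≤ ``flat_tol``
    relative to max) are excluded from the peak list. The pooled median of
    peak positions over lines/frames/cells is the actin position threshold.
    """
    cx, cy = geom.csmac_centers[frame]
    mask = geom.synapse_masks[frame]
    if not mask.any():
        raise ValueError("degenerate geometry: empty synapse mask")
    img = np.asarray(actin_frame, float)
    rows, peaks = [], []
    rs = np.linspace(0.0, 1.0, n_samples)
    for k in range(n_lines):
        theta = 2 * math.pi * k / n_lines
        ux, uy = math.cos(theta), math.sin(theta)
        probe = (cx + ux, cy + uy)
        try:
            edge = _ray_edge_distance(mask, (cx, cy), probe)
        except ValueError:
            continue
        xs = cx + ux * rs * edge
        ys = cy + uy * rs * edge
        vals = ndimage.map_coordinates(img, [ys, xs], order=1, mode="nearest")
        for r, v in zip(rs, vals):
            rows.append({"line": k, "r": float(r), "intensity": float(v)})
        if vals.max() - vals.min() > flat_tol * max(abs(vals.max()), 1.0):
            peaks.append(float(rs[int(np.argmax(vals))]))
    return pd.DataFrame(rows), peaks


def _contour_tangent(contour: np.ndarray, point_yx: tuple[float, float],
                     window: int = 2) -> float:
    """Tangent angle (degrees, mod 180) of the boundary contour at the contour
    point nearest to ``point_yx``, from a 5-point central difference."""
    if len(contour) < 2 * window + 1:
        raise ValueError("contour too short for tangent estimation")
    d = np.hypot(contour[:, 0] - point_yx[0], contour[:, 1] - point_yx[1])
    i = int(np.argmin(d))
    n = len(contour)
    a = contour[(i - window) % n]
    b = contour[(i + window) % n]
    return math.degrees(math.atan2(b[0] - a[0], b[1] - a[1])) % 180.0


def speckle_orientation_fractions(
    speckles,
    geom: SynapseGeometry,
    frame: int = 0,
    bin_width: float = 0.1,
    orientations_are_dipole: bool = False,
) -> pd.DataFrame:
    """Fraction of filaments perpendicular (±45°) to the synapse edge per
    radial bin.

    ``speckles`` is a record array / DataFrame with fields x, y,
    orientation_deg. A speckle counts as perpendicular when the acute angle
    between its filament orientation and the local edge tangent exceeds 45°.
    With ``orientations_are_dipole=True`` inputs are fluorescence-dipole
    orientations (orthogonal to the filament) and are rotated by 90° first.
    Empty bins are reported with fraction NaN.
    """
    df = pd.DataFrame(speckles)
    contour = geom.contours[frame]
    mask = geom.synapse_masks[frame]
    cx, cy = geom.csmac_centers[frame]

    n_bins = int(round(1.0 / bin_width))
    perp = np.zeros(n_bins, int)
    total = np.zeros(n_bins, int)
    for _, row in df.iterrows():
        x, y, ori = float(row.x), float(row.y), float(row.orientation_deg)
        if orientations_are_dipole:
            ori = (ori + 90.0) % 180.0
        try:
            r, _ = normalized_radial_position((x, y), geom, frame)
        except ValueError:
            continue
        # edge intersection along the ray for the tangent estimate
        edge_d = _ray_edge_distance(mask, (cx, cy), (x, y)) if (x, y) != (cx, cy) \
            else None
        if edge_d is None:
            continue
        d = math.hypot(x - cx, y - cy)
        ex = cx + (x - cx) / d * edge_d
        ey = cy + (y - cy) / d * edge_d
        tangent = _contour_tangent(contour, (ey, ex))
        acute = abs((ori - tangent + 90.0) % 180.0 - 90.0)
        b = min(int(r / bin_width), n_bins - 1)
        total[b] += 1
        if acute > 45.0:
            perp[b] += 1

    frac = np.where(total > 0, perp / np.maximum(total, 1), np.nan)
    return pd.DataFrame({
        "bin_lo": np.arange(n_bins) * bin_width,
        "bin_hi": (np.arange(n_bins) + 1) * bin_width,
        "n": total, "n_perpendicular": perp, "fraction_perpendicular": frac,
    })
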