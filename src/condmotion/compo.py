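"""Condensate composition analysis along the inward journey.

Protein content of a condensate is its mean intensity minus a local
background taken from a 2-px ring around the condensate's *aggregate* (the
proximity-connected group of condensates it belongs to). Each track's content
series is normalized by its own first-three-frame mean, the slave/master
ratio is pooled by the frame-by-frame normalized radial position into
0.1-wide bins (0.9–1 nearest the edge, 0.8–0.9, ...), and each bin is
summarised by its median with a notch 95% CI and compared to a reference bin
by a two-sided Wilcoxon rank-sum test at the Bonferroni-corrected threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.measure import label as sk_label
from skimage.morphology import disk

from .detect import CondensateSet
from .stackio import ImageStack
from .synapse import SynapseGeometry, normalized_radial_position
from .trackmotion import Track, track_anisotropy
from .binding import bonferroni

__all__ = [
    "condensate_content",
    "track_contents",
    "select_tracks",
    "composition_profile",
    "composition_profile_pooled",
    "photobleach_control",
    "CompositionProfile",
]


@dataclass
class CompositionProfile:
    """Per-radial-bin pooled normalized content ratios and statistics.

    ``table`` columns: bin_lo, bin_hi, n, median, ci_lo, ci_hi, p,
    significant, suppressed. ``threshold`` is the Bonferroni per-comparison
    threshold actually used.
    """

    table: pd.DataFrame
    pooled: dict[tuple[float, float], np.ndarray]
    reference_bin: tuple[float, float]
    threshold: float


def condensate_content(
    frame: np.ndarray,
    labels: np.ndarray,
    perimeter_px: int = 2,
    valid_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Background-subtracted mean content per condensate.

    Condensates whose masks, dilated by ``perimeter_px``, touch form an
    aggregate; the background mean and SD come from the ``perimeter_px``-thick
    ring around each aggregate, excluding all condensate pixels. Columns:
    id, content, bg_mean, bg_sd, aggregate, missing. Content may be negative
    (flagged ``missing=False`` still); an empty ring (aggregate at the frame
    border) flags the condensate missing.

    ``valid_mask`` optionally restricts both condensate and ring pixels to a
    measurement region (e.g. the synapse footprint minus the cSMAC), so that
    intensity steps at region borders do not leak into the local background.
    """
    frame = np.asarray(frame, float)
    if labels.shape != frame.shape:
        raise ValueError("labels and frame differ in shape")
    any_mask = labels > 0
    if not any_mask.any():
        return pd.DataFrame(columns=["id", "content", "bg_mean", "bg_sd",
                                     "aggregate", "missing"])
    selem = disk(perimeter_px)
    dilated = ndimage.binary_dilation(any_mask, structure=selem)
    groups = sk_label(dilated, connectivity=2)

    recs = []
    for g in range(1, groups.max() + 1):
        members = np.unique(labels[(groups == g) & any_mask])
        members = members[members > 0]
        if members.size == 0:
            continue
        agg_mask = np.isin(labels, members)
        ring = ndimage.binary_dilation(agg_mask, structure=selem) & ~any_mask
        if valid_mask is not None:
            ring &= valid_mask
        if ring.any():
            bg_mean = float(frame[ring].mean())
            bg_sd = float(frame[ring].std())
            missing = False
        else:
            bg_mean = bg_sd = np.nan
            missing = True
        for m in members:
            inside = labels == m
            full_area = int(inside.sum())
            if valid_mask is not None:
                inside &= valid_mask
            # a mask mostly outside the measurement region gives a content
            # estimate from a dim crescent of the spot; treat as missing
            if inside.sum() < max(1, full_area // 2):
                recs.append(dict(id=int(m), content=np.nan, bg_mean=bg_mean,
                                 bg_sd=bg_sd, aggregate=int(g), missing=True))
                continue
            content = float(frame[inside].mean()) - bg_mean if not missing else np.nan
            recs.append(dict(id=int(m), content=content, bg_mean=bg_mean,
                             bg_sd=bg_sd, aggregate=int(g), missing=missing))
    return pd.DataFrame.from_records(recs).sort_values("id").reset_index(drop=True)


def track_contents(
    stack: ImageStack,
    dets: CondensateSet,
    tracks: list[Track],
    perimeter_px: int = 2,
    geom: SynapseGeometry | None = None,
    edge_margin_px: int = 3,
) -> pd.DataFrame:
    """Per-track per-frame content read in ``stack`` at the master-channel
    condensate masks (no re-detection in the slave channel).

    When ``geom`` is given, measurements are restricted to the synapse
    footprint shrunk by ``edge_margin_px`` and excluding the cSMAC grown by
    the same margin, so the smoothed intensity falloff at either boundary
    cannot leak into the local background ring. Columns: track, frame,
    det_id, content, bg_sd, missing.
    """
    per_frame = {}
    rows = []
    for ti, tr in enumerate(tracks):
        for f, det_id in zip(tr.frames, tr.det_ids):
            f = int(f)
            if f not in per_frame:
                vm = None
                if geom is not None:
                    syn_m = geom.synapse_masks[f]
                    cs_m = geom.csmac_masks[f]
                    if edge_margin_px > 0:
                        syn_m = ndimage.binary_erosion(
                            syn_m, iterations=edge_margin_px)
                        if cs_m.any():
                            cs_m = ndimage.binary_dilation(
                                cs_m, iterations=edge_margin_px)
                    vm = syn_m & ~cs_m
                per_frame[f] = condensate_content(
                    stack.frames[f], dets.labels[f], perimeter_px,
                    valid_mask=vm).set_index("id")
            tab = per_frame[f]
            if det_id in tab.index:
                row = tab.loc[det_id]
                rows.append(dict(track=ti, frame=f, det_id=int(det_id),
                                 content=float(row.content),
                                 bg_sd=float(row.bg_sd),
                                 missing=bool(row.missing)))
            else:
                rows.append(dict(track=ti, frame=f, det_id=int(det_id),
                                 content=np.nan, bg_sd=np.nan, missing=True))
    return pd.DataFrame.from_records(rows)


def _track_r(track: Track, geom: SynapseGeometry) -> np.ndarray:
    rs = np.empty(track.n_points)
    for i, (f, x, y) in enumerate(zip(track.frames, track.x, track.y)):
        rs[i] = normalized_radial_position((x, y), geom, int(f))[0]
    return rs


def select_tracks(
    tracks: list[Track],
    geom: SynapseGeometry,
    slave_contents: pd.DataFrame,
    min_frames: int = 5,
    min_anisotropy: float = 3.0,
    position_threshold: float = 0.6,
) -> tuple[list[int], dict[str, int]]:
    """Composition-analysis track filters, applied in order.

    1. duration ≥ ``min_frames``;
    2. approximately linear: position-scatter anisotropy ≥ ``min_anisotropy``;
    3. starts outside the actin position threshold (r > threshold) and ends
       inside it (r < threshold);
    4. mean slave content over the first three time points exceeds the mean
       background SD over the first three time points.

    Returns (indices of surviving tracks, rejection count per filter).
    """
    rejections = {"duration": 0, "anisotropy": 0, "position": 0, "content": 0}
    survivors = []
    for ti, tr in enumerate(tracks):
        if tr.duration < min_frames:
            rejections["duration"] += 1
            continue
        try:
            aniso = track_anisotropy(tr)
        except ValueError:
            rejections["anisotropy"] += 1
            continue
        if aniso < min_anisotropy:
            rejections["anisotropy"] += 1
            continue
        rs = _track_r(tr, geom)
        if not (rs[0] > position_threshold and rs[-1] < position_threshold):
            rejections["position"] += 1
            continue
        rows = slave_contents[slave_contents.track == ti].sort_values("frame")
        if len(rows) < 3:
            raise ValueError(f"track {ti}: missing content rows")
        head = rows.iloc[:3]
        if head.content.isna().any() or head.bg_sd.isna().any():
            rejections["content"] += 1
            continue
        if head.content.mean() <= head.bg_sd.mean():
            rejections["content"] += 1
            continue
        survivors.append(ti)
    return survivors, rejections


def _notch_ci(values: np.ndarray) -> tuple[float, float]:
    """Boxplot notch 95% CI of the median: median ± 1.57·IQR/√n."""
    med = float(np.median(values))
    iqr = float(np.percentile(values, 75) - np.percentile(values, 25))
    half = 1.57 * iqr / math.sqrt(len(values))
    return med - half, med + half


def _radial_bins(bin_width: float, r_min: float) -> list[tuple[float, float]]:
    edges = np.round(np.arange(r_min, 1.0 + 1e-9, bin_width), 10)
    return [(float(edges[i]), float(edges[i + 1])) for i in range(len(edges) - 1)]


def _pool_ratios(
    tracks: list[Track],
    track_indices: list[int],
    master_contents: pd.DataFrame,
    slave_contents: pd.DataFrame,
    geom: SynapseGeometry,
    bins: list[tuple[float, float]],
    pooled: dict[tuple[float, float], list[float]],
) -> None:
    m_idx = master_contents.set_index(["track", "frame"]).content
    s_idx = slave_contents.set_index(["track", "frame"]).content
    for ti in track_indices:
        tr = tracks[ti]
        fr = [int(f) for f in tr.frames]
        m = np.array([m_idx.get((ti, f), np.nan) for f in fr])
        s = np.array([s_idx.get((ti, f), np.nan) for f in fr])
        if np.isnan(m[:3]).any() or np.isnan(s[:3]).any():
            raise ValueError(f"track {ti}: fewer than 3 leading content values")
        m0, s0 = m[:3].mean(), s[:3].mean()
        if m0 <= 0 or s0 <= 0:
            continue
        rs = _track_r(tr, geom)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(m > 0, (s / s0) / (m / m0), np.nan)
        for r, val in zip(rs, ratio):
            if not np.isfinite(val):
                continue
            for lo, hi in bins:
                if (lo <= r < hi) or (hi == 1.0 and r == 1.0):
                    pooled[(lo, hi)].append(float(val))
                    break


def composition_profile(
    tracks: list[Track],
    track_indices: list[int],
    master_contents: pd.DataFrame,
    slave_contents: pd.DataFrame,
    geom: SynapseGeometry,
    reference_bin: tuple[float, float] = (0.9, 1.0),
    bin_width: float = 0.1,
    r_min: float = 0.2,
    min_bin_n: int = 10,
    alpha_total: float = 0.05,
) -> CompositionProfile:
    """Pooled normalized slave/master content ratio vs radial position.

    Per time point of each selected track the slave and master contents are
    each normalized by their own first-three-frame mean and the ratio
    assigned to the radial bin of that frame's r. Bins are half-open
    [lo, hi) except the outermost [0.9, 1.0], running from 1.0 down to
    ``r_min``. Bins with fewer than ``min_bin_n`` points are suppressed.
    Each bin is tested against the reference bin by a two-sided rank-sum
    test; significance at alpha_total / (number of comparisons). When the
    outermost bin is sparsely populated, pass ``reference_bin=(0.8, 0.9)``.
    """
    return composition_profile_pooled(
        [(tracks, track_indices, master_contents, slave_contents, geom)],
        reference_bin, bin_width, r_min, min_bin_n, alpha_total)


def composition_profile_pooled(
    movies,
    reference_bin: tuple[float, float] = (0.9, 1.0),
    bin_width: float = 0.1,
    r_min: float = 0.2,
    min_bin_n: int = 10,
    alpha_total: float = 0.05,
) -> CompositionProfile:
    """Composition profile pooled over several movies/cells.

    ``movies`` is a sequence of tuples (tracks, track_indices,
    master_contents, slave_contents, geom); pooled values from all movies
    enter the per-bin statistics together, as when pooling cells of one
    condition.
    """
    bins = _radial_bins(bin_width, r_min)
    pooled: dict[tuple[float, float], list[float]] = {b: [] for b in bins}
    for tracks, idx, m_cont, s_cont, geom in movies:
        _pool_ratios(tracks, idx, m_cont, s_cont, geom, bins, pooled)

    pooled_arr = {b: np.asarray(v) for b, v in pooled.items()}
    ref = tuple(np.round(reference_bin, 10))
    if ref not in pooled_arr:
        raise ValueError(f"reference bin {reference_bin} outside the bin range")
    if len(pooled_arr[ref]) < min_bin_n:
        raise ValueError("reference bin suppressed (n < minimum); cannot test")

    compared = [b for b in bins
                if b != ref and len(pooled_arr[b]) >= min_bin_n]
    m_comparisons = max(len(compared), 1)
    threshold = bonferroni(alpha_total, m_comparisons)

    rows = []
    for lo, hi in bins:
        vals = pooled_arr[(lo, hi)]
        suppressed = len(vals) < min_bin_n
        if suppressed:
            rows.append(dict(bin_lo=lo, bin_hi=hi, n=len(vals), median=np.nan,
                             ci_lo=np.nan, ci_hi=np.nan, p=np.nan,
                             significant=False, suppressed=True))
            continue
        ci_lo, ci_hi = _notch_ci(vals)
        if (lo, hi) == ref:
            p = np.nan
            sig = False
        else:
            p = float(stats.ranksums(vals, pooled_arr[ref]).pvalue)
            sig = p < threshold
        rows.append(dict(bin_lo=lo, bin_hi=hi, n=len(vals),
                         median=float(np.median(vals)), ci_lo=ci_lo,
                         ci_hi=ci_hi, p=p, significant=sig, suppressed=False))
    table = pd.DataFrame(rows).sort_values("bin_lo", ascending=False,
                                           ignore_index=True)
    return CompositionProfile(table=table, pooled=pooled_arr,
                              reference_bin=ref, threshold=threshold)


def photobleach_control(
    stack: ImageStack,
    geom: SynapseGeometry,
    dets: CondensateSet | None = None,
) -> np.ndarray:
    """Per-frame mean intensity within the synapse but outside the cSMAC and
    detected condensates, normalized by the first frame.

    Frames whose region is empty are NaN; a zero first-frame mean is an
    error (normalization undefined).
    """
    series = np.empty(stack.n_frames)
    for t in range(stack.n_frames):
        region = geom.synapse_masks[t] & ~geom.csmac_masks[t]
        if dets is not None:
            region &= ~(dets.labels[t] > 0)
        series[t] = stack.frames[t][region].mean() if region.any() else np.nan
    if not np.isfinite(series[0]) or series[0] == 0:
        raise ValueError("first-frame background mean is zero or missing")
    return series / series[0]
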