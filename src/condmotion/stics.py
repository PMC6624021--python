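"""Spatio-temporal image correlation spectroscopy (STICS) velocity fields and
two-channel co-movement statistics.

Each image subregion (default 16×16 px window, 8 px step) yields one
displacement vector per analysis interval: the immobile component is removed
by subtracting the per-pixel temporal mean, then each window at frame t is
correlated against displaced copies of itself at frame t+shift (default
shift 3 frames) using normalized (Pearson) cross-correlation per candidate
displacement; the correlation surfaces are averaged over all frame pairs and
the vector is the sub-pixel (parabolic) location of the correlation peak.
A vector is valid only when the peak rises clearly above the correlation
surface's noise.

Co-movement statistics compare speeds and inter-channel vector angles per
co-valid subregion, with a seeded channel-randomization control and the
subsampled KS / rank-sum testing convention for large samples (subsample 500
per group, 100 repeats, mean p).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .stackio import ImageStack

__all__ = [
    "VectorField",
    "stics_field",
    "comovement",
    "randomize_control",
    "subsampled_test",
    "speed_histogram2d",
]


@dataclass
class VectorField:
    """Per-subregion displacement vectors.

    ``centers`` is (n, 2) of (x, y) px; ``dxy`` is (n, 2) displacement in px
    per temporal shift; ``valid`` flags subregions with a meaningful vector.
    Speeds are in px/frame (displacement / shift_frames).
    """

    centers: np.ndarray
    dxy: np.ndarray
    valid: np.ndarray
    shift_frames: int
    frame_interval_s: float
    pixel_size_um: float
    grid_shape: tuple[int, int]

    @property
    def speed_px_per_frame(self) -> np.ndarray:
        return np.hypot(self.dxy[:, 0], self.dxy[:, 1]) / self.shift_frames

    @property
    def speed_um_per_s(self) -> np.ndarray:
        return self.speed_px_per_frame * self.pixel_size_um / self.frame_interval_s

    @property
    def angle_deg(self) -> np.ndarray:
        return np.degrees(np.arctan2(self.dxy[:, 1], self.dxy[:, 0]))

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cx": self.centers[:, 0], "cy": self.centers[:, 1],
            "dx": self.dxy[:, 0], "dy": self.dxy[:, 1],
            "speed_px_per_frame": self.speed_px_per_frame,
            "angle_deg": self.angle_deg, "valid": self.valid,
        })


def _parabolic_peak(surface: np.ndarray, py: int, px: int) -> tuple[float, float]:
    """Sub-pixel peak location by 1-D parabolic interpolation along each axis."""
    def refine(c, lo, hi):
        denom = lo - 2 * c + hi
        if denom >= 0:   # not a local max in this axis
            return 0.0
        return 0.5 * (lo - hi) / denom

    h, w = surface.shape
    dy = dx = 0.0
    if 0 < py < h - 1:
        dy = refine(surface[py, px], surface[py - 1, px], surface[py + 1, px])
    if 0 < px < w - 1:
        dx = refine(surface[py, px], surface[py, px - 1], surface[py, px + 1])
    return dy, dx


def _refine_peak(early: np.ndarray, late: np.ndarray, y0: int, x0: int,
                 window: int, dy0: float, dx0: float,
                 frame_shape: tuple[int, int]) -> tuple[float, float]:
    """Sub-pixel displacement maximizing the mean Pearson correlation between
    each early window and the bilinearly-interpolated late window.

    Coordinate-symmetric pattern search (evaluate the 8 neighbors at the
    current step, move to the best, halve the step otherwise) so the result
    is exactly equivariant under 90° rotations of the movie.
    """
    from scipy import ndimage as ndi

    h, w = frame_shape
    yy, xx = np.mgrid[y0:y0 + window, x0:x0 + window].astype(float)
    a = early[:, y0:y0 + window, x0:x0 + window]
    a0 = a - a.mean(axis=(1, 2), keepdims=True)
    a_norm = np.sqrt((a0 * a0).sum(axis=(1, 2)))

    def corr(dy: float, dx: float) -> float:
        ys, xs = yy + dy, xx + dx
        if ys.min() < 0 or xs.min() < 0 or ys.max() > h - 1 or xs.max() > w - 1:
            return -np.inf
        rs = []
        for t in range(late.shape[0]):
            b = ndi.map_coordinates(late[t], [ys, xs], order=1)
            b0 = b - b.mean()
            den = a_norm[t] * math.sqrt((b0 * b0).sum())
            if den > 0:
                rs.append((a0[t] * b0).sum() / den)
        return float(np.mean(rs)) if rs else -np.inf

    cy, cx = dy0, dx0
    best = corr(cy, cx)
    step = 0.5
    while step >= 1e-3:
        cands = [(cy + sy * step, cx + sx * step)
                 for sy in (-1, 0, 1) for sx in (-1, 0, 1)
                 if (sy, sx) != (0, 0)]
        vals = [corr(*c) for c in cands]
        k = int(np.argmax(vals))
        if vals[k] > best + 1e-15:
            (cy, cx), best = cands[k], vals[k]
        else:
            step /= 2.0
    return cy, cx


def stics_field(
    stack: ImageStack,
    t_range: tuple[int, int] | None = None,
    window_px: int = 16,
    step_px: int = 8,
    shift_frames: int = 3,
    noise_floor_k: float = 5.0,
    min_speed_px_per_frame: float = 0.01,
    min_peak_corr: float = 0.2,
) -> VectorField:
    """One displacement vector per image subregion over an analysis interval.

    ``t_range`` is a half-open (start, stop) frame interval (default: whole
    movie) and must span at least ``shift_frames + 1`` frames. Vector = the
    sub-pixel peak of the average cross-correlation between frame pairs
    (t, t + shift); peak search restricted to displacements within
    ``window_px / 4``. Validity requires a peak above ``noise_floor_k`` times
    the surface's robust noise SD and a speed above
    ``min_speed_px_per_frame``.
    """
    t0, t1 = t_range if t_range is not None else (0, stack.n_frames)
    if t1 - t0 < shift_frames + 1:
        raise ValueError("t_range must span at least shift_frames + 1 frames")
    h, w = stack.shape
    if window_px > min(h, w):
        raise ValueError("window larger than frame")

    frames = stack.frames[t0:t1].astype(float)
    frames = frames - frames.mean(axis=0, keepdims=True)   # immobile removal

    max_disp = window_px // 4
    offsets = range(-max_disp, max_disp + 1)

    ys = list(range(0, h - window_px + 1, step_px))
    xs = list(range(0, w - window_px + 1, step_px))
    centers, dxy, valid = [], [], []
    n_pairs = frames.shape[0] - shift_frames
    early = frames[:n_pairs]
    late = frames[shift_frames:shift_frames + n_pairs]
    for y0 in ys:
        for x0 in xs:
            a = early[:, y0:y0 + window_px, x0:x0 + window_px]
            a0 = a - a.mean(axis=(1, 2), keepdims=True)
            a_norm = np.sqrt((a0 * a0).sum(axis=(1, 2)))
            surf = np.full((2 * max_disp + 1, 2 * max_disp + 1), -np.inf)
            for iy, dy_ in enumerate(offsets):
                yb = y0 + dy_
                if yb < 0 or yb + window_px > h:
                    continue
                for ix, dx_ in enumerate(offsets):
                    xb = x0 + dx_
                    if xb < 0 or xb + window_px > w:
                        continue
                    b = late[:, yb:yb + window_px, xb:xb + window_px]
                    b0 = b - b.mean(axis=(1, 2), keepdims=True)
                    b_norm = np.sqrt((b0 * b0).sum(axis=(1, 2)))
                    den = a_norm * b_norm
                    ok_pairs = den > 0
                    if not ok_pairs.any():
                        continue
                    r = ((a0 * b0).sum(axis=(1, 2))[ok_pairs] / den[ok_pairs])
                    surf[iy, ix] = r.mean()
            if not np.isfinite(surf).any():
                centers.append((x0 + (window_px - 1) / 2.0,
                                y0 + (window_px - 1) / 2.0))
                dxy.append((0.0, 0.0))
                valid.append(False)
                continue
            py, px = np.unravel_index(np.argmax(surf), surf.shape)
            finite_surf = np.where(np.isfinite(surf), surf, surf[py, px] - 1.0)
            dy0, dx0 = py - max_disp, px - max_disp
            dy, dx = _refine_peak(early, late, y0, x0, window_px,
                                  float(dy0), float(dx0), (h, w))
            if not (abs(dy - dy0) <= 1 and abs(dx - dx0) <= 1):
                ddy, ddx = _parabolic_peak(finite_surf, py, px)
                dy, dx = dy0 + ddy, dx0 + ddx
            peak = float(surf[py, px])
            # robust noise level: pixel-scale roughness of the correlation
            # surface (first differences), insensitive to its smooth structure
            flat = finite_surf.copy()
            flat[max(py - 1, 0):py + 2, max(px - 1, 0):px + 2] = np.nan
            diffs = np.concatenate([
                np.diff(flat, axis=0).ravel(), np.diff(flat, axis=1).ravel()])
            diffs = diffs[np.isfinite(diffs)]
            baseline = flat[np.isfinite(flat)]
            if diffs.size and baseline.size:
                sd = 1.4826 * np.median(np.abs(diffs)) / math.sqrt(2)
                prominence = peak - np.median(baseline)
            else:
                sd, prominence = 0.0, peak
            speed = math.hypot(dx, dy) / shift_frames
            ok = prominence > noise_floor_k * max(sd, 1e-12) \
                and peak > min_peak_corr \
                and speed > min_speed_px_per_frame
            centers.append((x0 + (window_px - 1) / 2.0, y0 + (window_px - 1) / 2.0))
            dxy.append((dx, dy))
            valid.append(bool(ok))

    return VectorField(
        centers=np.array(centers), dxy=np.array(dxy),
        valid=np.array(valid, bool), shift_frames=shift_frames,
        frame_interval_s=stack.frame_interval_s,
        pixel_size_um=stack.pixel_size_um, grid_shape=(len(ys), len(xs)))


def _check_grids(vfA: VectorField, vfB: VectorField) -> None:
    if vfA.grid_shape != vfB.grid_shape or not np.allclose(vfA.centers, vfB.centers):
        raise ValueError("vector fields have mismatched subregion grids")


def comovement(vfA: VectorField, vfB: VectorField) -> pd.DataFrame:
    """Paired speeds and inter-vector angle per co-valid subregion.

    Columns: cx, cy, speed_a, speed_b (px/frame), angle_deg in [0, 180].
    """
    _check_grids(vfA, vfB)
    both = vfA.valid & vfB.valid
    a = vfA.dxy[both]
    b = vfB.dxy[both]
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    cosang = np.clip((a * b).sum(1) / np.maximum(na * nb, 1e-300), -1.0, 1.0)
    return pd.DataFrame({
        "cx": vfA.centers[both, 0], "cy": vfA.centers[both, 1],
        "speed_a": na / vfA.shift_frames, "speed_b": nb / vfB.shift_frames,
        "angle_deg": np.degrees(np.arccos(cosang)),
    })


def randomize_control(vfA: VectorField, vfB: VectorField, seed: int) -> pd.DataFrame:
    """Co-movement after randomly permuting channel-A vectors across the
    co-valid subregion positions (seed-deterministic permutation)."""
    _check_grids(vfA, vfB)
    both = vfA.valid & vfB.valid
    idx = np.nonzero(both)[0]
    perm = np.random.default_rng(seed).permutation(len(idx))
    dxy = vfA.dxy.copy()
    dxy[idx] = vfA.dxy[idx][perm]
    shuffled = VectorField(vfA.centers, dxy, vfA.valid, vfA.shift_frames,
                           vfA.frame_interval_s, vfA.pixel_size_um, vfA.grid_shape)
    return comovement(shuffled, vfB)


def speed_histogram2d(speeds_a, speeds_b, bins: int = 30,
                      range_: tuple | None = None):
    """2-D speed-frequency histogram with counts normalized by the total."""
    hist, xe, ye = np.histogram2d(np.asarray(speeds_a), np.asarray(speeds_b),
                                  bins=bins, range=range_)
    total = hist.sum()
    if total > 0:
        hist = hist / total
    return hist, xe, ye


def subsampled_test(
    sampleA,
    sampleB,
    statistic: str = "ks",
    n_sub: int = 500,
    reps: int = 100,
    trigger_n: int = 1000,
    seed: int = 0,
) -> float:
    """Mean p-value over repeated subsampled two-sample tests.

    With both samples at or below ``trigger_n`` the plain test runs once.
    Otherwise ``reps`` repeats draw ``n_sub`` points from each sample without
    replacement (all points when a sample is smaller) and the arithmetic mean
    of the p-values is returned. ``statistic`` is ``"ks"`` (two-sample
    Kolmogorov–Smirnov) or ``"ranksum"`` (Wilcoxon rank-sum).
    """
    a = np.asarray(sampleA, float)
    b = np.asarray(sampleB, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    if statistic == "ks":
        test = lambda x, y: stats.ks_2samp(x, y).pvalue
    elif statistic == "ranksum":
        test = lambda x, y: stats.ranksums(x, y).pvalue
    else:
        raise ValueError(f"unknown statistic {statistic!r}; use 'ks' or 'ranksum'")

    if len(a) <= trigger_n and len(b) <= trigger_n:
        return float(test(a, b))

    rng = np.random.default_rng(seed)
    ps = []
    for _ in range(reps):
        sa = rng.choice(a, size=min(n_sub, len(a)), replace=False)
        sb = rng.choice(b, size=min(n_sub, len(b)), replace=False)
        ps.append(test(sa, sb))
    return float(np.mean(ps))
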