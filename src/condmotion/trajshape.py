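"""Deviation of condensate trajectories from a straight inward path.

A track's early edge-hugging phase is removed by finding the transition point
where the ratio of frame-to-frame change in distance-to-center to change in
turning angle first enters the top 10% of the track's ratios (top 25%
fallback when that point is already inside the actin position threshold); the
late phase after the condensate enters the cSMAC is trimmed; the remaining
segment is rotated so its endpoints sit on the x-axis, and every y-coordinate
is a signed deviation from the straight path (sign flipped so the majority of
deviations are positive).
"""

from __future__ import annotations

import math

import numpy as np

from .synapse import SynapseGeometry, normalized_radial_position
from .trackmotion import Track

__all__ = ["find_transition", "trim_track", "straight_path_deviation"]

ANGLE_FLOOR_RAD = 1e-3


def _ratio_series(track: Track, geom: SynapseGeometry) -> np.ndarray:
    """R(t) = |Δ distance to cSMAC center| / max(turn angle, ε) at interior
    time points t = 1 .. n−2."""
    n = track.n_points
    if n - 2 < 3:
        raise ValueError("transition detection needs at least 3 displacements")
    d = np.empty(n)
    for i, (f, x, y) in enumerate(zip(track.frames, track.x, track.y)):
        cx, cy = geom.csmac_centers[int(f)]
        d[i] = math.hypot(x - cx, y - cy)
    xy = track.xy
    disp = np.diff(xy, axis=0)
    ratios = np.empty(n - 2)
    for t in range(1, n - 1):
        ddist = abs(d[t + 1] - d[t])
        v0, v1 = disp[t - 1], disp[t]
        n0, n1 = np.linalg.norm(v0), np.linalg.norm(v1)
        if n0 == 0 or n1 == 0:
            dang = ANGLE_FLOOR_RAD
        else:
            cosang = np.clip(np.dot(v0, v1) / (n0 * n1), -1.0, 1.0)
            dang = max(math.acos(cosang), ANGLE_FLOOR_RAD)
        ratios[t - 1] = ddist / dang
    return ratios


def find_transition(
    track: Track,
    geom: SynapseGeometry,
    position_threshold: float = 0.6,
    min_track_frames: int = 5,
) -> tuple[int, float]:
    """Index (into the track's points) of the edge-to-inward transition.

    Returns (point index, r at that point). The first interior point whose
    distance/angle ratio reaches the 90th percentile of the track's ratios is
    chosen; if its r is already below ``position_threshold`` the 75th
    percentile is used instead. The returned r is reported for audit, not
    enforced.
    """
    if track.duration < min_track_frames:
        raise ValueError(
            f"track duration {track.duration} below minimum of {min_track_frames}")
    ratios = _ratio_series(track, geom)

    def first_at(pct: float) -> int:
        thr = np.percentile(ratios, pct)
        idx = int(np.argmax(ratios >= thr))
        return idx + 1  # interior offset

    t = first_at(90.0)
    r, _ = normalized_radial_position(
        (track.x[t], track.y[t]), geom, int(track.frames[t]))
    if r < position_threshold:
        t = first_at(75.0)
        r, _ = normalized_radial_position(
            (track.x[t], track.y[t]), geom, int(track.frames[t]))
    return t, r


def trim_track(track: Track, geom: SynapseGeometry, transition: int) -> Track:
    """Segment from the transition point to the last point before the
    condensate first falls inside the cSMAC mask."""
    if not 0 <= transition < track.n_points:
        raise ValueError("transition index out of range")
    end = track.n_points
    for i in range(track.n_points):
        f = int(track.frames[i])
        mask = geom.csmac_masks[f]
        yi, xi = int(round(track.y[i])), int(round(track.x[i]))
        if (0 <= yi < mask.shape[0] and 0 <= xi < mask.shape[1]
                and mask[yi, xi]):
            end = i
            break
    if end <= transition:
        raise ValueError("track enters the cSMAC before the transition point; "
                         "empty segment")
    return Track(frames=track.frames[transition:end],
                 x=track.x[transition:end], y=track.y[transition:end],
                 det_ids=track.det_ids[transition:end])


def straight_path_deviation(segment: Track | np.ndarray) -> np.ndarray:
    """Signed deviations of a track segment from the straight line between its
    endpoints.

    The segment is rigidly translated and rotated so start and end lie on the
    x-axis (y = 0); the y-coordinates of all points are the deviations.
    The sign is flipped, if necessary, so the count of positive deviations is
    at least the count of negative ones (ties broken toward the larger sum of
    positive deviations). Invariant to global rotation/translation.
    """
    xy = segment.xy if isinstance(segment, Track) else np.asarray(segment, float)
    if len(xy) < 3:
        raise ValueError("segment needs at least 3 points")
    start, end = xy[0], xy[-1]
    chord = end - start
    length = np.linalg.norm(chord)
    if length == 0:
        raise ValueError("segment endpoints coincide")
    c, s = chord / length
    rel = xy - start
    dev = -s * rel[:, 0] + c * rel[:, 1]   # y after rotating chord onto +x

    eps = 1e-9 * max(1.0, float(np.abs(dev).max()))   # ignore float dust at 0
    pos = int((dev > eps).sum())
    neg = int((dev < -eps).sum())
    if neg > pos:
        dev = -dev
    elif neg == pos:
        if dev[dev > eps].sum() < -dev[dev < -eps].sum():
            dev = -dev
    return dev
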