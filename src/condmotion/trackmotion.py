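"""Frame-to-frame track linking with gap closing, and moment-scaling-spectrum
(MSS) mobility analysis.

Linking follows the linear-assignment spirit of multiple-particle trackers:
per frame pair, a one-to-one assignment minimising total squared displacement,
with links beyond the search radius forbidden; track ends are then re-joined
to later track starts within the search radius and the gap-closing window.
Defaults: search radius 5 px, gap window 3 frames.

MSS analysis computes displacement moments μ_ν(τ) of orders ν = 0..6 over lag
times τ, extracts scaling exponents γ_ν from log-log fits, summarises them by
the MSS slope S (0.5 for Brownian motion, →1 ballistic, →0 confined), and an
effective diffusion coefficient D₂ from the second-moment intercept
(μ₂(τ) ≈ 4·D₂·τ^γ₂).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = ["Track", "MSSResult", "link_tracks", "mss", "track_anisotropy",
           "ANISOTROPY_SENTINEL"]

#: reported for perfectly collinear tracks (scatter matrix is singular)
ANISOTROPY_SENTINEL = 1e9


@dataclass
class Track:
    """An ordered sequence of positions; gap frames are absent from ``frames``
    but spanned (frames strictly increasing, not necessarily consecutive)."""

    frames: np.ndarray           # int, strictly increasing
    x: np.ndarray                # px or µm
    y: np.ndarray
    det_ids: np.ndarray          # detection id per point, -1 if synthetic
    merge_events: list = field(default_factory=list)   # (frame, other_track_idx)
    split_events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, int)
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        self.det_ids = np.asarray(self.det_ids, int)
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("track frames must be strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("track positions must be finite")

    @property
    def n_points(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> int:
        """Duration in frames, inclusive of both ends."""
        return int(self.frames[-1] - self.frames[0] + 1)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def to_records(self, track_id: int) -> list[dict]:
        return [
            {"track": track_id, "frame": int(f), "x": float(xx), "y": float(yy),
             "det_id": int(d)}
            for f, xx, yy, d in zip(self.frames, self.x, self.y, self.det_ids)
        ]


@dataclass
class MSSResult:
    gamma: np.ndarray            # γ_ν for ν = 0..6
    slope: float                 # S, least-squares slope of γ_ν vs ν (ν = 1..6)
    D2_um2_s: float              # effective diffusion coefficient
    n_lags: int

    def as_dict(self) -> dict:
        d = {f"gamma{v}": float(g) for v, g in enumerate(self.gamma)}
        d.update(mss_slope=float(self.slope), D2_um2_s=float(self.D2_um2_s),
                 n_lags=int(self.n_lags))
        return d


def _frame_detections(dets) -> dict[int, pd.DataFrame]:
    """Split a detections table (or CondensateSet) into per-frame tables."""
    if hasattr(dets, "records"):
        df = dets.records
    else:
        df = dets
    return {int(f): g.reset_index(drop=True) for f, g in df.groupby("frame")}


def _assign(prev: np.ndarray, curr: np.ndarray, radius: float) -> list[tuple[int, int]]:
    """One-to-one assignment minimising total squared displacement.

    Built as the standard augmented LAP: an n_prev+n_curr square cost matrix
    whose off-diagonal blocks let any point stay unlinked at the cost of the
    radius squared (birth/death), so forbidden links never force a pairing.
    """
    n0, n1 = len(prev), len(curr)
    if n0 == 0 or n1 == 0:
        return []
    d2 = ((prev[:, None, :] - curr[None, :, :]) ** 2).sum(-1)
    big = 1e12
    alt = radius * radius * (1 + 1e-9)
    cost = np.full((n0 + n1, n0 + n1), 0.0)
    link = np.where(d2 <= radius * radius, d2, big)
    cost[:n0, :n1] = link
    cost[:n0, n1:] = np.where(np.eye(n0, dtype=bool), alt, big)
    cost[n0:, :n1] = np.where(np.eye(n1, dtype=bool), alt, big)
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c)) for r, c in zip(rows, cols)
            if r < n0 and c < n1 and link[r, c] < big]


def link_tracks(
    dets,
    search_radius_px: float = 5.0,
    gap_window: int = 3,
    allow_merge_split: bool = True,
) -> list[Track]:
    """Link per-frame detections into tracks with gap closing.

    ``dets`` is a detections table with columns (frame, id, x, y) or a
    CondensateSet. Gap closing re-joins a track end at frame t_e to a later
    track start at frame t_s when t_s − t_e ≤ ``gap_window`` (at least one
    missing frame) and the positions are within the search radius.
    Merge/split events are annotated only, never alter positions.
    """
    by_frame = _frame_detections(dets)
    if not by_frame:
        return []
    frames = sorted(by_frame)

    # growing segments: dict of lists (frames, x, y, ids)
    segments: list[dict] = []
    active: dict[int, int] = {}   # index into current frame's table -> segment idx

    first = by_frame[frames[0]]
    for i in range(len(first)):
        segments.append({"frames": [frames[0]], "x": [first.x[i]],
                         "y": [first.y[i]], "ids": [int(first.id[i])]})
        active[i] = len(segments) - 1

    for fprev, fcurr in zip(frames[:-1], frames[1:]):
        prev_tab, curr_tab = by_frame[fprev], by_frame[fcurr]
        prev_xy = prev_tab[["x", "y"]].to_numpy(float)
        curr_xy = curr_tab[["x", "y"]].to_numpy(float)
        links = _assign(prev_xy, curr_xy, search_radius_px) \
            if fcurr - fprev == 1 else []
        new_active: dict[int, int] = {}
        linked_curr = set()
        for r, c in links:
            if r in active:
                seg = segments[active[r]]
                seg["frames"].append(fcurr)
                seg["x"].append(curr_tab.x[c])
                seg["y"].append(curr_tab.y[c])
                seg["ids"].append(int(curr_tab.id[c]))
                new_active[c] = active[r]
                linked_curr.add(c)
        for c in range(len(curr_tab)):
            if c not in linked_curr:
                segments.append({"frames": [fcurr], "x": [curr_tab.x[c]],
                                 "y": [curr_tab.y[c]], "ids": [int(curr_tab.id[c])]})
                new_active[c] = len(segments) - 1
        active = new_active

    # gap closing: ends -> later starts, optimal assignment on squared distance
    ends = [(i, s["frames"][-1], s["x"][-1], s["y"][-1]) for i, s in enumerate(segments)]
    starts = [(i, s["frames"][0], s["x"][0], s["y"][0]) for i, s in enumerate(segments)]
    big = 1e12
    pairs = []
    for ei, (i, fe, xe, ye) in enumerate(ends):
        for sj, (j, fs, xs_, ys_) in enumerate(starts):
            if i == j:
                continue
            dt = fs - fe
            if 2 <= dt <= gap_window:
                d2 = (xe - xs_) ** 2 + (ye - ys_) ** 2
                if d2 <= search_radius_px**2:
                    pairs.append((ei, sj, d2))
    merged_into: dict[int, int] = {}
    if pairs:
        eidx = sorted({p[0] for p in pairs})
        sidx = sorted({p[1] for p in pairs})
        cost = np.full((len(eidx), len(sidx)), big)
        for e, s, d2 in pairs:
            cost[eidx.index(e), sidx.index(s)] = d2
        rows, cols = linear_sum_assignment(cost)
        closures = [(eidx[r], sidx[c]) for r, c in zip(rows, cols)
                    if cost[r, c] < big]
        # apply closures end->start (chains resolved by repeated lookup)
        for e, s in closures:
            merged_into[s] = e

    def root(i: int) -> int:
        while i in merged_into:
            i = merged_into[i]
        return i

    assembled: dict[int, dict] = {}
    order = sorted(range(len(segments)), key=lambda i: segments[i]["frames"][0])
    for i in order:
        r = root(i)
        if r == i:
            assembled[i] = {k: list(v) for k, v in segments[i].items()}
        else:
            tgt = assembled[root(i)]
            seg = segments[i]
            tgt["frames"] += seg["frames"]
            tgt["x"] += seg["x"]
            tgt["y"] += seg["y"]
            tgt["ids"] += seg["ids"]

    tracks = [
        Track(frames=np.array(s["frames"]), x=np.array(s["x"]),
              y=np.array(s["y"]), det_ids=np.array(s["ids"]))
        for s in assembled.values()
    ]
    tracks.sort(key=lambda t: (t.frames[0], t.x[0], t.y[0]))

    if allow_merge_split:
        _annotate_merge_split(tracks, search_radius_px)
    return tracks


def _annotate_merge_split(tracks: list[Track], radius: float) -> None:
    """Mark unlinked track ends that terminate on top of a continuing track
    (merge) and starts that emerge from one (split). Annotation only."""
    for i, t in enumerate(tracks):
        fe = t.frames[-1]
        for j, other in enumerate(tracks):
            if j == i:
                continue
            if other.frames[0] <= fe < other.frames[-1]:
                k = np.searchsorted(other.frames, fe + 1)
                if k < other.n_points:
                    d = math.hypot(t.x[-1] - other.x[k], t.y[-1] - other.y[k])
                    if d <= radius:
                        t.merge_events.append((int(fe), j))
                        break
        fs = t.frames[0]
        for j, other in enumerate(tracks):
            if j == i:
                continue
            if other.frames[0] < fs <= other.frames[-1]:
                k = np.searchsorted(other.frames, fs - 1, side="right") - 1
                if 0 <= k < other.n_points:
                    d = math.hypot(t.x[0] - other.x[k], t.y[0] - other.y[k])
                    if d <= radius:
                        t.split_events.append((int(fs), j))
                        break


def mss(
    track: Track,
    frame_interval_s: float,
    pixel_size_um: float = 1.0,
    max_lag_fraction: float = 0.25,
    min_samples_per_lag: int = 5,
    min_track_frames: int = 5,
) -> MSSResult:
    """Moment scaling spectrum of one track.

    For each lag τ, μ_ν(τ) is the time average of |displacement over τ|^ν for
    ν = 0..6; γ_ν is the slope of log μ_ν vs log τ; S is the least-squares
    slope of γ_ν vs ν over ν = 1..6, fitted through the origin since
    γ₀ = 0 by construction; the effective diffusion coefficient D₂
    (µm²/s) comes from the ν = 2 fit via μ₂ ≈ 4·D₂·τ^γ₂, with the fitted
    line evaluated at the shortest lag (inside the fitted range, where the
    slope–intercept correlation does not inflate the estimate). Lags with
    fewer than ``min_samples_per_lag`` displacement samples are excluded
    (the two shortest lags are always retained so a fit exists).
    """
    if track.duration < min_track_frames:
        raise ValueError(
            f"track duration {track.duration} below minimum of {min_track_frames} frames")
    frames = track.frames
    xy = track.xy * pixel_size_um
    n = track.duration
    max_lag = max(2, int(math.floor(max_lag_fraction * n)))
    max_lag = min(max_lag, n - 1)

    pos = {int(f): xy[i] for i, f in enumerate(frames)}
    fmin = int(frames[0])
    lags, counts, disps = [], [], []
    for lag in range(1, max_lag + 1):
        d = [np.linalg.norm(pos[f + lag] - pos[f])
             for f in pos if (f + lag) in pos]
        if d:
            lags.append(lag)
            counts.append(len(d))
            disps.append(np.asarray(d))
    keep = [i for i, c in enumerate(counts) if c >= min_samples_per_lag]
    if len(keep) < 2:
        keep = list(range(min(2, len(lags))))
    if len(keep) < 2:
        raise ValueError("track has too few usable lags for an MSS fit")
    lags = [lags[i] for i in keep]
    disps = [disps[i] for i in keep]

    tau = np.array(lags, float) * frame_interval_s
    orders = np.arange(7)
    mu = np.array([[np.mean(d**v) for d in disps] for v in orders])  # (7, n_lag)

    if np.all(mu[2] <= 0):
        # immobile: all displacements are exactly zero
        return MSSResult(gamma=np.zeros(7), slope=0.0, D2_um2_s=0.0,
                         n_lags=len(lags))

    log_tau = np.log(tau)
    gamma = np.zeros(7)
    mu2_at_tau1 = 0.0
    for v in orders[1:]:
        good = mu[v] > 0
        if good.sum() < 2:
            gamma[v] = 0.0
            continue
        slope, icpt = np.polyfit(log_tau[good], np.log(mu[v][good]), 1)
        gamma[v] = slope
        if v == 2:
            mu2_at_tau1 = math.exp(slope * log_tau[0] + icpt)
    # the MSS line passes through the origin (gamma_0 = 0 by construction),
    # so S is the through-origin least-squares slope over nu = 1..6
    S = float((orders[1:] * gamma[1:]).sum() / (orders[1:] ** 2).sum())
    D2 = float(mu2_at_tau1 / (4.0 * tau[0]))
    return MSSResult(gamma=gamma, slope=float(S), D2_um2_s=D2, n_lags=len(lags))


def track_anisotropy(track: Track) -> float:
    """sqrt(largest/smallest eigenvalue) of the 2×2 position-scatter matrix.

    ≈1 for isotropic scatter, large for elongated (approximately linear)
    tracks; exactly collinear scatter returns ``ANISOTROPY_SENTINEL``.
    """
    xy = track.xy
    if len(np.unique(xy, axis=0)) < 3:
        raise ValueError("track_anisotropy requires >= 3 distinct positions")
    cov = np.cov(xy.T)
    evals = np.linalg.eigvalsh(cov)
    lo, hi = float(evals[0]), float(evals[1])
    if lo <= hi * 1e-12:
        return ANISOTROPY_SENTINEL
    return math.sqrt(hi / lo)


def tracks_to_table(tracks: list[Track]) -> pd.DataFrame:
    recs = []
    for i, t in enumerate(tracks):
        recs.extend(t.to_records(i))
    return pd.DataFrame.from_records(
        recs, columns=["track", "frame", "x", "y", "det_id"])


def tracks_from_table(df: pd.DataFrame) -> list[Track]:
    tracks = []
    for _, g in df.groupby("track"):
        g = g.sort_values("frame")
        tracks.append(Track(frames=g.frame.to_numpy(), x=g.x.to_numpy(),
                            y=g.y.to_numpy(), det_ids=g.det_id.to_numpy()))
    return tracks
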