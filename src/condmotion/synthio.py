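"""Synthetic movie, track, binding-curve and speckle generators with ground truth.

Every generator returns ``(data, GroundTruth)`` where the ground truth is
sufficient to compute the expected output of the downstream analysis stage in
closed form or by brute force. With ``noise_sd=0`` the output is an exact
deterministic function of the generator spec; identical seeds reproduce
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .stackio import ImageStack
from .trackmotion import Track

__all__ = [
    "Spot",
    "FlowSpec",
    "InwardTrackSpec",
    "GroundTruth",
    "make_invitro_movie",
    "make_tracks",
    "make_synapse_movie",
    "make_binding_curve",
    "make_speckles",
    "render_spots",
    "integer_shift",
]


@dataclass
class Spot:
    """A rendered condensate: integrated-Gaussian if ``radius_px`` is None,
    otherwise an extended blob (PSF-blurred disc of that radius)."""

    x: float
    y: float
    amplitude: float
    sigma_px: float = 0.46
    radius_px: float | None = None
    vx: float = 0.0  # px/frame
    vy: float = 0.0


@dataclass
class FlowSpec:
    """Velocity field advecting the actin texture.

    ``kind='uniform'``: constant (vx, vy) px/frame.
    ``kind='radial'``: contraction toward ``center`` at ``speed`` px/frame.
    """

    kind: str = "uniform"
    vx: float = 0.0
    vy: float = 0.0
    center: tuple[float, float] | None = None  # (x, y)
    speed: float = 0.0


@dataclass
class InwardTrackSpec:
    birth_frame: int
    birth_radius_px: float
    angle_rad: float
    radial_speed_px: float  # px/frame, inward
    wobble_sd_px: float = 0.0
    amplitude: float = 100.0
    sigma_px: float = 1.2
    death_frame: int | None = None  # condensate dissolves after this frame


@dataclass
class GroundTruth:
    """True counterparts of every quantity a downstream stage estimates."""

    positions: list[np.ndarray] | None = None     # per frame (n, 2) of (x, y)
    spots: list[Spot] | None = None
    drift: np.ndarray | None = None               # cumulative (dy, dx) per frame
    flow: FlowSpec | None = None
    motion_model: str | None = None
    D_um2_s: float | None = None
    v_um_s: float | None = None
    synapse_center: tuple[float, float] | None = None   # (x, y)
    synapse_radius_px: float | None = None
    csmac_radius_px: float | None = None
    decay_g: Callable[[float], float] | None = None
    bleach_k: float | None = None
    track_r: list[np.ndarray] | None = None       # per track, true r per frame
    track_frames: list[np.ndarray] | None = None
    track_xy: list[np.ndarray] | None = None      # per track (n, 2) of (x, y)
    spot_sigma_px: float | None = None
    hill: dict | None = None
    speckle_r: np.ndarray | None = None
    speckle_perpendicular: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


def _gauss_integral_1d(centers: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    # integral of a unit-height-normalised Gaussian over each unit pixel
    a = (centers - mu + 0.5) / (math.sqrt(2) * sigma)
    b = (centers - mu - 0.5) / (math.sqrt(2) * sigma)
    return 0.5 * (erf(a) - erf(b))


def render_spots(shape: tuple[int, int], spots: Sequence[Spot],
                 offset: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Render spots onto a zero image.

    Gaussian spots use exact per-pixel integration of a 2-D Gaussian whose
    peak pixel value equals ``amplitude``. Extended spots are a disc of
    ``radius_px`` blurred with a Gaussian of ``sigma_px``.
    """
    h, w = shape
    img = np.zeros((h, w), float)
    dy_off, dx_off = offset
    yy = np.arange(h, dtype=float)
    xx = np.arange(w, dtype=float)
    for s in spots:
        cx, cy = s.x + dx_off, s.y + dy_off
        if s.radius_px is None:
            if not (0 <= cx < w and 0 <= cy < h):
                raise ValueError(f"spot at ({s.x}, {s.y}) lies outside the frame")
            # normalise so the value integrated over the center pixel == amplitude
            gx = _gauss_integral_1d(xx, cx, s.sigma_px)
            gy = _gauss_integral_1d(yy, cy, s.sigma_px)
            peak = (_gauss_integral_1d(np.array([round(cx)]), cx, s.sigma_px)
                    * _gauss_integral_1d(np.array([round(cy)]), cy, s.sigma_px))[0]
            img += s.amplitude * np.outer(gy, gx) / peak
        else:
            if not (0 <= cx < w and 0 <= cy < h):
                raise ValueError(f"spot at ({s.x}, {s.y}) lies outside the frame")
            disc = ((xx[None, :] - cx) ** 2 + (yy[:, None] - cy) ** 2
                    <= s.radius_px ** 2).astype(float)
            img += s.amplitude * ndimage.gaussian_filter(disc, s.sigma_px)
    return img


def integer_shift(img: np.ndarray, dy: int, dx: int, cval: float = 0.0) -> np.ndarray:
    """Shift an image by whole pixels, filling exposed borders with ``cval``."""
    out = np.full_like(img, cval, dtype=float)
    h, w = img.shape
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ysrc = slice(max(-dy, 0), min(h - dy, h))
    xsrc = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = img[ysrc, xsrc]
    return out


def _filament_texture(size: int, rng: np.random.Generator,
                      n_segments: int | None = None,
                      seg_len: float = 4.0, psf_sigma: float = 0.7,
                      pad: int = 0) -> np.ndarray:
    """Random anti-aliased line segments blurred by a PSF-sized Gaussian.

    Short, sparse segments give the texture a narrow autocorrelation so that
    correlation-based velocimetry has an unambiguous peak.
    """
    from skimage.draw import line_aa

    n = size + 2 * pad
    if n_segments is None:
        n_segments = max(int(round(0.018 * n * n)), 30)
    img = np.zeros((n, n), float)
    for _ in range(n_segments):
        x0, y0 = rng.uniform(0, n, 2)
        theta = rng.uniform(0, 2 * np.pi)
        length = seg_len * (0.5 + rng.uniform())
        x1 = np.clip(x0 + length * np.cos(theta), 0, n - 1)
        y1 = np.clip(y0 + length * np.sin(theta), 0, n - 1)
        rr, cc, val = line_aa(int(round(y0)), int(round(x0)),
                              int(round(y1)), int(round(x1)))
        ok = (rr >= 0) & (rr < n) & (cc >= 0) & (cc < n)
        img[rr[ok], cc[ok]] += val[ok]
    return ndimage.gaussian_filter(img, psf_sigma)


def _advect_texture(texture: np.ndarray, pad: int, size: int, t: float,
                    flow: FlowSpec, drift_yx: tuple[int, int]) -> np.ndarray:
    """Sample the padded master texture at backward-mapped coordinates.

    Uniform flow: a point at x came from x - v*t. Radial contraction toward
    ``center``: a point at radius rho came from radius rho + speed*t along the
    same ray (pure inward advection at constant speed).
    """
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    dy, dx = drift_yx
    # undo drift first (drift shifts content by +(dy, dx))
    xs = xx - dx
    ys = yy - dy
    if flow.kind == "uniform":
        xs = xs - flow.vx * t
        ys = ys - flow.vy * t
    elif flow.kind == "radial":
        cx, cy = flow.center if flow.center is not None else ((size - 1) / 2,) * 2
        rx, ry = xs - cx, ys - cy
        rho = np.hypot(rx, ry)
        scale = np.where(rho > 1e-9, (rho + flow.speed * t) / np.maximum(rho, 1e-9), 1.0)
        xs = cx + rx * scale
        ys = cy + ry * scale
    else:
        raise ValueError(f"unknown flow kind {flow.kind!r}")
    return ndimage.map_coordinates(texture, [ys + pad, xs + pad], order=1, mode="constant")


def make_invitro_movie(
    n_frames: int,
    size_px: int,
    condensates: Sequence[Spot],
    actin_flow: FlowSpec | None = None,
    drift: Sequence[tuple[int, int]] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    bg_level: float = 10.0,
    bg_amplitude: float = 0.0,
    bg_sigma_px: float = 20.0,
    texture_kwargs: dict | None = None,
) -> tuple[ImageStack, ImageStack, GroundTruth]:
    """Two-channel in-vitro TIRF movie: condensate spots and an advected
    actin texture, both subject to the same per-frame integer stage drift.

    ``drift`` gives incremental integer (dy, dx) shifts per frame; cumulative
    shifts are applied (frame 0 unshifted when drift[0] == (0, 0)).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    flow = actin_flow or FlowSpec("uniform", 0.0, 0.0)
    if drift is None:
        inc = np.zeros((n_frames, 2), int)
    else:
        inc = np.asarray(drift, int)
        if inc.shape != (n_frames, 2):
            raise ValueError("drift must give one (dy, dx) pair per frame")
    cum = np.cumsum(inc, axis=0)

    # static inhomogeneous background, optionally smooth random
    bg = np.full((size_px, size_px), float(bg_level))
    if bg_amplitude > 0:
        rough = rng.standard_normal((size_px, size_px))
        smooth = ndimage.gaussian_filter(rough, bg_sigma_px)
        smooth -= smooth.min()
        if smooth.max() > 0:
            smooth /= smooth.max()
        bg = bg + bg_amplitude * smooth

    pad = int(np.abs(cum).max(initial=0) + abs(flow.vx) * n_frames
              + abs(flow.vy) * n_frames + flow.speed * n_frames + 8)
    texture = _filament_texture(size_px, rng, pad=pad,
                                **(texture_kwargs or {}))

    cond_frames = np.empty((n_frames, size_px, size_px))
    actin_frames = np.empty_like(cond_frames)
    positions = []
    noise_rng = np.random.default_rng(rng.integers(2**31))
    for t in range(n_frames):
        dy, dx = int(cum[t, 0]), int(cum[t, 1])
        spots_t = [
            Spot(s.x + s.vx * t, s.y + s.vy * t, s.amplitude, s.sigma_px,
                 s.radius_px) for s in condensates
        ]
        positions.append(np.array([[s.x, s.y] for s in spots_t]).reshape(-1, 2))
        cond = render_spots((size_px, size_px), spots_t, offset=(dy, dx))
        cond += integer_shift(bg, dy, dx, cval=bg_level)
        act = 50.0 * _advect_texture(texture, pad, size_px, t, flow, (dy, dx))
        if noise_sd > 0:
            cond = cond + noise_rng.normal(0, noise_sd, cond.shape)
            act = act + noise_rng.normal(0, noise_sd, act.shape)
        cond_frames[t] = np.clip(cond, 0, None)
        actin_frames[t] = np.clip(act, 0, None)

    truth = GroundTruth(positions=positions, spots=list(condensates),
                        drift=cum, flow=flow,
                        spot_sigma_px=condensates[0].sigma_px if condensates else None)
    cond_stack = ImageStack(cond_frames, channel_name="condensate")
    actin_stack = ImageStack(actin_frames, channel_name="actin")
    return cond_stack, actin_stack, truth


def make_tracks(
    n_tracks: int,
    n_frames: int,
    model: str,
    D: float = 0.0,
    v: float = 0.0,
    frame_interval_s: float = 15.0,
    confinement_radius_um: float = 0.5,
    seed: int = 0,
    origin_sd_um: float = 2.0,
) -> tuple[list[Track], GroundTruth]:
    """Simulate 2-D tracks (positions in µm) under a named motion model.

    ``brownian``: per-axis step variance 2·D·Δt. ``confined``: Brownian steps
    reflected at a circular boundary of ``confinement_radius_um`` around the
    origin. ``directed``: Brownian plus constant velocity ``v`` along a random
    fixed heading per track. ``immobile``: stationary.
    """
    if model not in {"brownian", "confined", "directed", "immobile"}:
        raise ValueError(f"unknown motion model {model!r}")
    if D < 0:
        raise ValueError("D must be >= 0")
    rng = np.random.default_rng(seed)
    step_sd = math.sqrt(2 * D * frame_interval_s)
    tracks: list[Track] = []
    for i in range(n_tracks):
        origin = rng.normal(0, origin_sd_um, 2)
        if model == "immobile":
            xy = np.tile(origin, (n_frames, 1))
        else:
            steps = rng.normal(0, step_sd, (n_frames - 1, 2))
            if model == "directed":
                heading = rng.uniform(0, 2 * np.pi)
                steps = steps + v * frame_interval_s * np.array(
                    [np.cos(heading), np.sin(heading)])
            xy = origin + np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
            if model == "confined":
                rel = xy - origin
                rho = np.hypot(rel[:, 0], rel[:, 1])
                over = rho > confinement_radius_um
                # radial reflection at the circular boundary
                rho_ref = np.where(over, 2 * confinement_radius_um - rho, rho)
                rho_ref = np.clip(rho_ref, 0, confinement_radius_um)
                with np.errstate(invalid="ignore", divide="ignore"):
                    unit = np.where(rho[:, None] > 0, rel / np.maximum(rho, 1e-300)[:, None], 0.0)
                xy = origin + unit * rho_ref[:, None]
        tracks.append(Track(frames=np.arange(n_frames),
                            x=xy[:, 0].copy(), y=xy[:, 1].copy(),
                            det_ids=np.full(n_frames, -1)))
    truth = GroundTruth(motion_model=model, D_um2_s=D, v_um_s=v)
    return tracks, truth


def make_synapse_movie(
    n_frames: int,
    synapse_radius_px: float,
    csmac_radius_px: float,
    tracks: Sequence[InwardTrackSpec] | int,
    decay_g: Callable[[float], float] = lambda r: 1.0,
    bleach_k: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    size_px: int | None = None,
    synapse_level: float = 60.0,
    csmac_level: float = 90.0,
    slave_bg_level: float = 40.0,
    frame_interval_s: float = 5.0,
) -> tuple[ImageStack, ImageStack, GroundTruth]:
    """Live-cell style movie: synapse disc + bright cSMAC + inward-moving
    condensates; the slave channel scales each condensate by ``decay_g`` of
    its normalized radial position and the whole channel by exp(−k·t).
    """
    if csmac_radius_px >= synapse_radius_px:
        raise ValueError("csmac_radius_px must be < synapse_radius_px")
    rng = np.random.default_rng(seed)
    size = size_px or int(math.ceil(2.6 * synapse_radius_px))
    cx = cy = (size - 1) / 2.0

    if isinstance(tracks, int):
        # births staggered over the movie; each condensate travels from near
        # the edge to well inside the actin threshold over its lifetime, then
        # dissolves (coalescence into the cSMAC)
        specs = []
        for _ in range(tracks):
            birth_r = rng.uniform(0.88, 0.97) * synapse_radius_px
            life = int(rng.integers(18, 28))
            birth_frame = int(rng.integers(0, max(1, n_frames - life)))
            target = rng.uniform(0.25, 0.45) * synapse_radius_px
            speed = (birth_r - target) / life
            specs.append(InwardTrackSpec(
                birth_frame=birth_frame, birth_radius_px=birth_r,
                angle_rad=rng.uniform(0, 2 * np.pi), radial_speed_px=speed,
                wobble_sd_px=0.2, amplitude=150.0, sigma_px=1.2,
                death_frame=birth_frame + life))
    else:
        specs = list(tracks)
    for s in specs:
        if s.birth_radius_px >= synapse_radius_px:
            raise ValueError("track birth radius lies outside the synapse")

    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    rho = np.hypot(xx - cx, yy - cy)
    synapse_disc = ndimage.gaussian_filter((rho <= synapse_radius_px).astype(float), 1.0)
    csmac_disc = ndimage.gaussian_filter((rho <= csmac_radius_px).astype(float), 1.0)

    track_xy: list[list] = [[] for _ in specs]
    track_frames: list[list] = [[] for _ in specs]
    track_r: list[list] = [[] for _ in specs]
    wobble = [rng.normal(0, s.wobble_sd_px, (n_frames, 2)) for s in specs]

    master = np.empty((n_frames, size, size))
    slave = np.empty_like(master)
    noise_rng = np.random.default_rng(rng.integers(2**31))
    for t in range(n_frames):
        m_spots, s_spots = [], []
        for i, s in enumerate(specs):
            if t < s.birth_frame:
                continue
            if s.death_frame is not None and t > s.death_frame:
                continue
            radius = s.birth_radius_px - s.radial_speed_px * (t - s.birth_frame)
            radius = max(radius, 0.02 * synapse_radius_px)
            x = cx + radius * math.cos(s.angle_rad) + wobble[i][t, 0]
            y = cy + radius * math.sin(s.angle_rad) + wobble[i][t, 1]
            r_norm = min(math.hypot(x - cx, y - cy) / synapse_radius_px, 1.0)
            track_xy[i].append((x, y))
            track_frames[i].append(t)
            track_r[i].append(r_norm)
            m_spots.append(Spot(x, y, s.amplitude, s.sigma_px))
            s_spots.append(Spot(x, y, s.amplitude * float(decay_g(r_norm)), s.sigma_px))
        m = synapse_level * synapse_disc + csmac_level * csmac_disc
        m += render_spots((size, size), m_spots)
        sl = slave_bg_level * synapse_disc + render_spots((size, size), s_spots)
        sl *= math.exp(-bleach_k * t)
        if noise_sd > 0:
            m = m + noise_rng.normal(0, noise_sd, m.shape)
            sl = sl + noise_rng.normal(0, noise_sd, sl.shape)
        master[t] = np.clip(m, 0, None)
        slave[t] = np.clip(sl, 0, None)

    truth = GroundTruth(
        synapse_center=(cx, cy), synapse_radius_px=synapse_radius_px,
        csmac_radius_px=csmac_radius_px, decay_g=decay_g, bleach_k=bleach_k,
        track_xy=[np.array(p).reshape(-1, 2) for p in track_xy],
        track_frames=[np.array(f, int) for f in track_frames],
        track_r=[np.array(r) for r in track_r],
        extra={"specs": specs, "size_px": size,
               "spot_sigma_px": specs[0].sigma_px if specs else 1.2},
    )
    return (ImageStack(master, frame_interval_s=frame_interval_s, channel_name="master"),
            ImageStack(slave, frame_interval_s=frame_interval_s, channel_name="slave"),
            truth)


def make_binding_curve(
    K_D: float,
    n: float,
    I_max: float,
    conc_grid: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Noisy Hill-shaped titration: I = I_max·c^n / (K_D^n + c^n) + noise."""
    import pandas as pd

    if K_D <= 0 or n <= 0:
        raise ValueError("K_D and n must be > 0")
    conc = np.asarray(conc_grid, float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    with np.errstate(divide="ignore", invalid="ignore"):
        intensity = I_max * conc**n / (K_D**n + conc**n)
    intensity = np.where(conc == 0, 0.0, intensity)
    if noise_sd > 0:
        intensity = intensity + rng.normal(0, noise_sd, conc.shape)
    table = pd.DataFrame({"concentration": conc, "intensity": intensity})
    truth = GroundTruth(hill={"K_D": K_D, "n": n, "I_max": I_max})
    return table, truth


def make_speckles(
    n: int,
    synapse_mask: np.ndarray,
    center: tuple[float, float],
    orientation_rule: Callable[[float], float],
    angle_noise_sd_deg: float = 0.0,
    seed: int = 0,
):
    """Point set of filament-orientation speckles inside a synapse mask.

    ``orientation_rule(r)`` returns the filament angle relative to the local
    edge tangent in degrees (90 = perpendicular to the edge, 0 = parallel).
    Absolute orientations are derived assuming the edge tangent is orthogonal
    to the ray from ``center`` (exact for a circular synapse). Returns an
    (n, 3) record array of (x, y, orientation_deg) plus ground truth.
    """
    if not synapse_mask.any():
        raise ValueError("synapse mask is empty")
    rng = np.random.default_rng(seed)
    ys, xs = np.nonzero(synapse_mask)
    idx = rng.integers(0, len(ys), n)
    # jitter inside the pixel to avoid gridded positions
    x = xs[idx] + rng.uniform(-0.4, 0.4, n)
    y = ys[idx] + rng.uniform(-0.4, 0.4, n)
    cxp, cyp = center
    radial_angle = np.degrees(np.arctan2(y - cyp, x - cxp))
    # maximum radius along each ray (circular-equivalent): use distance to
    # mask edge along the ray via the mask's EDT-free exact circular radius
    rho = np.hypot(x - cxp, y - cyp)
    # effective radius: for each ray, distance from center to last in-mask px
    r = np.empty(n)
    from .synapse import _ray_edge_distance

    for i in range(n):
        r[i] = min(rho[i] / _ray_edge_distance(synapse_mask, (cxp, cyp),
                                               (float(x[i]), float(y[i]))), 1.0)
    rel = np.array([orientation_rule(ri) for ri in r], float)
    if angle_noise_sd_deg > 0:
        rel = rel + rng.normal(0, angle_noise_sd_deg, n)
    # filament angle = edge tangent angle + rel; tangent = radial_angle + 90
    orientation = (radial_angle + 90.0 + rel) % 180.0
    speckles = np.rec.fromarrays([x, y, orientation],
                                 names="x,y,orientation_deg")
    truth = GroundTruth(speckle_r=r,
                        speckle_perpendicular=np.abs(((rel + 90) % 180) - 90) > 45.0)
    return speckles, truth
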