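"""Image-stack and table I/O, shared primitive types, and run configuration.

Coordinate convention used throughout the package: (row=y, col=x), 0-based,
pixel centers at integer coordinates. Sub-pixel positions are reported in the
same frame. Physical units attach to the stack: ``pixel_size_um`` (µm per
pixel) and ``frame_interval_s`` (seconds between frames), so that
``distance_px * pixel_size_um`` is a distance in µm (e.g. 16 px at the default
0.16 µm/px is 2.56 µm).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("condmotion")

__all__ = [
    "ImageStack",
    "RunConfig",
    "read_stack",
    "write_stack",
    "write_table",
    "read_table",
]

#: default pixel size, µm per pixel (TIRF camera scale: 16 px = 2.56 µm)
DEFAULT_PIXEL_SIZE_UM = 0.16
#: default frame intervals, seconds
DEFAULT_INTERVAL_STEADY_S = 15.0
DEFAULT_INTERVAL_CONTRACTION_S = 5.0


@dataclass
class ImageStack:
    """A time-ordered single-channel movie.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Non-negative intensities, camera background already subtracted.
    pixel_size_um : float
        Physical pixel size in µm per pixel, > 0.
    frame_interval_s : float
        Time between consecutive frames in seconds, > 0.
    channel_name : str
        Free-form channel label (e.g. ``"LAT"``, ``"actin"``).
    """

    frames: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_s: float = DEFAULT_INTERVAL_STEADY_S
    channel_name: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be a (time, y, x) array, got ndim={self.frames.ndim}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite values")
        if self.frames.size and self.frames.min() < 0:
            raise ValueError("frames contain negative intensities")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Frame shape (height, width)."""
        return self.frames.shape[1:]

    def px_to_um(self, px: float | np.ndarray) -> float | np.ndarray:
        return px * self.pixel_size_um

    def subtract_camera_background(self, level: float) -> "ImageStack":
        """Return a copy with a scalar camera background subtracted, clamped at 0."""
        return ImageStack(
            np.clip(self.frames.astype(float) - float(level), 0.0, None),
            self.pixel_size_um,
            self.frame_interval_s,
            self.channel_name,
        )


@dataclass
class RunConfig:
    """Named parameters for every pipeline stage, with defaults.

    Serializes losslessly to YAML. Every stochastic stage draws its seed from
    here so a run is reproducible from the config file alone.
    """

    seed: int = 0
    camera_background: float = 0.0
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_s: float = DEFAULT_INTERVAL_STEADY_S
    # detection
    psf_sigma_px: float = 0.46
    bg_sigma_px: float = 10.0
    noise_sigma_px: float = 1.0
    maxima_threshold_k: float = 5.0
    min_isolated_for_ratio: int = 20
    fallback_ratio_threshold: float = 2.0
    drift_max_shift_px: int = 10
    # tracking / motion
    search_radius_px: float = 5.0
    gap_window_frames: int = 3
    allow_merge_split: bool = True
    mss_max_lag_fraction: float = 0.25
    min_track_frames: int = 5
    # STICS
    stics_window_px: int = 16
    stics_step_px: int = 8
    stics_shift_frames: int = 3
    # synapse / composition
    smooth_sigma_px: float = 2.0
    n_profile_lines: int = 8
    position_threshold: float = 0.6
    min_anisotropy: float = 3.0
    radial_bin_width: float = 0.1
    min_bin_n: int = 10
    alpha_total: float = 0.05
    aggregate_perimeter_px: int = 2
    # subsampled tests
    subsample_n: int = 500
    subsample_reps: int = 100
    subsample_trigger_n: int = 1000

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def log_stage(self, stage: str, **params: Any) -> None:
        logger.info("stage=%s seed=%d %s", stage, self.seed,
                    " ".join(f"{k}={v}" for k, v in params.items()))


def read_stack(
    path: str | Path,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    frame_interval_s: float = DEFAULT_INTERVAL_STEADY_S,
    channel_name: str = "",
    camera_background: float = 0.0,
) -> ImageStack:
    """Read a multi-page TIFF as an ImageStack (one page per time point).

    Camera background, a single scalar per movie, is subtracted on load and
    intensities clamped at zero.
    """
    path = Path(path)
    try:
        frames = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image stack {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError(f"{path}: expected 2-D pages, got array of ndim {frames.ndim}")
    frames = frames.astype(float)
    if camera_background:
        frames = np.clip(frames - float(camera_background), 0.0, None)
    return ImageStack(frames, pixel_size_um, frame_interval_s, channel_name)


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write an ImageStack to a multi-page TIFF, one page per frame.

    Integer-valued inputs round-trip losslessly (stored as the smallest
    sufficient unsigned integer type); other inputs are stored as float32.
    """
    path = Path(path)
    frames = stack.frames
    if np.allclose(frames, np.round(frames)) and frames.size:
        ints = np.round(frames).astype(np.int64)
        if ints.max(initial=0) <= np.iinfo(np.uint16).max:
            frames = ints.astype(np.uint16)
        else:
            frames = ints.astype(np.uint32)
    else:
        frames = frames.astype(np.float32)
    try:
        tifffile.imwrite(path, frames, photometric="minisblack")
    except OSError as exc:
        raise OSError(f"cannot write image stack {path}: {exc}") from exc
    return path


def write_table(records: Sequence[Mapping[str, Any]] | pd.DataFrame,
                path: str | Path) -> Path:
    """Write uniform keyed records as a UTF-8 CSV with a header row."""
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        keys = None
        for rec in records:
            if keys is None:
                keys = list(rec.keys())
            elif list(rec.keys()) != keys:
                raise ValueError(
                    f"heterogeneous record keys: {list(rec.keys())} != {keys}"
                )
        df = pd.DataFrame.from_records(records, columns=keys)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path)
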