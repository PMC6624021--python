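"""Actin enrichment at condensates (point-to-continuum colocalization).

Enrichment for a movie is the ratio of actin intensity within condensates to
actin intensity outside condensates, averaged over all condensates, at the
last frame of the movie.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .detect import CondensateSet
from .stackio import ImageStack

__all__ = ["actin_enrichment"]


def actin_enrichment(
    actin: ImageStack | np.ndarray,
    dets: CondensateSet,
    frame_index: int | None = None,
    exclusion_dilation_px: int = 0,
) -> float:
    """Mean over condensates of (mean actin inside the condensate mask) /
    (mean actin over all non-condensate pixels of the frame).

    ``frame_index`` defaults to the last frame. ``exclusion_dilation_px``
    optionally removes a guard zone around condensates from the "outside"
    pool (default 0: outside = every pixel not in any condensate mask).
    """
    frames = actin.frames if isinstance(actin, ImageStack) else np.asarray(actin)
    if frames.ndim == 2:
        frames = frames[None]
    t = frames.shape[0] - 1 if frame_index is None else int(frame_index)
    frame = frames[t].astype(float)

    labels = dets.labels[t]
    if labels.shape != frame.shape:
        raise ValueError("actin frame and detection labels differ in shape")
    inside_any = labels > 0
    if not inside_any.any():
        raise ValueError(f"no condensates detected in frame {t}")

    excluded = inside_any
    if exclusion_dilation_px > 0:
        excluded = ndimage.binary_dilation(
            inside_any, iterations=exclusion_dilation_px)
    outside = ~excluded
    if not outside.any():
        raise ValueError("no outside pixels remain for normalization")
    outside_mean = float(frame[outside].mean())
    if outside_mean == 0:
        raise ValueError("outside actin mean is zero; ratio undefined")

    ratios = []
    for lab in np.unique(labels[labels > 0]):
        mask = labels == lab
        ratios.append(float(frame[mask].mean()) / outside_mean)
    return float(np.mean(ratios))
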