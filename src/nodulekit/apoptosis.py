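"""Pixel-level apoptosis co-localization from paired PI / apoTRACE images.

Each channel is background-subtracted and Otsu-thresholded on its own;
the apoptotic map is the bitwise AND of the two binary masks, and the
apoptotic fraction is taken over the PI-positive (dead) pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import EmptyWellError, UnthresholdableError
from .morphometry import otsu_threshold
from .viability import subtract_background

__all__ = ["ApoptosisResult", "apoptosis_map"]


@dataclass
class ApoptosisResult:
    pi_mask: np.ndarray
    apotrace_mask: np.ndarray
    apoptotic_mask: np.ndarray
    apoptotic_fraction: float


def apoptosis_map(
    pi: np.ndarray,
    apotrace: np.ndarray,
    *,
    min_object_px: int = 0,
) -> ApoptosisResult:
    """Compute the binary apoptotic-cell map of a PI / apoTRACE pair.

    Parameters
    ----------
    pi, apotrace : ndarray
        Same-shape intensity images of the dead-cell and apoptosis stains.
    min_object_px : int, optional
        If positive, remove connected objects smaller than this from each
        thresholded mask before combining (off by default).

    Raises
    ------
    EmptyWellError
        If the PI mask is empty, leaving the fraction undefined.
    """
    if pi.shape != apotrace.shape:
        raise ValueError("pi and apotrace must share a shape")
    pi_mask = _threshold_channel(pi, min_object_px)
    apo_mask = _threshold_channel(apotrace, min_object_px)
    apoptotic = pi_mask & apo_mask
    n_pi = int(pi_mask.sum())
    if n_pi == 0:
        raise EmptyWellError("PI mask is empty; apoptotic fraction undefined")
    return ApoptosisResult(
        pi_mask=pi_mask,
        apotrace_mask=apo_mask,
        apoptotic_mask=apoptotic,
        apoptotic_fraction=float(apoptotic.sum() / n_pi),
    )


def _threshold_channel(channel: np.ndarray, min_object_px: int) -> np.ndarray:
    sub = subtract_background(channel)
    if not np.any(sub > 0):  # stain entirely absent: nothing to threshold
        return np.zeros(channel.shape, dtype=bool)
    try:
        mask = sub > otsu_threshold(sub)
    except UnthresholdableError:  # no contrast left after subtraction
        return np.zeros(channel.shape, dtype=bool)
    if min_object_px > 0:
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
        if n:
            sizes = np.bincount(labels.ravel())
            mask = sizes[labels] >= min_object_px
            mask &= labels > 0
    return mask
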