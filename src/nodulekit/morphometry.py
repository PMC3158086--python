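"""Per-nodule segmentation, morphometry, and size-response fits.

Segmentation follows the assay recipe exactly: background-subtract each
fluorescence channel, sum them into a single intensity image, Otsu
threshold, label connected components (8-connectivity), and discard
debris below a minimum equivalent diameter. The binary mask is then
applied back to the background-subtracted channels for per-nodule
intensity accounting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import OutOfRangeError, UnthresholdableError
from .viability import subtract_background

__all__ = [
    "NoduleRecord",
    "PowerLawFit",
    "PenetrationDepthResult",
    "otsu_threshold",
    "segment_nodules",
    "nodule_metrics",
    "fit_powerlaw",
    "penetration_depth",
    "records_to_frame",
]

#: epsilon (intensity units) used for live:dead ratios with zero dead signal
RATIO_EPSILON = 1.0


@dataclass
class NoduleRecord:
    """Morphometry and viability metrics of one segmented nodule."""

    label: int
    area: float  # um^2
    equivalent_diameter: float  # um
    volume: float  # um^3
    live_sum: float
    dead_sum: float
    live_dead_ratio: float
    viability: float
    centroid_xy: tuple[float, float]  # um
    ratio_clipped: bool = False  # True when dead_sum was zero


@dataclass(frozen=True)
class PowerLawFit:
    prefactor: float
    exponent: float
    r_squared: float
    n: int


@dataclass(frozen=True)
class PenetrationDepthResult:
    depth: float  # um
    full_penetration: bool
    boundary_intensity: float
    profile_depths: np.ndarray  # um
    profile_means: np.ndarray


def otsu_threshold(values: np.ndarray | tuple[np.ndarray, np.ndarray], bins: int = 256) -> float:
    """Otsu's threshold: the histogram cut minimizing within-class variance.

    Parameters
    ----------
    values : ndarray or (counts, bin_centers)
        Either an intensity grid (histogrammed into ``bins`` bins over its
        observed range) or a precomputed histogram.
    bins : int, optional
        Number of histogram bins when a grid is given.

    Returns
    -------
    float
        The bin-center threshold ``t``; the low class is ``values <= t``.
        Ties are broken toward the lowest threshold.

    Raises
    ------
    UnthresholdableError
        For constant input.
    """
    if isinstance(values, tuple):
        counts = np.asarray(values[0], dtype=float)
        centers = np.asarray(values[1], dtype=float)
    else:
        arr = np.asarray(values, dtype=float).ravel()
        vmin, vmax = float(arr.min()), float(arr.max())
        if vmax - vmin <= np.spacing(max(abs(vmin), abs(vmax))) * bins:
            raise UnthresholdableError("constant input has no threshold")
        counts, edges = np.histogram(arr, bins=bins, range=(vmin, vmax))
        counts = counts.astype(float)
        centers = 0.5 * (edges[:-1] + edges[1:])

    if np.count_nonzero(counts) < 2:
        raise UnthresholdableError("histogram has fewer than two occupied bins")

    total = counts.sum()
    w0 = np.cumsum(counts)
    m = np.cumsum(counts * centers)
    m2 = np.cumsum(counts * centers**2)
    w1 = total - w0
    # within-class variance for a cut after each bin k (class 0 = bins <= k)
    with np.errstate(divide="ignore", invalid="ignore"):
        var0 = m2 - m**2 / np.where(w0 > 0, w0, np.nan)
        var1 = (m2[-1] - m2) - (m[-1] - m) ** 2 / np.where(w1 > 0, w1, np.nan)
    wcv = (np.nan_to_num(var0, nan=0.0) + np.nan_to_num(var1, nan=0.0))[:-1]
    valid = (w0[:-1] > 0) & (w1[:-1] > 0)
    wcv[~valid] = np.inf
    k = int(np.argmin(wcv))  # argmin takes the first (lowest) minimizer
    return float(centers[k])


def segment_nodules(
    live: np.ndarray,
    dead: np.ndarray,
    pixel_size: float,
    min_diameter: float = 30.0,
) -> np.ndarray:
    """Segment nodules from a live/dead channel pair.

    Channels are background-subtracted, summed, Otsu-thresholded and
    labelled with 8-connectivity; components whose equivalent diameter is
    below ``min_diameter`` (um) are dropped and labels are compacted.

    Returns
    -------
    ndarray of int32
        Label map, background 0.
    """
    if live.shape != dead.shape:
        raise ValueError("live and dead channels must share a shape")
    intensity = subtract_background(live) + subtract_background(dead)
    thr = otsu_threshold(intensity)
    binary = intensity > thr
    labels, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return labels.astype(np.int32)
    areas_px = np.bincount(labels.ravel())[1:]
    eq_diam = 2.0 * np.sqrt(areas_px * pixel_size**2 / np.pi)
    keep = np.flatnonzero(eq_diam >= min_diameter) + 1
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1, dtype=np.int32)
    return remap[labels]


def _border_labels(labels: np.ndarray) -> set[int]:
    edge = np.concatenate([labels[0], labels[-1], labels[:, 0], labels[:, -1]])
    return set(np.unique(edge[edge > 0]).tolist())


def nodule_metrics(
    labels: np.ndarray,
    live: np.ndarray,
    dead: np.ndarray,
    pixel_size: float,
) -> tuple[list[NoduleRecord], list[int]]:
    """Per-nodule morphometry and viability from a label map.

    Nodules touching the image border are excluded from the records
    (their truncated geometry would corrupt diameter and volume) and
    returned separately as a list of flagged labels.

    Returns
    -------
    (records, border_labels)
    """
    if labels.shape != live.shape or labels.shape != dead.shape:
        raise ValueError("label map and channels must share a shape")
    live_sub = subtract_background(live)
    dead_sub = subtract_background(dead)
    present = np.unique(labels[labels > 0])
    border = _border_labels(labels)

    areas_px = np.bincount(labels.ravel(), minlength=int(labels.max()) + 1)
    live_sums = ndimage.sum_labels(live_sub, labels, index=present)
    dead_sums = ndimage.sum_labels(dead_sub, labels, index=present)
    centroids = ndimage.center_of_mass(np.ones_like(labels), labels, index=present)

    records: list[NoduleRecord] = []
    for lab, ls, ds, (cy, cx) in zip(present, live_sums, dead_sums, centroids):
        if int(lab) in border:
            continue
        area = areas_px[lab] * pixel_size**2
        eqd = 2.0 * np.sqrt(area / np.pi)
        volume = np.pi / 6.0 * eqd**3
        clipped = ds <= 0.0
        ratio = ls / (ds + RATIO_EPSILON) if clipped else ls / ds
        viability = ls / (ls + ds) if (ls + ds) > 0 else float("nan")
        records.append(
            NoduleRecord(
                label=int(lab),
                area=float(area),
                equivalent_diameter=float(eqd),
                volume=float(volume),
                live_sum=float(ls),
                dead_sum=float(ds),
                live_dead_ratio=float(ratio),
                viability=float(viability),
                centroid_xy=((cx + 0.5) * pixel_size, (cy + 0.5) * pixel_size),
                ratio_clipped=bool(clipped),
            )
        )
    return records, sorted(border)


def fit_powerlaw(volumes: np.ndarray, ratios: np.ndarray) -> PowerLawFit:
    """Ordinary least squares of log(ratio) on log(volume).

    Returns the fitted ``ratio = prefactor * volume**exponent`` with the
    coefficient of determination of the log-log regression.
    """
    v = np.asarray(volumes, dtype=float)
    r = np.asarray(ratios, dtype=float)
    if v.size != r.size:
        raise ValueError("volumes and ratios must align")
    if v.size < 3:
        raise ValueError("need at least three points")
    if np.any(v <= 0) or np.any(r <= 0):
        raise ValueError("log-log fit requires strictly positive values")
    x, y = np.log(v), np.log(r)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(
        prefactor=float(np.exp(intercept)),
        exponent=float(slope),
        r_squared=float(r2),
        n=int(v.size),
    )


def penetration_depth(
    uptake: np.ndarray,
    nodule_mask: np.ndarray,
    pixel_size: float,
) -> PenetrationDepthResult:
    """Depth at which the boundary-referenced radial profile falls to 1/e.

    The mean background-subtracted intensity is profiled over one-pixel
    distance shells from the mask boundary (Euclidean distance
    transform); the returned depth is where the profile first drops below
    ``1/e`` of the boundary-shell value, linearly interpolated between
    shells. If the profile never falls that far the nodule is flagged as
    fully penetrated and the maximum depth (~ the radius) is returned.
    """
    if uptake.shape != nodule_mask.shape:
        raise ValueError("uptake and mask must share a shape")
    mask = nodule_mask.astype(bool)
    if not mask.any():
        raise ValueError("empty nodule mask")
    n_regions = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))[1]
    if n_regions != 1:
        raise ValueError("mask must contain a single connected nodule")

    intensity = subtract_background(uptake)
    edt = ndimage.distance_transform_edt(mask)
    shell_idx = np.ceil(edt[mask]).astype(int) - 1  # shell k: edt in (k, k+1]
    vals = intensity[mask]
    n_shells = shell_idx.max() + 1
    sums = np.bincount(shell_idx, weights=vals, minlength=n_shells)
    counts = np.bincount(shell_idx, minlength=n_shells)
    dist_sums = np.bincount(shell_idx, weights=edt[mask], minlength=n_shells)
    means = sums / counts
    # shell depth referenced to the true boundary, half a pixel outside
    # the outermost pixel centers
    depths = (dist_sums / counts - 0.5) * pixel_size

    boundary = means[0]
    target = boundary / np.e
    if not np.any(means < target):
        return PenetrationDepthResult(
            depth=float(depths[-1]),
            full_penetration=True,
            boundary_intensity=float(boundary),
            profile_depths=depths,
            profile_means=means,
        )
    j = int(np.argmax(means < target))  # first shell below target
    if j == 0:
        depth = float(depths[0])
    else:
        d0, d1 = depths[j - 1], depths[j]
        m0, m1 = means[j - 1], means[j]
        depth = float(d0 + (m0 - target) / (m0 - m1) * (d1 - d0))
    return PenetrationDepthResult(
        depth=depth,
        full_penetration=False,
        boundary_intensity=float(boundary),
        profile_depths=depths,
        profile_means=means,
    )


def records_to_frame(records: list[NoduleRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = vars(rec).copy()
        cx, cy = row.pop("centroid_xy")
        row["centroid_x"] = cx
        row["centroid_y"] = cy
        rows.append(row)
    return pd.DataFrame(rows)
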