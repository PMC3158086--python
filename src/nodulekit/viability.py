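"""Well-level viability scoring, normalization, and significance tests.

The assay works on intensity totals: each fluorescence channel is
background-subtracted using the modal intensity of its histogram, clipped
at zero, and summed; well viability is the live total divided by the sum
of the live and dead totals, normalized afterwards to the mean of the
no-treatment (NT) control wells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateInputError,
    EmptyWellError,
    MissingControlError,
    OutOfRangeError,
)

__all__ = [
    "WellRecord",
    "TTestResult",
    "estimate_background",
    "well_viability",
    "normalize_viability",
    "student_t_test",
    "estimate_ld50",
    "summarize_irradiance_series",
    "wells_to_frame",
]


@dataclass
class WellRecord:
    well_id: str
    condition: str = "treated"
    dose: float = 0.0
    irradiance: float = 0.0
    atmosphere: str = "normoxic"
    live_total: float = float("nan")
    dead_total: float = float("nan")
    viability: float = float("nan")
    normalized_viability: float = float("nan")


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float


def _hist_mode(values: np.ndarray, bins: int = 256) -> tuple[float, float]:
    """Return (modal bin center, bin width) of a 1D histogram."""
    vmin = float(values.min())
    vmax = float(values.max())
    # treat a range too narrow to split into distinct bins as constant
    if vmax - vmin <= np.spacing(max(abs(vmin), abs(vmax))) * bins:
        return vmin, 0.0
    counts, edges = np.histogram(values, bins=bins, range=(vmin, vmax))
    k = int(np.argmax(counts))
    width = edges[1] - edges[0]
    return float(0.5 * (edges[k] + edges[k + 1])), float(width)


def estimate_background(channel: np.ndarray) -> float:
    """Modal intensity of the channel histogram.

    A 256-bin histogram over the observed range locates the background
    peak; a second 256-bin pass over the modal bin's neighbourhood refines
    the estimate so it is not limited by the coarse bin width when the
    image has a long bright tail.
    """
    values = np.asarray(channel, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("channel is empty")
    mode, width = _hist_mode(values)
    if width == 0.0:
        return mode
    sub = values[(values >= mode - 2 * width) & (values <= mode + 2 * width)]
    if sub.size == 0:
        return mode
    fine_mode, _ = _hist_mode(sub)
    return fine_mode


def subtract_background(channel: np.ndarray) -> np.ndarray:
    """Background-subtract a channel and clip negatives at zero."""
    return np.clip(np.asarray(channel, dtype=float) - estimate_background(channel), 0.0, None)


def well_viability(live: np.ndarray, dead: np.ndarray) -> tuple[float, float, float]:
    """Compute (live_total, dead_total, viability) for one well.

    Both channels are background-subtracted and clipped before summation.

    Raises
    ------
    EmptyWellError
        If both totals vanish after subtraction.
    """
    if live.shape != dead.shape:
        raise ValueError("live and dead channels must share a shape")
    live_total = float(subtract_background(live).sum())
    dead_total = float(subtract_background(dead).sum())
    denom = live_total + dead_total
    if denom == 0.0:
        raise EmptyWellError("no signal in either channel after background subtraction")
    return live_total, dead_total, live_total / denom


def normalize_viability(wells: list[WellRecord]) -> list[WellRecord]:
    """Normalize every well's viability to the mean NT-control viability.

    Mutates and returns the input records. Raises ``MissingControlError``
    when no NT wells are present.
    """
    nt = [w.viability for w in wells if w.condition == "NT"]
    if not nt:
        raise MissingControlError("no NT control wells to normalize against")
    reference = float(np.mean(nt))
    for w in wells:
        w.normalized_viability = w.viability / reference
    return wells


def student_t_test(
    group_a: np.ndarray, group_b: np.ndarray, *, welch: bool = False
) -> TTestResult:
    """Two-sample Student's t-test (pooled variance by default).

    ``welch=True`` switches to the unequal-variance form. The two-sided
    p-value comes from the t distribution with ``n_a + n_b - 2`` degrees
    of freedom in the pooled case.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("each group needs at least two values")
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        raise DegenerateInputError("zero pooled variance")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    dof = float(res.df) if welch else float(a.size + b.size - 2)
    return TTestResult(
        t_statistic=float(res.statistic),
        degrees_of_freedom=dof,
        p_value=float(res.pvalue),
    )


def estimate_ld50(doses: np.ndarray, normalized_viabilities: np.ndarray) -> float:
    """Dose at which mean normalized viability first crosses 0.5.

    Per-dose means are linearly interpolated between adjacent doses; when
    several crossings exist the lowest-dose one is returned.

    Raises
    ------
    OutOfRangeError
        If the mean-viability curve never brackets 0.5.
    """
    doses = np.asarray(doses, dtype=float)
    vals = np.asarray(normalized_viabilities, dtype=float)
    if doses.shape != vals.shape:
        raise ValueError("doses and viabilities must align")
    frame = pd.DataFrame({"dose": doses, "v": vals}).groupby("dose")["v"].mean()
    if len(frame) < 2:
        raise ValueError("need at least two distinct doses")
    d = frame.index.to_numpy()
    v = frame.to_numpy()
    for i in range(len(d) - 1):
        lo, hi = v[i], v[i + 1]
        if lo == 0.5:
            return float(d[i])
        if (lo - 0.5) * (hi - 0.5) <= 0.0 and lo != hi:
            return float(d[i] + (lo - 0.5) / (lo - hi) * (d[i + 1] - d[i]))
    if v[-1] == 0.5:
        return float(d[-1])
    raise OutOfRangeError("mean viability never crosses 0.5 over the dose range")


def summarize_irradiance_series(
    wells: list[WellRecord], *, tolerance: float = 0.02
) -> tuple[pd.DataFrame, float, float]:
    """Summarize a fixed-fluence irradiance series.

    Returns a per-irradiance table of mean/sd/n of normalized viability,
    the irradiance with the lowest mean (maximum killing), and the
    plateau onset: the smallest irradiance whose mean lies within
    ``tolerance`` of the highest-irradiance mean.
    """
    treated = [w for w in wells if w.condition == "treated"]
    if len({w.irradiance for w in treated}) < 3:
        raise ValueError("need at least three irradiance levels")
    frame = (
        pd.DataFrame(
            {
                "irradiance": [w.irradiance for w in treated],
                "normalized_viability": [w.normalized_viability for w in treated],
            }
        )
        .groupby("irradiance")["normalized_viability"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .sort_values("irradiance", ignore_index=True)
    )
    argmin_irr = float(frame.loc[frame["mean"].idxmin(), "irradiance"])
    top_mean = float(frame["mean"].iloc[-1])
    within = frame[np.abs(frame["mean"] - top_mean) <= tolerance]
    plateau_irr = float(within["irradiance"].iloc[0])
    return frame, argmin_irr, plateau_irr


def wells_to_frame(wells: list[WellRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(w) for w in wells])
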