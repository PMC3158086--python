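"""Nodule field geometry: specs, conditions, and seeded field sampling."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import PackingError

__all__ = ["NoduleSpec", "CultureField", "sample_nodule_field"]

CONDITIONS = ("NT", "LO", "EO", "treated")
ATMOSPHERES = ("normoxic", "hypoxic")
AGENTS = ("EtNBS", "BPD", "carboplatin", "none")

#: minimum clear surface-to-surface gap between nodules, um
_MIN_GAP = 6.0
#: clearance between a nodule surface and the field border, um
_BORDER_PAD = 10.0


@dataclass(frozen=True)
class NoduleSpec:
    """Ground-truth geometry of a single circular nodule section.

    ``core_fraction`` is the radius fraction of the acidic/hypoxic core;
    the annulus outside it is the oxygenated periphery.
    """

    id: int
    center_xy: tuple[float, float]  # um
    diameter: float  # um
    core_fraction: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if not 0.0 <= self.core_fraction <= 1.0:
            raise ValueError("core_fraction must be in [0, 1]")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass
class CultureField:
    """A set of non-overlapping nodules plus the treatment condition.

    The control conditions carry their usual meaning: NT received neither
    photosensitizer nor light, LO light only, EO photosensitizer only.
    Only ``condition == 'treated'`` enables a dose effect.
    """

    nodules: list[NoduleSpec] = field(default_factory=list)
    condition: str = "NT"
    dose: float = 0.0  # J/cm^2
    irradiance: float = 0.0  # mW/cm^2
    atmosphere: str = "normoxic"
    agent: str = "none"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.atmosphere not in ATMOSPHERES:
            raise ValueError(f"atmosphere must be one of {ATMOSPHERES}")
        if self.agent not in AGENTS:
            raise ValueError(f"agent must be one of {AGENTS}")
        if self.dose < 0 or self.irradiance < 0:
            raise ValueError("dose and irradiance must be non-negative")

    @property
    def dose_effect_enabled(self) -> bool:
        return self.condition == "treated"


def core_fraction_for_diameter(diameter: float, rim_depth: float) -> float:
    """Radius fraction of the core for a nodule of given diameter.

    The core is the region deeper than ``rim_depth`` um from the surface
    (nodules thinner than twice the rim have no core), so larger nodules
    bury a growing share of their cells in the core.
    """
    return max(0.0, 1.0 - 2.0 * rim_depth / diameter)


def sample_nodule_field(
    n: int,
    diameter_range: tuple[float, float],
    field_size: tuple[float, float],
    seed: int,
    *,
    rim_depth: float = 100.0,
    core_fraction: float | None = None,
    max_attempts: int = 5000,
) -> list[NoduleSpec]:
    """Sample ``n`` non-overlapping nodules with log-uniform diameters.

    Diameters are stratified log-uniform over ``diameter_range`` (one draw
    per equal log-width stratum, randomly jittered and permuted), which
    keeps the marginal law log-uniform while stabilizing the per-field
    size mix. Centers are rejection-sampled, largest nodule first, until
    all pairwise surface gaps exceed a small clearance.

    Parameters
    ----------
    n : int
        Number of nodules; zero yields an empty list.
    diameter_range : (float, float)
        Inclusive diameter bounds in micrometres.
    field_size : (float, float)
        Field extent (width, height) in micrometres.
    seed : int
        Seeds all randomness; identical inputs give identical specs.
    rim_depth : float, optional
        Oxygenated rim thickness used to derive each nodule's
        ``core_fraction``; ignored when ``core_fraction`` is given.
    core_fraction : float, optional
        Constant core radius fraction overriding the rim rule.
    max_attempts : int, optional
        Rejection-sampling budget per nodule before the field is declared
        infeasibly crowded.

    Raises
    ------
    PackingError
        If a nodule cannot be placed within ``max_attempts`` attempts.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n == 0:
        return []
    dmin, dmax = float(diameter_range[0]), float(diameter_range[1])
    if not 0 < dmin <= dmax:
        raise ValueError("invalid diameter_range")
    width, height = float(field_size[0]), float(field_size[1])
    if dmax + 2 * _BORDER_PAD > min(width, height):
        raise ValueError("diameter_range does not fit in the field")

    rng = np.random.default_rng(seed)
    strata = (rng.permutation(n) + rng.random(n)) / n
    diameters = dmin * (dmax / dmin) ** strata

    order = np.argsort(diameters)[::-1]  # place large nodules first
    placed_xy: list[tuple[float, float]] = []
    placed_r: list[float] = []
    placed_d: list[float] = []
    for idx in order:
        r = diameters[idx] / 2.0
        lo_x, hi_x = r + _BORDER_PAD, width - r - _BORDER_PAD
        lo_y, hi_y = r + _BORDER_PAD, height - r - _BORDER_PAD
        for attempt in range(max_attempts):
            x = rng.uniform(lo_x, hi_x)
            y = rng.uniform(lo_y, hi_y)
            ok = all(
                np.hypot(x - px, y - py) > r + pr + _MIN_GAP
                for (px, py), pr in zip(placed_xy, placed_r)
            )
            if ok:
                placed_xy.append((x, y))
                placed_r.append(r)
                placed_d.append(float(diameters[idx]))
                break
        else:
            raise PackingError(
                f"could not place nodule of diameter {diameters[idx]:.0f} um "
                f"after {max_attempts} attempts; field too crowded"
            )

    specs = []
    child_seeds = rng.integers(0, 2**31 - 1, size=n)
    for i, ((x, y), d) in enumerate(zip(placed_xy, placed_d)):
        cf = (
            core_fraction
            if core_fraction is not None
            else core_fraction_for_diameter(d, rim_depth)
        )
        specs.append(
            NoduleSpec(
                id=i + 1,
                center_xy=(x, y),
                diameter=d,
                core_fraction=cf,
                seed=int(child_seeds[i]),
            )
        )
    return specs
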