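"""Rasterization of nodule fields into noisy multichannel imagery.

All render functions share one camera model: the noise-free signal is
Poisson-resampled at ``photon_scale`` counts per intensity unit, a
constant background offset is added, and Gaussian read noise is applied
last. Every function is deterministic given its seed and returns ground
truth (label maps, per-nodule survival, masks) alongside the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import NodulekitError
from ..image import CultureImage
from .diffusion import sphere_diffusion_concentration
from .dose import DoseResponseModel, survival_probability
from .geometry import CultureField, NoduleSpec
from .spectral import PhProfile

__all__ = [
    "NoiseModel",
    "NoduleTruth",
    "LiveDeadRender",
    "UptakeRender",
    "ApoptosisRender",
    "apply_noise",
    "render_livedead",
    "render_uptake",
    "render_apoptosis_pair",
]

UPTAKE_PROFILES = ("peripheral_decay", "core_concentrating")


@dataclass(frozen=True)
class NoiseModel:
    """Poisson + Gaussian camera noise with a constant background offset."""

    photon_scale: float = 0.25
    read_sigma: float = 5.0
    background_level: float = 200.0

    def __post_init__(self) -> None:
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be positive")
        if self.read_sigma < 0 or self.background_level < 0:
            raise ValueError("read_sigma and background_level must be >= 0")


def apply_noise(
    signal: np.ndarray,
    noise: NoiseModel | None,
    rng: np.random.Generator,
) -> np.ndarray:
    """Apply the camera model to a noise-free signal; clips at zero."""
    if noise is None:
        return signal.copy()
    counts = rng.poisson(noise.photon_scale * signal) / noise.photon_scale
    out = counts + noise.background_level
    if noise.read_sigma > 0:
        out = out + rng.normal(0.0, noise.read_sigma, size=signal.shape)
    return np.clip(out, 0.0, None)


@dataclass
class NoduleTruth:
    """Per-nodule ground truth carried alongside a render."""

    id: int
    center_xy: tuple[float, float]
    diameter: float
    core_fraction: float
    survival_core: float
    survival_periphery: float
    n_pixels: int
    n_core_pixels: int
    n_live_pixels: int
    n_live_core_pixels: int

    @property
    def true_viability(self) -> float:
        """Realized live pixel fraction (pre-noise)."""
        return self.n_live_pixels / self.n_pixels if self.n_pixels else float("nan")

    @property
    def core_viability(self) -> float:
        if self.n_core_pixels == 0:
            return float("nan")
        return self.n_live_core_pixels / self.n_core_pixels

    @property
    def periphery_viability(self) -> float:
        n = self.n_pixels - self.n_core_pixels
        if n == 0:
            return float("nan")
        return (self.n_live_pixels - self.n_live_core_pixels) / n


@dataclass
class LiveDeadRender:
    image: CultureImage
    labels: np.ndarray  # int32, 0 = background
    live_mask: np.ndarray  # bool, pre-noise live assignment
    truth: list[NoduleTruth] = field(default_factory=list)


@dataclass
class UptakeRender:
    image: CultureImage
    mask: np.ndarray  # bool nodule footprint


@dataclass
class ApoptosisRender:
    image: CultureImage
    pi_mask: np.ndarray
    apotrace_mask: np.ndarray
    labels: np.ndarray


def _field_grid(field_size: tuple[float, float], pixel_size: float) -> tuple[int, int]:
    nx = int(round(field_size[0] / pixel_size))
    ny = int(round(field_size[1] / pixel_size))
    return ny, nx


def _nodule_window(
    spec: NoduleSpec, shape: tuple[int, int], pixel_size: float
) -> tuple[slice, slice, np.ndarray, np.ndarray]:
    """Bounding-box slices plus (inside, normalized-radius) arrays."""
    cx, cy = spec.center_xy
    r_px = spec.radius / pixel_size
    cx_px, cy_px = cx / pixel_size, cy / pixel_size
    x0 = max(0, int(np.floor(cx_px - r_px)) - 1)
    x1 = min(shape[1], int(np.ceil(cx_px + r_px)) + 2)
    y0 = max(0, int(np.floor(cy_px - r_px)) - 1)
    y1 = min(shape[0], int(np.ceil(cy_px + r_px)) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    # pixel centers at index + 0.5 in pixel units
    rr = np.hypot(yy + 0.5 - cy_px, xx + 0.5 - cx_px) / r_px
    return slice(y0, y1), slice(x0, x1), rr <= 1.0, rr


def _region_survival(
    field: CultureField, model: DoseResponseModel, region: str
) -> float:
    if not field.dose_effect_enabled:
        return 1.0
    return survival_probability(
        model, field.dose, field.irradiance, region, field.atmosphere
    )


def render_livedead(
    field: CultureField,
    model: DoseResponseModel,
    noise: NoiseModel | None = None,
    pixel_size: float = 2.0,
    seed: int = 0,
    *,
    field_size: tuple[float, float] = (5000.0, 5000.0),
    brightness: float = 4000.0,
) -> LiveDeadRender:
    """Render a live/dead two-channel image of a nodule field.

    Each nodule pixel is assigned live or dead by an independent Bernoulli
    draw from the survival probability of its region (core vs periphery);
    live pixels light the ``live`` channel at ``brightness``, dead pixels
    the ``dead`` channel. Control conditions (NT/LO/EO) disable the dose
    effect entirely.
    """
    rng = np.random.default_rng(seed)
    shape = _field_grid(field_size, pixel_size)
    live = np.zeros(shape)
    dead = np.zeros(shape)
    labels = np.zeros(shape, dtype=np.int32)
    live_mask = np.zeros(shape, dtype=bool)
    truth: list[NoduleTruth] = []

    s_core = _region_survival(field, model, "core")
    s_peri = _region_survival(field, model, "periphery")

    for spec in field.nodules:
        ys, xs, inside, rr = _nodule_window(spec, shape, pixel_size)
        core = inside & (rr < spec.core_fraction)
        p = np.where(core, s_core, s_peri)
        alive = (rng.random(inside.shape) < p) & inside
        dead_px = inside & ~alive
        live[ys, xs][alive] = brightness
        dead[ys, xs][dead_px] = brightness
        labels[ys, xs][inside] = spec.id
        live_mask[ys, xs] |= alive
        truth.append(
            NoduleTruth(
                id=spec.id,
                center_xy=spec.center_xy,
                diameter=spec.diameter,
                core_fraction=spec.core_fraction,
                survival_core=s_core,
                survival_periphery=s_peri,
                n_pixels=int(inside.sum()),
                n_core_pixels=int(core.sum()),
                n_live_pixels=int(alive.sum()),
                n_live_core_pixels=int((alive & core).sum()),
            )
        )

    channels = {
        "live": apply_noise(live, noise, rng),
        "dead": apply_noise(dead, noise, rng),
    }
    image = CultureImage(
        channels=channels,
        pixel_size=pixel_size,
        background_level=noise.background_level if noise else 0.0,
    )
    return LiveDeadRender(image=image, labels=labels, live_mask=live_mask, truth=truth)


def render_uptake(
    spec: NoduleSpec,
    profile: str,
    params: dict,
    t: float = np.inf,
    noise: NoiseModel | None = None,
    pixel_size: float = 2.0,
    *,
    seed: int = 0,
    brightness: float = 4000.0,
    margin: float = 50.0,
) -> UptakeRender:
    """Render a single-nodule photosensitizer uptake image.

    ``peripheral_decay`` mimics a surface-trapped agent: intensity decays
    exponentially with depth from the boundary with 1/e length
    ``params['decay_length']`` (um). ``core_concentrating`` mimics a
    pH-partitioning agent: the spherical-diffusion filling fraction at
    time ``t`` (characteristic time ``params['tau']``) is weighted by a
    trapping factor ``10**(s * (ph_edge - pH(r)))`` with
    ``s = params['trap_strength']``, so at equilibrium the surface sits at
    unit relative intensity and the acidic core accumulates agent.
    """
    if profile not in UPTAKE_PROFILES:
        raise NodulekitError(f"unknown uptake profile {profile!r}")

    rng = np.random.default_rng(seed)
    r_px = spec.radius / pixel_size
    half = int(np.ceil(r_px + margin / pixel_size))
    n = 2 * half + 1
    yy, xx = np.mgrid[0:n, 0:n]
    rr = np.hypot(yy - half, xx - half) / r_px
    inside = rr <= 1.0

    signal = np.zeros((n, n))
    if profile == "peripheral_decay":
        decay_length = float(params["decay_length"])
        depth_um = (1.0 - rr[inside]) * spec.radius
        signal[inside] = np.exp(-depth_um / decay_length)
    else:
        tau = float(params["tau"])
        s = float(params["trap_strength"])
        if s < 0:
            raise ValueError("trap_strength must be >= 0")
        ph_profile: PhProfile = params.get("ph_profile") or PhProfile()
        conc = sphere_diffusion_concentration(rr[inside], t, tau) if np.isfinite(t) else 1.0
        trap = 10.0 ** (s * (ph_profile.ph_edge - np.asarray(ph_profile(rr[inside]))))
        signal[inside] = conc * trap

    image = CultureImage(
        channels={"uptake": apply_noise(brightness * signal, noise, rng)},
        pixel_size=pixel_size,
        background_level=noise.background_level if noise else 0.0,
    )
    return UptakeRender(image=image, mask=inside)


def render_apoptosis_pair(
    field: CultureField,
    model: DoseResponseModel,
    apoptotic_fraction: float,
    noise: NoiseModel | None = None,
    seed: int = 0,
    *,
    pixel_size: float = 2.0,
    field_size: tuple[float, float] = (5000.0, 5000.0),
    brightness: float = 4000.0,
) -> ApoptosisRender:
    """Render a paired PI / apoTRACE image of a treated field.

    Dead pixels (from the same Bernoulli survival draw as the live/dead
    render) are PI-positive; each dead pixel is independently
    apoTRACE-positive with probability ``apoptotic_fraction``. Live pixels
    are negative in both channels.
    """
    if not 0.0 <= apoptotic_fraction <= 1.0:
        raise ValueError("apoptotic_fraction must be in [0, 1]")
    ld = render_livedead(
        field,
        model,
        noise=None,
        pixel_size=pixel_size,
        seed=seed,
        field_size=field_size,
        brightness=brightness,
    )
    rng = np.random.default_rng(seed + 1)
    dead_mask = (ld.labels > 0) & ~ld.live_mask
    apo_mask = dead_mask & (rng.random(dead_mask.shape) < apoptotic_fraction)

    pi = np.where(dead_mask, brightness, 0.0)
    apo = np.where(apo_mask, brightness, 0.0)
    channels = {
        "pi": apply_noise(pi, noise, rng),
        "apotrace": apply_noise(apo, noise, rng),
    }
    image = CultureImage(
        channels=channels,
        pixel_size=pixel_size,
        background_level=noise.background_level if noise else 0.0,
    )
    return ApoptosisRender(
        image=image, pi_mask=dead_mask, apotrace_mask=apo_mask, labels=ld.labels
    )
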