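"""Radial pH profiles, a two-state ratiometric dye model, and cube rendering.

The dye's emission is a pH-weighted mixture of an acid-form and a
base-form spectrum. The forms are modelled as unit-peak Gaussians (acid
peaked near 580 nm, base near 640 nm) so that the 570/650 band ratio is
strictly monotone in pH; the acid fraction follows the Henderson-
Hasselbalch sigmoid ``alpha = 1 / (1 + 10**(pH - pKa))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..image import CultureImage, HyperspectralCube, STANDARD_BAND_CENTERS, STANDARD_BANDWIDTH
from .geometry import NoduleSpec

__all__ = ["PhProfile", "SnarfModel", "acid_fraction", "render_hyperspectral"]


@dataclass(frozen=True)
class PhProfile:
    """Radial pH profile ``pH(r) = ph_core + (ph_edge - ph_core) * r**exponent``.

    ``r`` is the normalized radius; the core is acidic, the edge neutral.
    """

    ph_core: float = 5.5
    ph_edge: float = 7.2
    exponent: float = 2.0

    def __post_init__(self) -> None:
        if not 4.0 <= self.ph_core <= self.ph_edge <= 8.0:
            raise ValueError("require 4 <= ph_core <= ph_edge <= 8")
        if self.exponent <= 0:
            raise ValueError("exponent must be positive")

    def __call__(self, r: np.ndarray | float) -> np.ndarray | float:
        r = np.clip(r, 0.0, 1.0)
        return self.ph_core + (self.ph_edge - self.ph_core) * r**self.exponent


@dataclass(frozen=True)
class SnarfModel:
    """Two-form emission model of the ratiometric pH dye."""

    pka: float = 6.4
    acid_peak: float = 580.0  # nm
    base_peak: float = 640.0  # nm
    sigma: float = 30.0  # nm
    brightness: float = 3000.0

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.brightness <= 0:
            raise ValueError("sigma and brightness must be positive")

    def acid_weight(self, wavelength: np.ndarray | float) -> np.ndarray | float:
        """Acid-form emission weight, normalized to unit peak."""
        return np.exp(-0.5 * ((np.asarray(wavelength) - self.acid_peak) / self.sigma) ** 2)

    def base_weight(self, wavelength: np.ndarray | float) -> np.ndarray | float:
        """Base-form emission weight, normalized to unit peak."""
        return np.exp(-0.5 * ((np.asarray(wavelength) - self.base_peak) / self.sigma) ** 2)

    def band_ratio(self, ph: np.ndarray | float, low: float = 570.0, high: float = 650.0):
        """Noise-free emission ratio ``I(low) / I(high)`` at a given pH."""
        a = acid_fraction(ph, self.pka)
        num = a * self.acid_weight(low) + (1 - a) * self.base_weight(low)
        den = a * self.acid_weight(high) + (1 - a) * self.base_weight(high)
        return num / den


def acid_fraction(ph: np.ndarray | float, pka: float) -> np.ndarray | float:
    """Henderson-Hasselbalch acid-form fraction at the given pH."""
    return 1.0 / (1.0 + 10.0 ** (np.asarray(ph, dtype=float) - pka))


def render_hyperspectral(
    spec: NoduleSpec,
    ph: PhProfile,
    snarf: SnarfModel,
    noise: "NoiseModel | None" = None,
    pixel_size: float = 2.0,
    *,
    seed: int = 0,
    margin: float = 50.0,
) -> HyperspectralCube:
    """Render one nodule as a hyperspectral cube on the standard band axis.

    Each nodule pixel carries the spectrum
    ``background + brightness * (alpha * acid + (1 - alpha) * base)`` with
    ``alpha`` set by the radial pH profile; pixels outside the nodule
    contain background only. The cube spans the nodule plus ``margin`` um
    on each side.
    """
    from .render import apply_noise  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    r_px = spec.radius / pixel_size
    half = int(np.ceil(r_px + margin / pixel_size))
    n = 2 * half + 1
    yy, xx = np.mgrid[0:n, 0:n]
    rr = np.hypot(yy - half, xx - half) / r_px  # normalized radius
    inside = rr <= 1.0

    alpha = np.zeros((n, n))
    alpha[inside] = acid_fraction(ph(rr[inside]), snarf.pka)

    centers = STANDARD_BAND_CENTERS
    acid = snarf.acid_weight(centers)
    base = snarf.base_weight(centers)
    planes = snarf.brightness * (
        alpha[None, :, :] * acid[:, None, None]
        + (1.0 - alpha[None, :, :]) * base[:, None, None]
    )
    planes[:, ~inside] = 0.0
    planes = np.stack([apply_noise(p, noise, rng) for p in planes])
    return HyperspectralCube(
        planes=planes,
        band_centers=centers,
        bandwidth=STANDARD_BANDWIDTH,
        pixel_size=pixel_size,
    )
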