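"""Spectral fluence-rate correction between treatment wavelengths.

When the same absorbed dose rate must be delivered with two lasers of
different emission spectra, the fluence rate of the second laser has to
be rescaled by the ratio of the absorber-weighted mean absorbances seen
by each laser. Integrals are trapezoidal on the union wavelength grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NodulekitError

__all__ = ["Spectrum", "fluence_correction"]


@dataclass(frozen=True)
class Spectrum:
    """A sampled spectrum: strictly increasing wavelengths, finite values.

    ``values`` are per-nm emission density for lasers or absorbance for
    absorbers; both must be non-negative.
    """

    wavelengths: np.ndarray  # nm
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("spectrum needs at least two wavelength samples")
        if vals.shape != wl.shape:
            raise ValueError("wavelengths and values must align")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError("values must be finite and non-negative")

    def interpolate(self, grid: np.ndarray, *, outside_zero: bool) -> np.ndarray:
        """Linear interpolation; outside the domain either zero or edge-held."""
        if outside_zero:
            return np.interp(grid, self.wavelengths, self.values, left=0.0, right=0.0)
        return np.interp(grid, self.wavelengths, self.values)


def _mean_absorbance(laser: Spectrum, absorber: Spectrum, grid: np.ndarray) -> float:
    emission = laser.interpolate(grid, outside_zero=True)
    absorbance = absorber.interpolate(grid, outside_zero=False)
    power = np.trapezoid(emission, grid)
    if power <= 0:
        raise NodulekitError("laser delivers no power on the integration grid")
    absorbed = np.trapezoid(emission * absorbance, grid)
    return float(absorbed / power)


def fluence_correction(
    laser_a: Spectrum, laser_b: Spectrum, absorber: Spectrum
) -> float:
    """Multiplier for laser_b's fluence rate to match laser_a's absorbed dose rate.

    Computed as the ratio of emission-weighted mean absorbances,

        factor = <A>_a / <A>_b ,

    so multiplying laser_b's fluence rate by ``factor`` equalizes the
    absorbed power density between the two sources. The factor is
    invariant under rescaling any spectrum and inverts when the lasers
    are swapped.

    Raises
    ------
    NodulekitError
        If either laser has no spectral overlap with the grid, or the
        absorber-weighted power of laser_b vanishes.
    """
    for laser in (laser_a, laser_b):
        if (
            laser.wavelengths[-1] < absorber.wavelengths[0]
            or laser.wavelengths[0] > absorber.wavelengths[-1]
        ):
            raise NodulekitError("laser spectrum does not overlap the absorber domain")
    grid = np.unique(
        np.concatenate(
            [laser_a.wavelengths, laser_b.wavelengths, absorber.wavelengths]
        )
    )
    mean_a = _mean_absorbance(laser_a, absorber, grid)
    mean_b = _mean_absorbance(laser_b, absorber, grid)
    if mean_b == 0.0:
        raise NodulekitError("laser_b absorbs no power; correction undefined")
    return mean_a / mean_b
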