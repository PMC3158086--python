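"""Diffusion into a sphere with fixed surface concentration.

Classical series solution for an initially empty sphere whose surface is
held at unit concentration:

    C(r, t) / C_s = 1 + (2 / (pi * x)) * sum_{n>=1} ((-1)^n / n)
                    * sin(n * pi * x) * exp(-n^2 * pi^2 * t / tau)

with ``x = r / R`` the normalized radius and ``tau = R^2 / D`` the
characteristic diffusion time. At the center (x -> 0) the series reduces
to ``1 + 2 * sum (-1)^n exp(-n^2 pi^2 t / tau)``.
"""

from __future__ import annotations

import numpy as np

from ..errors import SeriesTruncationError

__all__ = ["sphere_diffusion_concentration", "fill_time"]

_MAX_TERMS = 2000


def sphere_diffusion_concentration(
    r: float | np.ndarray,
    t: float,
    tau: float,
    *,
    tol: float = 1e-10,
) -> float | np.ndarray:
    """Concentration fraction ``C(r, t) / C_surface`` inside the sphere.

    Parameters
    ----------
    r : float or ndarray
        Normalized radius in [0, 1].
    t : float
        Elapsed time, same units as ``tau``.
    tau : float
        Characteristic diffusion time ``R**2 / D``.
    tol : float, optional
        Absolute truncation tolerance for the series tail.

    Raises
    ------
    SeriesTruncationError
        If the term budget is exhausted before the tail bound drops
        below ``tol`` (only possible at extremely small ``t / tau``).
    """
    x = np.asarray(r, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("normalized radius must be in [0, 1]")
    if t < 0:
        raise ValueError("t must be non-negative")
    if tau <= 0:
        raise ValueError("tau must be positive")

    out = np.ones_like(x)
    if t == 0.0:
        out[x < 1.0] = 0.0
        return float(out[0]) if scalar else out

    theta = np.pi**2 * t / tau
    interior = x < 1.0
    xi = x[interior]
    small = xi < 1e-9  # series limit at the exact center
    acc = np.ones_like(xi)
    converged = False
    for n in range(1, _MAX_TERMS + 1):
        decay = np.exp(-(n**2) * theta)
        term = np.empty_like(xi)
        term[~small] = (
            2.0 / (np.pi * xi[~small]) * ((-1.0) ** n / n)
            * np.sin(n * np.pi * xi[~small]) * decay
        )
        term[small] = 2.0 * (-1.0) ** n * decay
        acc += term
        # tail bound: |sum_{m>n}| <= 2 * sum_{m>n} exp(-m^2 theta)
        #           <= 2 * exp(-(n+1)^2 theta) / (1 - exp(-(2n+3) theta))
        tail = 2.0 * np.exp(-((n + 1) ** 2) * theta)
        denom = 1.0 - np.exp(-(2 * n + 3) * theta)
        if denom > 0 and tail / denom < tol:
            converged = True
            break
    if not converged:
        raise SeriesTruncationError(
            f"series did not reach tolerance {tol} within {_MAX_TERMS} terms "
            f"(t/tau = {t / tau:g})"
        )
    out[interior] = np.clip(acc, 0.0, 1.0)
    return float(out[0]) if scalar else out


def fill_time(
    tau: float,
    threshold: float = 0.9,
    *,
    rtol: float = 1e-8,
) -> float:
    """Time for the sphere center to reach ``threshold`` of the surface level.

    Solved by bisection on the series solution; scales linearly with
    ``tau`` and therefore quadratically with sphere diameter.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    lo, hi = 1e-6 * tau, 10.0 * tau
    while sphere_diffusion_concentration(0.0, hi, tau) < threshold:
        hi *= 2.0
    while hi - lo > rtol * tau:
        mid = 0.5 * (lo + hi)
        if sphere_diffusion_concentration(0.0, mid, tau) < threshold:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
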