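"""Independent reference implementations used only by the test suite.

Each oracle is deliberately written with a different method than the
package code it checks (explicit loops, finite differences, closed
forms), so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_otsu(counts: np.ndarray, centers: np.ndarray) -> float:
    """Exhaustive within-class-variance minimizer over all histogram cuts.

    Loops over every cut, computing both class variances directly from
    first principles; returns the lowest bin-center threshold among the
    minimizers.
    """
    counts = np.asarray(counts, dtype=float)
    centers = np.asarray(centers, dtype=float)
    best_wcv = math.inf
    best_t = None
    for k in range(len(centers) - 1):
        w0 = counts[: k + 1].sum()
        w1 = counts[k + 1 :].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: k + 1] * centers[: k + 1]).sum() / w0
        mu1 = (counts[k + 1 :] * centers[k + 1 :]).sum() / w1
        var0 = (counts[: k + 1] * (centers[: k + 1] - mu0) ** 2).sum() / w0
        var1 = (counts[k + 1 :] * (centers[k + 1 :] - mu1) ** 2).sum() / w1
        wcv = (w0 * var0 + w1 * var1) / (w0 + w1)
        if wcv < best_wcv - 1e-12:
            best_wcv = wcv
            best_t = centers[k]
    return float(best_t)


def pooled_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Textbook pooled-variance two-sample t-test (statistic, two-sided p)."""
    from scipy.stats import t as t_dist

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t_stat = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2.0 * t_dist.sf(abs(t_stat), na + nb - 2)
    return t_stat, p


def fd_sphere_diffusion(
    r_eval: np.ndarray,
    t: float,
    tau: float,
    *,
    n_r: int = 400,
    n_t: int = 8000,
) -> np.ndarray:
    """Finite-difference solver for diffusion into a unit sphere.

    Solves the radial diffusion equation through the substitution
    ``u = r * C`` (plain 1D heat equation, Crank-Nicolson in time) with
    ``C(1, t) = 1`` and ``C(r, 0) = 0``; ``tau = R**2 / D`` with R = 1.
    """
    from scipy.linalg import solve_banded

    dr = 1.0 / n_r
    dt = t / n_t
    d_coeff = 1.0 / tau  # D with R = 1
    lam = d_coeff * dt / dr**2
    r = np.linspace(0.0, 1.0, n_r + 1)

    # interior unknowns u_1 .. u_{n_r-1}; u_0 = 0, u_{n_r} = r_N * 1 = 1
    n = n_r - 1
    main = np.full(n, 1.0 + lam)
    off = np.full(n - 1, -lam / 2.0)
    ab = np.zeros((3, n))
    ab[0, 1:] = off
    ab[1] = main
    ab[2, :-1] = off

    u = np.zeros(n_r + 1)
    u[-1] = 1.0
    for _ in range(n_t):
        rhs = u[1:-1] + (lam / 2.0) * (u[2:] - 2.0 * u[1:-1] + u[:-2])
        rhs[-1] += (lam / 2.0) * u[-1]  # boundary term on the new level
        u[1:-1] = solve_banded((1, 1), ab, rhs)
    c = np.empty_like(u)
    c[1:] = u[1:] / r[1:]
    c[0] = c[1]  # symmetric center; value via nearest interior node
    return np.interp(np.asarray(r_eval, dtype=float), r, c)


def binomial_ci(k_prob: float, n: int, level: float = 0.99) -> tuple[float, float]:
    """Exact central binomial interval for the success fraction."""
    from scipy.stats import binom

    alpha = 1.0 - level
    lo = binom.ppf(alpha / 2, n, k_prob) / n
    hi = binom.ppf(1 - alpha / 2, n, k_prob) / n
    return float(lo), float(hi)
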