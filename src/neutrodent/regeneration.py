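"""Axolotl-inspired regenerative healing dynamics.

Pediatric tissue regeneration is modeled after the exceptional healing
of *Ambystoma mexicanum*: a baseline regeneration rate ``lambda0``
(day^-1) is modulated by a Gaussian age profile peaking at
``age_optimal`` and by a sinusoidal hormonal factor.  Growth-factor
concentration follows a reaction-diffusion equation with production,
first-order degradation and cellular consumption.  A healing
trajectory summarizes lesion recovery as
``1 - severity * exp(-lambda(age) * t)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from neutrodent.diffusion import laplacian

__all__ = [
    "RegenParams",
    "growth_factor_step",
    "healing_trajectory",
    "hormonal_factor",
    "regeneration_rate",
]


@dataclass(frozen=True)
class RegenParams:
    """Parameters of the regeneration model.

    ``d_g`` is the growth-factor diffusion coefficient in physical
    units (cm^2/s); ``d_g_scale`` converts it to grid units per step so
    diffusion and degradation act on comparable magnitudes.
    ``k_degradation`` is expected within its plausible range
    [0.1, 0.3] day^-1 unless ``allow_out_of_range`` is set.
    """

    lambda0: float = 0.25  # day^-1
    age_optimal: float = 8.0  # years
    sigma_age: float = 4.0  # years
    hormonal_amplitude: float = 0.4
    d_g: float = 1e-7  # cm^2/s
    d_g_scale: float = 1e6  # grid-unit rescale; default puts D_G ~ 0.1
    k_degradation: float = 0.2  # day^-1
    k_consumption: float = 0.1
    dt: float = 0.1  # days
    n_steps: int = 10
    allow_out_of_range: bool = False

    def __post_init__(self) -> None:
        if self.lambda0 <= 0 or self.sigma_age <= 0:
            raise ValueError("lambda0 and sigma_age must be strictly positive")
        if self.d_g < 0 or self.k_consumption < 0:
            raise ValueError("d_g and k_consumption must be non-negative")
        if not self.allow_out_of_range and not (0.1 <= self.k_degradation <= 0.3):
            raise ValueError(
                "k_degradation outside its plausible range [0.1, 0.3] day^-1; "
                "set allow_out_of_range to override"
            )
        if self.dt <= 0 or self.n_steps < 1:
            raise ValueError("dt must be positive and n_steps a positive integer")

    @property
    def d_g_grid(self) -> float:
        """Diffusion coefficient in grid units."""
        return self.d_g * self.d_g_scale


def _check_age(age: float) -> None:
    if not (3.0 <= age <= 17.0):
        raise ValueError(f"age must lie in [3, 17] years, got {age!r}")


def hormonal_factor(age: float, p: RegenParams | None = None) -> float:
    """Sinusoidal hormonal modulation over the pediatric age span.

    ``1 + A * sin(2 pi (age - 3) / 14)`` — one full period across ages
    3-17, neutral at both endpoints and at the midpoint.  Requires
    ``|A| < 1`` so the factor stays positive.
    """
    p = p if p is not None else RegenParams()
    _check_age(age)
    if abs(p.hormonal_amplitude) >= 1.0:
        raise ValueError("hormonal amplitude must satisfy |A| < 1 for positivity")
    return 1.0 + p.hormonal_amplitude * float(np.sin(2.0 * np.pi * (age - 3.0) / 14.0))


def regeneration_rate(age: float, h: float = 1.0, p: RegenParams | None = None) -> float:
    """Age-dependent regeneration rate (day^-1).

    Gaussian-modulated baseline: ``lambda0 * exp(-(age - age_optimal)^2
    / (2 sigma_age^2)) * h`` where ``h`` is the hormonal factor.  The
    unique maximum over age (at ``h = 1``) is ``lambda0`` at
    ``age_optimal``.
    """
    p = p if p is not None else RegenParams()
    _check_age(age)
    if h <= 0:
        raise ValueError("hormonal factor must be strictly positive")
    gauss = np.exp(-((age - p.age_optimal) ** 2) / (2.0 * p.sigma_age**2))
    return p.lambda0 * float(gauss) * h


def growth_factor_step(
    g_grid: np.ndarray,
    cells_grid: np.ndarray,
    production_grid: np.ndarray,
    p: RegenParams | None = None,
) -> np.ndarray:
    """One explicit Euler step of the growth-factor reaction-diffusion law.

    ``dG/dt = D_G lap(G) + R_production - K_deg * G - K_cons * G * C``
    with zero-flux boundaries; the result is clipped at 0 from below.
    """
    p = p if p is not None else RegenParams()
    g = np.asarray(g_grid, dtype=float)
    cells = np.asarray(cells_grid, dtype=float)
    prod = np.asarray(production_grid, dtype=float)
    if g.shape != cells.shape or g.shape != prod.shape:
        raise ValueError("G, cells and production grids must share dimensions")
    d = p.d_g_grid
    if d > 0 and p.dt * d > 0.25:
        raise ValueError(
            f"explicit step unstable: dt*D_G = {p.dt * d:.6g} exceeds 0.25 "
            f"(maximal admissible dt = {0.25 / d:.6g})"
        )
    rhs = prod - p.k_degradation * g - p.k_consumption * g * cells
    if d > 0:
        rhs = rhs + d * laplacian(g)
    return np.maximum(g + p.dt * rhs, 0.0)


def healing_trajectory(
    age: float,
    severity: float,
    horizon_days: int,
    p: RegenParams | None = None,
    hormonal: float = 1.0,
) -> np.ndarray:
    """Daily healing fractions over ``horizon_days`` (day 0 included).

    ``healing(t) = 1 - severity * exp(-lambda(age) * t)`` — monotone
    non-decreasing from ``1 - severity`` toward 1.  ``hormonal``
    defaults to the neutral factor; pass ``hormonal_factor(age, p)``
    to include the sinusoidal modulation.
    """
    p = p if p is not None else RegenParams()
    if not (0.0 <= severity <= 1.0):
        raise ValueError("severity must lie in [0, 1]")
    if horizon_days < 1:
        raise ValueError("horizon_days must be a positive integer")
    lam = regeneration_rate(age, hormonal, p)
    t = np.arange(horizon_days + 1, dtype=float)
    return 1.0 - severity * np.exp(-lam * t)
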