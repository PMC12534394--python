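"""Spatio-temporal evolution of neutrosophic evidence grids.

Truth evolves by an anatomically constrained heat equation

    dT/dt = D_T lap(T) + S_T * A_anatomy - lambda_T * T

and indeterminacy by an advection-diffusion equation

    dI/dt = D_I lap(I) + v . grad(I) - mu_I * I

both integrated with explicit Euler on a unit-spaced grid, a 5-point
Laplacian with zero-flux (Neumann) boundaries, and first-order upwind
advection.  The advection term enters with a plus sign, transporting
indeterminacy anti-parallel to the velocity field.  A separate scalar
temporal-decay operator ``x * exp(-lambda * t)`` models information
degradation over time with ``lambda`` constrained to ``(0, 1]``.

Falsehood is not evolved; it is recomputed from the diffused truth and
indeterminacy so the neutrosophic coupling stays consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "DiffusionParams",
    "SourceField",
    "evolve_indeterminacy",
    "evolve_truth",
    "laplacian",
    "stability_limit",
    "temporal_decay",
]

_STENCIL_BOUND = 0.25  # dt * D / h^2 bound for the explicit 5-point scheme


def stability_limit(d_t: float, d_i: float) -> float:
    """Maximal admissible explicit time step for the given diffusion coefficients."""
    dmax = max(d_t, d_i)
    if dmax <= 0:
        return np.inf
    return _STENCIL_BOUND / dmax


@dataclass
class DiffusionParams:
    """Coefficients and discretization of the evidence-evolution PDEs.

    ``dt`` defaults to 0.9x the explicit stability limit
    ``0.25 h^2 / max(D_T, D_I)`` on the unit-spaced grid (h = 1).
    ``decay_lambda`` parameterizes the scalar temporal-decay operator
    and must lie in (0, 1].
    """

    d_t: float = 0.15
    lambda_t: float = 0.025
    d_i: float = 0.15
    mu_i: float = 0.025
    velocity: Optional[tuple[np.ndarray, np.ndarray]] = None
    dt: Optional[float] = None
    n_steps: int = 10
    decay_lambda: float = 0.025

    def __post_init__(self) -> None:
        for name in ("d_t", "lambda_t", "d_i", "mu_i"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 < self.decay_lambda <= 1.0):
            raise ValueError(f"decay_lambda must lie in (0, 1], got {self.decay_lambda}")
        if self.n_steps < 1:
            raise ValueError("n_steps must be a positive integer")
        limit = stability_limit(self.d_t, self.d_i)
        if self.dt is None:
            self.dt = 0.9 * limit if np.isfinite(limit) else 1.0
        if self.dt <= 0:
            raise ValueError("dt must be strictly positive")
        if self.dt > limit:
            raise ValueError(
                f"explicit scheme unstable: dt={self.dt} exceeds the "
                f"admissible maximum {limit:.6g} for max(D_T, D_I)="
                f"{max(self.d_t, self.d_i)}"
            )


@dataclass
class SourceField:
    """Observation-driven source term S_T with an anatomical mask A."""

    s_grid: np.ndarray
    anatomy: Optional[np.ndarray] = None

    def resolved(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        s = np.asarray(self.s_grid, dtype=float)
        if s.shape != shape:
            raise ValueError(f"source grid shape {s.shape} does not match {shape}")
        if np.any(s < 0):
            raise ValueError("source grid must be non-negative")
        if self.anatomy is None:
            a = np.ones(shape, dtype=float)
        else:
            a = np.asarray(self.anatomy, dtype=float)
            if a.shape != shape:
                raise ValueError(f"anatomy mask shape {a.shape} does not match {shape}")
            if a.min() < 0 or a.max() > 1:
                raise ValueError("anatomy mask values must lie in [0, 1]")
        return s, a


def temporal_decay(x, lam: float, t: float):
    """Exponential information decay ``x * exp(-lam * t)``, ``lam`` in (0, 1]."""
    if not (0.0 < lam <= 1.0):
        raise ValueError(f"decay parameter lambda must lie in (0, 1], got {lam}")
    if t < 0:
        raise ValueError("time must be non-negative")
    out = np.asarray(x, dtype=float) * np.exp(-lam * t)
    return float(out) if out.ndim == 0 else out


def laplacian(grid: np.ndarray) -> np.ndarray:
    """5-point Laplacian with zero-flux (mirrored) boundaries on a unit grid.

    Under the mirrored boundary the stencil conserves mass: the output
    sums to zero for every input.
    """
    g = np.asarray(grid, dtype=float)
    if g.ndim != 2 or g.shape[0] < 2 or g.shape[1] < 2:
        raise ValueError("grid must be 2-D with both dimensions >= 2")
    padded = np.pad(g, 1, mode="edge")
    return (
        padded[:-2, 1:-1] + padded[2:, 1:-1] + padded[1:-1, :-2] + padded[1:-1, 2:]
        - 4.0 * g
    )


def evolve_truth(t_grid: np.ndarray, src: SourceField, p: DiffusionParams) -> np.ndarray:
    """Advance the truth grid ``p.n_steps`` explicit Euler steps.

    Integrates ``dT/dt = D_T lap(T) + S_T * A - lambda_T * T`` and clips
    the final field to [0, 1].
    """
    t = np.array(t_grid, dtype=float)
    s, a = src.resolved(t.shape)
    forcing = s * a
    for _ in range(p.n_steps):
        t = t + p.dt * (p.d_t * laplacian(t) + forcing - p.lambda_t * t)
    return np.clip(t, 0.0, 1.0)


def _upwind_advection(i_grid: np.ndarray, vx: np.ndarray, vy: np.ndarray) -> np.ndarray:
    """First-order upwind discretization of ``+ v . grad(I)``.

    The term transports the field with effective velocity ``-v``; the
    upwind direction is chosen against that effective velocity.  Axis 0
    is y (rows), axis 1 is x (columns); zero-gradient boundaries.
    """
    padded = np.pad(i_grid, 1, mode="edge")
    # One-sided differences of I along each axis.
    d_back_y = i_grid - padded[:-2, 1:-1]
    d_fwd_y = padded[2:, 1:-1] - i_grid
    d_back_x = i_grid - padded[1:-1, :-2]
    d_fwd_x = padded[1:-1, 2:] - i_grid
    # For dI/dt = ... + v.grad(I), effective transport velocity is c = -v.
    # Upwind w.r.t. c: c > 0 uses the backward difference.
    cx, cy = -vx, -vy
    grad_x = np.where(cx > 0, d_back_x, d_fwd_x)
    grad_y = np.where(cy > 0, d_back_y, d_fwd_y)
    return vx * grad_x + vy * grad_y


def evolve_indeterminacy(i_grid: np.ndarray, p: DiffusionParams) -> np.ndarray:
    """Advance the indeterminacy grid ``p.n_steps`` explicit Euler steps.

    Integrates ``dI/dt = D_I lap(I) + v . grad(I) - mu_I * I`` with
    first-order upwind advection, then clips to [0, 1].  Requires the
    advection CFL condition ``dt * max|v| <= h``.
    """
    i = np.array(i_grid, dtype=float)
    if p.velocity is None:
        vx = vy = None
    else:
        vx = np.asarray(p.velocity[0], dtype=float)
        vy = np.asarray(p.velocity[1], dtype=float)
        if vx.shape != i.shape or vy.shape != i.shape:
            raise ValueError("velocity component grids must match the field shape")
        vmax = max(np.abs(vx).max(), np.abs(vy).max())
        if p.dt * vmax > 1.0:
            raise ValueError(
                f"advection CFL violated: dt*max|v| = {p.dt * vmax:.6g} > 1"
            )
    for _ in range(p.n_steps):
        rhs = p.d_i * laplacian(i) - p.mu_i * i
        if vx is not None:
            rhs = rhs + _upwind_advection(i, vx, vy)
        i = i + p.dt * rhs
    return np.clip(i, 0.0, 1.0)
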