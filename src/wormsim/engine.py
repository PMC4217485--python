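"""Predictive-corrective incompressible SPH (PCISPH) engine.

One timestep of :func:`advance` does, in order:

1. neighbor search (uniform grid, cell size h),
2. density summation over all particles, including frozen BOUNDARY
   particles so that walls contribute to fluid density,
3. non-pressure forces: gravity, symmetric viscosity, linear-strain
   springs, cohesion-style surface tension, plus any caller-supplied
   external forces,
4. pressure correction: pressures are accumulated iteratively from
   predicted density errors with a precomputed stiffness factor until the
   maximum relative compression falls below a tolerance,
5. semi-implicit (symplectic) Euler integration,
6. boundary enforcement (analytic box walls, if configured).

All internal pairwise forces (pressure, viscosity, springs, surface
tension) are constructed antisymmetrically, so internal momentum is
conserved to rounding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .kernels import (
    poly6_coeff,
    spiky_grad_coeff,
    viscosity_lap_coeff,
)
from .particles import BOUNDARY, LIQUID, ParticleSystem, SpringSet, neighbor_pairs

_R_EPS = 1e-12


def _scatter_add(out: np.ndarray, idx: np.ndarray, values: np.ndarray) -> None:
    """out[idx] += values via bincount (much faster than np.add.at)."""
    n = out.shape[0]
    if out.ndim == 1:
        out += np.bincount(idx, weights=values, minlength=n)
    else:
        for k in range(out.shape[1]):
            out[:, k] += np.bincount(idx, weights=values[:, k], minlength=n)


@dataclass
class Box:
    """Axis-aligned analytic walls. Particles are kept inside [lo, hi]."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        self.lo = np.asarray(self.lo, dtype=float)
        self.hi = np.asarray(self.hi, dtype=float)
        if np.any(self.hi <= self.lo):
            raise ValueError("box hi must exceed lo in every axis")


@dataclass
class PCISPHParams:
    eta: float = 0.01  # max allowed relative density error
    min_iters: int = 3
    max_iters: int = 7
    relaxation: float = 0.5  # under-relaxation of the pressure increment;
    # the prototype-neighborhood stiffness slightly overshoots on deficient
    # neighborhoods (free surfaces, walls), which otherwise sustains a
    # pressure oscillation that pumps energy into splashes


class NumericError(RuntimeError):
    pass


def _pair_geometry(positions: np.ndarray, pairs: np.ndarray):
    """Displacement x_i - x_j, distance (clamped away from 0) and unit vector."""
    i, j = pairs[:, 0], pairs[:, 1]
    dx = positions[i] - positions[j]
    r = np.sqrt(np.einsum("ij,ij->i", dx, dx))
    r_safe = np.maximum(r, _R_EPS)
    return dx, r, dx / r_safe[:, None]


def compute_densities(
    sys: ParticleSystem,
    pairs: np.ndarray | None = None,
    positions: np.ndarray | None = None,
) -> np.ndarray:
    """SPH density summation rho_i = sum_j m_j W(|x_i - x_j|, h).

    Includes the self-contribution m_i W(0) and BOUNDARY neighbors, so a
    fluid particle resting against a wall sees a filled neighborhood.
    """
    positions = sys.positions if positions is None else positions
    if pairs is None:
        pairs = neighbor_pairs(positions, sys.h)
    h, d = sys.h, sys.dimension
    c = poly6_coeff(h, d)
    rho = sys.masses * (c * h**6)  # self term: W(0) = c h^6
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        dx = positions[i] - positions[j]
        r2 = np.einsum("ij,ij->i", dx, dx)
        w = c * (h * h - r2) ** 3
        _scatter_add(rho, i, sys.masses[j] * w)
        _scatter_add(rho, j, sys.masses[i] * w)
    return rho


def compute_spring_forces(sys: ParticleSystem, springs: SpringSet) -> np.ndarray:
    """Linear-strain spring law F = k (L - r0) / r0 along the link."""
    f = np.zeros_like(sys.positions)
    if springs is None or springs.n == 0:
        return f
    dx, r, unit = _pair_geometry(sys.positions, springs.pairs)
    mag = springs.stiffness * (r - springs.rest_lengths) / springs.rest_lengths
    # positive mag (stretched) pulls endpoints together
    fvec = -mag[:, None] * unit
    _scatter_add(f, springs.pairs[:, 0], fvec)
    _scatter_add(f, springs.pairs[:, 1], -fvec)
    return f


def compute_nonpressure_forces(
    sys: ParticleSystem,
    springs: SpringSet | None = None,
    gravity: np.ndarray | None = None,
    pairs: np.ndarray | None = None,
) -> np.ndarray:
    """Gravity + symmetric viscosity + spring forces, per particle [N, d].

    Viscosity uses the pairwise-antisymmetric form
    F_ij = mu m_i m_j (v_j - v_i) lapW(r) / (rho_i rho_j),
    which damps relative motion while conserving momentum exactly.
    """
    if pairs is None:
        pairs = neighbor_pairs(sys.positions, sys.h)
    f = np.zeros_like(sys.positions)
    if gravity is not None:
        g = np.asarray(gravity, dtype=float)
        f += sys.masses[:, None] * g[None, :]
    if sys.mu > 0 and len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        _, r, _ = _pair_geometry(sys.positions, pairs)
        lap = viscosity_lap_coeff(sys.h, sys.dimension) * (sys.h - r)
        coef = (
            sys.mu
            * sys.masses[i]
            * sys.masses[j]
            / (sys.densities[i] * sys.densities[j])
            * lap
        )
        dv = sys.velocities[j] - sys.velocities[i]
        fvec = coef[:, None] * dv
        _scatter_add(f, i, fvec)
        _scatter_add(f, j, -fvec)
    f += compute_spring_forces(sys, springs)
    return f


def compute_surface_tension(
    sys: ParticleSystem, pairs: np.ndarray | None = None
) -> np.ndarray:
    """Cohesion-style surface tension between LIQUID pairs.

    F_i = -kappa sum_j m_j W(r) (x_i - x_j): each particle is pulled toward
    its liquid neighbors; contributions are pairwise antisymmetric.
    """
    f = np.zeros_like(sys.positions)
    if sys.kappa == 0:
        return f
    if pairs is None:
        pairs = neighbor_pairs(sys.positions, sys.h)
    if not len(pairs):
        return f
    liquid = sys.kinds == LIQUID
    sel = liquid[pairs[:, 0]] & liquid[pairs[:, 1]]
    pairs = pairs[sel]
    if not len(pairs):
        return f
    i, j = pairs[:, 0], pairs[:, 1]
    dx = sys.positions[i] - sys.positions[j]
    r2 = np.einsum("ij,ij->i", dx, dx)
    w = poly6_coeff(sys.h, sys.dimension) * (sys.h * sys.h - r2) ** 3
    fvec = -sys.kappa * (sys.masses[j] * sys.masses[i] * w)[:, None] * dx
    _scatter_add(f, i, fvec)
    _scatter_add(f, j, -fvec)
    return f


_DELTA_CACHE: dict[tuple, float] = {}


def precompute_delta(
    h: float, d: int, spacing: float, mass: float, rho0: float, dt: float
) -> float:
    """PCISPH pressure stiffness from a prototype filled neighborhood.

    A particle at the origin is surrounded by a regular lattice of spacing
    ``spacing`` out to the support radius; the stiffness maps a density
    error to the pressure increment that would cancel it in one step.
    """
    cache_key = (h, d, spacing, mass, rho0, dt)
    if cache_key in _DELTA_CACHE:
        return _DELTA_CACHE[cache_key]
    ranges = [np.arange(-int(np.ceil(h / spacing)) - 1, int(np.ceil(h / spacing)) + 2)] * d
    grids = np.meshgrid(*ranges, indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1) * spacing
    r = np.linalg.norm(pts, axis=1)
    sel = (r > _R_EPS) & (r < h)
    pts, r = pts[sel], r[sel]
    grad = spiky_grad_coeff(h, d) * (h - r) ** 2
    grads = grad[:, None] * (pts / r[:, None])  # grad_i W(|x_i - x_j|) at x_i = 0... sign folded below
    sum_grad = grads.sum(axis=0)
    sum_dot = np.einsum("ij,ij->", grads, grads)
    beta = 2.0 * (dt * mass / rho0) ** 2
    denom = beta * (sum_grad @ sum_grad + sum_dot)
    if denom <= 0:
        raise ValueError("degenerate prototype neighborhood for delta")
    _DELTA_CACHE[cache_key] = 1.0 / denom
    return _DELTA_CACHE[cache_key]


def _pressure_forces(
    sys: ParticleSystem,
    pairs: np.ndarray,
    pressures: np.ndarray,
    densities: np.ndarray,
    positions: np.ndarray,
) -> np.ndarray:
    """Symmetric pressure force with mirrored pressure at BOUNDARY neighbors."""
    f = np.zeros_like(positions)
    if not len(pairs):
        return f
    i, j = pairs[:, 0], pairs[:, 1]
    dx = positions[i] - positions[j]
    r = np.sqrt(np.einsum("ij,ij->i", dx, dx))
    r_safe = np.maximum(r, _R_EPS)
    unit = dx / r_safe[:, None]
    gradw = spiky_grad_coeff(sys.h, sys.dimension) * (sys.h - r) ** 2
    bnd = sys.kinds == BOUNDARY
    p_i = np.where(bnd[i], pressures[j], pressures[i])
    p_j = np.where(bnd[j], pressures[i], pressures[j])
    rho_i = np.where(bnd[i], densities[j], densities[i])
    rho_j = np.where(bnd[j], densities[i], densities[j])
    coef = -sys.masses[i] * sys.masses[j] * (
        p_i / rho_i**2 + p_j / rho_j**2
    ) * gradw
    fvec = coef[:, None] * unit
    _scatter_add(f, i, fvec)
    _scatter_add(f, j, -fvec)
    return f


def pcisph_correct(
    sys: ParticleSystem,
    f_ext: np.ndarray,
    dt: float,
    params: PCISPHParams | None = None,
    pairs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Iterative pressure correction (predict positions -> densities -> pressures).

    Returns (pressures, pressure_forces, info); ``info['max_density_error']``
    is the maximum relative compression after the final iteration
    (rarefaction at free surfaces is not counted as error).
    """
    if params is None:
        params = PCISPHParams()
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not 0 < params.eta < 1:
        raise ValueError("eta must be in (0, 1)")
    if pairs is None:
        pairs = neighbor_pairs(sys.positions, sys.h)
    spacing = sys.spacing if sys.spacing is not None else sys.h / 1.3
    m_ref = float(np.median(sys.masses))
    delta = params.relaxation * precompute_delta(
        sys.h, sys.dimension, spacing, m_ref, sys.rho0, dt
    )

    mobile = sys.mobile
    p = np.zeros(sys.n)
    fp = np.zeros_like(sys.positions)
    err = np.inf
    it = 0
    inv_m = 1.0 / sys.masses[:, None]
    while it < params.min_iters or (it < params.max_iters and err > params.eta):
        v_pred = sys.velocities + dt * (f_ext + fp) * inv_m
        v_pred[~mobile] = 0.0
        x_pred = sys.positions + dt * v_pred
        x_pred[~mobile] = sys.positions[~mobile]
        rho_pred = compute_densities(sys, pairs=pairs, positions=x_pred)
        rho_err = rho_pred - sys.rho0
        p = np.maximum(p + delta * rho_err, 0.0)
        p[~mobile] = 0.0
        fp = _pressure_forces(sys, pairs, p, rho_pred, x_pred)
        err = float(np.max(np.maximum(rho_err, 0.0)[mobile], initial=0.0) / sys.rho0)
        it += 1
    if err > 10 * params.eta:
        warnings.warn(
            f"PCISPH hit iteration cap with relative density error {err:.3g}",
            RuntimeWarning,
            stacklevel=2,
        )
    return p, fp, {"max_density_error": err, "iterations": it}


def enforce_boundaries(sys: ParticleSystem, box: Box | None) -> None:
    """Project penetrating particles back to analytic box walls.

    Normal velocity of a penetrating particle is removed (inelastic
    contact); tangential velocity is preserved. BOUNDARY particles are
    untouched.
    """
    if box is None:
        return
    mobile = sys.mobile
    for ax in range(sys.dimension):
        x = sys.positions[:, ax]
        v = sys.velocities[:, ax]
        low = mobile & (x < box.lo[ax])
        x[low] = box.lo[ax]
        v[low] = np.maximum(v[low], 0.0)
        high = mobile & (x > box.hi[ax])
        x[high] = box.hi[ax]
        v[high] = np.minimum(v[high], 0.0)


def cfl_dt(sys: ParticleSystem, safety: float = 0.25) -> float:
    """CFL-style timestep cap dt <= safety * h / v_max."""
    vmax = float(np.max(np.linalg.norm(sys.velocities, axis=1), initial=0.0))
    if vmax == 0:
        return np.inf
    return safety * sys.h / vmax


def advance(
    sys: ParticleSystem,
    springs: SpringSet | None,
    dt: float,
    gravity: np.ndarray | None = None,
    box: Box | None = None,
    external_forces: np.ndarray | None = None,
    pcisph: PCISPHParams | None = None,
    incompressible: bool = True,
) -> dict:
    """One full timestep; mutates ``sys`` in place and returns diagnostics.

    Deterministic given identical state; BOUNDARY particles never move.
    ``incompressible=False`` skips the pressure solve (useful for purely
    elastic scenes).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    cap = cfl_dt(sys)
    if dt > cap:
        warnings.warn(
            f"dt={dt:.3g} exceeds CFL cap {cap:.3g}; expect instability",
            RuntimeWarning,
            stacklevel=2,
        )
    pairs = neighbor_pairs(sys.positions, sys.h)
    sys.densities = compute_densities(sys, pairs=pairs)
    f = compute_nonpressure_forces(sys, springs, gravity, pairs=pairs)
    f += compute_surface_tension(sys, pairs=pairs)
    if external_forces is not None:
        f += external_forces
    info = {"max_density_error": 0.0, "iterations": 0}
    if incompressible:
        p, fp, info = pcisph_correct(sys, f, dt, params=pcisph, pairs=pairs)
        sys.pressures = p
        f = f + fp
    mobile = sys.mobile
    sys.velocities[mobile] += dt * f[mobile] / sys.masses[mobile, None]
    sys.positions[mobile] += dt * sys.velocities[mobile]
    enforce_boundaries(sys, box)
    bad = np.isnan(sys.positions).any(axis=1) | np.isnan(sys.velocities).any(axis=1)
    if bad.any():
        first = int(np.argmax(bad))
        raise NumericError(f"NaN state at particle {first}")
    return info
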