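"""Compact-support smoothing kernels for SPH interpolation.

Three canonical kernels are used, each for the quantity it is numerically
best suited to:

* ``poly6`` for density summation (smooth, nonnegative, maximal at r=0),
* the ``spiky`` gradient for pressure forces (non-vanishing gradient at
  small separations, so overlapping particles still repel),
* the viscosity Laplacian (nonnegative, so viscous coupling always damps
  relative motion).

All kernels have support radius ``h`` and dimension-specific normalization
so that the density kernel integrates to one over its support in both 2D
and 3D.
"""

from __future__ import annotations

from enum import Enum

import numpy as np


class KernelKind(str, Enum):
    DENSITY = "density"
    PRESSURE_GRAD = "pressure_grad"
    VISCOSITY_LAP = "viscosity_lap"


def poly6_coeff(h: float, d: int) -> float:
    """Normalization of the poly6 kernel W(r) = C (h^2 - r^2)^3."""
    if d == 2:
        return 4.0 / (np.pi * h**8)
    if d == 3:
        return 315.0 / (64.0 * np.pi * h**9)
    raise ValueError(f"dimension must be 2 or 3, got {d}")


def spiky_grad_coeff(h: float, d: int) -> float:
    """Radial derivative coefficient of the spiky kernel: dW/dr = C (h - r)^2.

    C is negative (W decreases with r).
    """
    if d == 2:
        return -30.0 / (np.pi * h**5)
    if d == 3:
        return -45.0 / (np.pi * h**6)
    raise ValueError(f"dimension must be 2 or 3, got {d}")


def viscosity_lap_coeff(h: float, d: int) -> float:
    """Laplacian coefficient of the viscosity kernel: lap W = C (h - r)."""
    if d == 2:
        return 40.0 / (np.pi * h**5)
    if d == 3:
        return 45.0 / (np.pi * h**6)
    raise ValueError(f"dimension must be 2 or 3, got {d}")


def eval_kernel(r, h: float, kind: KernelKind | str, d: int = 2):
    """Evaluate a smoothing kernel (or its radial derivative/Laplacian).

    Parameters
    ----------
    r : float or array
        Particle separation, meters; must be nonnegative.
    h : float
        Smoothing length (support radius), meters.
    kind : KernelKind
        DENSITY -> poly6 value; PRESSURE_GRAD -> radial derivative dW/dr of
        the spiky kernel (negative inside the support); VISCOSITY_LAP ->
        Laplacian of the viscosity kernel.
    d : int
        Spatial dimension, 2 or 3.

    Returns
    -------
    Kernel value(s); exactly zero for r >= h (compact support).
    """
    if h <= 0:
        raise ValueError(f"smoothing length h must be positive, got {h}")
    kind = KernelKind(kind)
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("separation r must be nonnegative")
    inside = r < h
    out = np.zeros_like(r)
    if kind is KernelKind.DENSITY:
        out = np.where(inside, poly6_coeff(h, d) * (h**2 - r**2) ** 3, 0.0)
    elif kind is KernelKind.PRESSURE_GRAD:
        out = np.where(inside, spiky_grad_coeff(h, d) * (h - r) ** 2, 0.0)
    elif kind is KernelKind.VISCOSITY_LAP:
        out = np.where(inside, viscosity_lap_coeff(h, d) * (h - r), 0.0)
    return out if out.ndim else float(out)
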