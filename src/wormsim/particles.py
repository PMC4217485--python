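"""Particle containers and neighbor search for the SPH engine.

A :class:`ParticleSystem` holds the state of every physics particle: fluid
(LIQUID), soft-tissue (ELASTIC, connected by springs) and frozen wall
particles (BOUNDARY, never integrated). A :class:`SpringSet` holds the
elastic links, including which body-wall muscle (if any) each spring
belongs to.

Neighbor search is a uniform grid with cell size equal to the smoothing
length; a brute-force O(N^2) variant is kept as an independent oracle for
testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# particle kinds
LIQUID = 0
ELASTIC = 1
BOUNDARY = 2

KIND_NAMES = {LIQUID: "LIQUID", ELASTIC: "ELASTIC", BOUNDARY: "BOUNDARY"}


@dataclass
class ParticleSystem:
    """State of all physics particles.

    Units are SI throughout; in 2D, densities are kg/m^2 and the rest
    density default of 1000 is interpreted per unit depth.
    """

    dimension: int
    positions: np.ndarray  # [N, d], m
    velocities: np.ndarray  # [N, d], m/s
    masses: np.ndarray  # [N], kg
    kinds: np.ndarray  # [N], LIQUID/ELASTIC/BOUNDARY
    h: float  # smoothing length, m
    rho0: float = 1000.0  # rest density, kg/m^d
    mu: float = 0.0  # dynamic viscosity
    kappa: float = 0.0  # surface-tension scaling (dimensionless)
    spacing: float | None = None  # particle spacing used at construction
    densities: np.ndarray = field(default=None)  # [N]
    pressures: np.ndarray = field(default=None)  # [N]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.kinds = np.asarray(self.kinds, dtype=np.int64)
        if self.densities is None:
            self.densities = np.zeros(self.n)
        if self.pressures is None:
            self.pressures = np.zeros(self.n)
        self.validate()

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def validate(self) -> None:
        if self.dimension not in (2, 3):
            raise ValueError(f"dimension must be 2 or 3, got {self.dimension}")
        n, d = self.positions.shape
        if d != self.dimension:
            raise ValueError("positions second axis must equal dimension")
        for name, arr, shape in (
            ("velocities", self.velocities, (n, d)),
            ("masses", self.masses, (n,)),
            ("kinds", self.kinds, (n,)),
            ("densities", self.densities, (n,)),
            ("pressures", self.pressures, (n,)),
        ):
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        if self.h <= 0:
            raise ValueError("smoothing length h must be positive")
        if self.rho0 <= 0:
            raise ValueError("rest density rho0 must be positive")
        if not np.all(np.isin(self.kinds, (LIQUID, ELASTIC, BOUNDARY))):
            raise ValueError("unknown particle kind")

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            dimension=self.dimension,
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            masses=self.masses.copy(),
            kinds=self.kinds.copy(),
            h=self.h,
            rho0=self.rho0,
            mu=self.mu,
            kappa=self.kappa,
            spacing=self.spacing,
            densities=self.densities.copy(),
            pressures=self.pressures.copy(),
        )

    @property
    def mobile(self) -> np.ndarray:
        """Boolean mask of particles that are integrated (not BOUNDARY)."""
        return self.kinds != BOUNDARY


@dataclass
class SpringSet:
    """Elastic links between particle pairs.

    ``stiffness`` is the force (N) at 100% strain: F = k (L - r0) / r0.
    ``muscle_id`` gives the primary owning muscle per spring, -1 for none;
    muscles may additionally share springs (see the body model).
    """

    pairs: np.ndarray  # [S, 2] int
    rest_lengths: np.ndarray  # [S], m
    stiffness: np.ndarray  # [S], N
    muscle_id: np.ndarray = None  # [S] int, -1 = none

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        self.rest_lengths = np.asarray(self.rest_lengths, dtype=float)
        self.stiffness = np.asarray(self.stiffness, dtype=float)
        if self.muscle_id is None:
            self.muscle_id = np.full(len(self.pairs), -1, dtype=np.int64)
        self.muscle_id = np.asarray(self.muscle_id, dtype=np.int64)
        s = len(self.pairs)
        if self.rest_lengths.shape != (s,) or self.stiffness.shape != (s,):
            raise ValueError("spring arrays must share leading dimension")
        if np.any(self.pairs[:, 0] == self.pairs[:, 1]):
            raise ValueError("spring endpoints must be distinct")
        if np.any(self.rest_lengths <= 0):
            raise ValueError("rest lengths must be positive")
        if np.any(self.stiffness < 0):
            raise ValueError("stiffness must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.pairs)

    @classmethod
    def empty(cls) -> "SpringSet":
        return cls(
            pairs=np.zeros((0, 2), dtype=np.int64),
            rest_lengths=np.zeros(0),
            stiffness=np.zeros(0),
        )


def neighbor_pairs_bruteforce(positions: np.ndarray, h: float) -> np.ndarray:
    """All pairs (i < j) with |x_i - x_j| < h, by direct O(N^2) evaluation."""
    n = positions.shape[0]
    if n < 2:
        return np.zeros((0, 2), dtype=np.int64)
    diff = positions[:, None, :] - positions[None, :, :]
    r2 = np.einsum("ijk,ijk->ij", diff, diff)
    iu, ju = np.triu_indices(n, k=1)
    mask = r2[iu, ju] < h * h
    return np.column_stack([iu[mask], ju[mask]])


def _multi_range(starts: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Concatenate ranges [starts_k, starts_k + counts_k) without a loop."""
    total = int(counts.sum())
    if total == 0:
        return np.zeros(0, dtype=np.int64)
    reset = np.repeat(starts - np.concatenate([[0], np.cumsum(counts)[:-1]]), counts)
    return np.arange(total, dtype=np.int64) + reset


def neighbor_pairs_grid(positions: np.ndarray, h: float) -> np.ndarray:
    """All pairs (i < j) with |x_i - x_j| < h via a uniform grid, cell size h.

    Particles are binned into cells, sorted by linearized cell key, and a
    forward half-stencil of neighbor cells is matched with searchsorted, so
    each candidate cell pair is visited once and everything stays
    vectorized.
    """
    n, d = positions.shape
    if n < 2:
        return np.zeros((0, 2), dtype=np.int64)
    cells = np.floor(positions / h).astype(np.int64)
    cells -= cells.min(axis=0) - 1  # pad so +/-1 offsets never wrap keys
    dims = cells.max(axis=0) + 3
    key = cells[:, 0]
    for ax in range(1, d):
        key = key * dims[ax] + cells[:, ax]
    order = np.argsort(key, kind="stable")
    skey = key[order]
    spos = positions[order]

    offsets = [
        off
        for off in np.ndindex(*([3] * d))
        if tuple(o - 1 for o in off) > tuple([0] * d)
    ]
    offsets = [tuple(o - 1 for o in off) for off in offsets]

    cand_i: list[np.ndarray] = []
    cand_j: list[np.ndarray] = []
    idx = np.arange(n, dtype=np.int64)
    # same cell: contiguous run after sorting; take j > i within the run
    run_end = np.searchsorted(skey, skey, side="right")
    counts0 = run_end - idx - 1
    cand_i.append(np.repeat(idx, counts0))
    cand_j.append(_multi_range(idx + 1, counts0))
    for off in offsets:
        dkey = off[0]
        for ax in range(1, d):
            dkey = dkey * dims[ax] + off[ax]
        tk = skey + dkey
        starts = np.searchsorted(skey, tk, side="left")
        ends = np.searchsorted(skey, tk, side="right")
        counts = ends - starts
        cand_i.append(np.repeat(idx, counts))
        cand_j.append(_multi_range(starts, counts))
    ci = np.concatenate(cand_i)
    cj = np.concatenate(cand_j)
    diff = spos[ci] - spos[cj]
    mask = np.einsum("ij,ij->i", diff, diff) < h * h
    i = order[ci[mask]]
    j = order[cj[mask]]
    lo = np.minimum(i, j)
    hi = np.maximum(i, j)
    sorter = np.lexsort((hi, lo))
    return np.column_stack([lo[sorter], hi[sorter]])


def neighbor_pairs(positions: np.ndarray, h: float, method: str = "grid") -> np.ndarray:
    if method == "grid":
        return neighbor_pairs_grid(positions, h)
    if method == "bruteforce":
        pairs = neighbor_pairs_bruteforce(positions, h)
        return pairs
    raise ValueError(f"unknown neighbor search method {method!r}")
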