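"""Canonical worm body: elastic shell, pressurized interior, 95 muscles.

The body is a hydrostatic skeleton: a closed loop of ELASTIC shell
particles linked by springs (structural along the outline, cross "ribs"
between dorsal and ventral edges, and diagonals for shear stiffness)
enclosing LIQUID particles whose mass is raised slightly above the ambient
rest mass, so the interior is pressurized and keeps the shell inflated.

The 95 body-wall muscles are laid out in four longitudinal rows — dorsal
left (24), dorsal right (24), ventral left (23), ventral right (24),
anterior to posterior, matching the anatomical arrangement in C. elegans.
In the default 2D body the two dorsal rows act on the dorsal edge springs
and the two ventral rows on the ventral edge springs; each edge spring is
therefore shared by one left-row and one right-row muscle, and the
rest-length scaling factors of co-owning muscles multiply.

Muscle activation a in [0, 1] contracts a muscle by scaling the rest
lengths of its springs to r0 (1 - c_max a); the scaling is always applied
to the original rest lengths, so repeated application is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LinearRing

from .kernels import eval_kernel
from .particles import ELASTIC, LIQUID, ParticleSystem, SpringSet

ROWS = ("DL", "DR", "VL", "VR")
ROW_COUNTS = {"DL": 24, "DR": 24, "VL": 23, "VR": 24}
N_MUSCLES = 95


@dataclass
class BodySpec:
    """Geometry and material parameters of the default worm body.

    Lengths are meters. The default is a 1 mm body with 10:1 aspect ratio,
    particle spacing 20 um, and an interior pressurization of 5% above the
    ambient rest density.
    """

    length: float = 1.0e-3
    width: float | None = None  # default length / 10
    spacing: float = 2.0e-5
    rho0: float = 1000.0
    mu: float = 2.0e-4  # explicit viscosity must respect dt < s^2 rho / (4 mu)
    shell_stiffness: float = 2.0e-5  # N at 100% strain
    cross_stiffness: float = 1.0e-5
    diag_stiffness: float = 5.0e-6
    interior_pressure_offset: float = 0.05
    c_max: float = 0.3  # max fractional muscle contraction

    def __post_init__(self) -> None:
        if self.width is None:
            self.width = self.length / 10.0


@dataclass
class MuscleElement:
    id: int  # 0..94
    row: str  # DL / DR / VL / VR
    segment_index: int  # along the body axis within its row
    spring_ids: np.ndarray  # indices into the body's SpringSet
    activation: float = 0.0


@dataclass
class WormBody:
    system: ParticleSystem
    springs: SpringSet
    shell_indices: np.ndarray  # ordered closed loop (ELASTIC)
    dorsal_indices: np.ndarray  # head -> tail along the dorsal edge
    ventral_indices: np.ndarray  # head -> tail along the ventral edge
    head_tip: int
    tail_tip: int
    interior_indices: np.ndarray  # LIQUID inside the shell
    muscles: list = field(default_factory=list)
    body_length: float = 0.0
    c_max: float = 0.3
    base_rest_lengths: np.ndarray = None

    def __post_init__(self) -> None:
        if self.base_rest_lengths is None:
            self.base_rest_lengths = self.springs.rest_lengths.copy()

    @property
    def membrane_segments(self) -> np.ndarray:
        """Consecutive shell index pairs forming the closed membrane loop."""
        nxt = np.roll(self.shell_indices, -1)
        return np.column_stack([self.shell_indices, nxt])

    def shell_polygon(self) -> np.ndarray:
        return self.system.positions[self.shell_indices]

    def shell_area(self) -> float:
        """Signed shoelace area of the shell loop (2D)."""
        pts = self.shell_polygon()
        x, y = pts[:, 0], pts[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _capsule_inside(pts: np.ndarray, length: float, radius: float, margin: float) -> np.ndarray:
    """True where points lie inside the capsule shrunk by ``margin``."""
    ax = np.clip(pts[:, 0], radius, length - radius)
    d = np.sqrt((pts[:, 0] - ax) ** 2 + pts[:, 1] ** 2)
    return d < radius - margin


def _calibrated_mass(spacing: float, h: float, rho0: float, d: int) -> float:
    """Mass making a filled regular lattice sum to rho0 exactly."""
    k = int(np.ceil(h / spacing)) + 1
    r = np.arange(-k, k + 1)
    grids = np.meshgrid(*([r] * d), indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1) * spacing
    rr = np.linalg.norm(pts, axis=1)
    wsum = float(np.sum(eval_kernel(rr[rr < h], h, "density", d)))
    return rho0 / wsum


def build_worm_body(spec: BodySpec | None = None) -> WormBody:
    """Construct the canonical 2D worm body from a :class:`BodySpec`.

    The shell is a capsule outline (two straight edges plus semicircular
    head and tail caps) sampled at the particle spacing; the interior is a
    regular lattice of LIQUID particles. Exactly 95 muscles are laid out
    along the edges; construction fails if the discretization is too
    coarse for every muscle to own at least one spring.
    """
    if spec is None:
        spec = BodySpec()
    length, width, s = spec.length, spec.width, spec.spacing
    if s > width / 4:
        raise ValueError(
            f"particle spacing {s:g} exceeds width/4 = {width / 4:g}; "
            "the shell would not be impermeable"
        )
    radius = width / 2.0
    straight = length - 2 * radius
    if straight <= 0:
        raise ValueError("length must exceed width (elongated body)")
    h = 1.3 * s

    n_edge = int(round(straight / s))
    xs = radius + np.arange(n_edge + 1) * (straight / n_edge)
    dorsal = np.column_stack([xs, np.full(n_edge + 1, radius)])
    ventral = np.column_stack([xs, np.full(n_edge + 1, -radius)])

    n_cap = max(int(round(np.pi * radius / s)) - 1, 1)
    # head cap: from dorsal-first around the nose to ventral-first (x < radius)
    ang = np.pi / 2 + np.arange(1, n_cap + 1) * np.pi / (n_cap + 1)
    head_cap = np.column_stack([radius + radius * np.cos(ang), radius * np.sin(ang)])
    # tail cap: from dorsal-last around the tail to ventral-last (x > length - radius)
    ang_t = np.pi / 2 - np.arange(1, n_cap + 1) * np.pi / (n_cap + 1)
    tail_cap = np.column_stack(
        [length - radius + radius * np.cos(ang_t), radius * np.sin(ang_t)]
    )

    # loop order: dorsal head->tail, tail cap, ventral tail->head, head cap
    shell_pts = np.concatenate([dorsal, tail_cap, ventral[::-1], head_cap[::-1]])
    n_shell = len(shell_pts)
    dorsal_idx = np.arange(n_edge + 1)
    tail_cap_idx = np.arange(n_edge + 1, n_edge + 1 + n_cap)
    ventral_idx = np.arange(
        n_edge + 1 + n_cap, 2 * (n_edge + 1) + n_cap
    )[::-1]  # head -> tail order
    head_cap_idx = np.arange(2 * (n_edge + 1) + n_cap, n_shell)
    head_tip = int(head_cap_idx[len(head_cap_idx) // 2])
    tail_tip = int(tail_cap_idx[len(tail_cap_idx) // 2])

    # interior lattice
    gx = np.arange(s, length, s)
    gy = np.arange(-radius + s, radius, s)
    gxx, gyy = np.meshgrid(gx, gy, indexing="ij")
    lattice = np.column_stack([gxx.ravel(), gyy.ravel()])
    inside = _capsule_inside(lattice, length, radius, 0.75 * s)
    interior_pts = lattice[inside]
    n_int = len(interior_pts)

    positions = np.concatenate([shell_pts, interior_pts])
    n = len(positions)
    kinds = np.concatenate(
        [np.full(n_shell, ELASTIC, dtype=np.int64), np.full(n_int, LIQUID, dtype=np.int64)]
    )
    m0 = _calibrated_mass(s, h, spec.rho0, 2)
    masses = np.full(n, m0)
    masses[n_shell:] *= 1.0 + spec.interior_pressure_offset

    system = ParticleSystem(
        dimension=2,
        positions=positions,
        velocities=np.zeros_like(positions),
        masses=masses,
        kinds=kinds,
        h=h,
        rho0=spec.rho0,
        mu=spec.mu,
        kappa=0.0,
        spacing=s,
    )

    # springs: structural loop, cross ribs, diagonals
    pairs, stiff = [], []
    loop = np.arange(n_shell)
    for a, b in zip(loop, np.roll(loop, -1)):
        pairs.append((a, b))
        stiff.append(spec.shell_stiffness)
    n_loop = len(pairs)
    for k in range(n_edge + 1):
        pairs.append((dorsal_idx[k], ventral_idx[k]))
        stiff.append(spec.cross_stiffness)
    for k in range(n_edge):
        pairs.append((dorsal_idx[k], ventral_idx[k + 1]))
        stiff.append(spec.diag_stiffness)
        pairs.append((ventral_idx[k], dorsal_idx[k + 1]))
        stiff.append(spec.diag_stiffness)
    pairs = np.asarray(pairs, dtype=np.int64)
    stiff = np.asarray(stiff)
    rest = np.linalg.norm(positions[pairs[:, 0]] - positions[pairs[:, 1]], axis=1)
    springs = SpringSet(pairs=pairs, rest_lengths=rest, stiffness=stiff)

    # dorsal edge springs are loop springs 0..n_edge-1; ventral edge springs
    # run along the ventral straight section of the loop
    dorsal_springs = np.arange(n_edge)
    ventral_loop_start = n_edge + 1 + n_cap  # first ventral particle in loop order
    # loop springs connect (k, k+1); ventral straight section spans those indices
    ventral_springs = np.arange(ventral_loop_start, ventral_loop_start + n_edge)

    def spring_axial_fraction(spring_ids: np.ndarray) -> np.ndarray:
        mid = 0.5 * (
            positions[pairs[spring_ids, 0], 0] + positions[pairs[spring_ids, 1], 0]
        )
        return (mid - radius) / straight

    muscles: list[MuscleElement] = []
    mid = 0
    edge_map = {"DL": dorsal_springs, "DR": dorsal_springs,
                "VL": ventral_springs, "VR": ventral_springs}
    for row in ROWS:
        n_row = ROW_COUNTS[row]
        edge = edge_map[row]
        frac = np.clip(spring_axial_fraction(edge), 0.0, 1.0 - 1e-12)
        bins = np.floor(frac * n_row).astype(int)
        for seg in range(n_row):
            own = edge[bins == seg]
            if len(own) == 0:
                raise ValueError(
                    f"muscle {row}{seg} owns no spring; decrease particle spacing"
                )
            muscles.append(
                MuscleElement(id=mid, row=row, segment_index=seg, spring_ids=own)
            )
            mid += 1
    assert len(muscles) == N_MUSCLES

    # primary owner per spring (first muscle claiming it)
    for m in reversed(muscles):
        springs.muscle_id[m.spring_ids] = m.id

    return WormBody(
        system=system,
        springs=springs,
        shell_indices=loop,
        dorsal_indices=dorsal_idx,
        ventral_indices=ventral_idx,
        head_tip=head_tip,
        tail_tip=tail_tip,
        interior_indices=np.arange(n_shell, n),
        muscles=muscles,
        body_length=length,
        c_max=spec.c_max,
    )


def set_muscle_activations(body: WormBody, a: np.ndarray) -> WormBody:
    """Apply activations a[95] in [0,1] by scaling muscle-spring rest lengths.

    Springs shared between a left-row and right-row muscle multiply their
    factors. Always starts from the original rest lengths (idempotent).
    """
    a = np.asarray(a, dtype=float)
    if a.shape != (N_MUSCLES,):
        raise ValueError(f"activations must have shape ({N_MUSCLES},), got {a.shape}")
    if np.any((a < 0) | (a > 1)) or np.any(np.isnan(a)):
        raise ValueError("activations must lie in [0, 1]")
    factors = np.ones(body.springs.n)
    for m in body.muscles:
        m.activation = float(a[m.id])
        factors[m.spring_ids] *= 1.0 - body.c_max * a[m.id]
    body.springs.rest_lengths = body.base_rest_lengths * factors
    return body


def extract_midline(body: WormBody, n_points: int = 49) -> np.ndarray:
    """Midline by pairing opposite dorsal/ventral shell particles.

    Returns ``n_points`` points head -> tail, equally spaced by arc length.
    Raises on a self-intersecting (degenerate) shell.
    """
    ring = LinearRing(body.shell_polygon())
    if not ring.is_simple:
        raise ValueError("shell loop is self-intersecting; midline undefined")
    pos = body.system.positions
    mids = 0.5 * (pos[body.dorsal_indices] + pos[body.ventral_indices])
    pts = np.concatenate([[pos[body.head_tip]], mids, [pos[body.tail_tip]]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, arc[-1], n_points)
    out = np.column_stack(
        [np.interp(targets, arc, pts[:, k]) for k in range(pts.shape[1])]
    )
    return out


def _segments_cross(p0, p1, q0, q1) -> np.ndarray:
    """Vectorized proper-intersection test between segment batches."""

    def orient(a, b, c):
        return (b[..., 0] - a[..., 0]) * (c[..., 1] - a[..., 1]) - (
            b[..., 1] - a[..., 1]
        ) * (c[..., 0] - a[..., 0])

    d1 = orient(q0, q1, p0)
    d2 = orient(q0, q1, p1)
    d3 = orient(p0, p1, q0)
    d4 = orient(p0, p1, q1)
    return (d1 * d2 < 0) & (d3 * d4 < 0)


def enforce_membrane(body: WormBody, old_positions: np.ndarray) -> int:
    """Keep interior liquid inside the shell by segment-crossing reflection.

    Any interior particle whose step crossed a membrane segment is
    reflected back across that segment's line and loses its normal
    velocity component. Returns the number of corrected particles.
    """
    sys = body.system
    segs = body.membrane_segments
    q0 = sys.positions[segs[:, 0]]  # [M, 2]
    q1 = sys.positions[segs[:, 1]]
    idx = body.interior_indices
    p0 = old_positions[idx]
    p1 = sys.positions[idx]
    corrected = 0
    for _ in range(2):  # a reflection may cross a second segment at corners
        cross = _segments_cross(
            p0[:, None, :], p1[:, None, :], q0[None, :, :], q1[None, :, :]
        )  # [n_int, M]
        hit_any = cross.any(axis=1)
        if not hit_any.any():
            break
        which = np.argmax(cross, axis=1)
        for k in np.flatnonzero(hit_any):
            m = which[k]
            a, b = q0[m], q1[m]
            t = b - a
            t = t / max(np.linalg.norm(t), 1e-300)
            nrm = np.array([-t[1], t[0]])
            i = idx[k]
            x = sys.positions[i]
            dist = (x - a) @ nrm
            sys.positions[i] = x - 2.0 * dist * nrm
            vn = sys.velocities[i] @ nrm
            sys.velocities[i] = sys.velocities[i] - vn * nrm
            corrected += 1
        p1 = sys.positions[idx]
    return corrected
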