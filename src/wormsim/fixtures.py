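"""Synthetic generators: every module is testable without downloads.

Each generator derives its random stream from ``(kind, seed)`` through a
namespaced counter-based seed, so adding new fixtures never perturbs the
output of existing ones, and the same (spec, seed) always reproduces the
same bytes.
"""

from __future__ import annotations

import zlib

import numpy as np

from .behavior import MidlineTrack
from .neural import Connectome, Neuron, Synapse, CHEMICAL, ELECTRICAL, EXC, INH
from .particles import BOUNDARY, LIQUID, ParticleSystem
from .body import N_MUSCLES, _calibrated_mass
from .engine import Box


def _rng(kind: str, seed: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(kind.encode())])
    )


def make_toy_connectome(
    n_sensory: int,
    n_inter: int,
    n_motor: int,
    p_edge: float,
    seed: int = 0,
    p_recurrent_scale: float = 0.3,
):
    """Random feed-forward-biased digraph with categorized neurons.

    Forward edges (sensory->inter, inter->motor) appear with probability
    ``p_edge``; recurrent inter->inter edges with ``p_recurrent_scale *
    p_edge``. About 10% of edges are ELECTRICAL. Motor neurons get
    ``target_muscle`` assignments cycling 0..94.

    Returns (Connectome, metadata list of Neuron).
    """
    if min(n_sensory, n_inter, n_motor) < 0 or not 0 <= p_edge <= 1:
        raise ValueError("counts must be nonnegative and p_edge in [0, 1]")
    rng = _rng("TOY_CONNECTOME", seed)
    sensory = [f"SEN{i:02d}" for i in range(n_sensory)]
    inter = [f"INT{i:02d}" for i in range(n_inter)]
    motor = [f"MOT{i:02d}" for i in range(n_motor)]
    neurons = (
        [Neuron(nm, "SENSORY") for nm in sensory]
        + [Neuron(nm, "INTER") for nm in inter]
        + [Neuron(nm, "MOTOR", k % N_MUSCLES) for k, nm in enumerate(motor)]
    )
    synapses = []

    def maybe_edge(pre: str, post: str, p: float) -> None:
        if rng.random() >= p:
            return
        kind = ELECTRICAL if rng.random() < 0.1 else CHEMICAL
        pol = INH if (kind == CHEMICAL and rng.random() < 0.3) else EXC
        w = float(rng.uniform(0.5, 2.0))
        synapses.append(Synapse(pre, post, kind, w, pol))

    for a in sensory:
        for b in inter:
            maybe_edge(a, b, p_edge)
    for a in inter:
        for b in motor:
            maybe_edge(a, b, p_edge)
    for a in inter:
        for b in inter:
            if a != b:
                maybe_edge(a, b, p_edge * p_recurrent_scale)
    return Connectome(neurons=neurons, synapses=synapses), neurons


def make_wave_track(
    L: float = 1.0e-3,
    amplitude: float = 5.0e-5,
    wavelength_frac: float = 0.6,
    freq: float = 0.5,
    speed: float = 1.0e-4,
    duration: float = 20.0,
    dt: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_points: int = 49,
    label: str = "wave",
) -> MidlineTrack:
    """Analytic traveling-wave midline advected at constant speed.

    y(u, t) = A sin(2 pi u / lambda_frac - 2 pi f t), with the per-frame
    mean of y subtracted so the centroid moves exactly at ``speed`` along
    the body axis (head first, toward +x).
    """
    if min(L, wavelength_frac, duration, dt) <= 0 or wavelength_frac > 2:
        raise ValueError("invalid wave-track parameters")
    rng = _rng("WAVE_TRACK", seed)
    times = np.arange(0.0, duration, dt)
    u = np.linspace(0.0, 1.0, n_points)  # head at u = 0
    tt = times[:, None]
    y = amplitude * np.sin(2 * np.pi * u[None, :] / wavelength_frac - 2 * np.pi * freq * tt)
    y = y - y.mean(axis=1, keepdims=True)
    x = speed * tt - u[None, :] * L
    pts = np.stack([x, y], axis=-1)
    if noise_sd > 0:
        pts = pts + rng.normal(0.0, noise_sd, size=pts.shape)
    return MidlineTrack(times=times, points=pts, label=label)


def make_wave_population(
    n_tracks: int,
    seed: int = 0,
    speed_mean: float = 1.0e-4,
    speed_sd: float = 1.0e-5,
    freq_mean: float = 0.5,
    freq_sd: float = 0.05,
    amplitude_mean: float = 5.0e-5,
    amplitude_sd: float = 5.0e-6,
    wavelength_mean: float = 0.6,
    wavelength_sd: float = 0.05,
    noise_sd: float = 2.0e-6,
    duration: float = 20.0,
    dt: float = 0.1,
) -> list:
    """A population of wave tracks with animal-to-animal variability.

    Per-track kinematic parameters are drawn from independent normals
    (clipped to positive), emulating the spread of individual worms within
    one strain; used as the null generator of the imitation game.
    """
    rng = _rng("WAVE_POPULATION", seed)
    tracks = []
    for k in range(n_tracks):
        speed = max(rng.normal(speed_mean, speed_sd), speed_mean * 0.1)
        freq = max(rng.normal(freq_mean, freq_sd), freq_mean * 0.1)
        amp = max(rng.normal(amplitude_mean, amplitude_sd), amplitude_mean * 0.1)
        wl = float(np.clip(rng.normal(wavelength_mean, wavelength_sd), 0.2, 1.8))
        tracks.append(
            make_wave_track(
                amplitude=amp,
                wavelength_frac=wl,
                freq=freq,
                speed=speed,
                duration=duration,
                dt=dt,
                noise_sd=noise_sd,
                seed=int(rng.integers(2**31 - 1)),
                label=f"wave{k}",
            )
        )
    return tracks


def make_reversal_track(
    L: float = 1.0e-3,
    speed: float = 1.0e-4,
    t_switch: float = 10.0,
    duration: float = 20.0,
    dt: float = 0.1,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> MidlineTrack:
    """Straight body translating head-first, then reversing at ``t_switch``."""
    rng = _rng("REVERSAL_TRACK", seed)
    times = np.arange(0.0, duration, dt)
    u = np.linspace(0.0, 1.0, 49)
    disp = np.where(times < t_switch, speed * times, speed * (2 * t_switch - times))
    x = disp[:, None] - u[None, :] * L
    y = np.zeros_like(x)
    pts = np.stack([x, y], axis=-1)
    if jitter_sd > 0:
        pts = pts + rng.normal(0.0, jitter_sd, size=pts.shape)
    return MidlineTrack(times=times, points=pts, label="reversal")


def make_curl_track(
    L: float = 1.0e-3,
    min_headtail_frac: float = 0.2,
    hold_frames: int = 5,
    duration: float = 20.0,
    dt: float = 0.1,
    seed: int = 0,
) -> MidlineTrack:
    """Body curls from straight into a constant-curvature arc and back.

    At peak curl the head-to-tail chord equals ``min_headtail_frac`` of the
    arc length, held for ``hold_frames`` frames.
    """
    from scipy.optimize import brentq

    times = np.arange(0.0, duration, dt)
    n_t = len(times)
    u = np.linspace(0.0, 1.0, 49)

    # chord/arc for a circular arc of total turn theta: sin(theta/2)/(theta/2)
    def chord_frac(theta):
        return np.sin(theta / 2.0) / (theta / 2.0)

    theta_max = brentq(lambda th: chord_frac(th) - min_headtail_frac, 1e-6, 2 * np.pi - 1e-9)
    mid = n_t // 2
    ramp_frames = max((n_t - hold_frames) // 2, 1)
    theta = np.zeros(n_t)
    start = mid - hold_frames // 2
    for k in range(n_t):
        if start <= k < start + hold_frames:
            theta[k] = theta_max
        elif k < start:
            theta[k] = theta_max * max(0.0, 1.0 - (start - k) / ramp_frames)
        else:
            theta[k] = theta_max * max(0.0, 1.0 - (k - (start + hold_frames - 1)) / ramp_frames)

    pts = np.zeros((n_t, 49, 2))
    for k in range(n_t):
        th = theta[k]
        if th < 1e-9:
            pts[k, :, 0] = -u * L
        else:
            R = L / th
            ang = u * th
            pts[k, :, 0] = -R * np.sin(ang)
            pts[k, :, 1] = R * (1 - np.cos(ang))
    return MidlineTrack(times=times, points=pts, label="curl")


def make_fluid_scene(
    kind: str,
    n_particles: int = 300,
    h: float = 2.6e-3,
    seed: int = 0,
    rho0: float = 1000.0,
    mu: float | None = None,
    kappa: float = 0.0,
    jitter: float = 0.0,
    velocity: tuple = (0.0, 0.0),
):
    """Toy 2D fluid scenes.

    ``DAM_BREAK``: a fluid column against the left wall of a closed box
    lined with frozen BOUNDARY particles; returns (system, box).
    ``DROPLET``: an isolated circular blob, no walls; returns (system, None).
    Deterministic per seed (jitter stream is namespaced).
    """
    if n_particles < 10:
        raise ValueError("n_particles must be >= 10")
    rng = _rng(kind, seed)
    s = h / 1.3
    m0 = _calibrated_mass(s, h, rho0, 2)
    if mu is None:
        # laminar regime keeps the desk-scale collapse resolvable at the
        # explicit timestep; the droplet default is close to water
        mu = 0.5 if kind == "DAM_BREAK" else 1.0e-3

    if kind == "DROPLET":
        r_blob = s * np.sqrt(n_particles / np.pi) * 1.5
        g = np.arange(-r_blob, r_blob + s, s)
        gx, gy = np.meshgrid(g, g, indexing="ij")
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        # n_particles lattice sites nearest the center: a compact round blob
        order = np.argsort(np.einsum("ij,ij->i", pts, pts), kind="stable")
        pts = pts[order[:n_particles]]
        if jitter > 0:
            pts = pts + rng.normal(0.0, jitter * s, size=pts.shape)
        vel = np.tile(np.asarray(velocity, dtype=float), (len(pts), 1))
        system = ParticleSystem(
            dimension=2,
            positions=pts,
            velocities=vel,
            masses=np.full(len(pts), m0),
            kinds=np.full(len(pts), LIQUID, dtype=np.int64),
            h=h,
            rho0=rho0,
            mu=mu,
            kappa=kappa,
            spacing=s,
        )
        return system, None

    if kind == "DAM_BREAK":
        # column ~ n_particles arranged 1:2 (width:height), box twice as wide
        ncol_x = max(int(np.sqrt(n_particles / 2.0)), 3)
        ncol_y = int(np.ceil(n_particles / ncol_x))
        width = 2.5 * ncol_x * s
        height = 1.5 * ncol_y * s
        fx = np.arange(ncol_x) * s + s
        fy = np.arange(ncol_y) * s + s
        gx, gy = np.meshgrid(fx, fy, indexing="ij")
        fluid = np.column_stack([gx.ravel(), gy.ravel()])[:n_particles]
        if jitter > 0:
            fluid = fluid + rng.normal(0.0, jitter * s, size=fluid.shape)
        # one layer of boundary particles around the box
        bx = np.arange(0.0, width + s / 2, s)
        by = np.arange(0.0, height + s / 2, s)
        bottom = np.column_stack([bx, np.zeros_like(bx)])
        top = np.column_stack([bx, np.full_like(bx, height)])
        left = np.column_stack([np.zeros_like(by[1:-1]), by[1:-1]])
        right = np.column_stack([np.full_like(by[1:-1], width), by[1:-1]])
        walls = np.concatenate([bottom, top, left, right])
        positions = np.concatenate([fluid, walls])
        kinds = np.concatenate(
            [
                np.full(len(fluid), LIQUID, dtype=np.int64),
                np.full(len(walls), BOUNDARY, dtype=np.int64),
            ]
        )
        system = ParticleSystem(
            dimension=2,
            positions=positions,
            velocities=np.zeros_like(positions),
            masses=np.full(len(positions), m0),
            kinds=kinds,
            h=h,
            rho0=rho0,
            mu=mu,
            kappa=kappa,
            spacing=s,
        )
        box = Box(lo=np.array([0.5 * s, 0.5 * s]), hi=np.array([width - 0.5 * s, height - 0.5 * s]))
        return system, box

    raise ValueError(f"unknown fluid scene kind {kind!r}")


def make_cpg_driver(
    freq: float = 2.0,
    amplitude: float = 1.0,
    wavelength_frac: float = 0.8,
):
    """Scripted central-pattern-generator surrogate.

    Returns a callable t_seconds -> activations[95]: a rectified sine wave
    traveling head to tail along each muscle row, dorsal and ventral rows
    in antiphase.
    """
    from .body import ROWS, ROW_COUNTS

    if not 0 < amplitude <= 1:
        raise ValueError("amplitude must be in (0, 1]")

    rows = []
    for row in ROWS:
        n_row = ROW_COUNTS[row]
        u = (np.arange(n_row) + 0.5) / n_row
        sign = 1.0 if row.startswith("D") else -1.0
        rows.append((u, sign))

    def driver(t: float) -> np.ndarray:
        out = []
        for u, sign in rows:
            phase = 2 * np.pi * (freq * t - u / wavelength_frac)
            out.append(np.maximum(sign * np.sin(phase), 0.0) * amplitude)
        return np.concatenate(out)

    return driver
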