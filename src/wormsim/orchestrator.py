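"""Couple the neural and physics modules on a shared clock.

The physics clock is the master (its timestep is the stability
bottleneck); the neural model is sub-stepped to fill each exchange window,
after which motor-neuron voltages are mapped to muscle activations and
held constant (sample-and-hold) until the next exchange.

Drivers:

* ``connectome`` — a loaded wiring diagram simulated at the LI or HH
  level; motor neurons with ``target_muscle`` metadata drive the muscles.
* ``cpg`` — a scripted central-pattern-generator surrogate producing
  rhythmic activations directly (no nervous system), for physics-only
  studies and calibration.
* ``none`` — passive body.

The default environment is a resistive medium: shell particles feel
anisotropic drag (normal coefficient larger than tangential), the standard
abstraction of a crawling/swimming substrate in undulatory-locomotion
models. Runs are bitwise reproducible for a fixed config and seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import engine
from .behavior import MidlineTrack
from .body import N_MUSCLES, BodySpec, WormBody, build_worm_body, enforce_membrane, extract_midline, set_muscle_activations
from .engine import Box, PCISPHParams
from .fixtures import make_cpg_driver
from .io import write_trajectory
from .neural import NetworkSimulator, load_connectome_table, load_connectome_neuroml

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class SimulationConfig:
    """Everything needed for one run; loadable from YAML."""

    body: dict = field(default_factory=dict)
    # resistive environment: normal drag 5x tangential turns undulation into
    # thrust; coefficients are per-particle, N s/m
    environment: dict = field(
        default_factory=lambda: {"drag_tangent": 1.6e-5, "drag_normal": 8.0e-5}
    )
    driver: dict = field(default_factory=lambda: {"kind": "none"})
    neural: dict = field(default_factory=dict)  # level, dt_ms, connectome paths, v_lo/v_hi
    dt_physics: float = 2.0e-4  # s
    exchange_every: int = 5  # physics steps per neural exchange
    duration: float = 1.0  # s
    frame_stride: int = 10  # physics steps per output frame
    seed: int = 0
    output: str | None = None
    schema_version: int = SCHEMA_VERSION
    incompressible: bool = True

    def __post_init__(self) -> None:
        if self.dt_physics <= 0 or self.duration <= 0:
            raise ValueError("dt_physics and duration must be positive")
        if self.exchange_every < 1 or self.frame_stride < 1:
            raise ValueError("exchange_every and frame_stride must be >= 1")
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {self.schema_version}")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class RunResult:
    output_path: str | None
    summary: dict
    midline_track: MidlineTrack
    datasets: dict


def motor_to_activation(
    v_motor: np.ndarray,
    mapping: list,
    v_lo: float = -50.0,
    v_hi: float = -20.0,
) -> np.ndarray:
    """Map motor-neuron voltages to muscle activations in [0, 1].

    ``mapping[k]`` lists the indices (into ``v_motor``) of the motor
    neurons innervating muscle k; the muscle activation is the mean mapped
    voltage rescaled linearly from [v_lo, v_hi] and clipped. Muscles with
    no mapped neuron stay at 0. Monotone in every input voltage.
    """
    if v_hi <= v_lo:
        raise ValueError("v_hi must exceed v_lo")
    v_motor = np.asarray(v_motor, dtype=float)
    a = np.zeros(len(mapping))
    for k, idx in enumerate(mapping):
        if len(idx):
            a[k] = (v_motor[idx].mean() - v_lo) / (v_hi - v_lo)
    return np.clip(a, 0.0, 1.0)


def apply_shell_drag(
    body: WormBody, c_tangent: float, c_normal: float, dt: float
) -> None:
    """Anisotropic resistive drag on shell particles, applied implicitly.

    The local tangent at each shell particle comes from its loop
    neighbors; the tangential and normal velocity components decay as
    exp(-c dt / m) with drag coefficients c in N s/m. A larger normal than
    tangential coefficient is what turns undulation into thrust
    (resistive-force theory). The exact exponential decay is
    unconditionally stable, so realistic substrate coefficients do not
    constrain the physics timestep.
    """
    sys = body.system
    idx = body.shell_indices
    pos = sys.positions[idx]
    tangent = np.roll(pos, -1, axis=0) - np.roll(pos, 1, axis=0)
    tangent /= np.maximum(np.linalg.norm(tangent, axis=1, keepdims=True), 1e-300)
    v = sys.velocities[idx]
    v_t = np.einsum("ij,ij->i", v, tangent)[:, None] * tangent
    v_n = v - v_t
    m = sys.masses[idx, None]
    sys.velocities[idx] = v_t * np.exp(-c_tangent * dt / m) + v_n * np.exp(
        -c_normal * dt / m
    )


def _add_liquid_blocks(body: WormBody, rects) -> None:
    """Append lattice LIQUID particles filling axis-aligned rectangles.

    Lets a scene immerse the worm in an explicit fluid bath. Points inside
    (or within one spacing of) the shell are skipped; the body's particle
    indices are unaffected because new particles append at the end.
    """
    from shapely.geometry import Point, Polygon

    sys = body.system
    s = sys.spacing if sys.spacing is not None else sys.h / 1.3
    shell = Polygon(body.shell_polygon()).buffer(s)
    pts = []
    for x0, y0, x1, y1 in rects:
        gx = np.arange(x0, x1, s)
        gy = np.arange(y0, y1, s)
        for x in gx:
            for y in gy:
                if not shell.contains(Point(x, y)):
                    pts.append((x, y))
    if not pts:
        return
    pts = np.asarray(pts)
    m0 = float(np.median(sys.masses))
    sys.positions = np.concatenate([sys.positions, pts])
    sys.velocities = np.concatenate([sys.velocities, np.zeros_like(pts)])
    sys.masses = np.concatenate([sys.masses, np.full(len(pts), m0)])
    from wormsim.particles import LIQUID as _LIQ

    sys.kinds = np.concatenate([sys.kinds, np.full(len(pts), _LIQ, dtype=np.int64)])
    sys.densities = np.concatenate([sys.densities, np.zeros(len(pts))])
    sys.pressures = np.concatenate([sys.pressures, np.zeros(len(pts))])
    sys.validate()


def _build_neural_driver(cfg: SimulationConfig):
    """Returns (step_window(t0_s, window_s) -> activations[95], recorder)."""
    ncfg = dict(cfg.neural)
    kind = cfg.driver.get("kind", "none")
    if kind == "cpg":
        params = {k: v for k, v in cfg.driver.items() if k != "kind"}
        driver = make_cpg_driver(**params)

        def step_window(t0: float, window: float) -> np.ndarray:
            return driver(t0 + window)

        return step_window, None

    if kind == "none":
        zeros = np.zeros(N_MUSCLES)
        return (lambda t0, window: zeros), None

    if kind != "connectome":
        raise ValueError(f"unknown driver kind {kind!r}")

    if ncfg.get("neuroml"):
        net = load_connectome_neuroml(ncfg["neuroml"])
    else:
        net = load_connectome_table(
            ncfg["connectome_csv"], ncfg.get("metadata_csv")
        )
    level = ncfg.get("level", "LI")
    sim = NetworkSimulator(net, level=level)
    state = sim.init_state()
    dt_ms = float(ncfg.get("dt_ms", 0.5 if level == "LI" else 0.02))
    v_lo = float(ncfg.get("v_lo", -50.0))
    v_hi = float(ncfg.get("v_hi", -20.0))
    inputs = ncfg.get("inputs", {})  # neuron -> constant current
    motor_idx = [
        k for k, nr in enumerate(net.neurons)
        if nr.category == "MOTOR" and nr.target_muscle is not None
    ]
    mapping: list = [[] for _ in range(N_MUSCLES)]
    for pos, k in enumerate(motor_idx):
        mapping[net.neurons[k].target_muscle].append(pos)
    recorder = {"V": [], "s": [], "sim": sim}

    def step_window(t0: float, window: float) -> np.ndarray:
        nonlocal state
        n_sub = max(int(round(window * 1000.0 / dt_ms)), 1)
        sub_dt = window * 1000.0 / n_sub
        for _ in range(n_sub):
            state = sim.step(state, inputs, sub_dt)
        recorder["V"].append(state.V.copy())
        recorder["s"].append(state.s.copy())
        v_motor = state.V[motor_idx] if motor_idx else np.zeros(0)
        return motor_to_activation(v_motor, mapping, v_lo, v_hi)

    return step_window, recorder


def run_simulation(cfg: SimulationConfig) -> RunResult:
    """Run a complete coupled simulation and write all outputs.

    Deterministic for fixed config+seed; errors are re-raised with the
    phase in which they occurred, after flushing whatever frames exist
    (marked incomplete).
    """
    timers: dict[str, float] = {"build": 0.0, "neural": 0.0, "physics": 0.0}
    t0 = time.perf_counter()
    body = build_worm_body(BodySpec(**cfg.body))
    sys = body.system
    env = dict(cfg.environment)
    gravity = np.asarray(env.get("gravity", (0.0, 0.0)), dtype=float)
    c_t = float(env.get("drag_tangent", 0.0))
    c_n = float(env.get("drag_normal", 0.0))
    box = None
    if "box" in env and env["box"]:
        box = Box(lo=np.asarray(env["box"][0]), hi=np.asarray(env["box"][1]))
    if env.get("liquid_blocks"):
        _add_liquid_blocks(body, env["liquid_blocks"])
    try:
        step_window, recorder = _build_neural_driver(cfg)
    except Exception as exc:
        raise RuntimeError("simulation failed during build phase") from exc
    timers["build"] = time.perf_counter() - t0

    n_steps = int(round(cfg.duration / cfg.dt_physics))
    window_s = cfg.exchange_every * cfg.dt_physics
    pcisph = PCISPHParams()

    frames_t, frames_pos, frames_vel, frames_mid = [], [], [], []
    frames_act, frames_tension = [], []
    activations = np.zeros(N_MUSCLES)
    phase = "init"
    incomplete = False
    try:
        for step in range(n_steps):
            if step % cfg.exchange_every == 0:
                phase = "neural"
                tn = time.perf_counter()
                activations = step_window(step * cfg.dt_physics, window_s)
                set_muscle_activations(body, activations)
                timers["neural"] += time.perf_counter() - tn
            phase = "physics"
            tp = time.perf_counter()
            old_pos = sys.positions.copy()
            engine.advance(
                sys,
                body.springs,
                cfg.dt_physics,
                gravity=gravity,
                box=box,
                pcisph=pcisph,
                incompressible=cfg.incompressible,
            )
            if c_t > 0 or c_n > 0:
                apply_shell_drag(body, c_t, c_n, cfg.dt_physics)
            enforce_membrane(body, old_pos)
            timers["physics"] += time.perf_counter() - tp
            if (step + 1) % cfg.frame_stride == 0:
                frames_t.append((step + 1) * cfg.dt_physics)
                frames_pos.append(sys.positions.copy())
                frames_vel.append(sys.velocities.copy())
                frames_mid.append(extract_midline(body))
                frames_act.append(activations.copy())
                muscle = body.springs.muscle_id >= 0
                dx = (
                    sys.positions[body.springs.pairs[muscle, 0]]
                    - sys.positions[body.springs.pairs[muscle, 1]]
                )
                lengths = np.linalg.norm(dx, axis=1)
                tension = np.abs(
                    body.springs.stiffness[muscle]
                    * (lengths - body.springs.rest_lengths[muscle])
                    / body.springs.rest_lengths[muscle]
                )
                frames_tension.append(float(tension.sum()))
    except Exception as exc:
        incomplete = True
        logger.error("simulation failed during %s phase: %s", phase, exc)
        if cfg.output and frames_t:
            write_trajectory(
                cfg.output,
                {
                    "time": np.asarray(frames_t),
                    "midline": np.asarray(frames_mid),
                    "meta/incomplete": np.asarray(1),
                },
            )
        raise RuntimeError(f"simulation failed during {phase} phase") from exc

    datasets = {
        "time": np.asarray(frames_t),
        "positions": np.asarray(frames_pos),
        "velocities": np.asarray(frames_vel),
        "kinds": sys.kinds,
        "midline": np.asarray(frames_mid),
        "muscle_activations": np.asarray(frames_act),
        "forces/muscle_tension": np.asarray(frames_tension),
        "meta/incomplete": np.asarray(int(incomplete)),
        "meta/seed": np.asarray(cfg.seed),
        "meta/schema_version": np.asarray(cfg.schema_version),
    }
    if recorder is not None and recorder["V"]:
        datasets["neural/V"] = np.asarray(recorder["V"])
        datasets["neural/s"] = np.asarray(recorder["s"])
    if cfg.output:
        write_trajectory(cfg.output, datasets)

    track = MidlineTrack(
        times=datasets["time"], points=datasets["midline"], label="simulation"
    )
    centroid = datasets["midline"].mean(axis=1)
    displacement = float(np.linalg.norm(centroid[-1] - centroid[0])) if len(centroid) > 1 else 0.0
    summary = {
        "frames": len(frames_t),
        "n_particles": sys.n,
        "net_displacement_m": displacement,
        "body_length_m": body.body_length,
        "timers_s": timers,
        "incomplete": incomplete,
    }
    for name, val in timers.items():
        logger.info("phase %s: %.2f s", name, val)
    return RunResult(
        output_path=cfg.output, summary=summary, midline_track=track, datasets=datasets
    )
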