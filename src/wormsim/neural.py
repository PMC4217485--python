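"""Connectome loading and neural dynamics.

Two abstraction levels for the membrane equation:

* ``LI`` — leaky integrator, tau dV/dt = -(V - V_rest) + R (I_ext + I_syn),
  advanced by the exact exponential update (the linear ODE is solved in
  closed form over each step).
* ``HH`` — classic single-compartment Hodgkin-Huxley with squid-axon
  conductances, advanced by RK4.

Synapses: chemical synapses are graded (transmitter release varies
continuously with presynaptic voltage, the dominant mode in C. elegans),
with activation dynamics ds/dt = (s_inf(V_pre) - s)/tau_s and sigmoid
s_inf; gap junctions are ohmic, I = w g_gap (V_j - V_i), applied
antisymmetrically, so the summed gap-junction current over the network is
exactly zero.

Units: mV, ms, nS, pA (so g * V gives pA directly); HH currents are
densities in uA/cm^2, converted with a configurable membrane area.

The network update is synchronous with synaptic currents lagged one step,
so results do not depend on neuron iteration order; neurons and synapses
are canonically sorted by name, making trajectories invariant to the
ordering of the input wiring data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from lxml import etree

logger = logging.getLogger(__name__)

CHEMICAL = "CHEMICAL"
ELECTRICAL = "ELECTRICAL"
EXC = "EXC"
INH = "INH"
CATEGORIES = ("SENSORY", "INTER", "MOTOR")

_KIND_ALIASES = {
    "chemical": CHEMICAL,
    "send": CHEMICAL,
    "electrical": ELECTRICAL,
    "gapjunction": ELECTRICAL,
    "gap_junction": ELECTRICAL,
}


@dataclass(frozen=True)
class Neuron:
    name: str
    category: str = "INTER"
    target_muscle: int | None = None


@dataclass(frozen=True)
class Synapse:
    pre: str
    post: str
    kind: str  # CHEMICAL or ELECTRICAL
    weight: float
    polarity: str = EXC  # meaningful for CHEMICAL only


class ConnectomeError(ValueError):
    pass


@dataclass
class Connectome:
    """Neurons plus typed synapses, canonically ordered.

    Duplicate (pre, post, kind) entries are aggregated by summing weight;
    ELECTRICAL synapses are stored once per unordered pair.
    """

    neurons: list = field(default_factory=list)
    synapses: list = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [nr.name for nr in self.neurons]
        if len(set(names)) != len(names):
            raise ConnectomeError("neuron names must be unique")
        self.neurons = sorted(self.neurons, key=lambda nr: nr.name)
        known = set(names)
        agg: dict[tuple, list] = {}
        for syn in self.synapses:
            if syn.pre not in known or syn.post not in known:
                raise ConnectomeError(
                    f"synapse {syn.pre}->{syn.post} references unknown neuron"
                )
            if syn.weight < 0:
                raise ConnectomeError("synapse weight must be nonnegative")
            if syn.kind == ELECTRICAL:
                a, b = sorted((syn.pre, syn.post))
                key = (a, b, ELECTRICAL, "")
                syn = replace(syn, pre=a, post=b)
            elif syn.kind == CHEMICAL:
                key = (syn.pre, syn.post, CHEMICAL, syn.polarity)
            else:
                raise ConnectomeError(f"unknown synapse kind {syn.kind!r}")
            if key in agg:
                agg[key][1] += syn.weight
            else:
                agg[key] = [syn, syn.weight]
        self.synapses = [
            replace(syn, weight=w) for syn, w in (agg[k] for k in sorted(agg))
        ]

    @property
    def neuron_names(self) -> list:
        return [nr.name for nr in self.neurons]

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    def index(self, name: str) -> int:
        return self.neuron_names.index(name)


def _apply_metadata(neurons: dict, meta: pd.DataFrame, source: str) -> None:
    bad_rows = []
    for row_no, rec in enumerate(meta.itertuples(index=False), start=2):
        if rec.name not in neurons:
            bad_rows.append(row_no)
            continue
        tm = rec.target_muscle
        tm = None if pd.isna(tm) else int(tm)
        cat = str(rec.category).upper()
        if cat not in CATEGORIES:
            raise ConnectomeError(
                f"{source}: unknown category {rec.category!r} at row {row_no}"
            )
        neurons[rec.name] = Neuron(rec.name, cat, tm)
    if bad_rows:
        raise ConnectomeError(
            f"{source}: metadata rows {bad_rows} reference neurons absent "
            "from the wiring table"
        )


def load_connectome_table(path, metadata_path=None) -> Connectome:
    """Load a connectome from CSV (header: pre,post,kind,weight,polarity).

    Duplicate (pre, post, kind) rows are summed. An optional metadata CSV
    (name,category,target_muscle) assigns cell categories and the muscle a
    motor neuron innervates.
    """
    df = pd.read_csv(path)
    required = {"pre", "post", "kind", "weight"}
    if not required.issubset(df.columns):
        raise ConnectomeError(
            f"connectome CSV must have columns {sorted(required)}; got {list(df.columns)}"
        )
    if "polarity" not in df.columns:
        df["polarity"] = EXC
    bad_kind, bad_weight = [], []
    synapses = []
    for row_no, rec in enumerate(df.itertuples(index=False), start=2):
        kind = _KIND_ALIASES.get(str(rec.kind).strip().lower())
        if kind is None:
            bad_kind.append(row_no)
            continue
        w = float(rec.weight)
        if w < 0:
            bad_weight.append(row_no)
            continue
        pol = EXC if pd.isna(rec.polarity) else str(rec.polarity).strip().upper()
        if pol not in (EXC, INH):
            raise ConnectomeError(f"unknown polarity {rec.polarity!r} at row {row_no}")
        synapses.append(Synapse(str(rec.pre), str(rec.post), kind, w, pol))
    errors = []
    if bad_kind:
        errors.append(f"unknown synapse kind at rows {bad_kind}")
    if bad_weight:
        errors.append(f"negative weight at rows {bad_weight}")
    if errors:
        raise ConnectomeError(f"{path}: " + "; ".join(errors))
    names = sorted({s.pre for s in synapses} | {s.post for s in synapses})
    neurons = {nm: Neuron(nm) for nm in names}
    if metadata_path is not None:
        meta = pd.read_csv(metadata_path)
        _apply_metadata(neurons, meta, str(metadata_path))
    return Connectome(neurons=list(neurons.values()), synapses=synapses)


def _strip_ns(tag) -> str:
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else ""


def _cell_id(raw: str, populations: dict) -> str:
    """Resolve NeuroML connection endpoint ids of the common dialects.

    Accepts '../PopId/3/CellType', 'PopId[3]', 'PopId/3' and bare 'PopId'.
    """
    raw = raw.strip()
    if raw.startswith("../"):
        parts = raw.split("/")
        pop, idx = parts[1], int(parts[2])
    elif "[" in raw:
        pop, rest = raw.split("[", 1)
        idx = int(rest.rstrip("]"))
    elif "/" in raw:
        pop, idx_s = raw.split("/", 1)
        idx = int(idx_s.split("/")[0])
    else:
        pop, idx = raw, 0
    size = populations.get(pop, 1)
    return pop if size == 1 else f"{pop}[{idx}]"


def load_connectome_neuroml(path) -> Connectome:
    """Load a restricted NeuroML subset: populations + explicit connections.

    Chemical connections come from <projection>/<continuousProjection>,
    gap junctions from <electricalProjection>. Unsupported elements are
    skipped (count logged). Synapse component ids containing 'inh' map to
    inhibitory polarity.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ConnectomeError(f"{path}: malformed XML: {exc}") from exc
    root = tree.getroot()

    populations: dict[str, int] = {}
    synapses: list[Synapse] = []
    skipped = 0

    for pop in root.iter():
        if _strip_ns(pop.tag) != "population":
            continue
        pid = pop.get("id")
        if pid is None:
            skipped += 1
            continue
        populations[pid] = int(pop.get("size", "1"))

    def pop_names(pid: str) -> list:
        size = populations.get(pid, 1)
        return [pid] if size == 1 else [f"{pid}[{k}]" for k in range(size)]

    for proj in root.iter():
        tag = _strip_ns(proj.tag)
        if tag not in ("projection", "electricalProjection", "continuousProjection"):
            continue
        pre_pop = proj.get("presynapticPopulation")
        post_pop = proj.get("postsynapticPopulation")
        syn_comp = (proj.get("synapse") or "").lower()
        kind = ELECTRICAL if tag == "electricalProjection" else CHEMICAL
        for conn in proj:
            ctag = _strip_ns(conn.tag)
            if "onnection" not in ctag:
                continue
            pre_raw = conn.get("preCellId") or conn.get("preCell")
            post_raw = conn.get("postCellId") or conn.get("postCell")
            if pre_raw is None or post_raw is None:
                skipped += 1
                continue
            comp = (
                conn.get("synapse")
                or conn.get("postComponent")
                or conn.get("preComponent")
                or syn_comp
                or ""
            ).lower()
            pol = INH if "inh" in comp else EXC
            w = float(conn.get("weight", "1"))
            pre = _cell_id(pre_raw, populations) if pre_pop is None else None
            if pre_pop is not None and ("/" in pre_raw or "[" in pre_raw):
                pre = _cell_id(pre_raw, populations)
                post = _cell_id(post_raw, populations)
            elif pre_pop is not None:
                pre = pop_names(pre_pop)[int(pre_raw) if pre_raw.isdigit() else 0]
                post = pop_names(post_pop)[int(post_raw) if post_raw.isdigit() else 0]
            else:
                post = _cell_id(post_raw, populations)
            synapses.append(Synapse(pre, post, kind, w, pol))
    if skipped:
        logger.info("NeuroML reader skipped %d unsupported elements", skipped)
    if not synapses:
        raise ConnectomeError(
            f"{path}: no connections parsed (unsupported NeuroML dialect?)"
        )
    names = {nm for pid in populations for nm in pop_names(pid)}
    names |= {s.pre for s in synapses} | {s.post for s in synapses}
    neurons = [Neuron(nm) for nm in sorted(names)]
    return Connectome(neurons=neurons, synapses=synapses)


# ---------------------------------------------------------------------------
# membrane dynamics


@dataclass
class HHParams:
    """Classic squid-axon parameters; V in mV, conductances mS/cm^2."""

    C: float = 1.0  # uF/cm^2
    g_na: float = 120.0
    g_k: float = 36.0
    g_l: float = 0.3
    e_na: float = 50.0
    e_k: float = -77.0
    e_l: float = -54.387


@dataclass
class LIParams:
    tau: float = 10.0  # ms
    R: float = 0.1  # GOhm (so R * pA = mV)
    v_rest: float = -65.0  # mV


@dataclass
class SynapseParams:
    """Graded chemical synapse + gap junction parameters."""

    v_th: float = -35.0  # mV, half-activation of release
    v_slope: float = 5.0  # mV
    tau_s: float = 10.0  # ms
    e_exc: float = 0.0  # mV
    e_inh: float = -70.0  # mV
    g_syn: float = 1.0  # nS per unit weight
    g_gap: float = 1.0  # nS per unit weight


def hh_rates(v):
    """Standard alpha/beta gating rates (1/ms) at potential v (mV)."""
    v = np.asarray(v, dtype=float)

    def vtrap(x, y):
        # x / (exp(x/y) - 1), stable near x = 0
        x = np.asarray(x, dtype=float)
        small = np.abs(x / y) < 1e-6
        return np.where(small, y * (1 - x / y / 2.0), x / np.expm1(x / y))

    a_m = 0.1 * vtrap(-(v + 40.0), 10.0)
    b_m = 4.0 * np.exp(-(v + 65.0) / 18.0)
    a_h = 0.07 * np.exp(-(v + 65.0) / 20.0)
    b_h = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    a_n = 0.01 * vtrap(-(v + 55.0), 10.0)
    b_n = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return a_m, b_m, a_h, b_h, a_n, b_n


def hh_derivatives(v, m, h, n, i_ext, p: HHParams):
    a_m, b_m, a_h, b_h, a_n, b_n = hh_rates(v)
    i_ion = (
        p.g_na * m**3 * h * (v - p.e_na)
        + p.g_k * n**4 * (v - p.e_k)
        + p.g_l * (v - p.e_l)
    )
    dv = (i_ext - i_ion) / p.C
    return dv, a_m * (1 - m) - b_m * m, a_h * (1 - h) - b_h * h, a_n * (1 - n) - b_n * n


def hh_steady_gates(v):
    a_m, b_m, a_h, b_h, a_n, b_n = hh_rates(v)
    return a_m / (a_m + b_m), a_h / (a_h + b_h), a_n / (a_n + b_n)


HH_DT_MAX = 0.05  # ms; stiffness cap


def hh_step(v, m, h, n, i_ext, dt: float, params: HHParams | None = None):
    """One RK4 step of the Hodgkin-Huxley equations (vectorized).

    ``i_ext`` is a current density in uA/cm^2 held constant over the step.
    """
    if params is None:
        params = HHParams()
    if dt < 0:
        raise ValueError("dt must be nonnegative")
    if dt == 0:
        return v, m, h, n
    if dt > HH_DT_MAX:
        raise ValueError(f"dt={dt} ms exceeds the HH stiffness cap {HH_DT_MAX} ms")
    y = (v, m, h, n)
    k1 = hh_derivatives(*y, i_ext, params)
    k2 = hh_derivatives(*(a + 0.5 * dt * b for a, b in zip(y, k1)), i_ext, params)
    k3 = hh_derivatives(*(a + 0.5 * dt * b for a, b in zip(y, k2)), i_ext, params)
    k4 = hh_derivatives(*(a + dt * b for a, b in zip(y, k3)), i_ext, params)
    out = [
        a + dt / 6.0 * (b1 + 2 * b2 + 2 * b3 + b4)
        for a, b1, b2, b3, b4 in zip(y, k1, k2, k3, k4)
    ]
    v_new = out[0]
    gates = [np.clip(g, 0.0, 1.0) for g in out[1:]]
    if np.any(np.isnan(np.asarray(v_new))):
        raise FloatingPointError("NaN membrane potential in HH step")
    return (v_new, *gates)


def li_step(v, i_ext, dt: float, params: LIParams | None = None):
    """Exact exponential update of the leaky integrator over dt (ms)."""
    if params is None:
        params = LIParams()
    if dt < 0:
        raise ValueError("dt must be nonnegative")
    v_inf = params.v_rest + params.R * np.asarray(i_ext, dtype=float)
    return v_inf + (v - v_inf) * np.exp(-dt / params.tau)


def s_inf(v_pre, p: SynapseParams):
    return 1.0 / (1.0 + np.exp(-(np.asarray(v_pre, dtype=float) - p.v_th) / p.v_slope))


# ---------------------------------------------------------------------------
# network simulation


@dataclass
class NetworkState:
    V: np.ndarray  # [M] mV
    s: np.ndarray  # [n_chemical] in [0, 1]
    t: float = 0.0  # ms
    m: np.ndarray | None = None  # HH gating, [M]
    h: np.ndarray | None = None
    n: np.ndarray | None = None

    def copy(self) -> "NetworkState":
        return NetworkState(
            V=self.V.copy(),
            s=self.s.copy(),
            t=self.t,
            m=None if self.m is None else self.m.copy(),
            h=None if self.h is None else self.h.copy(),
            n=None if self.n is None else self.n.copy(),
        )


class NetworkSimulator:
    """Compiled connectome + chosen membrane model, stepped synchronously.

    Synaptic currents are computed from the previous state and then every
    neuron is integrated, so the update is independent of neuron order.
    """

    def __init__(
        self,
        net: Connectome,
        level: str = "LI",
        syn_params: SynapseParams | None = None,
        li_params: LIParams | None = None,
        hh_params: HHParams | None = None,
        membrane_area_cm2: float = 5e-6,
    ) -> None:
        if level not in ("LI", "HH"):
            raise ValueError("level must be 'LI' or 'HH'")
        self.net = net
        self.level = level
        self.syn = syn_params or SynapseParams()
        self.li = li_params or LIParams()
        self.hh = hh_params or HHParams()
        self.area = membrane_area_cm2
        names = net.neuron_names
        self._index = {nm: k for k, nm in enumerate(names)}
        chem = [s for s in net.synapses if s.kind == CHEMICAL]
        elec = [s for s in net.synapses if s.kind == ELECTRICAL]
        self.chem_pre = np.array([self._index[s.pre] for s in chem], dtype=np.int64)
        self.chem_post = np.array([self._index[s.post] for s in chem], dtype=np.int64)
        self.chem_g = np.array([s.weight for s in chem]) * self.syn.g_syn
        self.chem_erev = np.array(
            [self.syn.e_exc if s.polarity == EXC else self.syn.e_inh for s in chem]
        )
        self.gap_i = np.array([self._index[s.pre] for s in elec], dtype=np.int64)
        self.gap_j = np.array([self._index[s.post] for s in elec], dtype=np.int64)
        self.gap_g = np.array([s.weight for s in elec]) * self.syn.g_gap
        self.n_chem = len(chem)

    @property
    def n_neurons(self) -> int:
        return self.net.n_neurons

    def init_state(self, v0: float | None = None) -> NetworkState:
        mn = self.n_neurons
        if self.level == "LI":
            v = np.full(mn, self.li.v_rest if v0 is None else v0)
            state = NetworkState(V=v, s=np.zeros(self.n_chem))
        else:
            v = np.full(mn, -65.0 if v0 is None else v0)
            gm, gh, gn = hh_steady_gates(v)
            state = NetworkState(
                V=v, s=np.zeros(self.n_chem), m=np.asarray(gm), h=np.asarray(gh),
                n=np.asarray(gn),
            )
        return state

    def synaptic_currents(self, state: NetworkState, dt: float):
        """Graded-synapse + gap-junction currents (pA) and updated s."""
        i_syn = np.zeros(self.n_neurons)
        s_new = state.s
        if self.n_chem:
            target = s_inf(state.V[self.chem_pre], self.syn)
            decay = np.exp(-dt / self.syn.tau_s) if dt > 0 else 1.0
            s_new = target + (state.s - target) * decay
            i_chem = self.chem_g * state.s * (self.chem_erev - state.V[self.chem_post])
            np.add.at(i_syn, self.chem_post, i_chem)
        if len(self.gap_i):
            dv = state.V[self.gap_j] - state.V[self.gap_i]
            i_gap = self.gap_g * dv
            np.add.at(i_syn, self.gap_i, i_gap)
            np.add.at(i_syn, self.gap_j, -i_gap)
        return i_syn, s_new

    def step(self, state: NetworkState, inputs: dict | None, dt: float) -> NetworkState:
        """One synchronous network step of dt milliseconds.

        ``inputs`` maps neuron name -> external current (pA in LI mode,
        uA/cm^2 in HH mode).
        """
        i_ext = np.zeros(self.n_neurons)
        if inputs:
            for nm, val in inputs.items():
                if nm not in self._index:
                    raise KeyError(f"input names unknown neuron {nm!r}")
                i_ext[self._index[nm]] += val
        i_syn, s_new = self.synaptic_currents(state, dt)
        new = state.copy()
        new.s = np.clip(s_new, 0.0, 1.0)
        if self.level == "LI":
            new.V = li_step(state.V, i_ext + i_syn, dt, self.li)
        else:
            i_total = i_ext + i_syn * 1e-6 / self.area  # pA -> uA/cm^2
            new.V, new.m, new.h, new.n = hh_step(
                state.V, state.m, state.h, state.n, i_total, dt, self.hh
            )
        new.t = state.t + dt
        return new

    def run(self, state: NetworkState, inputs, dt: float, n_steps: int):
        """Run n_steps; ``inputs`` is a dict or a callable t_ms -> dict."""
        for _ in range(n_steps):
            cur = inputs(state.t) if callable(inputs) else inputs
            state = self.step(state, cur, dt)
        return state


def step_network(
    net: Connectome, state: NetworkState, sensory_input: dict, dt: float,
    level: str = "LI", **kwargs,
) -> NetworkState:
    """Functional one-step wrapper over :class:`NetworkSimulator`."""
    sim = NetworkSimulator(net, level=level, **kwargs)
    return sim.step(state, sensory_input, dt)


def step_synapses(net: Connectome, state: NetworkState, dt: float, **kwargs):
    """Synaptic currents (pA) and updated graded activations."""
    sim = NetworkSimulator(net, **kwargs)
    return sim.synaptic_currents(state, dt)
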