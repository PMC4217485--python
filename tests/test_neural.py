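"""Connectome loading and neural dynamics at both abstraction levels."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from wormsim.neural import (
    CHEMICAL,
    ELECTRICAL,
    Connectome,
    ConnectomeError,
    HHParams,
    LIParams,
    NetworkSimulator,
    Neuron,
    Synapse,
    SynapseParams,
    hh_derivatives,
    hh_steady_gates,
    hh_step,
    li_step,
    load_connectome_neuroml,
    load_connectome_table,
    s_inf,
    step_network,
    step_synapses,
)

TOY_CSV = """pre,post,kind,weight,polarity
AVAL,VA01,chemical,2.0,EXC
AVAL,VA01,chemical,3.0,EXC
AVBL,DB01,chemical,1.5,INH
AVAL,AVBL,electrical,1.0,
"""

TOY_NEUROML = """<?xml version="1.0" encoding="UTF-8"?>
<neuroml xmlns="http://www.neuroml.org/schema/neuroml2" id="toy">
  <network id="net">
    <population id="AVAL" component="cell" size="1"/>
    <population id="VA01" component="cell" size="1"/>
    <population id="DB01" component="cell" size="1"/>
    <projection id="p0" presynapticPopulation="AVAL" postsynapticPopulation="VA01" synapse="exc_syn">
      <connection id="0" preCellId="../AVAL/0/cell" postCellId="../VA01/0/cell"/>
    </projection>
    <electricalProjection id="p1" presynapticPopulation="AVAL" postsynapticPopulation="DB01">
      <electricalConnection id="0" preCell="../AVAL/0/cell" postCell="../DB01/0/cell" synapse="gap"/>
    </electricalProjection>
  </network>
</neuroml>
"""


@pytest.fixture()
def toy_csv(tmp_path):
    p = tmp_path / "net.csv"
    p.write_text(TOY_CSV)
    return p


class TestCSVLoader:
    def test_basic_load_and_union_of_neurons(self, toy_csv):
        net = load_connectome_table(toy_csv)
        assert sorted(net.neuron_names) == ["AVAL", "AVBL", "DB01", "VA01"]
        assert len(net.synapses) == 3

    def test_duplicate_edges_aggregate_weights(self, toy_csv):
        net = load_connectome_table(toy_csv)
        syn = next(
            s for s in net.synapses if s.pre == "AVAL" and s.post == "VA01"
        )
        assert syn.weight == pytest.approx(5.0)

    def test_unknown_kind_names_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("pre,post,kind,weight,polarity\nA,B,axo-axonic,1,EXC\n")
        with pytest.raises(ConnectomeError, match=r"rows \[2\]"):
            load_connectome_table(p)

    def test_negative_weight_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("pre,post,kind,weight,polarity\nA,B,chemical,-1,EXC\n")
        with pytest.raises(ConnectomeError, match="negative weight"):
            load_connectome_table(p)

    def test_metadata_sidecar_and_dangling_reference(self, toy_csv, tmp_path):
        meta = tmp_path / "meta.csv"
        meta.write_text("name,category,target_muscle\nAVAL,INTER,\nDB01,MOTOR,7\n")
        net = load_connectome_table(toy_csv, meta)
        db = net.neurons[net.index("DB01")]
        assert db.category == "MOTOR" and db.target_muscle == 7
        bad = tmp_path / "meta2.csv"
        bad.write_text("name,category,target_muscle\nNOPE,MOTOR,3\n")
        with pytest.raises(ConnectomeError, match=r"\[2\]"):
            load_connectome_table(toy_csv, bad)


class TestNeuroMLLoader:
    def test_fixture_roundtrip(self, tmp_path):
        p = tmp_path / "net.nml"
        p.write_text(TOY_NEUROML)
        net = load_connectome_neuroml(p)
        assert net.n_neurons == 3
        kinds = sorted(s.kind for s in net.synapses)
        assert kinds == [CHEMICAL, ELECTRICAL]

    def test_matches_csv_loader_for_matched_content(self, tmp_path):
        nml = tmp_path / "net.nml"
        nml.write_text(TOY_NEUROML)
        csv = tmp_path / "net.csv"
        csv.write_text(
            "pre,post,kind,weight,polarity\n"
            "AVAL,VA01,chemical,1.0,EXC\n"
            "AVAL,DB01,electrical,1.0,\n"
        )
        a = load_connectome_neuroml(nml)
        b = load_connectome_table(csv)
        assert a.neuron_names == b.neuron_names
        assert [
            (s.pre, s.post, s.kind, s.weight, s.polarity) for s in a.synapses
        ] == [(s.pre, s.post, s.kind, s.weight, s.polarity) for s in b.synapses]

    def test_malformed_xml_rejected(self, tmp_path):
        p = tmp_path / "bad.nml"
        p.write_text("<neuroml><population id='A'>")
        with pytest.raises(ConnectomeError, match="malformed"):
            load_connectome_neuroml(p)

    def test_zero_connections_rejected(self, tmp_path):
        p = tmp_path / "empty.nml"
        p.write_text("<neuroml><network><population id='A'/></network></neuroml>")
        with pytest.raises(ConnectomeError, match="no connections"):
            load_connectome_neuroml(p)


@pytest.fixture(scope="module")
def reference():
    """High-accuracy adaptive integration of the same HH equations."""
    p = HHParams()

    def protocol(t):
        return 10.0 if 20.0 <= t <= 80.0 else 0.0

    def rhs(t, y):
        return hh_derivatives(y[0], y[1], y[2], y[3], protocol(t), p)

    gm, gh, gn = hh_steady_gates(-65.0)
    sol = solve_ivp(
        rhs, (0.0, 100.0), [-65.0, gm, gh, gn],
        rtol=1e-10, atol=1e-12, dense_output=True, max_step=0.5,
    )
    return sol, protocol


class TestHodgkinHuxley:
    def test_zero_dt_is_identity(self):
        gm, gh, gn = hh_steady_gates(-65.0)
        out = hh_step(-65.0, gm, gh, gn, 0.0, 0.0)
        assert out == (-65.0, gm, gh, gn)

    def test_stiffness_cap_enforced(self):
        gm, gh, gn = hh_steady_gates(-65.0)
        with pytest.raises(ValueError, match="stiffness cap"):
            hh_step(-65.0, gm, gh, gn, 0.0, 0.1)

    def test_resting_potential_settles(self, reference):
        sol, _ = reference
        v_rest_ref = sol.sol(19.9)[0]  # just before stimulus, fully settled
        v, m, h, n = -65.0, *hh_steady_gates(-65.0)
        for k in range(int(19.9 / 0.01)):
            v, m, h, n = hh_step(v, m, h, n, 0.0, 0.01)
        assert abs(v - v_rest_ref) < 1.0

    def test_sustained_current_spikes(self):
        v, m, h, n = -65.0, *hh_steady_gates(-65.0)
        vs = []
        for _ in range(int(200 / 0.01)):
            v, m, h, n = hh_step(v, m, h, n, 10.0, 0.01)
            vs.append(v)
        vs = np.asarray(vs)
        peaks = np.sum((np.diff(np.sign(np.diff(vs))) < 0) & (vs[1:-1] > 0))
        assert peaks >= 5

    def test_coarse_step_matches_reference(self, reference):
        """RK4 at dt = 0.01 ms stays within 0.5 mV RMS of the fine solution."""
        sol, protocol = reference
        dt = 0.01
        v, m, h, n = -65.0, *hh_steady_gates(-65.0)
        vs = []
        n_steps = int(100 / dt)
        for k in range(n_steps):
            v, m, h, n = hh_step(v, m, h, n, protocol(k * dt), dt)
            vs.append(v)
        ts = np.arange(1, n_steps + 1) * dt
        rms = np.sqrt(np.mean((np.asarray(vs) - sol.sol(ts)[0]) ** 2))
        assert rms < 0.5


class TestLeakyIntegrator:
    def test_rest_is_fixed_point(self):
        p = LIParams()
        assert li_step(p.v_rest, 0.0, 5.0, p) == pytest.approx(p.v_rest)

    def test_steady_state_under_constant_current(self):
        p = LIParams()
        v = p.v_rest
        for _ in range(100):
            v = li_step(v, 50.0, 10.0, p)
        assert v == pytest.approx(p.v_rest + p.R * 50.0, abs=1e-9)

    def test_single_step_equals_closed_form(self):
        p = LIParams(tau=7.0, R=0.2, v_rest=-60.0)
        v0, i, dt = -51.3, 33.0, 2.37
        v_inf = p.v_rest + p.R * i
        exact = v_inf + (v0 - v_inf) * np.exp(-dt / p.tau)
        assert abs(li_step(v0, i, dt, p) - exact) < 1e-10


class TestSynapses:
    def test_sigmoid_half_activation_at_threshold(self):
        p = SynapseParams()
        assert s_inf(p.v_th, p) == pytest.approx(0.5)

    def test_gap_junction_current_and_antisymmetry(self):
        net = Connectome(
            neurons=[Neuron("A"), Neuron("B")],
            synapses=[Synapse("A", "B", ELECTRICAL, 2.0)],
        )
        sim = NetworkSimulator(net, level="LI")
        state = sim.init_state()
        state.V = np.array([-60.0, -50.0])  # V_B - V_A = 10 mV
        i_syn, _ = sim.synaptic_currents(state, dt=0.1)
        assert i_syn[0] == pytest.approx(20.0)  # w * g_gap = 2 nS -> 20 pA
        assert i_syn[1] == pytest.approx(-20.0)

    def test_equal_potentials_no_gap_current(self):
        net = Connectome(
            neurons=[Neuron("A"), Neuron("B")],
            synapses=[Synapse("A", "B", ELECTRICAL, 3.0)],
        )
        i_syn, _ = step_synapses(net, NetworkSimulator(net).init_state(), 0.1)
        assert np.allclose(i_syn, 0.0)


class TestNetwork:
    def test_empty_connectome_state_unchanged(self):
        net = Connectome(neurons=[Neuron("A")], synapses=[])
        state = NetworkSimulator(net, level="LI").init_state()
        new = step_network(net, state, {}, 0.5, level="LI")
        assert np.allclose(new.V, state.V)

    def test_unknown_input_neuron_rejected(self):
        net = Connectome(neurons=[Neuron("A")], synapses=[])
        sim = NetworkSimulator(net)
        with pytest.raises(KeyError, match="NOPE"):
            sim.step(sim.init_state(), {"NOPE": 1.0}, 0.5)

    def test_gap_currents_sum_to_zero_network_wide(self):
        from wormsim.fixtures import make_toy_connectome

        net, _ = make_toy_connectome(4, 8, 6, 0.8, seed=3)
        sim = NetworkSimulator(net, level="LI")
        state = sim.init_state()
        rng = np.random.default_rng(0)
        state.V = rng.uniform(-80, 0, sim.n_neurons)
        # chemical currents off: compare total current with gap-only network
        sim.chem_g = sim.chem_g * 0.0
        i_syn, _ = sim.synaptic_currents(state, 0.1)
        assert abs(i_syn.sum()) < 1e-10 * max(np.abs(i_syn).max(), 1.0)

    def test_mutual_gap_junction_equalizes_potentials(self):
        net = Connectome(
            neurons=[Neuron("A"), Neuron("B")],
            synapses=[Synapse("A", "B", ELECTRICAL, 20.0)],
        )
        sim = NetworkSimulator(net, level="LI")
        state = sim.init_state()
        state.V = np.array([-70.0, -50.0])
        gaps = [abs(state.V[0] - state.V[1])]
        for _ in range(200):
            state = sim.step(state, None, 0.5)
            gaps.append(abs(state.V[0] - state.V[1]))
        assert all(b <= a + 1e-12 for a, b in zip(gaps, gaps[1:]))
        assert gaps[-1] < 0.05 * gaps[0]

    def test_order_invariance_of_trajectories(self):
        """Identical wiring presented in shuffled order gives identical runs."""
        from wormsim.fixtures import make_toy_connectome

        net, _ = make_toy_connectome(3, 5, 4, 0.7, seed=9)
        rng = np.random.default_rng(4)
        neurons = list(net.neurons)
        synapses = list(net.synapses)
        rng.shuffle(neurons)
        rng.shuffle(synapses)
        net2 = Connectome(neurons=neurons, synapses=synapses)
        out = []
        for n in (net, net2):
            sim = NetworkSimulator(n, level="LI")
            state = sim.init_state()
            inputs = {n.neuron_names[0]: 30.0}
            for _ in range(50):
                state = sim.step(state, inputs, 0.5)
            out.append(state.V.copy())
        assert (out[0] == out[1]).all()

    @settings(deadline=None, max_examples=20)
    @given(seed=st.integers(0, 10_000))
    def test_gates_and_activations_stay_in_unit_interval(self, seed):
        from wormsim.fixtures import make_toy_connectome

        net, _ = make_toy_connectome(2, 4, 3, 0.8, seed=seed)
        sim = NetworkSimulator(net, level="HH")
        state = sim.init_state()
        rng = np.random.default_rng(seed)
        names = net.neuron_names
        for _ in range(60):
            inputs = {nm: float(rng.normal(0, 20)) for nm in names[:2]}
            state = sim.step(state, inputs, 0.02)
            for arr in (state.m, state.h, state.n, state.s):
                assert (arr >= 0.0).all() and (arr <= 1.0).all()


def test_gating_bounds_many_li_steps():
    """Synaptic activations stay in [0,1] over ~1e5 random-input neuron-steps."""
    from wormsim.fixtures import make_toy_connectome

    net, _ = make_toy_connectome(5, 30, 20, 0.4, seed=11)
    sim = NetworkSimulator(net, level="LI")
    state = sim.init_state()
    rng = np.random.default_rng(2)
    names = net.neuron_names
    for _ in range(2000):  # 2000 steps x 55 neurons
        inputs = {nm: float(rng.normal(0, 100)) for nm in names[:5]}
        state = sim.step(state, inputs, 0.5)
        assert (state.s >= 0.0).all() and (state.s <= 1.0).all()
        assert np.isfinite(state.V).all()
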