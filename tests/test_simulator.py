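import math

import numpy as np
import pytest
from scipy.stats import chisquare

from dendrocable.distributions import apply_biophys
from dendrocable.fixtures import (
    make_passive_config,
    make_point_neuron,
    make_single_cylinder,
)
from dendrocable.model import Model
from dendrocable.morphology import build_segments, read_swc, split_to_sections
from dendrocable.simulator import (
    SpikeSource,
    StepCurrent,
    Synapse,
    build_circuit,
    dual_exp_conductance,
    make_synapse,
    nmda_gate,
    place_synapses,
    run,
    spike_train,
)


class TestCircuitAssembly:
    def test_single_compartment_no_axial(self, passive_point_model):
        sys = passive_point_model.circuit()
        assert sys.n == 1
        assert sys.g_axial[0] == 0.0

    def test_uniform_cylinder_axial_symmetric(self):
        """Axial resistance between adjacent centers of a uniform cable:
        R = Ra·(L/nseg)/(π r²), identical for every interior pair."""
        L, d, Ra = 100.0, 2.0, 150.0
        tree = read_swc(make_single_cylinder(L, d, n_points=11))
        stree = build_segments(split_to_sections(tree), nseg=5)
        cfg = make_passive_config(Ra=Ra)
        table = apply_biophys(cfg, stree)
        sys = build_circuit(stree, table)
        r_expected = Ra * (L / 5 * 1e-4) / (math.pi * (d / 2 * 1e-4) ** 2)  # Ω
        g_expected = 1e6 / r_expected  # µS
        assert sys.g_axial[1:] == pytest.approx(np.full(4, g_expected), rel=1e-9)

    def test_branch_point_couples_children_independently(self, y_tree_model):
        sys = y_tree_model.circuit()
        stree = y_tree_model.stree
        # both branch-root segments couple to the same stem-end segment
        branch_roots = [
            stree.section_segments[sec.idx][0]
            for sec in stree.sectree.sections
            if sec.parent is not None
            and stree.sectree.sections[sec.parent].domain == "apical"
        ]
        parents = {sys.parent[i] for i in branch_roots}
        assert len(branch_roots) == 2
        assert len(parents) == 1
        assert all(sys.g_axial[i] > 0 for i in branch_roots)

    def test_total_membrane_area_conserved(self, y_tree_model):
        sys = y_tree_model.circuit()
        # capacitance implies area: C = cm·area·1e-5
        area_from_C = np.sum(sys.C) / 1e-5
        assert area_from_C == pytest.approx(
            sum(s.area for s in y_tree_model.stree), rel=1e-12
        )

    def test_missing_passive_rejected(self, y_tree_model):
        table = apply_biophys(y_tree_model.config, y_tree_model.stree)
        del table.values["Ra"]
        with pytest.raises(ValueError, match="Ra"):
            build_circuit(y_tree_model.stree, table)


class TestIntegration:
    def test_rc_charging_analytic(self, passive_point_model):
        """Passive point neuron: V(t) = E + IR(1−e^(−t/τ)) within 0.1%."""
        m = passive_point_model
        area = m.stree.segments[0].area * 1e-8  # cm²
        R = 1e-6 / (1e-4 * area)  # MΩ
        tau = 10.0  # ms = Rm·cm
        I = -0.05
        tr = m.run_step(I, delay=20, duration=100, tstop=140, dt=0.025)["v@0"]
        t, v = tr.t, tr.values
        mask = (t >= 20) & (t <= 120)
        analytic = -65.0 + I * R * (1 - np.exp(-(t[mask] - 20) / tau))
        assert np.max(np.abs(v[mask] - analytic)) / abs(I * R) < 1e-3

    def test_equilibrium_stays_at_rest(self, passive_point_model):
        tr = passive_point_model.run_step(0.0, tstop=50)["v@0"]
        assert np.allclose(tr.values, -65.0, atol=1e-9)

    def test_richardson_convergence_orders(self, passive_point_model):
        """Halving dt halves the error (backward Euler) or quarters it
        (Crank–Nicolson) against the closed-form RC response."""
        m = passive_point_model
        area = m.stree.segments[0].area * 1e-8
        R = 1e-6 / (1e-4 * area)

        def max_err(dt, theta):
            tr = m.run_step(-0.05, delay=20, duration=100, tstop=140,
                            dt=dt, theta=theta)["v@0"]
            mask = (tr.t >= 20) & (tr.t <= 120)
            ana = -65.0 - 0.05 * R * (1 - np.exp(-(tr.t[mask] - 20) / 10.0))
            return np.max(np.abs(tr.values[mask] - ana))

        for theta, order in ((1.0, 2.0), (0.5, 4.0)):
            e1, e2 = max_err(0.05, theta), max_err(0.025, theta)
            assert e1 / e2 == pytest.approx(order, rel=0.1)

    def test_unconditional_stability_large_dt(self, y_tree_model):
        sys = y_tree_model.circuit()
        traces = run(
            sys,
            stimuli=[StepCurrent(0, -0.2, 10.0, 500.0)],
            tstop=1000.0,
            dt=10.0,
            v_init=-65.0,
        )
        v = traces["v@0"].values
        assert np.all(np.isfinite(v))
        # bounded by rest and the steady-state hyperpolarization
        assert np.all(v <= -64.9)
        assert np.all(v >= -65.0 - 0.2 * 500.0)  # far below any R_in·I

    def test_charge_balance_at_steady_state(self, passive_point_model):
        """Injected current equals total leak current at steady state."""
        m = passive_point_model
        I = -0.05
        tr = m.run_step(I, delay=10, duration=400, tstop=420)["v@0"]
        in_step = (tr.t >= 405.0) & (tr.t <= 410.0)  # late in the step
        v_ss = tr.values[in_step].mean()
        g_leak = 1e-4 * m.stree.segments[0].area * 1e-2  # µS
        i_leak = g_leak * (v_ss - (-65.0))  # nA
        assert i_leak == pytest.approx(I, rel=1e-6)

    def test_distal_attenuation(self, y_tree_model):
        m = y_tree_model
        distal = m.comp_at(len(m.stree.sectree.sections) - 1, 0.9)
        tr = m.run_step(
            -0.1, delay=10, duration=300, tstop=320, record_comps=(0, distal)
        )
        dv0 = tr["v@0"].values[-1] - tr["v@0"].values[0]
        dvd = tr[f"v@{distal}"].values[-1] - tr[f"v@{distal}"].values[0]
        assert abs(dvd) < abs(dv0)

    def test_deterministic_repeatability(self, hh_point_model):
        a = hh_point_model.run_step(0.1, delay=10, duration=50, tstop=70)["v@0"]
        b = hh_point_model.run_step(0.1, delay=10, duration=50, tstop=70)["v@0"]
        assert np.array_equal(a.values, b.values)

    def test_excitability_threshold(self, hh_point_model):
        from dendrocable.protocols import detect_spikes

        sub = hh_point_model.run_step(0.01, delay=10, duration=50, tstop=70)["v@0"]
        supra = hh_point_model.run_step(0.2, delay=10, duration=50, tstop=70)["v@0"]
        assert len(detect_spikes(sub)) == 0
        assert len(detect_spikes(supra)) >= 1

    def test_bad_dt_rejected(self, passive_point_model):
        from dendrocable.simulator import advance

        with pytest.raises(ValueError):
            advance(passive_point_model.circuit(), -0.1)


class TestSynapticPrimitives:
    def test_dual_exp_zero_at_zero(self):
        assert dual_exp_conductance(0.0, 1.0, 0.5, 5.0) == 0.0

    def test_dual_exp_peak_normalized(self):
        tr, td, gmax = 0.5, 5.0, 2.0
        tp = tr * td / (td - tr) * math.log(td / tr)
        assert dual_exp_conductance(tp, gmax, tr, td) == pytest.approx(gmax)
        t = np.linspace(0, 50, 5001)
        assert dual_exp_conductance(t, gmax, tr, td).max() <= gmax * (1 + 1e-6)

    def test_dual_exp_alpha_limit(self):
        """τr→τd approaches the alpha function g = gmax·(t/τ)e^(1−t/τ)."""
        td = 5.0
        tr = 0.999 * td
        t = np.linspace(0.01, 30, 200)
        g = dual_exp_conductance(t, 1.0, tr, td)
        alpha = (t / td) * np.exp(1 - t / td)
        assert np.max(np.abs(g - alpha)) < 5e-3

    def test_dual_exp_invalid_taus(self):
        with pytest.raises(ValueError):
            dual_exp_conductance(1.0, 1.0, 5.0, 0.5)

    def test_nmda_gate_saturates_and_increases(self):
        v = np.linspace(-90, 40, 131)
        g = nmda_gate(v)
        assert np.all(np.diff(g) > 0)
        assert nmda_gate(200.0) > 0.999
        v_half = math.log(0.28) / 0.062
        assert nmda_gate(v_half) == pytest.approx(0.5)


class TestSpikeTrains:
    def test_regular_train(self):
        times = spike_train(SpikeSource(rate=10.0, noise=0.0, onset=0.0, duration=1000.0))
        assert len(times) == 10
        assert np.allclose(np.diff(times), 100.0)

    def test_poisson_cv(self):
        times = spike_train(
            SpikeSource(rate=50.0, noise=1.0, onset=0.0, duration=100_000.0, seed=7)
        )
        isi = np.diff(times)
        assert isi.std() / isi.mean() == pytest.approx(1.0, abs=0.05)

    def test_zero_duration_empty(self):
        assert len(spike_train(SpikeSource(rate=10.0, duration=0.0))) == 0

    def test_reproducible_under_seed(self):
        a = spike_train(SpikeSource(rate=20.0, noise=0.7, duration=1000.0, seed=3))
        b = spike_train(SpikeSource(rate=20.0, noise=0.7, duration=1000.0, seed=3))
        assert np.array_equal(a, b)

    def test_onset_respected(self):
        times = spike_train(SpikeSource(rate=100.0, noise=1.0, onset=50.0,
                                        duration=100.0, seed=1))
        assert np.all(times >= 50.0)
        assert np.all(times < 150.0)


class TestPlacement:
    def test_zero_count_empty(self):
        assert place_synapses(0, [], rng=0) == []

    def test_single_segment_gets_all(self, ball_and_stick_segments):
        seg = ball_and_stick_segments.segments[2]
        locs = place_synapses(5, [seg], rng=1)
        assert all(s is seg for s, _ in locs)
        assert all(0 <= x < 1 for _, x in locs)

    def test_length_weighted_split(self):
        class Seg:
            def __init__(self, L):
                self.length = L

        segs = [Seg(10.0), Seg(90.0)]
        locs = place_synapses(10_000, segs, rng=42)
        n0 = sum(1 for s, _ in locs if s is segs[0])
        _stat, p = chisquare([n0, 10_000 - n0], [1000, 9000])
        assert p > 0.01

    def test_empty_set_with_positive_n_rejected(self):
        with pytest.raises(ValueError):
            place_synapses(3, [], rng=0)


class TestSynapticIntegration:
    def test_epsp_depolarizes(self, passive_point_model):
        peak = passive_point_model.epsp_peak(5e-4, 0, kind="AMPA")
        assert 0.1 < peak < 40.0

    def test_gaba_hyperpolarizes_from_neutral(self, passive_point_model):
        syns = make_synapse("GABA_A", 0, gmax=5e-4, spike_times=[10.0], e=-80.0)
        tr = passive_point_model.run_synapses(syns, tstop=60)["v@0"]
        assert tr.values.min() < -65.0 - 0.1

    def test_synapse_requires_ordered_taus(self):
        with pytest.raises(ValueError):
            Synapse(comp=0, gmax=1.0, e=0.0, tau_rise=5.0, tau_decay=1.0)

    def test_ampa_nmda_composite(self):
        syns = make_synapse("AMPA_NMDA", 0, gmax=1e-3, spike_times=[5.0])
        assert len(syns) == 2
        assert {s.voltage_gated for s in syns} == {True, False}


class TestProtocolFiles:
    def test_json_csv_protocol_round(self, passive_point_model, toy_channels):
        from dendrocable.fixtures import make_ball_and_stick, make_passive_config
        from dendrocable.model import Model

        m = Model(
            make_ball_and_stick(), make_passive_config(), channels=toy_channels,
            d_lambda=0.1,
        )
        settings = '{"tstop": 120.0, "dt": 0.05, "v_init": -65.0}'
        elements = (
            "kind,section,x,amp,delay,duration,n,syn_kind,gmax,rate,noise,onset,seed\n"
            "iclamp,0,0.5,-0.05,20,80,,,,,,,\n"
            "recording,0,0.5,,,,,,,,,,\n"
            "recording,1,0.9,,,,,,,,,,\n"
            "synapse_population,1,0.5,,,,5,AMPA,0.0005,20,1.0,10,3\n"
        )
        traces = m.run_protocol(settings, elements)
        assert len(traces) == 2
        for tr in traces.values():
            assert tr.t[-1] == 120.0
            assert np.all(np.isfinite(tr.values))

    def test_unknown_element_kind_rejected(self, passive_point_model):
        import pytest as _pytest

        with _pytest.raises(ValueError, match="teleport"):
            passive_point_model.run_protocol(
                '{"tstop": 10}', "kind,section,x\nteleport,0,0.5\n"
            )
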