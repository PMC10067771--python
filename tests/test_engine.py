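"""Integration engine: equilibria, analytic cable checks, a high-accuracy
single-compartment reference, spike detection and determinism."""

import math

import numpy as np
import pytest

from hcnhomeo.engine import (SimulationConfig, build_model, detect_spikes,
                             run)
from hcnhomeo.morphology import (Morphology, PassiveParams, Section,
                                 compartmentalize)
from oracles import (reference_single_comp_spikes,
                     sealed_cable_input_resistance_mohm)


def _step(model, amp_nA, duration=1000.0, dt=0.025, hold=True, settle=300.0):
    wave = np.full(int(round(duration / dt)), amp_nA)
    cfg = SimulationConfig(duration=duration, dt=dt, settle=settle,
                           v_init=model.v_rest, hold=hold)
    return run(model, None, cfg, i_inj=wave)


class TestEquilibrium:
    def test_passive_rest(self, synthetic_tree):
        model = build_model(synthetic_tree, active=False)
        cfg = SimulationConfig(duration=500.0, settle=0.0, hold=False,
                               record=(0, model.n // 2, model.n - 1))
        res = run(model, None, cfg)
        # leak-balanced rest: every compartment stays at the leak reversal
        assert np.all(np.abs(res.v - model.v_rest) < 0.5)

    def test_charge_drift_passive(self, synthetic_tree):
        model = build_model(synthetic_tree, active=False)
        cfg = SimulationConfig(duration=1000.0, settle=0.0, hold=False)
        res = run(model, None, cfg)
        v = res.voltage(0)
        assert abs(v[-1] - v[0]) < 1e-3 * abs(model.v_rest)


class TestAnalyticCable:
    def test_sealed_end_input_resistance(self):
        """Somatic input resistance of a uniform passive cable matches the
        sealed-end analytic solution within 1%."""
        d, L = 2.0, 800.0
        p = PassiveParams(Rm_max=10.0, Rm_min=10.0, Ra_max=120.0, Ra_min=120.0)
        soma = Section(0, "soma", np.array([[-1.0, 0, 0], [1.0, 0, 0]]),
                       np.array([d, d]), parent=-1)
        cable = Section(1, "apical", np.array([[0.0, 0, 0], [0.0, L, 0]]),
                        np.array([d, d]), parent=0)
        tree = compartmentalize(Morphology([soma, cable]), p)
        model = build_model(tree, active=False)

        l_soma = tree.length[tree.region == "soma"][0]
        r_analytic = sealed_cable_input_resistance_mohm(d, L, l_soma, 10.0,
                                                        120.0)

        amp = 0.01  # nA
        res = _step(model, amp, duration=600.0, hold=False, settle=0.0)
        v = res.voltage(0)
        r_measured = (v[-1] - model.v_rest) / amp
        assert r_measured == pytest.approx(r_analytic, rel=0.01)


@pytest.fixture(scope="module")
def engine_counts(single_comp_model):
    counts = {}
    for dt in (0.025, 0.0125):
        res = _step(single_comp_model, 0.08, duration=1000.0, dt=dt,
                    hold=False, settle=300.0)
        counts[dt] = res.spike_count
    return counts


class TestSingleCompartmentOracle:
    def test_repetitive_firing_at_stated_densities(self, single_comp_model,
                                                   engine_counts):
        # gNa 16 / gKDR 10 mS/cm^2: sustained suprathreshold firing
        assert engine_counts[0.025] >= 10
        res = _step(single_comp_model, 0.08, hold=False, settle=300.0)
        assert res.spike_times[-1] > 800.0

    def test_matches_adaptive_reference(self, single_comp_model,
                                        engine_counts):
        ref = reference_single_comp_spikes(single_comp_model, 0.08, 1000.0)
        assert abs(engine_counts[0.025] - len(ref)) <= 1

    def test_dt_convergence(self, engine_counts):
        assert abs(engine_counts[0.025] - engine_counts[0.0125]) <= 1


class TestDetectSpikes:
    def test_flat_trace(self):
        assert len(detect_spikes(np.full(1000, -65.0), 0.1)) == 0

    def test_constructed_train(self):
        dt = 0.1
        v = np.full(5000, -65.0)
        onsets = np.arange(200, 4800, 500)
        for i in onsets:
            v[i:i + 10] = 10.0
        times = detect_spikes(v, dt, threshold=0.0)
        np.testing.assert_allclose(times, onsets * dt)

    def test_refractory(self):
        dt = 0.1
        v = np.full(200, -65.0)
        v[50:53] = 10.0
        v[60:63] = 10.0   # 1 ms later
        v[120:123] = 10.0
        times = detect_spikes(v, dt, threshold=0.0, refractory=2.0)
        assert len(times) == 2


class TestDeterminism:
    def test_bit_identical_reruns(self, small_active_model):
        from hcnhomeo.stimulation import poisson_train
        events = [poisson_train(8.0, 0.5, np.random.default_rng(i))
                  for i in range(len(small_active_model.synapses))]
        cfg = SimulationConfig(duration=500.0, settle=200.0, plasticity=True)
        r1 = run(small_active_model.copy(), events, cfg)
        r2 = run(small_active_model.copy(), events, cfg)
        np.testing.assert_array_equal(r1.spike_times, r2.spike_times)
        np.testing.assert_array_equal(r1.final_w, r2.final_w)
        np.testing.assert_array_equal(r1.v, r2.v)


class TestWeightBounds:
    def test_weights_bounded_during_induction(self, small_active_model):
        from hcnhomeo.stimulation import poisson_train
        m = small_active_model.copy()
        for s in m.synapses:
            s.shell.free_fraction = 0.008
        events = [poisson_train(12.0, 2.0, np.random.default_rng(100 + i))
                  for i in range(len(m.synapses))]
        cfg = SimulationConfig(duration=2000.0, settle=200.0, plasticity=True,
                               w_rec_every_ms=50.0)
        res = run(m, events, cfg)
        assert np.all(res.w >= 0.0)
        assert np.all(res.w <= 1.05)
        assert np.all(res.final_w <= 1.05)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(duration=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(duration=100.0, dt=-0.025)
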