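"""EPSPs, dendritic democracy, input resistance, I/O profiles, RMSE."""

import numpy as np
import pytest

from hcnhomeo.engine import build_model
from hcnhomeo.measurements import (MeasurementError, ResponseProfile,
                                   democracy_tune, epsp_amplitude,
                                   epsp_amplitudes, input_resistance,
                                   io_profile, rmse)
from hcnhomeo.synapse import place_synapses


class TestRMSE:
    def test_identical(self):
        p = ResponseProfile(np.arange(1, 6), np.random.default_rng(0)
                            .poisson(10.0, (5, 4)).astype(float))
        assert rmse(p, p) == 0.0

    def test_constant_offset(self):
        base = ResponseProfile([1, 2], np.zeros((2, 3)))
        new = ResponseProfile([1, 2], np.full((2, 3), 5.0))
        assert rmse(new, base) == pytest.approx(5.0)

    def test_hand_computed_2x2(self):
        base = ResponseProfile([1, 2], [[0.0, 0.0], [10.0, 10.0]])
        new = ResponseProfile([1, 2], [[1.0, 1.0], [13.0, 13.0]])
        assert rmse(new, base) == pytest.approx(np.sqrt(5.0))

    def test_dimension_mismatch(self):
        a = ResponseProfile([1, 2], np.zeros((2, 3)))
        b = ResponseProfile([1, 2, 3], np.zeros((3, 3)))
        with pytest.raises(ValueError):
            rmse(a, b)


class TestEPSP:
    def test_zero_permeability_zero_amplitude(self, synthetic_tree):
        from hcnhomeo.synapse import ReceptorParams
        syns = place_synapses(synthetic_tree, max_count=3,
                              params=ReceptorParams(P_ampa=0.0))
        model = build_model(synthetic_tree, synapses=syns)
        amps = epsp_amplitudes(model)
        # zero up to the sub-mV settling drift of the holding bias
        assert np.all(np.abs(amps) < 5e-3)

    def test_monotone_in_weight(self, small_active_model):
        """Somatic EPSP amplitude grows with the synaptic weight at
        proximal, mid and distal locations."""
        from dataclasses import replace
        base = small_active_model.copy()
        base.scale_synapses(0.25)   # keep w = 1 subthreshold
        nsyn = len(base.synapses)
        for si in (0, nsyn // 2, nsyn - 1):
            amps = []
            for w in (0.25, 0.5, 1.0):
                m = base.copy()
                m.synapses[si].w = w
                amps.append(epsp_amplitude(m, si))
            assert amps[0] < amps[1] < amps[2]


class TestDemocracy:
    def test_distal_needs_higher_permeability(self, synthetic_tree):
        syns = place_synapses(synthetic_tree, max_count=3)
        model = build_model(synthetic_tree, synapses=syns)
        P = democracy_tune(model, target=1.0, tol=0.02)
        xs = [model.x[s.compartment] for s in model.synapses]
        assert P[np.argmax(xs)] > P[np.argmin(xs)]

    def test_tuned_state_is_fixed_point(self, tuned_model):
        before = np.array([s.params.P_ampa for s in tuned_model.synapses])
        m = tuned_model.copy()
        democracy_tune(m, target=2.0, tol=0.05)
        after = np.array([s.params.P_ampa for s in m.synapses])
        np.testing.assert_allclose(after, before, rtol=0.35)
        amps = epsp_amplitudes(m)
        assert np.all(np.abs(amps - 2.0) <= 0.05)


class TestInputResistance:
    def test_linearity_on_passive_model(self, synthetic_tree):
        # small pulses: the passive reduced cell is high-impedance (~GOhm)
        model = build_model(synthetic_tree, active=False)
        amps = np.array([-10.0, -5.0, 0.0, 5.0, 10.0])
        rin = input_resistance(model, amps_pA=amps, pulse_ms=200.0)
        assert rin > 0.0

    def test_hcn_decreases_rin(self, tuned_model):
        amps = np.array([-40.0, -20.0, 20.0, 40.0])
        r1 = input_resistance(tuned_model, amps_pA=amps, pulse_ms=250.0)
        m = tuned_model.copy()
        m.scale_gh(2.0)
        r2 = input_resistance(m, amps_pA=amps, pulse_ms=250.0)
        assert r2 < r1


class TestIOProfile:
    def test_zero_permeability_silent(self, synthetic_tree):
        from hcnhomeo.synapse import ReceptorParams
        syns = place_synapses(synthetic_tree, max_count=5,
                              params=ReceptorParams(P_ampa=0.0))
        model = build_model(synthetic_tree, synapses=syns)
        prof = io_profile(model, freqs=[5.0, 20.0], trials=2, seed=0,
                          duration=400.0)
        assert np.all(prof.rates == 0.0)

    def test_seed_reproducibility(self, tuned_model):
        p1 = io_profile(tuned_model, freqs=[10.0], trials=2, seed=7,
                        duration=500.0)
        p2 = io_profile(tuned_model, freqs=[10.0], trials=2, seed=7,
                        duration=500.0)
        np.testing.assert_array_equal(p1.rates, p2.rates)

    def test_profile_csv_round_trip(self, tmp_path):
        p = ResponseProfile([1.0, 2.0], [[0.0, 1.0], [2.0, 3.0]])
        path = tmp_path / "prof.csv"
        p.to_csv(path)
        import pandas as pd
        df = pd.read_csv(path)
        assert list(df["stim_hz"]) == [1.0, 2.0]
        assert df.shape == (2, 3)
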