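"""Receptor gating, magnesium block, GHK receptor currents and the
calcium shell."""

import math

import numpy as np
import pytest

from hcnhomeo.mechanisms import CONSTANTS, nernst
from hcnhomeo.synapse import (CalciumShell, ReceptorParams, SynapseState,
                              gating_norm, gating_peak_time, gating_s,
                              mg_block, receptor_currents, step_calcium)


class TestMgBlock:
    def test_zero_mv(self):
        # 1 / (1 + 2/3.57)
        assert mg_block(0.0, 2.0) == pytest.approx(0.6409, abs=1e-4)

    def test_hyperpolarized(self):
        assert mg_block(-65.0, 2.0) == pytest.approx(0.0307, abs=1e-4)

    def test_limits_and_monotonicity(self):
        assert mg_block(300.0, 2.0) == pytest.approx(1.0, abs=1e-6)
        v = np.linspace(-100.0, 60.0, 321)
        b = mg_block(v, 2.0)
        assert np.all(np.diff(b) > 0)
        assert np.all((b > 0) & (b <= 1))


class TestGating:
    def test_zero_at_onset_and_decay(self):
        assert gating_s(0.0, 5.0, 50.0) == pytest.approx(0.0)
        assert gating_s(5000.0, 5.0, 50.0) == pytest.approx(0.0, abs=1e-12)

    def test_nmda_peak_time_and_unit_peak(self):
        tp = gating_peak_time(5.0, 50.0)
        assert tp == pytest.approx(12.79, abs=0.01)
        assert gating_s(tp, 5.0, 50.0) == pytest.approx(1.0, rel=1e-12)
        t = np.linspace(0.0, 400.0, 8001)
        assert gating_s(t, 5.0, 50.0).max() == pytest.approx(1.0, abs=1e-5)

    def test_requires_rise_below_decay(self):
        with pytest.raises(ValueError):
            gating_s(1.0, 10.0, 2.0)

    def test_superposition_periodic_and_sublinear(self):
        t = np.linspace(0.0, 2000.0, 40001)
        peaks = {}
        for f in (10.0, 20.0, 40.0):
            events = np.arange(0.0, 2000.0, 1000.0 / f)
            s = gating_s(t, 2.0, 10.0, events=events)
            late = s[t > 1000.0]
            peaks[f] = late.max()
            # period-1/f steady state: peaks of consecutive cycles agree
            per = 1000.0 / f
            c1 = s[(t > 1500.0) & (t <= 1500.0 + per)].max()
            c2 = s[(t > 1500.0 + per) & (t <= 1500.0 + 2 * per)].max()
            assert c1 == pytest.approx(c2, rel=5e-2)
        assert peaks[20.0] < 2.0 * peaks[10.0]
        assert peaks[40.0] < 2.0 * peaks[20.0]


class TestReceptorCurrents:
    def setup_method(self):
        self.state = SynapseState(compartment=0, w=0.25,
                                  params=ReceptorParams(P_ampa=2e-6))

    def test_sodium_components_vanish_at_sodium_nernst(self):
        v = nernst(1, CONSTANTS.Na_i, CONSTANTS.Na_o)
        out = receptor_currents(v, 0.5, 0.5, self.state)
        assert out["I_NMDA_Na"] == pytest.approx(0.0, abs=1e-15)
        assert out["I_AMPA_Na"] == pytest.approx(0.0, abs=1e-15)

    def test_zero_weight_silences_ampa(self):
        self.state.w = 0.0
        for v in (-70.0, 0.0, 30.0):
            out = receptor_currents(v, 1.0, 1.0, self.state)
            assert out["I_AMPA_Na"] == 0.0 and out["I_AMPA_K"] == 0.0

    def test_linear_in_permeability(self):
        out1 = receptor_currents(-40.0, 0.7, 0.0, self.state)
        big = SynapseState(compartment=0, w=0.25,
                           params=ReceptorParams(P_ampa=4e-6))
        out2 = receptor_currents(-40.0, 0.7, 0.0, big)
        for key in ("I_NMDA_Na", "I_NMDA_K", "I_NMDA_Ca"):
            assert out2[key] == pytest.approx(2.0 * out1[key], rel=1e-12)

    def test_total_nmda_reverses_near_zero(self):
        def total(v):
            out = receptor_currents(v, 1.0, 0.0, self.state)
            return out["I_NMDA_Na"] + out["I_NMDA_K"] + out["I_NMDA_Ca"]
        assert total(-5.0) < 0 < total(5.0)


class TestCalciumShell:
    def test_fixed_point(self):
        sh = CalciumShell(ca=1e-4)
        step_calcium(sh, 0.0, 0.0, 1.0)
        assert sh.ca == pytest.approx(1e-4, rel=1e-12)

    def test_exponential_decay(self):
        sh = CalciumShell(ca=2e-4)
        step_calcium(sh, 0.0, 0.0, 30.0)
        assert sh.ca == pytest.approx(1e-4 + 1e-4 / math.e, rel=1e-9)

    def test_constant_influx_steady_state(self):
        sh = CalciumShell(ca=1e-4)
        I = -1e-3  # inward calcium current density, mA/cm^2
        influx = -10000.0 * I / (3.6 * sh.dpt * CONSTANTS.F)
        for _ in range(100):
            step_calcium(sh, I, 0.0, 10.0)
        assert sh.ca == pytest.approx(sh.ca_inf + sh.tau_ca * influx, rel=1e-6)

    def test_negative_clamped(self, caplog):
        sh = CalciumShell(ca=1e-4)
        with caplog.at_level("WARNING"):
            step_calcium(sh, 1.0, 0.0, 50.0)  # strong outward flux
        assert sh.ca == 0.0
        assert any("clamped" in r.message for r in caplog.records)

    def test_free_fraction_scales_influx(self):
        a = CalciumShell(ca=1e-4, free_fraction=1.0)
        b = CalciumShell(ca=1e-4, free_fraction=0.5)
        step_calcium(a, -1e-3, 0.0, 5.0)
        step_calcium(b, -1e-3, 0.0, 5.0)
        assert (b.ca - 1e-4) == pytest.approx(0.5 * (a.ca - 1e-4), rel=1e-9)

    def test_nonnegative_under_random_drive(self):
        rng = np.random.default_rng(7)
        sh = CalciumShell(ca=1e-4)
        for _ in range(500):
            step_calcium(sh, rng.normal(0.0, 5e-3), rng.normal(0.0, 1e-3), 0.5)
            assert sh.ca >= 0.0


def test_norm_constant_makes_unit_peak():
    for tr, td in ((2.0, 10.0), (5.0, 50.0), (0.5, 3.0)):
        a = gating_norm(tr, td)
        tp = gating_peak_time(tr, td)
        assert a * (math.exp(-tp / td) - math.exp(-tp / tr)) == pytest.approx(1.0)


def test_placement_table(tmp_path):
    from hcnhomeo.morphology import PassiveParams, compartmentalize
    from hcnhomeo.synapse import place_synapses, placement_table
    from hcnhomeo.synthetic import make_morphology
    tree = compartmentalize(make_morphology(seed=0), PassiveParams())
    syns = place_synapses(tree, max_count=5)
    df = placement_table(syns, tree)
    assert list(df.columns) == ["synapse", "compartment", "x_um",
                                "P_ampa_cm_s", "nar", "w"]
    assert len(df) == 5
    assert np.all((df["x_um"] >= 12.5) & (df["x_um"] <= 286.7))
    df.to_csv(tmp_path / "placement.csv", index=False)
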