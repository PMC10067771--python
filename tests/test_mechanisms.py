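"""Channel gradients, half-activation rules, gate kinetics and GHK flux."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hcnhomeo import mechanisms as mech
from hcnhomeo.mechanisms import (CONSTANTS, GradientParams, gate_inf_tau,
                                 ghk_flux, gradient_density,
                                 hcn_half_activation, ka_model_select, nernst)


class TestGradients:
    def test_ka_somatic_density(self):
        assert gradient_density("KA", 0.0, GradientParams()) == pytest.approx(3.1)

    def test_hcn_midpoint(self):
        # sigmoid midpoint at h_d = 320 um: 25 * (1 + 12/2)
        assert gradient_density("HCN", 320.0, GradientParams()) == pytest.approx(175.0)

    def test_cat_asymptote(self):
        # 80 * (1 + 30)
        assert gradient_density("CaT", 1e7, GradientParams()) == pytest.approx(2480.0)

    def test_unknown_channel(self):
        with pytest.raises(ValueError):
            gradient_density("Kv7", 10.0, GradientParams())

    @pytest.mark.parametrize("channel", ["KA", "HCN", "CaT"])
    def test_continuous_monotone_nondecreasing(self, channel):
        x = np.linspace(0.0, 600.0, 1201)
        g = gradient_density(channel, x, GradientParams())
        assert np.all(np.diff(g) >= -1e-12)
        assert np.max(np.abs(np.diff(g))) < 0.05 * g.max()  # no jumps


class TestHCNHalfActivation:
    @pytest.mark.parametrize("x,expect", [(50.0, -82.0), (100.0, -82.0),
                                          (200.0, -86.0), (300.0, -90.0),
                                          (400.0, -90.0)])
    def test_piecewise_values(self, x, expect):
        assert hcn_half_activation(x) == pytest.approx(expect)


class TestKASelect:
    @pytest.mark.parametrize("x,expect", [(0.0, "proximal"), (99.9, "proximal"),
                                          (100.0, "distal"), (250.0, "distal")])
    def test_boundary(self, x, expect):
        assert ka_model_select(x) == expect


class TestGHK:
    def test_zero_at_nernst(self):
        c = CONSTANTS
        for z, ci, co in [(1, c.Na_i, c.Na_o), (1, c.K_i, c.K_o),
                          (2, c.Ca_i, c.Ca_o)]:
            e = nernst(z, ci, co)
            assert abs(ghk_flux(e, z, ci, co, 1e-6)) < 1e-12

    def test_v_zero_limit(self):
        # I(0) = 1e-3 * P z F (Ci - Co)
        c = CONSTANTS
        got = ghk_flux(0.0, 1, c.Na_i, c.Na_o, 2e-6)
        assert got == pytest.approx(1e-3 * 2e-6 * c.F * (c.Na_i - c.Na_o),
                                    rel=1e-9)
        # continuity across the series switch
        assert ghk_flux(1e-7, 1, c.Na_i, c.Na_o, 2e-6) == pytest.approx(
            ghk_flux(-1e-7, 1, c.Na_i, c.Na_o, 2e-6), rel=1e-4)

    def test_ohmic_when_symmetric(self):
        v = np.array([-40.0, -10.0, 10.0, 40.0])
        i = ghk_flux(v, 1, 100.0, 100.0, 1e-6)
        np.testing.assert_allclose(i / v, i[0] / v[0], rtol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=-120.0, max_value=60.0),
           st.floats(min_value=0.01, max_value=50.0))
    def test_strictly_increasing_in_v(self, v, dv):
        i1 = ghk_flux(v, 2, 1e-4, 2.0, 1e-6)
        i2 = ghk_flux(v + dv, 2, 1e-4, 2.0, 1e-6)
        assert i2 > i1

    def test_negative_permeability_rejected(self):
        with pytest.raises(ValueError):
            ghk_flux(0.0, 1, 10.0, 100.0, -1e-6)


ALL_GATES = [("na", "m"), ("na", "h"), ("na", "s"), ("kdr", "n"),
             ("ka_proximal", "n"), ("ka_proximal", "l"), ("ka_distal", "n"),
             ("hcn", "l"), ("cat", "m"), ("cat", "h")]


class TestGateKinetics:
    @pytest.mark.parametrize("channel,gate", ALL_GATES)
    @pytest.mark.parametrize("v", [-90.0, -65.0, -30.0, 0.0])
    def test_relaxation_to_steady_state(self, channel, gate, v):
        """Exponential-Euler stepping at fixed v reaches the steady-state
        curve within 5 tau to 1%."""
        inf, tau = gate_inf_tau(channel, gate, v)
        assert 0.0 <= inf <= 1.0
        assert tau > 0.0
        dt = 0.025
        x = 0.0 if inf > 0.5 else 1.0
        alpha = 1.0 - math.exp(-dt / tau)
        for _ in range(int(5.0 * tau / dt) + 1):
            x += (inf - x) * alpha
        assert abs(x - inf) <= 0.01 * max(inf, 1.0 - inf, 0.05)

    def test_hcn_activated_by_hyperpolarization(self):
        lo, _ = gate_inf_tau("hcn", "l", -110.0, vhalf=-82.0)
        hi, _ = gate_inf_tau("hcn", "l", -50.0, vhalf=-82.0)
        assert lo > 0.9 > 0.1 > hi

    def test_na_slow_inactivation_residual(self):
        # ar = 1 disables the gate; dendritic ar leaves that residual open
        s_off, _ = gate_inf_tau("na", "s", 0.0, ar=1.0)
        assert s_off == pytest.approx(1.0)
        s_dend, _ = gate_inf_tau("na", "s", 0.0, ar=0.7)
        assert s_dend == pytest.approx(0.7, abs=1e-6)


def test_reversal_potentials_match_concentrations():
    # the stated concentration set produces ~+55 / -90 mV equilibria
    assert nernst(1, CONSTANTS.Na_i, CONSTANTS.Na_o) == pytest.approx(55.0, abs=1.5)
    assert nernst(1, CONSTANTS.K_i, CONSTANTS.K_o) == pytest.approx(-90.0, abs=2.0)


def test_export_kinetics_round_trips(tmp_path):
    import json
    from hcnhomeo.mechanisms import CHANNEL_KINETICS, export_kinetics
    path = tmp_path / "kinetics.json"
    export_kinetics(path)
    assert json.loads(path.read_text()) == json.loads(
        json.dumps(CHANNEL_KINETICS))
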