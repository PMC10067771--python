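"""Morphology: SWC parsing, passive gradients, d-lambda discretization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hcnhomeo.morphology import (Morphology, PassiveParams, Section,
                                 SWCParseError, assign_passive,
                                 compartmentalize, lambda_f, load_swc,
                                 write_swc)

TOY_SWC = """\
# toy: soma point + two apical points
1 1 0 0 0 5 -1
2 4 0 10 0 1 1
3 4 0 30 0 1 2
"""


def _write(tmp_path, text):
    p = tmp_path / "cell.swc"
    p.write_text(text)
    return p


class TestLoadSWC:
    def test_toy_geometry(self, tmp_path):
        m = load_swc(_write(tmp_path, TOY_SWC))
        regions = sorted(s.region for s in m.sections)
        assert regions == ["apical", "soma"]
        apical = next(s for s in m.sections if s.region == "apical")
        # length = Euclidean distance between the two apical sample points
        assert apical.length == pytest.approx(20.0)

    def test_forward_parent_reference_rejected(self, tmp_path):
        bad = "1 1 0 0 0 5 -1\n2 4 0 10 0 1 3\n3 4 0 30 0 1 2\n"
        with pytest.raises(SWCParseError, match="line 2"):
            load_swc(_write(tmp_path, bad))

    @pytest.mark.parametrize("bad,msg", [
        ("1 1 0 0 0 5 -1\n2 4 0 10 0 -1 1\n", "radius"),
        ("1 1 0 0 0 5 -1\n2 4 0 10 0 1\n", "columns"),
        ("1 1 0 0 0 5 -1\n2 4 0 x 0 1 1\n", "non-numeric"),
    ])
    def test_malformed_rows(self, tmp_path, bad, msg):
        with pytest.raises(SWCParseError, match=msg):
            load_swc(_write(tmp_path, bad))

    def test_soma_collapsed_to_equivalent_area_cylinder(self, tmp_path):
        m = load_swc(_write(tmp_path, TOY_SWC))
        soma = m.soma
        # single-point soma of radius 5 -> sphere area 4*pi*25
        assert soma.frustum_area() == pytest.approx(4 * math.pi * 25 * 1e-8,
                                                    rel=1e-6)


class TestAssignPassive:
    def test_midpoint_value(self, passive_params):
        # sigmoid midpoint at x = Rm_d: (125 + 85) / 2
        assert assign_passive(300.0, passive_params, "Rm") == pytest.approx(105.0)

    def test_somatic_value(self, passive_params):
        # 125 - 40 / (1 + e^6)
        expect = 125.0 - 40.0 / (1.0 + math.exp(6.0))
        assert assign_passive(0.0, passive_params, "Rm") == pytest.approx(expect)
        assert assign_passive(0.0, passive_params, "Rm") == pytest.approx(124.90, abs=0.01)

    def test_distal_asymptote(self, passive_params):
        assert assign_passive(1e6, passive_params, "Rm") == pytest.approx(85.0)
        assert assign_passive(1e6, passive_params, "Ra") == pytest.approx(70.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=0.0, max_value=2000.0),
           st.floats(min_value=0.0, max_value=2000.0))
    def test_monotone_decreasing_and_bounded(self, x1, x2):
        params = PassiveParams()
        lo, hi = sorted([x1, x2])
        a = assign_passive(lo, params, "Rm")
        b = assign_passive(hi, params, "Rm")
        assert a >= b
        assert 85.0 <= b <= a <= 125.0


class TestCompartmentalize:
    def _cylinder(self, L, d):
        soma = Section(0, "soma", np.array([[-2.0, 0, 0], [2.0, 0, 0]]),
                       np.array([4.0, 4.0]), parent=-1)
        apical = Section(1, "apical",
                         np.array([[0.0, 0, 0], [0.0, L, 0]]),
                         np.array([d, d]), parent=0)
        return Morphology([soma, apical])

    def test_odd_count_at_exact_lambda(self):
        # uniform passives so lambda is exact; L = lambda_100 -> 11 comps
        p = PassiveParams(Ra_max=120.0, Ra_min=120.0, Rm_max=100.0,
                         Rm_min=100.0)
        lam = lambda_f(2.0, 100.0, 120.0, 1.0)
        tree = compartmentalize(self._cylinder(lam, 2.0), p)
        apical_n = int(np.sum(tree.region == "apical"))
        assert apical_n == 11

    def test_short_section_single_compartment(self, passive_params):
        tree = compartmentalize(self._cylinder(5.0, 2.0), passive_params)
        assert int(np.sum(tree.region == "apical")) == 1

    def test_compartment_shorter_than_dlambda(self, passive_params):
        # the rule is per section: lambda_100 from the section's equivalent
        # diameter and the axial resistivity at its midpoint distance
        L = 900.0
        tree = compartmentalize(self._cylinder(L, 2.0), passive_params)
        from hcnhomeo.morphology import assign_passive
        ra_mid = assign_passive(L / 2.0, passive_params, "Ra")
        lam = lambda_f(2.0, 100.0, ra_mid, passive_params.Cm)
        apical = tree.region == "apical"
        assert np.all(tree.length[apical] <= 0.1 * lam * 1.0001)
        assert int(np.sum(apical)) % 2 == 1

    def test_area_conservation(self, passive_params):
        m = self._cylinder(700.0, 2.0)
        m.sections[1].diam = np.array([3.0, 1.0])  # tapering
        tree = compartmentalize(m, passive_params)
        total = tree.area[tree.region == "apical"].sum()
        assert total == pytest.approx(m.sections[1].frustum_area(), rel=1e-3)

    def test_idempotent(self, passive_params):
        m = self._cylinder(700.0, 2.0)
        t1 = compartmentalize(m, passive_params)
        t2 = compartmentalize(m, passive_params)
        np.testing.assert_array_equal(t1.x, t2.x)
        np.testing.assert_array_equal(t1.area, t2.area)

    def test_zero_length_section_rejected(self, passive_params):
        soma = Section(0, "soma", np.array([[-2.0, 0, 0], [2.0, 0, 0]]),
                       np.array([4.0, 4.0]), parent=-1)
        degenerate = Section(1, "apical",
                             np.array([[0.0, 0, 0], [0.0, 0, 0]]),
                             np.array([2.0, 2.0]), parent=0)
        with pytest.raises(ValueError, match="zero length"):
            compartmentalize(Morphology([soma, degenerate]), passive_params)


def test_write_read_round_trip(tmp_path, passive_params):
    from hcnhomeo.synthetic import make_morphology, tag_ais
    m = make_morphology(seed=3)
    path = tmp_path / "syn.swc"
    write_swc(m, path)
    m2 = tag_ais(load_swc(path))
    t1 = compartmentalize(m, passive_params)
    t2 = compartmentalize(m2, passive_params)
    assert t1.n == t2.n
    # SWC text stores coordinates to 1e-4 um
    np.testing.assert_allclose(t1.x, t2.x, atol=1e-3)
    np.testing.assert_allclose(t1.area, t2.area, rtol=1e-4)
    assert list(t1.region) == list(t2.region)
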