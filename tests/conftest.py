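"""Shared fixtures.

Heavy objects (democracy-tuned reduced models, protocol runs) are
session-scoped so the expensive simulations run once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from hcnhomeo.engine import build_model
from hcnhomeo.morphology import Morphology, PassiveParams, Section, compartmentalize
from hcnhomeo.protocols import make_reduced_model, reduced_protocol
from hcnhomeo.synapse import place_synapses
from hcnhomeo.synthetic import make_morphology


@pytest.fixture(scope="session")
def passive_params():
    return PassiveParams()


@pytest.fixture(scope="session")
def synthetic_tree(passive_params):
    return compartmentalize(make_morphology(seed=0), passive_params)


@pytest.fixture(scope="session")
def single_comp_model():
    """A one-compartment soma-only cell with Na and KDR only."""
    soma = Section(0, "soma",
                   np.array([[-10.0, 0, 0], [10.0, 0, 0]]),
                   np.array([20.0, 20.0]), parent=-1)
    tree = compartmentalize(Morphology([soma]), PassiveParams())
    model = build_model(tree)
    model.gka[:] = 0.0
    model.gh[:] = 0.0
    model.gcat[:] = 0.0
    return model


@pytest.fixture(scope="session")
def small_active_model(synthetic_tree):
    """Untuned active model on the synthetic morphology with synapses."""
    return build_model(synthetic_tree, synapses=place_synapses(synthetic_tree))


@pytest.fixture(scope="session")
def tuned_model():
    """Democracy-tuned reduced preset model (the acceptance substrate)."""
    return make_reduced_model(seed=0)


@pytest.fixture(scope="session")
def proto_cfg():
    """Reduced protocol shrunk further for the test suite: 5 stimulus
    frequencies x 2 trials (biophysics unchanged)."""
    from dataclasses import replace
    return replace(reduced_protocol(), io_freqs=(2, 6, 10, 14, 18),
                   io_trials=2)
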