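"""Glutamatergic synapses: GHK-based AMPA/NMDA currents, magnesium block,
double-exponential gating and the submembrane calcium shell.

A synapse co-localizes AMPA and NMDA receptors on one compartment (the model
places at most one synapse per compartment).  Receptor currents follow the
constant-field (GHK) formulation with ionic permeability ratios
P_Ca : P_Na : P_K = 10.6 : 1 : 1 for NMDA and P_Na : P_K = 1 : 1 for AMPA;
NMDA current is additionally gated by the voltage-dependent magnesium block.
Permeabilities are surface densities over the host compartment's membrane,
so currents scale with compartment area — consistent with the density-style
calcium shell below.

Calcium entering through NMDA receptors and T-type Ca channels accumulates
in a thin submembrane shell (depth 0.1 um) and relaxes back to its resting
value with a 30 ms time constant:

    d[Ca]/dt = -10000 * I_Ca / (3.6 * dpt * F) + ([Ca]_inf - [Ca]) / tau_Ca

with I_Ca in mA/cm^2 and [Ca] in mM (the printed constants are kept
verbatim; see docs/methods.md for the unit bookkeeping).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .mechanisms import CONSTANTS, PhysicalConstants, ghk_flux

__all__ = [
    "ReceptorParams", "CalciumShell", "SynapseState",
    "mg_block", "gating_s", "gating_peak_time", "gating_norm",
    "receptor_currents", "step_calcium", "place_synapses",
    "placement_table",
]

logger = logging.getLogger(__name__)

#: Shell influx factor of the calcium balance, 10000 / 3.6 (units absorbed;
#: combined with dpt (um) and F it converts mA/cm^2 to mM/ms).
SHELL_NUMERATOR = 10000.0
SHELL_DENOM = 3.6


@dataclass(frozen=True)
class ReceptorParams:
    """AMPA/NMDA receptor parameters.

    ``P_ampa`` is the maximum AMPA permeability (cm/s, density over the host
    compartment); NMDA permeability is ``nar * P_ampa`` with the NMDA-to-AMPA
    ratio ``nar``.  Rise/decay time constants (ms): NMDA 5/50, AMPA 2/10.
    """

    P_ampa: float = 2e-6      # cm/s
    nar: float = 1.5          # NMDA : AMPA permeability ratio
    p_ca_nmda: float = 10.6   # P_Ca : P_Na : P_K = 10.6 : 1 : 1
    tau_r_nmda: float = 5.0
    tau_d_nmda: float = 50.0
    tau_r_ampa: float = 2.0
    tau_d_ampa: float = 10.0

    def __post_init__(self) -> None:
        if self.nar <= 0:
            raise ValueError("NAR must be > 0")
        if not (self.tau_r_nmda < self.tau_d_nmda
                and self.tau_r_ampa < self.tau_d_ampa):
            raise ValueError("rise time constant must be below decay")

    @property
    def P_nmda(self) -> float:
        return self.nar * self.P_ampa


@dataclass
class CalciumShell:
    """Submembrane calcium shell of one plastic synapse (concentrations mM).

    ``free_fraction`` scales the influx term: the fraction of entering
    calcium that remains free (unbuffered) and visible to the plasticity
    machinery.  The default of 1 integrates the balance exactly as printed;
    model presets set a calibrated value (see docs/methods.md).
    """

    ca: float = 1e-4
    tau_ca: float = 30.0      # ms
    dpt: float = 0.1          # um, shell depth
    ca_inf: float = 1e-4      # mM
    free_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.ca < 0:
            raise ValueError("[Ca]i must be >= 0")


@dataclass
class SynapseState:
    """Bookkeeping for one synapse: location, weight, event queue and shell."""

    compartment: int
    w: float = 0.25
    params: ReceptorParams = field(default_factory=ReceptorParams)
    events: list = field(default_factory=list)   # presynaptic event times (ms)
    shell: CalciumShell = field(default_factory=CalciumShell)
    plastic: bool = True
    has_nmda: bool = True

    def __post_init__(self) -> None:
        if self.w < 0:
            raise ValueError("weight must be >= 0")


def mg_block(v, mg_o: float = CONSTANTS.Mg_o):
    """Voltage-dependent magnesium unblock fraction of the NMDA receptor:
    ``1 / (1 + ([Mg]o / 3.57) * exp(-0.062 v))`` -- in (0, 1], increasing in v.
    """
    if mg_o < 0:
        raise ValueError("[Mg]o must be >= 0")
    v = np.asarray(v, dtype=float)
    out = 1.0 / (1.0 + (mg_o / 3.57) * np.exp(-0.062 * v))
    return float(out) if out.ndim == 0 else out


def gating_peak_time(tau_r: float, tau_d: float) -> float:
    """Time to peak (ms) of the double exponential, ln(tau_d/tau_r)
    * tau_r tau_d / (tau_d - tau_r)."""
    return math.log(tau_d / tau_r) * tau_r * tau_d / (tau_d - tau_r)


def gating_norm(tau_r: float, tau_d: float) -> float:
    """Normalization ``a`` such that a single event peaks at exactly 1."""
    tp = gating_peak_time(tau_r, tau_d)
    return 1.0 / (math.exp(-tp / tau_d) - math.exp(-tp / tau_r))


def gating_s(t, tau_r: float, tau_d: float, events=None):
    """Receptor gating variable ``s(t) = a [exp(-t/tau_d) - exp(-t/tau_r)]``.

    With ``events`` given (sequence of onset times, ms), contributions of all
    past events superpose linearly; each single-event contribution lies in
    [0, 1].  Without events, ``t`` is the time since a single onset at 0.
    """
    if tau_r >= tau_d:
        raise ValueError("requires tau_r < tau_d")
    a = gating_norm(tau_r, tau_d)
    t = np.asarray(t, dtype=float)

    def _one(dt):
        dtc = np.clip(dt, 0.0, None)
        return np.where(dt >= 0,
                        a * (np.exp(-dtc / tau_d) - np.exp(-dtc / tau_r)),
                        0.0)

    if events is None:
        out = _one(t)
    else:
        out = np.zeros_like(t, dtype=float)
        for t0 in events:
            out += _one(t - t0)
    return float(out) if out.ndim == 0 else out


def receptor_currents(v: float, s_nmda: float, s_ampa: float,
                      state: SynapseState,
                      c: PhysicalConstants = CONSTANTS) -> dict:
    """Ionic receptor current densities (mA/cm^2, outward positive).

    NMDA components are scaled by the magnesium unblock ``MgB(v)``; AMPA
    components by the synaptic weight ``w``.  Calcium GHK flux uses the
    shell's instantaneous [Ca]i.
    """
    p = state.params
    mgb = mg_block(v, c.Mg_o)
    pn = p.P_nmda * s_nmda * mgb
    pa = p.P_ampa * state.w * s_ampa
    return {
        "I_NMDA_Na": ghk_flux(v, 1, c.Na_i, c.Na_o, pn, c),
        "I_NMDA_K": ghk_flux(v, 1, c.K_i, c.K_o, pn, c),
        "I_NMDA_Ca": ghk_flux(v, 2, state.shell.ca, c.Ca_o,
                              pn * p.p_ca_nmda, c),
        "I_AMPA_Na": ghk_flux(v, 1, c.Na_i, c.Na_o, pa, c),
        "I_AMPA_K": ghk_flux(v, 1, c.K_i, c.K_o, pa, c),
    }


def step_calcium(shell: CalciumShell, I_NMDA_Ca: float, I_CaT_Ca: float,
                 dt: float, c: PhysicalConstants = CONSTANTS) -> CalciumShell:
    """Advance the shell calcium by ``dt`` (ms) under the given calcium
    current densities (mA/cm^2, negative = inward).

    The linear balance is integrated exactly over the step (exponential
    relaxation toward the influx-shifted fixed point).  A negative result is
    clamped at zero with a warning.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    influx = -shell.free_fraction * SHELL_NUMERATOR * (I_NMDA_Ca + I_CaT_Ca) / (
        SHELL_DENOM * shell.dpt * c.F)
    target = shell.ca_inf + shell.tau_ca * influx
    decay = math.exp(-dt / shell.tau_ca)
    ca = target + (shell.ca - target) * decay
    if ca < 0:
        logger.warning("shell calcium went negative (%.3g mM); clamped at 0", ca)
        ca = 0.0
    shell.ca = ca
    return shell


def place_synapses(tree, x_min: float = 12.5, x_max: float = 286.7,
                   max_count: int | None = None, w_init: float = 0.25,
                   params: ReceptorParams | None = None,
                   plastic: bool = True, has_nmda: bool = True,
                   ca_free_fraction: float = 1.0,
                   exclude_comps=(),
                   rng: np.random.Generator | None = None) -> list[SynapseState]:
    """Assign one synapse to each apical compartment within [x_min, x_max] um.

    With ``max_count`` given and fewer compartments needed, an evenly spaced
    (or random, if ``rng`` given) subset of eligible compartments is used.
    Returns a list of :class:`SynapseState`.
    """
    params = params or ReceptorParams()
    eligible = [i for i in range(tree.n)
                if tree.region[i] == "apical" and x_min <= tree.x[i] <= x_max
                and i not in set(exclude_comps)]
    if not eligible:
        raise ValueError("no apical compartments in the requested range")
    if max_count is not None and max_count < len(eligible):
        if rng is not None:
            eligible = sorted(rng.choice(eligible, size=max_count, replace=False))
        else:
            idx = np.linspace(0, len(eligible) - 1, max_count).round().astype(int)
            eligible = [eligible[i] for i in sorted(set(idx))]
    return [SynapseState(compartment=i, w=w_init, params=params,
                         plastic=plastic, has_nmda=has_nmda,
                         shell=CalciumShell(free_fraction=ca_free_fraction))
            for i in eligible]


def placement_table(synapses: list[SynapseState], tree):
    """Synapse placement table as a DataFrame (writable to CSV):
    synapse id, compartment id, path distance, AMPA permeability, NMDA:AMPA
    ratio and current weight."""
    import pandas as pd

    return pd.DataFrame({
        "synapse": np.arange(len(synapses)),
        "compartment": [s.compartment for s in synapses],
        "x_um": [tree.x[s.compartment] for s in synapses],
        "P_ampa_cm_s": [s.params.P_ampa for s in synapses],
        "nar": [s.params.nar for s in synapses],
        "w": [s.w for s in synapses],
    })
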