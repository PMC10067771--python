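"""Voltage-gated channel kinetics, dendritic conductance gradients and GHK
electrochemistry.

The model expresses five conductances: fast Na, delayed-rectifier K (KDR),
A-type K (KA, distinct proximal and distal variants), low-threshold T-type Ca
(CaT, GHK-based) and the hyperpolarization-activated HCN (h) current.  Na and
KDR densities are uniform; KA rises linearly and HCN/CaT sigmoidally with
path distance from the soma.  Kinetic schemes follow the canonical published
CA1 formulations for each channel family; every rate function is an
inspectable closed form whose coefficients live in :data:`CHANNEL_KINETICS`.

Gate helpers are numba-compiled scalars so the simulation engine uses exactly
the same code that the unit tests exercise.

Units: voltage mV, time ms, distance um, conductance density as stated per
channel (KA and Na/KDR in mS/cm^2; HCN and CaT in uS/cm^2), permeability
cm/s, concentration mM, current density mA/cm^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "PhysicalConstants", "GradientParams", "CHANNEL_KINETICS",
    "gradient_density", "hcn_half_activation", "ka_model_select",
    "ghk_flux", "nernst", "gate_inf_tau", "export_kinetics",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants and ionic concentrations (mM) at 34 degrees C."""

    F: float = 96485.3329     # C/mol
    R: float = 8.31446        # J/(mol*K)
    celsius: float = 34.0
    Na_o: float = 140.0
    Na_i: float = 18.0
    K_o: float = 5.0
    K_i: float = 140.0
    Ca_o: float = 2.0
    Ca_i: float = 1e-4
    Mg_o: float = 2.0

    @property
    def T(self) -> float:
        """Absolute temperature (K)."""
        return 273.15 + self.celsius

    @property
    def vt(self) -> float:
        """Thermal voltage RT/F in mV."""
        return 1e3 * self.R * self.T / self.F


CONSTANTS = PhysicalConstants()

#: Fixed reversal potentials (mV) of the ohmic currents.
E_NA, E_K, E_H = 55.0, -90.0, -30.0


@dataclass(frozen=True)
class GradientParams:
    """Channel density gradient parameters along the somato-apical axis.

    KA rises linearly, ``gKA(x) = A_gB * (1 + A_F * x / 100)`` (mS/cm^2);
    HCN and CaT rise sigmoidally,
    ``g(x) = gB * (1 + F / (1 + exp((d - x)/k)))`` (uS/cm^2).  Na and KDR are
    uniform, with a five-fold Na multiplier in the axon initial segment.
    """

    A_gB: float = 3.1        # mS/cm^2 at the soma
    A_F: float = 8.0
    h_gB: float = 25.0       # uS/cm^2 at the soma
    h_F: float = 12.0
    h_d: float = 320.0       # um
    h_k: float = 50.0        # um
    T_gB: float = 80.0       # uS/cm^2 at the soma
    T_F: float = 30.0
    T_d: float = 350.0       # um
    T_k: float = 50.0        # um
    gNa: float = 16.0        # mS/cm^2, uniform
    gKDR: float = 10.0       # mS/cm^2, uniform
    ais_na_mult: float = 5.0

    def __post_init__(self) -> None:
        if min(self.A_gB, self.h_gB, self.T_gB, self.gNa, self.gKDR) < 0:
            raise ValueError("conductance densities must be >= 0")
        if min(self.A_F, self.h_F, self.T_F) < 0:
            raise ValueError("fold factors must be >= 0")


#: Variant used for the place-field (theta-driven) configuration: the neuron
#: carries lower Na and much lower KDR density.
THETA_GRADIENTS = GradientParams(gNa=15.4, gKDR=2.0)


def gradient_density(channel: str, x, g: GradientParams):
    """Maximal conductance density at path distance ``x`` (um) from the soma.

    ``channel`` is one of ``"KA"`` (returns mS/cm^2), ``"HCN"`` or ``"CaT"``
    (uS/cm^2).  Basal and axonal compartments should be queried at x = 0.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    if channel == "KA":
        out = g.A_gB * (1.0 + g.A_F * x / 100.0)
    elif channel == "HCN":
        out = g.h_gB * (1.0 + g.h_F / (1.0 + np.exp((g.h_d - x) / g.h_k)))
    elif channel == "CaT":
        out = g.T_gB * (1.0 + g.T_F / (1.0 + np.exp((g.T_d - x) / g.T_k)))
    else:
        raise ValueError(f"unknown channel {channel!r}")
    return float(out) if out.ndim == 0 else out


def hcn_half_activation(x) -> float:
    """Half-maximal activation voltage (mV) of the h current at distance x.

    -82 mV up to 100 um, linear to -90 mV at 300 um, -90 mV beyond.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    out = np.where(x <= 100.0, -82.0,
                   np.where(x >= 300.0, -90.0,
                            -82.0 - 8.0 * (x - 100.0) / 200.0))
    return float(out) if out.ndim == 0 else out


def ka_model_select(x) -> str:
    """Pick the KA kinetic variant: proximal below 100 um, distal beyond."""
    if np.ndim(x) == 0:
        if x < 0:
            raise ValueError("x must be >= 0")
        return "proximal" if x < 100.0 else "distal"
    x = np.asarray(x, dtype=float)
    return np.where(x < 100.0, "proximal", "distal")


def nernst(z: float, Ci: float, Co: float, c: PhysicalConstants = CONSTANTS) -> float:
    """Nernst equilibrium potential (mV)."""
    return c.vt / z * math.log(Co / Ci)


def ghk_flux(v, z, Ci, Co, P, c: PhysicalConstants = CONSTANTS):
    """Goldman-Hodgkin-Katz constant-field current density (mA/cm^2).

    ``I = P z^2 F^2 v / (RT) * (Ci - Co exp(-zFv/RT)) / (1 - exp(-zFv/RT))``
    with permeability ``P`` in cm/s, concentrations in mM and voltage in mV.
    Continuous at v = 0 through the series limit ``P z F (Ci - Co)``
    (times the mM/(mol/cm^3) and A->mA unit factor of 1e-3).
    """
    if np.any(np.asarray(P) < 0):
        raise ValueError("permeability must be >= 0")
    v = np.asarray(v, dtype=float)
    u = z * v / c.vt
    small = np.abs(u) < 1e-6
    us = np.where(small, 1.0, u)  # avoid 0/0 in the masked branch
    exact = us * (Ci - Co * np.exp(-us)) / (1.0 - np.exp(-us))
    series = (Ci - Co) + u * (Ci + Co) / 2.0
    out = 1e-3 * P * z * c.F * np.where(small, series, exact)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Gate kinetics: closed forms + coefficient registry
#
# Forms used:
#   trap(x, y)      = x / (1 - exp(-x/y))         (linoid rate)
#   boltz(v, h, k)  = 1 / (1 + exp((v - h)/k))    (sigmoid steady state)
#   thermo(v, h, z) = exp(1e-3 z (v - h) F / RT)  (thermodynamic rate)

_FoRT = 1e-3 * CONSTANTS.F / (CONSTANTS.R * CONSTANTS.T)  # 1/mV

CHANNEL_KINETICS: dict = {
    "temperature_celsius": CONSTANTS.celsius,
    "na": {
        "reversal_mV": E_NA,
        "q10": 2.0, "q10_ref_celsius": 24.0,
        "m": {"form": "linoid_pair", "Ra": 0.4, "Rb": 0.124,
              "tha": -30.0, "qa": 7.2, "tau_min": 0.02},
        "h": {"form": "linoid_pair+boltz", "Rd": 0.03, "Rg": 0.01,
              "thi": -45.0, "qd": 1.5, "thinf": -50.0, "qinf": 4.0,
              "tau_min": 0.5},
        # slow inactivation, dendrites only ("ar" = depolarized residual;
        # ar = 1 disables the gate)
        "s": {"form": "thermo", "vhalf": -58.0, "vs": 2.0, "ar_dend": 0.7,
              "zetas": 12.0, "gms": 0.2, "a0s": 3e-4, "vvh": -60.0,
              "tau_min": 10.0},
    },
    "kdr": {
        "reversal_mV": E_K,
        "q10": 1.0, "q10_ref_celsius": 24.0,
        "n": {"form": "thermo", "vhalf": 13.0, "zeta": -3.0, "gm": 0.7,
              "a0": 0.02, "tau_min": 2.0},
    },
    "ka_proximal": {
        "reversal_mV": E_K,
        "q10": 5.0, "q10_ref_celsius": 24.0,
        "n": {"form": "thermo_gated", "vhalf": 11.0, "zeta": -1.5,
              "pw": -1.0, "tq": -40.0, "qq": 5.0, "gm": 0.55, "a0": 0.05,
              "tau_min": 0.1},
        "l": {"form": "thermo+linear_tau", "vhalf": -56.0, "zeta": 3.0,
              "tau_slope": 0.26, "tau_voffset": 50.0, "tau_min": 2.0},
    },
    "ka_distal": {
        "reversal_mV": E_K,
        "q10": 5.0, "q10_ref_celsius": 24.0,
        "n": {"form": "thermo_gated", "vhalf": -1.0, "zeta": -1.5,
              "pw": -1.0, "tq": -45.0, "qq": 5.0, "gm": 0.55, "a0": 0.05,
              "tau_min": 0.1},
        "l": {"form": "thermo+linear_tau", "vhalf": -56.0, "zeta": 3.0,
              "tau_slope": 0.26, "tau_voffset": 50.0, "tau_min": 2.0},
    },
    "hcn": {
        "reversal_mV": E_H,
        "q10": 1.0, "q10_ref_celsius": 34.0,
        # vhalf is location-dependent: -82 mV proximally to -90 mV distally
        "l": {"form": "boltz+thermo_tau", "k": 8.0, "zetat": 2.2,
              "vhalft": -75.0, "a0t": 0.011, "gmt": 0.4, "coeff": 0.0378,
              "tau_min": 2.0},
    },
    "cat": {
        "ghk": True,  # permeability-like density, GHK driving force
        "q10": 2.0, "q10_ref_celsius": 24.0,
        "m": {"form": "boltz+cosh_tau", "vhalf": -36.0, "k": -7.4,
              "tau_base": 0.5, "tau_amp": 2.0, "tau_vc": -36.0,
              "tau_vk": 20.0, "tau_min": 0.5},
        "h": {"form": "boltz+cosh_tau", "vhalf": -68.0, "k": 5.0,
              "tau_base": 8.0, "tau_amp": 30.0, "tau_vc": -60.0,
              "tau_vk": 10.0, "tau_min": 5.0},
    },
}


def q10_factor(channel: str, celsius: float = CONSTANTS.celsius) -> float:
    """Temperature scaling qt = q10^((celsius - ref)/10) for a channel."""
    cfg = CHANNEL_KINETICS[channel]
    return cfg["q10"] ** ((celsius - cfg["q10_ref_celsius"]) / 10.0)


@njit(cache=True)
def _trap(x: float, y: float) -> float:
    """Linoid x / (1 - exp(-x/y)), continuous at x = 0."""
    if abs(x / y) < 1e-6:
        return y * (1.0 + x / (2.0 * y))
    return x / (1.0 - math.exp(-x / y))


@njit(cache=True)
def na_m(v: float, qt: float):
    am = 0.4 * _trap(v + 30.0, 7.2)
    bm = 0.124 * _trap(-(v + 30.0), 7.2)
    minf = am / (am + bm)
    mtau = 1.0 / (am + bm) / qt
    if mtau < 0.02:
        mtau = 0.02
    return minf, mtau


@njit(cache=True)
def na_h(v: float, qt: float):
    ah = 0.03 * _trap(v + 45.0, 1.5)
    bh = 0.01 * _trap(-(v + 45.0), 1.5)
    htau = 1.0 / (ah + bh) / qt
    if htau < 0.5:
        htau = 0.5
    hinf = 1.0 / (1.0 + math.exp((v + 50.0) / 4.0))
    return hinf, htau


@njit(cache=True)
def na_s(v: float, qt: float, ar: float):
    """Slow (dendritic) Na inactivation; ``ar`` is the depolarized residual."""
    sinf = ar + (1.0 - ar) / (1.0 + math.exp((v + 58.0) / 2.0))
    alps = math.exp(1e-3 * 12.0 * (v + 60.0) * _FoRT * 1e3)
    bets = math.exp(1e-3 * 12.0 * 0.2 * (v + 60.0) * _FoRT * 1e3)
    staus = bets / (3e-4 * (1.0 + alps)) / qt
    if staus < 10.0:
        staus = 10.0
    return sinf, staus


@njit(cache=True)
def kdr_n(v: float, qt: float):
    alpn = math.exp(1e-3 * (-3.0) * (v - 13.0) * _FoRT * 1e3)
    betn = math.exp(1e-3 * (-3.0) * 0.7 * (v - 13.0) * _FoRT * 1e3)
    ninf = 1.0 / (1.0 + alpn)
    taun = betn / (0.02 * (1.0 + alpn)) / qt
    if taun < 2.0:
        taun = 2.0
    return ninf, taun


@njit(cache=True)
def ka_n(v: float, qt: float, vhalf: float, tq: float):
    zeta = -1.5 + (-1.0) / (1.0 + math.exp((v - tq) / 5.0))
    alpn = math.exp(1e-3 * zeta * (v - vhalf) * _FoRT * 1e3)
    betn = math.exp(1e-3 * zeta * 0.55 * (v - vhalf) * _FoRT * 1e3)
    ninf = 1.0 / (1.0 + alpn)
    taun = betn / (0.05 * (1.0 + alpn)) / qt
    if taun < 0.1:
        taun = 0.1
    return ninf, taun


@njit(cache=True)
def ka_l(v: float, qt: float):
    alpl = math.exp(1e-3 * 3.0 * (v + 56.0) * _FoRT * 1e3)
    linf = 1.0 / (1.0 + alpl)
    taul = 0.26 * (v + 50.0) / qt
    if taul < 2.0:
        taul = 2.0
    return linf, taul


@njit(cache=True)
def hcn_l(v: float, qt: float, vhalf: float):
    linf = 1.0 / (1.0 + math.exp((v - vhalf) / 8.0))
    alpt = math.exp(0.0378 * 2.2 * (v + 75.0))
    bett = math.exp(0.0378 * 2.2 * 0.4 * (v + 75.0))
    taul = bett / (0.011 * (1.0 + alpt)) / qt
    if taul < 2.0:
        taul = 2.0
    return linf, taul


@njit(cache=True)
def cat_m(v: float, qt: float):
    minf = 1.0 / (1.0 + math.exp(-(v + 36.0) / 7.4))
    mtau = (0.5 + 2.0 / (math.exp((v + 36.0) / 20.0)
                         + math.exp(-(v + 36.0) / 20.0))) / qt
    if mtau < 0.5:
        mtau = 0.5
    return minf, mtau


@njit(cache=True)
def cat_h(v: float, qt: float):
    hinf = 1.0 / (1.0 + math.exp((v + 68.0) / 5.0))
    htau = (8.0 + 30.0 / (math.exp((v + 60.0) / 10.0)
                          + math.exp(-(v + 60.0) / 10.0))) / qt
    if htau < 5.0:
        htau = 5.0
    return hinf, htau


@njit(cache=True)
def ghk_mv(v: float, cai: float, cao: float, vt2: float) -> float:
    """Driving-force term (mV) of the conductance-scaled GHK CaT current:
    ``-vt2 * (1 - (cai/cao) exp(v/vt2)) * efun(v/vt2)`` with vt2 = RT/2F.
    """
    z = v / vt2
    if abs(z) < 1e-6:
        ef = 1.0 - z / 2.0
    else:
        ef = z / (math.exp(z) - 1.0)
    return -vt2 * (1.0 - (cai / cao) * math.exp(z)) * ef


_GATE_FUNCS = {
    ("na", "m"): lambda v, ctx: na_m(v, ctx.get("qt", 1.0)),
    ("na", "h"): lambda v, ctx: na_h(v, ctx.get("qt", 1.0)),
    ("na", "s"): lambda v, ctx: na_s(v, ctx.get("qt", 1.0), ctx.get("ar", 0.7)),
    ("kdr", "n"): lambda v, ctx: kdr_n(v, ctx.get("qt", 1.0)),
    ("ka_proximal", "n"): lambda v, ctx: ka_n(v, ctx.get("qt", 1.0), 11.0, -40.0),
    ("ka_distal", "n"): lambda v, ctx: ka_n(v, ctx.get("qt", 1.0), -1.0, -45.0),
    ("ka_proximal", "l"): lambda v, ctx: ka_l(v, ctx.get("qt", 1.0)),
    ("ka_distal", "l"): lambda v, ctx: ka_l(v, ctx.get("qt", 1.0)),
    ("hcn", "l"): lambda v, ctx: hcn_l(v, ctx.get("qt", 1.0),
                                       ctx.get("vhalf", -82.0)),
    ("cat", "m"): lambda v, ctx: cat_m(v, ctx.get("qt", 1.0)),
    ("cat", "h"): lambda v, ctx: cat_h(v, ctx.get("qt", 1.0)),
}


def export_kinetics(path) -> None:
    """Write the channel-kinetics registry (named closed forms plus their
    coefficients, per channel and gate) as JSON."""
    import json

    with open(path, "w") as fh:
        json.dump(CHANNEL_KINETICS, fh, indent=2)


def gate_inf_tau(channel: str, gate: str, v: float, **ctx):
    """Steady-state value and time constant (ms) of one gating variable.

    ``ctx`` supplies context: ``qt`` (temperature factor, defaults to the
    channel's registry value), ``vhalf`` for HCN, ``ar`` for the dendritic
    slow Na inactivation residual.
    """
    key = (channel, gate)
    if key not in _GATE_FUNCS:
        raise ValueError(f"unknown gate {channel}.{gate}")
    ctx.setdefault("qt", q10_factor(channel))
    return _GATE_FUNCS[key](float(v), ctx)
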