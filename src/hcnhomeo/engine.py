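"""Time integration of the full compartmental model.

The branched cable equation is advanced with an implicit (backward-Euler)
step solved by Hines elimination on the tree (compartments ordered so that
``parent[i] < i``), with staggered gating updates: ohmic channel currents
(Na, KDR, KA, HCN, leak) enter the implicit system through their
conductances, while GHK currents (CaT, synaptic AMPA/NMDA) are evaluated
explicitly at the previous voltage — stable at the default 25 us step.
Gating variables relax exactly (exponential Euler) using steady-state /
time-constant values looked up from precomputed voltage tables built from
the closed-form kinetics in :mod:`hcnhomeo.mechanisms`.

Synaptic event trains, the submembrane calcium shells, the calcium-control
weight dynamics and the synaptic-to-HCN coupling co-evolve inside the same
compiled loop, so every run is bit-reproducible for a given model, stimulus
and configuration.

Units: mV, ms, nA, uS, nF, cm^2, mM; conductance densities are converted to
absolute uS per compartment at model build time.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from . import mechanisms as mech
from .mechanisms import (CONSTANTS, E_H, E_K, E_NA, GradientParams,
                         PhysicalConstants, gradient_density,
                         hcn_half_activation, q10_factor)
from .morphology import CompartmentTree
from .plasticity import DEFAULT_PLASTICITY, HCNCoupling, PlasticityParams
from .synapse import SynapseState, gating_norm

__all__ = [
    "SimulationConfig", "SimulationResult", "CellModel",
    "build_model", "run", "detect_spikes", "SimulationError",
]


class SimulationError(RuntimeError):
    """Raised when the integrator diverges; names the compartment and time."""


# ---------------------------------------------------------------------------
# Gate-table construction (single source of truth: mechanisms.* njit scalars)

_VMIN, _VMAX, _DV = -250.0, 100.0, 0.05
_NTAB = int(round((_VMAX - _VMIN) / _DV)) + 1

# table columns: pairs (inf, alpha = 1 - exp(-dt/tau))
(C_NAM_I, C_NAM_A, C_NAH_I, C_NAH_A, C_NAS_I, C_NAS_A, C_KDR_I, C_KDR_A,
 C_KAPN_I, C_KAPN_A, C_KADN_I, C_KADN_A, C_KAL_I, C_KAL_A, C_HCN_A,
 C_CATM_I, C_CATM_A, C_CATH_I, C_CATH_A, C_HCN_I) = range(20)


@njit(cache=True)
def _fill_tables(tab, vmin, dv, dt, qt_na, qt_kdr, qt_ka, qt_hcn, qt_cat):
    for i in range(tab.shape[0]):
        v = vmin + dv * i
        inf, tau = mech.na_m(v, qt_na)
        tab[i, C_NAM_I], tab[i, C_NAM_A] = inf, 1.0 - math.exp(-dt / tau)
        inf, tau = mech.na_h(v, qt_na)
        tab[i, C_NAH_I], tab[i, C_NAH_A] = inf, 1.0 - math.exp(-dt / tau)
        inf, tau = mech.na_s(v, qt_na, 0.0)  # ar-independent base and tau
        tab[i, C_NAS_I], tab[i, C_NAS_A] = inf, 1.0 - math.exp(-dt / tau)
        inf, tau = mech.kdr_n(v, qt_kdr)
        tab[i, C_KDR_I], tab[i, C_KDR_A] = inf, 1.0 - math.exp(-dt / tau)
        inf, tau = mech.ka_n(v, qt_ka, 11.0, -40.0)
        tab[i, C_KAPN_I], tab[i, C_KAPN_A] = inf, 1.0 - math.exp(-dt / tau)
        inf, tau = mech.ka_n(v, qt_ka, -1.0, -45.0)
        tab[i, C_KADN_I], tab[i, C_KADN_A] = inf, 1.0 - math.exp(-dt / tau)
        inf, tau = mech.ka_l(v, qt_ka)
        tab[i, C_KAL_I], tab[i, C_KAL_A] = inf, 1.0 - math.exp(-dt / tau)
        inf, tau = mech.hcn_l(v, qt_hcn, -82.0)
        tab[i, C_HCN_A] = 1.0 - math.exp(-dt / tau)
        # HCN steady state indexed by (v - vhalf) on the same grid
        tab[i, C_HCN_I] = 1.0 / (1.0 + math.exp(v / 8.0))
        inf, tau = mech.cat_m(v, qt_cat)
        tab[i, C_CATM_I], tab[i, C_CATM_A] = inf, 1.0 - math.exp(-dt / tau)
        inf, tau = mech.cat_h(v, qt_cat)
        tab[i, C_CATH_I], tab[i, C_CATH_A] = inf, 1.0 - math.exp(-dt / tau)


_TABLE_CACHE: dict = {}


def _gate_tables(dt: float, celsius: float) -> np.ndarray:
    key = (round(dt, 9), round(celsius, 3))
    if key not in _TABLE_CACHE:
        tab = np.empty((_NTAB, 20))
        _fill_tables(tab, _VMIN, _DV, dt,
                     q10_factor("na", celsius), q10_factor("kdr", celsius),
                     q10_factor("ka_proximal", celsius),
                     q10_factor("hcn", celsius), q10_factor("cat", celsius))
        _TABLE_CACHE[key] = tab
    return _TABLE_CACHE[key]


# ---------------------------------------------------------------------------
# Model assembly

@dataclass
class CellModel:
    """Solver-ready cell: flat parameter arrays plus live synapse states."""

    tree: CompartmentTree
    parent: np.ndarray
    g_ax: np.ndarray       # uS, coupling to parent (0 at root)
    cap: np.ndarray        # nF
    g_leak: np.ndarray     # uS
    e_leak: np.ndarray     # mV (leak-balanced at v_rest)
    gna: np.ndarray        # uS
    gkdr: np.ndarray       # uS
    gka: np.ndarray        # uS
    ka_prox: np.ndarray    # bool
    gh: np.ndarray         # uS (current values, include accumulated scaling)
    hcn_vhalf: np.ndarray  # mV
    gcat: np.ndarray       # S/cm^2 (density; GHK driving force)
    area: np.ndarray       # cm^2
    ar: np.ndarray         # dendritic slow-Na residual (1 = gate disabled)
    x: np.ndarray          # um
    synapses: list[SynapseState] = field(default_factory=list)
    constants: PhysicalConstants = CONSTANTS
    gradients: GradientParams = field(default_factory=GradientParams)
    plasticity: PlasticityParams = DEFAULT_PLASTICITY
    v_rest: float = -65.0
    gh_scale: float = 1.0  # cumulative HCN scaling applied so far

    @property
    def n(self) -> int:
        return len(self.parent)

    @property
    def soma_index(self) -> int:
        return 0

    def copy(self) -> "CellModel":
        import copy as _copy
        m = replace(self)
        for name in ("g_ax", "cap", "g_leak", "e_leak", "gna", "gkdr", "gka",
                     "ka_prox", "gh", "hcn_vhalf", "gcat", "area", "ar", "x",
                     "parent"):
            setattr(m, name, getattr(self, name).copy())
        m.synapses = _copy.deepcopy(self.synapses)
        return m

    def scale_gh(self, factor: float) -> None:
        """Rescale the whole h-conductance gradient (somatic value and all)."""
        self.gh *= factor
        self.gh_scale *= factor

    def scale_synapses(self, factor: float) -> None:
        """Multiply every synapse's AMPA permeability (NMDA follows via NAR)."""
        for s in self.synapses:
            s.params = replace(s.params, P_ampa=s.params.P_ampa * factor)

    def comp_of_synapse(self) -> np.ndarray:
        return np.array([s.compartment for s in self.synapses], dtype=np.int64)


def _axial_conductance(tree: CompartmentTree) -> np.ndarray:
    """Axial conductance (uS) between each compartment's center and its
    parent's center: series half-cylinder resistances."""
    g = np.zeros(tree.n)
    for i in range(1, tree.n):
        p = tree.parent[i]
        r_i = (tree.Ra[i] * (tree.length[i] * 1e-4 / 2.0)
               / (math.pi * (tree.diam[i] * 1e-4 / 2.0) ** 2))
        r_p = (tree.Ra[p] * (tree.length[p] * 1e-4 / 2.0)
               / (math.pi * (tree.diam[p] * 1e-4 / 2.0) ** 2))
        g[i] = 1e6 / (r_i + r_p)  # Ohm -> uS
    return g


def build_model(tree: CompartmentTree,
                gradients: GradientParams | None = None,
                constants: PhysicalConstants = CONSTANTS,
                synapses: list[SynapseState] | None = None,
                v_rest: float = -65.0,
                active: bool = True,
                ais_sections: np.ndarray | None = None,
                dendritic_ar: float | None = None,
                balance_leak: bool = False) -> CellModel:
    """Assemble a :class:`CellModel` from a compartment tree.

    Channel densities follow the somato-apical gradients on the apical
    arbor; soma and basal dendrites carry somatic (x = 0) values; the axon is
    passive except the initial segment (``region == 'ais'``), which carries
    the somatic Na density times the AIS multiplier (plus somatic KDR for
    repolarization).  With ``balance_leak`` the leak reversal is set per
    compartment so the cell rests exactly at ``v_rest``.
    """
    g = gradients or GradientParams()
    n = tree.n
    region = tree.region
    apical = region == "apical"
    soma = region == "soma"
    basal = region == "basal"
    ais = region == "ais"
    axon = region == "axon"
    x_eff = np.where(apical, tree.x, 0.0)   # somatic values off the apical axis

    area = tree.area
    cap = tree.Cm * area * 1e3              # uF -> nF
    g_leak = area / tree.Rm * 1e3           # mS -> uS

    gna = np.zeros(n)
    gkdr = np.zeros(n)
    gka = np.zeros(n)
    gh = np.zeros(n)
    gcat = np.zeros(n)
    if active:
        dend_mask = soma | apical | basal
        gna[dend_mask] = g.gNa
        gna[ais] = g.gNa * g.ais_na_mult
        gkdr[dend_mask] = g.gKDR
        gkdr[ais] = g.gKDR
        gka[dend_mask] = gradient_density("KA", x_eff[dend_mask], g)
        gh_dens = np.zeros(n)
        gh_dens[dend_mask] = gradient_density("HCN", x_eff[dend_mask], g)
        gcat_dens = np.zeros(n)
        gcat_dens[dend_mask] = gradient_density("CaT", x_eff[dend_mask], g)
        gh = gh_dens * area                  # uS/cm^2 * cm^2 = uS
        gcat = gcat_dens * 1e-6              # uS/cm^2 -> S/cm^2
    gna = gna * area * 1e3                   # mS -> uS
    gkdr = gkdr * area * 1e3
    gka = gka * area * 1e3

    ka_prox = np.array([mech.ka_model_select(x) == "proximal" for x in x_eff])
    hcn_vhalf = np.where(apical, hcn_half_activation(tree.x), -82.0)

    if dendritic_ar is None:
        dendritic_ar = mech.CHANNEL_KINETICS["na"]["s"]["ar_dend"]
    ar = np.where(apical | basal, dendritic_ar, 1.0)

    model = CellModel(
        tree=tree, parent=tree.parent.astype(np.int64),
        g_ax=_axial_conductance(tree), cap=cap, g_leak=g_leak,
        e_leak=np.full(n, v_rest), gna=gna, gkdr=gkdr, gka=gka,
        ka_prox=ka_prox, gh=gh, hcn_vhalf=hcn_vhalf, gcat=gcat,
        area=area, ar=ar, x=tree.x.copy(), synapses=synapses or [],
        constants=constants, gradients=g, v_rest=v_rest,
    )
    if balance_leak and active:
        model.e_leak = _balanced_leak(model)
    return model


def _steady_gates(model: CellModel, v: float) -> np.ndarray:
    """Gate steady states at a uniform holding voltage."""
    G = np.empty((model.n, 9))
    cel = model.constants.celsius
    for i in range(model.n):
        G[i, 0] = mech.na_m(v, 1.0)[0]
        G[i, 1] = mech.na_h(v, 1.0)[0]
        base = mech.na_s(v, 1.0, 0.0)[0]
        G[i, 2] = model.ar[i] + (1.0 - model.ar[i]) * base
        G[i, 3] = mech.kdr_n(v, 1.0)[0]
        if model.ka_prox[i]:
            G[i, 4] = mech.ka_n(v, 1.0, 11.0, -40.0)[0]
        else:
            G[i, 4] = mech.ka_n(v, 1.0, -1.0, -45.0)[0]
        G[i, 5] = mech.ka_l(v, 1.0)[0]
        G[i, 6] = mech.hcn_l(v, 1.0, model.hcn_vhalf[i])[0]
        G[i, 7] = mech.cat_m(v, 1.0)[0]
        G[i, 8] = mech.cat_h(v, 1.0)[0]
    return G


def _balanced_leak(model: CellModel) -> np.ndarray:
    """Leak reversal per compartment cancelling active currents at rest."""
    v = model.v_rest
    G = _steady_gates(model, v)
    c = model.constants
    e = np.empty(model.n)
    for i in range(model.n):
        g_na = model.gna[i] * G[i, 0] ** 3 * G[i, 1] * G[i, 2]
        g_kdr = model.gkdr[i] * G[i, 3]
        g_ka = model.gka[i] * G[i, 4] * G[i, 5]
        g_h = model.gh[i] * G[i, 6]
        i_active = (g_na * (v - E_NA) + (g_kdr + g_ka) * (v - E_K)
                    + g_h * (v - E_H))
        i_cat = (model.gcat[i] * G[i, 7] ** 2 * G[i, 8]
                 * mech.ghk_mv(v, c.Ca_i, c.Ca_o, c.vt / 2.0)
                 * model.area[i] * 1e6)
        e[i] = v + (i_active + i_cat) / model.g_leak[i]
    return e


# ---------------------------------------------------------------------------
# Simulation configuration and results

@dataclass(frozen=True)
class SimulationConfig:
    """Run control.

    ``duration`` (ms) excludes the ``settle`` equilibration window that
    precedes every protocol at the holding potential; recordings, spike
    times and stimulus times are all relative to the end of settling.
    """

    duration: float
    dt: float = 0.025                 # ms
    v_init: float = -65.0             # mV
    settle: float = 200.0             # ms
    seed: int | None = None           # metadata only; generators own RNG
    record: tuple = (0,)              # compartment indices to record
    rec_every: int = 4                # record every rec_every * dt
    w_rec_every_ms: float = 100.0
    spike_threshold: float = -20.0    # mV upward crossing
    refractory: float = 2.0           # ms
    hold: bool = True                 # maintain v_init as the pre-stimulus
                                      # potential via a somatic holding bias
    plasticity: bool = False
    coupling: HCNCoupling | None = None
    record_ca_synapse: int = -1       # synapse index, -1 = off
    weight_stride: int = 10           # weight-update cadence in steps

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be > 0")


@dataclass
class SimulationResult:
    """Recorded traces and final state of one run."""

    t: np.ndarray                 # ms, shared time base
    v: np.ndarray                 # (ntime, nrec) mV
    record: tuple
    spike_times: np.ndarray       # ms, soma
    w_t: np.ndarray               # ms
    w: np.ndarray                 # (ntime_w, nsyn)
    gh_scale_t: np.ndarray        # ms, coupling-update times
    gh_scale: np.ndarray          # cumulative h-conductance scale factor
    ca: np.ndarray | None         # mM trace of the requested synapse shell
    final_w: np.ndarray
    final_gh_scale: float
    meta: dict = field(default_factory=dict)

    def voltage(self, comp: int = 0) -> np.ndarray:
        return self.v[:, self.record.index(comp)]

    @property
    def spike_count(self) -> int:
        return len(self.spike_times)


def detect_spikes(v: np.ndarray, dt: float, threshold: float = -20.0,
                  refractory: float = 2.0) -> np.ndarray:
    """Spike times (ms) as upward threshold crossings separated by at least
    the refractory period, on a uniformly sampled trace."""
    v = np.asarray(v, dtype=float)
    cross = np.flatnonzero((v[:-1] < threshold) & (v[1:] >= threshold)) + 1
    times = []
    last = -np.inf
    for i in cross:
        t = i * dt
        if t - last >= refractory:
            times.append(t)
            last = t
    return np.array(times)


# ---------------------------------------------------------------------------
# The compiled integration kernel

@njit(cache=True)
def _ghk_u(u: float, ci: float, co: float) -> float:
    """u * (ci - co e^{-u}) / (1 - e^{-u}), continuous at u = 0."""
    if abs(u) < 1e-6:
        return (ci - co) + u * (ci + co) / 2.0
    return u * (ci - co * math.exp(-u)) / (1.0 - math.exp(-u))


@njit(cache=True)
def _kernel(parent, g_ax, cap, g_leak, e_leak, gna, gkdr, gka, ka_prox,
            gh, hcn_vhalf, gcat, area, ar,
            G, tab, const,
            syn_comp, syn_pampa, syn_pnmda, syn_w, syn_plastic, syn_nmda,
            syn_ca, rstate, dec, comp2syn,
            ev_step, ev_syn,
            plast, plasticity_on, w_stride,
            coupled, slope, dw_mult, nup, g_floor_scale,
            i_inj, inj_comp, hold,
            nsteps, settle, v_init, thresh, refr_steps,
            rec_comps, rec_every, v_out, w_out, w_every,
            gh_t_out, gh_out, ca_syn_idx, ca_out, spikes, err):
    n = parent.shape[0]
    m = syn_comp.shape[0]
    dt = const[0]
    vt = const[1]
    F = const[2]
    nai, nao, ki, ko, cao, mgo = const[3], const[4], const[5], const[6], const[7], const[8]
    e_na, e_k, e_h = const[9], const[10], const[11]
    vt2 = const[12]
    tau_ca, ca_inf, shell_fac = const[13], const[14], const[15]
    a_ampa, a_nmda = const[16], const[17]
    ca_decay = math.exp(-dt / tau_ca)

    P1, P2, P3, P4 = plast[0], plast[1], plast[2], plast[3]
    al1, al2, be1, be2, winit = plast[4], plast[5], plast[6], plast[7], plast[8]
    dt_w_s = w_stride * dt * 1e-3

    inv_dv = 1.0 / _DV

    v = np.full(n, v_init)
    diag = np.empty(n)
    rhs = np.empty(n)
    i_syn = np.zeros(n)       # nA, outward positive (explicit divalent part)
    g_syn = np.zeros(n)       # uS, chord conductance of monovalent GHK part
    i_cat_dens = np.zeros(n)  # mA/cm^2
    i_nmda_ca = np.zeros(m)   # mA/cm^2
    # zero crossing of the combined monovalent (Na+K) GHK flux
    e_syn = vt * math.log((nao + ko) / (nai + ki))

    gh_scale = 1.0
    wsum_ref = 0.0
    nplast = 0
    for s in range(m):
        if syn_plastic[s]:
            wsum_ref += syn_w[s]
            nplast += 1
    upd_idx = 0
    if coupled == 1 and upd_idx < gh_out.shape[0]:
        gh_t_out[upd_idx] = -settle * dt
        gh_out[upd_idx] = gh_scale
        upd_idx += 1

    ev_ptr = 0
    nspk = 0
    last_spk_step = -10 ** 9
    v_prev0 = v_init
    v_row = 0
    w_row = 0
    status = 0

    # somatic holding: voltage clamp at v_init during settle, then a constant
    # bias current equal to the steady clamp current (experimental bridge)
    g_clamp = 1.0e5                     # uS; >> any membrane conductance
    bias = 0.0
    bias_acc = 0.0
    bias_n = 0
    bias_from = (3 * settle) // 4

    for k in range(nsteps):
        # --- record state at the start of the step
        if k >= settle and (k - settle) % rec_every == 0 and v_row < v_out.shape[0]:
            for j in range(rec_comps.shape[0]):
                v_out[v_row, j] = v[rec_comps[j]]
            if ca_syn_idx >= 0:
                ca_out[v_row] = syn_ca[ca_syn_idx]
            v_row += 1
        if k >= settle and (k - settle) % w_every == 0 and w_row < w_out.shape[0]:
            for s in range(m):
                w_out[w_row, s] = syn_w[s]
            w_row += 1

        # --- presynaptic events arriving this step
        while ev_ptr < ev_step.shape[0] and ev_step[ev_ptr] == k:
            s = ev_syn[ev_ptr]
            rstate[s, 0] += 1.0
            rstate[s, 1] += 1.0
            if syn_nmda[s]:
                rstate[s, 2] += 1.0
                rstate[s, 3] += 1.0
            ev_ptr += 1

        # --- synaptic currents at the previous voltage; the monovalent GHK
        #     part enters the implicit system through its chord conductance
        for i in range(n):
            i_syn[i] = 0.0
            g_syn[i] = 0.0
        for s in range(m):
            rstate[s, 0] *= dec[0]
            rstate[s, 1] *= dec[1]
            rstate[s, 2] *= dec[2]
            rstate[s, 3] *= dec[3]
            i_nmda_ca[s] = 0.0
            ic = syn_comp[s]
            vc = v[ic]
            u = vc / vt
            f_na = _ghk_u(u, nai, nao)
            f_k = _ghk_u(u, ki, ko)
            s_a = a_ampa * (rstate[s, 1] - rstate[s, 0])
            mono = 1e-3 * F * syn_pampa[s] * syn_w[s] * s_a * (f_na + f_k)
            if syn_nmda[s]:
                s_n = a_nmda * (rstate[s, 3] - rstate[s, 2])
                mgb = 1.0 / (1.0 + (mgo / 3.57) * math.exp(-0.062 * vc))
                pn = syn_pnmda[s] * s_n * mgb
                mono += 1e-3 * F * pn * (f_na + f_k)
                u2 = 2.0 * vc / vt
                ica = 1e-3 * pn * 10.6 * 2.0 * F * _ghk_u(u2, syn_ca[s], cao)
                i_syn[ic] += ica * area[ic] * 1e6
                i_nmda_ca[s] = ica
            dv = vc - e_syn
            if dv > -0.5 and dv < 0.5:
                dv = 0.5 if dv >= 0.0 else -0.5
            g_syn[ic] += mono * area[ic] * 1e6 / dv

        # --- gating update (exponential Euler from tables) and implicit
        #     conductances; assemble diagonal and rhs
        for i in range(n):
            vi = v[i]
            fidx = (vi - _VMIN) * inv_dv
            if fidx < 0.0:
                fidx = 0.0
            elif fidx > _NTAB - 2:
                fidx = float(_NTAB - 2)
            i0 = int(fidx)
            fr = fidx - i0

            nam_i = tab[i0, C_NAM_I] + fr * (tab[i0 + 1, C_NAM_I] - tab[i0, C_NAM_I])
            nam_a = tab[i0, C_NAM_A] + fr * (tab[i0 + 1, C_NAM_A] - tab[i0, C_NAM_A])
            nah_i = tab[i0, C_NAH_I] + fr * (tab[i0 + 1, C_NAH_I] - tab[i0, C_NAH_I])
            nah_a = tab[i0, C_NAH_A] + fr * (tab[i0 + 1, C_NAH_A] - tab[i0, C_NAH_A])
            nas_b = tab[i0, C_NAS_I] + fr * (tab[i0 + 1, C_NAS_I] - tab[i0, C_NAS_I])
            nas_a = tab[i0, C_NAS_A] + fr * (tab[i0 + 1, C_NAS_A] - tab[i0, C_NAS_A])
            kdr_i = tab[i0, C_KDR_I] + fr * (tab[i0 + 1, C_KDR_I] - tab[i0, C_KDR_I])
            kdr_a = tab[i0, C_KDR_A] + fr * (tab[i0 + 1, C_KDR_A] - tab[i0, C_KDR_A])
            if ka_prox[i]:
                kan_i = tab[i0, C_KAPN_I] + fr * (tab[i0 + 1, C_KAPN_I] - tab[i0, C_KAPN_I])
                kan_a = tab[i0, C_KAPN_A] + fr * (tab[i0 + 1, C_KAPN_A] - tab[i0, C_KAPN_A])
            else:
                kan_i = tab[i0, C_KADN_I] + fr * (tab[i0 + 1, C_KADN_I] - tab[i0, C_KADN_I])
                kan_a = tab[i0, C_KADN_A] + fr * (tab[i0 + 1, C_KADN_A] - tab[i0, C_KADN_A])
            kal_i = tab[i0, C_KAL_I] + fr * (tab[i0 + 1, C_KAL_I] - tab[i0, C_KAL_I])
            kal_a = tab[i0, C_KAL_A] + fr * (tab[i0 + 1, C_KAL_A] - tab[i0, C_KAL_A])
            hcn_a = tab[i0, C_HCN_A] + fr * (tab[i0 + 1, C_HCN_A] - tab[i0, C_HCN_A])
            catm_i = tab[i0, C_CATM_I] + fr * (tab[i0 + 1, C_CATM_I] - tab[i0, C_CATM_I])
            catm_a = tab[i0, C_CATM_A] + fr * (tab[i0 + 1, C_CATM_A] - tab[i0, C_CATM_A])
            cath_i = tab[i0, C_CATH_I] + fr * (tab[i0 + 1, C_CATH_I] - tab[i0, C_CATH_I])
            cath_a = tab[i0, C_CATH_A] + fr * (tab[i0 + 1, C_CATH_A] - tab[i0, C_CATH_A])

            # HCN steady state at shifted voltage
            us = vi - hcn_vhalf[i]
            sidx = (us - _VMIN) * inv_dv
            if sidx < 0.0:
                sidx = 0.0
            elif sidx > _NTAB - 2:
                sidx = float(_NTAB - 2)
            s0 = int(sidx)
            sfr = sidx - s0
            hcn_i = tab[s0, C_HCN_I] + sfr * (tab[s0 + 1, C_HCN_I] - tab[s0, C_HCN_I])

            G[i, 0] += (nam_i - G[i, 0]) * nam_a
            G[i, 1] += (nah_i - G[i, 1]) * nah_a
            sinf = ar[i] + (1.0 - ar[i]) * nas_b
            G[i, 2] += (sinf - G[i, 2]) * nas_a
            G[i, 3] += (kdr_i - G[i, 3]) * kdr_a
            G[i, 4] += (kan_i - G[i, 4]) * kan_a
            G[i, 5] += (kal_i - G[i, 5]) * kal_a
            G[i, 6] += (hcn_i - G[i, 6]) * hcn_a
            G[i, 7] += (catm_i - G[i, 7]) * catm_a
            G[i, 8] += (cath_i - G[i, 8]) * cath_a

            # CaT (GHK, explicit): use the local shell [Ca] if present
            cai = ca_inf
            si = comp2syn[i]
            if si >= 0 and syn_plastic[si]:
                cai = syn_ca[si]
            z2 = vi / vt2
            if abs(z2) < 1e-6:
                ef = 1.0 - z2 / 2.0
            else:
                ef = z2 / (math.exp(z2) - 1.0)
            ghkv = -vt2 * (1.0 - (cai / cao) * math.exp(z2)) * ef
            i_cat_dens[i] = gcat[i] * G[i, 7] * G[i, 7] * G[i, 8] * ghkv

            g_na_eff = gna[i] * G[i, 0] ** 3 * G[i, 1] * G[i, 2]
            g_kdr_eff = gkdr[i] * G[i, 3]
            g_ka_eff = gka[i] * G[i, 4] * G[i, 5]
            g_h_eff = gh[i] * G[i, 6]

            diag[i] = (cap[i] / dt + g_leak[i] + g_na_eff + g_kdr_eff
                       + g_ka_eff + g_h_eff + g_syn[i] + g_ax[i])
            rhs[i] = (cap[i] / dt * vi + g_leak[i] * e_leak[i]
                      + g_na_eff * e_na + (g_kdr_eff + g_ka_eff) * e_k
                      + g_h_eff * e_h + g_syn[i] * e_syn
                      - i_cat_dens[i] * area[i] * 1e6 - i_syn[i])
            if i == inj_comp:
                rhs[i] += i_inj[k]
            if hold == 1 and i == 0:
                if k < settle:
                    diag[i] += g_clamp
                    rhs[i] += g_clamp * v_init
                else:
                    rhs[i] += bias

        # child axial contributions to parents
        for i in range(1, n):
            diag[parent[i]] += g_ax[i]

        # --- Hines elimination (children before parents) and back-solve
        for i in range(n - 1, 0, -1):
            p = parent[i]
            f = g_ax[i] / diag[i]
            diag[p] -= f * g_ax[i]
            rhs[p] += f * rhs[i]
        v[0] = rhs[0] / diag[0]
        for i in range(1, n):
            v[i] = (rhs[i] + g_ax[i] * v[parent[i]]) / diag[i]

        if hold == 1 and k < settle:
            if k >= bias_from:
                bias_acc += g_clamp * (v_init - v[0])
                bias_n += 1
            if k == settle - 1 and bias_n > 0:
                bias = bias_acc / bias_n

        if not math.isfinite(v[0]) or abs(v[0]) > 500.0:
            bad = 0
            for i in range(n):
                if not math.isfinite(v[i]) or abs(v[i]) > 500.0:
                    bad = i
                    break
            err[0] = float(bad)
            err[1] = (k - settle) * dt
            status = 1
            break

        # --- calcium shells and weights
        for s in range(m):
            if syn_plastic[s]:
                influx = -shell_fac * (i_nmda_ca[s] + i_cat_dens[syn_comp[s]])
                target = ca_inf + tau_ca * influx
                can = target + (syn_ca[s] - target) * ca_decay
                if can < 0.0:
                    can = 0.0
                syn_ca[s] = can
        if plasticity_on == 1 and (k % w_stride) == 0:
            for s in range(m):
                if syn_plastic[s]:
                    ca_um = syn_ca[s] * 1e3
                    om = (winit
                          + 1.0 / (1.0 + math.exp(-be2 * (ca_um - al2)))
                          - winit / (1.0 + math.exp(-be1 * (ca_um - al1))))
                    tau_s = P1 + P2 / (P3 + ca_um ** P4)
                    syn_w[s] += (om - syn_w[s]) * (1.0 - math.exp(-dt_w_s / tau_s))

        # --- HCN coupling
        if coupled == 1 and nup > 0 and (k + 1) % nup == 0:
            wsum = 0.0
            for s in range(m):
                if syn_plastic[s]:
                    wsum += syn_w[s]
            if wsum_ref > 0.0:
                dw = (wsum - wsum_ref) / wsum_ref * dw_mult
                fac = 1.0 + dw * slope
                if gh_scale * fac < g_floor_scale:
                    fac = g_floor_scale / gh_scale
                if fac != 1.0:
                    for i in range(n):
                        gh[i] *= fac
                    gh_scale *= fac
            wsum_ref = wsum
            if upd_idx < gh_out.shape[0]:
                gh_t_out[upd_idx] = (k + 1 - settle) * dt
                gh_out[upd_idx] = gh_scale
                upd_idx += 1

        # --- soma spike detection: upward crossing + refractory
        if v[0] >= thresh and v_prev0 < thresh:
            if k - last_spk_step >= refr_steps:
                if k >= settle and nspk < spikes.shape[0]:
                    spikes[nspk] = (k + 1 - settle) * dt
                    nspk += 1
                last_spk_step = k
        v_prev0 = v[0]

    return status, nspk, upd_idx, gh_scale, bias


# ---------------------------------------------------------------------------
# Python driver

def run(model: CellModel, events: list | None, cfg: SimulationConfig,
        i_inj: np.ndarray | None = None, inj_comp: int = 0,
        update_model: bool = False) -> SimulationResult:
    """Integrate the model under the given stimulation.

    ``events`` is a list of per-synapse presynaptic event-time arrays (ms,
    relative to the end of settling; one entry per synapse in
    ``model.synapses``).  ``i_inj`` is an optional somatic current waveform
    (nA) sampled at ``cfg.dt`` over the protocol window.  With
    ``update_model`` the final weights and HCN scaling are written back into
    ``model`` (used by plasticity-induction protocols); otherwise the model
    is untouched and the run is side-effect free.
    """
    c = model.constants
    dt = cfg.dt
    settle_steps = int(round(cfg.settle / dt))
    proto_steps = int(round(cfg.duration / dt))
    nsteps = settle_steps + proto_steps
    m = len(model.synapses)

    if events is None:
        events = [np.empty(0) for _ in range(m)]
    if len(events) != m:
        raise ValueError("events list length must match the synapse count")

    ev_pairs = []
    for s, tlist in enumerate(events):
        for t in np.asarray(tlist, dtype=float):
            if 0.0 <= t < cfg.duration:
                ev_pairs.append((settle_steps + int(round(t / dt)), s))
    if ev_pairs:
        ev_pairs.sort()
        ev_step = np.array([p[0] for p in ev_pairs], dtype=np.int64)
        ev_syn = np.array([p[1] for p in ev_pairs], dtype=np.int64)
    else:
        ev_step = np.empty(0, dtype=np.int64)
        ev_syn = np.empty(0, dtype=np.int64)

    inj = np.zeros(nsteps)
    if i_inj is not None:
        wave = np.asarray(i_inj, dtype=float)
        k = min(len(wave), proto_steps)
        inj[settle_steps:settle_steps + k] = wave[:k]

    # synapse arrays
    syn_comp = model.comp_of_synapse() if m else np.empty(0, dtype=np.int64)
    syn_pampa = np.array([s.params.P_ampa for s in model.synapses])
    syn_pnmda = np.array([s.params.P_nmda for s in model.synapses])
    syn_w = np.array([s.w for s in model.synapses])
    syn_plastic = np.array([s.plastic for s in model.synapses], dtype=np.bool_)
    syn_nmda = np.array([s.has_nmda for s in model.synapses], dtype=np.bool_)
    syn_ca = np.array([s.shell.ca for s in model.synapses])
    comp2syn = np.full(model.n, -1, dtype=np.int64)
    for s in range(m):
        comp2syn[syn_comp[s]] = s
    rstate = np.zeros((m, 4))
    if m:
        p0 = model.synapses[0].params
        taus = (p0.tau_r_ampa, p0.tau_d_ampa, p0.tau_r_nmda, p0.tau_d_nmda)
        a_ampa = gating_norm(p0.tau_r_ampa, p0.tau_d_ampa)
        a_nmda = gating_norm(p0.tau_r_nmda, p0.tau_d_nmda)
    else:
        taus = (2.0, 10.0, 5.0, 50.0)
        a_ampa = a_nmda = 1.0
    dec = np.array([math.exp(-dt / tc) for tc in taus])

    if m:
        sh = model.synapses[0].shell
        shell_fac = sh.free_fraction * 10000.0 / (3.6 * sh.dpt * c.F)
    else:
        shell_fac = 10000.0 / (3.6 * 0.1 * c.F)
    const = np.array([
        dt, c.vt, c.F, c.Na_i, c.Na_o, c.K_i, c.K_o, c.Ca_o, c.Mg_o,
        E_NA, E_K, E_H, c.vt / 2.0,
        model.synapses[0].shell.tau_ca if m else 30.0,
        model.synapses[0].shell.ca_inf if m else 1e-4,
        shell_fac, a_ampa, a_nmda,
    ])
    pp = model.plasticity
    plast = np.array([pp.P1, pp.P2, pp.P3, pp.P4, pp.alpha1, pp.alpha2,
                      pp.beta1, pp.beta2, pp.w_init])

    coupling = cfg.coupling
    coupled = 1 if coupling is not None else 0
    slope = coupling.slope if coupling else 0.0
    dw_mult = coupling.dw_multiplier if coupling else 1.0
    nup = int(round(coupling.dt_update / dt)) if coupling else 0
    g_floor = coupling.g_floor_scale if coupling else 1e-3
    n_updates = (nsteps // nup + 2) if nup else 1
    gh_t_out = np.zeros(n_updates)
    gh_out = np.ones(n_updates)

    rec_comps = np.array(cfg.record, dtype=np.int64)
    n_rows = (proto_steps + cfg.rec_every - 1) // cfg.rec_every
    v_out = np.zeros((n_rows, len(rec_comps)))
    w_every = max(1, int(round(cfg.w_rec_every_ms / dt)))
    w_rows = (proto_steps + w_every - 1) // w_every
    w_out = np.zeros((w_rows, m))
    ca_out = np.zeros(n_rows if cfg.record_ca_synapse >= 0 else 1)
    spikes = np.zeros(200000)
    err = np.zeros(2)

    gh_arr = model.gh.copy()
    G = _steady_gates(model, cfg.v_init)

    status, nspk, upd_n, gh_scale, hold_bias = _kernel(
        model.parent, model.g_ax, model.cap, model.g_leak, model.e_leak,
        model.gna, model.gkdr, model.gka, model.ka_prox,
        gh_arr, model.hcn_vhalf, model.gcat, model.area, model.ar,
        G, _gate_tables(dt, c.celsius), const,
        syn_comp, syn_pampa, syn_pnmda, syn_w, syn_plastic, syn_nmda,
        syn_ca, rstate, dec, comp2syn, ev_step, ev_syn,
        plast, 1 if cfg.plasticity else 0, int(cfg.weight_stride),
        coupled, slope, dw_mult, nup, g_floor,
        inj, int(inj_comp), 1 if cfg.hold else 0,
        nsteps, settle_steps, cfg.v_init,
        cfg.spike_threshold, int(round(cfg.refractory / dt)),
        rec_comps, int(cfg.rec_every), v_out, w_out, w_every,
        gh_t_out, gh_out,
        int(cfg.record_ca_synapse), ca_out, spikes, err)

    if status == 1:
        raise SimulationError(
            f"integration diverged at compartment {int(err[0])}, "
            f"t = {err[1]:.3f} ms")

    t = np.arange(n_rows) * dt * cfg.rec_every
    w_t = np.arange(w_rows) * dt * w_every
    meta = {"seed": cfg.seed, "config_hash": _config_hash(cfg, model),
            "hold_bias_nA": float(hold_bias)}
    result = SimulationResult(
        t=t, v=v_out, record=tuple(cfg.record),
        spike_times=spikes[:nspk].copy(),
        w_t=w_t, w=w_out,
        gh_scale_t=gh_t_out[:upd_n].copy(), gh_scale=gh_out[:upd_n].copy(),
        ca=ca_out.copy() if cfg.record_ca_synapse >= 0 else None,
        final_w=syn_w.copy(), final_gh_scale=gh_scale, meta=meta)

    if update_model:
        for s, syn in enumerate(model.synapses):
            syn.w = float(syn_w[s])
            syn.shell.ca = float(syn_ca[s])
        model.gh = gh_arr
        model.gh_scale *= gh_scale
    return result


def _config_hash(cfg: SimulationConfig, model: CellModel) -> str:
    payload = json.dumps({
        "dt": cfg.dt, "duration": cfg.duration, "v_init": cfg.v_init,
        "settle": cfg.settle, "n": model.n, "nsyn": len(model.synapses),
        "plasticity": cfg.plasticity,
        "slope": cfg.coupling.slope if cfg.coupling else None,
    }, sort_keys=True)
    return hashlib.sha1(payload.encode()).hexdigest()[:12]
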