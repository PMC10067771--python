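"""Independent reference computations used by the acceptance checks."""

import math

import numpy as np
from scipy.integrate import solve_ivp

from hcnhomeo import mechanisms as mech
from hcnhomeo.engine import detect_spikes


def reference_single_comp_spikes(model, amp_nA, duration_ms):
    """Spike times of the one-compartment Na+KDR cell by adaptive
    high-accuracy ODE integration (independent of the fixed-step engine)."""
    gna, gkdr = model.gna[0], model.gkdr[0]
    gl, el = model.g_leak[0], model.e_leak[0]
    cap = model.cap[0]
    qna = mech.q10_factor("na")
    qk = mech.q10_factor("kdr")

    def rhs(t, y):
        v, m, h, n = y
        minf, mtau = mech.na_m(v, qna)
        hinf, htau = mech.na_h(v, qna)
        ninf, ntau = mech.kdr_n(v, qk)
        ina = gna * m ** 3 * h * (v - mech.E_NA)
        ik = gkdr * n * (v - mech.E_K)
        il = gl * (v - el)
        return [(-ina - ik - il + amp_nA) / cap,
                (minf - m) / mtau, (hinf - h) / htau, (ninf - n) / ntau]

    v0 = model.v_rest
    y0 = [v0, mech.na_m(v0, qna)[0], mech.na_h(v0, qna)[0],
          mech.kdr_n(v0, qk)[0]]
    sol = solve_ivp(rhs, (0.0, duration_ms), y0,
                    t_eval=np.arange(0.0, duration_ms, 0.05),
                    rtol=1e-8, atol=1e-8, method="LSODA")
    return detect_spikes(sol.y[0], 0.05)


def sealed_cable_input_resistance_mohm(d_um, L_um, l_soma_um, rm_kohm_cm2,
                                       ra_ohm_cm):
    """Analytic steady-state input resistance (MOhm) at a point near one
    sealed end of a uniform finite cable."""
    lam_cm = math.sqrt((rm_kohm_cm2 * 1e3 / ra_ohm_cm) * (d_um * 1e-4 / 4.0))
    r_inf = ra_ohm_cm * lam_cm / (math.pi * (d_um * 1e-4 / 2.0) ** 2)
    x0 = l_soma_um / 2.0
    l1 = (x0 * 1e-4) / lam_cm
    l2 = ((L_um + l_soma_um - x0) * 1e-4) / lam_cm
    return r_inf / (math.tanh(l1) + math.tanh(l2)) / 1e6
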