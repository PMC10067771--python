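"""Calcium-control synaptic plasticity and the synaptic-to-HCN coupling rule.

The synaptic weight ``w`` relaxes toward a calcium-dependent target
``Omega([Ca])`` at a calcium-dependent rate ``1/tau([Ca])`` (the calcium
control hypothesis):

    dw/dt = (Omega([Ca]) - w) / tau([Ca])
    tau([Ca]) = P1 + P2 / (P3 + [Ca]^P4)                    (seconds)
    Omega([Ca]) = 0.25 + sigm(b2, [Ca]-a2) - 0.25 sigm(b1, [Ca]-a1)

``Omega`` is flat at the initial weight (0.25) for resting calcium, dips
into an LTD trough between a1 = 0.35 and a2 = 0.55 and saturates at the LTP
plateau of 1 above a2.  The calcium argument is the submembrane shell
concentration expressed in uM (the scale on which the thresholds a1/a2 are
defined).  At resting calcium tau is about 3 hours, so unstimulated weights
are effectively frozen.

HCN coupling ties intrinsic excitability to net synaptic change: at every
update interval the somatic maximal h conductance is rescaled by

    g_h(t + dt) = g_h(t) * (1 + dW * slope)

where ``dW`` is the fractional (default; optionally percent) change of the
summed synaptic weights over the interval.  The whole spatial h-conductance
gradient scales through the somatic value, mimicking the experimentally
observed widespread HCN increase after LTP induction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PlasticityParams", "HCNCoupling",
    "omega", "learning_tau", "learning_eta", "step_weight", "update_hcn",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlasticityParams:
    """Constants of the calcium-control rule (tau in seconds, Ca in uM)."""

    P1: float = 1.0
    P2: float = 0.1
    P3: float = 0.1e-4      # P2 * 1e-4
    P4: float = 3.0
    alpha1: float = 0.35
    alpha2: float = 0.55
    beta1: float = 80.0
    beta2: float = 80.0
    w_init: float = 0.25

    def __post_init__(self) -> None:
        if min(self.P1, self.P2, self.P3, self.P4) <= 0:
            raise ValueError("P1..P4 must be > 0")
        if not self.alpha1 < self.alpha2:
            raise ValueError("requires alpha1 < alpha2")
        if min(self.beta1, self.beta2) <= 0:
            raise ValueError("beta1, beta2 must be > 0")


DEFAULT_PLASTICITY = PlasticityParams()


@dataclass(frozen=True)
class HCNCoupling:
    """Linear synaptic-to-HCN coupling.

    ``slope`` is dimensionless under the fractional dW convention (the
    default); the ``percent`` convention multiplies dW by 100 and rescales
    the meaning of slope accordingly.  ``g_floor_scale`` bounds how far the
    conductance may be scaled down, keeping g_h positive.
    """

    slope: float = 3.5
    dt_update: float = 100.0          # ms between updates
    convention: str = "fractional"    # or "percent"
    g_floor_scale: float = 1e-3

    def __post_init__(self) -> None:
        if self.slope < 0:
            raise ValueError("slope must be >= 0")
        if self.convention not in ("fractional", "percent"):
            raise ValueError("convention must be 'fractional' or 'percent'")

    @property
    def dw_multiplier(self) -> float:
        return 100.0 if self.convention == "percent" else 1.0


def omega(ca, p: PlasticityParams = DEFAULT_PLASTICITY):
    """Calcium-dependent target weight (double sigmoid; ca in uM)."""
    ca = np.asarray(ca, dtype=float)
    if np.any(ca < 0):
        raise ValueError("calcium must be >= 0")
    out = (p.w_init
           + 1.0 / (1.0 + np.exp(-p.beta2 * (ca - p.alpha2)))
           - p.w_init / (1.0 + np.exp(-p.beta1 * (ca - p.alpha1))))
    return float(out) if out.ndim == 0 else out


def learning_tau(ca, p: PlasticityParams = DEFAULT_PLASTICITY):
    """Calcium-dependent learning time constant (seconds; ca in uM).

    Strictly decreasing: about 3 h at resting calcium, the P1 floor (1 s)
    for saturating calcium.
    """
    ca = np.asarray(ca, dtype=float)
    if np.any(ca < 0):
        raise ValueError("calcium must be >= 0")
    out = p.P1 + p.P2 / (p.P3 + ca ** p.P4)
    return float(out) if out.ndim == 0 else out


def learning_eta(ca, p: PlasticityParams = DEFAULT_PLASTICITY):
    """Learning rate 1/tau (1/s)."""
    return 1.0 / learning_tau(ca, p)


def step_weight(w: float, ca: float, dt: float,
                p: PlasticityParams = DEFAULT_PLASTICITY) -> float:
    """Advance the weight by ``dt`` seconds at fixed calcium (uM).

    Exact exponential pursuit of Omega(ca): the result lies between ``w``
    and the target.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    om = omega(ca, p)
    return om + (w - om) * math.exp(-dt / learning_tau(ca, p))


def update_hcn(g_soma: float, weights_now, weights_ref,
               coupling: HCNCoupling) -> float:
    """One HCN update: ``g' = g * (1 + dW * slope)`` with
    ``dW = (sum(w_now) - sum(w_ref)) / sum(w_ref)`` (fractional convention).

    A non-positive result is clamped at ``g_floor_scale * g_soma`` and
    logged.
    """
    s_ref = float(np.sum(weights_ref))
    if s_ref <= 0:
        raise ValueError("sum of reference weights must be > 0")
    dw = (float(np.sum(weights_now)) - s_ref) / s_ref * coupling.dw_multiplier
    g_new = g_soma * (1.0 + dw * coupling.slope)
    floor = coupling.g_floor_scale * g_soma
    if g_new <= floor:
        logger.warning("HCN update would drive g_h to %.3g; clamped", g_new)
        g_new = floor
    return g_new
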