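"""Presynaptic event-time generators and somatic current waveforms.

Two input regimes drive the model: homogeneous Poisson trains (input/output
profiling and plasticity induction) and theta-modulated trains in which
events cluster, Gaussian-fashion, around the midpoint of each 8 Hz theta
cycle (place-field simulations).  A calibrated asymmetric current ramp
emulates the slow depolarization a place cell receives while the animal
crosses the field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusSet", "poisson_train", "theta_train",
    "ramp_waveform", "ramp_current", "RampCalibrationError",
]


@dataclass
class StimulusSet:
    """Per-synapse event trains plus an optional somatic current waveform."""

    events: list = field(default_factory=list)    # per-synapse arrays (ms)
    i_inj: np.ndarray | None = None               # nA, sampled at dt
    meta: dict = field(default_factory=dict)


def poisson_train(rate: float, duration: float,
                  rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Event times (ms) of a homogeneous Poisson process.

    ``rate`` in Hz, ``duration`` in seconds.  ``rng`` may be a Generator or a
    seed; a fixed seed reproduces the train exactly.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rate == 0 or duration <= 0:
        return np.empty(0)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    # draw gaps in ms; expected count + 6 sigma margin, top up if short
    mean_n = rate * duration
    out = []
    t = 0.0
    n_draw = max(16, int(mean_n + 6.0 * math.sqrt(mean_n) + 10))
    scale = 1000.0 / rate
    dur_ms = duration * 1000.0
    while t < dur_ms:
        gaps = rng.exponential(scale, size=n_draw)
        times = t + np.cumsum(gaps)
        out.append(times[times < dur_ms])
        t = times[-1]
    return np.concatenate(out) if out else np.empty(0)


def theta_train(T_theta: float = 125.0, sigma: float | None = None,
                A: float = 1.0, duration: float = 10.0,
                rng: np.random.Generator | int | None = None,
                window: tuple | None = None) -> np.ndarray:
    """Theta-modulated event times (ms).

    Per theta cycle of period ``T_theta`` (ms; 125 ms for 8 Hz) the number of
    events is Poisson with mean ``A`` and each event's phase is Gaussian
    around the cycle midpoint with SD ``sigma`` (default ``T_theta / 8``).
    ``duration`` is in seconds; ``window=(t0, t1)`` (ms) restricts events to
    a sub-interval.
    """
    if T_theta <= 0:
        raise ValueError("T_theta must be > 0")
    if A < 0:
        raise ValueError("A must be >= 0")
    if sigma is None:
        sigma = T_theta / 8.0
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    dur_ms = duration * 1000.0
    t0, t1 = (0.0, dur_ms) if window is None else window
    out = []
    n_cycles = int(math.ceil(dur_ms / T_theta))
    for c in range(n_cycles):
        start = c * T_theta
        if start + T_theta < t0 or start > t1:
            # keep the RNG stream independent of the window for reproducible
            # phase structure? no: skip cycles entirely outside the window
            continue
        count = rng.poisson(A)
        if count == 0:
            continue
        phases = rng.normal(T_theta / 2.0, sigma, size=count)
        keep = (phases >= 0.0) & (phases < T_theta)
        times = start + phases[keep]
        times = times[(times >= t0) & (times < t1) & (times < dur_ms)]
        out.append(times)
    return np.sort(np.concatenate(out)) if out else np.empty(0)


def ramp_waveform(amplitude: float, window: tuple, duration: float,
                  dt: float, rise_frac: float = 0.8) -> np.ndarray:
    """Asymmetric triangular ramp (nA sampled at dt over ``duration`` ms).

    Rises linearly over the first ``rise_frac`` of the window (slow on) and
    falls over the remainder (fast off); zero elsewhere.
    """
    t0, t1 = window
    if not (0.0 <= t0 < t1 <= duration):
        raise ValueError("window must lie within the simulation duration")
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    wave = np.zeros(n)
    t_peak = t0 + rise_frac * (t1 - t0)
    rise = (t >= t0) & (t < t_peak)
    fall = (t >= t_peak) & (t < t1)
    wave[rise] = amplitude * (t[rise] - t0) / (t_peak - t0)
    wave[fall] = amplitude * (t1 - t[fall]) / (t1 - t_peak)
    return wave


class RampCalibrationError(RuntimeError):
    """Raised when the ramp amplitude cannot be calibrated to the target."""


def ramp_current(model, window: tuple, peak_depol_target: float = 4.0,
                 duration: float = 10000.0, dt: float = 0.025,
                 tol: float = 0.5, rise_frac: float = 0.8,
                 max_iter: int = 8) -> np.ndarray:
    """Calibrate the ramp amplitude so the peak somatic depolarization of
    the otherwise unstimulated model is about ``peak_depol_target`` mV.

    The subthreshold response is close to linear in the amplitude, so a
    few multiplicative corrections converge; a non-monotone (or spiking)
    response raises :class:`RampCalibrationError`.
    """
    from .engine import SimulationConfig, run  # local import avoids a cycle

    amp = 0.02
    cfg = SimulationConfig(duration=duration, dt=dt, v_init=model.v_rest,
                           settle=200.0, rec_every=40)
    last = None
    for _ in range(max_iter):
        wave = ramp_waveform(amp, window, duration, dt)
        res = run(model, None, cfg, i_inj=wave)
        v = res.voltage(0)
        t = res.t
        base = float(np.mean(v[t < window[0]])) if window[0] > 0 else v[0]
        peak = float(np.max(v[(t >= window[0]) & (t <= window[1])]))
        depol = peak - base
        if len(res.spike_times) > 0:
            amp *= 0.5
            continue
        if depol <= 0:
            raise RampCalibrationError("no depolarization measured")
        if last is not None and last[0] < amp and depol < last[1] - 1e-9:
            raise RampCalibrationError("non-monotone amplitude response")
        if abs(depol - peak_depol_target) <= tol:
            return wave
        last = (amp, depol)
        amp *= peak_depol_target / depol
    raise RampCalibrationError(
        f"calibration did not converge (last depolarization {depol:.2f} mV)")
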