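"""The measurement battery: EPSP amplitudes, dendritic-democracy tuning,
input resistance, input/output response profiles and profile RMSE.

The input/output profile stimulates every synapse with independent Poisson
trains at a common rate, repeats each rate K times, and counts somatic
spikes in the 1 s stimulation window.  Baseline transmission measurements
(EPSP, I/O profile) use AMPA receptors only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .engine import CellModel, SimulationConfig, run
from .stimulation import poisson_train

__all__ = [
    "ResponseProfile", "MeasurementError",
    "epsp_amplitude", "epsp_amplitudes", "democracy_tune",
    "input_resistance", "io_profile", "rmse",
]


class MeasurementError(RuntimeError):
    pass


@dataclass
class ResponseProfile:
    """Response firing rates indexed by (stimulus frequency, trial).

    ``rates[i, k]`` is the somatic spike count in the 1 s window (spikes/s)
    for stimulus frequency ``freqs[i]`` on trial ``k``.
    """

    freqs: np.ndarray          # Hz
    rates: np.ndarray          # (nfreq, K)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.shape[0] != len(self.freqs):
            raise ValueError("rates/freqs dimension mismatch")
        if np.any(self.rates < 0):
            raise ValueError("rates must be >= 0")

    @property
    def trials(self) -> int:
        return self.rates.shape[1]

    def mean(self) -> np.ndarray:
        return self.rates.mean(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rates,
                          columns=[f"trial_{k}" for k in range(self.trials)])
        df.insert(0, "stim_hz", self.freqs)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def ampa_only(model: CellModel) -> CellModel:
    """A copy of the model with NMDA receptors and plasticity disabled
    (baseline-transmission measurement condition)."""
    m = model.copy()
    for s in m.synapses:
        s.has_nmda = False
        s.plastic = False
    return m


def epsp_amplitudes(model: CellModel, syn_indices=None, dt: float = 0.025,
                    spacing: float = 150.0, settle: float = 200.0) -> np.ndarray:
    """Somatic EPSP amplitudes (mV) of the given synapses (default: all).

    Synapses are activated once each, staggered ``spacing`` ms apart in a
    single run (AMPA only); the amplitude is the peak somatic deflection
    above the immediately preceding baseline.  A somatic spike during the
    measurement raises :class:`MeasurementError`.
    """
    m = ampa_only(model)
    nsyn = len(m.synapses)
    if syn_indices is None:
        syn_indices = list(range(nsyn))
    events = [np.empty(0) for _ in range(nsyn)]
    onsets = {}
    for j, s in enumerate(syn_indices):
        t0 = 20.0 + j * spacing
        events[s] = np.array([t0])
        onsets[s] = t0
    duration = 20.0 + len(syn_indices) * spacing
    cfg = SimulationConfig(duration=duration, dt=dt, v_init=model.v_rest,
                           settle=settle, rec_every=4)
    res = run(m, events, cfg)
    if len(res.spike_times) > 0:
        raise MeasurementError("spike evoked during EPSP measurement")
    v = res.voltage(0)
    t = res.t
    amps = np.empty(len(syn_indices))
    for j, s in enumerate(syn_indices):
        t0 = onsets[s]
        pre = v[(t >= t0 - 10.0) & (t < t0)]
        baseline = float(np.mean(pre)) if len(pre) else v[0]
        seg = v[(t >= t0) & (t < t0 + spacing - 10.0)]
        amps[j] = float(np.max(seg)) - baseline
    return amps


def epsp_amplitude(model: CellModel, syn_index: int, **kw) -> float:
    """Somatic EPSP amplitude (mV) of a single synapse (AMPA only)."""
    return float(epsp_amplitudes(model, [syn_index], **kw)[0])


def democracy_tune(model: CellModel, target: float = 0.2, tol: float = 0.01,
                   max_iter: int = 30, **kw) -> np.ndarray:
    """Tune per-synapse AMPA permeabilities until all somatic EPSP
    amplitudes match ``target`` mV within ``tol`` (dendritic democracy).

    Multiplicative fixed-point iteration (P <- P * target/amplitude, capped
    at 3x per sweep); modifies the model's synapses in place and returns the
    final permeability vector (cm/s).  Raises on non-convergence.
    """
    nsyn = len(model.synapses)
    if nsyn == 0:
        raise ValueError("model has no synapses")
    for it in range(max_iter):
        amps = epsp_amplitudes(model, **kw)
        if np.all(np.abs(amps - target) <= tol):
            return np.array([s.params.P_ampa for s in model.synapses])
        for s, amp in zip(model.synapses, amps):
            if amp <= 0:
                raise MeasurementError(
                    f"synapse at compartment {s.compartment}: no EPSP")
            factor = min(max(target / amp, 1.0 / 3.0), 3.0)
            s.params = replace(s.params, P_ampa=s.params.P_ampa * factor)
    raise MeasurementError(f"democracy tuning did not converge in {max_iter} "
                           "iterations")


def input_resistance(model: CellModel, comp: int = 0,
                     amps_pA=None, pulse_ms: float = 300.0,
                     dt: float = 0.025) -> float:
    """Input resistance (MOhm) at a compartment from the slope of the
    steady-state V-I relationship over current pulses of -50..+50 pA
    (steps of 10 pA by default)."""
    if amps_pA is None:
        amps_pA = np.arange(-50.0, 51.0, 10.0)
    amps_pA = np.asarray(amps_pA, dtype=float)
    vss = np.empty(len(amps_pA))
    cfg = SimulationConfig(duration=pulse_ms + 50.0, dt=dt,
                           v_init=model.v_rest, settle=200.0,
                           record=(comp,), rec_every=20)
    nstep = int(round((pulse_ms + 50.0) / dt))
    for j, a in enumerate(amps_pA):
        wave = np.zeros(nstep)
        wave[:int(round(pulse_ms / dt))] = a * 1e-3  # pA -> nA
        res = run(model, None, cfg, i_inj=wave, inj_comp=comp)
        if len(res.spike_times) > 0:
            raise MeasurementError(f"spiking during {a} pA pulse")
        v = res.voltage(comp)
        t = res.t
        vss[j] = float(np.mean(v[(t > pulse_ms - 50.0) & (t <= pulse_ms)]))
    slope = np.polyfit(amps_pA * 1e-3, vss, 1)[0]   # mV / nA = MOhm
    return float(slope)


def io_profile(model: CellModel, freqs=None, trials: int = 10,
               duration: float = 1000.0, seed: int = 0,
               dt: float = 0.025) -> ResponseProfile:
    """Synaptically driven input/output response profile.

    All synapses are stimulated simultaneously with independent Poisson
    trains at each stimulus frequency; each frequency is repeated ``trials``
    times with fresh realizations and the somatic spike count in the
    ``duration`` window is the response rate.  AMPA-only transmission.

    The event realization for (frequency, trial, synapse) depends only on
    ``seed`` and the grid — not on the model — so profiles of a perturbed
    model are trial-paired with its baseline.
    """
    if freqs is None:
        freqs = np.arange(1.0, 51.0, 1.0)
    freqs = np.asarray(freqs, dtype=float)
    m = ampa_only(model)
    nsyn = len(m.synapses)
    cfg = SimulationConfig(duration=duration, dt=dt, v_init=model.v_rest,
                           settle=200.0, rec_every=40)
    rates = np.zeros((len(freqs), trials))
    for i, fhz in enumerate(freqs):
        for k in range(trials):
            rng = np.random.default_rng(
                np.random.SeedSequence([seed, int(round(fhz * 1000)), k]))
            events = [poisson_train(fhz, duration / 1000.0, rng)
                      for _ in range(nsyn)]
            res = run(m, events, cfg)
            rates[i, k] = res.spike_count * 1000.0 / duration
    return ResponseProfile(freqs=freqs, rates=rates)


def rmse(new: ResponseProfile, base: ResponseProfile) -> float:
    """Root mean squared difference (Hz) between trial-paired profiles:
    ``sqrt(mean((new - base)^2))`` over all (frequency, trial) cells."""
    if new.rates.shape != base.rates.shape:
        raise ValueError("profile dimensions differ")
    return float(np.sqrt(np.mean((new.rates - base.rates) ** 2)))
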