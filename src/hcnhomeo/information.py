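"""Rate-coding mutual information between stimulus and response frequency.

Each stimulus frequency s elicits response rates whose trial mean and SD
define a Gaussian response distribution p[r|s], discretized on a 1 Hz grid
(1-100 Hz by default) and renormalized.  With uniform stimulus priors p[s],
the mutual information is the difference between the total response entropy
H = -sum_r p[r] log2 p[r] and the noise entropy
H_noise = sum_s p[s] H(p[r|s]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .measurements import ResponseProfile

__all__ = [
    "InfoResult", "default_bins", "conditional_distributions",
    "mutual_information", "info_from_profile",
]


@dataclass
class InfoResult:
    """Discretized channel description and its entropies (bits)."""

    bins: np.ndarray          # response bin centers, Hz
    p_rs: np.ndarray          # (nstim, nbins), rows sum to 1
    p_s: np.ndarray           # (nstim,)
    p_r: np.ndarray           # (nbins,)
    H: float                  # response entropy
    H_noise: float
    I_m: float                # mutual information

    def to_dict(self) -> dict:
        return {"H_bits": self.H, "H_noise_bits": self.H_noise,
                "I_m_bits": self.I_m}


def default_bins(lo: float = 1.0, hi: float = 100.0,
                 step: float = 1.0) -> np.ndarray:
    """Response-rate bin centers (Hz), 1 Hz resolution over 1-100 Hz."""
    return np.arange(lo, hi + step / 2, step)


def conditional_distributions(profile: ResponseProfile,
                              bins: np.ndarray | None = None) -> np.ndarray:
    """Per-stimulus Gaussian response distributions p[r|s] on the bin grid.

    For each stimulus the trial mean and SD parameterize a Gaussian
    evaluated at the bin centers and renormalized (tail mass re-enters the
    grid).  Zero SD collapses to a delta on the nearest bin.
    """
    if profile.trials < 2:
        raise ValueError("need at least 2 trials per stimulus")
    if bins is None:
        bins = default_bins()
    bins = np.asarray(bins, dtype=float)
    mu = profile.rates.mean(axis=1)
    sd = profile.rates.std(axis=1, ddof=0)
    p = np.zeros((len(mu), len(bins)))
    for i in range(len(mu)):
        if sd[i] == 0.0:
            p[i, int(np.argmin(np.abs(bins - mu[i])))] = 1.0
        else:
            row = np.exp(-0.5 * ((bins - mu[i]) / sd[i]) ** 2)
            total = row.sum()
            if total <= 0:  # mean far outside the grid: nearest-bin fallback
                p[i, int(np.argmin(np.abs(bins - mu[i])))] = 1.0
            else:
                p[i] = row / total
    return p


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def mutual_information(p_rs: np.ndarray,
                       p_s: np.ndarray | None = None,
                       bins: np.ndarray | None = None) -> InfoResult:
    """Entropies and mutual information of a discrete channel p[r|s].

    ``p_s`` defaults to uniform (each stimulus equally likely).  Rows of
    ``p_rs`` must be normalized; 0 log 0 is taken as 0.
    """
    p_rs = np.asarray(p_rs, dtype=float)
    nstim, nbins = p_rs.shape
    if p_s is None:
        p_s = np.full(nstim, 1.0 / nstim)
    p_s = np.asarray(p_s, dtype=float)
    if not np.allclose(p_rs.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("rows of p[r|s] must sum to 1")
    if not np.isclose(p_s.sum(), 1.0, atol=1e-9):
        raise ValueError("p[s] must sum to 1")
    if bins is None:
        bins = default_bins()
        if len(bins) != nbins:
            bins = np.arange(nbins, dtype=float)
    p_r = p_s @ p_rs
    H = _entropy(p_r)
    H_noise = float(sum(p_s[i] * _entropy(p_rs[i]) for i in range(nstim)))
    return InfoResult(bins=np.asarray(bins, dtype=float), p_rs=p_rs, p_s=p_s,
                      p_r=p_r, H=H, H_noise=H_noise, I_m=H - H_noise)


def info_from_profile(profile: ResponseProfile,
                      bins: np.ndarray | None = None,
                      stim_range: tuple | None = None) -> InfoResult:
    """Mutual information of a measured response profile.

    ``stim_range=(lo, hi)`` restricts the stimulus ensemble (e.g. 10-50 Hz
    for the information-maximization analysis); the prior stays uniform on
    the retained stimuli.
    """
    if stim_range is not None:
        keep = (profile.freqs >= stim_range[0]) & (profile.freqs <= stim_range[1])
        profile = ResponseProfile(freqs=profile.freqs[keep],
                                  rates=profile.rates[keep])
    p_rs = conditional_distributions(profile, bins)
    return mutual_information(p_rs, bins=bins)
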