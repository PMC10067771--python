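"""Synthetic inputs: parameterized CA1-like morphologies and fixture
response profiles.

The morphology generator emulates the gross architecture the analysis needs
— a soma, a tapering apical trunk of ~425 um with oblique side branches, a
basal stub and an axon with an initial segment — without reproducing any
particular reconstruction's branching statistics.  Everything downstream
(gradients, synapse placement, protocols) runs on it offline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .measurements import ResponseProfile
from .morphology import Morphology, Section

__all__ = [
    "SyntheticMorphologySpec", "make_morphology", "tag_ais",
    "make_fixture_profile",
]


@dataclass(frozen=True)
class SyntheticMorphologySpec:
    """Geometry of the synthetic cell (lengths/diameters in um)."""

    trunk_length: float = 425.0
    trunk_diam_prox: float = 2.5
    trunk_diam_dist: float = 1.0
    n_obliques: int = 6
    oblique_length: float = 60.0
    oblique_diam: float = 1.0
    soma_diam: float = 15.0
    n_basal: int = 2
    basal_length: float = 110.0
    basal_diam: float = 1.5
    axon_length: float = 100.0
    axon_diam: float = 1.0
    ais_length: float = 30.0

    def __post_init__(self) -> None:
        if min(self.trunk_length, self.trunk_diam_prox, self.trunk_diam_dist,
               self.oblique_length, self.oblique_diam, self.soma_diam,
               self.basal_length, self.basal_diam, self.axon_length,
               self.axon_diam, self.ais_length) <= 0:
            raise ValueError("all lengths and diameters must be positive")


def _trunk_diam(spec: SyntheticMorphologySpec, s: float) -> float:
    """Linearly tapering trunk diameter at arc distance s from the soma."""
    f = s / spec.trunk_length
    return spec.trunk_diam_prox + f * (spec.trunk_diam_dist - spec.trunk_diam_prox)


def make_morphology(spec: SyntheticMorphologySpec | None = None,
                    seed: int | None = 0) -> Morphology:
    """Build a soma + tapered apical trunk + obliques + basal + axon cell.

    The trunk runs along +y and is split into sections at each oblique
    attachment point; oblique azimuths and exact attachment positions are
    randomized by ``seed`` (the trunk itself is seed-independent).  The
    returned morphology round-trips losslessly through the SWC writer and
    reader followed by :func:`tag_ais`.
    """
    spec = spec or SyntheticMorphologySpec()
    rng = np.random.default_rng(seed)

    sections: list[Section] = []
    d = spec.soma_diam
    soma = Section(0, "soma",
                   np.array([[-d / 2.0, 0.0, 0.0], [d / 2.0, 0.0, 0.0]]),
                   np.array([d, d]), parent=-1)
    sections.append(soma)

    # oblique attachment arc positions along the trunk (jittered, interior)
    n_ob = spec.n_obliques
    if n_ob > 0:
        base = np.linspace(0.15, 0.75, n_ob) * spec.trunk_length
        jitter = rng.uniform(-0.03, 0.03, n_ob) * spec.trunk_length
        attach = np.sort(np.clip(base + jitter, 10.0, spec.trunk_length - 10.0))
    else:
        attach = np.empty(0)

    # trunk: chain of sections between attachment points
    cuts = np.concatenate([[0.0], attach, [spec.trunk_length]])
    parent_idx = 0
    trunk_section_at: list[tuple[float, int]] = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        npts = max(2, int(math.ceil((b - a) / 20.0)) + 1)
        arcs = np.linspace(a, b, npts)
        pts = np.column_stack([np.zeros(npts), arcs, np.zeros(npts)])
        diam = np.array([_trunk_diam(spec, s) for s in arcs])
        sec = Section(len(sections), "apical", pts, diam, parent=parent_idx)
        sections.append(sec)
        parent_idx = sec.index
        trunk_section_at.append((b, sec.index))

    # obliques: leave each junction horizontally at a random azimuth
    for j, a in enumerate(attach):
        parent = trunk_section_at[j][1]
        phi = rng.uniform(0.0, 2.0 * math.pi)
        direction = np.array([math.cos(phi), 0.0, math.sin(phi)])
        start = np.array([0.0, a, 0.0])
        npts = max(2, int(math.ceil(spec.oblique_length / 20.0)) + 1)
        arcs = np.linspace(0.0, spec.oblique_length, npts)
        pts = start + np.outer(arcs, direction)
        diam = np.full(npts, spec.oblique_diam)
        sections.append(Section(len(sections), "apical", pts, diam,
                                parent=parent))

    # basal dendrites from the soma, fanning into -y
    for j in range(spec.n_basal):
        phi = 2.0 * math.pi * j / max(spec.n_basal, 1)
        direction = np.array([0.6 * math.cos(phi), -0.8, 0.6 * math.sin(phi)])
        direction /= np.linalg.norm(direction)
        npts = max(2, int(math.ceil(spec.basal_length / 25.0)) + 1)
        arcs = np.linspace(0.0, spec.basal_length, npts)
        pts = np.outer(arcs, direction)
        sections.append(Section(len(sections), "basal", pts,
                                np.full(npts, spec.basal_diam), parent=0))

    # axon (single section; tag_ais splits off the initial segment)
    total_ax = spec.ais_length + spec.axon_length
    npts = max(3, int(math.ceil(total_ax / 25.0)) + 1)
    arcs = np.linspace(0.0, total_ax, npts)
    pts = np.column_stack([arcs * 0.0, -arcs, arcs * 0.0]) + [0.0, -1e-9, 0.0]
    sections.append(Section(len(sections), "axon", pts,
                            np.full(npts, spec.axon_diam), parent=0))

    m = Morphology(sections)
    return tag_ais(m, spec.ais_length)


def tag_ais(m: Morphology, length: float = 30.0) -> Morphology:
    """Split the proximal ``length`` um of the soma-attached axon into an
    axon-initial-segment section (region tag ``'ais'``).

    Idempotent: if an AIS of that length already exists the morphology is
    returned unchanged.  Used after SWC round trips (SWC has no AIS type).
    """
    for sec in m.sections:
        if sec.region == "ais":
            return m
    ax = next((s for s in m.sections
               if s.region == "axon" and m.sections[s.parent].region == "soma"),
              None)
    if ax is None:
        return m
    arc = ax.arc
    if arc[-1] <= length:
        ax.region = "ais"
        return m
    # interpolate the split point, rebuild the section list with renumbering
    pts, diam = ax.points, ax.diam
    split_pt = np.array([np.interp(length, arc, pts[:, k]) for k in range(3)])
    split_d = float(np.interp(length, arc, diam))
    prox_keep = arc < length - 1e-9
    dist_keep = arc > length + 1e-9
    prox_pts = np.vstack([pts[prox_keep], split_pt])
    prox_d = np.concatenate([diam[prox_keep], [split_d]])
    dist_pts = np.vstack([split_pt, pts[dist_keep]])
    dist_d = np.concatenate([[split_d], diam[dist_keep]])

    new_sections: list[Section] = []
    index_map: dict[int, int] = {}
    for sec in m.sections:
        if sec.index == ax.index:
            ais = Section(len(new_sections), "ais", prox_pts, prox_d,
                          parent=index_map[sec.parent])
            new_sections.append(ais)
            index_map[sec.index] = ais.index  # children re-attach to distal part
            dist = Section(len(new_sections), "axon", dist_pts, dist_d,
                           parent=ais.index)
            new_sections.append(dist)
            index_map[sec.index] = dist.index
        else:
            ns = Section(len(new_sections), sec.region, sec.points.copy(),
                         sec.diam.copy(),
                         parent=index_map[sec.parent] if sec.parent >= 0 else -1)
            new_sections.append(ns)
            index_map[sec.index] = ns.index
    return Morphology(new_sections)


def make_fixture_profile(shape: str, freqs=None, trials: int = 10,
                         sd: float = 2.0, lo: float = 1.0, hi: float = 45.0,
                         seed: int = 0) -> ResponseProfile:
    """Synthetic response profile whose rate marginal follows a named shape.

    ``shape`` is one of ``uniform``, ``exponential``, ``bimodal`` or
    ``lognormal`` — the marginal response-rate distributions the analysis
    distinguishes.  Per stimulus the trial values are the shape-determined
    mean plus Gaussian trial noise of SD ``sd`` (clipped at 0).
    """
    if freqs is None:
        freqs = np.arange(1.0, 51.0, 1.0)
    freqs = np.asarray(freqs, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(freqs)
    q = (np.arange(n) + 0.5) / n     # deterministic quantile grid
    if shape == "uniform":
        mu = lo + q * (hi - lo)
    elif shape == "exponential":
        mu = lo + (-np.log1p(-q * (1 - math.exp(-3.0)))) / 3.0 * (hi - lo)
    elif shape == "bimodal":
        half = n // 2
        mu = np.empty(n)
        mu[:half] = lo + 0.2 * (hi - lo) * q[:half] / q[half - 1]
        mu[half:] = lo + (hi - lo) * (0.75 + 0.25 * (q[half:] - q[half]) /
                                      max(q[-1] - q[half], 1e-9))
    elif shape == "lognormal":
        z = (q - 0.5) * 3.46  # approx standard normal quantiles
        mu = lo + (hi - lo) * np.exp(0.5 * z) / np.exp(0.5 * 3.46 / 2)
        mu = np.clip(mu, lo, hi)
    else:
        raise ValueError(f"unknown shape {shape!r}")
    rates = np.clip(mu[:, None] + rng.normal(0.0, sd, size=(n, trials)), 0.0,
                    None)
    return ResponseProfile(freqs=freqs, rates=rates)
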