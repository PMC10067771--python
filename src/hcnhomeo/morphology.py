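"""Neuronal morphologies: SWC I/O, passive-property gradients and discretization.

A :class:`Morphology` is a tree of unbranched neurite sections carrying 3D
points and per-point diameters.  Specific membrane resistivity (Rm) and axial
resistivity (Ra) vary sigmoidally with path distance ``x`` from the soma along
the apical arbor, while the soma, basal dendrites and axon carry the somatic
(``x = 0``) values.  :func:`compartmentalize` discretizes each section with the
d-lambda rule (compartments shorter than ``d_lambda * lambda_100``, odd counts
per section) and produces the flat :class:`CompartmentTree` the simulation
engine consumes.

Units: lengths and diameters in um, membrane area in cm^2, Cm in uF/cm^2,
Rm in kOhm*cm^2, Ra in Ohm*cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SWCParseError",
    "PassiveParams",
    "Section",
    "Morphology",
    "CompartmentTree",
    "load_swc",
    "write_swc",
    "assign_passive",
    "lambda_f",
    "compartmentalize",
]

#: SWC integer type codes -> region tags.
SWC_REGIONS = {1: "soma", 2: "axon", 3: "basal", 4: "apical"}
REGION_CODES = {v: k for k, v in SWC_REGIONS.items()}
REGION_CODES["ais"] = 2  # the initial segment is written as axon type


class SWCParseError(ValueError):
    """Raised for malformed SWC content; message names the offending line."""


@dataclass(frozen=True)
class PassiveParams:
    """Passive membrane parameters of the sigmoidal somato-apical gradients.

    ``Rm(x) = Rm_max + (Rm_min - Rm_max) / (1 + exp((Rm_d - x)/Rm_k))`` and the
    analogous expression for Ra.  ``Rm_max``/``Ra_max`` hold at the soma and
    ``Rm_min``/``Ra_min`` at the distal end of the apical trunk (~425 um).
    """

    Cm: float = 1.0          # uF/cm^2
    Rm_max: float = 125.0    # kOhm*cm^2, somatic
    Rm_min: float = 85.0     # kOhm*cm^2, distal trunk
    Ra_max: float = 120.0    # Ohm*cm, somatic
    Ra_min: float = 70.0     # Ohm*cm, distal trunk
    Rm_d: float = 300.0      # um, half-maximal distance
    Rm_k: float = 50.0       # um, slope
    Ra_d: float = 300.0      # um
    Ra_k: float = 50.0       # um

    def __post_init__(self) -> None:
        vals = [self.Cm, self.Rm_max, self.Rm_min, self.Ra_max, self.Ra_min,
                self.Rm_d, self.Rm_k, self.Ra_d, self.Ra_k]
        if any(v <= 0 for v in vals):
            raise ValueError("all passive parameters must be positive")
        if self.Rm_min > self.Rm_max or self.Ra_min > self.Ra_max:
            raise ValueError("min resistivity exceeds max")


@dataclass
class Section:
    """An unbranched neurite segment.

    ``points`` is an (N, 3) array of 3D coordinates (um) and ``diam`` the
    per-point diameters (um); ``parent`` indexes the parent section (-1 for
    the root soma).
    """

    index: int
    region: str
    points: np.ndarray
    diam: np.ndarray
    parent: int = -1

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.diam = np.asarray(self.diam, dtype=float).ravel()
        if len(self.diam) != len(self.points):
            raise ValueError("points/diam length mismatch")
        if np.any(self.diam <= 0):
            raise ValueError(f"section {self.index}: non-positive diameter")

    @property
    def arc(self) -> np.ndarray:
        """Cumulative arc length at each point (um)."""
        if len(self.points) == 1:
            return np.zeros(1)
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arc[-1])

    def frustum_area(self, s0: float | None = None, s1: float | None = None) -> float:
        """Lateral surface area (cm^2) of the chain of frusta over arc span [s0, s1]."""
        arc = self.arc
        if s0 is None:
            s0 = 0.0
        if s1 is None:
            s1 = float(arc[-1])
        r = self.diam / 2.0
        # radius is piecewise linear in arc length; clip each frustum to [s0, s1]
        area = 0.0
        for i in range(len(arc) - 1):
            a, b = arc[i], arc[i + 1]
            lo, hi = max(a, s0), min(b, s1)
            if hi <= lo or b == a:
                continue
            t0, t1 = (lo - a) / (b - a), (hi - a) / (b - a)
            r0 = r[i] + (r[i + 1] - r[i]) * t0
            r1 = r[i] + (r[i + 1] - r[i]) * t1
            slant = math.hypot(hi - lo, r1 - r0)
            area += math.pi * (r0 + r1) * slant
        return area * 1e-8  # um^2 -> cm^2

    def diam_at(self, s: float) -> float:
        """Diameter (um) interpolated at arc position ``s``."""
        return float(np.interp(s, self.arc, self.diam))


@dataclass
class Morphology:
    """A tree of sections with exactly one soma root."""

    sections: list[Section] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        roots = [s for s in self.sections if s.parent < 0]
        somas = [s for s in self.sections if s.region == "soma"]
        if len(somas) != 1 or len(roots) != 1 or roots[0].region != "soma":
            raise ValueError("morphology must have exactly one soma root")
        for s in self.sections:
            if s.parent >= s.index:
                raise ValueError("parent links must be acyclic (parent < child)")
            if s.region not in REGION_CODES:
                raise ValueError(f"unknown region tag {s.region!r}")

    @property
    def soma(self) -> Section:
        return next(s for s in self.sections if s.region == "soma")

    def children(self, index: int) -> list[Section]:
        return [s for s in self.sections if s.parent == index]

    def section_origin_distance(self, index: int) -> float:
        """Path distance (um) from the soma center to the proximal end of a section."""
        x = 0.0
        sec = self.sections[index]
        while sec.parent >= 0:
            parent = self.sections[sec.parent]
            if parent.region != "soma":
                x += parent.length
            sec = parent
        return x

    def apical_extent(self) -> float:
        """Maximum path distance (um) reached by the apical arbor."""
        return max(
            (self.section_origin_distance(s.index) + s.length
             for s in self.sections if s.region == "apical"),
            default=0.0,
        )


# ---------------------------------------------------------------------------
# SWC reading / writing

def _equivalent_soma(points: np.ndarray, radii: np.ndarray) -> Section:
    """Collapse soma sample points into a single cylinder of equivalent area.

    A single-point soma is treated as a sphere (area 4*pi*r^2); a multi-point
    contour as a chain of frusta.  The equivalent cylinder has L = diam so
    that pi*d*L matches the source area.
    """
    if len(points) == 1:
        area = 4.0 * math.pi * radii[0] ** 2
    else:
        seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
        area = float(np.sum(math.pi * (radii[:-1] + radii[1:]) *
                            np.hypot(seg, np.diff(radii))))
        if area <= 0:  # coincident points: fall back to sphere of mean radius
            area = 4.0 * math.pi * float(np.mean(radii)) ** 2
    d = math.sqrt(area / math.pi)
    center = points.mean(axis=0)
    p0 = center - [d / 2.0, 0, 0]
    p1 = center + [d / 2.0, 0, 0]
    return Section(0, "soma", np.vstack([p0, p1]), np.array([d, d]), parent=-1)


def load_swc(path) -> Morphology:
    """Read a standard 7-column SWC file into a :class:`Morphology`.

    Type codes map 1->soma, 2->axon, 3->basal, 4->apical.  Soma samples are
    collapsed to one equivalent-area cylindrical section.  Malformed rows,
    forward/orphan parent references and non-positive radii raise
    :class:`SWCParseError` naming the line.
    """
    nodes: dict[int, tuple[int, np.ndarray, float, int]] = {}
    order: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 7:
                raise SWCParseError(f"line {lineno}: expected 7 columns, got {len(cols)}")
            try:
                nid, ntype = int(cols[0]), int(cols[1])
                xyz = np.array([float(c) for c in cols[2:5]])
                radius = float(cols[5])
                parent = int(cols[6])
            except ValueError as err:
                raise SWCParseError(f"line {lineno}: non-numeric field ({err})") from None
            if radius <= 0:
                raise SWCParseError(f"line {lineno}: non-positive radius {radius}")
            if parent != -1 and parent not in nodes:
                raise SWCParseError(f"line {lineno}: parent id {parent} not yet defined")
            if nid in nodes:
                raise SWCParseError(f"line {lineno}: duplicate node id {nid}")
            if ntype not in SWC_REGIONS:
                raise SWCParseError(f"line {lineno}: unknown SWC type {ntype}")
            nodes[nid] = (ntype, xyz, radius, parent)
            order.append(nid)
    if not order:
        raise SWCParseError("file contains no sample points")

    soma_ids = [i for i in order if nodes[i][0] == 1]
    if not soma_ids:
        raise SWCParseError("no soma (type 1) samples present")
    soma_pts = np.array([nodes[i][1] for i in soma_ids])
    soma_r = np.array([nodes[i][2] for i in soma_ids])
    sections: list[Section] = [_equivalent_soma(soma_pts, soma_r)]

    children: dict[int, list[int]] = {}
    for i in order:
        children.setdefault(nodes[i][3], []).append(i)

    # Section heads: non-soma nodes whose parent is soma, absent, a branch
    # point, or of a different type.
    node_section: dict[int, int] = {i: 0 for i in soma_ids}

    def is_head(nid: int) -> bool:
        parent = nodes[nid][3]
        if parent == -1 or nodes[parent][0] == 1:
            return True
        if nodes[parent][0] != nodes[nid][0]:
            return True
        return len(children.get(parent, [])) > 1

    for nid in order:
        ntype, xyz, radius, parent = nodes[nid]
        if ntype == 1:
            continue
        if not is_head(nid):
            continue
        # walk the unbranched chain starting at nid
        chain = [nid]
        cur = nid
        while True:
            kids = [k for k in children.get(cur, []) if nodes[k][0] == nodes[cur][0]]
            if len(children.get(cur, [])) == 1 and len(kids) == 1:
                cur = kids[0]
                chain.append(cur)
            else:
                break
        pts = [nodes[i][1] for i in chain]
        rad = [nodes[i][2] for i in chain]
        if parent != -1 and nodes[parent][0] not in (1,):
            # include the parent (branch) point for geometric continuity,
            # unless the child already starts at that point
            if np.linalg.norm(nodes[parent][1] - pts[0]) > 1e-9:
                pts = [nodes[parent][1]] + pts
                rad = [nodes[parent][2]] + rad
            parent_section = node_section[parent]
        elif parent == -1:
            parent_section = 0
        else:
            parent_section = 0  # attached to the (collapsed) soma
        if len(pts) == 1:
            # single-sample section: make a short stub along the parent direction
            pts = [pts[0], pts[0] + np.array([2 * rad[0], 0.0, 0.0])]
            rad = [rad[0], rad[0]]
        sec = Section(len(sections), SWC_REGIONS[ntype], np.array(pts),
                      2.0 * np.array(rad), parent=parent_section)
        if sec.length <= 0:
            raise SWCParseError(f"section starting at node {nid} has zero length")
        sections.append(sec)
        for i in chain:
            node_section[i] = sec.index
    return Morphology(sections)


def write_swc(m: Morphology, path) -> None:
    """Write a morphology back to 7-column SWC (inverse of :func:`load_swc`)."""
    lines = ["# generated by hcnhomeo"]
    nid = 0
    last_node_of: dict[int, int] = {}
    for sec in m.sections:
        code = REGION_CODES[sec.region]
        if sec.region == "soma":
            nid += 1
            c = sec.points.mean(axis=0)
            lines.append(f"{nid} 1 {c[0]:.4f} {c[1]:.4f} {c[2]:.4f} "
                         f"{sec.diam[0] / 2:.4f} -1")
            last_node_of[sec.index] = nid
            continue
        parent_node = last_node_of[sec.parent]
        parent_sec = m.sections[sec.parent]
        # skip the leading branch point only if it fully duplicates the
        # parent's endpoint (position and diameter)
        start = 0
        if (parent_sec.region != "soma"
                and np.linalg.norm(sec.points[0] - parent_sec.points[-1]) <= 1e-9
                and abs(sec.diam[0] - parent_sec.diam[-1]) <= 1e-9):
            start = 1
        for p, d in zip(sec.points[start:], sec.diam[start:]):
            nid += 1
            lines.append(f"{nid} {code} {p[0]:.4f} {p[1]:.4f} {p[2]:.4f} "
                         f"{d / 2:.4f} {parent_node}")
            parent_node = nid
        last_node_of[sec.index] = nid
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Passive gradients and discretization

def assign_passive(x: float, params: PassiveParams, which: str):
    """Sigmoidal resistivity at path distance ``x`` (um) from the soma.

    ``which`` selects ``"Rm"`` (kOhm*cm^2) or ``"Ra"`` (Ohm*cm).  Accepts
    scalars or arrays.  Basal/axonal compartments should be queried at x=0.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("x must be >= 0")
    if which == "Rm":
        hi, lo, d, k = params.Rm_max, params.Rm_min, params.Rm_d, params.Rm_k
    elif which == "Ra":
        hi, lo, d, k = params.Ra_max, params.Ra_min, params.Ra_d, params.Ra_k
    else:
        raise ValueError(f"which must be 'Rm' or 'Ra', got {which!r}")
    out = hi + (lo - hi) / (1.0 + np.exp((d - x) / k))
    return float(out) if out.ndim == 0 else out


def lambda_f(diam: float, f: float, Ra: float, Cm: float) -> float:
    """AC length constant (um) at frequency ``f`` (Hz) for a cable of the
    given diameter (um), axial resistivity (Ohm*cm) and capacitance (uF/cm^2):
    ``lambda_f = (1/2) * sqrt(d / (pi * f * Ra * Cm))`` in consistent units.
    """
    return 1e5 * math.sqrt(diam / (4.0 * math.pi * f * Ra * Cm))


@dataclass
class CompartmentTree:
    """Flat, solver-ready discretization of a morphology.

    Arrays are indexed by compartment, ordered so that ``parent[i] < i``
    (root soma compartment first, ``parent[0] = -1``).
    """

    section: np.ndarray   # section index per compartment
    parent: np.ndarray    # parent compartment index (-1 at root)
    length: np.ndarray    # um
    diam: np.ndarray      # um (area-consistent mean over the span)
    area: np.ndarray      # cm^2 (frustum lateral area)
    x: np.ndarray         # um, path distance of the midpoint from the soma
    Rm: np.ndarray        # kOhm*cm^2
    Ra: np.ndarray        # Ohm*cm
    Cm: np.ndarray        # uF/cm^2
    region: np.ndarray    # object array of region tags

    @property
    def n(self) -> int:
        return len(self.parent)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": np.arange(self.n), "section": self.section,
            "parent": self.parent, "x_um": self.x, "L_um": self.length,
            "diam_um": self.diam, "area_cm2": self.area,
            "Rm_kohm_cm2": self.Rm, "Ra_ohm_cm": self.Ra,
            "Cm_uf_cm2": self.Cm, "region": self.region,
        })

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def compartmentalize(m: Morphology, p: PassiveParams,
                     d_lambda: float = 0.1, f: float = 100.0) -> CompartmentTree:
    """Discretize a morphology with the d-lambda rule.

    Each section receives the smallest odd number of equal-length compartments
    such that every compartment is shorter than ``d_lambda * lambda_f``.  Rm
    and Ra are assigned in two passes: a coarse pass using the section
    midpoint distance (entering the length-constant estimate) and a final pass
    at each compartment midpoint.  Basal/axonal sections take somatic (x = 0)
    values; apical sections follow the gradients.
    """
    if not (0.0 < d_lambda <= 1.0):
        raise ValueError("d_lambda must be in (0, 1]")
    if f <= 0:
        raise ValueError("f must be positive")

    section_idx, parent_arr, lengths, diams, areas = [], [], [], [], []
    xs, rms, ras, cms, regions = [], [], [], [], []
    last_comp_of: dict[int, int] = {}

    for sec in m.sections:
        L = sec.length
        if L <= 0:
            raise ValueError(f"section {sec.index} has zero length")
        x0 = m.section_origin_distance(sec.index)
        graded = sec.region == "apical"
        # pass 1: coarse passive values at the section midpoint
        x_mid = x0 + L / 2.0 if graded else 0.0
        ra_coarse = assign_passive(x_mid, p, "Ra")
        d_mean = sec.frustum_area() / (math.pi * L * 1e-8)  # area-equivalent diam
        lam = lambda_f(d_mean, f, ra_coarse, p.Cm)
        nseg = max(1, int(math.ceil(L / (d_lambda * lam))))
        if nseg % 2 == 0:
            nseg += 1
        edges = np.linspace(0.0, L, nseg + 1)
        prev = last_comp_of.get(sec.parent, -1)
        for k in range(nseg):
            s0, s1 = edges[k], edges[k + 1]
            mid = 0.5 * (s0 + s1)
            a = sec.frustum_area(s0, s1)
            seg_len = s1 - s0
            d_eq = a / (math.pi * seg_len * 1e-8)
            x = x0 + mid if graded else (0.0 if sec.region == "soma" else x0 + mid)
            x_for_passive = x if graded else 0.0
            idx = len(parent_arr)
            section_idx.append(sec.index)
            parent_arr.append(prev)
            lengths.append(seg_len)
            diams.append(d_eq)
            areas.append(a)
            xs.append(0.0 if sec.region == "soma" else x)
            rms.append(assign_passive(x_for_passive, p, "Rm"))
            ras.append(assign_passive(x_for_passive, p, "Ra"))
            cms.append(p.Cm)
            regions.append(sec.region)
            prev = idx
        last_comp_of[sec.index] = prev

    return CompartmentTree(
        section=np.array(section_idx), parent=np.array(parent_arr),
        length=np.array(lengths), diam=np.array(diams), area=np.array(areas),
        x=np.array(xs), Rm=np.array(rms), Ra=np.array(ras), Cm=np.array(cms),
        region=np.array(regions, dtype=object),
    )
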