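"""RGC geometry: region layout, elliptical axon trajectories, discretization.

The cell is a rooted tree of cylindrical compartments.  The soma-to-axon path
visits the six regions in the fixed order soma, hillock, sodium channel band
(SOCB), narrow region, axon; dendrites (optional) hang off the soma.  The
coordinate frame places the retinal surface at z = 0 with tissue at z < 0, so
an epiretinal electrode sits at positive z.

Region geometry defaults (length x diameter, um): soma 20 x 20,
hillock 40 x 3, SOCB 40 with a linear 3 -> 0.8 taper, narrow region 75 x 0.8,
axon 3000 x 1.  The axon hillock begins at the upper end of the soma and the
path ascends along a quarter-ellipse from the soma to the nerve fiber layer,
continuing horizontally (+x) once the curve is exhausted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import swc as swcmod

__all__ = [
    "REGIONS", "AXIAL_REGIONS", "SectionSpec", "TrajectorySpec", "Morphology",
    "default_sections", "elliptical_axon_path", "equivalent_cylinder_dendrite",
    "build_rgc", "discretize", "surface_area", "DEFAULT_DX",
]

REGIONS = ("dendrite", "soma", "hillock", "socb", "narrow", "axon")
AXIAL_REGIONS = ("soma", "hillock", "socb", "narrow", "axon")

# Optimized per-region compartment lengths (um) used by default.
DEFAULT_DX = {"dendrite": 10.0, "soma": 4.0, "hillock": 5.0,
              "socb": 5.0, "narrow": 5.0, "axon": 5.0}

NFL_DEPTH_DEFAULT = 15.0   # um below the retinal surface


@dataclass(frozen=True)
class SectionSpec:
    """One unbranched cell region: length and (possibly tapered) diameter, um."""

    region: str
    length: float
    proximal_diameter: float
    distal_diameter: float | None = None

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.length <= 0:
            raise ValueError("section length must be positive")
        d1 = self.distal_diameter if self.distal_diameter is not None else self.proximal_diameter
        if self.proximal_diameter <= 0 or d1 <= 0:
            raise ValueError("section diameters must be positive")

    @property
    def d_prox(self) -> float:
        return self.proximal_diameter

    @property
    def d_dist(self) -> float:
        return self.distal_diameter if self.distal_diameter is not None else self.proximal_diameter


@dataclass(frozen=True)
class TrajectorySpec:
    """Quarter-ellipse ascent of the axon from the soma to the nerve fiber layer."""

    soma_depth: float = 35.0         # um below the retinal surface
    nfl_depth: float = NFL_DEPTH_DEFAULT
    horizontal_reach: float = 150.0  # um, horizontal semi-axis of the ellipse

    def __post_init__(self):
        if not self.soma_depth > self.nfl_depth > 0:
            raise ValueError(
                f"require soma_depth > nfl_depth > 0, got soma_depth={self.soma_depth}, "
                f"nfl_depth={self.nfl_depth}")
        if self.horizontal_reach <= 0:
            raise ValueError("horizontal_reach must be positive")

    @property
    def rise(self) -> float:
        return self.soma_depth - self.nfl_depth


@dataclass
class Morphology:
    """Tree of cylindrical compartments (struct-of-arrays).

    ``arc`` is the arc-length coordinate (um) of each compartment center along
    the soma->axon path, measured from the proximal (deep) end of the soma;
    dendritic compartments carry NaN.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    length: np.ndarray
    d_prox: np.ndarray
    d_dist: np.ndarray
    region: np.ndarray          # array of region label strings
    parent: np.ndarray          # index into arrays, -1 for the root
    arc: np.ndarray

    def __len__(self) -> int:
        return len(self.x)

    @property
    def diameter(self) -> np.ndarray:
        """Mean (frustum) diameter per compartment, um."""
        return 0.5 * (self.d_prox + self.d_dist)

    @property
    def centers(self) -> np.ndarray:
        return np.column_stack([self.x, self.y, self.z])

    @property
    def is_axial(self) -> np.ndarray:
        return self.region != "dendrite"

    def region_index(self, region: str) -> np.ndarray:
        return np.flatnonzero(self.region == region)

    def validate(self) -> None:
        """Assert the structural invariants; raise ValueError on violation."""
        n = len(self)
        if n == 0:
            raise ValueError("empty morphology")
        if np.any(self.length <= 0) or np.any(self.d_prox <= 0) or np.any(self.d_dist <= 0):
            raise ValueError("lengths and diameters must be positive")
        if np.sum(self.parent == -1) != 1:
            raise ValueError("exactly one root required")
        for j, p in enumerate(self.parent):
            if p >= j:
                raise ValueError("parents must precede children (topological order)")
        arc = self.arc[self.is_axial]
        if not np.all(np.diff(arc) > 0):
            raise ValueError("arc length must increase strictly along the soma->axon path")
        order = [r for r in AXIAL_REGIONS]
        seen = [r for r in pd.unique(self.region[self.is_axial])]
        if seen != [r for r in order if r in seen] or seen[0] != "soma":
            raise ValueError(f"axial regions out of order: {seen}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": np.arange(len(self)),
            "parent": self.parent,
            "x": self.x, "y": self.y, "z": self.z,
            "length": self.length, "diameter": self.diameter,
            "region": self.region, "arc": self.arc,
        })


def default_sections(hillock_diameter: float = 3.0,
                     narrow_diameter: float = 0.8,
                     axon_length: float = 3000.0,
                     axon_diameter: float = 1.0) -> list[SectionSpec]:
    """Standard region geometry; the SOCB tapers from the hillock diameter down
    to the narrow-region diameter so the regions connect smoothly."""
    return [
        SectionSpec("soma", 20.0, 20.0),
        SectionSpec("hillock", 40.0, hillock_diameter),
        SectionSpec("socb", 40.0, hillock_diameter, narrow_diameter),
        SectionSpec("narrow", 75.0, narrow_diameter),
        SectionSpec("axon", axon_length, axon_diameter),
    ]


def _ellipse_polyline(spec: TrajectorySpec, n_dense: int = 4001):
    """Dense quarter-ellipse polyline from the soma vertex to the NFL vertex.

    Parameterized so the tangent is vertical at the soma vertex
    (0, 0, -soma_depth) and horizontal at the nerve-fiber-layer vertex
    (reach, 0, -nfl_depth).
    """
    a = spec.horizontal_reach
    b = spec.rise
    t = np.linspace(0.0, np.pi / 2.0, n_dense)
    x = a * (1.0 - np.cos(t))
    z = -spec.soma_depth + b * np.sin(t)
    pts = np.column_stack([x, np.zeros_like(x), z])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return pts, s


def elliptical_axon_path(spec: TrajectorySpec, n_points: int) -> np.ndarray:
    """Quarter-ellipse polyline (n_points x 3, um) resampled uniformly in arc
    length, ordered from the soma vertex to the nerve-fiber-layer vertex."""
    if n_points < 2:
        raise ValueError("n_points must be at least 2")
    pts, s = _ellipse_polyline(spec)
    target = np.linspace(0.0, s[-1], n_points)
    out = np.column_stack([np.interp(target, s, pts[:, k]) for k in range(3)])
    out[0] = (0.0, 0.0, -spec.soma_depth)
    out[-1] = (spec.horizontal_reach, 0.0, -spec.nfl_depth)
    return out


class _AxialPath:
    """Arc-length evaluator for soma (vertical) + ellipse + horizontal axon."""

    def __init__(self, spec: TrajectorySpec, soma_length: float, total_length: float):
        pts, s = _ellipse_polyline(spec)
        self.soma_length = soma_length
        self.curve_pts = pts
        self.curve_s = s + soma_length           # curve starts after the soma
        self.curve_end = float(self.curve_s[-1])
        self.spec = spec
        self.total = total_length

    def __call__(self, s):
        s = np.atleast_1d(np.asarray(s, dtype=float))
        out = np.empty((len(s), 3))
        soma_top = -self.spec.soma_depth
        for k, sk in enumerate(s):
            if sk <= self.soma_length:  # vertical soma segment below the vertex
                out[k] = (0.0, 0.0, soma_top - (self.soma_length - sk))
            elif sk <= self.curve_end:
                out[k] = [np.interp(sk, self.curve_s, self.curve_pts[:, i]) for i in range(3)]
            else:  # horizontal continuation in the nerve fiber layer
                out[k] = (self.spec.horizontal_reach + (sk - self.curve_end),
                          0.0, -self.spec.nfl_depth)
        return out


def equivalent_cylinder_dendrite() -> list[SectionSpec]:
    """Lumped-impedance dendrite: a 10 um x 4 um vertical stub descending from
    the soma, feeding two 810 um x 2 um horizontal branches (+x and -x), so the
    horizontal length totals 1620 um and the somatodendritic surface area
    matches the traced arbor it replaces."""
    return [
        SectionSpec("dendrite", 10.0, 4.0),    # vertical, -z
        SectionSpec("dendrite", 810.0, 2.0),   # +x branch
        SectionSpec("dendrite", 810.0, 2.0),   # -x branch
    ]


def _split_counts(length: float, dx: float) -> int:
    return max(1, math.ceil(length / dx - 1e-9))


def build_rgc(sections: list[SectionSpec] | None = None,
              trajectory: TrajectorySpec | None = None,
              dendrite_mode: str = "none",
              dendrite_source: "swcmod.SwcData | str | None" = None,
              per_region_dx: dict[str, float] | None = None,
              seed: int = 0) -> Morphology:
    """Build a discretized RGC morphology.

    Parameters
    ----------
    sections
        Region specs covering soma, hillock, socb, narrow, axon (in that
        order); defaults to :func:`default_sections`.
    trajectory
        Elliptical ascent of the axon; default soma depth 35 um, NFL depth
        15 um, reach 150 um.
    dendrite_mode
        ``"none"``, ``"equivalent-cylinder"``, or ``"branched-from-file"``
        (which reads ``dendrite_source``, an SWC path/``SwcData``; if absent, a
        synthetic tree with the standard somatodendritic area is generated from
        ``seed``).
    per_region_dx
        Target compartment lengths per region (um); defaults to the optimized
        values in :data:`DEFAULT_DX`.
    """
    if sections is None:
        sections = default_sections()
    if trajectory is None:
        trajectory = TrajectorySpec()
    dx = dict(DEFAULT_DX)
    if per_region_dx:
        dx.update(per_region_dx)

    order = {r: i for i, r in enumerate(AXIAL_REGIONS)}
    axial = sorted([s for s in sections if s.region != "dendrite"],
                   key=lambda s: order[s.region])
    if [s.region for s in axial] != list(AXIAL_REGIONS):
        raise ValueError("sections must cover soma, hillock, socb, narrow, axon exactly once")

    soma_len = axial[0].length
    total = sum(s.length for s in axial)
    path = _AxialPath(trajectory, soma_len, total)

    x, y, z, length, dp, dd, region, parent, arc = [], [], [], [], [], [], [], [], []

    def add(cx, cy, cz, L, d0, d1, reg, par, s_arc):
        x.append(cx); y.append(cy); z.append(cz)
        length.append(L); dp.append(d0); dd.append(d1)
        region.append(reg); parent.append(par); arc.append(s_arc)
        return len(x) - 1

    # --- axial path ---
    s0 = 0.0
    prev = -1
    for sec in axial:
        ncomp = _split_counts(sec.length, dx[sec.region])
        edges = s0 + np.linspace(0.0, sec.length, ncomp + 1)
        for i in range(ncomp):
            smid = 0.5 * (edges[i] + edges[i + 1])
            c = path(smid)[0]
            f0 = (edges[i] - s0) / sec.length
            f1 = (edges[i + 1] - s0) / sec.length
            d0 = sec.d_prox + (sec.d_dist - sec.d_prox) * f0
            d1 = sec.d_prox + (sec.d_dist - sec.d_prox) * f1
            prev = add(c[0], c[1], c[2], edges[i + 1] - edges[i], d0, d1,
                       sec.region, prev, smid)
        s0 += sec.length

    # --- dendrites, attached at the deep (proximal) end of the soma ---
    soma_bottom = np.array([0.0, 0.0, -trajectory.soma_depth - soma_len])
    root = 0
    if dendrite_mode == "none":
        pass
    elif dendrite_mode == "equivalent-cylinder":
        specs = equivalent_cylinder_dendrite()
        vert, plus, minus = specs
        ddx = dx["dendrite"]
        # vertical stub descending in -z
        nv = _split_counts(vert.length, ddx)
        par = root
        pos = soma_bottom.copy()
        for i in range(nv):
            L = vert.length / nv
            c = pos + np.array([0.0, 0.0, -(i + 0.5) * L])
            par = add(c[0], c[1], c[2], L, vert.d_prox, vert.d_dist, "dendrite", par, np.nan)
        stub_last = par
        stub_end = pos + np.array([0.0, 0.0, -vert.length])
        for branch, sign in ((plus, 1.0), (minus, -1.0)):
            nb = _split_counts(branch.length, ddx)
            par = stub_last
            for i in range(nb):
                L = branch.length / nb
                c = stub_end + np.array([sign * (i + 0.5) * L, 0.0, 0.0])
                par = add(c[0], c[1], c[2], L, branch.d_prox, branch.d_dist,
                          "dendrite", par, np.nan)
    elif dendrite_mode == "branched-from-file":
        if dendrite_source is None:
            data = swcmod.synthesize_dendrite(
                target_area=11560.0 - math.pi * 20.0 * 20.0, seed=seed)
        elif isinstance(dendrite_source, swcmod.SwcData):
            data = dendrite_source
        else:
            data = swcmod.read_swc(dendrite_source)
        index = {i: k for k, i in enumerate(data.ids)}
        root_k = int(np.flatnonzero(data.parent == -1)[0])
        offset = soma_bottom - data.xyz[root_k]
        comp_of_sample: dict[int, int] = {root_k: root}
        # samples are segments from parent sample to sample
        ksorted = _topo_order(data, index, root_k)
        for k in ksorted:
            p = data.parent[k]
            if p == -1:
                continue
            kp = index[p]
            a = data.xyz[kp] + offset
            b = data.xyz[k] + offset
            L = float(np.linalg.norm(b - a))
            if L <= 0:
                continue
            c = 0.5 * (a + b)
            par_comp = comp_of_sample[kp]
            comp_of_sample[k] = add(c[0], c[1], c[2], L,
                                    2.0 * data.radius[kp], 2.0 * data.radius[k],
                                    "dendrite", par_comp, np.nan)
    else:
        raise ValueError(f"unknown dendrite_mode {dendrite_mode!r}")

    morph = Morphology(np.asarray(x), np.asarray(y), np.asarray(z),
                       np.asarray(length), np.asarray(dp), np.asarray(dd),
                       np.asarray(region, dtype=object), np.asarray(parent),
                       np.asarray(arc))
    morph.validate()
    return morph


def _topo_order(data: swcmod.SwcData, index: dict, root_k: int) -> list[int]:
    """Sample indices ordered root-first so parents precede children."""
    children: dict[int, list[int]] = {}
    for k in range(len(data)):
        p = data.parent[k]
        if p != -1:
            children.setdefault(index[p], []).append(k)
    out, stack = [], [root_k]
    while stack:
        k = stack.pop()
        out.append(k)
        stack.extend(reversed(children.get(k, [])))
    return out


def discretize(morph: Morphology, per_region_dx: dict[str, float]) -> Morphology:
    """Split each compartment into the minimal number of equal pieces of length
    at most its region's dx.  Region boundaries are never straddled, arc length
    and linear taper are preserved, and the operation is idempotent."""
    for r, v in per_region_dx.items():
        if v <= 0:
            raise ValueError(f"dx for {r} must be positive")
    x, y, z, length, dp, dd, region, parent, arc = [], [], [], [], [], [], [], [], []
    new_index = {}
    for j in range(len(morph)):
        reg = morph.region[j]
        dx = per_region_dx.get(reg, np.inf)
        n = _split_counts(morph.length[j], dx)
        par = new_index[morph.parent[j]] if morph.parent[j] != -1 else -1
        # reconstruct the compartment axis from parent center (or use stored arc)
        L = morph.length[j] / n
        # direction of this compartment: from parent center toward own center
        if morph.parent[j] != -1:
            d = np.array([morph.x[j] - morph.x[morph.parent[j]],
                          morph.y[j] - morph.y[morph.parent[j]],
                          morph.z[j] - morph.z[morph.parent[j]]])
        else:
            d = np.array([0.0, 0.0, 1.0])
        norm = np.linalg.norm(d)
        d = d / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
        c0 = np.array([morph.x[j], morph.y[j], morph.z[j]]) - d * (morph.length[j] / 2.0)
        a0 = morph.arc[j] - morph.length[j] / 2.0
        for i in range(n):
            f0, f1 = i / n, (i + 1) / n
            c = c0 + d * ((i + 0.5) * L)
            x.append(c[0]); y.append(c[1]); z.append(c[2])
            length.append(L)
            dp.append(morph.d_prox[j] + (morph.d_dist[j] - morph.d_prox[j]) * f0)
            dd.append(morph.d_prox[j] + (morph.d_dist[j] - morph.d_prox[j]) * f1)
            region.append(reg)
            parent.append(par)
            arc.append(a0 + (i + 0.5) * L if np.isfinite(morph.arc[j]) else np.nan)
            par = len(x) - 1
        new_index[j] = par
    return Morphology(np.asarray(x), np.asarray(y), np.asarray(z),
                      np.asarray(length), np.asarray(dp), np.asarray(dd),
                      np.asarray(region, dtype=object), np.asarray(parent),
                      np.asarray(arc))


def surface_area(morph: Morphology, regions=None) -> float:
    """Lateral cylinder/frustum area pi * mean(d) * L (um^2) summed over the
    selected regions (all regions when ``regions`` is None)."""
    mask = np.ones(len(morph), dtype=bool)
    if regions is not None:
        regions = {regions} if isinstance(regions, str) else set(regions)
        mask = np.isin(morph.region.astype(str), list(regions))
    return float(np.sum(np.pi * morph.diameter[mask] * morph.length[mask]))
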