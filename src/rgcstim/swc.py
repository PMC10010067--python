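"""Minimal SWC reader/writer and a synthetic dendritic-tree generator.

SWC is the standard 7-column plain-text morphology format
(id, type, x, y, z, radius, parent).  Only the tree topology, coordinates and
radii are used here; type codes are not interpreted beyond sanity checks.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["SwcData", "read_swc", "write_swc", "synthesize_dendrite"]


@dataclass
class SwcData:
    """Columnar SWC samples. ``parent`` holds SWC ids (-1 for the root)."""

    ids: np.ndarray
    types: np.ndarray
    xyz: np.ndarray       # (n, 3) um
    radius: np.ndarray    # um
    parent: np.ndarray

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def diameters(self) -> np.ndarray:
        return 2.0 * self.radius

    def segment_lengths(self) -> np.ndarray:
        """Euclidean length of each non-root sample's segment to its parent."""
        index = {i: k for k, i in enumerate(self.ids)}
        out = []
        for k in range(len(self)):
            p = self.parent[k]
            if p == -1:
                continue
            out.append(float(np.linalg.norm(self.xyz[k] - self.xyz[index[p]])))
        return np.asarray(out)

    def total_length(self) -> float:
        return float(self.segment_lengths().sum())

    def lateral_area(self) -> float:
        """Sum of frustum lateral areas pi * mean(d) * L over segments (um^2)."""
        index = {i: k for k, i in enumerate(self.ids)}
        area = 0.0
        for k in range(len(self)):
            p = self.parent[k]
            if p == -1:
                continue
            kp = index[p]
            length = float(np.linalg.norm(self.xyz[k] - self.xyz[kp]))
            area += np.pi * (self.radius[k] + self.radius[kp]) * length
        return float(area)

    def bounding_box_xy(self) -> tuple[float, float]:
        span = self.xyz.max(axis=0) - self.xyz.min(axis=0)
        return float(span[0]), float(span[1])


class SwcFormatError(ValueError):
    pass


def read_swc(file) -> SwcData:
    """Read an SWC file (path, or open text handle).

    Validates that parents exist and precede no cycle, that there is exactly
    one root, and that all radii are positive.
    """
    if hasattr(file, "read"):
        text = file.read()
    else:
        text = Path(file).read_text()
    ids, types, xyz, radius, parent = [], [], [], [], []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) != 7:
            raise SwcFormatError(f"line {lineno}: expected 7 columns, got {len(cols)}")
        try:
            ids.append(int(cols[0]))
            types.append(int(cols[1]))
            xyz.append([float(c) for c in cols[2:5]])
            radius.append(float(cols[5]))
            parent.append(int(cols[6]))
        except ValueError as exc:
            raise SwcFormatError(f"line {lineno}: non-numeric field ({exc})") from None
    if len(ids) < 2:
        raise SwcFormatError("SWC file must contain at least two samples")
    ids_a = np.asarray(ids)
    if len(np.unique(ids_a)) != len(ids_a):
        raise SwcFormatError("duplicate sample ids")
    radius_a = np.asarray(radius, dtype=float)
    if np.any(radius_a <= 0):
        raise SwcFormatError("non-positive radius")
    parent_a = np.asarray(parent)
    roots = np.sum(parent_a == -1)
    if roots != 1:
        raise SwcFormatError(f"expected exactly one root, found {roots}")
    idset = set(ids)
    index = {i: k for k, i in enumerate(ids)}
    for k, p in enumerate(parent):
        if p == -1:
            continue
        if p == ids[k]:
            raise SwcFormatError(f"sample {ids[k]} is its own parent")
        if p not in idset:
            raise SwcFormatError(f"sample {ids[k]} references missing parent {p}")
    # cycle check by walking to the root from every node
    for k in range(len(ids)):
        seen = set()
        cur = k
        while parent[cur] != -1:
            if cur in seen:
                raise SwcFormatError("cyclic parent references")
            seen.add(cur)
            cur = index[parent[cur]]
    return SwcData(ids_a, np.asarray(types), np.asarray(xyz, dtype=float),
                   radius_a, parent_a)


def write_swc(data: SwcData, file) -> None:
    """Write samples in standard 7-column SWC form."""
    buf = io.StringIO()
    buf.write("# id type x y z radius parent\n")
    for k in range(len(data)):
        x, y, z = data.xyz[k]
        buf.write(f"{data.ids[k]} {data.types[k]} {x:.6g} {y:.6g} {z:.6g} "
                  f"{data.radius[k]:.6g} {data.parent[k]}\n")
    if hasattr(file, "write"):
        file.write(buf.getvalue())
    else:
        Path(file).write_text(buf.getvalue())


def synthesize_dendrite(target_area: float,
                        field_extent: tuple[float, float] = (168.0, 183.0),
                        seed: int = 0,
                        n_primary: int = 5,
                        branch_depth: int = 6) -> SwcData:
    """Generate a random planar binary-branching dendritic tree as SWC samples.

    The tree stands in for an ex-vivo tracing of a mid-peripheral parasol
    cell: ``n_primary`` stems radiate from the origin in the x-y plane
    (drooping slightly in -z) and bifurcate ``branch_depth`` times with random
    headings, giving a few millimeters of total dendritic length at roughly
    micron diameters that taper with branch order — the length/diameter
    balance matters because the passive load the arbor puts on the soma
    depends on how a given membrane area is distributed.  Diameters are
    finally rescaled (lateral area is linear in diameter) so the total
    lateral surface area matches ``target_area`` exactly, well within the 1%
    contract.  The x-y bounding box is kept inside ``field_extent`` by
    construction.  Deterministic for a fixed seed.
    """
    if target_area <= 0:
        raise ValueError("target_area must be positive")
    ex, ey = field_extent
    if ex <= 0 or ey <= 0:
        raise ValueError("field_extent must be positive")
    rng = np.random.default_rng(seed)

    half = np.array([ex, ey]) / 2.0
    ids = [1]
    types = [1]
    xyz = [np.zeros(3)]
    radius = [0.7]
    parent = [-1]
    next_id = 2

    def add_sample(pos, rad, par):
        nonlocal next_id
        ids.append(next_id)
        types.append(3)
        xyz.append(pos)
        radius.append(rad)
        parent.append(par)
        next_id += 1
        return next_id - 1

    base_step = min(ex, ey) / 3.6

    def grow(par_id, pos, heading, depth):
        step = float(rng.uniform(0.7, 1.0)) * base_step * 0.65 ** depth
        new = pos + step * np.array([np.cos(heading), np.sin(heading), 0.0])
        new[2] = pos[2] - float(rng.uniform(0.0, 1.5))  # gentle droop
        new[:2] = np.clip(new[:2], -half * 0.98, half * 0.98)
        rad = max(0.2, 0.7 * 0.82 ** depth)
        sid = add_sample(new, rad, par_id)
        if depth < branch_depth:
            spread = float(rng.uniform(0.35, 0.8))
            grow(sid, new, heading + spread, depth + 1)
            grow(sid, new, heading - spread, depth + 1)

    for k in range(n_primary):
        heading = 2.0 * np.pi * k / n_primary + float(rng.uniform(-0.3, 0.3))
        grow(1, xyz[0], heading, 0)

    data = SwcData(np.asarray(ids), np.asarray(types),
                   np.asarray(xyz, dtype=float), np.asarray(radius, dtype=float),
                   np.asarray(parent))
    area = data.lateral_area()
    scale = target_area / area
    if scale > 40.0:
        raise ValueError(
            f"infeasible extent/area combination: would need a {scale:.0f}x "
            "diameter scale-up; enlarge field_extent or lower target_area")
    data.radius *= scale
    return data
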