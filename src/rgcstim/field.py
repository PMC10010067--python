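"""Extracellular potential sources and stimulus waveforms.

Quasi-static assumption: retinal tissue is purely resistive at stimulation
frequencies, so the potential field computed for a unit electrode current is
simply scaled by the instantaneous stimulus current.  All sources therefore
return potential per unit current (mV uA^-1) at 3D points in um; the tissue
occupies z < 0 and the sources place the return electrode at infinity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "FieldSource", "DiscElectrode", "PointSource", "PulseWaveform",
    "disc_electrode_potential", "point_source_potential", "waveform_value",
    "load_potential_table", "save_potential_table",
]

SIGMA_DEFAULT = 1.0        # S m^-1, homogeneous half-space conductivity
DISC_DIAMETER_DEFAULT = 200.0  # um, Argus II - scale electrode


def disc_electrode_potential(points, center, radius: float,
                             sigma: float = SIGMA_DEFAULT) -> np.ndarray:
    """Potential per unit current (mV uA^-1) of an equipotential disc electrode
    on the surface of a semi-infinite conductive medium (Wiley-Webster
    solution).

    phi(r, z) = I/(4 sigma a) * (2/pi) * arcsin(2a / (sqrt((r-a)^2+z^2)
                + sqrt((r+a)^2+z^2))), in electrode-centered cylindrical
    coordinates.  Points on the disc itself return the disc potential
    I/(4 sigma a) by continuity.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    center = np.asarray(center, dtype=float)
    rel = pts - center
    r = np.hypot(rel[:, 0], rel[:, 1])
    z = rel[:, 2]
    a = radius
    denom = np.sqrt((r - a) ** 2 + z ** 2) + np.sqrt((r + a) ** 2 + z ** 2)
    arg = np.clip(2.0 * a / denom, -1.0, 1.0)
    # unit analysis: 1 uA / (4 * sigma[S/m] * a[um]) = 1/(4 sigma a) V = same in mV/uA
    phi0 = 1.0 / (4.0 * sigma * a * 1e-6) * 1e-6 * 1e3  # mV per uA on the disc
    phi = phi0 * (2.0 / np.pi) * np.arcsin(arg)
    return phi if np.ndim(points) > 1 else phi


def point_source_potential(points, position, sigma: float = SIGMA_DEFAULT) -> np.ndarray:
    """Point current source on the boundary of a semi-infinite medium:
    phi = I/(2 pi sigma d) (mV uA^-1), twice the infinite-medium value by the
    method of images."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    d = np.linalg.norm(pts - np.asarray(position, dtype=float), axis=1)
    if np.any(d == 0):
        raise ValueError("field point coincides with the source")
    return 1.0 / (2.0 * np.pi * sigma * d * 1e-6) * 1e-6 * 1e3


@dataclass(frozen=True)
class FieldSource:
    """A unit-current extracellular potential source."""

    kind: str
    center: tuple[float, float, float]
    radius: float = 0.0
    sigma: float = SIGMA_DEFAULT

    def unit_potentials(self, points) -> np.ndarray:
        """mV per uA of electrode current at each point (n x 3 um)."""
        if self.kind == "disc":
            return disc_electrode_potential(points, self.center, self.radius, self.sigma)
        if self.kind == "point":
            return point_source_potential(points, self.center, self.sigma)
        raise ValueError(f"unknown source kind {self.kind!r}")

    def at(self, center) -> "FieldSource":
        return FieldSource(self.kind, tuple(float(c) for c in center),
                           self.radius, self.sigma)


def DiscElectrode(center=(0.0, 0.0, 50.0), diameter: float = DISC_DIAMETER_DEFAULT,
                  sigma: float = SIGMA_DEFAULT) -> FieldSource:
    return FieldSource("disc", tuple(center), diameter / 2.0, sigma)


def PointSource(center=(0.0, 0.0, 50.0), sigma: float = SIGMA_DEFAULT) -> FieldSource:
    return FieldSource("point", tuple(center), 0.0, sigma)


@dataclass(frozen=True)
class PulseWaveform:
    """Charge-balanced biphasic current pulse (cathodic phase first).

    ``amplitude`` is the per-phase current magnitude in uA; the signed current
    is -amplitude during the leading cathodic phase and +amplitude during the
    return phase.
    """

    amplitude: float
    phase_width: float = 0.45   # ms per phase
    interphase_gap: float = 0.0
    onset: float = 1.0          # ms

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        if self.phase_width <= 0:
            raise ValueError("phase_width must be positive")

    @property
    def end(self) -> float:
        return self.onset + 2.0 * self.phase_width + self.interphase_gap

    def value(self, t) -> np.ndarray | float:
        return waveform_value(self, t)

    def with_amplitude(self, amplitude: float) -> "PulseWaveform":
        return PulseWaveform(amplitude, self.phase_width, self.interphase_gap, self.onset)


def waveform_value(pulse: PulseWaveform, t):
    """Signed electrode current (uA) at time(s) ``t`` (ms)."""
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t, dtype=float)
    t0 = pulse.onset
    t1 = t0 + pulse.phase_width
    t2 = t1 + pulse.interphase_gap
    t3 = t2 + pulse.phase_width
    out = np.where((t >= t0) & (t < t1), -pulse.amplitude, out)
    out = np.where((t >= t2) & (t < t3), pulse.amplitude, out)
    return float(out) if out.ndim == 0 else out


def save_potential_table(path, values, source_current: float = 1e-6,
                         comment: str = "") -> None:
    """Write one potential per line (mV at ``source_current`` amperes)."""
    lines = ["# extracellular potential table (mV)",
             f"# source_current_A = {source_current:g}"]
    if comment:
        lines.append(f"# {comment}")
    lines += [f"{v:.10g}" for v in np.asarray(values, dtype=float)]
    Path(path).write_text("\n".join(lines) + "\n")


def load_potential_table(path, morph=None) -> np.ndarray:
    """Read per-compartment extracellular potentials and rescale to mV uA^-1.

    The file holds one value per line (optionally ``id value``); ``#`` lines
    are comments and may declare ``source_current_A = <amps>`` (default 1e-6,
    i.e. the table is already per uA; a table computed for a 1 A source
    declares 1.0 and is scaled by 1e-6).  If ``morph`` is given the row count
    must match its compartment count.
    """
    source_current = 1e-6
    values = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            if "source_current_A" in s and "=" in s:
                source_current = float(s.split("=", 1)[1])
            continue
        cols = s.split()
        try:
            values.append(float(cols[-1]))
        except ValueError:
            raise ValueError(f"{path}: non-numeric value on line {lineno}") from None
    vals = np.asarray(values, dtype=float)
    if morph is not None and len(vals) != len(morph):
        raise ValueError(
            f"{path}: {len(vals)} rows but morphology has {len(morph)} compartments")
    # rescale so the returned vector is mV per uA
    return vals * (1e-6 / source_current)
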