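"""Activation threshold search and threshold maps/profiles.

Threshold is found by bisection on the stimulus amplitude to a 0.1 uA bracket
width.  "Activation" means a propagating spike at the distal axon by default
(somatic invasion can fail at small axon diameters without abolishing the
propagating response); the criterion compartment is configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cable
from .cable import CableSystem, SolverConfig, simulate
from .field import FieldSource, PulseWaveform

__all__ = ["ThresholdResult", "ElectrodeGrid", "find_threshold",
           "threshold_map", "threshold_profile", "BracketError"]

DEFAULT_TOLERANCE = 0.1   # uA
BRACKET_START = 100.0     # uA
BRACKET_CAP = 1600.0      # uA


class BracketError(RuntimeError):
    pass


@dataclass
class ThresholdResult:
    threshold: float            # uA (upper end of the final bracket)
    bracket: tuple[float, float]
    iterations: int
    initiation_region: str | None = None
    initiation_arc: float | None = None


@dataclass(frozen=True)
class ElectrodeGrid:
    """Electrode positions on a regular x-y grid above the retina."""

    step: float = 50.0       # um
    extent: tuple[float, float] = (1000.0, 1000.0)   # um, full span
    height: float = 50.0     # um above the retinal surface
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("step must be positive")

    def offsets(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis offsets including both endpoints."""
        ex, ey = self.extent
        nx = int(round(ex / self.step))
        ny = int(round(ey / self.step))
        xs = self.center[0] + (np.arange(nx + 1) - nx / 2.0) * self.step
        ys = self.center[1] + (np.arange(ny + 1) - ny / 2.0) * self.step
        return xs, ys

    @property
    def n_nodes(self) -> int:
        xs, ys = self.offsets()
        return len(xs) * len(ys)


def _spikes_at(system: CableSystem, ve_unit, pulse: PulseWaveform, amplitude: float,
               config: SolverConfig, criterion_comp: int,
               record_all: bool) -> tuple[bool, cable.SimulationResult]:
    cfg = SolverConfig(config.dt, config.duration, config.equilibration,
                       None if record_all else np.array([criterion_comp]),
                       config.record_every)
    res = simulate(system, ve_unit, pulse.with_amplitude(amplitude), cfg)
    return len(res.spike_times(criterion_comp)) > 0, res


def find_threshold(system: CableSystem, field_source: FieldSource | None = None,
                   electrode_pos=None, *, ve_unit=None,
                   pulse: PulseWaveform | None = None,
                   tolerance: float = DEFAULT_TOLERANCE,
                   initial_bracket: tuple[float, float] = (0.0, BRACKET_START),
                   config: SolverConfig | None = None,
                   criterion: str = "distal_axon",
                   locate_initiation: bool = False) -> ThresholdResult:
    """Bisection search for the activation threshold (uA).

    Either pass a ``field_source`` plus ``electrode_pos`` (um) or a
    precomputed per-compartment unit-potential vector ``ve_unit``.  The upper
    bracket doubles (up to 1600 uA) until suprathreshold; bisection then
    narrows the bracket to ``tolerance`` and the reported threshold is the
    upper (spiking) end.
    """
    if ve_unit is None:
        if field_source is None:
            raise ValueError("provide either ve_unit or field_source")
        src = field_source.at(electrode_pos) if electrode_pos is not None else field_source
        ve_unit = src.unit_potentials(system.morph.centers)
    if pulse is None:
        pulse = PulseWaveform(1.0)
    if config is None:
        config = SolverConfig()
    crit = system.landmark(criterion)

    lo, hi = initial_bracket
    iters = 0
    spiking, _ = _spikes_at(system, ve_unit, pulse, hi, config, crit, False)
    iters += 1
    while not spiking:
        if hi >= BRACKET_CAP:
            raise BracketError(
                f"bracket failure: no spike at {hi:g} uA (cap {BRACKET_CAP:g} uA)")
        lo, hi = hi, min(2.0 * hi, BRACKET_CAP)
        spiking, _ = _spikes_at(system, ve_unit, pulse, hi, config, crit, False)
        iters += 1
    if lo > 0:
        low_spiking, _ = _spikes_at(system, ve_unit, pulse, lo, config, crit, False)
        iters += 1
        if low_spiking:
            hi = lo
            lo = 0.0
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        spiking, _ = _spikes_at(system, ve_unit, pulse, mid, config, crit, False)
        iters += 1
        if spiking:
            hi = mid
        else:
            lo = mid
    result = ThresholdResult(hi, (lo, hi), iters)
    if locate_initiation:
        _, res = _spikes_at(system, ve_unit, pulse, hi, config, crit, True)
        region, arc = cable.initiation_site(res, system.morph)
        result.initiation_region = region
        result.initiation_arc = arc
    return result


def threshold_map(system: CableSystem, grid: ElectrodeGrid,
                  field_source: FieldSource | None = None,
                  pulse: PulseWaveform | None = None,
                  config: SolverConfig | None = None,
                  tolerance: float = DEFAULT_TOLERANCE) -> pd.DataFrame:
    """Thresholds over an electrode grid; one row per node, ordered by (x, y).

    Nodes where the bracket search fails are recorded with NaN threshold
    rather than aborting the map.  Nodes are independent: the result does not
    depend on evaluation order.
    """
    from .field import DiscElectrode
    if field_source is None:
        field_source = DiscElectrode()
    xs, ys = grid.offsets()
    rows = []
    for x in xs:
        for y in ys:
            pos = (float(x), float(y), grid.height)
            try:
                r = find_threshold(system, field_source, pos, pulse=pulse,
                                   config=config, tolerance=tolerance)
                rows.append({"x": x, "y": y, "threshold": r.threshold,
                             "iterations": r.iterations, "error": ""})
            except BracketError as exc:
                rows.append({"x": x, "y": y, "threshold": np.nan,
                             "iterations": 0, "error": str(exc)})
    return pd.DataFrame(rows)


def socb_geometry(system: CableSystem, electrode_pos) -> tuple[float, float]:
    """(distance um, angle deg) of the sodium channel band relative to an
    electrode position: distance from the electrode center to the SOCB center,
    angle as the x-z incline of the line from the first to the last SOCB
    compartment (0 deg = horizontal)."""
    m = system.morph
    idx = m.region_index("socb")
    center = m.centers[idx].mean(axis=0)
    dist = float(np.linalg.norm(np.asarray(electrode_pos, dtype=float) - center))
    first, last = m.centers[idx[0]], m.centers[idx[-1]]
    dx = last[0] - first[0]
    dz = last[2] - first[2]
    angle = math.degrees(math.atan2(dz, dx))
    return dist, angle


def threshold_profile(system: CableSystem, x_offsets, height: float = 50.0,
                      field_source: FieldSource | None = None,
                      pulse: PulseWaveform | None = None,
                      config: SolverConfig | None = None,
                      tolerance: float = DEFAULT_TOLERANCE) -> pd.DataFrame:
    """Thresholds as the electrode moves horizontally along the axon (y = 0),
    annotated with the SOCB-electrode distance and the SOCB incline angle."""
    from .field import DiscElectrode
    if field_source is None:
        field_source = DiscElectrode()
    x_offsets = np.asarray(x_offsets, dtype=float)
    if np.any(np.diff(x_offsets) < 0):
        raise ValueError("x_offsets must be sorted")
    rows = []
    for x in x_offsets:
        pos = (float(x), 0.0, height)
        dist, angle = socb_geometry(system, pos)
        try:
            r = find_threshold(system, field_source, pos, pulse=pulse,
                               config=config, tolerance=tolerance)
            thr = r.threshold
            err = ""
        except BracketError as exc:
            thr, err = np.nan, str(exc)
        rows.append({"x": x, "threshold": thr, "socb_distance": dist,
                     "socb_angle": angle, "error": err})
    return pd.DataFrame(rows)
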