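"""Scripted sensitivity studies: dendrite representation, axon trajectory,
axon diameter, discretization, and activating-function threshold predictors.

Each study runs on the analytic disc-electrode field in a homogeneous
half-space (an imported potential table can be substituted through the
library API).  Absolute thresholds therefore differ from values obtained with
a layered finite-element tissue model; the study surface is the qualitative
structure: where minima sit, how trajectories and diameters reorder
thresholds, and how discretization changes predictions.

``scale="desk"`` (default) runs reduced grids suited to a laptop;
``scale="full"`` runs the full 21 x 21 grids.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cable, morphology, predictors, threshold
from .field import DiscElectrode, PulseWaveform
from .morphology import TrajectorySpec, build_rgc, default_sections
from .threshold import ElectrodeGrid

__all__ = ["ExperimentConfig", "run_dendrite_comparison", "run_trajectory_sweep",
           "run_diameter_sweep", "run_discretization_sweep",
           "run_predictor_evaluation", "STUDIES", "run_study"]


@dataclass
class ExperimentConfig:
    study: str = ""
    scale: str = "desk"            # "desk" or "full"
    seed: int = 0
    out_dir: str | Path | None = None
    soma_depth: float = 35.0
    nfl_depth: float = 15.0
    reach: float = 150.0
    electrode: dict = dc_field(default_factory=dict)   # DiscElectrode overrides
    solver: dict = dc_field(default_factory=dict)      # SolverConfig overrides

    def grid(self) -> ElectrodeGrid:
        if self.scale == "full":
            return ElectrodeGrid(step=50.0, extent=(1000.0, 1000.0))
        # desk: 5 x 5 nodes at a step that still resolves the cell-scale
        # structure a 200 um disc can distinguish
        return ElectrodeGrid(step=125.0, extent=(500.0, 500.0))

    def source(self) -> "DiscElectrode":
        return DiscElectrode(**self.electrode) if self.electrode else DiscElectrode()

    def solver_config(self) -> cable.SolverConfig:
        return cable.SolverConfig(**self.solver) if self.solver else cable.SolverConfig()

    def trajectory(self) -> TrajectorySpec:
        return TrajectorySpec(self.soma_depth, self.nfl_depth, self.reach)


def _write(df: pd.DataFrame, cfg: ExperimentConfig, name: str) -> None:
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / name, index=False)


def _cell(cfg: ExperimentConfig, dendrite_mode: str = "none", sections=None,
          dendrite_source=None, channels=None):
    m = build_rgc(sections=sections, trajectory=cfg.trajectory(),
                  dendrite_mode=dendrite_mode, dendrite_source=dendrite_source,
                  seed=cfg.seed)
    system = cable.assemble(m, channels=channels)
    cable.equilibrate(system)
    return system


def run_dendrite_comparison(config: ExperimentConfig) -> dict:
    """Threshold maps for branched, equivalent-cylinder, and dendrite-free
    variants of the standard cell, with per-variant minima and their
    locations."""
    variants = {}
    for mode in ("branched-from-file", "equivalent-cylinder", "none"):
        system = _cell(config, dendrite_mode=mode)
        df = threshold.threshold_map(system, config.grid(),
                                     field_source=config.source(),
                                     config=config.solver_config())
        _write(df, config, f"dendrite_map_{mode}.csv")
        socb = system.morph.region_index("socb")
        socb_x = (float(system.morph.x[socb].min()), float(system.morph.x[socb].max()))
        i = int(df["threshold"].idxmin())
        variants[mode] = {
            "map": df,
            "min_threshold": float(df["threshold"][i]),
            "min_location": (float(df["x"][i]), float(df["y"][i])),
            "socb_x_range": socb_x,
        }
    summary = pd.DataFrame({
        "variant": list(variants),
        "min_threshold": [variants[k]["min_threshold"] for k in variants],
        "min_x": [variants[k]["min_location"][0] for k in variants],
        "min_y": [variants[k]["min_location"][1] for k in variants],
    })
    _write(summary, config, "dendrite_summary.csv")
    return {"variants": variants, "summary": summary}


def run_trajectory_sweep(config: ExperimentConfig,
                         soma_depths=(35.0, 55.0, 75.0),
                         reach_factors=(1.0, 2.0, 4.0, 8.0)) -> dict:
    """Threshold profiles along the axon for elliptical trajectories of
    varying steepness (reach = factor x rise) and soma depth.

    Reports, per depth, the maximum near-soma threshold decrease between the
    most gradual and the steepest trajectory.
    """
    if config.scale == "full":
        xs = np.arange(-100.0, 525.0, 25.0)
    else:
        xs = np.array([-50.0, 0.0, 50.0, 100.0, 150.0, 250.0, 400.0])
    near_soma = xs[np.abs(xs) <= 100.0]
    profiles = []
    decreases = {}
    for depth in soma_depths:
        rise = depth - config.nfl_depth
        per_reach = {}
        for f in reach_factors:
            traj = TrajectorySpec(depth, config.nfl_depth, f * rise)
            m = build_rgc(trajectory=traj)
            system = cable.assemble(m)
            cable.equilibrate(system)
            prof = threshold.threshold_profile(
                system, xs, field_source=config.source(),
                config=config.solver_config())
            prof["soma_depth"] = depth
            prof["reach_factor"] = f
            profiles.append(prof)
            per_reach[f] = prof
        steep = per_reach[min(reach_factors)]
        gradual = per_reach[max(reach_factors)]
        mask = np.isin(steep["x"], near_soma)
        dec = (gradual["threshold"][mask] - steep["threshold"][mask]) / gradual["threshold"][mask]
        decreases[depth] = float(np.max(dec) * 100.0)
    table = pd.concat(profiles, ignore_index=True)
    _write(table, config, "trajectory_profiles.csv")
    dec_df = pd.DataFrame({"soma_depth": list(decreases),
                           "max_near_soma_decrease_pct": list(decreases.values())})
    _write(dec_df, config, "trajectory_decreases.csv")
    return {"profiles": table, "max_decrease_pct": decreases}


def run_diameter_sweep(config: ExperimentConfig,
                       hillock_diameters=(4.0, 3.0, 2.0),
                       narrow_diameters=(0.8,),
                       offsets=(0.0,),
                       channels=None,
                       amplitude_factor: float = 1.25) -> pd.DataFrame:
    """Propagation-regime table over hillock and narrow-region diameters.

    Uses the branched-dendrite standard cell.  At each (hillock d, narrow d,
    electrode offset) the activation threshold is found and the response to a
    mildly suprathreshold pulse (``amplitude_factor`` x threshold) is
    classified as bidirectional, echo_spike, soma_failure, or no_spike; at
    exactly threshold the initiating spike is marginal by construction, so a
    small suprathreshold margin probes the propagation regime rather than the
    threshold bracket.  ``channels`` optionally overrides the conductance
    table (e.g. raised Na+/K+ density in the narrow region).
    """
    rows = []
    for hd in hillock_diameters:
        for nd in narrow_diameters:
            sections = default_sections(hillock_diameter=hd, narrow_diameter=nd)
            system = _cell(config, dendrite_mode="branched-from-file",
                           sections=sections, channels=channels)
            for xoff in offsets:
                pos = (xoff, 0.0, config.source().center[2])
                try:
                    r = threshold.find_threshold(
                        system, config.source(), pos,
                        config=config.solver_config())
                    ve = config.source().at(pos).unit_potentials(system.morph.centers)
                    res = cable.simulate(system, ve,
                                         PulseWaveform(amplitude_factor * r.threshold),
                                         config.solver_config())
                    label = cable.classify_propagation(res, system.morph, system)
                    thr = r.threshold
                except threshold.BracketError:
                    label, thr = "no_spike", np.nan
                rows.append({"hillock_d": hd, "narrow_d": nd, "x_offset": xoff,
                             "threshold": thr, "classification": label})
    df = pd.DataFrame(rows)
    _write(df, config, "diameter_sweep.csv")
    return df


def run_discretization_sweep(config: ExperimentConfig,
                             dts_us=(1.0, 2.0, 5.0, 10.0, 20.0, 50.0),
                             electrode_offsets=(0.0, 150.0)) -> dict:
    """Threshold change versus spatial and temporal resolution.

    The reference is dx = 1 um / dt = 1 us; the optimized settings are the
    per-region section lengths in :data:`morphology.DEFAULT_DX` and dt = 5 us.
    Reports percent threshold change per setting and wall time.
    """
    fine_dx = {r: 1.0 for r in morphology.REGIONS}
    rows = []
    for xoff in electrode_offsets:
        pos = (xoff, 0.0, config.source().center[2])
        # spatial: optimized vs reference at dt = 5 us
        thr_dx = {}
        for label, dx in (("reference_dx1um", fine_dx), ("optimized", None)):
            t0 = time.perf_counter()
            m = build_rgc(trajectory=config.trajectory(), per_region_dx=dx)
            system = cable.assemble(m)
            cable.equilibrate(system)
            r = threshold.find_threshold(system, config.source(), pos)
            thr_dx[label] = r.threshold
            rows.append({"kind": "dx", "setting": label, "x_offset": xoff,
                         "threshold": r.threshold, "n_compartments": len(m),
                         "wall_s": time.perf_counter() - t0})
        # temporal: dt sweep on the optimized cell
        m = build_rgc(trajectory=config.trajectory())
        system = cable.assemble(m)
        cable.equilibrate(system)
        base = None
        for dt_us in dts_us:
            t0 = time.perf_counter()
            r = threshold.find_threshold(
                system, config.source(), pos,
                config=cable.SolverConfig(dt=dt_us * 1e-3))
            if base is None:
                base = r.threshold
            rows.append({"kind": "dt", "setting": f"{dt_us:g}us", "x_offset": xoff,
                         "threshold": r.threshold, "n_compartments": len(m),
                         "wall_s": time.perf_counter() - t0,
                         "change_pct": 100.0 * (r.threshold - base) / base})
    df = pd.DataFrame(rows)
    _write(df, config, "discretization_sweep.csv")
    dx_rows = df[df["kind"] == "dx"]
    return {"table": df,
            "dx_threshold_change_uA": {
                x: float(abs(dx_rows[(dx_rows.x_offset == x)
                                     & (dx_rows.setting == "optimized")].threshold.iloc[0]
                             - dx_rows[(dx_rows.x_offset == x)
                                       & (dx_rows.setting == "reference_dx1um")].threshold.iloc[0]))
                for x in electrode_offsets}}


def run_predictor_evaluation(config: ExperimentConfig, n_weighted_range=(1, 50)) -> dict:
    """Activating-function predictor evaluation over a population of electrode
    positions, with exponential threshold-distance fits and a weighted-AF
    sweep over the number of summed compartments."""
    system = _cell(config, dendrite_mode="none")
    result = predictors.evaluate_predictors(
        system, config.grid(), config.source(),
        config=config.solver_config())
    table = result["table"]
    _write(table, config, "predictor_table.csv")
    # weighted-AF sweep over n
    w = result["weights"]
    pf_idx = np.flatnonzero(system.morph.is_axial)
    w_axial = w[pf_idx]
    n_lo, n_hi = n_weighted_range
    n_values = range(n_lo, min(n_hi, len(w_axial)) + 1)
    sweep_rows = []
    src = config.source()
    for _, row in table.iterrows():
        ve_unit = src.at((row.x, row.y, src.center[2])).unit_potentials(system.morph.centers)
        pf = predictors.path_field(system.morph, ve_unit * (-row.threshold))
        af = predictors.activating_function(pf)
        for nn in n_values:
            sweep_rows.append({"x": row.x, "y": row.y, "n": nn,
                               "score": predictors.weighted_af(af, w_axial, nn)})
    sweep = pd.DataFrame(sweep_rows)
    _write(sweep, config, "weighted_af_sweep.csv")
    if config.out_dir is not None:
        (Path(config.out_dir) / "predictor_fits.json").write_text(
            json.dumps({"fits": result["fits"], "summary": result["summary"]}, indent=2))
    result["weighted_af_sweep"] = sweep
    return result


STUDIES = {
    "dendrites": run_dendrite_comparison,
    "trajectory": run_trajectory_sweep,
    "diameter": run_diameter_sweep,
    "discretization": run_discretization_sweep,
    "predictors": run_predictor_evaluation,
}


def run_study(name: str, config: ExperimentConfig):
    if name not in STUDIES:
        raise ValueError(f"unknown study {name!r}; choose from {sorted(STUDIES)}")
    config.study = name
    return STUDIES[name](config)
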