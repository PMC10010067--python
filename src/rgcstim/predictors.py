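"""Activating-function threshold predictors and their evaluation.

The activating function (AF) is the second spatial derivative of the
extracellular potential along the fiber, the first-order driver of membrane
polarization.  Three predictor variants are provided: the plain AF along the
soma->axon arc, the instantaneous passive transmembrane current after one
time step (which folds in axial-resistance differences from non-uniform
diameters), and the weighted AF of Esler and colleagues, where each
compartment's AF value is scaled by its passive influence on the sodium
channel band (SOCB) and the top-n weighted values are summed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.sparse.linalg

from . import cable
from .cable import CableSystem, SolverConfig
from .field import FieldSource, PulseWaveform
from .morphology import Morphology

__all__ = ["PathField", "path_field", "activating_function",
           "passive_instantaneous_current", "compartment_weights",
           "weighted_af", "fit_threshold_distance", "evaluate_predictors"]


@dataclass
class PathField:
    """Extracellular potential sampled along the soma->axon path (dendrites
    excluded).  ``arc`` strictly increasing, um; ``ve`` mV; ``region`` labels;
    ``index`` the compartment indices into the parent morphology."""

    arc: np.ndarray
    ve: np.ndarray
    region: np.ndarray
    index: np.ndarray


def path_field(morph: Morphology, ve: np.ndarray) -> PathField:
    """Restrict a per-compartment potential vector to the axial path."""
    mask = morph.is_axial
    idx = np.flatnonzero(mask)
    return PathField(morph.arc[idx], np.asarray(ve, dtype=float)[idx],
                     morph.region[idx], idx)


def activating_function(path: PathField) -> np.ndarray:
    """Second derivative of V_e with respect to arc length (mV um^-2 per unit
    of the supplied potential), by the three-point finite-difference formula
    for unequal spacing; one-sided second differences at the two endpoints."""
    x, f = path.arc, path.ve
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 compartments for a second derivative")
    out = np.empty(n)
    h1 = x[1:-1] - x[:-2]
    h2 = x[2:] - x[1:-1]
    out[1:-1] = 2.0 * (f[:-2] / (h1 * (h1 + h2))
                       - f[1:-1] / (h1 * h2)
                       + f[2:] / (h2 * (h1 + h2)))
    # one-sided: reuse the nearest interior 3-point stencil
    def _one_sided(i0, i1, i2):
        ha = x[i1] - x[i0]
        hb = x[i2] - x[i1]
        return 2.0 * (f[i0] / (ha * (ha + hb)) - f[i1] / (ha * hb)
                      + f[i2] / (hb * (ha + hb)))
    out[0] = _one_sided(0, 1, 2)
    out[-1] = _one_sided(n - 3, n - 2, n - 1)
    return out


def passive_instantaneous_current(system: CableSystem, ve_unit,
                                  pulse: PulseWaveform,
                                  t_probe: float = 0.005) -> np.ndarray:
    """Net transmembrane current density (mA cm^-2, positive outward) of the
    passive cell one backward-Euler step (``t_probe`` ms) into the cathodic
    phase.

    On a uniform passive cable this profile is proportional to the AF; on the
    real geometry it additionally reflects axial-resistance differences.
    """
    passive = system.passive_copy()
    dt = t_probe
    n = len(passive)
    ve = np.asarray(ve_unit, dtype=float) * (-pulse.amplitude)  # cathodic phase, mV
    e_pas = cable.membrane.E_PAS
    v0 = np.full(n, e_pas)
    g_mem = passive.gbar["pas"] * passive.area_cm2 * 1e3      # uS
    lap = passive.axial_laplacian().tocsc()
    cdt = passive.cap_nF / dt
    A = scipy.sparse.diags(cdt + g_mem) + lap
    b = cdt * v0 + g_mem * e_pas - lap @ ve
    v1 = scipy.sparse.linalg.spsolve(A.tocsc(), b)
    # net outward transmembrane current (capacitive + ionic) equals the axial
    # current flowing in: -(L (v1 + ve))_j
    i_nA = -(lap @ v1 + lap @ ve)
    return i_nA * 1e-6 / passive.area_cm2                      # mA cm^-2, outward


def compartment_weights(system: CableSystem, injection_nA: float = 1.0,
                        socb_comp: int | None = None) -> np.ndarray:
    """Passive influence weight of every compartment on the SOCB.

    w_j is the steady-state SOCB depolarization per 1 nA injected into
    compartment j of the passive cell, normalized to a maximum of 1.  By
    reciprocity of the symmetric passive system this equals the voltage
    everywhere when the SOCB compartment itself is injected, so a single
    linear solve suffices.
    """
    passive = system.passive_copy()
    if socb_comp is None:
        socb_comp = system.landmark("socb")
    g_mem = passive.gbar["pas"] * passive.area_cm2 * 1e3
    A = scipy.sparse.diags(g_mem) + passive.axial_laplacian()
    rhs = np.zeros(len(passive))
    rhs[socb_comp] = injection_nA
    v = scipy.sparse.linalg.spsolve(A.tocsc(), rhs)   # mV deviation from rest
    w = v / v.max()
    return w


def weighted_af(af: np.ndarray, weights: np.ndarray, n: int) -> float:
    """Sum of AF x weight over the ``n`` highest-weight compartments."""
    af = np.asarray(af, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if not 1 <= n <= len(af):
        raise ValueError(f"n must be in [1, {len(af)}]")
    order = np.argsort(weights)[::-1][:n]
    return float(np.sum(af[order] * weights[order]))


def fit_threshold_distance(values, distances_mm):
    """Least-squares fit of y = a * 10**(b*x) + c to predictor values at
    threshold versus electrode-soma distance (mm).

    Returns ``(a, b, c, r_squared)``.  Degenerate data (near-constant y)
    yields b ~ 0 and R^2 ~ 0 rather than an exception; true non-convergence
    raises RuntimeError carrying the residuals.
    """
    y = np.asarray(values, dtype=float)
    x = np.asarray(distances_mm, dtype=float)
    if len(y) < 4:
        raise ValueError("need at least 4 points")

    def model(xx, a, b, c):
        return a * np.power(10.0, b * xx) + c

    yspan = y.max() - y.min()
    p0 = (yspan if yspan > 0 else 1.0, -1.0, y.min())
    try:
        popt, _ = scipy.optimize.curve_fit(model, x, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        resid = y - model(x, *p0)
        raise RuntimeError(f"exponential fit failed: {exc}; residuals {resid}") from None
    resid = y - model(x, *popt)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    a, b, c = (float(p) for p in popt)
    return a, b, c, r2


def evaluate_predictors(system: CableSystem, grid, field_source: FieldSource,
                        pulse: PulseWaveform | None = None,
                        config: SolverConfig | None = None,
                        n_weighted: int = 25,
                        progress: bool = False) -> dict:
    """Predictor table over a population of electrode/soma offsets.

    For each grid node the full cable model's threshold is found first; the
    predictors are then evaluated on the extracellular potential vector at
    that threshold amplitude ("the threshold V_e vector").  Returns a dict
    with the per-position DataFrame, exponential fits of each predictor
    against electrode-soma distance, and peak-location summaries.
    """
    from .threshold import find_threshold, BracketError
    if pulse is None:
        pulse = PulseWaveform(1.0)
    morph = system.morph
    weights_full = compartment_weights(system)
    pf0 = path_field(morph, np.zeros(len(morph)))
    axial_idx = pf0.index
    w_axial = weights_full[axial_idx]
    soma_center = morph.centers[system.landmark("soma")]
    rows = []
    xs, ys = grid.offsets()
    for x in xs:
        for y in ys:
            pos = np.array([x, y, grid.height])
            ve_unit = field_source.at(pos).unit_potentials(morph.centers)
            try:
                thr = find_threshold(system, ve_unit=ve_unit, pulse=pulse,
                                     config=config, locate_initiation=True)
            except BracketError:
                continue
            ve_thr = ve_unit * (-thr.threshold)       # cathodic-phase potentials
            pf = path_field(morph, ve_thr)
            af = activating_function(pf)
            interior = slice(1, -1)                    # endpoints excluded from peaks
            k_af = 1 + int(np.argmax(af[interior]))
            imem = passive_instantaneous_current(
                system, ve_unit, pulse.with_amplitude(thr.threshold))
            imem_axial = imem[axial_idx]
            k_im = 1 + int(np.argmax(imem_axial[interior]))
            dist_mm = float(np.linalg.norm(pos - soma_center)) * 1e-3
            rows.append({
                "x": x, "y": y, "threshold": thr.threshold,
                "distance_mm": dist_mm,
                "af_peak": float(af[k_af]), "af_peak_region": pf.region[k_af],
                "imem_peak": float(imem_axial[k_im]),
                "imem_peak_region": pf.region[k_im],
                "weighted_af": weighted_af(af, w_axial, n_weighted),
                "cable_init_region": thr.initiation_region,
            })
    table = pd.DataFrame(rows)
    fits = {}
    for col in ("af_peak", "imem_peak", "weighted_af"):
        try:
            a, b, c, r2 = fit_threshold_distance(table[col], table["distance_mm"])
            fits[col] = {"a": a, "b": b, "c": c, "r2": r2}
        except (RuntimeError, ValueError) as exc:
            fits[col] = {"error": str(exc)}
    summary = {
        "n_positions": len(table),
        "af_peak_in_socb_fraction": float((table["af_peak_region"] == "socb").mean()),
        "imem_peak_in_socb_fraction": float((table["imem_peak_region"] == "socb").mean()),
        "cable_init_in_socb_fraction": float((table["cable_init_region"] == "socb").mean()),
    }
    return {"table": table, "fits": fits, "summary": summary,
            "weights": weights_full}
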