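"""Mammalian RGC membrane dynamics: ion-channel kinetics and calcium handling.

The membrane model is the Fohlmeister-type five-conductance description of a
mammalian retinal ganglion cell at 37.1 degC: fast sodium (m^3 h), delayed
rectifier potassium (n^4), calcium (c^3), a ligand-gated calcium-activated
potassium conductance, and a passive leak.  The voltage-gated rate constants
are already temperature-adjusted; no further Q10 scaling is applied.

Units follow the conventions of compartmental neural simulators: voltages in
mV, time in ms, conductance densities in mS cm^-2, current densities in
uA cm^-2 (note: 1 mS cm^-2 x 1 mV = 1 uA cm^-2), concentrations in M (mol/l).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RateSet",
    "GatingState",
    "RegionChannelParams",
    "NernstSet",
    "CalciumParams",
    "CHANNEL_TABLE",
    "gating_rates",
    "gating_steady_state",
    "kca_conductance",
    "calcium_nernst",
    "calcium_derivative",
    "ionic_current",
]

# Nernst potentials (mV); E_Ca is dynamic, computed from calcium.
E_NA = 61.02
E_K = -102.3
E_PAS = -65.02

FARADAY = 96489.0       # C mol^-1
GAS_CONSTANT = 8.314    # J mol^-1 K^-1
TEMPERATURE = 310.25    # K (37.1 degC)
SHELL_DEPTH_UM = 0.1    # um, depth of the submembrane calcium shell
CA_REST = 1e-7          # M, calcium pump target
CA_TAU = 1.5            # ms, calcium pump time constant
CA_EXT_DEFAULT = 1.8e-3  # M, extracellular calcium (not printed; literature value)


@dataclass(frozen=True)
class RateSet:
    """Opening/closing rates (ms^-1) of the four voltage-gated state variables."""

    alpha_m: float
    beta_m: float
    alpha_h: float
    beta_h: float
    alpha_n: float
    beta_n: float
    alpha_c: float
    beta_c: float


@dataclass
class GatingState:
    """Gating variables (dimensionless, in [0,1]) and intracellular calcium (M)."""

    m: float
    h: float
    n: float
    c: float
    ca_i: float = CA_REST


@dataclass(frozen=True)
class RegionChannelParams:
    """Maximum conductance densities of one cell region (mS cm^-2)."""

    gbar_na: float
    gbar_k: float
    gbar_ca: float
    gbar_kca: float
    gbar_pas: float


# Regional maximum conductances (mS cm^-2), indexed by region label.
CHANNEL_TABLE: dict[str, RegionChannelParams] = {
    "dendrite": RegionChannelParams(60.0, 35.0, 1.0, 0.17, 0.1),
    "soma": RegionChannelParams(60.0, 35.0, 0.75, 0.17, 0.1),
    "hillock": RegionChannelParams(150.0, 90.0, 0.75, 0.17, 0.1),
    "socb": RegionChannelParams(420.0, 250.0, 0.75, 0.11, 0.1),
    "narrow": RegionChannelParams(150.0, 90.0, 0.75, 0.2, 0.1),
    "axon": RegionChannelParams(100.0, 50.0, 0.75, 0.2, 0.1),
}


@dataclass(frozen=True)
class NernstSet:
    """Equilibrium potentials (mV). e_ca is a starting value; it is recomputed
    from the instantaneous calcium concentration during simulation."""

    e_na: float = E_NA
    e_k: float = E_K
    e_pas: float = E_PAS
    e_ca: float = 120.0


@dataclass(frozen=True)
class CalciumParams:
    faraday: float = FARADAY
    shell_depth_um: float = SHELL_DEPTH_UM
    gas_constant: float = GAS_CONSTANT
    temperature: float = TEMPERATURE
    ca_e: float = CA_EXT_DEFAULT
    ca_rest: float = CA_REST
    pump_tau: float = CA_TAU


def _vtrap(v: np.ndarray | float, vhalf: float, rate: float) -> np.ndarray | float:
    """Evaluate rate*(-(v-vhalf))/(exp(-0.1(v-vhalf))-1) removing the v=vhalf
    singularity by its analytic limit rate/0.1."""
    u = np.asarray(v, dtype=float) - vhalf
    x = -0.1 * u
    small = np.abs(x) < 1e-9
    xs = np.where(small, 1.0, x)  # placeholder so expm1 never sees the 0/0 point
    with np.errstate(invalid="ignore"):
        out = np.where(small, rate / 0.1 * (1.0 - x / 2.0), rate * u / (-np.expm1(xs)))
    return out if out.shape else float(out)


def gating_rates(v):
    """Voltage-dependent rate constants (ms^-1) of m, h, n, c at voltage ``v`` (mV).

    Removable singularities (alpha_m at -35 mV, alpha_n at -37 mV, alpha_c at
    -13 mV) are evaluated by their analytic limits.  Accepts scalars or arrays.
    """
    v = np.asarray(v, dtype=float)
    alpha_m = _vtrap(v, -35.0, 3.136)
    beta_m = 104.545 * np.exp(-(v + 60.0) / 20.0)
    alpha_h = 2.091 * np.exp(-(v + 52.0) / 20.0)
    beta_h = 31.365 / (1.0 + np.exp(-0.1 * (v + 22.0)))
    alpha_n = _vtrap(v, -37.0, 0.110)
    beta_n = 2.191 * np.exp(-(v + 47.0) / 80.0)
    alpha_c = _vtrap(v, -13.0, 1.568)
    beta_c = 52.267 * np.exp(-(v + 38.0) / 18.0)
    if v.shape == ():
        return RateSet(float(alpha_m), float(beta_m), float(alpha_h), float(beta_h),
                       float(alpha_n), float(beta_n), float(alpha_c), float(beta_c))
    return RateSet(alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n, alpha_c, beta_c)


def gating_steady_state(v):
    """Steady state x_inf = a/(a+b) and time constant tau = 1/(a+b) (ms) at ``v``.

    Returns a dict keyed by gate name with (x_inf, tau) tuples.
    """
    r = gating_rates(v)
    out = {}
    for gate in ("m", "h", "n", "c"):
        a = getattr(r, f"alpha_{gate}")
        b = getattr(r, f"beta_{gate}")
        out[gate] = (a / (a + b), 1.0 / (a + b))
    return out


def kca_conductance(ca_i, gbar_kca):
    """Calcium-activated potassium conductance (mS cm^-2).

    Half-activated at the 1 uM calcium reference concentration:
    gbar * (ca/1uM)^2 / (1 + (ca/1uM)^2).
    """
    x = (np.asarray(ca_i, dtype=float) / 1e-6) ** 2
    out = gbar_kca * x / (1.0 + x)
    return float(out) if np.ndim(out) == 0 else out


def calcium_nernst(ca_i, params: CalciumParams = CalciumParams()):
    """Calcium equilibrium potential (mV): (RT/2F) ln(ca_e / ca_i)."""
    ca_i = np.asarray(ca_i, dtype=float)
    if np.any(ca_i <= 0):
        raise ValueError("ca_i must be positive")
    volts = (params.gas_constant * params.temperature
             / (2.0 * params.faraday)) * np.log(params.ca_e / ca_i)
    out = 1000.0 * volts
    return float(out) if np.ndim(out) == 0 else out


def calcium_derivative(i_ca_ma, ca_i, params: CalciumParams = CalciumParams()):
    """Rate of change of submembrane calcium (M ms^-1).

    ``i_ca_ma`` is the calcium current density in mA cm^-2 (positive outward).
    The influx term is -3 i_Ca / (2 F r) with r the shell depth; the pump term
    relaxes toward the resting level with a 1.5 ms time constant.
    """
    r_cm = params.shell_depth_um * 1e-4
    # mA cm^-2 -> A cm^-2 (1e-3); mol cm^-3 s^-1 -> M s^-1 (1e3); s^-1 -> ms^-1 (1e-3)
    influx = -3.0 * (np.asarray(i_ca_ma, dtype=float) * 1e-3) / (2.0 * params.faraday * r_cm) * 1e3 * 1e-3
    pump = -(np.asarray(ca_i, dtype=float) - params.ca_rest) / params.pump_tau
    out = influx + pump
    return float(out) if np.ndim(out) == 0 else out


def ionic_current(v, state: GatingState, params: RegionChannelParams,
                  nernst: NernstSet | None = None,
                  calcium: CalciumParams = CalciumParams()):
    """Total ionic current density (uA cm^-2, positive outward) and breakdown.

    Returns ``(total, parts)`` where ``parts`` maps channel name to its current
    density.  The calcium component feeds :func:`calcium_derivative` (note that
    function expects mA cm^-2 = 1e-3 x the value returned here).
    """
    if nernst is None:
        nernst = NernstSet()
    e_ca = calcium_nernst(state.ca_i, calcium)
    g_kca = kca_conductance(state.ca_i, params.gbar_kca)
    i_na = params.gbar_na * state.m ** 3 * state.h * (v - nernst.e_na)
    i_k = (params.gbar_k * state.n ** 4 + g_kca) * (v - nernst.e_k)
    i_ca = params.gbar_ca * state.c ** 3 * (v - e_ca)
    i_pas = params.gbar_pas * (v - nernst.e_pas)
    parts = {"na": i_na, "k": i_k, "ca": i_ca, "pas": i_pas}
    return i_na + i_k + i_ca + i_pas, parts
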