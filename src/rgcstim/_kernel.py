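"""Numba-compiled inner loop of the cable integrator.

Staggered second-order implicit scheme, the higher-accuracy mode of the
classic compartmental simulators: gating states are advanced first by
exponential (Rush-Larsen) updates with rates frozen at the step-start
voltage — so the states live on the half-step grid — and the voltage is then
advanced by a Crank-Nicolson (trapezoid) step using those states, solved with
one Hines tree-elimination per step (parents ordered before children).
Submembrane calcium follows the gates explicitly.

Unit system: mV, ms, uA cm^-2, mS cm^-2, uS, nA, nF, M.
"""

import math

import numpy as np
from numba import njit

# physical constants (see membrane module)
_F = 96489.0
_R = 8.314
_T = 310.25
_R_SHELL_CM = 0.1e-4
_CA_REST = 1e-7
_CA_TAU = 1.5
# d[Ca]/dt (M/ms) per uA cm^-2 of calcium current
_CA_CONV = 3.0e-6 / (2.0 * _F * _R_SHELL_CM)
_ECA_COEF = 1000.0 * _R * _T / (2.0 * _F)  # mV

_THETA = 0.5  # implicitness of the voltage step (0.5 = trapezoid)


@njit(cache=True, inline="always")
def _vtrap(v, vhalf, rate):
    u = v - vhalf
    x = -0.1 * u
    if abs(x) < 1e-9:
        return rate / 0.1 * (1.0 - 0.5 * x)
    return rate * u / (-math.expm1(x))


@njit(cache=True)
def integrate(parent, g_ax, cap_nF, area_cm2,
              gna, gk, gca, gkca, gpas,          # densities, mS cm^-2
              e_na, e_k, e_pas, ca_e,
              ve_unit,                            # mV per uA
              amp, onset, phase_width, gap,       # pulse (uA, ms)
              inject_idx, inject_nA, inj_on, inj_off,
              dt, n_steps,
              v, m, h, n, c, ca,                  # state, modified in place
              record_idx, record_every):
    """Advance the cable system ``n_steps`` of size ``dt``.

    Returns ``(recorded, bad_step, bad_comp)`` where ``recorded`` holds the
    voltages of ``record_idx`` every ``record_every`` steps (initial state as
    row 0) and ``bad_step``/``bad_comp`` flag a non-finite abort (-1 if none).
    """
    theta = _THETA
    N = v.shape[0]
    n_rec = record_idx.shape[0]
    n_kept = n_steps // record_every + 1
    out = np.empty((n_kept, n_rec))
    for r in range(n_rec):
        out[0, r] = v[record_idx[r]]

    diag = np.empty(N)
    b = np.empty(N)
    e_ca_arr = np.empty(N)
    kept = 1
    t_c0 = onset
    t_c1 = onset + phase_width
    t_a0 = t_c1 + gap
    t_a1 = t_a0 + phase_width

    for j in range(N):
        e_ca_arr[j] = _ECA_COEF * math.log(ca_e / ca[j])

    for step in range(n_steps):
        t_old = step * dt
        t_new = t_old + dt
        # exact step-average of the piecewise-constant stimulus current, so
        # pulse edges carry no charge bias at any dt
        cath = max(0.0, min(t_new, t_c1) - max(t_old, t_c0))
        anod = max(0.0, min(t_new, t_a1) - max(t_old, t_a0))
        i_avg = amp * (anod - cath) / dt

        # --- gates and calcium first (states live on the half-step grid:
        # the first step advances them dt/2, every later step a full dt) ---
        gdt = 0.5 * dt if step == 0 else dt
        for j in range(N):
            vj = v[j]
            am = _vtrap(vj, -35.0, 3.136)
            bm = 104.545 * math.exp(-(vj + 60.0) / 20.0)
            ah = 2.091 * math.exp(-(vj + 52.0) / 20.0)
            bh = 31.365 / (1.0 + math.exp(-0.1 * (vj + 22.0)))
            an = _vtrap(vj, -37.0, 0.110)
            bn = 2.191 * math.exp(-(vj + 47.0) / 80.0)
            ac = _vtrap(vj, -13.0, 1.568)
            bc = 52.267 * math.exp(-(vj + 38.0) / 18.0)
            s = am + bm
            m[j] = am / s + (m[j] - am / s) * math.exp(-gdt * s)
            s = ah + bh
            h[j] = ah / s + (h[j] - ah / s) * math.exp(-gdt * s)
            s = an + bn
            n[j] = an / s + (n[j] - an / s) * math.exp(-gdt * s)
            s = ac + bc
            c[j] = ac / s + (c[j] - ac / s) * math.exp(-gdt * s)

            # calcium: influx frozen over the step, pump integrated exactly
            i_ca = gca[j] * c[j] ** 3 * (vj - e_ca_arr[j])   # uA cm^-2
            target = _CA_REST - _CA_CONV * i_ca * _CA_TAU
            ca[j] = target + (ca[j] - target) * math.exp(-gdt / _CA_TAU)
            if ca[j] < 1e-10:
                ca[j] = 1e-10
            e_ca_arr[j] = _ECA_COEF * math.log(ca_e / ca[j])

        # --- trapezoid voltage step with frozen channel states ---
        for j in range(N):
            x = (ca[j] / 1e-6) ** 2
            gkca_now = gkca[j] * x / (1.0 + x)
            gna_j = gna[j] * m[j] ** 3 * h[j]
            gk_j = gk[j] * n[j] ** 4 + gkca_now
            gca_j = gca[j] * c[j] ** 3
            scale = area_cm2[j] * 1.0e3                  # mS -> uS absolute
            g_tot = (gna_j + gk_j + gca_j + gpas[j]) * scale
            g_e = (gna_j * e_na + gk_j * e_k + gca_j * e_ca_arr[j]
                   + gpas[j] * e_pas) * scale
            cdt = cap_nF[j] / dt
            diag[j] = cdt + theta * g_tot
            b[j] = cdt * v[j] + g_e - (1.0 - theta) * g_tot * v[j]

        # intracellular injection (nA), step-averaged like the field drive
        if inject_idx.shape[0] > 0:
            w = max(0.0, min(t_new, inj_off) - max(t_old, inj_on)) / dt
            if w > 0.0:
                for k in range(inject_idx.shape[0]):
                    b[inject_idx[k]] += w * inject_nA[k]

        # axial coupling and extracellular drive
        for j in range(1, N):
            p = parent[j]
            g = g_ax[j]
            diag[j] += theta * g
            diag[p] += theta * g
            dve = ve_unit[p] - ve_unit[j]
            expl = (1.0 - theta) * g * (v[p] - v[j]) + g * i_avg * dve
            b[j] += expl
            b[p] -= expl

        # Hines solve (parents precede children)
        for j in range(N - 1, 0, -1):
            p = parent[j]
            g = theta * g_ax[j]
            f = g / diag[j]
            diag[p] -= f * g
            b[p] += f * b[j]
        v[0] = b[0] / diag[0]
        for j in range(1, N):
            v[j] = (b[j] + theta * g_ax[j] * v[parent[j]]) / diag[j]

        for j in range(N):
            if not math.isfinite(v[j]):
                return out[:kept], step + 1, j

        if (step + 1) % record_every == 0:
            for r in range(n_rec):
                out[kept, r] = v[record_idx[r]]
            kept += 1
    return out, -1, -1
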