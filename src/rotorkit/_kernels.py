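"""Compiled inner loops for the monodomain solver.

All kernels advance a three-variable phenomenological excitable-medium
model (fast inward current gated by ``v``, slow inward gated by ``w``,
ungated slow outward) with explicit forward Euler in time and, in 1-D/2-D,
a nearest-neighbour Laplacian with mirror (no-flux) boundaries on the
tissue mask.

The parameter vector ``p`` is laid out as

    0 tau_d    fast-inward time constant (1/g_fi), ms
    1 tau_r    slow-outward repolarization constant, ms
    2 tau_si   slow-inward constant, ms
    3 tau_0    slow-outward diastolic constant, ms
    4 tau_vp   v-gate closing constant, ms
    5 tau_v1m  v-gate reopening constant above u_v, ms
    6 tau_v2m  v-gate reopening constant below u_v, ms
    7 tau_wp   w-gate closing constant, ms
    8 tau_wm   w-gate reopening constant, ms
    9 u_c      excitation threshold (dimensionless)
   10 u_v      v-gate switch level
   11 u_csi    slow-inward activation midpoint
   12 k_si     slow-inward activation steepness

Conductance scalings (drug block) are folded into the tau values by the
caller before the kernel runs.
"""

import math

import numpy as np
from numba import njit

__all__ = ["integrate_0d", "integrate_1d", "integrate_2d"]


@njit(cache=True, inline="always")
def _reaction(u, v, w, p):
    """Return (du, dv, dw) for one cell; du excludes diffusion and stimulus."""
    if u < p[9]:
        if u > p[10]:
            dv = (1.0 - v) / p[5]
        else:
            dv = (1.0 - v) / p[6]
        dw = (1.0 - w) / p[8]
        j_fi = 0.0
        j_so = u / p[3]
    else:
        dv = -v / p[4]
        dw = -w / p[7]
        j_fi = -v * (1.0 - u) * (u - p[9]) / p[0]
        j_so = 1.0 / p[1]
    j_si = -w * (1.0 + math.tanh(p[12] * (u - p[11]))) / (2.0 * p[2])
    return -(j_fi + j_so + j_si), dv, dw


@njit(cache=True)
def integrate_0d(y, p, dt, n_steps, record_every, out,
                 stim_step0, stim_step1, stim_amp):
    """Advance a single cell; record u into ``out`` every ``record_every`` steps."""
    u, v, w = y[0], y[1], y[2]
    n_ev = stim_step0.shape[0]
    k = 0
    for step in range(n_steps):
        if step % record_every == 0 and k < out.shape[0]:
            out[k] = u
            k += 1
        istim = 0.0
        for e in range(n_ev):
            if stim_step0[e] <= step < stim_step1[e]:
                istim += stim_amp[e]
        du, dv, dw = _reaction(u, v, w, p)
        u += dt * (du + istim)
        v += dt * dv
        w += dt * dw
        if u < 0.0:
            u = 0.0
    y[0], y[1], y[2] = u, v, w
    return k


@njit(cache=True)
def integrate_1d(u, v, w, p, d_over_dx2, dt, n_steps, record_every, out,
                 stim_step0, stim_step1, stim_amp, stim_i0, stim_i1):
    """Cable with no-flux ends; stimulus events cover index ranges [i0, i1)."""
    n = u.shape[0]
    n_ev = stim_step0.shape[0]
    du_arr = np.empty(n)
    k = 0
    for step in range(n_steps):
        if step % record_every == 0 and k < out.shape[0]:
            for i in range(n):
                out[k, i] = u[i]
            k += 1
        for i in range(n):
            lap = 0.0
            if i > 0:
                lap += u[i - 1] - u[i]
            if i < n - 1:
                lap += u[i + 1] - u[i]
            du, dv, dw = _reaction(u[i], v[i], w[i], p)
            du_arr[i] = dt * (du + d_over_dx2 * lap)
            v[i] += dt * dv
            w[i] += dt * dw
        for e in range(n_ev):
            if stim_step0[e] <= step < stim_step1[e]:
                for i in range(stim_i0[e], stim_i1[e]):
                    du_arr[i] += dt * stim_amp[e]
        for i in range(n):
            u[i] += du_arr[i]
            if u[i] < 0.0:
                u[i] = 0.0
    return k


@njit(cache=True)
def integrate_2d(u, v, w, inside, p, d_over_dx2, dt, n_steps, record_every,
                 out, stim_step0, stim_step1, stim_amp, stim_mask_idx,
                 stim_masks):
    """Sheet solver on a masked grid.

    ``inside`` marks tissue pixels; neighbours outside the mask contribute
    nothing to the Laplacian (mirror/no-flux condition). ``stim_masks`` is a
    stack of boolean footprints; event ``e`` injects ``stim_amp[e]`` on
    footprint ``stim_mask_idx[e]`` while ``stim_step0[e] <= step < stim_step1[e]``.
    Frames are written to ``out`` (n_frames, rows, cols) every
    ``record_every`` steps; returns the number of frames written.
    """
    rows, cols = u.shape
    n_ev = stim_step0.shape[0]
    du_arr = np.zeros((rows, cols))
    k = 0
    for step in range(n_steps):
        if step % record_every == 0 and k < out.shape[0]:
            for i in range(rows):
                for j in range(cols):
                    out[k, i, j] = u[i, j] if inside[i, j] else np.nan
            k += 1
        for i in range(rows):
            for j in range(cols):
                if not inside[i, j]:
                    continue
                uc = u[i, j]
                lap = 0.0
                if i > 0 and inside[i - 1, j]:
                    lap += u[i - 1, j] - uc
                if i < rows - 1 and inside[i + 1, j]:
                    lap += u[i + 1, j] - uc
                if j > 0 and inside[i, j - 1]:
                    lap += u[i, j - 1] - uc
                if j < cols - 1 and inside[i, j + 1]:
                    lap += u[i, j + 1] - uc
                du, dv, dw = _reaction(uc, v[i, j], w[i, j], p)
                du_arr[i, j] = dt * (du + d_over_dx2 * lap)
                v[i, j] += dt * dv
                w[i, j] += dt * dw
        for e in range(n_ev):
            if stim_step0[e] <= step < stim_step1[e]:
                m = stim_masks[stim_mask_idx[e]]
                for i in range(rows):
                    for j in range(cols):
                        if m[i, j] and inside[i, j]:
                            du_arr[i, j] += dt * stim_amp[e]
        for i in range(rows):
            for j in range(cols):
                if inside[i, j]:
                    un = u[i, j] + du_arr[i, j]
                    u[i, j] = un if un > 0.0 else 0.0
    return k
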