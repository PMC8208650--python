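"""Numba kernels for network integration.

The full network state is packed into one flat float64 vector::

    [ v_s(n_s) | m | h | n | ms | mhf | mhs      (stellate blocks, n_s each)
    | v_i(n_i) | m_i | h_i | n_i                 (interneuron blocks, n_i each)
    | s_s(n_s) | s_i(n_i) ]                      (synaptic gates, per source)

``network_rhs`` evaluates the coupled right-hand side at time t; the Euler
and RK4 steppers share it, differing only in the update scheme.  Spike
detection (upward threshold crossing, linear interpolation, refractory
window) and gate clamping to [0, 1] happen inside the steppers.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .channels import (
    interneuron_alpha_h,
    interneuron_alpha_m,
    interneuron_alpha_n,
    interneuron_beta_h,
    interneuron_beta_m,
    interneuron_beta_n,
    stellate_alpha_h,
    stellate_alpha_m,
    stellate_alpha_n,
    stellate_beta_h,
    stellate_beta_m,
    stellate_beta_n,
    stellate_mhf_inf,
    stellate_mhs_inf,
    stellate_ms_inf,
    stellate_tau_mhf,
    stellate_tau_mhs,
)

TWO_PI = 2.0 * math.pi


@njit(cache=True)
def theta_phase_kernel(t, th):
    """Accumulated sinusoid argument; th = [A, f0, mod_amp, mod_period, phi0, v_th]."""
    ph = TWO_PI * th[1] * t / 1000.0 + th[4]
    if th[2] != 0.0:
        tm = th[3]
        ph += TWO_PI * th[2] / 1000.0 * (tm / TWO_PI) * (1.0 - math.cos(TWO_PI * t / tm))
    return ph


@njit(cache=True)
def pulse_value_kernel(t, p_low, p_high, tau_r, tau_f, width, onsets):
    """Pulse current at t given this neuron's sorted onset times."""
    idx = np.searchsorted(onsets, t, side="right") - 1
    if idx < 0:
        return p_low
    ts = onsets[idx]
    te = ts + width
    if t < te:
        return p_high + (p_low - p_high) * math.exp(-(t - ts) / tau_r)
    p_end = p_high + (p_low - p_high) * math.exp(-width / tau_r)
    return p_low + (p_end - p_low) * math.exp(-(t - te) / tau_f)


@njit(cache=True)
def network_rhs(
    t,
    y,
    out,
    n_s,
    n_i,
    sp,        # stellate params, see engine._pack_stellate_params
    ip,        # interneuron params
    syn,       # [alpha_inh, beta_inh, alpha_exc, beta_exc, e_inh, e_exc]
    g_is,      # (n_s, n_i) inhibitory conductance onto stellates (w_ie.T)
    g_si,      # (n_i, n_s) excitatory conductance onto interneurons (w_ei.T)
    g_ii_t,    # (n_i, n_i) inhibitory conductance between interneurons (w_ii.T)
    iext_s,
    iext_i,
    th,        # theta params, amplitude 0 disables
    pulse_par,     # (n_i, 5): p_low, p_high, tau_r, tau_f, width
    has_pulse,     # (n_i,) uint8
    onsets_data,   # concatenated onset times
    onsets_indptr, # (n_i+1,) CSR offsets into onsets_data
    u_s,       # (n_s,) held noise draws
    u_i,       # (n_i,)
    g_noise_s,
    g_noise_i,
    e_noise,
):
    b = 7 * n_s
    c = b + 4 * n_i
    d = c + n_s
    s_s = y[c:d]
    s_i = y[d:d + n_i]

    gin_s = np.dot(g_is, s_i)       # inhibitory conductance onto each stellate
    gexc_i = np.dot(g_si, s_s)      # excitatory conductance onto each interneuron
    ginh_i = np.dot(g_ii_t, s_i)    # inhibitory conductance onto each interneuron

    sin_th = 0.0
    if th[0] > 0.0:
        sin_th = math.sin(theta_phase_kernel(t, th))

    # --- stellate cells ---
    for j in range(n_s):
        v = y[j]
        m = y[n_s + j]
        h = y[2 * n_s + j]
        n = y[3 * n_s + j]
        msp = y[4 * n_s + j]
        mhf = y[5 * n_s + j]
        mhs = y[6 * n_s + j]
        i_na = sp[1] * m * m * m * h * (v - sp[6])
        i_k = sp[2] * n * n * n * n * (v - sp[7])
        i_nap = sp[3] * msp * (v - sp[6])
        i_h = sp[4] * (sp[11] * mhf + sp[12] * mhs) * (v - sp[8])
        i_leak = sp[5] * (v - sp[9])
        i_syn = gin_s[j] * (v - syn[4])
        i_noise = g_noise_s * u_s[j] * (v - e_noise)
        out[j] = (iext_s[j] - i_na - i_k - i_leak - i_h - i_nap - i_syn - i_noise) / sp[0]
        out[n_s + j] = stellate_alpha_m(v) * (1.0 - m) - stellate_beta_m(v) * m
        out[2 * n_s + j] = stellate_alpha_h(v) * (1.0 - h) - stellate_beta_h(v) * h
        out[3 * n_s + j] = stellate_alpha_n(v) * (1.0 - n) - stellate_beta_n(v) * n
        out[4 * n_s + j] = (stellate_ms_inf(v) - msp) / sp[10]
        out[5 * n_s + j] = (stellate_mhf_inf(v) - mhf) / stellate_tau_mhf(v)
        out[6 * n_s + j] = (stellate_mhs_inf(v) - mhs) / stellate_tau_mhs(v)

    # --- interneurons ---
    for i in range(n_i):
        v = y[b + i]
        h = y[b + 2 * n_i + i]
        n = y[b + 3 * n_i + i]
        # Na activation slaved to voltage (fast-spiking model convention)
        am = interneuron_alpha_m(v)
        m = am / (am + interneuron_beta_m(v))
        i_na = ip[1] * m * m * m * h * (v - ip[4])
        i_k = ip[2] * n * n * n * n * (v - ip[5])
        i_leak = ip[3] * (v - ip[6])
        i_syn = ginh_i[i] * (v - syn[4]) + gexc_i[i] * (v - syn[5])
        i_noise = g_noise_i * u_i[i] * (v - e_noise)
        i_theta = th[0] * sin_th * (v - th[5])
        i_pulse = 0.0
        if has_pulse[i] == 1:
            on = onsets_data[onsets_indptr[i]:onsets_indptr[i + 1]]
            i_pulse = pulse_value_kernel(
                t, pulse_par[i, 0], pulse_par[i, 1], pulse_par[i, 2],
                pulse_par[i, 3], pulse_par[i, 4], on,
            )
        out[b + i] = (
            iext_i[i] + i_pulse - i_na - i_k - i_leak - i_syn - i_noise - i_theta
        ) / ip[0]
        phi = ip[7]
        out[b + n_i + i] = 0.0  # m slot unused (instantaneous gate)
        out[b + 2 * n_i + i] = phi * (
            interneuron_alpha_h(v) * (1.0 - h) - interneuron_beta_h(v) * h
        )
        out[b + 3 * n_i + i] = phi * (
            interneuron_alpha_n(v) * (1.0 - n) - interneuron_beta_n(v) * n
        )

    # --- synaptic gates (one per presynaptic cell) ---
    for j in range(n_s):
        f = 0.5 * (1.0 + math.tanh(y[j] / 4.0))
        out[c + j] = f * syn[2] * (1.0 - s_s[j]) - syn[3] * s_s[j]
    for i in range(n_i):
        f = 0.5 * (1.0 + math.tanh(y[b + i] / 4.0))
        out[d + i] = f * syn[0] * (1.0 - s_i[i]) - syn[1] * s_i[i]


@njit(cache=True)
def _clamp_gates(y, n_s, n_i):
    """Clamp all gating/synaptic variables to [0, 1]; return clamp count."""
    b = 7 * n_s
    count = 0
    for k in range(n_s, b):  # stellate gates
        if y[k] < 0.0:
            y[k] = 0.0
            count += 1
        elif y[k] > 1.0:
            y[k] = 1.0
            count += 1
    for k in range(b + n_i, y.size):  # interneuron gates + synaptic gates
        if y[k] < 0.0:
            y[k] = 0.0
            count += 1
        elif y[k] > 1.0:
            y[k] = 1.0
            count += 1
    return count


@njit(cache=True)
def _detect_step_spikes(
    y, prev_v, t_new, dt, n_s, n_i, thr, refrac, spikes, counts, last_spike
):
    b = 7 * n_s
    n_cells = n_s + n_i
    for cell in range(n_cells):
        v_new = y[cell] if cell < n_s else y[b + (cell - n_s)]
        v_old = prev_v[cell]
        if v_old < thr <= v_new:
            tc = t_new - dt + dt * (thr - v_old) / (v_new - v_old)
            if tc - last_spike[cell] >= refrac:
                if counts[cell] < spikes.shape[1]:
                    spikes[cell, counts[cell]] = tc
                    counts[cell] += 1
                last_spike[cell] = tc
        prev_v[cell] = v_new


@njit(cache=True)
def _store_prev_v(y, prev_v, n_s, n_i):
    b = 7 * n_s
    for cell in range(n_s + n_i):
        prev_v[cell] = y[cell] if cell < n_s else y[b + (cell - n_s)]


@njit(cache=True)
def euler_run(
    y0, dt, n_steps, n_s, n_i, sp, ip, syn, g_is, g_si, g_ii_t, iext_s, iext_i,
    th, pulse_par, has_pulse, onsets_data, onsets_indptr,
    noise_seed, resample_steps, g_noise_s, g_noise_i, e_noise,
    record_stride, thr, refrac, max_spikes, v_div,
):
    """Forward-Euler integration of the packed network state.

    Returns (rec_t, rec_v, spikes, counts, clamp_count, diverged_at) where
    ``diverged_at`` < 0 means no divergence.
    """
    n_cells = n_s + n_i
    y = y0.copy()
    dy = np.empty_like(y)
    u_s = np.zeros(n_s)
    u_i = np.zeros(n_i)
    noisy = (g_noise_s > 0.0) or (g_noise_i > 0.0)
    if noisy:
        np.random.seed(noise_seed)

    n_rec = (n_steps // record_stride + 1) if record_stride > 0 else 0
    rec_t = np.zeros(n_rec)
    rec_v = np.zeros((n_rec, n_cells))
    spikes = np.zeros((n_cells, max_spikes))
    counts = np.zeros(n_cells, dtype=np.int64)
    last_spike = np.full(n_cells, -1.0e9)
    prev_v = np.empty(n_cells)
    _store_prev_v(y, prev_v, n_s, n_i)

    irec = 0
    if record_stride > 0:
        rec_t[0] = 0.0
        for cell in range(n_cells):
            rec_v[0, cell] = prev_v[cell]
        irec = 1

    clamp_count = 0
    diverged_at = -1.0
    for step in range(n_steps):
        t = step * dt
        if noisy and step % resample_steps == 0:
            for j in range(n_s):
                u_s[j] = np.random.uniform(-1.0, 1.0)
            for i in range(n_i):
                u_i[i] = np.random.uniform(-1.0, 1.0)
        network_rhs(
            t, y, dy, n_s, n_i, sp, ip, syn, g_is, g_si, g_ii_t, iext_s, iext_i,
            th, pulse_par, has_pulse, onsets_data, onsets_indptr,
            u_s, u_i, g_noise_s, g_noise_i, e_noise,
        )
        for k in range(y.size):
            y[k] += dt * dy[k]
        clamp_count += _clamp_gates(y, n_s, n_i)
        t_new = (step + 1) * dt
        _detect_step_spikes(
            y, prev_v, t_new, dt, n_s, n_i, thr, refrac, spikes, counts, last_spike
        )
        for cell in range(n_cells):
            if abs(prev_v[cell]) > v_div:
                diverged_at = t_new
                break
        if diverged_at >= 0.0:
            break
        if record_stride > 0 and (step + 1) % record_stride == 0 and irec < n_rec:
            rec_t[irec] = t_new
            for cell in range(n_cells):
                rec_v[irec, cell] = prev_v[cell]
            irec += 1
    return rec_t, rec_v, spikes, counts, clamp_count, diverged_at


@njit(cache=True)
def rk4_run(
    y0, dt, n_steps, n_s, n_i, sp, ip, syn, g_is, g_si, g_ii_t, iext_s, iext_i,
    th, pulse_par, has_pulse, onsets_data, onsets_indptr,
    record_stride, thr, refrac, max_spikes, v_div,
):
    """Classical 4th-order fixed-step integration (noise-free reference)."""
    n_cells = n_s + n_i
    y = y0.copy()
    k1 = np.empty_like(y)
    k2 = np.empty_like(y)
    k3 = np.empty_like(y)
    k4 = np.empty_like(y)
    ytmp = np.empty_like(y)
    u_s = np.zeros(n_s)
    u_i = np.zeros(n_i)

    n_rec = (n_steps // record_stride + 1) if record_stride > 0 else 0
    rec_t = np.zeros(n_rec)
    rec_v = np.zeros((n_rec, n_cells))
    spikes = np.zeros((n_cells, max_spikes))
    counts = np.zeros(n_cells, dtype=np.int64)
    last_spike = np.full(n_cells, -1.0e9)
    prev_v = np.empty(n_cells)
    _store_prev_v(y, prev_v, n_s, n_i)

    irec = 0
    if record_stride > 0:
        rec_t[0] = 0.0
        for cell in range(n_cells):
            rec_v[0, cell] = prev_v[cell]
        irec = 1

    clamp_count = 0
    diverged_at = -1.0
    for step in range(n_steps):
        t = step * dt
        network_rhs(t, y, k1, n_s, n_i, sp, ip, syn, g_is, g_si, g_ii_t,
                    iext_s, iext_i, th, pulse_par, has_pulse, onsets_data,
                    onsets_indptr, u_s, u_i, 0.0, 0.0, 0.0)
        for k in range(y.size):
            ytmp[k] = y[k] + 0.5 * dt * k1[k]
        network_rhs(t + 0.5 * dt, ytmp, k2, n_s, n_i, sp, ip, syn, g_is, g_si,
                    g_ii_t, iext_s, iext_i, th, pulse_par, has_pulse,
                    onsets_data, onsets_indptr, u_s, u_i, 0.0, 0.0, 0.0)
        for k in range(y.size):
            ytmp[k] = y[k] + 0.5 * dt * k2[k]
        network_rhs(t + 0.5 * dt, ytmp, k3, n_s, n_i, sp, ip, syn, g_is, g_si,
                    g_ii_t, iext_s, iext_i, th, pulse_par, has_pulse,
                    onsets_data, onsets_indptr, u_s, u_i, 0.0, 0.0, 0.0)
        for k in range(y.size):
            ytmp[k] = y[k] + dt * k3[k]
        network_rhs(t + dt, ytmp, k4, n_s, n_i, sp, ip, syn, g_is, g_si,
                    g_ii_t, iext_s, iext_i, th, pulse_par, has_pulse,
                    onsets_data, onsets_indptr, u_s, u_i, 0.0, 0.0, 0.0)
        for k in range(y.size):
            y[k] += dt / 6.0 * (k1[k] + 2.0 * k2[k] + 2.0 * k3[k] + k4[k])
        clamp_count += _clamp_gates(y, n_s, n_i)
        t_new = (step + 1) * dt
        _detect_step_spikes(
            y, prev_v, t_new, dt, n_s, n_i, thr, refrac, spikes, counts, last_spike
        )
        for cell in range(n_cells):
            if abs(prev_v[cell]) > v_div:
                diverged_at = t_new
                break
        if diverged_at >= 0.0:
            break
        if record_stride > 0 and (step + 1) % record_stride == 0 and irec < n_rec:
            rec_t[irec] = t_new
            for cell in range(n_cells):
                rec_v[irec, cell] = prev_v[cell]
            irec += 1
    return rec_t, rec_v, spikes, counts, clamp_count, diverged_at
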