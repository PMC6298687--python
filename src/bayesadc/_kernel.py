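"""Compiled closed-loop inner kernel.

One jitted function advances the two-population surrogate, the alpha-SWIFT
estimator and the pulse policy together at the 1 kHz sample rate.  The
arithmetic and the RNG consumption order (OU draw, then the two population
noise draws, once per step, after the controller acts) mirror the pure
Python reference path in :mod:`bayesadc.neuromass`, so both produce
bit-identical trajectories from the same seed (numba's ``np.random``
implements the same legacy MT19937 generator).

Policy modes: 0 = OFF, 1 = isochronal train at ``train_rate`` Hz,
2 = power-gated isochronal train, 3 = phase-triggered, 4 = phase-triggered
with power gate, 5 = phase-triggered off the oscillator's internal phase
(diagnostic oracle; not reachable through the public policy enum).

Isochronal trains use accumulated-phase scheduling (`acc += rate*dt`, fire
on wrap), which at 130 Hz and 1 kHz yields alternating 7/8-sample intervals
and an exactly correct long-run rate.

``template`` (if non-empty) is the per-pulse evoked-response template,
already scaled to the pulse amplitude; it is subtracted from the estimator
input stream to keep the phase estimator from locking onto the stimulus
artifact.  An empty array disables subtraction.
"""

import math

import numpy as np
from numba import njit

__all__ = ["closed_loop"]


@njit(cache=True)
def closed_loop(
    n_steps,
    seed,
    # model
    dt,
    delay_steps,
    gamma,
    g_ei,  # excitatory -> inhibitory
    g_ie,  # inhibitory -> excitatory
    qmax,
    v_th,
    slope,
    noise,
    drive,
    wander_frac,
    wander_tau,
    # estimator
    omega,  # rad/sample
    tau_slow_samples,
    tau_fast_samples,
    norm_gain,
    # policy
    mode,
    theta,
    p_th_db,
    pulse_dv,
    train_rate,
    stim_start_n,
    template,
    # measurement
    win_start_n,
):
    """Returns (lfp, pulse_idx, n_pulses, mean_linear_power, err_idx).

    ``err_idx`` is -1 on success, else the index of the first non-finite
    step.  ``mean_linear_power`` averages (|X_alpha|/norm_gain)^2 over
    samples at or after ``win_start_n``.
    """
    np.random.seed(seed)

    # fixed point by damped iteration (matches SimParams.fixed_point)
    ve0 = 0.0
    vi0 = 0.0
    for _ in range(800):
        se = qmax / (1.0 + np.exp(-(ve0 - v_th) / slope)) - qmax / 2.0
        vi0 += 0.1 * (g_ei * se - vi0)
        si = qmax / (1.0 + np.exp(-(vi0 - v_th) / slope)) - qmax / 2.0
        ve0 += 0.1 * ((drive - g_ie * si) - ve0)

    ve = ve0
    vi = vi0
    dve = 0.0
    dvi = 0.0
    d = delay_steps
    buf_e = np.full(d, ve0)
    buf_i = np.full(d, vi0)
    ptr = 0

    lfp = np.empty(n_steps)
    pulse_idx = np.empty(n_steps // 6 + 2, dtype=np.int64)
    n_pulses = 0

    ds_re = math.exp(-1.0 / tau_slow_samples) * math.cos(omega)
    ds_im = math.exp(-1.0 / tau_slow_samples) * math.sin(omega)
    df_re = math.exp(-1.0 / tau_fast_samples) * math.cos(omega)
    df_im = math.exp(-1.0 / tau_fast_samples) * math.sin(omega)
    xs = 0.0 + 0.0j
    xf = 0.0 + 0.0j
    ds = complex(ds_re, ds_im)
    df = complex(df_re, df_im)

    a_ou = math.exp(-dt / wander_tau)
    s_ou = wander_frac * math.sqrt(1.0 - a_ou * a_ou)
    eta = 0.0

    w0 = omega / dt  # rad/s at the center frequency

    ntmpl = len(template)
    abuf = np.zeros(ntmpl if ntmpl > 0 else 1)

    ph_prev = 0.0
    latch = False
    acc = 0.0
    x_prev = 0.0

    pow_sum = 0.0
    pow_cnt = 0

    err_idx = -1

    for k in range(n_steps):
        # --- estimator update on the previous LFP sample ---
        x = x_prev
        if ntmpl > 0:
            j = k % ntmpl
            x -= abuf[j]
            abuf[j] = 0.0
        xs = ds * xs + x
        xf = df * xf + x
        xa = xs - xf
        mag = abs(xa)
        if mag > 0.0:
            pw = 20.0 * math.log10(mag / norm_gain)
        else:
            pw = -300.0
        ph = math.atan2(xa.imag, xa.real)
        if k >= win_start_n:
            pow_sum += (mag / norm_gain) ** 2
            pow_cnt += 1

        # --- pulse decision ---
        phx = ph
        if mode == 5:
            phx = math.atan2(-dvi / w0, vi - vi0)
        pulse = 0.0
        if mode > 0 and k >= stim_start_n:
            if mode == 1 or mode == 2:
                gated = True
                if mode == 2 and pw <= p_th_db:
                    gated = False
                if gated:
                    acc += train_rate * dt
                    if acc >= 1.0:
                        acc -= 1.0
                        pulse = pulse_dv
            else:
                if phx - ph_prev < -math.pi:
                    latch = False
                dp = ph_prev - theta
                dp = math.atan2(math.sin(dp), math.cos(dp))
                dn = phx - theta
                dn = math.atan2(math.sin(dn), math.cos(dn))
                ok = (not latch) and dp < 0.0 and dn >= 0.0 and (dn - dp) < math.pi
                if ok and mode == 4 and pw <= p_th_db:
                    ok = False
                if ok:
                    pulse = pulse_dv
                    latch = True
        ph_prev = phx

        if pulse != 0.0:
            pulse_idx[n_pulses] = k
            n_pulses += 1
            ve += pulse
            if ntmpl > 0:
                for j in range(ntmpl - 1):
                    abuf[(k + 1 + j) % ntmpl] += template[j]

        # --- dynamics (matches neuromass.step) ---
        eta = a_ou * eta + s_ou * np.random.standard_normal()
        gam = gamma * (1.0 + eta)
        g2 = gam * gam
        se = qmax / (1.0 + np.exp(-(buf_e[ptr] - v_th) / slope)) - qmax / 2.0
        si = qmax / (1.0 + np.exp(-(buf_i[ptr] - v_th) / slope)) - qmax / 2.0
        n_e = noise * np.random.standard_normal()
        n_i = noise * np.random.standard_normal()
        acc_e = -2.0 * gam * dve - g2 * ve + g2 * (drive - g_ie * si + n_e)
        acc_i = -2.0 * gam * dvi - g2 * vi + g2 * (g_ei * se + n_i)
        buf_e[ptr] = ve
        buf_i[ptr] = vi
        ptr += 1
        if ptr == d:
            ptr = 0
        ve += dt * dve
        vi += dt * dvi
        dve += dt * acc_e
        dvi += dt * acc_i
        lfp[k] = vi - vi0
        x_prev = lfp[k]
        if not (math.isfinite(ve) and math.isfinite(vi)):
            err_idx = k
            break

    mean_pow = pow_sum / pow_cnt if pow_cnt > 0 else 0.0
    return lfp, pulse_idx[:n_pulses], n_pulses, mean_pow, err_idx
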