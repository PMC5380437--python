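"""Numba cores for the within-rendition closed-loop simulations.

The tutor reads the motor error of the unfolding rendition causally, so
the rate and spiking engines step through time with exponential-Euler
recursions for every filter state.  Everything that does not depend on
the loop state (conductor drive, plasticity-filtered conductor rates,
weight updates) is precomputed or postcomputed with vectorized numpy in
the drivers.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def rate_rendition(
    base,  # (n_t, n_s) conductor drive W^T c per student
    ybar,  # (n_ch, n_t) target
    M,  # (n_ch, n_s) true student-output map
    M_err,  # (n_ch, n_s) map the tutor believes (may be scrambled)
    theta,
    zeta_eff,  # zeta / (alpha - beta)
    w_gain,
    x_inh,
    dt,
    tau_out,
    tau_tutor,
    rho,
    saturating,  # 0/1
    g_out,  # (n_t, n_s) filled with tutor rates
    y_out,  # (n_ch, n_t) filled with motor output
):
    """One rendition of the rate model with a causal error-integrating tutor."""
    n_t, n_s = base.shape
    n_ch = ybar.shape[0]
    d_out = np.exp(-dt / tau_out)
    d_tut = np.exp(-dt / tau_tutor)
    b_tut = 1.0 - d_tut
    A = np.zeros(n_s)  # tutor error-integral state
    I = np.zeros(n_s)  # unnormalized tau_out filter state per student
    y = np.zeros(n_ch)
    e = np.zeros(n_ch)
    for n in range(n_t):
        for j in range(n_s):
            arg = zeta_eff * A[j]
            if saturating:
                g = theta - rho * np.tanh(arg / rho)
            else:
                g = theta - arg
            g_out[n, j] = g
            s = base[n, j] + w_gain * g - x_inh
            I[j] = I[j] * d_out + dt * s
        for a in range(n_ch):
            acc = 0.0
            for j in range(n_s):
                acc += M[a, j] * I[j]
            y[a] = acc
            y_out[a, n] = acc
            e[a] = acc - ybar[a, n]
        for j in range(n_s):
            eps = 0.0
            for a in range(n_ch):
                eps += M_err[a, j] * e[a]
            A[j] = A[j] * d_tut + b_tut * eps


@njit(cache=True)
def spiking_rendition(
    cond_drive,  # (n_t, n_s) summed conductor AMPA increments per step
    uniforms,  # (n_t, n_s) iid U(0,1) for tutor spike generation
    f_prog,  # (n_t, n_s) tutor rate program; used when use_prog == 1
    use_prog,  # 0: closed-loop saturating tutor; 1: fixed rate program
    ybar,  # (n_ch, n_t)
    M,
    M_err,
    # LIF constants
    V_R,
    V_th,
    tau_m,
    tau_ref,
    R_eff,
    tau_AMPA,
    tau_NMDA,
    tau_inh,
    r_nmda,
    w_tutor,
    g_inh,
    mg_over,  # Mg_conc / 3.57
    # tutor/output constants
    theta,
    rho,
    zeta_eff,
    tau_out,
    tau_tutor,
    dt,
    # outputs
    tut_spikes,  # (n_t, n_s) 0/1
    raster,  # (n_t, n_s) 0/1 student spikes
    y_out,  # (n_ch, n_t)
):
    """One rendition of the spiking student with an online Poisson tutor.

    Returns -1 on success, or the step index at which the membrane
    state stopped being finite.
    """
    n_t, n_s = cond_drive.shape
    n_ch = ybar.shape[0]
    dA = np.exp(-dt / tau_AMPA)
    dN = np.exp(-dt / tau_NMDA)
    dS = np.exp(-dt / tau_inh)
    em = np.exp(-dt / tau_m)
    d_out = np.exp(-dt / tau_out)
    d_tut = np.exp(-dt / tau_tutor)
    b_tut = 1.0 - d_tut

    V = np.full(n_s, V_R)
    I_A = np.zeros(n_s)
    I_N = np.zeros(n_s)
    S = np.zeros(n_s)
    ref = np.zeros(n_s)
    r_out = np.zeros(n_s)  # student rate estimate feeding the output
    A = np.zeros(n_s)  # tutor error-integral state
    y = np.zeros(n_ch)
    e = np.zeros(n_ch)

    for n in range(n_t):
        S_sum = 0.0
        for j in range(n_s):
            S[j] *= dS
            S_sum += S[j]
        V_inh = g_inh / n_s * S_sum
        for j in range(n_s):
            # tutor rate for this step
            if use_prog == 1:
                rate = f_prog[n, j]
            else:
                rate = theta - rho * np.tanh(zeta_eff * A[j] / rho)
            if rate < 0.0:
                rate = 0.0
            spk_t = 1.0 if uniforms[n, j] < rate * dt else 0.0
            tut_spikes[n, j] = spk_t

            I_A[j] = I_A[j] * dA + cond_drive[n, j] + (1.0 - r_nmda) * w_tutor * spk_t
            G = 1.0 / (1.0 + mg_over * np.exp(-V[j] / 16.13))
            I_N[j] = I_N[j] * dN + r_nmda * w_tutor * G * spk_t

            spike = 0.0
            if ref[j] > 0.0:
                ref[j] -= dt
                V[j] = V_R
            else:
                V_inf = V_R + R_eff * (I_A[j] + I_N[j]) - V_inh
                V[j] = V_inf + (V[j] - V_inf) * em
                if not np.isfinite(V[j]):
                    return n
                if V[j] >= V_th:
                    V[j] = V_R
                    ref[j] = tau_ref
                    S[j] += 1.0
                    spike = 1.0
            raster[n, j] = spike
            r_out[j] = r_out[j] * d_out + spike / tau_out
        for a in range(n_ch):
            acc = 0.0
            for j in range(n_s):
                acc += M[a, j] * r_out[j]
            y[a] = acc
            y_out[a, n] = acc
            e[a] = acc - ybar[a, n]
        for j in range(n_s):
            eps = 0.0
            for a in range(n_ch):
                eps += M_err[a, j] * e[a]
            A[j] = A[j] * d_tut + b_tut * eps
    return -1
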