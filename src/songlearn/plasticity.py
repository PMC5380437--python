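"""Two-timescale heterosynaptic plasticity of conductor-student synapses.

The conductor-student weight W_ij changes at a rate proportional to a
kernel-filtered copy of the conductor rate c_i and the deviation of the
tutor drive g_j from a threshold theta:

    dW_ij/dt = eta * (K * c_i)(t) * (g_j(t) - theta),
    K(t) = alpha * K1(t) - beta * K2(t),   K_i(t) = exp(-t/tau_i)/tau_i  (t >= 0).

alpha = 0 (or beta = 0) recovers a pure rate rule (sign of plasticity set
by the tutor rate vs. threshold); alpha/beta ~ 1 with alpha - beta = 1
mimics timing-dependent rules where conductor-leads-tutor potentiates and
coincident firing depresses.  The kernel shape fixes the optimal timescale
on which a tutor should integrate the motor error:

    tau_tutor* = (alpha*tau1 - beta*tau2) / (alpha - beta).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import Signal, exp_filter

__all__ = [
    "PlasticityParams",
    "kernel",
    "filter_conductor",
    "weight_update",
    "optimal_timescale",
]


@dataclass
class PlasticityParams:
    """Parameters of the heterosynaptic learning rule.

    alpha, beta : dimensionless kernel coefficients.  By convention
        alpha - beta = 1 (their overall scale is degenerate with eta);
        construction enforces this unless ``enforce_normalization`` is
        switched off for exploratory use.
    tau1, tau2 : kernel timescales in seconds (defaults 80 ms / 40 ms).
    eta : learning rate per rendition.
    theta : tutor firing-rate threshold in Hz.
    """

    alpha: float = 1.0
    beta: float = 0.0
    tau1: float = 0.080
    tau2: float = 0.040
    eta: float = 1e-3
    theta: float = 80.0
    enforce_normalization: bool = True

    def __post_init__(self) -> None:
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("plasticity timescales must be positive")
        if self.eta < 0:
            raise ValueError("eta must be non-negative")
        if self.enforce_normalization and abs((self.alpha - self.beta) - 1.0) > 1e-9:
            raise ValueError(
                "alpha - beta must equal 1 (pass enforce_normalization=False "
                "to lift the convention)"
            )


def kernel(t, p: PlasticityParams) -> np.ndarray:
    """Evaluate the plasticity kernel K(t); causal (0 for t < 0).

    Vectorized over ``t`` (seconds).
    """
    t = np.asarray(t, dtype=float)
    k1 = np.where(t >= 0, np.exp(-np.clip(t, 0, None) / p.tau1) / p.tau1, 0.0)
    k2 = np.where(t >= 0, np.exp(-np.clip(t, 0, None) / p.tau2) / p.tau2, 0.0)
    return p.alpha * k1 - p.beta * k2


def filter_conductor(c: Signal, p: PlasticityParams) -> Signal:
    """Kernel-filtered conductor rates, c~_i = (K * c_i)(t)."""
    f1 = exp_filter(c, p.tau1, normalized=True)
    f2 = exp_filter(c, p.tau2, normalized=True)
    return Signal(c.grid, p.alpha * f1.values - p.beta * f2.values, c.units)


def weight_update(
    W: np.ndarray,
    c_filtered: Signal,
    g: Signal,
    p: PlasticityParams,
    positivity: bool = True,
) -> np.ndarray:
    """Apply one rendition's accumulated weight change.

    Delta W_ij = eta * int_0^T c~_i(t) (g_j(t) - theta) dt, evaluated by
    trapezoid quadrature on the grid.  Returns the updated matrix; with
    ``positivity`` (default) the result is clipped at 0 elementwise
    after the rendition's update, modelling excitatory synapses that
    cannot change sign.
    """
    W = np.asarray(W, dtype=float)
    if W.shape != (c_filtered.n_channels, g.n_channels):
        raise ValueError(
            f"W shape {W.shape} inconsistent with {c_filtered.n_channels} "
            f"conductors x {g.n_channels} students"
        )
    if c_filtered.grid.n_samples != g.grid.n_samples:
        raise ValueError("conductor and tutor signals must share a grid")
    dt = g.grid.dt
    # trapezoid weights on the shared grid
    wts = np.full(g.grid.n_samples, dt)
    wts[0] = wts[-1] = dt / 2.0
    dW = p.eta * (c_filtered.values * wts) @ (g.values - p.theta).T
    W_new = W + dW
    if positivity:
        np.clip(W_new, 0.0, None, out=W_new)
    return W_new


def optimal_timescale(p: PlasticityParams) -> float:
    """Matched tutor error-integration timescale tau_tutor* (seconds).

    tau_tutor* = (alpha*tau1 - beta*tau2)/(alpha - beta).  Raises for
    alpha = beta, where the kernel has zero net area and no matched
    timescale exists.
    """
    denom = p.alpha - p.beta
    if denom == 0:
        raise ZeroDivisionError("optimal timescale undefined for alpha == beta")
    return (p.alpha * p.tau1 - p.beta * p.tau2) / denom
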