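"""Tutor signals: matched, saturating, and reinforcement-learned.

The ideal (matched) tutor reports the motor error integrated over the
recent past with timescale tau_tutor,

    g_j(t) = theta - [zeta/(alpha-beta)] * (1/tau_tutor)
             * int_0^t eps_j(t') exp(-(t-t')/tau_tutor) dt',

and drives gradient-descent learning in the student exactly when
tau_tutor equals the optimum implied by the student plasticity kernel.
The saturating variant passes the same integral through a tanh so
firing rates stay in [theta - rho, theta + rho] (typically 0-160 Hz).
The reinforcement tutor knows nothing of the student-output map: it
shapes its firing-rate program f_j(t) from a scalar reward by
correlating its own rate fluctuations with reward fluctuations
(node perturbation with reward and activity baselines).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .signals import Signal, exp_filter
from .plasticity import PlasticityParams

__all__ = [
    "TutorSpec",
    "ReinforcementState",
    "matched_tutor",
    "saturating_tutor",
    "reinforcement_update",
    "reward_from_loss",
]

#: exponential timescale (s) for the within-rendition reward baseline
REWARD_BASELINE_TAU = 1.0
#: e-fold decay of the tutor-activity baseline: one e-fold per 5 renditions
GBAR_DECAY_RENDITIONS = 5.0


@dataclass
class TutorSpec:
    """How the guiding signal is produced.

    mode : 'matched' | 'saturating' | 'reinforcement'
    tau_tutor : error-integration (or eligibility) timescale, seconds.
        0 is allowed only in reinforcement mode (memory-less tutor).
    zeta : gain of the error-to-rate conversion (the ratio of the
        gradient-descent rate to the synaptic learning rate).
    rho : half-range of tutor firing rates in Hz (saturating mode).
    theta : baseline tutor rate in Hz, shared with the plasticity
        threshold.
    eta_tutor : learning rate of the reinforcement rule.
    """

    mode: str = "matched"
    tau_tutor: float = 0.080
    zeta: float = 200.0
    rho: float = 80.0
    theta: float = 80.0
    eta_tutor: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("matched", "saturating", "reinforcement"):
            raise ValueError(f"unknown tutor mode {self.mode!r}")
        if self.tau_tutor < 0:
            raise ValueError("tau_tutor must be non-negative")
        if self.mode != "reinforcement" and self.tau_tutor == 0:
            raise ValueError("tau_tutor must be positive outside reinforcement mode")
        if self.mode == "saturating" and self.rho <= 0:
            raise ValueError("rho must be positive in saturating mode")


def _integrated_error(eps: Signal, spec: TutorSpec, p: PlasticityParams) -> np.ndarray:
    if p.alpha == p.beta:
        raise ValueError("tutor gain undefined for alpha == beta")
    filt = exp_filter(eps, spec.tau_tutor, normalized=True)
    return (spec.zeta / (p.alpha - p.beta)) * filt.values


def matched_tutor(eps: Signal, spec: TutorSpec, p: PlasticityParams) -> Signal:
    """Ideal tutor rates from the motor error (unbounded linear form)."""
    return Signal(eps.grid, spec.theta - _integrated_error(eps, spec, p), units="Hz")


def saturating_tutor(eps: Signal, spec: TutorSpec, p: PlasticityParams) -> Signal:
    """Tutor rates passed through a sigmoidal bound.

    g~_j(t) = theta - rho * tanh(arg/rho) with arg the matched-tutor
    integral term, so rates lie in [theta - rho, theta + rho]; with
    theta = rho = 80 Hz the range is 0-160 Hz.  Agrees with
    :func:`matched_tutor` to first order for |arg| << rho.
    """
    if spec.rho <= 0:
        raise ValueError("rho must be positive")
    arg = _integrated_error(eps, spec, p)
    return Signal(
        eps.grid, spec.theta - spec.rho * np.tanh(arg / spec.rho), units="Hz"
    )


def reward_from_loss(y: Signal, y_target: Signal) -> Signal:
    """Instantaneous scalar reward R(t) = -sum_a (y_a - ybar_a)^2.

    Any bounded monotone transform of the per-time mismatch would do;
    the negative squared error makes the reward integrate to -2x the
    quadratic loss.
    """
    if y.grid.n_samples != y_target.grid.n_samples:
        raise ValueError("output and target must share a grid")
    d = y.values - y_target.values
    return Signal(y.grid, -np.sum(d * d, axis=0, keepdims=True))


@dataclass
class ReinforcementState:
    """Carry-over state of the reinforcement tutor.

    f : current tutor firing-rate program (Hz, >= 0 elementwise).
    g_bar : rendition-averaged tutor activity baseline (same shape).
    R_bar : reward carried across renditions — the reward at the end of
        one rendition seeds the baseline at the start of the next.
    """

    f: Signal
    g_bar: Signal
    R_bar: float = 0.0

    def __post_init__(self) -> None:
        if np.any(self.f.values < 0):
            raise ValueError("tutor firing rates must be non-negative")
        if self.f.values.shape != self.g_bar.values.shape:
            raise ValueError("f and g_bar must have the same shape")


def reinforcement_update(
    state: ReinforcementState,
    g_actual: Signal,
    R: Signal,
    spec: TutorSpec,
) -> ReinforcementState:
    """One rendition's update of the tutor firing-rate program.

    With xi_j(t) = g_j(t) - gbar_j(t) the rate fluctuation of the just
    completed rendition and Rbar(t) the running reward baseline
    (exponential smoothing of R with a 1 s timescale, seeded by the
    previous rendition's terminal reward):

    tau_tutor = 0:  Delta f_j(t) = eta_tutor (R(t) - Rbar(t)) xi_j(t)
    tau_tutor > 0:  the same product filtered causally over tau_tutor.

    The updated f is clipped at zero (firing rates); the activity
    baseline gbar relaxes toward the realized rates with one e-fold of
    decay per five renditions; the new carried reward baseline is the
    rendition's terminal reward.
    """
    if g_actual.grid.n_samples != R.grid.n_samples:
        raise ValueError("tutor activity and reward must share a grid")
    if g_actual.values.shape != state.f.values.shape:
        raise ValueError("tutor activity shape mismatch with stored program")

    grid = g_actual.grid
    # within-rendition reward baseline, seeded by the carried terminal reward
    a = np.exp(-grid.dt / REWARD_BASELINE_TAU)
    r = R.values[0]
    rbar = np.empty_like(r)
    prev = state.R_bar
    for k in range(r.size):
        prev = a * prev + (1.0 - a) * r[k]
        rbar[k] = prev

    xi = g_actual.values - state.g_bar.values
    drive = (r - rbar) * xi  # broadcast over student rows
    if spec.tau_tutor > 0:
        drive = exp_filter(Signal(grid, drive), spec.tau_tutor, normalized=True).values
    f_new = np.clip(state.f.values + spec.eta_tutor * drive, 0.0, None)

    lam = np.exp(-1.0 / GBAR_DECAY_RENDITIONS)
    gbar_new = lam * state.g_bar.values + (1.0 - lam) * g_actual.values

    return ReinforcementState(
        f=Signal(grid, f_new, units="Hz"),
        g_bar=Signal(grid, gbar_new, units="Hz"),
        R_bar=float(r[-1]),
    )
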