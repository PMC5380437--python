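"""Linear rate-based conductor-student-output network.

The conductor (an HVC-like timebase) drives the student (an RA-like
premotor pool) through plastic weights W; the student's activity is
linearly combined into a small number of motor output channels and
smoothed with a muscle-like exponential response:

    s_j(t) = sum_i W_ij c_i(t) + w * g_j(t) - x_inh
    y_a(t) = sum_j M_aj int_0^t s_j(t') exp(-(t-t')/tau_out) dt'

Learning performance is scored by a quadratic loss over the rendition,
and the per-student-neuron motor error projects the output mismatch
back through the student-output map M.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .signals import Signal, TimeGrid, exp_filter, make_rng

__all__ = [
    "NetworkState",
    "TargetSpec",
    "generate_conductor_rates",
    "student_rates",
    "motor_output",
    "motor_error",
    "loss",
    "rms_error",
    "generate_target",
    "make_output_map",
    "init_rate_weights",
]

#: muscle-like output smoothing timescale (seconds)
DEFAULT_TAU_OUT = 0.025


@dataclass
class NetworkState:
    """Weights and biases of the rate-based network.

    W : (n_conductor, n_student) conductor-student weights (plastic).
    M : (n_channels, n_student) student-output map; in the default
        construction each student neuron contributes to exactly one
        channel with weight 1/(students per channel).
    w : scalar tutor-student gain.
    x_inh : constant inhibitory bias subtracted from every student rate.
    """

    W: np.ndarray
    M: np.ndarray
    w: float = 1.0
    x_inh: float = 0.0

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.M = np.asarray(self.M, dtype=float)
        if self.W.shape[1] != self.M.shape[1]:
            raise ValueError("W and M disagree on the number of student neurons")

    @property
    def n_conductor(self) -> int:
        return self.W.shape[0]

    @property
    def n_student(self) -> int:
        return self.W.shape[1]

    @property
    def n_channels(self) -> int:
        return self.M.shape[0]


@dataclass
class TargetSpec:
    """Specification of a smooth random target output.

    The targets emulate air-sac-pressure-like traces: smooth, with a
    characteristic timescale of tens of milliseconds, but otherwise
    arbitrary.
    """

    n_channels: int = 2
    smoothness: float = 0.050  # seconds
    amplitude: tuple[float, float] = (0.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.smoothness <= 0:
            raise ValueError("smoothness timescale must be positive")


def generate_conductor_rates(
    grid: TimeGrid,
    n_conductor: int,
    burst_len: float = 0.010,
    burst_rate: float = 100.0,
) -> Signal:
    """Burst raster of conductor firing rates.

    Each neuron is silent except for a single contiguous burst of
    duration ``burst_len`` (default 10 ms) at constant rate
    ``burst_rate``; burst onsets are spread evenly so the population
    tiles the whole program and no pattern repeats.  With
    ``n_conductor * burst_len >= T`` the active windows cover [0, T]
    and the summed population rate is approximately constant in time.
    """
    T = grid.duration
    if burst_len > T:
        raise ValueError("burst_len must not exceed the program duration")
    if burst_len <= 0:
        raise ValueError("burst_len must be positive")
    n_t = grid.n_samples
    values = np.zeros((n_conductor, n_t))
    n_burst = max(1, int(round(burst_len / grid.dt)))
    for i in range(n_conductor):
        start = int(round(n_t * i / n_conductor))
        values[i, start : min(start + n_burst, n_t)] = burst_rate
    return Signal(grid, values, units="Hz")


def student_rates(state: NetworkState, c: Signal, g: Signal) -> Signal:
    """Student firing rates s_j(t) = sum_i W_ij c_i + w g_j - x_inh."""
    if c.n_channels != state.n_conductor:
        raise ValueError("conductor signal rows != n_conductor")
    if g.n_channels != state.n_student:
        raise ValueError("tutor signal rows != n_student")
    if c.grid.n_samples != g.grid.n_samples:
        raise ValueError("conductor and tutor signals must share a grid")
    s = state.W.T @ c.values + state.w * g.values - state.x_inh
    return Signal(c.grid, s, units="Hz")


def motor_output(
    state: NetworkState, s: Signal, tau_out: float = DEFAULT_TAU_OUT
) -> Signal:
    """Smoothed motor output y_a(t).

    y_a(t) = sum_j M_aj int_0^t s_j(t') exp(-(t-t')/tau_out) dt'
    (unnormalized kernel; the smoothing mimics slow muscle response and
    stabilizes learning by removing high-frequency output components).
    """
    if s.n_channels != state.n_student:
        raise ValueError("student signal rows != n_student")
    filt = exp_filter(s, tau_out, normalized=False)
    return Signal(s.grid, state.M @ filt.values, units=s.units)


def motor_error(state: NetworkState, y: Signal, y_target: Signal) -> Signal:
    """Per-student-neuron motor error eps_j(t) = sum_a M_aj (y_a - ybar_a)."""
    if y.grid.n_samples != y_target.grid.n_samples or y.grid.dt != y_target.grid.dt:
        raise ValueError("output and target must share a grid")
    if y.n_channels != y_target.n_channels or y.n_channels != state.n_channels:
        raise ValueError("output/target channel count mismatch")
    return Signal(y.grid, state.M.T @ (y.values - y_target.values), units=y.units)


def loss(y: Signal, y_target: Signal) -> float:
    """Quadratic loss L = 1/2 sum_a int_0^T (y_a - ybar_a)^2 dt (trapezoid)."""
    if y.grid.n_samples != y_target.grid.n_samples or y.grid.dt != y_target.grid.dt:
        raise ValueError("output and target must share a grid")
    if y.n_channels != y_target.n_channels:
        raise ValueError("output/target channel count mismatch")
    d2 = (y.values - y_target.values) ** 2
    return 0.5 * float(np.sum(np.trapezoid(d2, dx=y.grid.dt, axis=1)))


def rms_error(y: Signal, y_target: Signal) -> float:
    """Per-sample RMS mismatch, a normalized companion to :func:`loss`."""
    d = y.values - y_target.values
    return float(np.sqrt(np.mean(d * d)))


def generate_target(spec: TargetSpec, grid: TimeGrid) -> Signal:
    """Smooth random target traces, deterministic given the spec's seed.

    Per channel: white noise low-pass filtered at the smoothness
    timescale (Gaussian kernel with sigma = smoothness), then affinely
    mapped into the amplitude range.
    """
    rng = make_rng(spec.seed)
    n_t = grid.n_samples
    sigma = spec.smoothness / grid.dt
    lo, hi = spec.amplitude
    values = np.empty((spec.n_channels, n_t))
    for a in range(spec.n_channels):
        x = gaussian_filter1d(rng.standard_normal(n_t), sigma, mode="reflect")
        xmin, xmax = x.min(), x.max()
        if xmax - xmin < 1e-12:
            values[a] = (lo + hi) / 2.0
        else:
            values[a] = lo + (hi - lo) * (x - xmin) / (xmax - xmin)
    return Signal(grid, values)


def make_output_map(n_channels: int, n_student: int) -> np.ndarray:
    """Student-output map M with disjoint student pools per channel.

    Each student neuron contributes to exactly one output channel
    (consecutive blocks), with equal weights 1/(students per channel).
    """
    if n_student % n_channels != 0:
        raise ValueError("n_student must be divisible by n_channels")
    per = n_student // n_channels
    M = np.zeros((n_channels, n_student))
    for a in range(n_channels):
        M[a, a * per : (a + 1) * per] = 1.0 / per
    return M


def init_rate_weights(
    n_conductor: int, n_student: int, rng: np.random.Generator, scale: float = 0.2
) -> np.ndarray:
    """Small positive uniform initial conductor-student weights."""
    return scale * rng.random((n_conductor, n_student))
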