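"""Leaky integrate-and-fire student network with AMPA/NMDA synapses.

The student is a pool of current-based LIF neurons.  Conductor spikes
arrive through plastic AMPA synapses W_ij; tutor spikes arrive through
a fixed-strength mixture of AMPA and NMDA (fraction ``r`` NMDA), with
the NMDA contribution gated by a voltage-dependent magnesium-block
factor G(V).  A global activity-dependent inhibition proportional to
the population spike-rate estimate stabilizes the network:

    tau_m dV_j/dt = (V_R - V_j) + R (I_AMPA + I_NMDA) - V_inh
    V_inh = (g_inh / N_student) * sum_j S_j,   dS_j/dt = -S_j/tau_inh + spikes_j

Conductor neurons are not simulated at the voltage level: each fires
one precisely timed burst of 5-6 spikes per program, with sub-ms onset
and per-spike jitter.  Tutor neurons fire inhomogeneous Poisson trains
whose rate program carries the guiding signal.

A note on units: all synaptic strengths are stated on the same
numerical scale as the network defaults (nA labels, mean conductor
synapse 32.6, tutor synapse 100).  The product R * I is converted to
millivolts of drive through a single ``current_scale`` constant chosen
so that unitary EPSPs land in the physiological few-mV range and the
network fires irregularly at juvenile-like rates before training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .signals import Signal, TimeGrid

__all__ = [
    "SpikingParams",
    "SpikeTrain",
    "LIFState",
    "nmda_gating",
    "step_network",
    "generate_conductor_spikes",
    "generate_poisson_tutor",
    "estimate_rates",
    "init_spiking_weights",
]


@dataclass
class SpikingParams:
    """Constants of the spiking student network (defaults: songbird-like).

    Voltages in mV, timescales in seconds, synaptic strengths in the
    model's nA-labelled units, input resistance in MOhm.
    """

    V_R: float = -72.3  # reset / rest potential, mV
    V_th: float = -48.6  # spike threshold, mV
    tau_m: float = 24.5e-3  # membrane time constant
    tau_ref: float = 1.1e-3  # absolute refractory period
    R_in: float = 353.0  # input resistance, MOhm
    tau_AMPA: float = 6.3e-3
    tau_NMDA: float = 81.5e-3
    r_nmda: float = 0.9  # NMDA fraction of tutor synapses
    w_tutor: float = 100.0  # tutor synapse strength
    g_inh: float = 1.80  # strength of global inhibition, mV
    tau_inh: float = 20e-3
    Mg_conc: float = 1.0  # mM; enters the NMDA gating factor
    n_conductor: int = 300
    n_student: int = 80
    synapses_per_student: int = 148
    W_mean: float = 32.6  # mean conductor-student synapse
    W_sd: float = 17.4  # sd of conductor-student synapses
    conductor_burst_rate: float = 632.0  # Hz, intra-burst firing rate
    burst_spikes_min: int = 5
    burst_spikes_max: int = 6
    onset_jitter: float = 0.3e-3  # uniform +- jitter on burst onset
    spike_jitter: float = 0.2e-3  # uniform +- jitter per spike
    current_scale: float = 1.0e-3  # mV of drive per (nA-unit x MOhm)

    def __post_init__(self) -> None:
        for name in ("tau_m", "tau_ref", "tau_AMPA", "tau_NMDA", "tau_inh"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.V_th <= self.V_R:
            raise ValueError("V_th must exceed V_R")
        if not 0.0 <= self.r_nmda <= 1.0:
            raise ValueError("r_nmda must lie in [0, 1]")

    @property
    def R_eff(self) -> float:
        """Effective resistance: mV of steady drive per unit current."""
        return self.R_in * self.current_scale


@dataclass
class SpikeTrain:
    """Per-neuron sorted spike-time lists (seconds)."""

    times: list  # list of 1-D float arrays, one per neuron

    def __post_init__(self) -> None:
        self.times = [np.sort(np.asarray(t, dtype=float)) for t in self.times]

    @property
    def n_neurons(self) -> int:
        return len(self.times)

    def counts(self) -> np.ndarray:
        return np.array([len(t) for t in self.times])

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Flatten to (neuron_id, time) event arrays."""
        ids = np.concatenate(
            [np.full(len(t), i, dtype=int) for i, t in enumerate(self.times)]
        ) if self.times else np.empty(0, dtype=int)
        ts = np.concatenate(self.times) if self.times else np.empty(0)
        return ids, ts

    def to_csv(self, path) -> None:
        import pandas as pd

        ids, ts = self.to_arrays()
        pd.DataFrame({"neuron_id": ids, "time_s": ts}).to_csv(path, index=False)

    @classmethod
    def from_raster(cls, raster: np.ndarray, grid: TimeGrid) -> "SpikeTrain":
        """Build from a (n_time, n_neurons) 0/1 raster on a grid."""
        t = grid.times
        return cls([t[raster[:, j] > 0] for j in range(raster.shape[1])])


@dataclass
class LIFState:
    """Mutable state of the student pool."""

    V: np.ndarray
    I_AMPA: np.ndarray
    I_NMDA: np.ndarray
    S: np.ndarray
    refractory: np.ndarray

    @classmethod
    def initial(cls, n_student: int, params: SpikingParams) -> "LIFState":
        z = lambda: np.zeros(n_student)
        return cls(np.full(n_student, params.V_R), z(), z(), z(), z())


def nmda_gating(V, Mg_conc: float = 1.0) -> np.ndarray:
    """Magnesium-block gating of NMDA current.

    G(V) = [1 + (Mg/3.57 mM) * exp(-V / 16.13 mV)]^-1, strictly
    increasing in V, approaching 1 at depolarized potentials.
    """
    V = np.asarray(V, dtype=float)
    return 1.0 / (1.0 + (Mg_conc / 3.57) * np.exp(-V / 16.13))


def step_network(
    state: LIFState,
    cond_input: np.ndarray,
    tutor_spikes: np.ndarray,
    params: SpikingParams,
    dt: float,
    I_ext: float = 0.0,
) -> np.ndarray:
    """Advance the student pool by one step of length ``dt`` in place.

    ``cond_input`` is the summed conductor AMPA increment per student
    for events in [t, t+dt) (i.e. sum_i W_ij over conductor spikes);
    ``tutor_spikes`` is the per-student tutor spike count in the step.
    Within a step: synaptic inputs are applied, the membrane relaxes by
    exponential Euler (exact for piecewise-constant input), and then
    thresholds are tested; crossing resets V to V_R, starts the
    refractory clock and increments the inhibition trace.  Returns the
    boolean array of student spikes emitted this step.

    Raises ``FloatingPointError`` (with the offending values) if the
    state leaves the finite range.
    """
    if dt > 0.1 * min(params.tau_AMPA, params.tau_m, params.tau_inh):
        raise ValueError("dt too coarse for the fastest synaptic timescale")
    p = params
    state.I_AMPA *= math.exp(-dt / p.tau_AMPA)
    state.I_NMDA *= math.exp(-dt / p.tau_NMDA)
    state.S *= math.exp(-dt / p.tau_inh)
    state.I_AMPA += cond_input + (1.0 - p.r_nmda) * p.w_tutor * tutor_spikes
    state.I_NMDA += p.r_nmda * p.w_tutor * nmda_gating(state.V, p.Mg_conc) * tutor_spikes

    V_inh = p.g_inh / state.V.size * state.S.sum()
    em = math.exp(-dt / p.tau_m)
    V_inf = p.V_R + p.R_eff * (state.I_AMPA + state.I_NMDA + I_ext) - V_inh
    active = state.refractory <= 0
    state.V[active] = V_inf[active] + (state.V[active] - V_inf[active]) * em
    state.V[~active] = p.V_R
    state.refractory[~active] -= dt

    if not np.all(np.isfinite(state.V)):
        raise FloatingPointError("membrane potential diverged (NaN/inf)")

    spiked = active & (state.V >= p.V_th)
    state.V[spiked] = p.V_R
    state.refractory[spiked] = p.tau_ref
    state.S[spiked] += 1.0
    return spiked


def generate_conductor_spikes(
    grid: TimeGrid,
    params: SpikingParams,
    rng: np.random.Generator,
    n_conductor: int | None = None,
    jitter: bool = True,
    randomize_burst_size: bool = False,
) -> SpikeTrain:
    """Precisely timed conductor bursts tiling the motor program.

    Each neuron fires one burst of 5-6 spikes (alternating
    deterministically unless ``randomize_burst_size``) at the
    intra-burst rate; burst onsets tile [0, T] evenly.  Onset jitter is
    uniform over +-0.3 ms and per-spike jitter uniform over +-0.2 ms,
    redrawn on every call (every rendition).
    """
    p = params
    n = p.n_conductor if n_conductor is None else n_conductor
    T = grid.duration
    isi = 1.0 / p.conductor_burst_rate
    trains = []
    for i in range(n):
        if randomize_burst_size:
            n_spk = int(rng.integers(p.burst_spikes_min, p.burst_spikes_max + 1))
        else:
            n_spk = p.burst_spikes_min + (i % 2) * (
                p.burst_spikes_max - p.burst_spikes_min
            )
        onset = grid.t_start + T * i / n
        if jitter:
            onset += rng.uniform(-p.onset_jitter, p.onset_jitter)
        t = onset + isi * np.arange(n_spk)
        if jitter:
            t = t + rng.uniform(-p.spike_jitter, p.spike_jitter, size=n_spk)
        t = t[(t >= grid.t_start) & (t < grid.t_end)]
        trains.append(np.sort(t))
    return SpikeTrain(trains)


def generate_poisson_tutor(f: Signal, rng: np.random.Generator) -> SpikeTrain:
    """Inhomogeneous Poisson spike trains with rate program f_j(t) (Hz).

    Per-bin Bernoulli realization with probability f * dt; requires
    f >= 0 everywhere.
    """
    if np.any(f.values < 0):
        raise ValueError("tutor firing rates must be non-negative")
    dt = f.grid.dt
    prob = np.clip(f.values * dt, 0.0, 1.0)
    hits = rng.random(prob.shape) < prob
    t = f.grid.times
    return SpikeTrain([t[hits[j]] for j in range(f.n_channels)])


def estimate_rates(spikes: SpikeTrain, tau_est: float, grid: TimeGrid) -> Signal:
    """Exponential-kernel firing-rate estimate in Hz.

    rate_j(t) = (1/tau_est) * sum_k exp(-(t - t_k)/tau_est) for t >= t_k,
    evaluated with spikes assigned to their grid bin.  tau_est between
    5 ms and 40 ms is the conventional range for feeding the plasticity
    rule; values outside it are accepted.
    """
    if tau_est <= 0:
        raise ValueError("tau_est must be positive")
    n_t = grid.n_samples
    counts = np.zeros((spikes.n_neurons, n_t))
    for j, t in enumerate(spikes.times):
        idx = np.floor((t - grid.t_start) / grid.dt).astype(int)
        idx = idx[(idx >= 0) & (idx < n_t)]
        np.add.at(counts[j], idx, 1.0)
    a = math.exp(-grid.dt / tau_est)
    rates = lfilter([1.0 / tau_est], [1.0, -a], counts, axis=1)
    return Signal(grid, rates, units="Hz")


def init_spiking_weights(
    params: SpikingParams,
    rng: np.random.Generator,
    n_conductor: int | None = None,
    n_student: int | None = None,
    n_synapses: int | None = None,
) -> np.ndarray:
    """Sparse log-normal initial conductor-student weight matrix.

    Each student neuron receives exactly ``n_synapses`` nonzero
    conductor synapses chosen uniformly at random; nonzero weights are
    drawn from the log-normal distribution whose moments match
    (W_mean, W_sd).  Returns a dense (n_conductor, n_student) matrix
    with zeros at absent synapses.
    """
    p = params
    n_c = p.n_conductor if n_conductor is None else n_conductor
    n_s = p.n_student if n_student is None else n_student
    k = p.synapses_per_student if n_synapses is None else n_synapses
    if k > n_c:
        raise ValueError("cannot place more synapses than conductors")
    sigma2 = math.log(1.0 + (p.W_sd / p.W_mean) ** 2)
    mu = math.log(p.W_mean) - sigma2 / 2.0
    W = np.zeros((n_c, n_s))
    for j in range(n_s):
        pre = rng.choice(n_c, size=k, replace=False)
        W[pre, j] = rng.lognormal(mu, math.sqrt(sigma2), size=k)
    return W
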