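"""Descriptive spike-train statistics, burst detection and pruning counts.

The statistics vector (mean rate, ISI coefficient of variation and
skewness, burst frequency/duration and intra-burst rate) summarizes how
juvenile-like (tonic, irregular) or adult-like (bursty, stereotyped) a
student spike pattern is.  Bursts are segmented with a hysteresis rule
on the estimated firing rate: a burst starts when the rate crosses
80 Hz upward and lasts until it falls below 40 Hz.  The scalar
relative-error objective compares a simulated statistics vector with an
observed one and is the fitting objective an external optimizer (e.g.
CMA-ES) would minimize; the optimizer itself is out of scope here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
from scipy import stats as sp_stats

from .signals import Signal, TimeGrid
from .spiking import SpikeTrain, estimate_rates

__all__ = [
    "SpikeStatsVector",
    "detect_bursts",
    "spike_statistics",
    "relative_error",
    "count_pruned",
    "mean_inputs_per_neuron",
    "BURST_ON_HZ",
    "BURST_OFF_HZ",
]

BURST_ON_HZ = 80.0
BURST_OFF_HZ = 40.0


@dataclass
class SpikeStatsVector:
    """Descriptive statistics of a spike pattern (NaN = undefined)."""

    mean_rate: float = np.nan  # Hz
    isi_cv: float = np.nan
    isi_skewness: float = np.nan
    burst_frequency: float = np.nan  # bursts per second
    mean_burst_duration: float = np.nan  # seconds
    intra_burst_rate: float = np.nan  # Hz

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])

    @property
    def names(self) -> list[str]:
        return [f.name for f in fields(self)]

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame([{f.name: getattr(self, f.name) for f in fields(self)}]).to_csv(
            path, index=False
        )


def _detect_bursts_row(rate: np.ndarray, times: np.ndarray, on: float, off: float):
    intervals = []
    in_burst = False
    start = 0.0
    for k in range(rate.size):
        if not in_burst and rate[k] > on:
            in_burst = True
            start = times[k]
        elif in_burst and rate[k] < off:
            intervals.append((start, times[k]))
            in_burst = False
    if in_burst:
        intervals.append((start, times[-1]))
    return intervals


def detect_bursts(
    rate: Signal, on: float = BURST_ON_HZ, off: float = BURST_OFF_HZ
):
    """Hysteresis burst segmentation of an estimated firing rate (Hz).

    A burst opens when the rate exceeds ``on`` (default 80 Hz) and
    closes when it drops below ``off`` (default 40 Hz).  For a
    single-row signal returns a list of (start, end) times; for a
    multi-row signal, a list of such lists (one per neuron).  Intervals
    are sorted and non-overlapping by construction.
    """
    per_row = [
        _detect_bursts_row(rate.values[j], rate.grid.times, on, off)
        for j in range(rate.n_channels)
    ]
    return per_row[0] if rate.n_channels == 1 else per_row


def spike_statistics(
    spikes: SpikeTrain,
    rate_kernel_tau: float = 0.010,
    grid: TimeGrid | None = None,
    duration: float | None = None,
    pooled: bool = False,
) -> SpikeStatsVector:
    """Descriptive statistics of a population spike pattern.

    ISI statistics need at least 2 intervals (CV) / 3 intervals
    (skewness) and are NaN otherwise.  Burst statistics are computed
    from the exponential-kernel rate estimate (``rate_kernel_tau``,
    default 10 ms) with the 80/40 Hz hysteresis rule.  By default each
    statistic is computed per neuron and then averaged over neurons
    with defined values; ``pooled=True`` pools ISIs across neurons
    instead.
    """
    if grid is None:
        if duration is None:
            tmax = max((t[-1] for t in spikes.times if len(t)), default=0.0)
            duration = tmax if tmax > 0 else 1.0
        grid = TimeGrid(t_end=duration, dt=1e-3)
    T = grid.duration

    rates = spikes.counts() / T
    all_isis = [np.diff(t) for t in spikes.times]

    if pooled:
        isis = np.concatenate([d for d in all_isis if d.size]) if any(
            d.size for d in all_isis
        ) else np.empty(0)
        cv = _isi_cv(isis)
        skew = _isi_skew(isis)
    else:
        cvs = [_isi_cv(d) for d in all_isis]
        skews = [_isi_skew(d) for d in all_isis]
        cv = _nanmean(cvs)
        skew = _nanmean(skews)

    est = estimate_rates(spikes, rate_kernel_tau, grid)
    burst_freqs, burst_durs, intra_rates = [], [], []
    for j in range(spikes.n_neurons):
        intervals = _detect_bursts_row(
            est.values[j], grid.times, BURST_ON_HZ, BURST_OFF_HZ
        )
        burst_freqs.append(len(intervals) / T)
        if intervals:
            durs = [e - s for s, e in intervals]
            burst_durs.append(float(np.mean(durs)))
            n_in = [
                np.sum((spikes.times[j] >= s) & (spikes.times[j] < e))
                for s, e in intervals
            ]
            tot_dur = float(np.sum(durs))
            if tot_dur > 0:
                intra_rates.append(float(np.sum(n_in)) / tot_dur)

    return SpikeStatsVector(
        mean_rate=float(np.mean(rates)),
        isi_cv=cv,
        isi_skewness=skew,
        burst_frequency=float(np.mean(burst_freqs)) if burst_freqs else np.nan,
        mean_burst_duration=_nanmean(burst_durs) if burst_durs else np.nan,
        intra_burst_rate=_nanmean(intra_rates) if intra_rates else np.nan,
    )


def _isi_cv(isis: np.ndarray) -> float:
    if isis.size < 2:
        return np.nan
    m = isis.mean()
    return float(isis.std() / m) if m > 0 else np.nan


def _isi_skew(isis: np.ndarray) -> float:
    if isis.size < 3:
        return np.nan
    return float(sp_stats.skew(isis))


def _nanmean(vals) -> float:
    arr = np.asarray(vals, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(np.nanmean(arr)) if arr.size else np.nan


def relative_error(sim: SpikeStatsVector, obs: SpikeStatsVector) -> float:
    """Scale-free distance between statistics vectors.

    [sum_i (x_i_sim / x_i_obs - 1)^2]^(1/2).  Statistics undefined
    (NaN) in either vector are excluded from the sum with a warning;
    a zero observed entry is an error.
    """
    s, o = sim.as_array(), obs.as_array()
    defined = ~(np.isnan(s) | np.isnan(o))
    if not np.all(defined):
        warnings.warn(
            "undefined statistics excluded from relative error: "
            + ", ".join(np.array(sim.names)[~defined]),
            stacklevel=2,
        )
    s, o = s[defined], o[defined]
    if np.any(o == 0):
        raise ValueError("observed statistics must be nonzero")
    return float(np.sqrt(np.sum((s / o - 1.0) ** 2)))


def count_pruned(
    W: np.ndarray, threshold: float = 1.0, connected: np.ndarray | None = None
) -> int:
    """Number of ever-connected synapses with weight below ``threshold``.

    ``threshold`` is on the same current scale as the weights (a synapse
    is pruned once the current it admits after a presynaptic spike drops
    below ~1 unit).  ``connected`` marks which entries were ever
    synapses (default: every entry of W).
    """
    W = np.asarray(W, dtype=float)
    mask = np.ones_like(W, dtype=bool) if connected is None else np.asarray(connected)
    return int(np.sum(mask & (W < threshold)))


def mean_inputs_per_neuron(
    W: np.ndarray, threshold: float = 1.0, connected: np.ndarray | None = None
) -> float:
    """Mean surviving (unpruned) conductor inputs per student neuron."""
    W = np.asarray(W, dtype=float)
    mask = np.ones_like(W, dtype=bool) if connected is None else np.asarray(connected)
    return float(np.mean(np.sum(mask & (W >= threshold), axis=0)))
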