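"""Time grids, sampled signals and causal exponential filtering.

Everything in the simulator lives on a uniform time grid covering one
rendition of the motor program (duration ``T``, typically 1 s for a
song-motif-like output).  A :class:`Signal` is a bundle of one row per
channel/neuron sampled on such a grid.  The causal exponential filter
implemented here is the single smoothing primitive the whole model is
built from: muscle-like output smoothing, plasticity kernels, tutor
error integration and spike-rate estimation are all exponential
convolutions with different time constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Union

import numpy as np
import h5py
import yaml


__all__ = [
    "TimeGrid",
    "Signal",
    "RunConfig",
    "exp_filter",
    "make_rng",
    "save_signal_h5",
    "load_signal_h5",
    "signal_to_csv",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class TimeGrid:
    """Uniform sampling grid over one rendition of the motor program.

    Parameters
    ----------
    t_end : float
        End of the program in seconds (the duration ``T`` when
        ``t_start`` is 0; ~1 s for a birdsong-motif-like program).
    dt : float
        Sampling step in seconds.  Rate-based runs default to 1 ms,
        spiking runs to 0.1 ms (sub-millisecond spike jitter needs the
        finer step).
    t_start : float
        Start time in seconds; 0 by default.
    """

    t_end: float
    dt: float
    t_start: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.n_samples < 2:
            raise ValueError("grid must contain at least 2 samples")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def n_samples(self) -> int:
        return int(round((self.t_end - self.t_start) / self.dt))

    @property
    def times(self) -> np.ndarray:
        return self.t_start + self.dt * np.arange(self.n_samples)


@dataclass
class Signal:
    """A multi-channel time series sampled on a :class:`TimeGrid`.

    ``values`` has one row per channel (neuron, output channel, ...)
    and one column per time sample.  1-D arrays are promoted to a
    single row.
    """

    grid: TimeGrid
    values: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[np.newaxis, :]
        if v.ndim != 2:
            raise ValueError("values must be 1-D or 2-D")
        if v.shape[1] != self.grid.n_samples:
            raise ValueError(
                f"values has {v.shape[1]} samples, grid has {self.grid.n_samples}"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("signal values must be finite")
        self.values = v

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @classmethod
    def zeros(cls, grid: TimeGrid, n_channels: int = 1, units: str = "") -> "Signal":
        return cls(grid, np.zeros((n_channels, grid.n_samples)), units)

    def copy(self) -> "Signal":
        return Signal(self.grid, self.values.copy(), self.units)


def exp_filter(x: Signal, tau: float, normalized: bool = True) -> Signal:
    """Causal exponential filtering of a signal.

    Computes, per channel,

    ``y(t) = (1/tau) * int_0^t x(t') exp(-(t-t')/tau) dt'``

    with zero initial state, using trapezoid quadrature of the
    convolution integral (evaluated by an exactly equivalent O(n)
    recursion).  With ``normalized=False`` the leading ``1/tau`` is
    dropped, which is the convention used for the muscle-like output
    smoothing.

    Parameters
    ----------
    x : Signal
    tau : float
        Filter time constant in seconds; must be positive.
    normalized : bool
        If True (default) the kernel integrates to 1 for long signals.
    """
    if tau <= 0:
        raise ValueError(f"filter timescale must be positive, got {tau}")
    dt = x.grid.dt
    a = np.exp(-dt / tau)
    v = x.values
    n = v.shape[1]
    # Recursion y[k] = a*y[k-1] + (dt/2)*(a*x[k-1] + x[k]), y[0] = 0,
    # which reproduces the trapezoid rule for the full integral exactly.
    from scipy.signal import lfilter

    b = np.array([dt / 2.0, a * dt / 2.0])
    den = np.array([1.0, -a])
    y = lfilter(b, den, v, axis=1)
    # lfilter starts from y[0] = (dt/2) x[0]; the integral over [0, 0] is 0.
    y -= (dt / 2.0) * v[:, :1] * a ** np.arange(n)
    if normalized:
        y /= tau
    return Signal(x.grid, y, x.units)


def make_rng(seed: int) -> np.random.Generator:
    """Deterministic random generator; identical seeds give identical runs."""
    return np.random.default_rng(seed)


@dataclass
class RunConfig:
    """Plumbing-level configuration shared by the experiment drivers."""

    seed: int = 0
    n_conductor: int = 100
    n_student: int = 20
    n_channels: int = 2
    n_renditions: int = 1000
    out_dir: str = "."

    def __post_init__(self) -> None:
        for name in ("n_conductor", "n_student", "n_channels", "n_renditions"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def save_signal_h5(path: Union[str, Path], sig: Signal, name: str = "signal") -> None:
    """Persist a signal (values + time axis + units attribute) to HDF5."""
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        g = f.create_group(name)
        g.create_dataset("values", data=sig.values)
        g.create_dataset("times", data=sig.grid.times)
        g.attrs["units"] = sig.units
        g.attrs["dt"] = sig.grid.dt
        g.attrs["t_start"] = sig.grid.t_start
        g.attrs["t_end"] = sig.grid.t_end


def load_signal_h5(path: Union[str, Path], name: str = "signal") -> Signal:
    with h5py.File(path, "r") as f:
        g = f[name]
        grid = TimeGrid(
            t_end=float(g.attrs["t_end"]),
            dt=float(g.attrs["dt"]),
            t_start=float(g.attrs["t_start"]),
        )
        return Signal(grid, g["values"][()], str(g.attrs["units"]))


def signal_to_csv(path: Union[str, Path], sig: Signal, prefix: str = "ch") -> None:
    """Write a signal as CSV: time column plus one column per channel."""
    import pandas as pd

    cols = {"time_s": sig.grid.times}
    for k in range(sig.n_channels):
        cols[f"{prefix}{k}"] = sig.values[k]
    pd.DataFrame(cols).to_csv(path, index=False)


def save_config(path: Union[str, Path], cfg: RunConfig, extra: dict | None = None) -> None:
    payload = asdict(cfg)
    if extra:
        payload.update(extra)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_config(path: Union[str, Path]) -> dict:
    """Load a YAML/JSON key-value config file as a plain dict."""
    return yaml.safe_load(Path(path).read_text())
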