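import numpy as np
import pytest

from songlearn import TimeGrid, Signal, make_rng


@pytest.fixture
def grid_1s():
    """1 s program on a 1 ms grid (rate-model resolution)."""
    return TimeGrid(t_end=1.0, dt=1e-3)


@pytest.fixture
def grid_short():
    """100 ms program on a 1 ms grid for cheap filter checks."""
    return TimeGrid(t_end=0.1, dt=1e-3)


@pytest.fixture
def rng():
    return make_rng(12345)


def brute_force_exp_filter(x: Signal, tau: float, normalized: bool = True) -> np.ndarray:
    """O(n^2) trapezoid quadrature of the causal exponential convolution.

    Independent oracle for the recursive implementation.
    """
    t = x.grid.times - x.grid.t_start
    n = t.size
    out = np.zeros_like(x.values)
    for k in range(1, n):
        kern = np.exp(-(t[k] - t[: k + 1]) / tau)
        out[:, k] = np.trapezoid(x.values[:, : k + 1] * kern, dx=x.grid.dt, axis=1)
    if normalized:
        out /= tau
    return out
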