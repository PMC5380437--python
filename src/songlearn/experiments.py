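"""Reproducible drivers for the model's computational experiments.

Each driver assembles a full learning loop — conductor activity in,
student activity and motor output out, tutor signal computed from the
unfolding motor error, conductor-student weights updated once per
rendition by the heterosynaptic rule — and returns a
:class:`LearningTrace` whose metadata is sufficient to re-run the
experiment exactly.  The drivers cover matched learning (rate or
spiking engine), tutor-student mismatch sweeps, credit mis-assignment,
and two-stage reinforcement learning where the tutor discovers its own
corrective signal from scalar reward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .signals import Signal, TimeGrid, exp_filter, make_rng
from .plasticity import PlasticityParams, filter_conductor, optimal_timescale
from .rate_model import (
    TargetSpec,
    generate_conductor_rates,
    generate_target,
    init_rate_weights,
    loss as quadratic_loss,
    make_output_map,
    rms_error,
)
from .tutor import ReinforcementState, TutorSpec, reinforcement_update, reward_from_loss
from .spiking import (
    SpikingParams,
    SpikeTrain,
    estimate_rates,
    generate_conductor_spikes,
    init_spiking_weights,
)
from .spike_stats import mean_inputs_per_neuron
from . import _engine

__all__ = [
    "ExperimentConfig",
    "LearningTrace",
    "SweepResult",
    "SimulationDiverged",
    "rate_preset",
    "spiking_preset",
    "run_matched",
    "run_mismatch_sweep",
    "run_credit_scramble",
    "run_reinforcement",
]


class SimulationDiverged(RuntimeError):
    """Raised when the loss exceeds 1000x its initial value.

    Carries the partial :class:`LearningTrace` in ``.trace``.
    """

    def __init__(self, message: str, trace: "LearningTrace"):
        super().__init__(message)
        self.trace = trace


@dataclass
class ExperimentConfig:
    """Everything needed to re-run a learning experiment exactly."""

    seed: int = 0
    engine: str = "rate"  # 'rate' | 'spiking'
    n_renditions: int = 1000
    t_end: float = 1.0
    dt: float | None = None  # default: 1 ms (rate), 0.1 ms (spiking)
    n_conductor: int = 100
    n_student: int = 20
    n_channels: int = 2
    n_synapses: int | None = None  # spiking engine; default scales Table-like density
    burst_len: float = 0.010
    burst_rate: float = 100.0
    tau_out: float = 0.025
    w: float = 1.0
    weight_scale: float = 0.2
    positivity: bool = True
    plasticity: PlasticityParams = field(default_factory=PlasticityParams)
    tutor: TutorSpec = field(default_factory=TutorSpec)
    match_tau: bool = True
    target_smoothness: float = 0.050
    target_amplitude: tuple[float, float] = (0.0, 1.0)
    tau_est: float = 0.010  # spike-rate estimation timescale (spiking engine)
    spiking: SpikingParams = field(default_factory=SpikingParams)
    explore_sigma: float = 15.0  # Hz, reinforcement exploration amplitude
    explore_tau: float = 0.040  # s, exploration noise correlation time
    prune_threshold: float = 1.0
    record_every: int = 0  # checkpoint interval in renditions (0: endpoints only)

    def grid(self) -> TimeGrid:
        dt = self.dt if self.dt is not None else (1e-4 if self.engine == "spiking" else 1e-3)
        return TimeGrid(t_end=self.t_end, dt=dt)

    def resolved_tau_tutor(self) -> float:
        if self.match_tau and self.tutor.mode != "reinforcement":
            return optimal_timescale(self.plasticity)
        return self.tutor.tau_tutor

    def metadata(self) -> dict:
        d = asdict(self)
        d["resolved_tau_tutor"] = self.resolved_tau_tutor()
        return d


@dataclass
class LearningTrace:
    """Per-rendition record of a learning run."""

    losses: np.ndarray
    rms: np.ndarray
    seed: int
    metadata: dict
    W_init: np.ndarray
    W_final: np.ndarray
    target: Signal
    final_output: Signal
    checkpoints: list = field(default_factory=list)
    pruning: np.ndarray | None = None  # mean surviving inputs per student
    aborted: bool = False

    @property
    def n_renditions(self) -> int:
        return len(self.losses)

    def save(self, path) -> None:
        """Persist losses, weights, outputs and metadata to HDF5."""
        import h5py
        import yaml

        with h5py.File(path, "w") as f:
            f.create_dataset("losses", data=self.losses)
            f.create_dataset("rms", data=self.rms)
            f.create_dataset("W_init", data=self.W_init)
            f.create_dataset("W_final", data=self.W_final)
            f.create_dataset("target", data=self.target.values)
            f.create_dataset("final_output", data=self.final_output.values)
            if self.pruning is not None:
                f.create_dataset("pruning", data=self.pruning)
            f.attrs["seed"] = self.seed
            f.attrs["aborted"] = self.aborted
            f.attrs["metadata_yaml"] = yaml.safe_dump(self.metadata)

    def losses_to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"rendition": np.arange(len(self.losses)), "loss": self.losses, "rms": self.rms}
        ).to_csv(path, index=False)


@dataclass
class SweepResult:
    """Final losses on a (tau_tutor* x tau_tutor) mismatch grid."""

    tau_star: np.ndarray  # row axis: matched timescale implied by (alpha, beta)
    tau_tutor: np.ndarray  # column axis: timescale actually used
    final_loss: np.ndarray  # (n_star, n_tutor) median over seeds
    initial_loss: np.ndarray  # same shape
    all_losses: np.ndarray  # (n_star, n_tutor, n_seeds)
    failed: np.ndarray  # bool mask of aborted cells (divergence)

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            self.final_loss,
            index=[f"{t * 1e3:.0f}ms" for t in self.tau_star],
            columns=[f"{t * 1e3:.0f}ms" for t in self.tau_tutor],
        )
        df.index.name = "tau_star"
        df.to_csv(path)


def rate_preset(**overrides) -> ExperimentConfig:
    """Representative rate-engine configuration (not a figure reproduction)."""
    cfg = ExperimentConfig(
        engine="rate",
        n_conductor=100,
        n_student=20,
        n_renditions=1000,
        plasticity=PlasticityParams(alpha=1.0, beta=0.0, eta=6e-4),
        tutor=TutorSpec(mode="matched", zeta=120.0),
    )
    return replace(cfg, **overrides)


def spiking_preset(**overrides) -> ExperimentConfig:
    """Reduced-size spiking configuration (desk-scale).

    The full songbird-like network (300 conductor, 80 student neurons)
    is available by overriding the sizes; the default here is half
    scale with proportional synapse density.
    """
    cfg = ExperimentConfig(
        engine="spiking",
        n_conductor=150,
        n_student=40,
        n_renditions=600,
        plasticity=PlasticityParams(alpha=1.0, beta=0.0, eta=1e-2, theta=80.0),
        tutor=TutorSpec(mode="saturating", zeta=6.0, rho=80.0, theta=80.0),
        target_amplitude=(20.0, 90.0),
        target_smoothness=0.050,
        tau_est=0.010,
    )
    return replace(cfg, **overrides)


# ---------------------------------------------------------------------------
# internal helpers


def _trapezoid_weights(n_t: int, dt: float) -> np.ndarray:
    w = np.full(n_t, dt)
    w[0] = w[-1] = dt / 2.0
    return w


def _scrambled_map(M: np.ndarray, rho: float, rng: np.random.Generator) -> np.ndarray:
    """Reassign a fraction rho of student neurons to the wrong channel."""
    if not 0.0 <= rho <= 1.0:
        raise ValueError("scramble fraction must lie in [0, 1]")
    n_channels, n_student = M.shape
    if n_channels != 2:
        raise ValueError("credit scrambling is defined for two output channels")
    M_err = M.copy()
    n_scr = int(round(rho * n_student))
    chosen = rng.choice(n_student, size=n_scr, replace=False)
    per = n_student // n_channels
    for j in chosen:
        true_ch = int(np.argmax(M[:, j] > 0))
        M_err[:, j] = 0.0
        M_err[1 - true_ch, j] = 1.0 / per
    return M_err


def _check_divergence(losses, trace_builder):
    if len(losses) >= 2 and losses[-1] > 1e3 * max(losses[0], 1e-30):
        trace = trace_builder(aborted=True)
        raise SimulationDiverged(
            f"loss {losses[-1]:.3g} exceeded 1000x initial {losses[0]:.3g}", trace
        )


# ---------------------------------------------------------------------------
# rate engine


def _run_rate(cfg: ExperimentConfig, M_err: np.ndarray | None = None) -> LearningTrace:
    grid = cfg.grid()
    rng = make_rng(cfg.seed)
    p = cfg.plasticity
    tau_t = cfg.resolved_tau_tutor()
    if tau_t <= 0:
        raise ValueError("rate engine requires a positive tutor timescale")

    C = generate_conductor_rates(grid, cfg.n_conductor, cfg.burst_len, cfg.burst_rate)
    target = generate_target(
        TargetSpec(
            n_channels=cfg.n_channels,
            smoothness=cfg.target_smoothness,
            amplitude=cfg.target_amplitude,
            seed=cfg.seed,
        ),
        grid,
    )
    M = make_output_map(cfg.n_channels, cfg.n_student)
    Me = M if M_err is None else M_err
    W = init_rate_weights(cfg.n_conductor, cfg.n_student, rng, cfg.weight_scale)
    W_init = W.copy()
    x_inh = float((W.T @ C.values).mean()) + cfg.w * cfg.tutor.theta

    c_filt = filter_conductor(C, p)
    wts = _trapezoid_weights(grid.n_samples, grid.dt)
    cw = c_filt.values * wts  # (n_cond, n_t), quadrature-weighted

    zeta_eff = cfg.tutor.zeta / (p.alpha - p.beta)
    saturating = 1 if cfg.tutor.mode == "saturating" else 0
    n_t, n_s = grid.n_samples, cfg.n_student
    g_out = np.empty((n_t, n_s))
    y_out = np.empty((cfg.n_channels, n_t))

    losses, rmss, checkpoints = [], [], []

    def builder(aborted=False):
        return LearningTrace(
            losses=np.array(losses),
            rms=np.array(rmss),
            seed=cfg.seed,
            metadata=cfg.metadata(),
            W_init=W_init,
            W_final=W.copy(),
            target=target,
            final_output=Signal(grid, y_out.copy()),
            checkpoints=checkpoints,
            aborted=aborted,
        )

    for k in range(cfg.n_renditions):
        base = (W.T @ C.values).T
        _engine.rate_rendition(
            base,
            target.values,
            M,
            Me,
            p.theta,
            zeta_eff,
            cfg.w,
            x_inh,
            grid.dt,
            cfg.tau_out,
            tau_t,
            cfg.tutor.rho,
            saturating,
            g_out,
            y_out,
        )
        y_sig = Signal(grid, y_out)
        losses.append(quadratic_loss(y_sig, target))
        rmss.append(rms_error(y_sig, target))
        if p.eta > 0:
            dW = p.eta * (cw @ (g_out - p.theta))
            W += dW
            if cfg.positivity:
                np.clip(W, 0.0, None, out=W)
        if cfg.record_every and (k % cfg.record_every == 0):
            checkpoints.append({"rendition": k, "W": W.copy(), "y": y_out.copy()})
        _check_divergence(losses, builder)
    return builder()


# ---------------------------------------------------------------------------
# spiking engine


def _spiking_sizes(cfg: ExperimentConfig) -> tuple[int, int, int]:
    sp = cfg.spiking
    n_c, n_s = cfg.n_conductor, cfg.n_student
    if cfg.n_synapses is not None:
        k = cfg.n_synapses
    else:
        k = int(round(sp.synapses_per_student * n_c / sp.n_conductor))
    return n_c, n_s, min(k, n_c)


def _run_spiking(
    cfg: ExperimentConfig,
    M_err: np.ndarray | None = None,
    reinforcement: bool = False,
) -> LearningTrace:
    grid = cfg.grid()
    rng = make_rng(cfg.seed)
    p = cfg.plasticity
    sp = cfg.spiking
    tau_t = cfg.resolved_tau_tutor()
    n_c, n_s, n_syn = _spiking_sizes(cfg)
    n_t = grid.n_samples

    target = generate_target(
        TargetSpec(
            n_channels=cfg.n_channels,
            smoothness=cfg.target_smoothness,
            amplitude=cfg.target_amplitude,
            seed=cfg.seed,
        ),
        grid,
    )
    M = make_output_map(cfg.n_channels, n_s)
    Me = M if M_err is None else M_err
    W = init_spiking_weights(sp, rng, n_c, n_s, n_syn)
    W_init = W.copy()
    connected = W > 0

    zeta_eff = cfg.tutor.zeta / (p.alpha - p.beta)
    a_est = np.exp(-grid.dt / cfg.tau_est)
    wts = _trapezoid_weights(n_t, grid.dt)

    tut_spikes = np.empty((n_t, n_s))
    raster = np.empty((n_t, n_s))
    y_out = np.empty((cfg.n_channels, n_t))
    dummy_prog = np.zeros((1, n_s))

    rl_state: ReinforcementState | None = None
    losses, rmss, checkpoints, pruning = [], [], [], []
    first_raster = last_raster = None

    def builder(aborted=False):
        return LearningTrace(
            losses=np.array(losses),
            rms=np.array(rmss),
            seed=cfg.seed,
            metadata=cfg.metadata(),
            W_init=W_init,
            W_final=W.copy(),
            target=target,
            final_output=Signal(grid, y_out.copy()),
            checkpoints=checkpoints,
            pruning=np.array(pruning) if pruning else None,
            aborted=aborted,
        )

    from scipy.signal import lfilter

    for k in range(cfg.n_renditions):
        cond = generate_conductor_spikes(grid, sp, rng, n_conductor=n_c)
        ids, times = cond.to_arrays()
        bins = np.floor((times - grid.t_start) / grid.dt).astype(int)
        keep = (bins >= 0) & (bins < n_t)
        cond_drive = np.zeros((n_t, n_s))
        np.add.at(cond_drive, bins[keep], W[ids[keep], :])

        uniforms = rng.random((n_t, n_s))
        if reinforcement:
            f_prog = rl_state.f.values.T if rl_state is not None else np.full(
                (n_t, n_s), cfg.tutor.theta
            )
            use_prog = 1
        else:
            f_prog = dummy_prog
            use_prog = 0

        fail = _engine.spiking_rendition(
            cond_drive,
            uniforms,
            np.ascontiguousarray(f_prog),
            use_prog,
            target.values,
            M,
            Me,
            sp.V_R,
            sp.V_th,
            sp.tau_m,
            sp.tau_ref,
            sp.R_eff,
            sp.tau_AMPA,
            sp.tau_NMDA,
            sp.tau_inh,
            sp.r_nmda,
            sp.w_tutor,
            sp.g_inh,
            sp.Mg_conc / 3.57,
            cfg.tutor.theta,
            cfg.tutor.rho,
            zeta_eff,
            cfg.tau_out,
            max(tau_t, grid.dt),
            grid.dt,
            tut_spikes,
            raster,
            y_out,
        )
        if fail >= 0:
            raise SimulationDiverged(
                f"spiking state non-finite at step {fail} of rendition {k}", builder(True)
            )

        y_sig = Signal(grid, y_out)
        losses.append(quadratic_loss(y_sig, target))
        rmss.append(rms_error(y_sig, target))
        if k == 0:
            first_raster = raster.copy()
        last_raster = raster

        # rate estimates feeding the plasticity rule
        g_est = lfilter([1.0 / cfg.tau_est], [1.0, -a_est], tut_spikes.T, axis=1)
        c_est = estimate_rates(cond, cfg.tau_est, grid)
        c_filt = filter_conductor(c_est, p)

        if reinforcement:
            R = reward_from_loss(y_sig, target)
            g_actual = Signal(grid, g_est, units="Hz")
            if rl_state is None:
                rl_state = ReinforcementState(
                    f=Signal(grid, np.full((n_s, n_t), cfg.tutor.theta), units="Hz"),
                    g_bar=g_actual.copy(),
                    R_bar=float(R.values[0, -1]),
                )
            rl_state = reinforcement_update(rl_state, g_actual, R, cfg.tutor)

        if p.eta > 0:
            W += p.eta * ((c_filt.values * wts) @ (g_est - p.theta).T)
            if cfg.positivity:
                np.clip(W, 0.0, None, out=W)
        pruning.append(mean_inputs_per_neuron(W, cfg.prune_threshold, connected))

        if cfg.record_every and (k % cfg.record_every == 0):
            checkpoints.append({"rendition": k, "W": W.copy(), "y": y_out.copy()})
        _check_divergence(losses, builder)

    trace = builder()
    if first_raster is not None:
        trace.checkpoints.append(
            {"rendition": 0, "raster": SpikeTrain.from_raster(first_raster, grid)}
        )
        trace.checkpoints.append(
            {
                "rendition": cfg.n_renditions - 1,
                "raster": SpikeTrain.from_raster(last_raster, grid),
            }
        )
    return trace


# ---------------------------------------------------------------------------
# public drivers


def run_matched(config: ExperimentConfig) -> LearningTrace:
    """Full learning loop with the tutor matched to the plasticity rule.

    With ``config.match_tau`` (default) the tutor error-integration
    timescale is set to the optimum implied by the plasticity kernel;
    switching it off runs the same loop at the configured (possibly
    mismatched) timescale.  Raises :class:`SimulationDiverged` if the
    loss exceeds 1000x its initial value.
    """
    if config.engine == "rate":
        return _run_rate(config)
    if config.engine == "spiking":
        return _run_spiking(config)
    raise ValueError(f"unknown engine {config.engine!r}")


def run_mismatch_sweep(
    config: ExperimentConfig,
    tau_stars: np.ndarray | None = None,
    tau_tutors: np.ndarray | None = None,
    n_seeds: int = 3,
) -> SweepResult:
    """Grid of runs over (plasticity-implied tau*, actual tau_tutor).

    For each row, alpha and beta are set (with alpha - beta = 1 and
    tau1 = 80 ms, tau2 = 40 ms fixed) so the matched timescale equals
    the requested tau*; each column forces the tutor to integrate at a
    given tau_tutor.  Diagonal cells are matched pairs.  Cells that
    diverge are recorded (final loss from the partial trace) and
    flagged.  The default grid is a desk-scale 5x5 with 200 renditions;
    medians over ``n_seeds`` seeds are reported.
    """
    if tau_stars is None:
        tau_stars = np.geomspace(0.040, 1.0, 5)
    if tau_tutors is None:
        tau_tutors = np.geomspace(0.040, 1.0, 5)
    tau_stars = np.asarray(tau_stars, dtype=float)
    tau_tutors = np.asarray(tau_tutors, dtype=float)
    p0 = config.plasticity
    n_a, n_b = len(tau_stars), len(tau_tutors)
    all_losses = np.empty((n_a, n_b, n_seeds))
    init_losses = np.empty((n_a, n_b, n_seeds))
    failed = np.zeros((n_a, n_b), dtype=bool)
    for ia, ts in enumerate(tau_stars):
        # with beta = alpha - 1: tau* = alpha*tau1 - (alpha-1)*tau2
        alpha = (ts - p0.tau2) / (p0.tau1 - p0.tau2)
        pl = replace(p0, alpha=alpha, beta=alpha - 1.0)
        for ib, tt in enumerate(tau_tutors):
            for s in range(n_seeds):
                cfg = replace(
                    config,
                    seed=config.seed + s,
                    plasticity=pl,
                    tutor=replace(config.tutor, tau_tutor=float(tt)),
                    match_tau=False,
                )
                try:
                    trace = run_matched(cfg)
                except SimulationDiverged as exc:
                    trace = exc.trace
                    failed[ia, ib] = True
                all_losses[ia, ib, s] = trace.losses[-1]
                init_losses[ia, ib, s] = trace.losses[0]
    return SweepResult(
        tau_star=tau_stars,
        tau_tutor=tau_tutors,
        final_loss=np.median(all_losses, axis=2),
        initial_loss=np.median(init_losses, axis=2),
        all_losses=all_losses,
        failed=failed,
    )


def run_credit_scramble(config: ExperimentConfig, rho: float) -> LearningTrace:
    """Learning with the tutor mis-assigning a fraction rho of students.

    The tutor computes the motor error with a scrambled copy of the
    student-output map (a fraction ``rho`` of student neurons
    attributed to the wrong channel) while the true map still produces
    the output.  rho = 0 reproduces :func:`run_matched` exactly.
    """
    M = make_output_map(config.n_channels, config.n_student)
    scramble_rng = make_rng(config.seed + 977)
    M_err = _scrambled_map(M, rho, scramble_rng)
    if config.engine == "rate":
        return _run_rate(config, M_err=M_err)
    return _run_spiking(config, M_err=M_err)


def run_reinforcement(config: ExperimentConfig) -> LearningTrace:
    """Two-stage learning: the tutor learns its signal from reward.

    The tutor firing-rate program starts flat at theta and is shaped
    across renditions by correlating its own rate fluctuations with
    reward fluctuations (baseline-subtracted on both sides); the
    student consolidates the signal through the reward-independent
    heterosynaptic rule.  With the memory-less tutor (tau_tutor = 0)
    only instantaneous reward-fluctuation coincidences drive the tutor;
    tau_tutor > 0 filters the update over an eligibility window.  In
    the rate engine the tutor explores with smooth Gaussian rate noise;
    in the spiking engine Poisson spiking supplies the variability.
    """
    if config.tutor.mode != "reinforcement":
        config = replace(config, tutor=replace(config.tutor, mode="reinforcement"))
    if config.engine == "spiking":
        return _run_spiking(config, reinforcement=True)

    cfg = config
    grid = cfg.grid()
    rng = make_rng(cfg.seed)
    p = cfg.plasticity
    n_t, n_s = grid.n_samples, cfg.n_student

    C = generate_conductor_rates(grid, cfg.n_conductor, cfg.burst_len, cfg.burst_rate)
    target = generate_target(
        TargetSpec(cfg.n_channels, cfg.target_smoothness, cfg.target_amplitude, cfg.seed),
        grid,
    )
    M = make_output_map(cfg.n_channels, n_s)
    W = init_rate_weights(cfg.n_conductor, n_s, rng, cfg.weight_scale)
    W_init = W.copy()
    x_inh = float((W.T @ C.values).mean()) + cfg.w * cfg.tutor.theta
    c_filt = filter_conductor(C, p)
    cw = c_filt.values * _trapezoid_weights(n_t, grid.dt)

    # white-noise scale such that the filtered exploration has sd explore_sigma
    sigma_w = cfg.explore_sigma * np.sqrt(2.0 * cfg.explore_tau / grid.dt)

    state: ReinforcementState | None = None
    losses, rmss, pruning, checkpoints = [], [], [], []
    y_sig = None

    def builder(aborted=False):
        return LearningTrace(
            losses=np.array(losses),
            rms=np.array(rmss),
            seed=cfg.seed,
            metadata=cfg.metadata(),
            W_init=W_init,
            W_final=W.copy(),
            target=target,
            final_output=y_sig if y_sig is not None else Signal.zeros(grid, cfg.n_channels),
            checkpoints=checkpoints,
            pruning=np.array(pruning) if pruning else None,
            aborted=aborted,
        )

    for k in range(cfg.n_renditions):
        white = Signal(grid, sigma_w * rng.standard_normal((n_s, n_t)))
        noise = exp_filter(white, cfg.explore_tau, normalized=True).values
        f = state.f.values if state is not None else np.full((n_s, n_t), cfg.tutor.theta)
        g = np.clip(f + noise, 0.0, None)
        s = W.T @ C.values + cfg.w * g - x_inh
        y = M @ exp_filter(Signal(grid, s), cfg.tau_out, normalized=False).values
        y_sig = Signal(grid, y)
        losses.append(quadratic_loss(y_sig, target))
        rmss.append(rms_error(y_sig, target))

        R = reward_from_loss(y_sig, target)
        g_sig = Signal(grid, g, units="Hz")
        if state is None:
            state = ReinforcementState(
                f=Signal(grid, f, units="Hz"),
                g_bar=g_sig.copy(),
                R_bar=float(R.values[0, -1]),
            )
        state = reinforcement_update(state, g_sig, R, cfg.tutor)

        if p.eta > 0:
            W += p.eta * (cw @ (g - p.theta).T)
            if cfg.positivity:
                np.clip(W, 0.0, None, out=W)
        pruning.append(
            mean_inputs_per_neuron(W, cfg.prune_threshold * cfg.weight_scale)
        )
        if cfg.record_every and (k % cfg.record_every == 0):
            checkpoints.append({"rendition": k, "W": W.copy(), "y": y.copy()})
        _check_divergence(losses, builder)
    return builder()
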