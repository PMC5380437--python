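import numpy as np
import pytest

from songlearn import (
    TimeGrid,
    Signal,
    SpikingParams,
    SpikeTrain,
    LIFState,
    make_rng,
    nmda_gating,
    step_network,
    generate_conductor_spikes,
    generate_poisson_tutor,
    estimate_rates,
    init_spiking_weights,
)


@pytest.fixture
def params():
    return SpikingParams()


@pytest.fixture
def fine_grid():
    return TimeGrid(t_end=0.5, dt=1e-4)


class TestNmdaGating:
    def test_saturates_at_depolarized_potentials(self):
        assert nmda_gating(1e4, 1.0) == pytest.approx(1.0)

    def test_strictly_increasing_in_voltage(self):
        V = np.linspace(-90, 40, 200)
        G = nmda_gating(V, 1.0)
        assert np.all(np.diff(G) > 0)

    def test_value_at_threshold_regression_pin(self, params):
        # independent direct evaluation of the gating formula
        expected = 1.0 / (1.0 + (1.0 / 3.57) * np.exp(48.6 / 16.13))
        assert nmda_gating(params.V_th, 1.0) == pytest.approx(expected, rel=1e-12)

    def test_no_block_without_magnesium(self):
        assert nmda_gating(-70.0, 0.0) == pytest.approx(1.0)


class TestLIFDynamics:
    def test_rest_is_fixed_point(self, params):
        st = LIFState.initial(3, params)
        for _ in range(500):
            step_network(st, np.zeros(3), np.zeros(3), params, 1e-4)
        assert np.allclose(st.V, params.V_R)

    def test_subthreshold_response_matches_closed_form(self, params):
        # constant current below rheobase: V(t) = V_R + R I (1 - exp(-t/tau_m))
        dt = 1e-5
        I = 0.5 * (params.V_th - params.V_R) / params.R_eff
        st = LIFState.initial(1, params)
        n = 2000
        V_trace = np.empty(n)
        for k in range(n):
            step_network(st, np.zeros(1), np.zeros(1), params, dt, I_ext=I)
            V_trace[k] = st.V[0]
        t = dt * np.arange(1, n + 1)
        expected = params.V_R + params.R_eff * I * (1 - np.exp(-t / params.tau_m))
        span = params.R_eff * I
        assert np.max(np.abs(V_trace - expected)) < 1e-3 * span

    def test_suprathreshold_isi_matches_analytic(self, params):
        # ISI = tau_ref + tau_m ln(RI / (RI - (V_th - V_R)))
        # (global inhibition off so the single-neuron closed form applies)
        params = SpikingParams(g_inh=0.0)
        dt = 1e-5
        gap = params.V_th - params.V_R
        I = 2.0 * gap / params.R_eff
        st = LIFState.initial(1, params)
        spikes = []
        for k in range(60000):
            if step_network(st, np.zeros(1), np.zeros(1), params, dt, I_ext=I)[0]:
                spikes.append((k + 1) * dt)
        isis = np.diff(spikes)
        expected = params.tau_ref + params.tau_m * np.log(2.0)
        assert len(isis) > 5
        assert np.all(np.abs(isis - expected) <= 2 * dt)

    def test_reset_and_refractory_contracts(self, params, fine_grid):
        # every emitted spike resets V to V_R and enforces ISI >= tau_ref
        rng = make_rng(0)
        st = LIFState.initial(4, params)
        dt = fine_grid.dt
        spike_times = [[] for _ in range(4)]
        for k in range(fine_grid.n_samples):
            drive = rng.random(4) * 200.0  # strong noisy conductor input
            spiked = step_network(st, drive, np.zeros(4), params, dt)
            assert np.all(st.V[spiked] == params.V_R)
            for j in np.nonzero(spiked)[0]:
                spike_times[j].append(k * dt)
        all_isis = np.concatenate([np.diff(t) for t in spike_times if len(t) > 1])
        assert all_isis.size > 10
        assert np.all(all_isis >= params.tau_ref - 1e-12)

    def test_coarse_dt_rejected(self, params):
        st = LIFState.initial(1, params)
        with pytest.raises(ValueError):
            step_network(st, np.zeros(1), np.zeros(1), params, dt=5e-3)

    def test_divergence_reported(self, params):
        st = LIFState.initial(1, params)
        st.V[0] = np.inf
        st.I_AMPA[0] = np.inf
        with pytest.raises(FloatingPointError):
            step_network(st, np.zeros(1), np.zeros(1), params, 1e-4)


class TestConductorSpikes:
    def test_zero_jitter_is_periodic_at_burst_rate(self, params):
        grid = TimeGrid(t_end=1.0, dt=1e-4)
        st = generate_conductor_spikes(grid, params, make_rng(0), n_conductor=10, jitter=False)
        for t in st.times:
            gaps = np.diff(t)
            assert np.allclose(gaps, 1.0 / params.conductor_burst_rate, atol=1e-12)

    def test_burst_sizes_are_five_or_six(self, params):
        grid = TimeGrid(t_end=1.0, dt=1e-4)
        st = generate_conductor_spikes(grid, params, make_rng(0), n_conductor=20, jitter=False)
        counts = st.counts()
        assert set(counts.tolist()) <= {5, 6}
        assert 5 in counts and 6 in counts  # alternating pattern uses both

    def test_onset_jitter_statistics(self, params):
        # uniform +-0.3 ms onset jitter: sd over renditions ~ 0.3/sqrt(3) ms
        grid = TimeGrid(t_end=1.0, dt=1e-4)
        rng = make_rng(1)
        onsets = []
        for _ in range(100):
            st = generate_conductor_spikes(grid, params, rng, n_conductor=5)
            onsets.append([t[0] for t in st.times])
        # neuron 0 bursts at t=0 where negative jitter is boundary-clipped,
        # so only interior neurons are compared.  The first spike carries
        # both the uniform onset jitter and its own per-spike jitter:
        # sd = sqrt(onset^2 + spike^2)/sqrt(3).
        sd = np.std(np.array(onsets), axis=0)[1:]
        expected = np.sqrt(params.onset_jitter**2 + params.spike_jitter**2) / np.sqrt(3)
        assert np.all(np.abs(sd - expected) < 0.2 * expected)

    def test_onsets_tile_program(self, params):
        grid = TimeGrid(t_end=1.0, dt=1e-4)
        st = generate_conductor_spikes(grid, params, make_rng(0), n_conductor=10, jitter=False)
        onsets = np.array([t[0] for t in st.times])
        assert np.allclose(onsets, 0.1 * np.arange(10), atol=1e-12)


class TestPoissonTutor:
    def test_zero_rate_gives_no_spikes(self, fine_grid):
        f = Signal.zeros(fine_grid, 3, units="Hz")
        st = generate_poisson_tutor(f, make_rng(0))
        assert np.all(st.counts() == 0)

    def test_mean_count_matches_rate(self):
        grid = TimeGrid(t_end=10.0, dt=1e-4)
        f = Signal(grid, np.full((200, grid.n_samples), 100.0), units="Hz")
        st = generate_poisson_tutor(f, make_rng(2))
        counts = st.counts()
        expected = 1000.0
        se = np.sqrt(expected / 200)
        assert abs(counts.mean() - expected) < 3 * se

    def test_fano_factor_near_one(self):
        grid = TimeGrid(t_end=10.0, dt=1e-4)
        f = Signal(grid, np.full((200, grid.n_samples), 100.0), units="Hz")
        counts = generate_poisson_tutor(f, make_rng(3)).counts()
        fano = counts.var() / counts.mean()
        assert 0.75 < fano < 1.25

    def test_negative_rate_rejected(self, fine_grid):
        f_vals = np.full((1, fine_grid.n_samples), -1.0)
        with pytest.raises(ValueError):
            generate_poisson_tutor(
                Signal(fine_grid, f_vals, units="Hz"), make_rng(0)
            )


class TestRateEstimation:
    def test_no_spikes_gives_zero(self, fine_grid):
        st = SpikeTrain([np.empty(0)])
        r = estimate_rates(st, 0.02, fine_grid)
        assert np.all(r.values == 0)

    def test_single_spike_impulse_response(self, fine_grid):
        t0 = 0.1
        st = SpikeTrain([np.array([t0])])
        tau = 0.02
        r = estimate_rates(st, tau, fine_grid)
        k0 = int(round(t0 / fine_grid.dt))
        t = fine_grid.times[k0:]
        expected = np.exp(-(t - t0) / tau) / tau
        assert np.allclose(r.values[0, k0:], expected, rtol=1e-9)
        assert np.all(r.values[0, :k0] == 0)

    def test_stationary_poisson_estimate_converges(self):
        grid = TimeGrid(t_end=50.0, dt=1e-3)
        f = Signal(grid, np.full((1, grid.n_samples), 50.0), units="Hz")
        st = generate_poisson_tutor(f, make_rng(4))
        r = estimate_rates(st, 0.04, grid)
        # skip the initial transient of the causal kernel
        avg = r.values[0, 1000:].mean()
        assert abs(avg - 50.0) / 50.0 < 0.05


class TestInitWeights:
    def test_synapse_count_per_student(self, params):
        W = init_spiking_weights(params, make_rng(0))
        assert np.all(np.sum(W > 0, axis=0) == params.synapses_per_student)

    def test_lognormal_moments(self, params):
        W = init_spiking_weights(params, make_rng(1))
        nz = W[W > 0]
        assert abs(nz.mean() - params.W_mean) / params.W_mean < 0.05
        assert abs(nz.std() - params.W_sd) / params.W_sd < 0.15

    def test_all_weights_nonnegative(self, params):
        W = init_spiking_weights(params, make_rng(2))
        assert np.all(W >= 0)
        assert np.all(W[W != 0] > 0)

    def test_oversubscription_rejected(self, params):
        with pytest.raises(ValueError):
            init_spiking_weights(params, make_rng(0), n_conductor=100, n_synapses=148)


class TestEngineMatchesReference:
    def test_numba_core_reproduces_step_network(self):
        """The compiled rendition loop and the numpy reference integrator
        must emit identical spike trains for identical inputs."""
        from songlearn import _engine

        params = SpikingParams(n_conductor=20, n_student=5, synapses_per_student=10)
        grid = TimeGrid(t_end=0.2, dt=1e-4)
        n_t, n_s = grid.n_samples, 5
        rng = make_rng(7)
        W = init_spiking_weights(params, rng, 20, 5, 10)
        cond = generate_conductor_spikes(grid, params, rng, n_conductor=20)
        ids, times = cond.to_arrays()
        bins = np.floor(times / grid.dt).astype(int)
        cond_drive = np.zeros((n_t, n_s))
        np.add.at(cond_drive, bins[(bins >= 0) & (bins < n_t)], W[ids[(bins >= 0) & (bins < n_t)], :])

        uniforms = rng.random((n_t, n_s))
        f_prog = np.full((n_t, n_s), 80.0)
        ybar = np.zeros((1, n_t))
        M = np.full((1, n_s), 1.0 / n_s)
        tut_spikes = np.empty((n_t, n_s))
        raster = np.empty((n_t, n_s))
        y_out = np.empty((1, n_t))
        fail = _engine.spiking_rendition(
            cond_drive, uniforms, f_prog, 1, ybar, M, M,
            params.V_R, params.V_th, params.tau_m, params.tau_ref, params.R_eff,
            params.tau_AMPA, params.tau_NMDA, params.tau_inh, params.r_nmda,
            params.w_tutor, params.g_inh, params.Mg_conc / 3.57,
            80.0, 80.0, 1.0, 0.025, 0.08, grid.dt,
            tut_spikes, raster, y_out,
        )
        assert fail == -1

        # reference path: same tutor spikes through step_network
        st = LIFState.initial(n_s, params)
        ref_raster = np.zeros((n_t, n_s))
        for k in range(n_t):
            spk_t = (uniforms[k] < f_prog[k] * grid.dt).astype(float)
            assert np.array_equal(spk_t, tut_spikes[k])
            spiked = step_network(st, cond_drive[k], spk_t, params, grid.dt)
            ref_raster[k] = spiked
        assert np.array_equal(raster, ref_raster)
        assert ref_raster.sum() > 0  # the comparison exercised real spiking
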