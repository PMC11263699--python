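"""Stochastic engine: initialization, stepping, division/death laws,
consistency with the mean-field limit and with the agent-level reference."""

import numpy as np
import pytest
from scipy import stats

from quasisync import (
    ModelParams,
    SingleSpeciesParams,
    init_population,
    integrate_meanfield,
    simulate,
    simulate_single_species,
)
from quasisync.engine import DEFAULT_DT, timer_window
from quasisync.observables import steady_state_init
from quasisync.reference import agent_simulate


class TestInit:
    def test_totals_match_request(self, s05):
        state = init_population((2000, 3000), s05, rng_seed=1)
        assert state.totals == (2000, 3000)

    def test_uniform_timer_histogram_is_flat(self, s05):
        state = init_population((50_000, 0), s05, rng_seed=2)
        t_bins = int(round(s05.T / DEFAULT_DT))
        occupied = state.counts[0][:t_bins]
        # chi-square against the flat profile (edge bins get half weight)
        chi2, p = stats.chisquare(occupied[1:-1])
        assert p > 0.001

    def test_memory_cap(self, s05):
        with pytest.raises(MemoryError):
            init_population((10**10, 10**10), s05)

    def test_negative_counts_rejected(self, s05):
        with pytest.raises(ValueError):
            init_population((-1, 10), s05)


class TestStepLaws:
    def test_noiseless_synchronous_doubling(self):
        """With w = 0, synchronized timers and negligible death pressure the
        population doubles exactly every T."""
        params = SingleSpeciesParams(b=1.0, K=10**12, w=0.0)
        ts = simulate_single_species(
            params, 3.2 * params.T, init=64, init_mode="synchronized",
            rng_seed=3, sample_every=8,
        )
        expected = 64 * 2 ** np.floor(ts.t / params.T + 1e-9)
        assert np.array_equal(ts.n, expected.astype(int))

    def test_certain_death_empties_both_species_in_one_step(self, s05):
        # p2*dt >= 1 and p4*x_A*dt >= 1 force death probability 1
        params = ModelParams(p1=1e-6, p2=600.0, p3=1e-6, p4=6000.0,
                             b=1.0, K=100, w=0.02)
        with pytest.warns(UserWarning, match="clamped"):
            ts = simulate(params, 10 * DEFAULT_DT, init=(50, 50), rng_seed=4,
                          sample_every=1)
        assert ts.status == "extinct_both"
        assert ts.meta["t_end"] == pytest.approx(DEFAULT_DT)

    def test_absorbing_state_is_never_left(self, s05):
        ts = simulate(s05.with_(K=100), 5.0, init=(0, 20), rng_seed=5)
        assert ts.status == "extinct_A"
        assert ts.meta["t_end"] <= 2 * DEFAULT_DT

    def test_expected_death_count(self):
        """Conditional on the state, E[deaths] = N * clamp(d*dt, 0, 1).

        Uses a synchronized population far from division so the only change
        in the first step is death."""
        params = ModelParams(p1=1e-6, p2=8.0, p3=1.0, p4=16.0, b=1.0,
                             K=1000, w=0.02)
        n0 = 800
        # p1 ~ 0 so d_A ~ p2 regardless of x_B
        p_death_a = params.p2 * DEFAULT_DT
        nsteps = 400
        deaths = []
        for seed in range(nsteps):
            ts = simulate(params, 2 * DEFAULT_DT, init=(n0, 200),
                          rng_seed=seed, init_mode="synchronized",
                          sample_every=1)
            deaths.append(n0 - ts.counts[1, 0])
        mean = np.mean(deaths)
        expected = n0 * p_death_a
        se = np.sqrt(n0 * p_death_a * (1 - p_death_a) / nsteps)
        assert abs(mean - expected) < 4 * se

    def test_dt_convergence(self):
        """Halving dt leaves the stationary mean and variance unchanged
        within statistical error."""
        params = SingleSpeciesParams(b=1.0, K=10_000, w=0.04)
        stats_ = {}
        for dt in (1 / 512, 1 / 1024):
            ts = simulate_single_species(params, 400.0, rng_seed=6, dt=dt,
                                         sample_every=8)
            n = ts.n[len(ts.n) // 4:].astype(float)
            stats_[dt] = (n.mean(), n.var())
        m1, v1 = stats_[1 / 512]
        m2, v2 = stats_[1 / 1024]
        assert m1 == pytest.approx(m2, rel=0.01)
        assert v1 == pytest.approx(v2, rel=0.25)


class TestAgentEquivalence:
    @pytest.mark.parametrize("dist", ["uniform", "exponential"])
    def test_binned_matches_agent_reference(self, dist):
        """The histogram engine and the per-agent reference produce the same
        distribution of (N_A, N_B) after 1000 steps (two-sample KS).

        Runs start at the coexistence fixed point so that no replicate hits
        the absorbing state within the window (extinct replicates would
        truncate the two series differently)."""
        params = ModelParams.preset(
            "S0.5", K=300, w=0.05, replication_dist=dist
        )
        init = steady_state_init(params)
        n_steps, n_rep = 1000, 120
        t_max = n_steps * DEFAULT_DT
        binned_runs = [
            simulate(params, t_max, init=init, rng_seed=1000 + r,
                     sample_every=n_steps)
            for r in range(n_rep)
        ]
        assert all(ts.status == "completed" for ts in binned_runs)
        binned = np.array([ts.counts[-1] for ts in binned_runs])
        agent = np.array(
            [
                agent_simulate(params, n_steps, init,
                               rng_seed=5000 + r,
                               sample_every=n_steps)[-1]
                for r in range(n_rep)
            ]
        )
        assert np.all(agent > 0)
        for col in (0, 1):
            _, p = stats.ks_2samp(binned[:, col], agent[:, col])
            assert p > 0.01


class TestMeanFieldLimit:
    def test_ensemble_mean_tracks_ode_after_equilibration(self):
        """Ensemble mean of N_A/K follows the mean-field ODE within 2% RMS
        once the timer distribution has reached its quasi-steady profile."""
        params = ModelParams(p1=30.0, p2=7.0, p3=7.0, p4=10.0, b=1.0,
                             K=100_000, w=0.02,
                             replication_dist="exponential")
        n_rep = 60
        t_warm, t_run = 1.25, 5.0
        trajs = []
        for r in range(n_rep):
            ts = simulate(params, t_warm + t_run, rng_seed=100 + r,
                          sample_every=8)
            trajs.append(ts.counts)
        trajs = np.array(trajs, dtype=float) / params.K
        ts0 = ts  # time grid shared across runs
        i0 = np.searchsorted(ts0.t, t_warm)
        mean_traj = trajs.mean(axis=0)
        t_grid = ts0.t[i0:]
        ode = integrate_meanfield(tuple(mean_traj[i0]), t_grid, params)
        rms = np.sqrt(np.mean((mean_traj[i0:, 0] - ode[:, 0]) ** 2))
        assert rms < 0.02 * ode[:, 0].mean()

    def test_stationary_mean_matches_fixed_point(self, s05):
        from quasisync import steady_state

        params = s05.with_(K=100_000, w=0.02)
        ts = simulate(params, 120.0, rng_seed=9,
                      init=steady_state_init(params))
        ss = steady_state(params)
        half = len(ts.t) // 2
        assert ts.n_A[half:].mean() / params.K == pytest.approx(
            ss.x_A, rel=0.02
        )

    def test_single_species_fluctuates_around_K(self):
        params = SingleSpeciesParams(b=1.0, K=50_000, w=0.08)
        ts = simulate_single_species(params, 800.0, rng_seed=10)
        n = ts.n[len(ts.n) // 3:]
        # mean within 1% of K (the long-lived synchrony mode limits the
        # effective sample count, so the bound is deliberately loose)
        assert abs(n.mean() - params.K) < 0.01 * params.K

    def test_small_k_goes_extinct(self):
        # the logistic death term is strongly stabilising, so the absorbing
        # state is reached quickly only for very small K
        params = SingleSpeciesParams(b=1.0, K=5, w=0.02)
        extinct = 0
        for seed in range(10):
            ts = simulate_single_species(params, 500.0, rng_seed=seed)
            extinct += ts.status == "extinct"
        assert extinct >= 8


class TestTimeSeries:
    def test_resume_from_state_continues_time(self, s05):
        params = s05.with_(K=2000)
        first = simulate(params, 2.0, rng_seed=11)
        second = simulate(params, 2.0, init=first.final_state, rng_seed=12)
        assert second.t[0] == pytest.approx(2.0)
        assert second.counts[0].tolist() == list(first.final_state.totals)
        assert second.meta["init_mode"] == "from_state"

    def test_frame_and_metadata(self, s05):
        params = s05.with_(K=2000)
        ts = simulate(params, 1.0, rng_seed=13)
        df = ts.to_frame()
        assert list(df.columns) == ["t", "N_A", "N_B"]
        assert ts.meta["seed"] == 13
        assert ts.meta["dt"] == DEFAULT_DT
        assert ts.meta["params"]["p1"] == 39.73

    def test_timer_window_covers_support(self, s05):
        win0, probs, n_bins = timer_window(s05.with_(w=0.1), DEFAULT_DT)
        T = s05.T
        assert probs.sum() == pytest.approx(1.0)
        lo = (win0 + 1) * DEFAULT_DT
        hi = (win0 + len(probs)) * DEFAULT_DT
        assert lo == pytest.approx(T * 0.9, abs=DEFAULT_DT)
        assert hi == pytest.approx(T * 1.1, abs=DEFAULT_DT)
        assert n_bins > win0 + len(probs) - 1
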