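import numpy as np
import pytest
from scipy.integrate import solve_ivp

from quorumsync.genetic_network import (
    ExtrinsicNoiseSpec,
    FluctuationAmplitudes,
    build_coupling_matrix,
    drift_single_cell,
)
from quorumsync.sde_sim import (
    ErrorTrajectory,
    SimulationConfig,
    TrajectoryEnsemble,
    compute_errors,
    euler_maruyama_step,
    filtering_ratio,
    monte_carlo_filtering,
    phase_jittered_initial,
    simulate_network,
    simulate_reference,
)


class TestEulerStep:
    def test_identity(self):
        x = np.ones((3, 7))
        out = euler_maruyama_step(x, np.zeros_like(x), np.zeros_like(x),
                                  np.zeros(7), 0.1, np.zeros(3), np.zeros(3))
        np.testing.assert_array_equal(out, x)

    def test_scalar_decay_one_step(self):
        x = np.array([[1.0] + [0.0] * 6])
        drift = -x
        out = euler_maruyama_step(x, drift, np.zeros_like(x), np.zeros(7),
                                  0.1, np.zeros(1), np.zeros(1))
        assert out[0, 0] == pytest.approx(0.9)

    def test_scalar_decay_bias_halves_with_step(self):
        # explicit Euler on dx = -x dt over t = 10: error vs e^-10 scales ~ dt
        def integrate(dt, n):
            x = np.array([[1.0] + [0.0] * 6])
            for _ in range(n):
                x = euler_maruyama_step(x, -x, np.zeros_like(x), np.zeros(7),
                                        dt, np.zeros(1), np.zeros(1))
            return x[0, 0]

        exact = np.exp(-10.0)
        err_coarse = abs(integrate(0.1, 100) - exact)
        err_fine = abs(integrate(0.05, 200) - exact)
        assert 1.5 < err_coarse / err_fine < 2.5

    def test_pure_noise_wiener_variance(self):
        # dx = dW: Var x(T) = T, checked over 2000 paths within 3 SE
        rng = np.random.default_rng(8)
        t_final, dt = 4.0, 0.01
        n_steps, n_paths = int(t_final / dt), 2000
        x = np.zeros((n_paths, 7))
        for _ in range(n_steps):
            dW = rng.normal(0.0, np.sqrt(dt), n_paths)
            x = euler_maruyama_step(x, np.zeros_like(x), np.ones_like(x),
                                    np.zeros(7), dt, dW, np.zeros(n_paths))
        var = x[:, 0].var(ddof=1)
        se = t_final * np.sqrt(2.0 / (n_paths - 1))
        assert abs(var - t_final) < 3 * se

    def test_invalid_dt(self):
        with pytest.raises(ValueError):
            euler_maruyama_step(np.zeros((1, 7)), np.zeros((1, 7)), np.zeros((1, 7)),
                                np.zeros(7), 0.0, np.zeros(1), np.zeros(1))


class TestSimulateNetwork:
    def test_single_cell_matches_ode(self, params, zero_amplitudes, quiet_noise):
        x0 = np.array([[0.0, 0.0, 0.0, 1.0, 2.0, 3.0, 0.0]])
        C = build_coupling_matrix(1, params.eta_s, params.Q_e, 0.0)
        cfg = SimulationConfig(dt=0.002, t_final=5.0, n_cells=1, init=x0, seed=0,
                               clip_negative=False)
        ens = simulate_network(params, zero_amplitudes, C, quiet_noise, cfg)
        ref = solve_ivp(
            lambda t, y: drift_single_cell(y, params), (0, 5.0), x0[0],
            rtol=1e-10, atol=1e-12, dense_output=True,
        )
        err = np.abs(ens.states[0, -1, 0] - ref.sol(5.0)).max()
        cfg2 = cfg.replace(dt=0.001)
        ens2 = simulate_network(params, zero_amplitudes, C, quiet_noise, cfg2)
        err2 = np.abs(ens2.states[0, -1, 0] - ref.sol(5.0)).max()
        assert err < 0.15
        assert 1.5 < err / err2 < 2.5        # first-order convergence

    def test_manifold_invariance_bitwise(self, params, zero_amplitudes, quiet_noise):
        init = np.tile(np.array([1.0, 2.0, 0.5, 1.5, 2.5, 3.0, 0.2]), (10, 1))
        C = build_coupling_matrix(10, params.eta_s, params.Q_e, 0.66)
        cfg = SimulationConfig(dt=0.005, t_final=2.0, n_cells=10, init=init, seed=0)
        ens = simulate_network(params, zero_amplitudes, C, quiet_noise, cfg)
        for c in range(1, 10):
            np.testing.assert_array_equal(ens.states[0, :, c], ens.states[0, :, 0])

    def test_bit_exact_determinism(self, params, amplitudes, ai_noise):
        C = build_coupling_matrix(5, params.eta_s, params.Q_e, 0.66)
        cfg = SimulationConfig(dt=0.005, t_final=3.0, n_cells=5, seed=42)
        a = simulate_network(params, amplitudes, C, ai_noise, cfg)
        b = simulate_network(params, amplitudes, C, ai_noise, cfg)
        np.testing.assert_array_equal(a.states, b.states)
        np.testing.assert_array_equal(a.v, b.v)

    def test_seed_changes_output(self, params, amplitudes, ai_noise):
        C = build_coupling_matrix(5, params.eta_s, params.Q_e, 0.66)
        cfg = SimulationConfig(dt=0.005, t_final=1.0, n_cells=5, seed=1)
        a = simulate_network(params, amplitudes, C, ai_noise, cfg)
        b = simulate_network(params, amplitudes, C, ai_noise, cfg.replace(seed=2))
        assert not np.array_equal(a.states, b.states)

    def test_coupling_dimension_mismatch(self, params, amplitudes, ai_noise):
        C = build_coupling_matrix(4, params.eta_s, params.Q_e)
        cfg = SimulationConfig(n_cells=5, t_final=1.0)
        with pytest.raises(ValueError):
            simulate_network(params, amplitudes, C, ai_noise, cfg)

    def test_phase_jitter_initial_on_attractor(self, params):
        rng = np.random.default_rng(0)
        init = phase_jittered_initial(params, 10, 0.3, rng)
        assert init.shape == (10, 7)
        assert np.all(init >= 0)
        assert len(np.unique(init[:, 0])) > 1


class TestErrors:
    def _tiny_ensemble(self, params, zero_amplitudes, quiet_noise, init, t_final=1.0):
        N = init.shape[0]
        C = build_coupling_matrix(N, params.eta_s, params.Q_e, 0.0)
        cfg = SimulationConfig(dt=0.01, t_final=t_final, n_cells=N, init=init, seed=0)
        return simulate_network(params, zero_amplitudes, C, quiet_noise, cfg)

    def test_identical_cells_zero_error(self, params, zero_amplitudes, quiet_noise):
        init = np.tile(np.linspace(0.5, 3.5, 7), (4, 1))
        ens = self._tiny_ensemble(params, zero_amplitudes, quiet_noise, init)
        err = compute_errors(ens)
        assert np.abs(err.e).max() < 1e-13

    def test_population_mean_centering(self, params, amplitudes, ai_noise):
        C = build_coupling_matrix(6, params.eta_s, params.Q_e, 0.0)
        cfg = SimulationConfig(dt=0.01, t_final=1.0, n_cells=6, seed=3)
        ens = simulate_network(params, amplitudes, C, ai_noise, cfg)
        err = compute_errors(ens)
        sums = err.e.sum(axis=2)
        np.testing.assert_allclose(sums, 0.0, atol=1e-12)

    def test_two_cell_symmetric_errors(self):
        # direct contract: states 1 and 3 -> centred errors -1 and +1
        t = np.array([0.0, 0.01])
        states = np.zeros((1, 2, 2, 7))
        states[0, :, 0, 0] = 1.0
        states[0, :, 1, 0] = 3.0
        ens = TrajectoryEnsemble(
            t=t, states=states, v=np.zeros((1, 1, 2)),
            config=SimulationConfig(dt=0.01, t_final=0.01, n_cells=2,
                                    init=states[0, 0]),
            run_seeds=(0,),
        )
        err = compute_errors(ens)
        assert err.e[0, 0, 0, 0] == -1.0
        assert err.e[0, 0, 1, 0] == +1.0

    def test_nominal_reference_kind(self, params, zero_amplitudes, quiet_noise):
        init = np.tile(np.array([1.0, 2.0, 0.5, 1.5, 2.5, 3.0, 0.2]), (3, 1))
        ens = self._tiny_ensemble(params, zero_amplitudes, quiet_noise, init)
        err = compute_errors(ens, "nominal-limit-cycle", params=params)
        # identical cells starting at the reference IC track it exactly
        np.testing.assert_allclose(err.e, 0.0, atol=1e-9)

    def test_unknown_reference(self, params, zero_amplitudes, quiet_noise):
        init = np.tile(np.ones(7), (2, 1))
        ens = self._tiny_ensemble(params, zero_amplitudes, quiet_noise, init)
        with pytest.raises(ValueError):
            compute_errors(ens, "bogus")


class TestFilteringRatio:
    def _fabricated(self, e_value, v_value, n_t=11, dt=0.1):
        t = np.arange(n_t) * dt
        states = np.zeros((1, n_t, 1, 7))
        v = np.full((1, n_t - 1, 1), v_value)
        cfg = SimulationConfig(dt=dt, t_final=(n_t - 1) * dt, n_cells=1,
                               init=np.zeros((1, 7)))
        ens = TrajectoryEnsemble(t=t, states=states, v=v, config=cfg, run_seeds=(0,))
        e = np.zeros((1, n_t, 1, 7))
        e[..., 0] = e_value
        err = ErrorTrajectory(e=e, reference=np.zeros((1, n_t, 7)),
                              kind="population-mean", t=t)
        return err, ens

    def test_zero_error_zero_ratio(self):
        err, ens = self._fabricated(0.0, 1.0)
        assert filtering_ratio(err, ens) == 0.0

    def test_constants_cancel(self):
        # e = 2, v = 1, R = identity: ratio 4 regardless of horizon and step
        for n_t, dt in ((11, 0.1), (101, 0.05)):
            err, ens = self._fabricated(2.0, 1.0, n_t=n_t, dt=dt)
            assert filtering_ratio(err, ens) == pytest.approx(4.0)

    def test_zero_denominator_raises(self):
        err, ens = self._fabricated(1.0, 0.0)
        with pytest.raises(ValueError, match="undefined"):
            filtering_ratio(err, ens)

    def test_initial_energy_subtraction(self):
        err, ens = self._fabricated(2.0, 1.0)
        P = np.eye(7) * 1e6
        assert filtering_ratio(err, ens, include_initial=True, P=P) == 0.0

    def test_species_weighting(self):
        err, ens = self._fabricated(2.0, 1.0)
        R = np.zeros(7)
        R[0] = 0.25
        assert filtering_ratio(err, ens, R=R) == pytest.approx(1.0)


class TestMonteCarlo:
    def test_determinism(self, params, amplitudes, ai_noise):
        C = build_coupling_matrix(3, params.eta_s, params.Q_e, 0.66)
        cfg = SimulationConfig(dt=0.01, t_final=2.0, n_cells=3)
        kw = dict(n_runs=3, base_seed=7)
        a = monte_carlo_filtering(params, amplitudes, C, ai_noise, cfg, **kw)
        b = monte_carlo_filtering(params, amplitudes, C, ai_noise, cfg, **kw)
        assert a.ratio == b.ratio
        assert a.se == b.se

    def test_pooling_is_ratio_of_sums(self, params, amplitudes, ai_noise):
        C = build_coupling_matrix(3, params.eta_s, params.Q_e, 0.66)
        cfg = SimulationConfig(dt=0.01, t_final=2.0, n_cells=3)
        mc = monte_carlo_filtering(params, amplitudes, C, ai_noise, cfg,
                                   n_runs=4, base_seed=11)
        assert mc.ratio == pytest.approx(mc.numerators.sum() / mc.denominators.sum())

    def test_requires_two_runs(self, params, amplitudes, ai_noise):
        C = build_coupling_matrix(3, params.eta_s, params.Q_e)
        cfg = SimulationConfig(dt=0.01, t_final=1.0, n_cells=3)
        with pytest.raises(ValueError):
            monte_carlo_filtering(params, amplitudes, C, ai_noise, cfg,
                                  n_runs=1, base_seed=0)

    def test_sigma_scaling_invariance(self, params, zero_amplitudes):
        # pre-synchronized, intrinsic noise off: the ratio is a linear-response
        # quantity, invariant to doubling sigma_v within 3 jackknife SEs
        h = np.zeros(7)
        h[6] = 1.0
        C = build_coupling_matrix(5, params.eta_s, params.Q_e, 0.66)
        cfg = SimulationConfig(dt=0.005, t_final=20.0, n_cells=5,
                               init_mode="phase-jitter", jitter_spread=0.0)
        results = []
        for sigma in (0.02, 0.04):
            noise = ExtrinsicNoiseSpec(h_cell=h, sigma_v=sigma)
            results.append(
                monte_carlo_filtering(params, zero_amplitudes, C, noise, cfg,
                                      n_runs=6, base_seed=5)
            )
        a, b = results
        tol = 3.0 * np.sqrt(a.se ** 2 + b.se ** 2)
        assert abs(a.ratio - b.ratio) <= tol

    def test_v_twin_estimator_zero_when_sigma_zero_everywhere(self, params, amplitudes, ai_noise):
        # twin runs share seeds: the delta isolates the extrinsic channel,
        # so it vanishes when the main run carries no extrinsic noise either
        C = build_coupling_matrix(3, params.eta_s, params.Q_e, 0.66)
        cfg = SimulationConfig(dt=0.01, t_final=1.0, n_cells=3)
        quiet = ExtrinsicNoiseSpec(h_cell=ai_noise.h_cell, sigma_v=0.0)
        with pytest.raises(ValueError):
            monte_carlo_filtering(params, amplitudes, C, quiet, cfg,
                                  n_runs=2, base_seed=0, estimator="v-twin")
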