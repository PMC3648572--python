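import numpy as np
import pytest

from dielgrowth import (
    DielGrowthModel,
    GrowthParameters,
    LightSchedule,
    NoiseModel,
    Replicate,
    adjusted_r_squared,
    fit_observation_set,
    fit_replicate,
    generate_counts,
    replicate_statistics,
    simulate,
    sse,
)
from dielgrowth.fitting import DEFAULT_INIT, FitResult


def _fit_results(values, name="delta"):
    out = []
    for i, v in enumerate(values):
        kw = {"gamma": 0.6, "delta": 0.1, "kappa": 8.0}
        kw[name] = v
        out.append(
            FitResult(
                replicate_id=f"r{i}", condition="pure", n0=9e3,
                sse=0.0, r2_adjusted=0.9, converged=True, n_iterations=10, **kw,
            )
        )
    return out


class TestSse:
    def test_zero_on_self_generated_data(self, pure_params, schedule, grid):
        traj = simulate(pure_params, schedule, grid)
        val = sse(pure_params, grid, traj.N, schedule)
        assert val == pytest.approx(0.0, abs=1e-6 * np.sum(traj.N**2))

    def test_known_residual_arithmetic(self, schedule):
        # residuals +100 and -200 cells/mL give SSE = 50,000
        p = GrowthParameters(gamma=0.5, delta=0.0, kappa=2.0, n0=1e4, m0=5e3)
        t = np.array([0.0, 1.0])
        traj = simulate(p, schedule, t)
        obs = traj.N + np.array([-100.0, 200.0])
        assert sse(p, t, obs, schedule) == pytest.approx(50_000.0)

    def test_true_parameters_beat_perturbed_gamma(self, pure_params, schedule, grid):
        traj = simulate(pure_params, schedule, grid)
        worse = GrowthParameters(
            gamma=1.5 * pure_params.gamma, delta=pure_params.delta,
            kappa=pure_params.kappa, n0=pure_params.n0,
        )
        assert sse(pure_params, grid, traj.N, schedule) < sse(worse, grid, traj.N, schedule)


class TestAdjustedRSquared:
    def test_perfect_prediction_gives_one(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert adjusted_r_squared(y, y, n_params=3) == pytest.approx(1.0)

    def test_mean_prediction_with_three_params(self):
        y = np.arange(10.0)
        pred = np.full(10, y.mean())
        assert adjusted_r_squared(y, pred, n_params=3) == pytest.approx(-0.5)

    def test_hand_computed_example(self):
        # SSE = 0.10, SStot = 5.0 -> R^2 = 0.98; n=4, p=1 -> adjusted = 0.97
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        pred = np.array([1.1, 1.9, 3.2, 3.8])
        assert adjusted_r_squared(obs, pred, n_params=1) == pytest.approx(0.97)

    def test_zero_variance_flagged(self):
        y = np.ones(8)
        with pytest.raises(ValueError, match="variance"):
            adjusted_r_squared(y, y + 0.1, n_params=3)


class TestEstimator:
    def test_noiseless_recovery_within_half_percent(self, noiseless_obs, pure_params):
        rep = noiseless_obs.replicates[0]
        res = fit_replicate(rep)
        for name in ("gamma", "delta", "kappa"):
            fitted, true = getattr(res, name), getattr(pure_params, name)
            assert abs(fitted - true) / true < 5e-3
        assert res.converged

    def test_init_at_optimum_stays_put(self, pure_params, schedule, grid):
        traj = simulate(pure_params, schedule, grid)
        est = DielGrowthModel(
            gamma_init=pure_params.gamma,
            delta_init=pure_params.delta,
            kappa_init=pure_params.kappa,
            n_restarts=1,
        ).fit(grid, traj.N)
        assert est.gamma_ == pytest.approx(pure_params.gamma, rel=1e-6)
        assert est.delta_ == pytest.approx(pure_params.delta, rel=1e-6)
        assert est.kappa_ == pytest.approx(pure_params.kappa, rel=1e-6)

    def test_fitted_sse_never_exceeds_init_sse(self, pure_params, schedule, grid):
        obs = generate_counts(pure_params, noise=NoiseModel(cv=0.15, seed=7))
        rep = obs.replicates[0]
        init = DEFAULT_INIT["pure"]
        init_params = GrowthParameters(**init, n0=rep.counts[0])
        res = fit_replicate(rep)
        assert res.sse <= sse(init_params, rep.times, rep.counts, schedule)

    def test_invariance_to_uniform_count_rescaling(self, pure_params):
        obs = generate_counts(pure_params, noise=NoiseModel(cv=0.10, seed=3))
        rep = obs.replicates[0]
        scaled = Replicate(
            replicate_id=rep.replicate_id, condition=rep.condition,
            times=rep.times, counts=10.0 * rep.counts,
        )
        a, b = fit_replicate(rep), fit_replicate(scaled)
        assert a.gamma == pytest.approx(b.gamma, rel=1e-4)
        assert a.delta == pytest.approx(b.delta, rel=1e-4)
        assert a.kappa == pytest.approx(b.kappa, rel=1e-4)
        assert b.n0 == pytest.approx(10.0 * a.n0)

    def test_sklearn_protocol(self, noiseless_obs):
        rep = noiseless_obs.replicates[0]
        est = DielGrowthModel(n_restarts=2)
        params = est.get_params()
        assert "gamma_init" in params and "loss" in params
        est.set_params(n_restarts=1)
        assert est.get_params()["n_restarts"] == 1
        with pytest.raises(ValueError):
            est.set_params(not_a_param=1)
        est.fit(rep.times[:, None], rep.counts)  # accepts (n, 1) design matrix
        assert est.score(rep.times, rep.counts) > 0.999
        pred = est.predict(rep.times)
        assert pred.shape == rep.times.shape

    def test_predict_before_fit_raises(self):
        with pytest.raises(RuntimeError):
            DielGrowthModel().predict(np.arange(5.0))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            DielGrowthModel().fit(np.array([0.0, 2.0, 4.0]), np.array([1e3, 2e3, 3e3]))

    def test_log_loss_also_recovers_noiseless_parameters(self, noiseless_obs, pure_params):
        rep = noiseless_obs.replicates[0]
        res = fit_replicate(rep, loss="log")
        assert res.delta == pytest.approx(pure_params.delta, rel=5e-3)


class TestReplicateStatistics:
    def test_identical_fits_have_zero_interval(self):
        stats = replicate_statistics(_fit_results([0.1, 0.1, 0.1]))
        assert stats["delta"]["ci95_half_width"] == pytest.approx(0.0, abs=1e-12)
        assert stats["delta"]["mean"] == pytest.approx(0.1)

    def test_t_interval_for_three_values(self):
        # sd = 1, n = 3, t(0.975, 2) = 4.3027 -> half-width 2.484
        stats = replicate_statistics(_fit_results([1.0, 2.0, 3.0], name="kappa"))
        assert stats["kappa"]["mean"] == pytest.approx(2.0)
        assert stats["kappa"]["ci95_half_width"] == pytest.approx(2.484, abs=1e-3)
        assert stats["kappa"]["sem"] == pytest.approx(1.0 / np.sqrt(3.0))

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            replicate_statistics(_fit_results([0.1]))

    def test_observation_set_fit_report_structure(self, noiseless_obs):
        report = fit_observation_set(noiseless_obs)
        assert len(report.per_replicate) == 3
        assert report.aggregate["n"] == 3
        assert report.aggregate["gamma"]["ci95_half_width"] >= 0.0
        d = report.to_dict()
        assert {"per_replicate", "aggregate"} <= set(d)
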