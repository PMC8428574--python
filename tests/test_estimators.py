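import numpy as np
import pytest

from survkit import (
    ConvergenceError,
    CoxPH,
    KaplanMeier,
    NelsonAalen,
    SimConfig,
    ValidationError,
    WeibullAFT,
    breslow_baseline,
    cox_partial_loglik,
    eval_survival,
    fit_coxph,
    fit_kaplan_meier,
    fit_nelson_aalen,
    fit_weibull_aft,
    make_task,
    simulate_surv,
)
from survkit.nonparametric import nelson_aalen_curve

from _oracles import km_oracle


class TestKaplanMeier:
    def test_hand_computed_curve(self, tiny_task):
        km = fit_kaplan_meier(tiny_task)
        S = eval_survival(km.baseline_, [1, 2, 3])[0]
        np.testing.assert_allclose(S, [2 / 3, 1 / 3, 1 / 3])

    def test_no_events_gives_unit_curve(self):
        task = make_task([[1], [2]], [1, 2], [0, 0])
        km = fit_kaplan_meier(task)
        np.testing.assert_allclose(km.baseline_.S, 1.0)

    def test_tied_deaths_hit_zero(self):
        task = make_task([[1], [2]], [1, 1], [1, 1])
        km = fit_kaplan_meier(task)
        assert eval_survival(km.baseline_, [1])[0, 0] == 0.0

    def test_prediction_replicates_curve_with_tied_crank(self, tiny_task):
        pred = fit_kaplan_meier(tiny_task).predict_surv(tiny_task.X)
        assert pred.distr.n == 3
        assert np.ptp(pred.crank) == 0
        assert pred.channels == {"crank", "distr"}

    def test_uncensored_km_is_one_minus_ecdf(self, rng):
        for _ in range(5):
            t = rng.exponential(1.0, 30)
            task = make_task(np.zeros((30, 1)) + rng.standard_normal((30, 1)),
                             t, np.ones(30))
            km = fit_kaplan_meier(task)
            ecdf = np.array([(t <= g).mean() for g in km.grid_])
            np.testing.assert_allclose(km.surv_, 1 - ecdf, atol=1e-12)

    def test_matches_independent_oracle(self, rng):
        t = np.round(rng.exponential(1, 25), 2) + 0.1
        s = rng.integers(0, 2, 25)
        s[0] = 1
        km = fit_kaplan_meier(make_task(np.zeros((25, 1)), t, s))
        oracle = km_oracle(t.tolist(), s.tolist())
        for tj, sj in oracle.items():
            assert eval_survival(km.baseline_, [tj])[0, 0] == pytest.approx(sj)

    def test_matches_lifelines(self, ph_task):
        from lifelines import KaplanMeierFitter

        task, _ = ph_task
        km = fit_kaplan_meier(task)
        lf = KaplanMeierFitter().fit(task.time, task.status)
        ref = lf.survival_function_at_times(km.grid_).to_numpy()
        np.testing.assert_allclose(km.surv_, ref, atol=1e-10)


class TestNelsonAalen:
    def test_hand_computed_hazard(self, tiny_task):
        na = fit_nelson_aalen(tiny_task)
        np.testing.assert_allclose(na.cum_hazard_, [1 / 3, 1 / 3 + 1 / 2])

    def test_single_subject(self):
        na = fit_nelson_aalen(make_task([[0.0]], [1], [1]))
        np.testing.assert_allclose(na.cum_hazard_, [1.0])
        np.testing.assert_allclose(na.baseline_.S[0], [np.exp(-1)])

    def test_exp_minus_H_dominates_km(self, rng):
        for _ in range(5):
            n = 40
            t = rng.exponential(1, n)
            s = rng.integers(0, 2, n)
            s[0] = 1
            task = make_task(rng.standard_normal((n, 1)), t, s)
            km, na = fit_kaplan_meier(task), fit_nelson_aalen(task)
            grid = km.grid_
            S_km = eval_survival(km.baseline_, grid)[0]
            S_na = eval_survival(na.baseline_, grid)[0]
            assert np.all(S_na >= S_km - 1e-12)


class TestCoxPH:
    def test_matches_grid_search_on_partial_likelihood(self):
        # interior-maximum fixture: events alternate between the two groups
        time, status, x = [1, 2, 3, 4], [1, 1, 1, 1], [1.0, 0.0, 1.0, 0.0]
        task = make_task([[v] for v in x], time, status)
        model = fit_coxph(task)
        grid = np.arange(-10, 10, 1e-3)
        lls = [cox_partial_loglik([b], [[v] for v in x], time, status) for b in grid]
        beta_grid = grid[int(np.argmax(lls))]
        assert model.coef_[0] == pytest.approx(beta_grid, abs=1e-2)

    def test_monotone_likelihood_raises(self):
        task = make_task([[1.0], [0.0]], [1, 2], [1, 1])
        with pytest.raises(ConvergenceError, match="covariate|monotone"):
            fit_coxph(task)

    def test_constant_covariate_raises(self):
        task = make_task([[1.0], [1.0], [1.0]], [1, 2, 3], [1, 1, 0])
        with pytest.raises(ValidationError, match="constant"):
            fit_coxph(task)

    def test_parameter_recovery_on_simulated_data(self):
        cfg = SimConfig(n=2000, p=2, beta=(0.5, -0.5), model="ph",
                        censoring=("exponential", 0.3), seed=7)
        task, _ = simulate_surv(cfg)
        model = fit_coxph(task)
        np.testing.assert_allclose(model.coef_, [0.5, -0.5], atol=0.1)
        assert model.final_grad_norm_ <= 1e-9

    def test_matches_scikit_survival_breslow(self, ph_task):
        from sksurv.linear_model import CoxPHSurvivalAnalysis

        task, _ = ph_task
        ours = fit_coxph(task)
        y = np.array(
            [(bool(s), t) for s, t in zip(task.status, task.time)],
            dtype=[("event", bool), ("time", float)],
        )
        ref = CoxPHSurvivalAnalysis(ties="breslow").fit(task.X, y)
        np.testing.assert_allclose(ours.coef_, ref.coef_, atol=1e-6)

    def test_rescaling_invariance(self, ph_task):
        task, _ = ph_task
        b1 = fit_coxph(task).coef_
        scaled = make_task(task.X * np.array([10.0, 0.25]), task.time, task.status)
        b2 = fit_coxph(scaled).coef_
        np.testing.assert_allclose(b2, b1 / np.array([10.0, 0.25]), atol=1e-6)

    def test_zero_beta_baseline_is_nelson_aalen(self, ph_task):
        task, _ = ph_task
        Xc = task.X - task.X.mean(axis=0)
        grid, H0 = breslow_baseline(Xc, task.time, task.status, np.zeros(task.p))
        grid_na, H_na = nelson_aalen_curve(task.time, task.status)
        np.testing.assert_allclose(grid, grid_na)
        np.testing.assert_allclose(H0, H_na, atol=1e-12)

    def test_prediction_channels_and_monotone_distr(self, ph_task):
        task, _ = ph_task
        pred = fit_coxph(task).predict_surv(task.X[:5])
        assert pred.channels == {"lp", "crank", "distr"}
        np.testing.assert_array_equal(pred.crank, pred.lp)
        assert np.all(np.diff(pred.distr.S, axis=1) <= 1e-12)


class TestWeibullAFT:
    def test_scale_recovery_without_censoring(self):
        cfg = SimConfig(n=5000, p=1, beta=(0.0,), model="aft",
                        baseline=("weibull", 2.0, 1.0), seed=3)
        task, _ = simulate_surv(cfg)
        model = fit_weibull_aft(task)
        assert model.scale_ == pytest.approx(0.5, abs=0.05)
        assert model.loglik_ >= model.loglik_init_

    def test_no_signal_gives_flat_lp(self, rng):
        X = rng.standard_normal((300, 2))
        t = rng.exponential(1, 300) + 0.01
        task = make_task(X, t, np.ones(300))
        model = fit_weibull_aft(task)
        np.testing.assert_allclose(model.coef_, 0.0, atol=0.15)

    def test_zero_time_rejected(self):
        task = make_task([[1.0], [2.0]], [0.0, 1.0], [1, 1])
        with pytest.raises(ValidationError, match="positive"):
            fit_weibull_aft(task)

    def test_matches_lifelines(self, ph_task):
        from lifelines import WeibullAFTFitter

        task, _ = ph_task
        ours = fit_weibull_aft(task)
        lf = WeibullAFTFitter().fit(task.to_frame(), duration_col="time",
                                    event_col="status")
        assert ours.intercept_ == pytest.approx(
            lf.params_["lambda_"]["Intercept"], abs=1e-3)
        np.testing.assert_allclose(
            ours.coef_, [lf.params_["lambda_"]["x1"], lf.params_["lambda_"]["x2"]],
            atol=1e-3)
        assert ours.scale_ == pytest.approx(
            np.exp(-lf.params_["rho_"]["Intercept"]), abs=1e-3)

    def test_prediction_channels_and_directions(self, ph_task):
        task, _ = ph_task
        pred = fit_weibull_aft(task).predict_surv(task.X[:10])
        assert pred.channels == {"response", "lp", "crank", "distr"}
        np.testing.assert_allclose(pred.crank, -pred.lp)
        # larger lp -> later predicted median
        order = np.argsort(pred.lp)
        assert np.all(np.diff(pred.response[order]) >= 0)


class TestEstimatorProtocol:
    @pytest.mark.parametrize("cls", [KaplanMeier, NelsonAalen, CoxPH, WeibullAFT])
    def test_sklearn_params_and_valid_predictions(self, cls, ph_task):
        task, _ = ph_task
        est = cls()
        params = est.get_params()
        est.set_params(**params)
        pred = est.fit(task.X, (task.time, task.status)).predict_surv(task.X[:7])
        assert pred.n == 7
        assert pred.channels == cls.predict_types
        risk = est.predict(task.X[:7])
        np.testing.assert_array_equal(risk, pred.crank)
        if pred.distr is not None:
            assert np.all((pred.distr.S >= 0) & (pred.distr.S <= 1))
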