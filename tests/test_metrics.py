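import numpy as np
import pytest

from survkit import (
    CensoringDistribution,
    ScoringError,
    SimConfig,
    SurvDistribution,
    SurvPrediction,
    ValidationError,
    fit_coxph,
    graf_score,
    harrell_c,
    houwelingen_beta,
    integrated_logloss,
    km_calibration,
    schmid_score,
    simulate_surv,
    uno_auc,
    uno_c,
)
from survkit.metrics import MEASURES

import _oracles as oracle


def sharp_prediction(event_time=5.0, n=1):
    """S(t) = 1 before the event, 0 from it on: a perfect sharp forecast."""
    return SurvDistribution(grid=[event_time], S=np.zeros((n, 1)))


class TestHarrellC:
    def test_perfect_ranking(self):
        assert harrell_c([3, 1, 2], [1, 3, 2], [1, 1, 1]) == 1.0

    def test_hand_enumerated_partial_ranking(self):
        # pairs (1,3),(1,2),(3,2): only crank ordering 1<3 vs times 1<2 wrong...
        assert harrell_c([1, 2, 3], [1, 3, 2], [1, 1, 1]) == pytest.approx(1 / 3)

    def test_constant_crank_is_half(self):
        assert harrell_c([1, 1, 1], [1, 2, 3], [1, 1, 0]) == 0.5

    def test_all_censored_raises(self):
        with pytest.raises(ScoringError, match="comparable"):
            harrell_c([1, 2], [1, 2], [0, 0])

    def test_reversal_symmetry_without_ties(self, rng):
        crank = rng.standard_normal(15)
        time = rng.exponential(1, 15)
        status = rng.integers(0, 2, 15)
        status[:2] = 1
        assert harrell_c(crank, time, status) + harrell_c(-crank, time, status) \
            == pytest.approx(1.0)

    def test_permutation_invariance(self, rng):
        crank = rng.standard_normal(12)
        time = rng.exponential(1, 12)
        status = np.ones(12)
        perm = rng.permutation(12)
        assert harrell_c(crank, time, status) == pytest.approx(
            harrell_c(crank[perm], time[perm], status[perm]))


class TestUnoC:
    def test_equals_harrell_when_uncensored(self, rng):
        crank = rng.standard_normal(20)
        time = rng.exponential(1, 20)
        status = np.ones(20)
        G = CensoringDistribution.fit(time, status)
        assert uno_c(crank, time, status, G) == pytest.approx(
            harrell_c(crank, time, status), abs=1e-12)

    def test_perfect_anticoncordance_is_zero(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        status = np.ones(4)
        G = CensoringDistribution.fit(time, status)
        assert uno_c([1, 2, 3, 4], time, status, G) == 0.0

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            time, status, _, _, crank = oracle.random_instance(rng, n_max=8)
            if status.sum() == 0:
                continue
            G = CensoringDistribution.fit(time, status)
            tau = float(time[status == 1].max())
            try:
                ours = uno_c(crank, time, status, G, tau=tau)
            except ScoringError:
                continue
            ref = oracle.uno_c_oracle(crank, time, status, G, tau)
            assert ours == pytest.approx(ref, abs=1e-12)


class TestScoringRules:
    def test_sharp_prediction_scores_zero(self):
        time, status = np.array([5.0]), np.array([1])
        G = CensoringDistribution.fit(time, status)
        d = sharp_prediction()
        ev = [3.0, 5.0, 7.0]
        assert graf_score(d, time, status, G, eval_times=ev) == 0.0
        assert schmid_score(d, time, status, G, eval_times=ev) == 0.0
        assert integrated_logloss(d, time, status, G, eval_times=ev) \
            == pytest.approx(0.0, abs=1e-12)

    def test_constant_half_probability(self):
        time, status = np.array([5.0]), np.array([1])
        G = CensoringDistribution.fit(time, status)
        d = SurvDistribution(grid=[0.1], S=[[0.5]])
        assert graf_score(d, time, status, G, eval_times=[4.0, 6.0]) \
            == pytest.approx(0.25)
        assert schmid_score(d, time, status, G, eval_times=[4.0, 6.0]) \
            == pytest.approx(0.5)
        assert integrated_logloss(d, time, status, G, eval_times=[4.0, 6.0]) \
            == pytest.approx(np.log(2))

    def test_empty_grid_rejected(self):
        time, status = np.array([5.0]), np.array([1])
        G = CensoringDistribution.fit(time, status)
        with pytest.raises(ScoringError):
            graf_score(sharp_prediction(), time, status, G, eval_times=[])

    @pytest.mark.parametrize(
        "ours,ref",
        [
            (graf_score, oracle.graf_oracle),
            (integrated_logloss, oracle.logloss_oracle),
            (schmid_score, oracle.schmid_oracle),
        ],
    )
    def test_matches_brute_force(self, ours, ref, rng):
        for _ in range(25):
            time, status, grid, S, _ = oracle.random_instance(rng)
            G = CensoringDistribution.fit(time, status)
            d = SurvDistribution(grid=grid, S=S)
            eval_times = np.unique(time[status == 1])
            got = ours(d, time, status, G, eval_times=eval_times)
            want = ref(grid, d.S, time, status, G, eval_times.tolist())
            assert got == pytest.approx(want, abs=1e-12)

    def test_bounded_scores(self, rng):
        time, status, grid, S, _ = oracle.random_instance(rng)
        G = CensoringDistribution.fit(time, status)
        d = SurvDistribution(grid=grid, S=S)
        assert 0 <= graf_score(d, time, status, G) <= 1 / G.floor
        assert schmid_score(d, time, status, G) >= 0
        assert integrated_logloss(d, time, status, G) >= 0

    def test_properness_of_graf_score(self):
        # the generating distribution scores no worse than a perturbed one
        margin_wins = 0
        for seed in range(5):
            cfg = SimConfig(n=300, p=0, beta=(), model="ph",
                            baseline=("exponential", 1.0),
                            censoring=("exponential", 0.3), seed=100 + seed)
            task, _ = simulate_surv(cfg)
            grid = np.linspace(0.05, 3.0, 40)
            S_true = np.tile(np.exp(-grid), (task.n, 1))
            S_bad = np.tile(np.exp(-2.5 * grid), (task.n, 1))
            G = CensoringDistribution.fit(task.time, task.status)
            true_score = graf_score(SurvDistribution(grid=grid, S=S_true),
                                    task.time, task.status, G)
            bad_score = graf_score(SurvDistribution(grid=grid, S=S_bad),
                                   task.time, task.status, G)
            margin_wins += true_score < bad_score
        assert margin_wins >= 4


class TestCalibration:
    def test_slope_near_one_for_true_lp(self):
        cfg = SimConfig(n=5000, p=2, beta=(0.5, -0.5), model="ph",
                        censoring=("exponential", 0.3), seed=17)
        task, truth = simulate_surv(cfg)
        assert houwelingen_beta(truth.lp, task.time, task.status) \
            == pytest.approx(1.0, abs=0.1)

    def test_slope_halves_for_doubled_lp(self):
        cfg = SimConfig(n=5000, p=2, beta=(0.5, -0.5), model="ph",
                        censoring=("exponential", 0.3), seed=18)
        task, truth = simulate_surv(cfg)
        assert houwelingen_beta(2.0 * truth.lp, task.time, task.status) \
            == pytest.approx(0.5, abs=0.1)

    def test_constant_lp_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            houwelingen_beta([1.0, 1.0, 1.0], [1, 2, 3], [1, 1, 0])

    def test_km_self_calibration_is_zero(self, tiny_task):
        from survkit import fit_kaplan_meier

        pred = fit_kaplan_meier(tiny_task).predict_surv(tiny_task.X)
        res = km_calibration(pred.distr, tiny_task.time, tiny_task.status)
        assert float(res) == pytest.approx(0.0, abs=1e-12)

    def test_unit_survival_gap_equals_one_minus_km(self, tiny_task):
        d = SurvDistribution(grid=[1.0], S=np.ones((3, 1)))
        res = km_calibration(d, tiny_task.time, tiny_task.status)
        assert res.discrepancy == pytest.approx(1 - 1 / 3)

    def test_well_specified_cox_calibrates(self):
        cfg = SimConfig(n=2000, p=2, beta=(0.5, -0.5), model="ph",
                        censoring=("exponential", 0.3), seed=19)
        task, _ = simulate_surv(cfg)
        pred = fit_coxph(task).predict_surv(task.X)
        res = km_calibration(pred.distr, task.time, task.status)
        assert res.discrepancy <= 0.05


class TestUnoAUC:
    def test_perfect_separation(self):
        time = np.array([1.0, 2.0, 8.0, 9.0])
        status = np.ones(4)
        G = CensoringDistribution.fit(time, status)
        assert uno_auc([4, 3, 2, 1], time, status, G, t=5.0) == 1.0

    def test_no_cases_or_controls_named(self):
        time, status = np.array([1.0, 2.0]), np.ones(2)
        G = CensoringDistribution.fit(time, status)
        with pytest.raises(ScoringError, match="controls"):
            uno_auc([1, 2], time, status, G, t=5.0)
        with pytest.raises(ScoringError, match="cases"):
            uno_auc([1, 2], time, status, G, t=0.5)

    def test_uninformative_marker_near_half(self, rng):
        n = 4000
        time = rng.exponential(1, n)
        marker = rng.standard_normal(n)
        status = np.ones(n)
        G = CensoringDistribution.fit(time, status)
        assert uno_auc(marker, time, status, G, t=float(np.median(time))) \
            == pytest.approx(0.5, abs=0.05)

    def test_matches_brute_force(self, rng):
        time = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        status = np.ones(6)
        marker = np.array([3.0, 5.0, 1.0, 1.0, 2.0, 0.0])
        G = CensoringDistribution.fit(time, status)
        assert uno_auc(marker, time, status, G, t=3.5) == pytest.approx(
            oracle.uno_auc_oracle(marker, time, status, G, 3.5), abs=1e-12)


class TestMeasureRegistry:
    def test_missing_channel_is_error_not_fallback(self, tiny_task):
        pred = SurvPrediction(n=3, crank=[1.0, 2.0, 3.0])
        with pytest.raises(Exception, match="distr"):
            MEASURES["surv.graf"](pred, tiny_task.time, tiny_task.status)

    def test_registry_scores_cox_prediction(self, ph_task):
        task, _ = ph_task
        pred = fit_coxph(task).predict_surv(task.X)
        G = CensoringDistribution.fit(task.time, task.status)
        for mid in ("surv.cindex", "surv.cindex.uno", "surv.graf",
                    "surv.intlogloss", "surv.schmid", "surv.calib.km", "surv.auc"):
            val = MEASURES[mid](pred, task.time, task.status, G=G)
            assert np.isfinite(val)
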