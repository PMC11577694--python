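import numpy as np
import pytest

from dksurv import (
    Dataset,
    DelayedKernelModel,
    EvalConfig,
    FitOptions,
    SimConfig,
    kfold_cross_validate,
    pe_fixed_base_curve,
    pe_fixed_window_curve,
    prediction_error,
    simulate_joint_dataset,
)
from dksurv.evaluation import _make_folds

from conftest import make_subject


class ConstantPredictor:
    """Assigns the same survival probability to everyone (conditional too)."""

    def __init__(self, pi, pic=None):
        self.pi = pi
        self.pic = pi if pic is None else pic

    def predict_survival(self, subj, u, t):
        return self.pi

    def conditional_survival_from_censoring(self, subj, t, u):
        return self.pic


class OraclePredictor:
    """Knows the true status at the horizon; optionally inverted."""

    def __init__(self, invert=False):
        self.invert = invert

    def predict_survival(self, subj, u, t):
        alive = subj.event_time >= u
        pi = 1.0 if alive else 0.0
        return 1.0 - pi if self.invert else pi

    def conditional_survival_from_censoring(self, subj, t, u):
        return self.predict_survival(subj, u, t)


def status_known_testset():
    """No censoring inside any window used below: statuses at u are known."""
    subs = [make_subject(f"s{i}", T, e) for i, (T, e) in enumerate(
        [(1.0, 1), (2.0, 1), (4.0, 1), (5.0, 0), (6.0, 0), (7.0, 1)]
    )]
    return Dataset(subs, ["z1"], [])


class TestPredictionError:
    def test_uniform_half_predictions_score_quarter(self):
        pe = prediction_error(ConstantPredictor(0.5), status_known_testset(),
                              t=1.5, u=3.5)
        assert pe == 0.25

    def test_perfect_predictions_score_zero(self):
        pe = prediction_error(OraclePredictor(), status_known_testset(),
                              t=1.5, u=3.5)
        assert pe == 0.0

    def test_inverted_predictions_score_one(self):
        pe = prediction_error(OraclePredictor(invert=True), status_known_testset(),
                              t=1.5, u=3.5)
        assert pe == 1.0

    def test_censored_subject_mixture_contribution(self):
        # single censored-in-window subject with pi=0.6, pi_conditional=0.8:
        # 0.8 * (1-0.6)^2 + 0.2 * 0.6^2 = 0.2
        d = Dataset([make_subject("c", 2.0, 0)], ["z1"], [])
        pe = prediction_error(ConstantPredictor(0.6, pic=0.8), d, t=1.0, u=3.0)
        assert pe == pytest.approx(0.2, abs=1e-12)

    def test_absolute_loss_supported(self):
        pe = prediction_error(ConstantPredictor(0.5), status_known_testset(),
                              t=1.5, u=3.5, loss="absolute")
        assert pe == 0.5

    def test_no_subjects_at_risk_is_an_error(self):
        with pytest.raises(ValueError, match="at risk"):
            prediction_error(ConstantPredictor(0.5), status_known_testset(),
                             t=100.0, u=101.0)

    def test_censoring_exactly_at_horizon_counts_as_survivor(self):
        d = Dataset([make_subject("c", 3.0, 0)], ["z1"], [])
        # T == u: survivor term L(1 - pi), not the censored mixture
        pe = prediction_error(ConstantPredictor(0.7, pic=0.0), d, t=1.0, u=3.0)
        assert pe == pytest.approx(0.3 ** 2, abs=1e-12)

    def test_terms_partition_the_risk_set(self):
        """Survivor, event, and censored-in-window contributions add up to
        the total: each at-risk subject lands in exactly one term."""
        t, u = 1.5, 3.5
        subs = [make_subject("surv", 6.0, 0), make_subject("dead", 2.0, 1),
                make_subject("cens", 2.5, 0), make_subject("gone", 1.0, 1)]
        d = Dataset(subs, ["z1"], [])
        p = ConstantPredictor(0.4, pic=0.9)
        pe = prediction_error(p, d, t, u)
        survivor = 0.6 ** 2
        dead = 0.4 ** 2
        cens = 0.9 * 0.6 ** 2 + 0.1 * 0.4 ** 2
        assert pe == pytest.approx((survivor + dead + cens) / 3, abs=1e-12)

    def test_degenerate_conditional_recovers_uncensored_formula(self):
        d = Dataset([make_subject("c", 2.0, 0)], ["z1"], [])
        as_survivor = prediction_error(ConstantPredictor(0.6, pic=1.0), d, 1.0, 3.0)
        as_event = prediction_error(ConstantPredictor(0.6, pic=0.0), d, 1.0, 3.0)
        assert as_survivor == pytest.approx(0.4 ** 2)
        assert as_event == pytest.approx(0.6 ** 2)

    def test_bounded_for_both_losses(self):
        d = status_known_testset()
        for loss in ("squared", "absolute"):
            for pi in (0.0, 0.3, 1.0):
                pe = prediction_error(ConstantPredictor(pi), d, 1.5, 3.5, loss)
                assert 0.0 <= pe <= 1.0


class TestCurves:
    def test_fixed_base_matches_pointwise_calls(self):
        d = status_known_testset()
        p = ConstantPredictor(0.4)
        u_grid = (2.0, 3.0, 4.5)
        curve = pe_fixed_base_curve(p, d, 1.5, u_grid)
        for row, u in zip(curve.rows, u_grid):
            assert row["pe"] == prediction_error(p, d, 1.5, u)
            assert row["n_at_risk"] == 5

    def test_degenerate_grid_at_base_time(self):
        d = status_known_testset()
        curve = pe_fixed_base_curve(ConstantPredictor(0.8), d, 1.5, (1.5,))
        # zero horizon: everyone at risk is a survivor
        assert curve.rows[0]["pe"] == pytest.approx(0.2 ** 2)

    def test_fixed_window_equals_fixed_base_when_grids_align(self):
        d = status_known_testset()
        p = ConstantPredictor(0.4)
        w = 1.0
        t_grid = (1.5, 2.5)
        wc = pe_fixed_window_curve(p, d, t_grid, w)
        for row, t in zip(wc.rows, t_grid):
            assert row["pe"] == prediction_error(p, d, t, t + w)

    def test_small_window_beats_large_window(self):
        cfg = SimConfig(n=150)
        d = simulate_joint_dataset(cfg, 3)
        res = DelayedKernelModel(d, "constant").fit()
        small = prediction_error(res, d, 2.0, 2.2)
        large = prediction_error(res, d, 2.0, 9.0)
        assert small < large


class TestCrossValidation:
    def test_leave_one_out_partition(self):
        folds = _make_folds(5, 5, seed=0)
        assert len(folds) == 5
        assert sorted(np.concatenate(folds).tolist()) == [0, 1, 2, 3, 4]
        assert all(len(f) == 1 for f in folds)

    def test_same_seed_same_folds(self):
        f1 = _make_folds(40, 10, seed=7)
        f2 = _make_folds(40, 10, seed=7)
        assert all(np.array_equal(a, b) for a, b in zip(f1, f2))

    def test_cv_deterministic_and_sane(self):
        d = simulate_joint_dataset(SimConfig(n=300), 9)
        med = float(np.median(d.event_times[d.events == 1]))
        cfg = EvalConfig(folds=10, seed=1, base_time=1.0, u_grid=(med,))
        opts = FitOptions(n_restarts=0, xtol=1e-3, ftol=1e-4)
        recipes = {"dk_B": lambda train: DelayedKernelModel(train, "B").fit(opts)}
        out1 = kfold_cross_validate(d, recipes, cfg)
        mean = out1["dk_B"]["mean"].to_frame()
        assert len(out1["dk_B"]["folds"]) == 10
        pe = float(mean["pe"].iloc[0])
        assert np.isfinite(pe) and 0.0 < pe <= 0.5
        out2 = kfold_cross_validate(d, recipes, cfg)
        assert out2["dk_B"]["mean"].to_frame()["pe"].iloc[0] == pe
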