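import math

import numpy as np
import pytest
from scipy.integrate import quad

from dksurv import (
    KernelSpec,
    Trajectory,
    kernel_b_longtime_limit,
    kernel_value,
    linear_predictor,
    locf_value,
    weighted_covariate_integral,
)
from dksurv.kernels import CONSTANT_ASSOC, DECAYING_ASSOC

from conftest import make_subject


def random_trajectory(rng, horizon=5.0):
    n = int(rng.integers(2, 6))
    times = np.concatenate([[0.0], np.sort(rng.uniform(0.1, horizon, n - 1))])
    return Trajectory(times, rng.normal(0.0, 2.0, n))


def quadrature_integral(spec, traj, t, s_eff):
    """Adaptive-quadrature oracle for the kernel-weighted covariate integral."""
    L = min(s_eff, t)
    knots = [x for x in traj.obs_times if x < L]
    val, _ = quad(
        lambda tp: kernel_value(spec, 0, t, tp, s_eff) * locf_value(traj, tp),
        0.0, L, points=knots + [L], limit=400,
    )
    return val


class TestKernelValue:
    def test_family_a_direct_evaluation(self):
        spec = KernelSpec("A", a=[1.0], tau=[1.0])
        # m = min(2, 1) = 1: e^{0.5} / (e - 1)
        expected = math.exp(0.5) / (math.e - 1.0)
        assert kernel_value(spec, 0, t=1.0, t_prime=0.5, s=2.0) == pytest.approx(
            expected, abs=1e-12
        )

    def test_family_b_direct_evaluation(self):
        spec = KernelSpec("B", a=[1.0], tau=[1.0])
        expected = math.exp(-1.0) + 1.0 - math.exp(-2.0) * (math.e - 1.0)
        assert kernel_value(spec, 0, t=2.0, t_prime=1.0, s=1.0) == pytest.approx(
            expected, abs=1e-12
        )

    @pytest.mark.parametrize("family", ["A", "B"])
    def test_causality_zero_for_future_covariates(self, family):
        spec = KernelSpec(family, a=[1.0], tau=[1.0])
        assert kernel_value(spec, 0, t=2.0, t_prime=3.0, s=5.0) == 0.0

    def test_baseline_only_subjects_rejected(self):
        spec = KernelSpec("A", a=[1.0], tau=[1.0])
        with pytest.raises(ValueError, match="baseline_only_rule"):
            kernel_value(spec, 0, t=1.0, t_prime=0.5, s=0.0)

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError, match="tau"):
            KernelSpec("A", a=[1.0], tau=[-1.0])

    def test_constant_family_has_no_pointwise_value(self):
        spec = KernelSpec("constant", a=[1.0])
        with pytest.raises(ValueError, match="integral"):
            kernel_value(spec, 0, 1.0, 0.5, 2.0)


class TestFamilyBLongTimeLimit:
    @pytest.mark.parametrize("a,s,expected", [(2.0, 4.0, 0.5), (1.0, 1.0, 1.0)])
    def test_printed_limit(self, a, s, expected):
        spec = KernelSpec("B", a=[a], tau=[1.0])
        assert kernel_b_longtime_limit(spec, 0, s) == expected

    def test_kernel_converges_to_limit(self):
        spec = KernelSpec("B", a=[1.3], tau=[0.7])
        s = 2.0
        val = kernel_value(spec, 0, t=1e3 * s, t_prime=0.5, s=s)
        assert abs(val - kernel_b_longtime_limit(spec, 0, s)) < 1e-8

    def test_monotone_convergence_in_t(self):
        spec = KernelSpec("B", a=[1.0], tau=[1.0])
        s, tp = 2.0, 0.5
        limit = kernel_b_longtime_limit(spec, 0, s)
        vals = [kernel_value(spec, 0, t, tp, s) for t in np.linspace(3, 50, 30)]
        gaps = np.abs(np.array(vals) - limit)
        assert np.all(np.diff(gaps) <= 0)  # monotone approach to the floor
        assert gaps[-1] < 1e-8

    def test_wrong_family_rejected(self):
        with pytest.raises(ValueError):
            kernel_b_longtime_limit(KernelSpec("A", a=[1.0], tau=[1.0]), 0, 2.0)


class TestNormalization:
    """Both kernels must integrate to the amplitude a over [0, min(s,t)]."""

    @pytest.mark.parametrize("family", ["A", "B"])
    def test_quadrature_equals_amplitude(self, family):
        rng = np.random.default_rng(1)
        for _ in range(100):
            a = rng.uniform(0.1, 3.0)
            tau = rng.uniform(0.05, 5.0)
            t = rng.uniform(0.05, 8.0)
            s = rng.uniform(0.05, 8.0)
            spec = KernelSpec(family, a=[a], tau=[tau])
            m = min(s, t)
            val, _ = quad(lambda tp: kernel_value(spec, 0, t, tp, s),
                          0.0, m, limit=400)
            assert abs(val - a) < 1e-8

    @pytest.mark.parametrize("family", ["A", "B"])
    def test_constant_trajectory_is_exactly_standard_cox(self, family):
        # closed form: no quadrature error for z = const
        traj = Trajectory([0.0, 1.0, 4.0], [2.0, 2.0, 2.0])
        for t, s_eff, tau in [(0.5, 4.0, 1.0), (3.0, 4.0, 0.2), (9.0, 4.0, 2.5)]:
            spec = KernelSpec(family, a=[1.5], tau=[tau])
            val = weighted_covariate_integral(spec, traj, 0, t, s_eff)
            assert val == pytest.approx(3.0, abs=1e-12)


class TestClosedFormIntegral:
    @pytest.mark.parametrize("family", ["A", "B"])
    def test_matches_quadrature_oracle(self, family):
        rng = np.random.default_rng(2)
        for _ in range(100):
            traj = random_trajectory(rng)
            a = rng.uniform(0.2, 2.0)
            tau = rng.uniform(0.05, 3.0)
            t = rng.uniform(0.1, 8.0)
            s_eff = rng.uniform(0.05, 6.0)
            spec = KernelSpec(family, a=[a], tau=[tau])
            cf = weighted_covariate_integral(spec, traj, 0, t, s_eff)
            assert abs(cf - quadrature_integral(spec, traj, t, s_eff)) < 1e-8

    @pytest.mark.parametrize("family", ["A", "B"])
    def test_instantaneous_cox_limit_small_tau(self, family):
        """tau -> 0 concentrates the kernel at t: integral -> a * z(t-)."""
        traj = Trajectory([0.0, 1.0, 2.0, 3.0], [1.0, 3.0, -2.0, 5.0])
        spec = KernelSpec(family, a=[1.0], tau=[1e-6])
        val = weighted_covariate_integral(spec, traj, 0, t=2.0, s_eff=3.0)
        assert abs(val - 3.0) < 1e-4  # z just below t=2 is 3.0

    def test_family_a_time_invariant_beyond_s(self):
        spec = KernelSpec("A", a=[0.8], tau=[1.3])
        s = 2.0
        vals = {kernel_value(spec, 0, t, 0.7, s) for t in (2.5, 5.0, 50.0, 1e4)}
        assert len({round(v, 15) for v in vals}) == 1

    def test_small_conditioning_window_taylor_guard(self):
        # min(s,t)/tau below the guard: integral collapses to a * z(0)
        traj = Trajectory([0.0, 1.0], [4.0, 9.0])
        spec = KernelSpec("A", a=[0.5], tau=[1e9])
        val = weighted_covariate_integral(spec, traj, 0, t=1e-6, s_eff=1e-6)
        assert val == pytest.approx(2.0, rel=1e-10)

    def test_baseline_only_rules(self):
        traj = Trajectory([0.0], [3.0])
        const = KernelSpec("A", a=[0.5], tau=[2.0], baseline_only_rule=CONSTANT_ASSOC)
        decay = KernelSpec("A", a=[0.5], tau=[2.0], baseline_only_rule=DECAYING_ASSOC)
        t = 4.0
        assert weighted_covariate_integral(const, traj, 0, t, 0.0) == pytest.approx(1.5)
        assert weighted_covariate_integral(decay, traj, 0, t, 0.0) == pytest.approx(
            1.5 * math.exp(-t / 2.0)
        )


class TestLinearPredictor:
    def test_fixed_covariates_only(self):
        subj = make_subject("x", 5.0, 1, [0.0, 1.0], np.zeros((1, 2)), fixed=[2.0])
        spec = KernelSpec("B", a=[1.0], tau=[1.0])
        assert linear_predictor(spec, [0.5], subj, t=3.0, s_eff=1.0) == pytest.approx(1.0)

    def test_constant_covariate_normalization(self):
        subj = make_subject("x", 5.0, 1, [0.0, 2.0], np.ones((1, 2)))
        spec = KernelSpec("A", a=[0.7], tau=[1.0])
        assert linear_predictor(spec, [], subj, t=1.5, s_eff=2.0) == pytest.approx(0.7)

    def test_matches_sum_of_quadrature_oracles(self):
        rng = np.random.default_rng(3)
        times = np.concatenate([[0.0], np.sort(rng.uniform(0.2, 4.0, 3))])
        values = rng.normal(0.0, 1.0, (2, 4))
        subj = make_subject("x", 6.0, 1, times, values, fixed=[1.0, -2.0])
        spec = KernelSpec("B", a=[0.8, -0.4], tau=[1.3, 0.6])
        gamma = np.array([0.3, 0.1])
        t, s_eff = 4.0, 2.5
        expected = float(gamma @ subj.fixed)
        for mu in range(2):
            sub = KernelSpec("B", a=[spec.a[mu]], tau=[spec.tau[mu]])
            expected += quadrature_integral(sub, subj.trajectory(mu), t, s_eff)
        got = linear_predictor(spec, gamma, subj, t, s_eff)
        assert abs(got - expected) < 1e-8

    def test_dimension_mismatch_rejected(self):
        subj = make_subject("x", 5.0, 1, [0.0], np.zeros((1, 1)), fixed=[1.0])
        spec = KernelSpec("A", a=[1.0], tau=[1.0])
        with pytest.raises(ValueError, match="gamma"):
            linear_predictor(spec, [0.5, 0.2], subj, 1.0, 0.0)
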