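import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fillin import glm
from fillin.protocol import DesignSpec, Event, TrialSequence, main_experiment_sequence
from fillin.synth import SimParams, convolve_boxcar, hrf, simulate_bold


def toy_design(n=10, k=3, seed=0):
    rng = np.random.default_rng(seed)
    X = np.column_stack([rng.standard_normal((n, k - 1)), np.ones(n)])
    return glm.DesignMatrix(X=X, columns=[f"c{i}" for i in range(k - 1)] + ["intercept_run0"],
                           condition_columns=[f"c{i}" for i in range(k - 1)])


class TestBuildDesign:
    def test_no_trials_gives_intercept_only(self):
        seq = TrialSequence(runs=[DesignSpec(tr_s=2.0, n_trs=10, events=[])])
        X = glm.build_design(seq)
        assert X.columns == ["intercept_run0"]
        assert np.allclose(X.X, 1.0)

    def test_ten_second_trial_is_five_on_trs(self):
        run = DesignSpec(tr_s=2.0, n_trs=12, events=[Event(0.0, 10.0, "Center")])
        assert run.boxcar("Center").sum() == 5

    def test_convolved_regressor_lags_by_hrf_peak(self):
        reg = convolve_boxcar(np.array([0.0]), 0.5, 0.5, 80)
        t_grid = np.arange(0, 30, 0.01)
        hrf_peak = t_grid[np.argmax(hrf(t_grid))]
        assert 0.5 * np.argmax(reg) == pytest.approx(hrf_peak, abs=0.5)

    def test_unlabeled_scotoma_trial_rejected(self):
        run = DesignSpec(tr_s=2.0, n_trs=24, events=[Event(0.0, 10.0, "Scotoma")])
        with pytest.raises(ValueError, match="label"):
            glm.build_design(TrialSequence(runs=[run]))

    def test_one_intercept_per_run(self):
        seq = main_experiment_sequence(n_runs=3, seed=0)
        Y = simulate_bold(seq, SimParams(n_voxels=2), seed=1)
        X = glm.build_design(Y.sequence)
        assert sum(c.startswith("intercept") for c in X.columns) == 3


class TestFit:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        X = toy_design(n=20, k=3, seed=3)
        Y = rng.standard_normal((20, 5))
        fit = glm.fit(Y, X)
        oracle = np.linalg.inv(X.X.T @ X.X) @ X.X.T @ Y
        assert np.allclose(fit.beta, oracle, rtol=1e-10, atol=1e-12)
        resid = Y - X.X @ oracle
        assert np.allclose(fit.sigma2, (resid**2).sum(0) / (20 - 3), rtol=1e-10)
        assert fit.df == 17

    def test_design_column_as_data_recovers_unit_beta(self):
        X = toy_design(n=12, k=3, seed=4)
        fit = glm.fit(X.X[:, [0]], X)
        assert fit.beta[0, 0] == pytest.approx(1.0, abs=1e-10)
        assert abs(fit.beta[1, 0]) < 1e-10
        assert fit.sigma2[0] == pytest.approx(0.0, abs=1e-16)

    def test_noiseless_simulation_recovers_injected_amplitudes(self):
        seq = main_experiment_sequence(n_runs=2, seed=5)
        params = SimParams(n_voxels=3, noise_sd=0.0, pattern_strength=0.0,
                           amp_jitter_sd=0.0)
        Y = simulate_bold(seq, params, seed=6)
        X = glm.build_design(Y.sequence)
        fit = glm.fit(Y, X)
        assert np.allclose(fit.condition_beta("Center"), params.amplitude("Center"),
                           atol=1e-8)
        assert np.allclose(fit.condition_beta("FullField"),
                           params.amplitude("FullField"), atol=1e-8)
        assert np.allclose(fit.baseline_beta(), params.baseline, atol=1e-8)

    def test_rank_deficiency_reported_with_columns(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(ValueError, match="intercept_run0"):
            glm.DesignMatrix(X=X, columns=["a", "intercept_run0"],
                             condition_columns=["a"])


class TestContrastT:
    def test_zero_contrast_gives_zero_t(self):
        X = toy_design()
        fit = glm.fit(np.random.default_rng(0).standard_normal((10, 4)), X)
        assert np.all(glm.contrast_t(fit, np.zeros(3)) == 0)

    def test_positive_scaling_invariance(self):
        X = toy_design()
        fit = glm.fit(np.random.default_rng(1).standard_normal((10, 4)), X)
        c = np.array([1.0, -1.0, 0.0])
        assert np.allclose(glm.contrast_t(fit, c), glm.contrast_t(fit, 7.5 * c))

    def test_hand_computed_six_point_regression(self):
        # y on x with intercept: beta, t for slope computed longhand
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.1, 3.9, 6.2, 7.8, 10.1, 11.9])[:, None]
        X = glm.DesignMatrix(X=np.column_stack([x, np.ones(6)]),
                             columns=["slope", "intercept_run0"],
                             condition_columns=["slope"])
        fit = glm.fit(y, X)
        sxx = ((x - x.mean())**2).sum()
        slope = ((x - x.mean()) * (y[:, 0] - y.mean())).sum() / sxx
        resid = y[:, 0] - (slope * x + (y.mean() - slope * x.mean()))
        s2 = (resid**2).sum() / 4
        t_oracle = slope / np.sqrt(s2 / sxx)
        t = glm.contrast_t(fit, np.array([1.0, 0.0]))[0]
        assert t == pytest.approx(t_oracle, rel=1e-10)

    def test_zero_variance_flagged_infinite(self):
        X = toy_design()
        fit = glm.GlmFit(beta=np.array([[1.0], [0.0], [0.0]]),
                         sigma2=np.array([0.0]), df=7, design=X)
        with pytest.warns(UserWarning, match="infinite"):
            t = glm.contrast_t(fit, np.array([1.0, 0.0, 0.0]))
        assert np.isinf(t[0])


class TestNormalizeBeta:
    def test_baseline_division(self):
        seq = main_experiment_sequence(n_runs=2, seed=8)
        Y = simulate_bold(seq, SimParams(n_voxels=2, noise_sd=0.0,
                                         pattern_strength=0.0, amp_jitter_sd=0.0),
                          seed=9)
        fit = glm.fit(Y, glm.build_design(Y.sequence))
        nb = glm.normalize_beta(fit)
        assert nb["Center"] == pytest.approx(1.5 / 100.0, rel=1e-6)

    def test_scale_invariance(self):
        seq = main_experiment_sequence(n_runs=2, seed=10)
        Y = simulate_bold(seq, SimParams(n_voxels=3), seed=11)
        X = glm.build_design(Y.sequence)
        f1 = glm.fit(Y, X)
        f2 = glm.fit(Y.data.reshape(-1, 3) * 3.7, X)
        n1, n2 = glm.normalize_beta(f1), glm.normalize_beta(f2)
        for cond in n1:
            assert np.allclose(n1[cond], n2[cond], rtol=1e-10)


class TestGroupTest:
    def test_paper_scale_effect_size(self):
        # t = -6.13 with n = 12 implies |d| = 6.13/sqrt(12) = 1.77
        assert abs(-6.13 / np.sqrt(12)) == pytest.approx(1.77, abs=0.005)

    def test_d_equals_t_over_sqrt_n(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            v = rng.standard_normal(12) - 0.5
            g = glm.group_test(v, tail="less")
            assert g.d == pytest.approx(g.t / np.sqrt(12), rel=1e-12)
            assert g.df == 11

    def test_all_zero_values(self):
        g = glm.group_test(np.zeros(8), tail="less")
        assert g.t == 0.0 and g.p == 0.5 and g.degenerate

    def test_bonferroni_alpha_for_12_tests(self):
        assert glm.bonferroni_alpha(0.05, 12) == pytest.approx(0.0042, abs=0.0001)

    def test_one_tail_matches_scipy_halving(self):
        from scipy import stats
        rng = np.random.default_rng(13)
        v = rng.standard_normal(10) - 1.0
        g = glm.group_test(v, tail="less")
        t, p2 = stats.ttest_1samp(v, 0.0)
        assert g.p == pytest.approx(p2 / 2 if t < 0 else 1 - p2 / 2, rel=1e-9)

    def test_type_one_error_calibrated(self):
        # one-tail test at alpha = 0.05 on pure-null cohorts
        rng = np.random.default_rng(14)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            v = rng.standard_normal(12)
            if glm.group_test(v, tail="less").p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_property_ols_equals_pinv_oracle(seed):
    rng = np.random.default_rng(seed)
    n, k = rng.integers(5, 20), rng.integers(1, 4)
    X = np.column_stack([rng.standard_normal((n, k)), np.ones(n)])
    dm = glm.DesignMatrix(X=X, columns=[f"c{i}" for i in range(k)] + ["intercept_run0"],
                          condition_columns=[f"c{i}" for i in range(k)])
    Y = rng.standard_normal((n, 2))
    fit = glm.fit(Y, dm)
    assert np.allclose(fit.beta, np.linalg.pinv(X) @ Y, rtol=1e-9, atol=1e-9)
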