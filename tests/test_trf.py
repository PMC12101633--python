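"""Unit and property tests for the core TRF estimation machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from trfseg import (
    DEFAULT_LAMBDA_GRID,
    CovarianceAccumulator,
    InvalidInputError,
    LagWindow,
    SegmentPair,
    TRFModel,
    TRFRidge,
    TRFRidgeCV,
    UndefinedCorrelationError,
    accumulate_covariances,
    build_lag_matrix,
    cross_validate,
    fit_trf,
    pearson_r,
    predict,
    solve_ridge,
)


def brute_force_lagged_sum(stimulus, weights, lags):
    """Explicit triple-loop evaluation of sum_n sum_tau w(tau,n) s(t-tau,n)."""
    n, nb = stimulus.shape
    out = np.zeros(n)
    for t in range(n):
        for li, lag in enumerate(lags):
            for b in range(nb):
                if 0 <= t - lag < n:
                    out[t] += weights[li, b] * stimulus[t - lag, b]
    return out


class TestBuildLagMatrix:
    def test_impulse_produces_shifted_columns(self):
        stim = np.zeros(6)
        stim[0] = 1.0
        x = build_lag_matrix(stim, LagWindow(0.0, 2.0, 1.0))
        assert x.shape == (6, 4)
        for lag in range(3):
            expected = np.zeros(6)
            expected[lag] = 1.0
            np.testing.assert_array_equal(x[:, lag], expected)
        np.testing.assert_array_equal(x[:, -1], np.ones(6))

    def test_zero_lag_window_is_identity(self, rng):
        stim = rng.standard_normal((20, 3))
        x = build_lag_matrix(stim, LagWindow(0.0, 0.0, 64.0))
        np.testing.assert_array_equal(x[:, :3], stim)
        np.testing.assert_array_equal(x[:, 3], np.ones(20))

    def test_rows_match_explicit_lagged_sum(self, rng):
        stim = rng.standard_normal((20, 2))
        lw = LagWindow(-1.0, 2.0, 1.0)
        w = rng.standard_normal((lw.n_lags, 2))
        x = build_lag_matrix(stim, lw)
        got = x[:, :-1] @ w.reshape(-1)
        expected = brute_force_lagged_sum(stim, w, lw.lags)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_empty_stimulus_rejected(self):
        with pytest.raises(InvalidInputError):
            build_lag_matrix(np.empty((0, 1)), LagWindow(0, 0.1, 64.0))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        n=st.integers(3, 30),
        nb=st.integers(1, 3),
        lo=st.integers(-3, 0),
        hi=st.integers(0, 3),
        seed=st.integers(0, 1000),
    )
    def test_reconstruction_property(self, n, nb, lo, hi, seed):
        """Any row of the lagged design reconstructs the convolution sum."""
        r = np.random.default_rng(seed)
        stim = r.standard_normal((n, nb))
        lw = LagWindow(float(lo), float(hi), 1.0)
        w = r.standard_normal((lw.n_lags, nb))
        x = build_lag_matrix(stim, lw)
        np.testing.assert_allclose(
            x[:, :-1] @ w.reshape(-1), brute_force_lagged_sum(stim, w, lw.lags), atol=1e-10
        )


class TestCovarianceAccumulation:
    def test_single_segment_is_normalized_gram(self, small_segments, lag_window):
        seg = small_segments[0]
        lw = LagWindow(0.0, 0.05, seg.fs)
        acc = accumulate_covariances([seg], lw)
        x = build_lag_matrix(seg.stimulus, lw)
        np.testing.assert_allclose(acc.sts, x.T @ x / seg.n_samples, rtol=1e-10)
        np.testing.assert_allclose(acc.str_, x.T @ seg.response / seg.n_samples, rtol=1e-10)

    def test_duplicate_segments_leave_average_unchanged(self, small_segments):
        lw = LagWindow(0.0, 0.05, small_segments[0].fs)
        one = accumulate_covariances(small_segments, lw)
        two = accumulate_covariances(small_segments * 2, lw)
        np.testing.assert_allclose(one.sts, two.sts, rtol=1e-12)
        np.testing.assert_allclose(one.str_, two.str_, rtol=1e-12)

    def test_split_differs_from_full_only_at_boundaries(self, rng):
        """Averaged split covariance deviates only by cross-boundary lag terms."""
        fs, n_splits = 1.0, 4
        stim = rng.standard_normal(200)
        resp = rng.standard_normal(200)
        lw = LagWindow(0.0, 2.0, fs)  # 3 lags
        full = accumulate_covariances([SegmentPair(stim, resp, fs)], lw)
        parts = [
            SegmentPair(stim[i * 50 : (i + 1) * 50], resp[i * 50 : (i + 1) * 50], fs)
            for i in range(n_splits)
        ]
        split = accumulate_covariances(parts, lw)
        diff = np.max(np.abs(full.sts - split.sts))
        assert diff > 0  # boundary terms exist
        smax2 = np.max(np.abs(stim)) ** 2
        bound = n_splits * lw.n_lags * smax2 / 50
        assert diff <= bound

    def test_empty_and_inconsistent_inputs_rejected(self, small_segments):
        lw = LagWindow(0.0, 0.05, 64.0)
        with pytest.raises(InvalidInputError):
            accumulate_covariances([], lw)
        odd = SegmentPair(np.ones((10, 1)), np.ones((10, 3)), 64.0)
        with pytest.raises(InvalidInputError):
            accumulate_covariances([small_segments[0], odd], lw)


class TestSolveRidge:
    def test_identity_covariance_halves_weights(self):
        lw = LagWindow(0.0, 2.0, 1.0)  # 3 lags, 1 band -> p=4
        rng = np.random.default_rng(0)
        str_ = rng.standard_normal((4, 2))
        acc = CovarianceAccumulator(np.eye(4), str_, 1, lw, 1)
        model = solve_ridge(acc, 1.0)
        np.testing.assert_allclose(model.weights.reshape(3, 2), str_[:3] / 2, rtol=1e-12)
        # intercept row is unpenalized: bias = str_ on the last row
        np.testing.assert_allclose(model.bias, str_[3], rtol=1e-12)

    def test_lambda_zero_matches_least_squares_oracle(self, rng):
        """Covariance-path ridge at lambda=0 equals lstsq on the explicit design."""
        stim = rng.standard_normal((30, 2))
        lw = LagWindow(0.0, 2.0, 1.0)  # 3 lags
        x = build_lag_matrix(stim, lw)
        w_true = rng.standard_normal(x.shape[1])
        resp = x @ w_true + 0.01 * rng.standard_normal(30)
        model = solve_ridge(
            accumulate_covariances([SegmentPair(stim, resp, 1.0)], lw), 0.0
        )
        w_ols, *_ = np.linalg.lstsq(x, resp, rcond=None)
        got = np.concatenate([model.weights.reshape(-1), model.bias])
        assert np.max(np.abs(got - w_ols)) < 1e-8

    def test_weight_norm_non_increasing_in_lambda(self, small_segments):
        lw = LagWindow(0.0, 0.05, small_segments[0].fs)
        acc = accumulate_covariances(small_segments, lw)
        norms = [
            np.linalg.norm(solve_ridge(acc, lam).weights)
            for lam in np.logspace(0, 6, 7)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_singular_system_falls_back_with_warning(self):
        seg = SegmentPair(np.ones((3, 2)), np.ones((3, 1)), 64.0)
        acc = accumulate_covariances([seg], LagWindow(0.0, 0.1, 64.0))
        with pytest.warns(RuntimeWarning, match="pseudo-inverse"):
            model = solve_ridge(acc, 0.0)
        assert np.all(np.isfinite(model.weights))

    def test_negative_lambda_rejected(self, small_segments):
        lw = LagWindow(0.0, 0.05, 64.0)
        acc = accumulate_covariances(small_segments, lw)
        with pytest.raises(InvalidInputError):
            solve_ridge(acc, -1.0)


class TestPredict:
    def test_delta_kernel_is_identity(self):
        lw = LagWindow(0.0, 0.0, 64.0)
        model = TRFModel(np.ones((1, 1, 1)), np.zeros(1), lw, 0.0)
        stim = np.arange(10.0)
        np.testing.assert_allclose(predict(model, stim)[:, 0], stim)

    def test_linearity(self, rng):
        lw = LagWindow(0.0, 2.0, 1.0)
        model = TRFModel(rng.standard_normal((3, 2, 2)), np.zeros(2), lw, 0.0)
        stim = rng.standard_normal((40, 2))
        np.testing.assert_allclose(
            predict(model, 3.5 * stim), 3.5 * predict(model, stim), rtol=1e-12
        )

    def test_matches_triple_loop_convolution(self, rng):
        lw = LagWindow(0.0, 2.0, 1.0)
        w = rng.standard_normal((3, 2))
        model = TRFModel(w[:, :, None], np.zeros(1), lw, 0.0)
        stim = rng.standard_normal((50, 2))
        got = predict(model, stim)[:, 0]
        np.testing.assert_allclose(got, brute_force_lagged_sum(stim, w, lw.lags), atol=1e-12)

    def test_shift_equivariance_away_from_edges(self, rng):
        lw = LagWindow(0.0, 2.0, 1.0)
        model = TRFModel(rng.standard_normal((3, 1, 1)), np.zeros(1), lw, 0.0)
        stim = np.zeros(60)
        stim[10:20] = rng.standard_normal(10)
        d = 7
        shifted = np.roll(stim, d)
        p0 = predict(model, stim)[:, 0]
        p1 = predict(model, shifted)[:, 0]
        np.testing.assert_allclose(p1[15 + d : 40], p0[15:40 - d], atol=1e-12)

    def test_band_mismatch_rejected(self, rng):
        lw = LagWindow(0.0, 2.0, 1.0)
        model = TRFModel(rng.standard_normal((3, 2, 1)), np.zeros(1), lw, 0.0)
        with pytest.raises(InvalidInputError):
            predict(model, rng.standard_normal((10, 3)))


class TestPearson:
    def test_reference_values(self):
        x = np.arange(10.0)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)
        # hand-computed: cov/sd/sd for x=(1,2,3,4), y=(2,4,5,9)
        assert pearson_r([1, 2, 3, 4], [2, 4, 5, 9]) == pytest.approx(11 / np.sqrt(5 * 26))

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            pearson_r([1.0, 2.0], [1.0, 2.0, 3.0])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 50))
    def test_bounded_and_symmetric(self, seed, n):
        r = np.random.default_rng(seed)
        x, y = r.standard_normal(n), r.standard_normal(n)
        val = pearson_r(x, y)
        assert -1.0 <= val <= 1.0
        assert val == pytest.approx(pearson_r(y, x))


class TestCrossValidate:
    def test_default_grid_spans_paper_range(self, small_segments):
        cv = cross_validate(small_segments, LagWindow(0.0, 0.05, 64.0), k=5, seed=0)
        np.testing.assert_allclose(cv.lambdas, np.logspace(-5, 3, 9))
        assert cv.best_lambda in cv.lambdas
        assert cv.best_accuracy == pytest.approx(np.max(cv.accuracy_per_lambda))

    def test_deterministic_under_seed(self, small_segments):
        lw = LagWindow(0.0, 0.05, 64.0)
        a = cross_validate(small_segments, lw, k=5, seed=42)
        b = cross_validate(small_segments, lw, k=5, seed=42)
        np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)
        np.testing.assert_array_equal(a.accuracy_per_lambda, b.accuracy_per_lambda)
        assert a.best_lambda == b.best_lambda

    def test_noiseless_data_recovered_nearly_perfectly(self, rng):
        fs = 64.0
        lw = LagWindow(0.0, 0.1, fs)
        w = rng.standard_normal((lw.n_lags, 1, 2))
        model = TRFModel(w, np.zeros(2), lw, 0.0)
        segs = []
        for _ in range(10):
            stim = rng.standard_normal((256, 1))
            segs.append(SegmentPair(stim, predict(model, stim), fs))
        cv = cross_validate(segs, lw, k=5, seed=0)
        assert cv.best_accuracy >= 0.99
        assert cv.best_lambda <= 0.1  # small end of the grid

    def test_shuffled_responses_score_near_zero(self, rng):
        fs = 64.0
        lw = LagWindow(0.0, 0.1, fs)
        w = rng.standard_normal((lw.n_lags, 1, 1))
        model = TRFModel(w, np.zeros(1), lw, 0.0)
        stims = [rng.standard_normal((256, 1)) for _ in range(12)]
        resps = [predict(model, s) for s in stims]
        shuffled = [resps[(i + 5) % 12] for i in range(12)]
        segs = [SegmentPair(s, r, fs) for s, r in zip(stims, shuffled)]
        cv = cross_validate(segs, lw, k=4, seed=1)
        n_test = 256
        assert abs(cv.best_accuracy) < 3 / np.sqrt(n_test)

    def test_too_few_segments_rejected(self, small_segments):
        with pytest.raises(InvalidInputError):
            cross_validate(small_segments[:3], LagWindow(0.0, 0.05, 64.0), k=5)


class TestEstimators:
    def test_ridge_estimator_matches_functional_path(self, small_segments):
        est = TRFRidge(tmin=0.0, tmax=0.05, fs=64.0, lam=1.0).fit(small_segments)
        ref = fit_trf(small_segments, LagWindow(0.0, 0.05, 64.0), 1.0)
        np.testing.assert_allclose(est.weights_, ref.weights, rtol=1e-12)
        np.testing.assert_allclose(est.bias_, ref.bias, rtol=1e-12)
        pred = est.predict(small_segments[0].stimulus)
        np.testing.assert_allclose(pred, predict(ref, small_segments[0].stimulus))
        assert -1.0 <= est.score(small_segments) <= 1.0

    def test_fit_accepts_arrays_and_lists(self, rng):
        stim = rng.standard_normal((100, 2))
        resp = rng.standard_normal((100, 3))
        est = TRFRidge(tmax=0.05, fs=64.0, lam=0.1).fit(stim, resp)
        assert est.weights_.shape == (LagWindow(0, 0.05, 64.0).n_lags, 2, 3)
        est2 = TRFRidge(tmax=0.05, fs=64.0, lam=0.1).fit([stim, stim], [resp, resp])
        np.testing.assert_allclose(est.weights_, est2.weights_, rtol=1e-10)

    def test_cv_estimator_exposes_selection(self, small_segments):
        est = TRFRidgeCV(tmax=0.05, fs=64.0, cv=5, random_state=0).fit(small_segments)
        assert est.lam_ in est.cv_result_.lambdas
        assert hasattr(est, "weights_")

    def test_sklearn_protocol(self):
        est = TRFRidgeCV(tmax=0.2, fs=64.0, cv=3, random_state=7)
        params = est.get_params()
        assert params["cv"] == 3 and params["random_state"] == 7
        cloned = clone(est)
        assert cloned.get_params() == params
        est.set_params(cv=4)
        assert est.get_params()["cv"] == 4
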