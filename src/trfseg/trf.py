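"""Ridge-regularized temporal response function (TRF) estimation.

A TRF is the kernel of a linear time-invariant mapping from stimulus
features to a multichannel neural response,

    r(t) = sum_n sum_tau w(tau, n) * s(t - tau, n) + eps(t),

estimated over a window of time lags tau by ridge (Tikhonov) regression on a
lagged design matrix.  Continuous recordings are handled as collections of
segments: each segment contributes per-sample-normalized covariance matrices
(S^T S and S^T r) which are averaged across segments before the ridge solve,
so that a recording split into many short pieces and the same recording kept
whole pose (up to segment-boundary effects) the same regression problem.

The public modeling surface is scikit-learn shaped (:class:`TRFRidge`,
:class:`TRFRidgeCV`); the module-level functions expose the individual steps
(lagged design, covariance accumulation, ridge solve, prediction, scoring,
cross-validated lambda selection) for direct use.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import InvalidInputError, UndefinedCorrelationError

__all__ = [
    "DEFAULT_LAMBDA_GRID",
    "LagWindow",
    "SegmentPair",
    "TRFModel",
    "CovarianceAccumulator",
    "CVResult",
    "build_lag_matrix",
    "accumulate_covariances",
    "solve_ridge",
    "predict",
    "pearson_r",
    "cross_validate",
    "fit_trf",
    "score_segments",
    "TRFRidge",
    "TRFRidgeCV",
]

#: Nine log-spaced regularization candidates spanning 1e-5 ... 1e3.
DEFAULT_LAMBDA_GRID = np.logspace(-5.0, 3.0, 9)


def _as_2d(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2:
        raise InvalidInputError(f"{name} must be 1- or 2-dimensional, got ndim={a.ndim}")
    return a


@dataclasses.dataclass(frozen=True)
class LagWindow:
    """Time-lag window of a TRF, in seconds, on a sampling grid.

    Lags run from ``round(tmin * fs)`` to ``round(tmax * fs)`` samples,
    inclusive; negative ``tmin`` admits acausal lags.
    """

    tmin: float = 0.0
    tmax: float = 0.4
    fs: float = 128.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise InvalidInputError(f"sampling rate must be positive, got {self.fs}")
        if self.tmin > self.tmax:
            raise InvalidInputError(f"tmin ({self.tmin}) exceeds tmax ({self.tmax})")

    @property
    def lags(self) -> np.ndarray:
        """Integer sample lags, ascending."""
        lo = int(round(self.tmin * self.fs))
        hi = int(round(self.tmax * self.fs))
        return np.arange(lo, hi + 1)

    @property
    def n_lags(self) -> int:
        return len(self.lags)

    @property
    def times(self) -> np.ndarray:
        """Lag times in seconds."""
        return self.lags / self.fs


@dataclasses.dataclass
class SegmentPair:
    """One stimulus-feature matrix aligned with one response matrix.

    ``stimulus`` is (n_samples, n_bands), ``response`` (n_samples, n_channels);
    1-D inputs are promoted to single columns.  Both share the sampling rate
    ``fs`` and must have identical length.
    """

    stimulus: np.ndarray
    response: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.stimulus = _as_2d(self.stimulus, "stimulus")
        self.response = _as_2d(self.response, "response")
        if self.fs <= 0:
            raise InvalidInputError(f"sampling rate must be positive, got {self.fs}")
        if self.stimulus.shape[0] != self.response.shape[0]:
            raise InvalidInputError(
                "stimulus and response lengths differ: "
                f"{self.stimulus.shape[0]} vs {self.response.shape[0]}"
            )
        if self.stimulus.shape[0] < 1:
            raise InvalidInputError("segment must contain at least one sample")

    @property
    def n_samples(self) -> int:
        return self.stimulus.shape[0]

    @property
    def n_bands(self) -> int:
        return self.stimulus.shape[1]

    @property
    def n_channels(self) -> int:
        return self.response.shape[1]


@dataclasses.dataclass
class TRFModel:
    """A fitted TRF: weights over (lag, band, channel) plus per-channel bias."""

    weights: np.ndarray  # (n_lags, n_bands, n_channels)
    bias: np.ndarray  # (n_channels,)
    lag_window: LagWindow
    lam: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.bias = np.atleast_1d(np.asarray(self.bias, dtype=float))
        if self.weights.ndim != 3:
            raise InvalidInputError("weights must have shape (n_lags, n_bands, n_channels)")
        if self.weights.shape[0] != self.lag_window.n_lags:
            raise InvalidInputError(
                f"weights have {self.weights.shape[0]} lags but the lag window "
                f"defines {self.lag_window.n_lags}"
            )
        if not np.all(np.isfinite(self.weights)):
            raise InvalidInputError("weights must be finite")

    @property
    def fs(self) -> float:
        return self.lag_window.fs

    @property
    def n_bands(self) -> int:
        return self.weights.shape[1]

    @property
    def n_channels(self) -> int:
        return self.weights.shape[2]

    def mean_abs_weight(self) -> float:
        """Mean absolute stimulus-lag weight (bias excluded)."""
        return float(np.mean(np.abs(self.weights)))


@dataclasses.dataclass
class CovarianceAccumulator:
    """Segment-averaged design covariances S^T S and S^T r.

    Each segment's matrices are divided by its own sample count before
    averaging, so lambda keeps a consistent meaning across segment durations.
    """

    sts: np.ndarray  # (L*n_bands + 1, L*n_bands + 1)
    str_: np.ndarray  # (L*n_bands + 1, n_channels)
    n_segments: int
    lag_window: LagWindow
    n_bands: int


@dataclasses.dataclass
class CVResult:
    """Outcome of k-fold cross-validated lambda selection."""

    lambdas: np.ndarray
    accuracy_per_lambda: np.ndarray
    best_lambda: float
    best_accuracy: float
    fold_assignment: np.ndarray  # fold index of each segment


def build_lag_matrix(stimulus: np.ndarray, lag_window: LagWindow) -> np.ndarray:
    """Expand a stimulus into the lagged (time-shifted) design matrix.

    Returns an (n_samples, n_lags * n_bands + 1) matrix whose block for lag
    tau holds the stimulus delayed by tau samples (zero-padded where the shift
    leaves the segment) and whose final column is the constant intercept.
    Column order is lag-major: lags ascend, bands cycle fastest.
    """
    stimulus = _as_2d(stimulus, "stimulus")
    n, nb = stimulus.shape
    if n < 1:
        raise InvalidInputError("stimulus must contain at least one sample")
    lags = lag_window.lags
    out = np.zeros((n, len(lags) * nb + 1))
    for i, lag in enumerate(lags):
        block = out[:, i * nb : (i + 1) * nb]
        if lag >= 0:
            if lag < n:
                block[lag:] = stimulus[: n - lag]
        else:
            if -lag < n:
                block[: n + lag] = stimulus[-lag:]
    out[:, -1] = 1.0
    return out


def _gram(x: np.ndarray) -> np.ndarray:
    """x.T @ x exploiting symmetry via BLAS syrk."""
    try:
        c = linalg.blas.dsyrk(1.0, np.asfortranarray(x), trans=1, lower=0)
        return c + np.triu(c, 1).T
    except Exception:  # pragma: no cover - BLAS always present in practice
        return x.T @ x


def _check_consistent(segments: Sequence[SegmentPair]) -> None:
    if len(segments) == 0:
        raise InvalidInputError("segment list is empty")
    first = segments[0]
    for s in segments[1:]:
        if (s.fs, s.n_bands, s.n_channels) != (first.fs, first.n_bands, first.n_channels):
            raise InvalidInputError(
                "segments disagree in sampling rate, band count or channel count"
            )


def accumulate_covariances(
    segments: Sequence[SegmentPair], lag_window: LagWindow
) -> CovarianceAccumulator:
    """Average per-sample-normalized covariances S^T S and S^T r over segments."""
    _check_consistent(segments)
    nb = segments[0].n_bands
    p = lag_window.n_lags * nb + 1
    sts = np.zeros((p, p))
    str_ = np.zeros((p, segments[0].n_channels))
    for seg in segments:
        x = build_lag_matrix(seg.stimulus, lag_window)
        sts += _gram(x) / seg.n_samples
        str_ += x.T @ seg.response / seg.n_samples
    k = len(segments)
    return CovarianceAccumulator(sts / k, str_ / k, k, lag_window, nb)


def _penalty(p: int) -> np.ndarray:
    """Identity over stimulus-lag rows, zero on the intercept row."""
    m = np.eye(p)
    m[-1, -1] = 0.0
    return m


def _ridge_weights(sts: np.ndarray, str_: np.ndarray, lam: float) -> np.ndarray:
    a = sts + lam * _penalty(sts.shape[0])
    try:
        if lam == 0.0 and np.linalg.cond(a) > 1e12:
            raise np.linalg.LinAlgError("near-singular system")
        w = linalg.solve(a, str_, assume_a="sym")
        if not np.all(np.isfinite(w)):
            raise np.linalg.LinAlgError("non-finite solution")
    except (np.linalg.LinAlgError, linalg.LinAlgError):
        warnings.warn(
            "singular covariance system (lambda=%g); falling back to pseudo-inverse" % lam,
            RuntimeWarning,
            stacklevel=3,
        )
        w = np.linalg.pinv(a) @ str_
    return w


def solve_ridge(acc: CovarianceAccumulator, lam: float) -> TRFModel:
    """Solve (S^T S + lambda M) w = S^T r for the TRF weights.

    The penalty M is the identity over stimulus-lag rows with a zero on the
    intercept row, so mean offsets are absorbed without shrinkage.  Singular
    systems (possible at lambda=0 on short segments) fall back to the
    pseudo-inverse with a warning.
    """
    if lam < 0:
        raise InvalidInputError(f"lambda must be non-negative, got {lam}")
    w = _ridge_weights(acc.sts, acc.str_, lam)
    L, nb = acc.lag_window.n_lags, acc.n_bands
    return TRFModel(
        weights=w[:-1].reshape(L, nb, -1),
        bias=w[-1],
        lag_window=acc.lag_window,
        lam=float(lam),
    )


def predict(model: TRFModel, stimulus: np.ndarray) -> np.ndarray:
    """Predict the multichannel response to ``stimulus`` (zero-padded edges)."""
    stimulus = _as_2d(stimulus, "stimulus")
    if stimulus.shape[1] != model.n_bands:
        raise InvalidInputError(
            f"stimulus has {stimulus.shape[1]} bands but the model expects {model.n_bands}"
        )
    x = build_lag_matrix(stimulus, model.lag_window)
    w_flat = model.weights.reshape(-1, model.n_channels)
    return x[:, :-1] @ w_flat + model.bias


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape or len(x) < 2:
        raise InvalidInputError("inputs must be equal-length vectors of length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        raise UndefinedCorrelationError("correlation undefined for zero-variance input")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _pearson_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Pearson r; degenerate (zero-variance) columns score 0."""
    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    denom = np.sqrt(np.sum(ac**2, axis=0) * np.sum(bc**2, axis=0))
    num = np.sum(ac * bc, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / np.maximum(denom, 1e-300), 0.0)
    return np.clip(r, -1.0, 1.0)


def cross_validate(
    segments: Sequence[SegmentPair],
    lag_window: LagWindow,
    lambdas: np.ndarray | Sequence[float] = DEFAULT_LAMBDA_GRID,
    k: int = 5,
    seed: int = 0,
) -> CVResult:
    """Select lambda by k-fold cross-validation over data segments.

    Segments are randomly partitioned once into ``k`` folds (the same folds
    are reused for every lambda).  For each lambda and fold the TRF is fitted
    on the k-1 training folds via covariance averaging, the held-out segments
    are predicted, and accuracy is the Pearson r averaged over channels and
    test segments; ``accuracy_per_lambda`` averages over folds.  Ties in the
    maximum break toward the smaller lambda.
    """
    _check_consistent(segments)
    n_seg = len(segments)
    if not 2 <= k <= n_seg:
        raise InvalidInputError(f"need at least k={k} segments for {k}-fold CV, got {n_seg}")
    lambdas = np.sort(np.asarray(lambdas, dtype=float))
    if np.any(lambdas < 0):
        raise InvalidInputError("lambda candidates must be non-negative")

    rng = np.random.default_rng(seed)
    fold_of = np.empty(n_seg, dtype=int)
    fold_of[rng.permutation(n_seg)] = np.arange(n_seg) % k

    nb = segments[0].n_bands
    p = lag_window.n_lags * nb + 1
    # Running per-fold covariance sums keep memory at O(k * p^2) regardless of
    # how many (possibly thousands of) short segments there are.
    sts_fold = np.zeros((k, p, p))
    str_fold = np.zeros((k, p, segments[0].n_channels))
    for i, seg in enumerate(segments):
        x = build_lag_matrix(seg.stimulus, lag_window)
        f = fold_of[i]
        sts_fold[f] += _gram(x) / seg.n_samples
        str_fold[f] += x.T @ seg.response / seg.n_samples
    sts_tot = sts_fold.sum(axis=0)
    str_tot = str_fold.sum(axis=0)
    counts = np.bincount(fold_of, minlength=k)

    scores = np.zeros((len(lambdas), k))
    for f in range(k):
        n_train = n_seg - counts[f]
        sts_train = (sts_tot - sts_fold[f]) / n_train
        str_train = (str_tot - str_fold[f]) / n_train
        w_per_lam = [_ridge_weights(sts_train, str_train, lam) for lam in lambdas]
        seg_scores = np.zeros((len(lambdas), int(counts[f])))
        for j, i in enumerate(np.flatnonzero(fold_of == f)):
            seg = segments[i]
            x = build_lag_matrix(seg.stimulus, lag_window)
            for li, w in enumerate(w_per_lam):
                pred = x @ w
                seg_scores[li, j] = _pearson_columns(pred, seg.response).mean()
        scores[:, f] = seg_scores.mean(axis=1)

    acc = scores.mean(axis=1)
    best = int(np.argmax(acc))  # first maximum = smallest lambda on ties
    return CVResult(
        lambdas=lambdas,
        accuracy_per_lambda=acc,
        best_lambda=float(lambdas[best]),
        best_accuracy=float(acc[best]),
        fold_assignment=fold_of,
    )


def fit_trf(
    segments: Sequence[SegmentPair], lag_window: LagWindow, lam: float
) -> TRFModel:
    """Fit a TRF on all segments at a fixed lambda (accumulate + solve)."""
    return solve_ridge(accumulate_covariances(segments, lag_window), lam)


def score_segments(model: TRFModel, segments: Sequence[SegmentPair]) -> float:
    """Prediction accuracy of a fitted TRF on held-out segments.

    For each segment the response is predicted from its stimulus and the
    Pearson r is averaged across channels; the returned accuracy is the mean
    over segments.  Degenerate (zero-variance) channels within a segment
    score 0.
    """
    _check_consistent(segments)
    return float(
        np.mean(
            [_pearson_columns(predict(model, s.stimulus), s.response).mean() for s in segments]
        )
    )


def _to_segments(X, y, fs: float) -> list[SegmentPair]:
    if isinstance(X, SegmentPair):
        return [X]
    if len(X) > 0 and isinstance(X[0], SegmentPair):
        return list(X)
    if y is None:
        raise InvalidInputError("y (responses) is required when X holds stimulus arrays")
    if isinstance(X, np.ndarray) and X.ndim <= 2:
        return [SegmentPair(X, np.asarray(y), fs)]
    return [SegmentPair(s, r, fs) for s, r in zip(X, y, strict=True)]


class TRFRidge(RegressorMixin, BaseEstimator):
    """Ridge-regularized temporal response function estimator.

    Parameters
    ----------
    tmin, tmax : float
        Lag window in seconds (``tmin`` may be negative for acausal lags).
    fs : float
        Sampling rate of stimulus and response, in Hz.
    lam : float
        Ridge regularization strength applied to stimulus-lag weights
        (the intercept is unpenalized).

    ``fit(X, y)`` accepts a single (n_samples, n_bands) stimulus with an
    (n_samples, n_channels) response, lists of such per-segment arrays, or a
    list of :class:`SegmentPair` as ``X`` (``y=None``).
    """

    def __init__(self, tmin: float = 0.0, tmax: float = 0.4, fs: float = 128.0,
                 lam: float = 0.0):
        self.tmin = tmin
        self.tmax = tmax
        self.fs = fs
        self.lam = lam

    def _lag_window(self) -> LagWindow:
        return LagWindow(self.tmin, self.tmax, self.fs)

    def fit(self, X, y=None):
        segments = _to_segments(X, y, self.fs)
        self.model_ = fit_trf(segments, self._lag_window(), self.lam)
        self.weights_ = self.model_.weights
        self.bias_ = self.model_.bias
        self.n_bands_ = self.model_.n_bands
        self.n_channels_ = self.model_.n_channels
        return self

    def predict(self, X):
        if not hasattr(self, "model_"):
            raise InvalidInputError("estimator is not fitted")
        if isinstance(X, np.ndarray) and X.ndim <= 2:
            return predict(self.model_, X)
        if isinstance(X, SegmentPair):
            return predict(self.model_, X.stimulus)
        return [predict(self.model_, s.stimulus if isinstance(s, SegmentPair) else s)
                for s in X]

    def score(self, X, y=None):
        """Mean Pearson r between predicted and observed responses."""
        segments = _to_segments(X, y, self.fs)
        rs = [
            _pearson_columns(predict(self.model_, s.stimulus), s.response).mean()
            for s in segments
        ]
        return float(np.mean(rs))


class TRFRidgeCV(TRFRidge):
    """TRF estimator with k-fold cross-validated lambda selection.

    After ``fit``, ``lam_`` holds the selected regularization strength,
    ``cv_result_`` the full accuracy-per-lambda table, and the final model is
    refitted on all segments at ``lam_``.
    """

    def __init__(self, tmin: float = 0.0, tmax: float = 0.4, fs: float = 128.0,
                 lambdas=None, cv: int = 5, random_state: int = 0):
        super().__init__(tmin=tmin, tmax=tmax, fs=fs, lam=0.0)
        self.lambdas = lambdas
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y=None):
        segments = _to_segments(X, y, self.fs)
        grid = DEFAULT_LAMBDA_GRID if self.lambdas is None else self.lambdas
        self.cv_result_ = cross_validate(
            segments, self._lag_window(), grid, k=self.cv, seed=self.random_state
        )
        self.lam_ = self.cv_result_.best_lambda
        self.model_ = fit_trf(segments, self._lag_window(), self.lam_)
        self.weights_ = self.model_.weights
        self.bias_ = self.model_.bias
        self.n_bands_ = self.model_.n_bands
        self.n_channels_ = self.model_.n_channels
        return self
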