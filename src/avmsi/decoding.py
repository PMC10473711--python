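"""Backward (stimulus-reconstruction) ridge decoding.

A backward decoder is a linear map from multichannel EEG, expanded over a
grid of stimulus-response time lags, to the speech envelope:

    s_hat(t) = sum_n sum_tau  r_n(t + tau) g(tau, n)

with the weights obtained by ridge regression on the lagged design matrix R,

    g = (R'R + lambda I)^-1 R's

The regularization strength lambda is selected by leave-one-trial-out
cross-validation over a geometric grid of candidates, maximizing the mean
per-trial Pearson correlation between the reconstructed and the actual
envelope on held-out trials.

Decoders never see raw trials twice: sufficient statistics (R'R, R's and
the column/target sums needed for an unpenalized intercept) are accumulated
per trial in a :class:`CovarianceAccumulator`, which makes leave-one-out
training a cheap subtraction and makes the summed-covariance (A+V) decoder
an exact sum of unisensory accumulators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg as sla
from sklearn.base import BaseEstimator, RegressorMixin

from ._exceptions import DegenerateSignalError, SingularSystemError

__all__ = [
    "LAMBDA_GRID",
    "LagGrid",
    "CovarianceAccumulator",
    "ReconstructionResult",
    "build_lagged_design",
    "solve_ridge",
    "crossval_lambda",
    "pearson_r",
    "EnvelopeDecoder",
    "SumCovarianceDecoder",
    "fit_condition_decoder",
    "fit_sum_decoder",
]

#: Default ridge-parameter grid: 10^-6, 10^-4, ..., 10^30 (19 candidates).
LAMBDA_GRID = 10.0 ** np.arange(-6, 31, 2)


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation that refuses to silently return nonsense.

    Raises
    ------
    DegenerateSignalError
        If either input is constant (zero variance) or non-finite, the
        correlation is undefined and is signaled instead of returned as 0.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("inputs must have equal length")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise DegenerateSignalError("non-finite values in correlation input")
    ac = a - a.mean()
    bc = b - b.mean()
    na = np.linalg.norm(ac)
    nb = np.linalg.norm(bc)
    if na == 0.0 or nb == 0.0:
        raise DegenerateSignalError("correlation undefined for a constant signal")
    return float(np.clip((ac @ bc) / (na * nb), -1.0, 1.0))


@dataclass(frozen=True)
class LagGrid:
    """Integer-sample lag grid between ``tau_min_ms`` and ``tau_max_ms``.

    Positive lags mean the EEG sample occurs *after* the stimulus sample it
    helps reconstruct. At 64 Hz the canonical integration window 0..500 ms
    yields 33 lags; the single-lag window -500..500 ms yields 65 lags spaced
    15.625 ms apart.
    """

    tau_min_ms: float = 0.0
    tau_max_ms: float = 500.0
    fs: float = 64.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.tau_max_ms < self.tau_min_ms:
            raise ValueError("tau_max_ms must be >= tau_min_ms")

    @property
    def lags(self) -> np.ndarray:
        lo = int(round(self.tau_min_ms * self.fs / 1000.0))
        hi = int(round(self.tau_max_ms * self.fs / 1000.0))
        return np.arange(lo, hi + 1)

    @property
    def n_lags(self) -> int:
        return len(self.lags)

    @property
    def lag_times_ms(self) -> np.ndarray:
        return self.lags * 1000.0 / self.fs


def build_lagged_design(eeg: np.ndarray, lag_grid: LagGrid) -> np.ndarray:
    """Expand a (channels x samples) trial into the lagged design matrix.

    Column ``(n, j)`` (stored channel-major, i.e. index ``n * n_lags + j``)
    at row ``t`` holds ``r_n(t + lags[j])``, zero-padded outside the trial.
    No intercept column is appended; the solver handles the intercept by
    centering, which is algebraically an unpenalized intercept.
    """
    eeg = np.asarray(eeg, dtype=float)
    if eeg.ndim != 2:
        raise ValueError("eeg must be a (channels, samples) array")
    n_ch, n_t = eeg.shape
    lags = lag_grid.lags
    if np.max(np.abs(lags)) >= n_t:
        raise ValueError(
            f"lag of {np.max(np.abs(lags))} samples exceeds trial length {n_t}"
        )
    out = np.zeros((n_t, n_ch, len(lags)))
    for j, lag in enumerate(lags):
        if lag >= 0:
            out[: n_t - lag, :, j] = eeg[:, lag:].T
        else:
            out[-lag:, :, j] = eeg[:, : n_t + lag].T
    return out.reshape(n_t, n_ch * len(lags))


class CovarianceAccumulator:
    """Sufficient statistics ``(R'R, R's, column sums)`` summed over trials.

    Supports multiple targets (columns of ``Xty``) so attended and
    unattended decoders trained on the same EEG share one gram matrix.
    Accumulators add and subtract exactly, which is what makes
    leave-one-trial-out training and the summed-covariance (A+V) decoder
    cheap and order-independent.
    """

    def __init__(self, n_cols: int, n_targets: int = 1):
        self.n_cols = int(n_cols)
        self.n_targets = int(n_targets)
        self.XtX = np.zeros((n_cols, n_cols))
        self.Xty = np.zeros((n_cols, n_targets))
        self.x_sum = np.zeros(n_cols)
        self.y_sum = np.zeros(n_targets)
        self.n_samples = 0

    def add_trial(self, R: np.ndarray, y: np.ndarray) -> "CovarianceAccumulator":
        y = np.asarray(y, dtype=float)
        if y.ndim == 1:
            y = y[:, None]
        if R.shape[0] != y.shape[0]:
            raise ValueError("design and target sample counts differ")
        if y.shape[1] != self.n_targets:
            raise ValueError("target count mismatch")
        self.XtX += R.T @ R
        self.Xty += R.T @ y
        self.x_sum += R.sum(axis=0)
        self.y_sum += y.sum(axis=0)
        self.n_samples += R.shape[0]
        return self

    @classmethod
    def from_trial(cls, R: np.ndarray, y: np.ndarray) -> "CovarianceAccumulator":
        y = np.asarray(y, dtype=float)
        k = 1 if y.ndim == 1 else y.shape[1]
        return cls(R.shape[1], k).add_trial(R, y)

    def copy(self) -> "CovarianceAccumulator":
        out = CovarianceAccumulator(self.n_cols, self.n_targets)
        out.XtX = self.XtX.copy()
        out.Xty = self.Xty.copy()
        out.x_sum = self.x_sum.copy()
        out.y_sum = self.y_sum.copy()
        out.n_samples = self.n_samples
        return out

    def _check_compatible(self, other: "CovarianceAccumulator") -> None:
        if self.n_cols != other.n_cols or self.n_targets != other.n_targets:
            raise ValueError("incompatible accumulators")

    def __add__(self, other: "CovarianceAccumulator") -> "CovarianceAccumulator":
        self._check_compatible(other)
        out = self.copy()
        out.XtX += other.XtX
        out.Xty += other.Xty
        out.x_sum += other.x_sum
        out.y_sum += other.y_sum
        out.n_samples += other.n_samples
        return out

    def __sub__(self, other: "CovarianceAccumulator") -> "CovarianceAccumulator":
        self._check_compatible(other)
        out = self.copy()
        out.XtX -= other.XtX
        out.Xty -= other.Xty
        out.x_sum -= other.x_sum
        out.y_sum -= other.y_sum
        out.n_samples -= other.n_samples
        return out

    def centered(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (XtX_c, Xty_c, x_mean, y_mean) with column means removed."""
        if self.n_samples <= 0:
            raise ValueError("empty accumulator")
        xbar = self.x_sum / self.n_samples
        ybar = self.y_sum / self.n_samples
        XtXc = self.XtX - self.n_samples * np.outer(xbar, xbar)
        Xtyc = self.Xty - self.n_samples * np.outer(xbar, ybar)
        return XtXc, Xtyc, xbar, ybar


def solve_ridge(
    acc: CovarianceAccumulator, lam: float
) -> tuple[np.ndarray, np.ndarray]:
    """Solve ``(R'R + lambda I) g = R's`` with an unpenalized intercept.

    The intercept is handled by centering the accumulated moments, which is
    exactly equivalent to appending an unpenalized constant column. Returns
    ``(coef, intercept)`` with ``coef`` of shape (n_cols, n_targets).

    Raises
    ------
    SingularSystemError
        If the penalized system is not positive definite (e.g. lambda = 0 on
        a rank-deficient design); the caller should raise lambda.
    """
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    XtXc, Xtyc, xbar, ybar = acc.centered()
    A = XtXc + lam * np.eye(acc.n_cols)
    try:
        c, low = sla.cho_factor(A, lower=True)
        coef = sla.cho_solve((c, low), Xtyc)
    except np.linalg.LinAlgError as exc:
        raise SingularSystemError(
            f"normal equations singular at lambda={lam}; increase lambda"
        ) from exc
    intercept = ybar - coef.T @ xbar
    return coef, intercept


class _CenteredEig:
    """Eigendecomposition of a centered gram matrix, reused across lambdas.

    One O(p^3) factorization per training set serves every ridge parameter
    and every target column, which is what keeps the lambda grid search,
    the single-lag sweep and the permutation nulls affordable.
    """

    def __init__(self, acc: CovarianceAccumulator):
        XtXc, Xtyc, xbar, ybar = acc.centered()
        self.w, self.V = sla.eigh(XtXc)
        self.xbar = xbar
        self.n_samples = acc.n_samples
        self.Xtyc = Xtyc
        self.ybar = ybar

    def coef(self, lam: float, Xtyc: np.ndarray | None = None) -> np.ndarray:
        B = self.V.T @ (self.Xtyc if Xtyc is None else Xtyc)
        return self.V @ (B / (self.w + lam)[:, None])

    def coef_many(self, lams: np.ndarray, Xtyc: np.ndarray | None = None) -> np.ndarray:
        """Coefficients for every lambda at once; shape (n_lams, p, k)."""
        B = self.V.T @ (self.Xtyc if Xtyc is None else Xtyc)
        scaled = B[None, :, :] / (self.w[None, :, None] + np.asarray(lams)[:, None, None])
        p = self.V.shape[0]
        G = self.V @ scaled.transpose(1, 0, 2).reshape(p, -1)
        return G.reshape(p, len(lams), -1).transpose(1, 0, 2)


def _loto_scores(
    designs: Sequence[np.ndarray],
    targets: Sequence[np.ndarray],
    lambdas: np.ndarray,
) -> np.ndarray:
    """Held-out Pearson r for every (lambda, trial) pair; NaN where undefined.

    Each trial is reconstructed by a decoder trained on the accumulated
    statistics of all other trials (covariance subtraction).
    """
    n_trials = len(designs)
    accs = [CovarianceAccumulator.from_trial(R, y) for R, y in zip(designs, targets)]
    total = accs[0].copy()
    for a in accs[1:]:
        total = total + a
    scores = np.full((len(lambdas), n_trials), np.nan)
    for i in range(n_trials):
        train = total - accs[i]
        eig = _CenteredEig(train)
        G = eig.coef_many(lambdas)  # (n_lams, p, 1)
        preds = designs[i] @ G[:, :, 0].T  # (T, n_lams); intercept irrelevant for r
        for li in range(len(lambdas)):
            try:
                scores[li, i] = pearson_r(preds[:, li], targets[i])
            except DegenerateSignalError:
                warnings.warn(
                    f"undefined correlation in fold {i} at lambda={lambdas[li]:g}; "
                    "fold excluded",
                    RuntimeWarning,
                    stacklevel=2,
                )
    return scores


def _select_lambda(mean_scores: np.ndarray, lambdas: np.ndarray) -> int:
    """Index of the best lambda; ties broken toward larger lambda."""
    finite = np.isfinite(mean_scores)
    if not finite.any():
        raise DegenerateSignalError("all cross-validation folds were undefined")
    best = np.nanmax(mean_scores)
    return int(np.flatnonzero(finite & (mean_scores == best)).max())


def crossval_lambda(
    trials: Sequence[np.ndarray],
    envelopes: Sequence[np.ndarray],
    lag_grid: LagGrid,
    lambdas: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Leave-one-trial-out selection of the ridge parameter.

    Returns ``(lambda_star, cv_curve)`` where ``cv_curve[i]`` is the mean
    held-out per-trial correlation at ``lambdas[i]``.
    """
    lambdas = LAMBDA_GRID if lambdas is None else np.asarray(lambdas, dtype=float)
    if len(trials) < 2:
        raise ValueError("leave-one-trial-out requires at least 2 trials")
    designs = [build_lagged_design(e, lag_grid) for e in trials]
    scores = _loto_scores(designs, envelopes, lambdas)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        curve = np.nanmean(scores, axis=1)
    idx = _select_lambda(curve, lambdas)
    return float(lambdas[idx]), curve


@dataclass
class ReconstructionResult:
    """Per-trial reconstructions and their accuracies for one decoder."""

    r: np.ndarray
    s_hat: list[np.ndarray] = field(repr=False)
    trial_ids: np.ndarray | None = None
    decoder_label: str | None = None

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.r))


class _BaseDecoder(BaseEstimator, RegressorMixin):
    """Shared prediction/scoring machinery for fitted backward decoders."""

    def _lag_grid(self) -> LagGrid:
        return LagGrid(self.tau_min_ms, self.tau_max_ms, self.fs)

    def _lambdas(self) -> np.ndarray:
        return LAMBDA_GRID if self.lambdas is None else np.asarray(self.lambdas, float)

    @staticmethod
    def _as_trial_list(X) -> list[np.ndarray]:
        if isinstance(X, np.ndarray) and X.ndim == 3:
            return [X[i] for i in range(X.shape[0])]
        if isinstance(X, np.ndarray) and X.ndim == 2:
            return [X]
        return [np.asarray(t, dtype=float) for t in X]

    def predict(self, X) -> list[np.ndarray]:
        """Reconstruct the envelope of each trial in X."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "coef_")
        trials = self._as_trial_list(X)
        grid = self._lag_grid()
        out = []
        for eeg in trials:
            R = build_lagged_design(eeg, grid)
            out.append(R @ self.coef_ + self.intercept_)
        return out

    def score_trials(self, X, y) -> np.ndarray:
        """Per-trial Pearson r between reconstruction and target envelope."""
        preds = self.predict(X)
        if np.all(self.coef_ == 0):
            raise DegenerateSignalError("decoder weights are identically zero")
        return np.array([pearson_r(p, t) for p, t in zip(preds, y)])

    def score(self, X, y) -> float:
        """Trial-averaged reconstruction accuracy (mean per-trial Pearson r)."""
        return float(np.mean(self.score_trials(X, y)))

    def reconstruct(self, X, y, trial_ids=None) -> ReconstructionResult:
        preds = self.predict(X)
        r = self.score_trials(X, y)
        return ReconstructionResult(
            r=r, s_hat=preds, trial_ids=None if trial_ids is None else np.asarray(trial_ids)
        )

    @property
    def weights_(self) -> np.ndarray:
        """Decoder weights reshaped to (n_channels, n_lags)."""
        return self.coef_.reshape(self.n_channels_, -1)


class EnvelopeDecoder(_BaseDecoder):
    """Backward ridge decoder with leave-one-trial-out lambda selection.

    Parameters
    ----------
    tau_min_ms, tau_max_ms : float
        Stimulus-response lag window; the canonical integrated decoder uses
        0..500 ms, single-lag decoders use a one-sample window.
    fs : float
        Sampling rate of both EEG and envelope (Hz).
    lambdas : array-like or None
        Ridge-parameter candidates; ``None`` uses the canonical grid
        10^-6 .. 10^30 in decade-squared steps (19 values).

    Attributes
    ----------
    coef_ : (n_channels * n_lags,) weights, channel-major.
    intercept_ : float
    lambda_ : selected ridge parameter.
    cv_scores_ : mean held-out r per lambda candidate.
    cv_fold_scores_ : (n_lambdas, n_trials) held-out r per fold.
    """

    def __init__(
        self,
        tau_min_ms: float = 0.0,
        tau_max_ms: float = 500.0,
        fs: float = 64.0,
        lambdas=None,
    ):
        self.tau_min_ms = tau_min_ms
        self.tau_max_ms = tau_max_ms
        self.fs = fs
        self.lambdas = lambdas

    def fit(self, X, y):
        trials = self._as_trial_list(X)
        targets = [np.asarray(t, dtype=float).ravel() for t in y]
        if len(trials) != len(targets):
            raise ValueError("trial and envelope counts differ")
        grid = self._lag_grid()
        lambdas = self._lambdas()
        self.n_channels_ = trials[0].shape[0]
        designs = [build_lagged_design(e, grid) for e in trials]
        if len(trials) >= 2:
            fold_scores = _loto_scores(designs, targets, lambdas)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                curve = np.nanmean(fold_scores, axis=1)
            idx = _select_lambda(curve, lambdas)
            self.cv_fold_scores_ = fold_scores
            self.cv_scores_ = curve
        elif len(lambdas) == 1:
            idx = 0
            self.cv_fold_scores_ = None
            self.cv_scores_ = None
        else:
            raise ValueError("lambda cross-validation requires at least 2 trials")
        self.lambda_ = float(lambdas[idx])
        total = CovarianceAccumulator(designs[0].shape[1])
        for R, t in zip(designs, targets):
            total.add_trial(R, t)
        coef, intercept = solve_ridge(total, self.lambda_)
        self.coef_ = coef[:, 0]
        self.intercept_ = float(intercept[0])
        self.lag_grid_ = grid
        return self


class SumCovarianceDecoder(_BaseDecoder):
    """Additive-model (A+V) decoder trained on summed unisensory covariances.

    The gram matrix and cross-covariance are accumulated separately over
    audio-only trials (target: the heard envelope) and visual-only trials
    (target: the unheard envelope matched to the visible face), summed, and
    solved once. The ridge parameter is selected to maximize reconstruction
    of the congruent audiovisual trials, which are never part of the
    training statistics.
    """

    def __init__(
        self,
        tau_min_ms: float = 0.0,
        tau_max_ms: float = 500.0,
        fs: float = 64.0,
        lambdas=None,
    ):
        self.tau_min_ms = tau_min_ms
        self.tau_max_ms = tau_max_ms
        self.fs = fs
        self.lambdas = lambdas

    def fit(self, X_a, y_a, X_v, y_v, X_av=None, y_av=None):
        trials_a = self._as_trial_list(X_a)
        trials_v = self._as_trial_list(X_v)
        if not trials_a or not trials_v:
            raise ValueError("both unisensory trial sets must be nonempty")
        grid = self._lag_grid()
        lambdas = self._lambdas()
        self.n_channels_ = trials_a[0].shape[0]
        acc = None
        for eeg, env in zip(trials_a, y_a):
            R = build_lagged_design(eeg, grid)
            a = CovarianceAccumulator.from_trial(R, np.asarray(env, float).ravel())
            acc = a if acc is None else acc + a
        for eeg, env in zip(trials_v, y_v):
            R = build_lagged_design(eeg, grid)
            acc = acc + CovarianceAccumulator.from_trial(R, np.asarray(env, float).ravel())
        if X_av is not None and len(lambdas) > 1:
            val_trials = self._as_trial_list(X_av)
            val_designs = [build_lagged_design(e, grid) for e in val_trials]
            eig = _CenteredEig(acc)
            G = eig.coef_many(lambdas)[:, :, 0]  # (n_lams, p)
            scores = np.full((len(lambdas), len(val_trials)), np.nan)
            for i, (R, env) in enumerate(zip(val_designs, y_av)):
                preds = R @ G.T
                for li in range(len(lambdas)):
                    try:
                        scores[li, i] = pearson_r(preds[:, li], env)
                    except DegenerateSignalError:
                        pass
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                curve = np.nanmean(scores, axis=1)
            idx = _select_lambda(curve, lambdas)
            self.cv_scores_ = curve
        elif len(lambdas) == 1:
            idx = 0
            self.cv_scores_ = None
        else:
            raise ValueError(
                "lambda selection requires validation AV trials or a single candidate"
            )
        self.lambda_ = float(lambdas[idx])
        coef, intercept = solve_ridge(acc, self.lambda_)
        self.coef_ = coef[:, 0]
        self.intercept_ = float(intercept[0])
        self.lag_grid_ = grid
        return self


def _condition_trials(trials, modality: str, gaze: str | None):
    sel = [t for t in trials if t.modality == modality]
    if gaze is not None:
        sel = [t for t in sel if t.gaze == gaze]
    return sel


def _targets(trials, attention: str) -> list[np.ndarray]:
    if attention not in ("attended", "unattended"):
        raise ValueError("attention must be 'attended' or 'unattended'")
    return [t.env_att if attention == "attended" else t.env_unatt for t in trials]


def fit_condition_decoder(
    trials,
    modality: str,
    attention: str,
    gaze: str | None = None,
    **decoder_params,
) -> EnvelopeDecoder:
    """Fit a per-condition decoder (AV, A or V) from a cohort of trials.

    The target envelope follows the experiment's fit/reconstruct mapping:
    AV decoders target the congruent audio envelope, A decoders the heard
    audio of the incongruent stimulus, and V decoders the *unheard* envelope
    matched to the visible face.
    """
    sel = _condition_trials(trials, modality, gaze)
    if not sel:
        raise ValueError(f"no trials for modality={modality!r}, gaze={gaze!r}")
    dec = EnvelopeDecoder(**decoder_params)
    dec.fit([t.eeg for t in sel], _targets(sel, attention))
    dec.condition_ = {"modality": modality, "attention": attention, "gaze": gaze}
    return dec


def fit_sum_decoder(
    trials,
    attention: str,
    gaze: str | None = None,
    **decoder_params,
) -> SumCovarianceDecoder:
    """Fit the (A+V) decoder for one condition cell of a cohort."""
    trials_a = _condition_trials(trials, "A", gaze)
    trials_v = _condition_trials(trials, "V", gaze)
    trials_av = _condition_trials(trials, "AV", gaze)
    if not trials_a or not trials_v:
        raise ValueError("both unisensory condition cells must be nonempty")
    dec = SumCovarianceDecoder(**decoder_params)
    dec.fit(
        [t.eeg for t in trials_a],
        _targets(trials_a, attention),
        [t.eeg for t in trials_v],
        _targets(trials_v, attention),
        X_av=[t.eeg for t in trials_av] or None,
        y_av=_targets(trials_av, attention) or None,
    )
    dec.condition_ = {"modality": "A+V", "attention": attention, "gaze": gaze}
    return dec
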