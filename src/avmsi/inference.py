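"""Statistical inference: permutation nulls, rank tests, FDR, behavior.

Chance levels for reconstruction accuracy are established by shuffling the
stimulus-EEG pairing between trials and re-running the full decoder fit
(including leave-one-trial-out lambda selection) for each shuffle; the
per-subject null summary is the mean of the shuffled accuracies, which is
then compared with the actual trial-averaged accuracies at the group level
by Wilcoxon signed-rank testing. Benjamini-Hochberg FDR controls multiple
comparisons across single-lag tests. Behavioral sensitivity uses the
equal-variance signal-detection d-prime with kind-specific hit windows
(2 s for glitches, 4 s for slow-motion events).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._exceptions import DegenerateSignalError
from .decoding import (
    LAMBDA_GRID,
    CovarianceAccumulator,
    LagGrid,
    _CenteredEig,
    _select_lambda,
    build_lagged_design,
)
from .synthetic import TARGET_WINDOWS, BehavioralEvents

__all__ = [
    "NullDistribution",
    "DPrimeResult",
    "permutation_null",
    "signed_rank",
    "rank_sum",
    "fdr_bh",
    "dprime",
    "comprehension_test",
]


@dataclass
class NullDistribution:
    """Null reconstruction accuracies from stimulus-EEG pair shuffling."""

    null_r: np.ndarray  # one mean held-out r per permutation
    actual_r: float  # actual trial-averaged held-out r
    actual_per_trial: np.ndarray
    n_perm: int
    seed: int | None

    @property
    def summary(self) -> float:
        """Per-subject null summary: the mean of the permuted accuracies."""
        return float(np.mean(self.null_r))


def _within_group_permutations(
    rng: np.random.Generator, n_trials: int, n_perm: int, groups: np.ndarray | None
) -> np.ndarray:
    perms = np.empty((n_perm, n_trials), dtype=int)
    base = np.arange(n_trials)
    for p in range(n_perm):
        perm = base.copy()
        if groups is None:
            rng.shuffle(perm)
        else:
            for g in np.unique(groups):
                idx = np.flatnonzero(groups == g)
                perm[idx] = idx[rng.permutation(len(idx))]
        perms[p] = perm
    return perms


def permutation_null(
    trials,
    envelopes,
    lag_grid: LagGrid | None = None,
    lambdas: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int | None = 0,
    groups: np.ndarray | None = None,
    permutations: np.ndarray | None = None,
) -> NullDistribution:
    """Null distribution of decoder accuracy under envelope-trial shuffling.

    Each permutation reassigns envelopes to trials (uniformly, within
    ``groups`` when given, so condition-specific envelope statistics are
    preserved), refits the decoder with the standard leave-one-trial-out
    lambda selection, and records the mean held-out per-trial Pearson r.
    Because shuffling only changes the stimulus side, the per-fold EEG gram
    matrices are shared across permutations, which is what makes 1000
    refits affordable.

    ``trials`` may be ``Trial`` objects or raw (channels x samples) arrays.
    Passing explicit ``permutations`` (n_perm x n_trials) overrides the
    random draw; the identity row reproduces the actual accuracy exactly.
    """
    eegs = [t.eeg if hasattr(t, "eeg") else np.asarray(t, float) for t in trials]
    n_trials = len(eegs)
    if n_trials < 3:
        raise ValueError("permutation null requires at least 3 trials")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 100:
        warnings.warn(
            "fewer than 100 permutations gives a coarse null", RuntimeWarning
        )
    grid = LagGrid() if lag_grid is None else lag_grid
    lams = LAMBDA_GRID if lambdas is None else np.asarray(lambdas, float)

    S = np.column_stack([np.asarray(e, float).ravel() for e in envelopes])  # (T, K)
    T = S.shape[0]
    designs = [build_lagged_design(e, grid) for e in eegs]
    p = designs[0].shape[1]

    # per-trial gram statistics and the full cross table R_i' s_j
    XtX = np.stack([R.T @ R for R in designs])  # (K, p, p)
    x_sums = np.stack([R.sum(axis=0) for R in designs])  # (K, p)
    cross = np.stack([R.T @ S for R in designs])  # (K, p, K)
    XtX_tot = XtX.sum(axis=0)
    x_tot = x_sums.sum(axis=0)
    y_sums = S.sum(axis=0)  # (K,)
    Sc = S - S.mean(axis=0, keepdims=True)
    S_norm = np.linalg.norm(Sc, axis=0)

    if permutations is None:
        rng = np.random.default_rng(seed)
        perms = _within_group_permutations(rng, n_trials, n_perm, groups)
    else:
        perms = np.asarray(permutations, dtype=int)
        n_perm = perms.shape[0]
    P = n_perm

    # total Xty per permutation: sum_j R_j' s_{perm(j)}
    cross_sw = cross.transpose(0, 2, 1)  # (K, K, p): [j, target, col]
    tot_xty = cross_sw[np.arange(n_trials)[None, :], perms, :].sum(axis=1)  # (P, p)
    tot_ysum = y_sums[perms].sum(axis=1)  # (P,)

    scores = np.empty((len(lams), n_trials, P))
    for i in range(n_trials):
        n_train = T * (n_trials - 1)
        acc = CovarianceAccumulator(p)
        acc.XtX = XtX_tot - XtX[i]
        acc.x_sum = x_tot - x_sums[i]
        acc.n_samples = n_train
        eig = _CenteredEig(acc)
        xty = (tot_xty - cross_sw[i, perms[:, i], :]).T  # (p, P)
        ybar = (tot_ysum - y_sums[perms[:, i]]) / n_train  # (P,)
        xtyc = xty - n_train * np.outer(eig.xbar, ybar)
        G = eig.coef_many(lams, xtyc)  # (n_lams, p, P)
        preds = designs[i] @ G.transpose(1, 0, 2).reshape(p, -1)  # (T, n_lams*P)
        preds = preds.reshape(T, len(lams), P)
        predc = preds - preds.mean(axis=0, keepdims=True)
        targ = Sc[:, perms[:, i]]  # (T, P)
        num = np.einsum("tlp,tp->lp", predc, targ)
        den = np.sqrt(np.einsum("tlp,tlp->lp", predc, predc)) * S_norm[perms[:, i]][None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            scores[:, i, :] = np.where(den > 0, num / den, np.nan)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        curves = np.nanmean(scores, axis=1)  # (n_lams, P)
    null_r = np.empty(P)
    for q in range(P):
        idx = _select_lambda(curves[:, q], lams)
        null_r[q] = curves[idx, q]

    # actual accuracy through the identical code path (identity assignment)
    identity = np.arange(n_trials)
    id_scores = np.empty((len(lams), n_trials))
    for i in range(n_trials):
        n_train = T * (n_trials - 1)
        acc = CovarianceAccumulator(p)
        acc.XtX = XtX_tot - XtX[i]
        acc.x_sum = x_tot - x_sums[i]
        acc.n_samples = n_train
        eig = _CenteredEig(acc)
        xty = (cross_sw[np.arange(n_trials), identity, :].sum(axis=0) - cross_sw[i, i, :])
        ybar = (y_sums.sum() - y_sums[i]) / n_train
        xtyc = (xty - n_train * eig.xbar * ybar)[:, None]
        G = eig.coef_many(lams, xtyc)[:, :, 0]  # (n_lams, p)
        preds = designs[i] @ G.T
        predc = preds - preds.mean(axis=0, keepdims=True)
        num = predc.T @ Sc[:, i]
        den = np.linalg.norm(predc, axis=0) * S_norm[i]
        with np.errstate(invalid="ignore", divide="ignore"):
            id_scores[:, i] = np.where(den > 0, num / den, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        id_curve = np.nanmean(id_scores, axis=1)
    idx = _select_lambda(id_curve, lams)
    return NullDistribution(
        null_r=null_r,
        actual_r=float(id_curve[idx]),
        actual_per_trial=id_scores[idx],
        n_perm=P,
        seed=seed,
    )


def signed_rank(paired_a, paired_b=None, alternative: str = "two-sided"):
    """Wilcoxon signed-rank test on paired samples (or on a - 0).

    Zero differences are dropped per the standard convention; all-zero
    differences return p = 1 by contract. The null distribution is exact
    for n <= 25 nonzero pairs (when ties permit) and a continuity-corrected
    normal approximation otherwise.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.zeros_like(a) if paired_b is None else np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0
    method = "exact" if d.size <= 25 else "approx"
    try:
        res = stats.wilcoxon(d, alternative=alternative, method=method, correction=method == "approx")
    except ValueError:
        res = stats.wilcoxon(d, alternative=alternative, method="approx", correction=True)
    return float(res.statistic), float(res.pvalue)


def rank_sum(group_a, group_b, alternative: str = "two-sided"):
    """Unpaired Wilcoxon rank-sum (Mann-Whitney) test with mid-rank ties."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    res = stats.mannwhitneyu(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def fdr_bh(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR: (rejection flags, adjusted p)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


@dataclass
class DPrimeResult:
    """Signal-detection scoring of visual-target detection."""

    hits: int
    misses: int
    false_alarms: int
    n_target_windows: int
    n_nontarget_windows: int
    hit_rate: float
    fa_rate: float
    dprime: float


def dprime(
    events: BehavioralEvents,
    trial_indices=None,
    duration_s: float = 60.0,
) -> DPrimeResult:
    """Score detection behavior pooled over trials.

    A response within the kind-specific window after a target onset (2 s
    glitch, 4 s slow-motion) is a hit, one response credited per target;
    remaining responses are false alarms. The false-alarm denominator is
    the number of window-length non-target bins tiling each trial. Perfect
    rates are corrected by 1/(2N) before the inverse-normal transform.
    """
    targets = events.targets
    responses = events.responses
    if trial_indices is not None:
        targets = targets[targets.trial_index.isin(trial_indices)]
        responses = responses[responses.trial_index.isin(trial_indices)]
    if len(targets) == 0:
        raise ValueError("d-prime undefined: no targets in the selected trials")

    hits = 0
    false_alarms = 0
    n_nontarget = 0
    for ti, tgt in targets.groupby("trial_index"):
        kind = tgt.target_kind.iloc[0]
        window = TARGET_WINDOWS[kind]
        resp = np.sort(responses.loc[responses.trial_index == ti, "response_time"].to_numpy())
        t_on = np.sort(tgt.target_time.to_numpy())
        used = np.zeros(len(resp), dtype=bool)
        for t0 in t_on:
            in_win = np.flatnonzero(~used & (resp >= t0) & (resp < t0 + window))
            if in_win.size:
                used[in_win[0]] = True
                hits += 1
        false_alarms += int((~used).sum())
        n_nontarget += max(int(duration_s // window) - len(t_on), 1)
    # responses in trials without any targets all count as false alarms
    extra = responses[~responses.trial_index.isin(targets.trial_index.unique())]
    false_alarms += len(extra)

    n_targets = len(targets)
    hr = hits / n_targets
    if hr == 0:
        hr = 1 / (2 * n_targets)
    elif hr == 1:
        hr = 1 - 1 / (2 * n_targets)
    fr = false_alarms / n_nontarget
    fr = min(fr, 1.0)
    if fr == 0:
        fr = 1 / (2 * n_nontarget)
    elif fr == 1:
        fr = 1 - 1 / (2 * n_nontarget)
    d = float(stats.norm.ppf(hr) - stats.norm.ppf(fr))
    return DPrimeResult(
        hits=hits,
        misses=n_targets - hits,
        false_alarms=false_alarms,
        n_target_windows=n_targets,
        n_nontarget_windows=n_nontarget,
        hit_rate=hr,
        fa_rate=fr,
        dprime=d,
    )


def comprehension_test(scores, chance: float = 0.25):
    """One-sided signed-rank of per-subject comprehension means vs chance.

    ``scores`` are per-subject mean proportions correct on four-choice
    questions; the test asks whether the group exceeds the 25% chance
    level.
    """
    return signed_rank(np.asarray(scores, float) - chance, alternative="greater")
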