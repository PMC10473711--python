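"""Gaze-effect linear mixed models and likelihood-ratio comparisons.

Responses (comprehension score, d-prime, speech tracking, MSI, attention
benefit) are modeled with Gaussian random-intercept models of the form

    y ~ gz + exp + (1 | ptc)        (full)
    y ~      exp + (1 | ptc)        (reduced)

where ``gz`` codes gaze numerically by its distance from the attention
target (direct = 0, crosshair = 1, eavesdrop = 2), ``exp`` indicates the
experiment, and the participant intercept absorbs individual variability
(participants appearing in both experiments share one intercept). Models
are fit by maximum likelihood (not REML) so nested fits can be compared
with the likelihood-ratio test, 2*(ll_full - ll_reduced) ~ chi-square with
df equal to the difference in fixed-effect count (1 for the gaze term).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM

from ._exceptions import DegenerateSignalError
from .inference import fdr_bh

__all__ = [
    "GAZE_CODE",
    "LmeSpec",
    "LmeFit",
    "LlrResult",
    "encode_gaze",
    "fit_lme",
    "llr_test",
    "llr_pvalue",
    "timewise_lme",
    "comprehension_from_msi",
]

#: Numeric gaze coding, ordered by angular distance from the attended face.
GAZE_CODE = {"d": 0, "c": 1, "e": 2}


def encode_gaze(gaze) -> np.ndarray:
    """Map gaze condition labels (d/c/e) to the ordered numeric code."""
    return pd.Series(gaze).map(GAZE_CODE).to_numpy(dtype=float)


@dataclass(frozen=True)
class LmeSpec:
    """Model specification: response, fixed effects, grouping factor."""

    response: str
    fixed: tuple[str, ...] = ("gz", "exp")
    group: str = "ptc"

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.fixed) if self.fixed else "1"
        return f"{self.response} ~ {rhs}"


@dataclass
class LmeFit:
    """Maximum-likelihood random-intercept fit."""

    spec: LmeSpec
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    llf: float
    n_obs: int
    n_groups: int
    converged: bool
    result: object = field(repr=False, default=None)


def fit_lme(data: pd.DataFrame, spec: LmeSpec) -> LmeFit:
    """Fit a Gaussian random-intercept model by maximum likelihood.

    Returns coefficient estimates with Wald standard errors and p-values.
    Non-convergence is signaled in ``converged`` (the optimizer diagnostics
    live on ``result``); a singular random-effect variance is retained with
    a warning rather than treated as failure.
    """
    missing = [c for c in (spec.response, *spec.fixed, spec.group) if c not in data]
    if missing:
        raise ValueError(f"columns missing from data: {missing}")
    y = data[spec.response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    if np.std(y) == 0:
        raise DegenerateSignalError("constant response: model is degenerate")
    if data[spec.group].nunique() < 2:
        raise ValueError("need at least 2 participants")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(spec.formula, groups=data[spec.group], data=data)

        def _valid(r):
            return (
                np.isfinite(r.llf)
                and np.all(np.isfinite(r.params))
                and np.all(np.isfinite(r.bse[: 1 + len(spec.fixed)]))
            )

        res = None
        for method in ("lbfgs", "powell", "bfgs"):
            try:
                cand = model.fit(reml=False, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if _valid(cand):
                res = cand
                break
        if res is None:
            # random-intercept variance at the zero boundary: the ML solution
            # degenerates to ordinary least squares (same likelihood)
            import statsmodels.api as sm

            X = sm.add_constant(
                data[list(spec.fixed)] if spec.fixed else pd.DataFrame(index=data.index)
            )
            if not spec.fixed:
                X = pd.DataFrame({"const": np.ones(len(data))}, index=data.index)
            ols = sm.OLS(y, X).fit()
            return LmeFit(
                spec=spec,
                params=ols.params,
                bse=ols.bse,
                pvalues=ols.pvalues,
                llf=float(ols.llf),
                n_obs=int(len(data)),
                n_groups=int(data[spec.group].nunique()),
                converged=True,
                result=ols,
            )
    return LmeFit(
        spec=spec,
        params=res.params[: 1 + len(spec.fixed)],
        bse=res.bse[: 1 + len(spec.fixed)],
        pvalues=res.pvalues[: 1 + len(spec.fixed)],
        llf=float(res.llf),
        n_obs=int(len(data)),
        n_groups=int(data[spec.group].nunique()),
        converged=bool(res.converged),
        result=res,
    )


@dataclass
class LlrResult:
    """Likelihood-ratio comparison of nested maximum-likelihood fits."""

    llr: float
    df: int
    p: float


def llr_pvalue(llr: float, df: int = 1) -> float:
    """Chi-square upper-tail p for a likelihood-ratio statistic."""
    return float(stats.chi2.sf(llr, df))


def llr_test(fit_full: LmeFit, fit_reduced: LmeFit) -> LlrResult:
    """LLR test of a full against a nested reduced fixed-effect model."""
    if fit_full.spec.response != fit_reduced.spec.response:
        raise ValueError("models have different responses; not nested")
    if not set(fit_reduced.spec.fixed) <= set(fit_full.spec.fixed):
        raise ValueError("reduced model is not nested in the full model")
    if fit_full.n_obs != fit_reduced.n_obs:
        raise ValueError("models were fit on different data")
    df = len(fit_full.spec.fixed) - len(fit_reduced.spec.fixed)
    llr = 2.0 * (fit_full.llf - fit_reduced.llf)
    if df == 0:
        return LlrResult(llr=llr, df=0, p=1.0)
    return LlrResult(llr=llr, df=df, p=llr_pvalue(max(llr, 0.0), df))


def timewise_lme(
    lag_data: pd.DataFrame,
    response: str = "value",
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-lag gaze models with FDR control across lags.

    ``lag_data`` is long-format with columns ``lag_ms, ptc, exp, gz`` and
    the response column; one full-vs-reduced LLR is fit per lag and the
    resulting p-values are Benjamini-Hochberg corrected across the lag
    grid. Lags where either fit fails to converge are flagged, not
    dropped.
    """
    full_spec = LmeSpec(response, ("gz", "exp"))
    red_spec = LmeSpec(response, ("exp",))
    rows = []
    for lag_ms, sub in lag_data.groupby("lag_ms", sort=True):
        try:
            full = fit_lme(sub, full_spec)
            red = fit_lme(sub, red_spec)
            llr = llr_test(full, red)
            rows.append(
                dict(
                    lag_ms=lag_ms,
                    beta_gz=float(full.params["gz"]),
                    se=float(full.bse["gz"]),
                    p_wald=float(full.pvalues["gz"]),
                    llr=llr.llr,
                    p_llr=llr.p,
                    converged=full.converged and red.converged,
                )
            )
        except (DegenerateSignalError, np.linalg.LinAlgError):
            rows.append(
                dict(
                    lag_ms=lag_ms,
                    beta_gz=np.nan,
                    se=np.nan,
                    p_wald=np.nan,
                    llr=np.nan,
                    p_llr=np.nan,
                    converged=False,
                )
            )
    out = pd.DataFrame(rows)
    ok = out.p_llr.notna()
    sig = np.zeros(len(out), dtype=bool)
    p_fdr = np.full(len(out), np.nan)
    if ok.any():
        rej, adj = fdr_bh(out.loc[ok, "p_llr"].to_numpy(), q=q)
        sig[np.flatnonzero(ok)] = rej
        p_fdr[np.flatnonzero(ok)] = adj
    out["p_fdr"] = p_fdr
    out["significant"] = sig
    return out


def comprehension_from_msi(trial_table: pd.DataFrame) -> tuple[LmeFit, LlrResult]:
    """Relate trial-by-trial comprehension to the trial-level MSI measure.

    ``trial_table`` needs columns ``qa`` (proportion correct), ``msi``,
    ``exp`` and ``ptc``; the full model adds ``msi`` to the experiment
    control, the reduced model omits it.
    """
    full = fit_lme(trial_table, LmeSpec("qa", ("msi", "exp")))
    red = fit_lme(trial_table, LmeSpec("qa", ("exp",)))
    return full, llr_test(full, red)
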