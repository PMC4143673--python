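"""Nested regression models for combined admixture and association testing.

Five nested linear models of the log-transformed trait are defined at each
marker (covariates X always include two of the three global-ancestry
proportions; E is omitted as collinear with the intercept):

* M1 (null):           y = a + X'b + e
* M2 (association):    y = a + X'b + b_g g + e
* M3 (admixture):      y = a + X'b + sum_c b_c D_c + e
* M4 (heterogeneous):  y = a + X'b + sum_c b_c D_c + sum_c b_{g,c} (g x D_c) + e
* M5 (homogeneous):    y = a + X'b + sum_c b_c D_c + b_g g + e

where D_c are diplotype-category indicators (EE reference) and the M4 sum
over g x D_c runs over *every* present category including EE, so the EE
genotype effect is the EE-stratum slope.  The nesting M1 c M2 c M5 c M4 and
M1 c M3 c M5 c M4 supports Wald and likelihood-ratio contrasts referenced to
chi-squared distributions.

Fits use ordinary least squares; the reported log-likelihood is the Gaussian
maximum with the MLE variance RSS/n, while the coefficient covariance uses
the unbiased RSS/(n - p) (the convention of standard regression software).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from admixscan.ancestry import CATEGORIES, dummy_code

logger = logging.getLogger(__name__)

#: relative tolerance for rank decisions during column pruning
_RANK_TOL = 1e-8


class ModelId(str, Enum):
    """The five nested models; values are stable identifiers."""

    M1_null = "M1_null"
    M2_association = "M2_association"
    M3_admixture = "M3_admixture"
    M4_heterogeneous = "M4_heterogeneous"
    M5_homogeneous = "M5_homogeneous"


@dataclass(frozen=True)
class CovariateSet:
    """Baseline covariates X, always carrying two global-ancestry proportions.

    ``frame`` holds one column per covariate; the global-ancestry columns
    (default ``ga_N`` and ``ga_A`` -- Native American and African proportions,
    with European omitted) must be present.  Exactly two of the three
    proportions may enter the design: the third is collinear with the
    intercept.
    """

    frame: pd.DataFrame
    global_columns: tuple[str, str] = ("ga_N", "ga_A")

    def __post_init__(self) -> None:
        missing = [c for c in self.global_columns if c not in self.frame.columns]
        if missing:
            raise ValueError(f"covariate frame missing global-ancestry columns {missing}")
        if "ga_E" in self.frame.columns and "ga_E" not in self.global_columns:
            raise ValueError(
                "all three global proportions in the design are collinear with the "
                "intercept; drop one (conventionally ga_E)"
            )

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)


@dataclass(frozen=True)
class FitResult:
    """An OLS fit: coefficients, covariance, RSS, Gaussian log-likelihood."""

    params: pd.Series
    cov: pd.DataFrame
    rss: float
    llf: float
    df_resid: float
    nobs: int
    columns: tuple[str, ...] = field(default=())
    dropped: tuple[str, ...] = field(default=())
    design: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.columns:
            object.__setattr__(self, "columns", tuple(self.params.index))

    @property
    def n_params(self) -> int:
        return len(self.columns)

    def bse(self) -> pd.Series:
        """Coefficient standard errors (unbiased-variance convention)."""
        return pd.Series(np.sqrt(np.diag(self.cov.to_numpy())), index=self.cov.index)

    def summary_table(self) -> pd.DataFrame:
        """Term / estimate / standard error / two-sided t p-value table."""
        se = self.bse()
        tvals = self.params / se
        pvals = 2 * stats.t.sf(np.abs(tvals), self.df_resid)
        return pd.DataFrame(
            {"estimate": self.params, "std_error": se, "p_value": pvals}
        ).rename_axis("term")


def _greedy_rank_prune(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop later columns that are numerically collinear with earlier ones."""
    arr = X.to_numpy(dtype=float)
    n = arr.shape[0]
    keep: list[int] = []
    basis = np.empty((n, 0))
    dropped: list[str] = []
    for j in range(arr.shape[1]):
        col = arr[:, j]
        resid = col - basis @ (basis.T @ col)
        norm = np.linalg.norm(resid)
        scale = np.linalg.norm(col)
        if scale == 0 or norm <= _RANK_TOL * max(scale, 1.0):
            dropped.append(X.columns[j])
            continue
        keep.append(j)
        basis = np.column_stack([basis, resid / norm])
    if dropped:
        warnings.warn(f"rank-deficient design: dropping columns {dropped}", stacklevel=3)
    return X.iloc[:, keep], dropped


def build_design(
    model: ModelId | str,
    g: Sequence[float] | np.ndarray | None,
    categories: Sequence[str] | np.ndarray | None,
    covariates: CovariateSet,
) -> tuple[pd.DataFrame, list[str]]:
    """Design matrix for one of the five models at a single marker.

    Returns ``(X, dropped)`` where X always starts with the intercept and the
    baseline covariates, followed by the model's marker terms; diplotype
    categories with no carriers contribute no columns, and any residual rank
    deficiency is resolved by dropping the offending later columns with a
    warning.  ``g`` may be non-integer (imputed dosages) but must lie in
    [0, 2].
    """
    model = ModelId(model)
    frame = covariates.frame
    n = len(frame)
    if n == 0:
        raise ValueError("empty sample")
    parts: list[pd.DataFrame] = [
        pd.DataFrame({"const": np.ones(n)}, index=frame.index),
        frame,
    ]
    needs_g = model in (ModelId.M2_association, ModelId.M4_heterogeneous, ModelId.M5_homogeneous)
    needs_cats = model in (
        ModelId.M3_admixture, ModelId.M4_heterogeneous, ModelId.M5_homogeneous,
    )
    if needs_g:
        if g is None:
            raise ValueError(f"{model.value} requires genotype dosages")
        g = np.asarray(g, dtype=float)
        if g.shape != (n,):
            raise ValueError("dosage vector does not align with covariates")
        if np.any(g < 0) or np.any(g > 2):
            raise ValueError("dosages must lie in [0, 2]")
    if needs_cats:
        if categories is None:
            raise ValueError(f"{model.value} requires diplotype categories")
        cats = np.asarray(categories, dtype=object)
        if cats.shape != (n,):
            raise ValueError("category vector does not align with covariates")
        dummies = dummy_code(cats)
        dummies.index = frame.index
        parts.append(dummies)
    if model is ModelId.M2_association or model is ModelId.M5_homogeneous:
        parts.append(pd.DataFrame({"g": g}, index=frame.index))
    if model is ModelId.M4_heterogeneous:
        cols = {}
        for cat in CATEGORIES:  # canonical order; EE included
            ind = (cats == cat).astype(float)
            if ind.any():
                cols[f"gxD_{cat}"] = g * ind
        parts.append(pd.DataFrame(cols, index=frame.index))
    X = pd.concat(parts, axis=1)
    return _greedy_rank_prune(X)


def fit_ols(design: pd.DataFrame, y_log: Sequence[float] | np.ndarray) -> FitResult:
    """Ordinary least squares of the log trait on a design matrix.

    The log-likelihood is the Gaussian maximum at the MLE variance RSS/n; the
    coefficient covariance uses the unbiased RSS/(n - p).
    """
    y = np.asarray(y_log, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("log trait contains non-finite values")
    X, dropped = _greedy_rank_prune(design)
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least p + 1 = {p + 1} observations; got {n}")
    res = sm.OLS(y, X).fit()
    return FitResult(
        params=res.params,
        cov=res.cov_params(),
        rss=float(res.ssr),
        llf=float(res.llf),
        df_resid=float(res.df_resid),
        nobs=n,
        columns=tuple(X.columns),
        dropped=tuple(dropped),
        design=X,
    )


def lrt(fit_full: FitResult, fit_reduced: FitResult) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fits: 2 (l_full - l_reduced) ~ chi2(df).

    df is the difference in retained column counts.  Identical column sets
    give statistic 0 and p = 1.  Nesting is checked by column names, falling
    back to a numeric column-span check when names differ (e.g. the
    homogeneous model's shared dosage column equals the sum of the
    heterogeneous model's stratified columns).
    """
    if fit_full.nobs != fit_reduced.nobs:
        raise ValueError("fits use different numbers of observations")
    if not set(fit_reduced.columns) <= set(fit_full.columns):
        if fit_full.design is None or fit_reduced.design is None:
            raise ValueError(
                "models are not nested: reduced columns not a subset of full columns"
            )
        Xf = fit_full.design.to_numpy(dtype=float)
        Xr = fit_reduced.design.to_numpy(dtype=float)
        resid = Xr - Xf @ np.linalg.lstsq(Xf, Xr, rcond=None)[0]
        scale = max(float(np.linalg.norm(Xr)), 1.0)
        if np.linalg.norm(resid) > 1e-7 * scale:
            raise ValueError(
                "models are not nested: reduced design not in the span of the full design"
            )
    df = fit_full.n_params - fit_reduced.n_params
    statistic = max(0.0, 2.0 * (fit_full.llf - fit_reduced.llf))
    p = 1.0 if df == 0 else float(stats.chi2.sf(statistic, df))
    return statistic, df, p


def wald(
    fit_full: FitResult, tested: Sequence[str], use_f: bool = False
) -> tuple[float, int, float]:
    """Wald test that the named coefficients are jointly zero.

    The chi-squared statistic b_S' V_SS^{-1} b_S with the fit's coefficient
    covariance; ``use_f=True`` instead refers statistic/df to
    F(df, df_resid), the finite-sample variant.
    """
    tested = list(tested)
    missing = [c for c in tested if c not in fit_full.columns]
    if missing:
        raise ValueError(f"tested columns not retained in fit: {missing}")
    if not tested:
        raise ValueError("no columns to test")
    beta = fit_full.params[tested].to_numpy()
    V = fit_full.cov.loc[tested, tested].to_numpy()
    try:
        statistic = float(beta @ np.linalg.solve(V, beta))
    except np.linalg.LinAlgError as err:
        raise ValueError("singular covariance submatrix for the tested coefficients") from err
    df = len(tested)
    if use_f:
        p = float(stats.f.sf(statistic / df, df, fit_full.df_resid))
    else:
        p = float(stats.chi2.sf(statistic, df))
    return statistic, df, p


def stepwise_covariates(
    candidates: pd.DataFrame,
    y_log: Sequence[float] | np.ndarray,
    base: CovariateSet,
    alpha: float = 0.05,
) -> CovariateSet:
    """Forward stepwise covariate selection at a fixed entry level.

    Starting from intercept + the base covariates (global ancestry),
    repeatedly add the candidate with the smallest partial-F p-value while
    that p-value is below ``alpha``; ties break by candidate column order.
    Performed once per trait, before any marker scan.
    """
    y = np.asarray(y_log, dtype=float)
    current = base.frame.copy()
    remaining = list(candidates.columns)
    n = len(current)

    def rss_of(frame: pd.DataFrame) -> tuple[float, int]:
        X = pd.concat(
            [pd.DataFrame({"const": np.ones(n)}, index=frame.index), frame], axis=1
        )
        X, _ = _greedy_rank_prune(X)
        res = sm.OLS(y, X).fit()
        return float(res.ssr), X.shape[1]

    while remaining:
        rss0, p0 = rss_of(current)
        best = None
        for name in remaining:
            trial = pd.concat([current, candidates[[name]]], axis=1)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rss1, p1 = rss_of(trial)
            if p1 <= p0:  # candidate collinear with current set
                continue
            fstat = (rss0 - rss1) / (rss1 / (n - p1))
            pval = float(stats.f.sf(fstat, 1, n - p1))
            if best is None or pval < best[1]:
                best = (name, pval)
        if best is None or best[1] >= alpha:
            break
        current = pd.concat([current, candidates[[best[0]]]], axis=1)
        remaining.remove(best[0])
        logger.info("stepwise: entered %s (partial-F p = %.3g)", best[0], best[1])
    return CovariateSet(frame=current, global_columns=base.global_columns)


def predict_response(
    fit: FitResult | Mapping[str, float], profile: Mapping[str, float]
) -> float:
    """Expected trait on the original scale for a covariate/ancestry/genotype profile.

    Computes exp(linear predictor) with no retransformation correction.  The
    profile must supply a value for every retained design column (``const``
    defaults to 1 when omitted); missing entries are rejected.
    """
    params = fit.params if isinstance(fit, FitResult) else pd.Series(dict(fit))
    lp = 0.0
    for name, coef in params.items():
        if name == "const" and name not in profile:
            value = 1.0
        elif name in profile:
            value = float(profile[name])
        else:
            raise ValueError(f"profile missing a value for design column {name!r}")
        lp += float(coef) * value
    return float(np.exp(lp))


def percent_change(beta: float) -> float:
    """Percent change in the original-scale trait per unit of a log-scale coefficient.

    100 (e^beta - 1): e.g. beta = 0.14 reads as a 15% higher trait on average.
    """
    return float(100.0 * np.expm1(beta))


__all__ = [
    "CovariateSet",
    "FitResult",
    "ModelId",
    "build_design",
    "fit_ols",
    "lrt",
    "percent_change",
    "predict_response",
    "stepwise_covariates",
    "wald",
]
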