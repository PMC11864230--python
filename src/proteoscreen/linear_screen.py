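"""Covariate-adjusted linear models: exposure-outcome fits, heterogeneity
tests, and the proteome-wide exposure-mediator screen.

Two analysis surfaces share the same covariate conventions:

* :func:`fit_adjusted_ols` - a single ordinary-least-squares fit of an outcome
  on the standardized exposure plus covariates (optionally with interaction
  terms), returning point estimates and the classical covariance. This is the
  workhorse behind both the exposure-outcome models and the mediator/outcome
  equations of the four-way decomposition.
* :func:`mediator_screen` - one OLS fit per protein with an identical design
  matrix, Bonferroni correction at family size m = number of proteins, and a
  two-part selection rule: family-wise significance AND an absolute
  standardized effect above a threshold (default 0.20 SD of protein per SD of
  exposure). Because the design matrix is shared, the screen solves the normal
  equations once and applies them to the whole protein matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ModelFit",
    "fit_adjusted_ols",
    "heterogeneity_test",
    "mediator_screen",
]


@dataclass
class ModelFit:
    """OLS point estimates with their sampling covariance."""

    params: pd.Series
    cov: pd.DataFrame
    n_obs: int
    df_resid: int
    resid_var: float

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2.0 * stats.t.sf(np.abs(self.tvalues), self.df_resid), index=self.params.index
        )


def _find_collinear(X: pd.DataFrame) -> list[str]:
    """Name columns involved in a rank deficiency via pivoted QR."""
    arr = X.to_numpy(dtype=float)
    r = np.linalg.matrix_rank(arr)
    if r == arr.shape[1]:
        return []
    from scipy.linalg import qr

    _, _, piv = qr(arr, mode="economic", pivoting=True)
    return [X.columns[i] for i in sorted(piv[r:])]


def _design(
    exposure: pd.Series,
    covariates: pd.DataFrame | None,
    extra: pd.DataFrame | None = None,
) -> pd.DataFrame:
    parts = [exposure.rename(exposure.name or "exposure").to_frame()]
    if covariates is not None and covariates.shape[1] > 0:
        parts.append(covariates)
    if extra is not None:
        parts.append(extra)
    X = pd.concat(parts, axis=1)
    X.insert(0, "intercept", 1.0)
    return X


def fit_adjusted_ols(
    outcome: pd.Series,
    exposure: pd.Series,
    covariates: pd.DataFrame | None = None,
    extra_terms: pd.DataFrame | None = None,
    robust: bool = False,
) -> ModelFit:
    """Fit outcome ~ exposure + covariates (+ extra terms) by OLS.

    Listwise deletion on all supplied columns; classical (non-robust)
    covariance by default, HC1 when ``robust=True``. Raises on rank-deficient
    designs, naming the collinear columns.
    """
    X = _design(exposure, covariates, extra_terms)
    frame = pd.concat([outcome.rename("__y__"), X], axis=1).dropna()
    if len(frame) <= X.shape[1]:
        raise ValueError(
            f"too few complete cases ({len(frame)}) for {X.shape[1]} parameters"
        )
    y = frame["__y__"]
    Xc = frame.drop(columns="__y__")
    bad = _find_collinear(Xc)
    if bad:
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    model = sm.OLS(y, Xc)
    res = model.fit(cov_type="HC1" if robust else "nonrobust")
    return ModelFit(
        params=res.params,
        cov=pd.DataFrame(res.cov_params(), index=res.params.index, columns=res.params.index),
        n_obs=int(res.nobs),
        df_resid=int(res.df_resid),
        resid_var=float(res.scale),
    )


def heterogeneity_test(
    outcome: pd.Series,
    exposure: pd.Series,
    covariates: pd.DataFrame,
    modifier: pd.Series,
    categorical: bool | None = None,
) -> dict:
    """Wald test for exposure-by-modifier effect heterogeneity.

    Adds the modifier's main effect(s) and exposure x modifier product term(s)
    to the adjusted model and jointly tests the interaction coefficients. A
    modifier with more than two levels (e.g., a polygenic-risk tertile) is
    dummy-coded against its lowest level, contributing a (levels-1)-df test.

    Returns a dict with ``p_value``, ``statistic``, ``df``, and the fit.
    """
    mod_name = modifier.name or "modifier"
    levels = np.sort(pd.Series(modifier).dropna().unique())
    if len(levels) < 2:
        raise ValueError(f"modifier {mod_name!r} is constant in the analysis sample")
    if categorical is None:
        categorical = len(levels) > 2

    exp_name = exposure.name or "exposure"
    extra = {}
    inter_names = []
    if categorical:
        for lev in levels[1:]:
            d = (modifier == lev).astype(float)
            d[modifier.isna()] = np.nan
            extra[f"{mod_name}_{lev}"] = d
            inter_names.append(f"{exp_name}:{mod_name}_{lev}")
            extra[inter_names[-1]] = exposure * d
    else:
        mz = modifier.astype(float)
        extra[mod_name] = mz
        inter_names.append(f"{exp_name}:{mod_name}")
        extra[inter_names[-1]] = exposure * mz
    # drop modifier columns already present among the covariates to avoid
    # duplicating the main effect (e.g., sex is usually a covariate)
    covs = covariates.drop(columns=[mod_name], errors="ignore")
    fit = fit_adjusted_ols(outcome, exposure, covs, extra_terms=pd.DataFrame(extra))

    idx = [fit.params.index.get_loc(n) for n in inter_names]
    b = fit.params.iloc[idx].to_numpy()
    V = fit.cov.iloc[idx, idx].to_numpy()
    stat = float(b @ np.linalg.solve(V, b))
    df = len(idx)
    p = float(stats.chi2.sf(stat, df))
    return {"p_value": p, "statistic": stat, "df": df, "fit": fit, "terms": inter_names}


def mediator_screen(
    exposure: pd.Series,
    proteins: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    effect_threshold: float = 0.20,
    auto_standardize: bool = True,
) -> pd.DataFrame:
    """Proteome-wide exposure-mediator screen with Bonferroni + effect-size selection.

    Fits one covariate-adjusted OLS model per protein (protein as outcome,
    shared design), on complete cases across the exposure, covariates, and all
    proteins. Proteins whose within-sample SD falls outside [0.8, 1.2] are
    re-standardized with a warning (they are expected to enter z-scored).

    Returns a ScreenTable DataFrame indexed by protein with columns ``effect``
    (SD of protein per SD of exposure), ``se``, ``p``, ``p_bonferroni``
    (= min(1, m*p), m = number of proteins tested), ``neg_log10_p`` (volcano
    y-axis), and ``selected`` (p_bonferroni < alpha AND |effect| strictly >
    effect_threshold).
    """
    X = _design(exposure, covariates)
    frame = pd.concat([X, proteins], axis=1).dropna()
    Xc = frame[X.columns]
    Y = frame[proteins.columns]
    n, p = Xc.shape
    m = Y.shape[1]
    if n <= p:
        raise ValueError(f"too few complete cases ({n}) for {p} parameters")

    sds = Y.std(ddof=1)
    off = sds[(sds < 0.8) | (sds > 1.2)]
    Yv = Y.to_numpy(dtype=float)
    if len(off) > 0:
        if not auto_standardize:
            raise ValueError(f"unstandardized protein columns: {list(off.index)}")
        warnings.warn(
            f"{len(off)} protein column(s) with SD outside [0.8, 1.2]; re-standardizing",
            stacklevel=2,
        )
        Yv = (Yv - Yv.mean(axis=0)) / Yv.std(axis=0, ddof=1)

    Xv = Xc.to_numpy(dtype=float)
    xtx_inv = np.linalg.inv(Xv.T @ Xv)
    B = xtx_inv @ (Xv.T @ Yv)  # p x m coefficient matrix
    resid = Yv - Xv @ B
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    j = list(Xc.columns).index(exposure.name or "exposure")
    effect = B[j]
    se = np.sqrt(sigma2 * xtx_inv[j, j])
    tval = effect / se
    pval = 2.0 * stats.t.sf(np.abs(tval), dof)
    p_bonf = np.minimum(1.0, m * pval)
    selected = (p_bonf < alpha) & (np.abs(effect) > effect_threshold)

    table = pd.DataFrame(
        {
            "effect": effect,
            "se": se,
            "p": pval,
            "p_bonferroni": p_bonf,
            "neg_log10_p": -np.log10(np.maximum(pval, 1e-300)),
            "selected": selected,
        },
        index=pd.Index(proteins.columns, name="protein"),
    )
    table.attrs["family_size"] = m
    table.attrs["n_obs"] = n
    return table
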