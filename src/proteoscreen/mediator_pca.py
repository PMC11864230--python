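"""Aggregate selected mediators into varimax-rotated principal components and
feed the component scores back through the four-way decomposition.

PCA runs on the correlation matrix of the (standardized) mediators; components
are retained by the Kaiser rule (eigenvalue strictly greater than 1), rotated
by varimax with Kaiser normalization for interpretability, and per-subject
scores are predicted by the regression method and re-standardized to unit
variance. Each component score then acts as a composite mediator in its own
decomposition, overall and within strata (sex, polygenic-risk tertiles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fourway import DecompositionSpec, fourway_analysis

__all__ = ["PCAModel", "fit_pca", "varimax", "decompose_pc"]


@dataclass
class PCAModel:
    """Correlation-matrix PCA with Kaiser retention and varimax rotation.

    ``eigenvalues`` covers all input variables (non-increasing, sums to the
    number of proteins); ``loadings`` and ``scores`` only the retained,
    rotated components. ``variance_explained`` is per retained component,
    post-rotation (the retained total is rotation-invariant).
    """

    eigenvalues: np.ndarray
    loadings: pd.DataFrame
    variance_explained: np.ndarray
    scores: pd.DataFrame
    n_retained: int


def varimax(loadings: np.ndarray, normalize: bool = True, tol: float = 1e-8, max_iter: int = 1000) -> np.ndarray:
    """Orthogonal varimax rotation of a loading matrix.

    Maximizes the variance of squared loadings within each column; with
    ``normalize`` (Kaiser normalization) rows are scaled to unit communality
    during rotation. Returns the rotated loading matrix (same shape).
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L
    comm = None
    if normalize:
        comm = np.sqrt((L**2).sum(axis=1))
        comm[comm == 0] = 1.0
        L = L / comm[:, None]
    R = np.eye(k)
    var_old = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        )
        R = u @ vt
        var_new = s.sum()
        if var_new < var_old * (1 + tol):
            break
        var_old = var_new
    out = L @ R
    if normalize:
        out = out * comm[:, None]
    return out


def fit_pca(mediators: pd.DataFrame, retain: int | None = None) -> PCAModel:
    """Correlation-matrix PCA of standardized mediators.

    Parameters
    ----------
    mediators
        Subjects x proteins; columns are z-scored internally (a constant
        column raises). Requires at least two proteins.
    retain
        Override the Kaiser rule with a fixed component count.

    Notes
    -----
    Sign convention: each retained component is oriented so that its
    largest-|loading| protein loads positively. Regression-method scores are
    computed as Z R^-1 Lambda (Z the z-scored data, R the correlation matrix,
    Lambda the rotated loadings) and re-standardized to unit sample variance.
    """
    if mediators.shape[1] < 2:
        raise ValueError("PCA requires at least 2 proteins")
    X = mediators.dropna()
    sds = X.std(ddof=1)
    if (sds == 0).any():
        raise ValueError(f"constant mediator column(s): {list(sds.index[sds == 0])}")
    Z = (X - X.mean()) / sds
    Zv = Z.to_numpy(dtype=float)
    n, p = Zv.shape
    R = np.corrcoef(Zv, rowvar=False)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]

    k = int((evals > 1.0).sum()) if retain is None else int(retain)
    load = evecs[:, :k] * np.sqrt(np.maximum(evals[:k], 0.0))
    if k >= 2:
        load = varimax(load)
        # re-order rotated components by explained variance, descending
        ssl = (load**2).sum(axis=0)
        load = load[:, np.argsort(ssl)[::-1]]
    # sign convention
    for j in range(k):
        i_max = np.argmax(np.abs(load[:, j]))
        if load[i_max, j] < 0:
            load[:, j] = -load[:, j]

    cols = [f"PC{j + 1}" for j in range(k)]
    loadings = pd.DataFrame(load, index=mediators.columns, columns=cols)
    var_explained = (load**2).sum(axis=0) / p

    if k > 0:
        # pinv tolerates singular R (perfectly collinear mediators)
        S = Zv @ (np.linalg.pinv(R) @ load)
        S = (S - S.mean(axis=0)) / S.std(axis=0, ddof=1)
    else:
        S = np.empty((n, 0))
    scores = pd.DataFrame(S, index=X.index, columns=cols)
    return PCAModel(
        eigenvalues=evals,
        loadings=loadings,
        variance_explained=var_explained,
        scores=scores,
        n_retained=k,
    )


def decompose_pc(
    pc_scores: pd.DataFrame,
    exposure: pd.Series,
    outcome: pd.Series,
    covariates: pd.DataFrame,
    spec: DecompositionSpec | None = None,
    strata: dict[str, pd.Series] | None = None,
    restandardize_within_stratum: bool = False,
    min_stratum_n: int = 50,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Four-way decomposition of each PC score, overall and within strata.

    ``strata`` maps stratum labels to boolean masks over the subject index
    (the "overall" stratum is always included). Strata below
    ``min_stratum_n`` complete cases are skipped and recorded with NaN
    estimates. Returns a long DataFrame: one row per (component, stratum)
    with the component estimates, p-values, PIE share of TE, and the
    mediation class label.
    """
    strata = {"overall": pd.Series(True, index=pc_scores.index), **(strata or {})}
    rows = []
    for comp in pc_scores.columns:
        for label, mask in strata.items():
            mask = mask.reindex(pc_scores.index).fillna(False).astype(bool)
            score = pc_scores.loc[mask, comp]
            if restandardize_within_stratum and score.std(ddof=1) > 0:
                score = (score - score.mean()) / score.std(ddof=1)
            score = score.rename(comp)
            sub_exp = exposure.loc[score.index]
            sub_out = outcome.loc[score.index]
            sub_cov = covariates.loc[score.index]
            # stratifying variables become constant within their own strata
            sub_cov = sub_cov.loc[:, sub_cov.nunique(dropna=True) > 1]
            n_complete = pd.concat([sub_out, sub_exp, score, sub_cov], axis=1).dropna().shape[0]
            base = {"component": comp, "stratum": label, "n": n_complete}
            if n_complete < min_stratum_n:
                rows.append({**base, "skipped": True, "label": "skipped"})
                continue
            est, cls = fourway_analysis(
                sub_out, sub_exp, score, sub_cov, spec=spec, alpha=alpha
            )
            rows.append({**base, "skipped": False, "label": cls.label, **est.to_series().to_dict()})
    return pd.DataFrame(rows)
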