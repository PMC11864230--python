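"""Four-way decomposition of a total effect into direct, interactive, and
mediated components, with delta-method inference and mediation classification.

For a continuous outcome Y, continuous mediator M, exposure A and covariates C,
two linear models are fitted on the same analysis sample:

    mediator model:  E[M | a, c] = beta0 + beta1 * a + beta2' c
    outcome model:   E[Y | a, m, c] = theta0 + theta1 * a + theta2 * m
                                      + theta3 * a * m + theta4' c

For the exposure contrast (a, a*), mediator reference m*, and covariates fixed
at cbar, the total effect splits exactly into four components:

    CDE    = (theta1 + theta3 * m*) * (a - a*)
    INTREF = theta3 * (beta0 + beta1 * a* + beta2' cbar - m*) * (a - a*)
    INTMED = theta3 * beta1 * (a - a*)^2
    PIE    = (theta2 + theta3 * a*) * beta1 * (a - a*)
    TE     = CDE + INTREF + INTMED + PIE          (an algebraic identity)

CDE is the effect with the mediator controlled at m*; INTREF the interaction
operating without mediation; INTMED the interaction requiring mediation; PIE
the pure (mediation-only) indirect effect. When theta3 = 0 the interaction
components vanish and PIE reduces to the classical product of coefficients
theta2 * beta1 * (a - a*).

Standard errors come from the multivariate delta method on the stacked
parameter vector (theta-block, beta-block), treating the two fitted models'
parameter blocks as independent; p-values use the normal reference. A
nonparametric bootstrap is available to audit that approximation.

Mediation is classified per component signs, magnitudes and p-values:
"consistent" when the indirect path reinforces a significant total effect
(|CDE| < |TE|, PIE of the same sign as TE, and PIE either significant or
carrying >20% of TE), "inconsistent" when a significant PIE opposes it
(opposite sign, |CDE| > |TE|), else "none".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .linear_screen import ModelFit, fit_adjusted_ols

__all__ = [
    "DecompositionSpec",
    "FourWayEstimate",
    "MediationClass",
    "fit_mediator_model",
    "fit_outcome_model",
    "decompose",
    "delta_se",
    "proportions",
    "classify_mediation",
    "bootstrap_se",
    "fourway_analysis",
]

COMPONENTS = ("te", "cde", "intref", "intmed", "pie")


@dataclass
class DecompositionSpec:
    """Exposure contrast and reference levels for the decomposition.

    Defaults compare a = 1 vs a* = 0 on the standardized exposure scale (a
    one-SD contrast), with the mediator referenced at m* = 0 (its sample mean
    on the standardized scale) and covariates at their sample means.
    """

    a: float = 1.0
    a_star: float = 0.0
    m_star: float = 0.0
    covariate_values: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.a == self.a_star:
            raise ValueError("exposure contrast requires a != a_star")


@dataclass
class FourWayEstimate:
    """Point estimates (and, once filled, SEs, p-values, proportions of TE)."""

    te: float
    cde: float
    intref: float
    intmed: float
    pie: float
    se: dict[str, float] = field(default_factory=dict)
    p: dict[str, float] = field(default_factory=dict)
    prop: dict[str, float] = field(default_factory=dict)
    te_is_zero: bool = False

    def component(self, name: str) -> float:
        return getattr(self, name)

    def to_series(self) -> pd.Series:
        d = {c: self.component(c) for c in COMPONENTS}
        d.update({f"se_{k}": v for k, v in self.se.items()})
        d.update({f"p_{k}": v for k, v in self.p.items()})
        d.update({f"prop_{k}": v for k, v in self.prop.items()})
        return pd.Series(d)


@dataclass
class MediationClass:
    """Label in {none, consistent, inconsistent} plus the criteria that fired."""

    label: str
    rationale_flags: dict[str, bool]


def fit_mediator_model(
    mediator: pd.Series,
    exposure: pd.Series,
    covariates: pd.DataFrame | None = None,
    robust: bool = False,
) -> ModelFit:
    """OLS of the mediator on exposure + covariates (the beta equation)."""
    return fit_adjusted_ols(mediator, exposure, covariates, robust=robust)


def fit_outcome_model(
    outcome: pd.Series,
    exposure: pd.Series,
    mediator: pd.Series,
    covariates: pd.DataFrame | None = None,
    robust: bool = False,
) -> ModelFit:
    """OLS of the outcome on exposure, mediator, their product, + covariates.

    The product term is named ``<exposure>:<mediator>`` in the coefficient
    vector (the theta3 moderation coefficient).
    """
    exp_name = exposure.name or "exposure"
    med_name = mediator.name or "mediator"
    extra = pd.DataFrame(
        {med_name: mediator, f"{exp_name}:{med_name}": exposure * mediator}
    )
    return fit_adjusted_ols(outcome, exposure, covariates, extra_terms=extra, robust=robust)


def _names(outcome_fit: ModelFit, mediator_fit: ModelFit) -> tuple[str, str, str, list[str]]:
    """Resolve (exposure, mediator, interaction, covariate) coefficient names."""
    inter = [n for n in outcome_fit.params.index if ":" in n]
    if len(inter) != 1:
        raise ValueError(
            "outcome model must contain exactly one exposure:mediator product term"
        )
    inter_name = inter[0]
    exp_name, med_name = inter_name.split(":", 1)
    for name, fit, label in (
        (exp_name, outcome_fit, "outcome"),
        (med_name, outcome_fit, "outcome"),
        (exp_name, mediator_fit, "mediator"),
    ):
        if name not in fit.params.index:
            raise ValueError(f"coefficient {name!r} missing from the {label} model")
    med_covs = [n for n in mediator_fit.params.index if n not in ("intercept", exp_name)]
    out_covs = [
        n for n in outcome_fit.params.index if n not in ("intercept", exp_name, med_name, inter_name)
    ]
    if set(med_covs) != set(out_covs):
        raise ValueError(
            "mediator and outcome models must share the covariate set; "
            f"mismatch: {sorted(set(med_covs) ^ set(out_covs))}"
        )
    return exp_name, med_name, inter_name, med_covs


def decompose(
    outcome_fit: ModelFit,
    mediator_fit: ModelFit,
    spec: DecompositionSpec | None = None,
) -> FourWayEstimate:
    """Closed-form four-way decomposition from the two fitted linear models.

    The mediator and outcome fits must come from the same analysis sample and
    covariate set. Covariates without an entry in ``spec.covariate_values``
    contribute through value 0 (appropriate for centered covariates); pass the
    sample means otherwise (``fourway_analysis`` does this automatically).
    """
    spec = spec or DecompositionSpec()
    spec.validate()
    exp_name, med_name, inter_name, covs = _names(outcome_fit, mediator_fit)

    th1 = outcome_fit.params[exp_name]
    th2 = outcome_fit.params[med_name]
    th3 = outcome_fit.params[inter_name]
    b0 = mediator_fit.params["intercept"]
    b1 = mediator_fit.params[exp_name]
    cbar = np.array([spec.covariate_values.get(c, 0.0) for c in covs])
    b2c = float(mediator_fit.params[covs].to_numpy() @ cbar) if covs else 0.0

    d = spec.a - spec.a_star
    cde = (th1 + th3 * spec.m_star) * d
    intref = th3 * (b0 + b1 * spec.a_star + b2c - spec.m_star) * d
    intmed = th3 * b1 * d**2
    pie = (th2 + th3 * spec.a_star) * b1 * d
    te = cde + intref + intmed + pie
    return FourWayEstimate(te=te, cde=cde, intref=intref, intmed=intmed, pie=pie)


def _gradients(
    outcome_fit: ModelFit, mediator_fit: ModelFit, spec: DecompositionSpec
) -> tuple[dict[str, np.ndarray], list[str], list[str]]:
    """Analytic gradients of each component w.r.t. (theta-block, beta-block)."""
    exp_name, med_name, inter_name, covs = _names(outcome_fit, mediator_fit)
    th_names = [exp_name, med_name, inter_name]
    be_names = ["intercept", exp_name] + covs

    th3 = outcome_fit.params[inter_name]
    th2 = outcome_fit.params[med_name]
    b0 = mediator_fit.params["intercept"]
    b1 = mediator_fit.params[exp_name]
    cbar = np.array([spec.covariate_values.get(c, 0.0) for c in covs])
    b2c = float(mediator_fit.params[covs].to_numpy() @ cbar) if covs else 0.0
    d = spec.a - spec.a_star
    nb = len(be_names)

    def g(dth1=0.0, dth2=0.0, dth3=0.0, db0=0.0, db1=0.0, db2=None):
        vec = np.zeros(3 + nb)
        vec[0], vec[1], vec[2] = dth1, dth2, dth3
        vec[3], vec[4] = db0, db1
        if db2 is not None:
            vec[5:] = db2
        return vec

    grads = {
        "cde": g(dth1=d, dth3=spec.m_star * d),
        "intref": g(
            dth3=(b0 + b1 * spec.a_star + b2c - spec.m_star) * d,
            db0=th3 * d,
            db1=th3 * spec.a_star * d,
            db2=th3 * d * cbar if covs else None,
        ),
        "intmed": g(dth3=b1 * d**2, db1=th3 * d**2),
        "pie": g(dth2=b1 * d, dth3=b1 * spec.a_star * d, db1=(th2 + th3 * spec.a_star) * d),
    }
    grads["te"] = sum(grads[c] for c in ("cde", "intref", "intmed", "pie"))
    return grads, th_names, be_names


def delta_se(
    estimate: FourWayEstimate,
    outcome_fit: ModelFit,
    mediator_fit: ModelFit,
    spec: DecompositionSpec | None = None,
) -> FourWayEstimate:
    """Delta-method SEs and two-sided normal p-values for every component.

    The joint covariance stacks the outcome-model block (theta1, theta2,
    theta3) and the full mediator-model block (beta0, beta1, covariate
    coefficients) as independent; within-block covariances are the classical
    OLS ones. INTREF depends on the mediator-model covariate coefficients
    through beta2' cbar, so their covariance enters its SE.
    """
    spec = spec or DecompositionSpec()
    grads, th_names, be_names = _gradients(outcome_fit, mediator_fit, spec)
    V_th = outcome_fit.cov.loc[th_names, th_names].to_numpy()
    V_be = mediator_fit.cov.loc[be_names, be_names].to_numpy()
    nt = len(th_names)
    V = np.zeros((nt + len(be_names), nt + len(be_names)))
    V[:nt, :nt] = V_th
    V[nt:, nt:] = V_be

    se, p = {}, {}
    for comp, grad in grads.items():
        var = float(grad @ V @ grad)
        if var < 0:
            raise ValueError(f"negative delta-method variance for {comp}")
        se[comp] = np.sqrt(var)
        est = estimate.component(comp)
        p[comp] = 2.0 * stats.norm.sf(abs(est) / se[comp]) if se[comp] > 0 else (0.0 if est else 1.0)
    return replace(estimate, se=se, p=p)


def numeric_gradient_check(
    outcome_fit: ModelFit,
    mediator_fit: ModelFit,
    spec: DecompositionSpec,
    eps: float = 1e-6,
) -> float:
    """Max relative disagreement between analytic and central-difference gradients."""
    grads, th_names, be_names = _gradients(outcome_fit, mediator_fit, spec)

    def eval_components(th_vals, be_vals):
        of = replace(outcome_fit, params=outcome_fit.params.copy())
        mf = replace(mediator_fit, params=mediator_fit.params.copy())
        of.params[th_names] = th_vals
        mf.params[be_names] = be_vals
        est = decompose(of, mf, spec)
        return np.array([est.component(c) for c in COMPONENTS])

    th0 = outcome_fit.params[th_names].to_numpy().copy()
    be0 = mediator_fit.params[be_names].to_numpy().copy()
    x0 = np.concatenate([th0, be0])
    num = np.zeros((len(COMPONENTS), len(x0)))
    for i in range(len(x0)):
        xp, xm = x0.copy(), x0.copy()
        h = eps * max(1.0, abs(x0[i]))
        xp[i] += h
        xm[i] -= h
        fp = eval_components(xp[: len(th0)], xp[len(th0):])
        fm = eval_components(xm[: len(th0)], xm[len(th0):])
        num[:, i] = (fp - fm) / (2 * h)
    ana = np.vstack([grads[c] for c in COMPONENTS])
    scale = np.maximum(np.abs(ana), 1.0)
    return float(np.max(np.abs(num - ana) / scale))


def proportions(estimate: FourWayEstimate) -> FourWayEstimate:
    """Each component as a proportion of the total effect (prop_* = x / te).

    Proportions sum to 1 by construction. A numerically zero total effect is
    flagged (``te_is_zero``) and yields NaN proportions.
    """
    if estimate.te == 0.0:
        prop = {c: float("nan") for c in COMPONENTS if c != "te"}
        return replace(estimate, prop=prop, te_is_zero=True)
    prop = {c: estimate.component(c) / estimate.te for c in COMPONENTS if c != "te"}
    return replace(estimate, prop=prop)


def classify_mediation(
    estimate: FourWayEstimate,
    alpha: float = 0.05,
    prop_threshold: float = 0.20,
) -> MediationClass:
    """Classify the mediation pattern as none / consistent / inconsistent.

    consistent:   p_te < alpha AND |cde| < |te| AND sign(pie) = sign(te)
                  AND (p_pie < alpha OR prop_pie > prop_threshold)
    inconsistent: p_pie < alpha AND |cde| > |te| AND sign(pie) != sign(te)
    none:         otherwise
    """
    if "te" not in estimate.p or "pie" not in estimate.p:
        raise ValueError("classification requires p-values; run delta_se first")
    if not estimate.prop:
        estimate = proportions(estimate)
    flags = {
        "te_significant": estimate.p["te"] < alpha,
        "pie_significant": estimate.p["pie"] < alpha,
        "cde_smaller_than_te": abs(estimate.cde) < abs(estimate.te),
        "pie_same_sign_as_te": np.sign(estimate.pie) == np.sign(estimate.te),
        "pie_share_above_threshold": bool(
            not estimate.te_is_zero and estimate.prop.get("pie", np.nan) > prop_threshold
        ),
    }
    consistent = (
        flags["te_significant"]
        and flags["cde_smaller_than_te"]
        and flags["pie_same_sign_as_te"]
        and (flags["pie_significant"] or flags["pie_share_above_threshold"])
    )
    inconsistent = (
        flags["pie_significant"]
        and not flags["cde_smaller_than_te"]
        and not flags["pie_same_sign_as_te"]
    )
    label = "consistent" if consistent else "inconsistent" if inconsistent else "none"
    return MediationClass(label=label, rationale_flags=flags)


def bootstrap_se(
    outcome: pd.Series,
    exposure: pd.Series,
    mediator: pd.Series,
    covariates: pd.DataFrame | None,
    spec: DecompositionSpec | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, float]:
    """Nonparametric bootstrap SEs of the four components (audit for delta_se)."""
    spec = spec or DecompositionSpec()
    rng = np.random.default_rng(seed)
    frame = pd.concat(
        [outcome.rename("__y__"), exposure, mediator]
        + ([covariates] if covariates is not None else []),
        axis=1,
    ).dropna().reset_index(drop=True)
    n = len(frame)
    cov_cols = list(covariates.columns) if covariates is not None else []
    draws = {c: np.empty(n_boot) for c in COMPONENTS}
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        fb = frame.iloc[idx]
        covs = fb[cov_cols] if cov_cols else None
        of = fit_outcome_model(fb["__y__"], fb[exposure.name], fb[mediator.name], covs)
        mf = fit_mediator_model(fb[mediator.name], fb[exposure.name], covs)
        est = decompose(of, mf, spec)
        for c in COMPONENTS:
            draws[c][b] = est.component(c)
    return {c: float(np.std(draws[c], ddof=1)) for c in COMPONENTS}


def fourway_analysis(
    outcome: pd.Series,
    exposure: pd.Series,
    mediator: pd.Series,
    covariates: pd.DataFrame | None = None,
    spec: DecompositionSpec | None = None,
    alpha: float = 0.05,
    prop_threshold: float = 0.20,
) -> tuple[FourWayEstimate, MediationClass]:
    """Convenience wrapper: fit both models, decompose, infer, and classify.

    Covariate reference values default to the complete-case sample means
    (population-averaged INTREF). Complete cases are shared across both model
    fits so the decomposition identity holds exactly.
    """
    parts = [outcome.rename("__y__"), exposure, mediator]
    if covariates is not None:
        parts.append(covariates)
    frame = pd.concat(parts, axis=1).dropna()
    covs = frame[list(covariates.columns)] if covariates is not None else None
    spec = spec or DecompositionSpec()
    if covs is not None and not spec.covariate_values:
        spec = replace(spec, covariate_values={c: float(covs[c].mean()) for c in covs.columns})
    of = fit_outcome_model(frame["__y__"], frame[exposure.name], frame[mediator.name], covs)
    mf = fit_mediator_model(frame[mediator.name], frame[exposure.name], covs)
    est = decompose(of, mf, spec)
    est = delta_se(est, of, mf, spec)
    est = proportions(est)
    return est, classify_mediation(est, alpha=alpha, prop_threshold=prop_threshold)
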