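"""Shared fixtures and the counterfactual simulation oracle.

The oracle estimates the four effect components by brute-force simulation of
the potential outcomes Y(a, M(a*)) etc. under known linear model parameters;
it never calls the closed-form decomposition it is used to check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from proteoscreen import CohortSpec, generate_cohort, reverse_z

ANALYSIS_COVARIATES = ["age", "sex", "race_minority", "household_size", "ses_z", "time_elapsed_days"]


@dataclass
class OracleResult:
    estimates: dict[str, float]
    mc_se: dict[str, float]


def counterfactual_oracle(
    theta: tuple[float, float, float, float],
    beta: tuple[float, float],
    a: float,
    a_star: float,
    m_star: float,
    sigma_m: float = 1.0,
    n_draws: int = 1_000_000,
    seed: int = 0,
) -> OracleResult:
    """Monte-Carlo potential-outcome contrasts for the four-way decomposition.

    theta = (theta0, theta1, theta2, theta3) of the outcome model, beta =
    (beta0, beta1) of the mediator model (no covariates; covariate terms fold
    into the intercepts). Outcome noise cancels in every contrast, so only
    mediator noise is simulated; each component is a mean of per-draw
    contrasts with its plain Monte-Carlo standard error.
    """
    th0, th1, th2, th3, = theta
    b0, b1 = beta
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(n_draws) * sigma_m
    m_a = b0 + b1 * a + eps  # shared noise draw across counterfactual levels
    m_astar = b0 + b1 * a_star + eps

    def y(a_val, m_val):
        return th0 + th1 * a_val + th2 * m_val + th3 * a_val * m_val

    cde = y(a, m_star) - y(a_star, m_star)  # deterministic
    intref_draws = (y(a, m_astar) - y(a_star, m_astar)) - cde
    intmed_draws = y(a, m_a) - y(a_star, m_a) - y(a, m_astar) + y(a_star, m_astar)
    pie_draws = y(a_star, m_a) - y(a_star, m_astar)
    te_draws = y(a, m_a) - y(a_star, m_astar)

    out, se = {}, {}
    for name, draws in (
        ("te", te_draws),
        ("intref", intref_draws),
        ("intmed", intmed_draws),
        ("pie", pie_draws),
    ):
        out[name] = float(np.mean(draws))
        se[name] = float(np.std(draws, ddof=1) / np.sqrt(n_draws))
    out["cde"] = float(cde)
    se["cde"] = 0.0
    return OracleResult(estimates=out, mc_se=se)


@pytest.fixture(scope="session")
def small_cohort():
    """n=5000 cohort with 3 planted mediators out of 10 proteins."""
    spec = CohortSpec(n_subjects=5000, n_proteins=10, n_true_mediators=3, seed=7)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def single_mediator_cohort():
    """n=5000 cohort with one planted mediator (clean product-path truth)."""
    spec = CohortSpec(n_subjects=5000, n_proteins=4, n_true_mediators=1, seed=11)
    return generate_cohort(spec)


@pytest.fixture()
def analysis_frame(small_cohort):
    """Exposure, covariates and latent outcome ready for model fitting."""
    df = small_cohort.data
    exposure = reverse_z(df["le8_total"]).values.rename("le8_z_rev")
    covariates = df[ANALYSIS_COVARIATES]
    return small_cohort, exposure, covariates
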