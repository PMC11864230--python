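"""Four-way decomposition: closed forms, counterfactual oracle, delta-method
inference, proportions, and the mediation classifier."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proteoscreen import (
    DecompositionSpec,
    classify_mediation,
    decompose,
    delta_se,
    fit_mediator_model,
    fit_outcome_model,
    fourway_analysis,
    proportions,
    reference_estimate,
    reverse_z,
)
from proteoscreen.fourway import COMPONENTS, bootstrap_se, numeric_gradient_check
from proteoscreen.linear_screen import ModelFit
from proteoscreen.reference import REFERENCE_PROTEINS, load_reference_table

from conftest import ANALYSIS_COVARIATES, counterfactual_oracle


def mk_fit(params: dict, cov: pd.DataFrame | None = None, n=1000) -> ModelFit:
    s = pd.Series(params, dtype=float)
    if cov is None:
        cov = pd.DataFrame(0.0, index=s.index, columns=s.index)
    return ModelFit(params=s, cov=cov, n_obs=n, df_resid=n - len(s), resid_var=1.0)


def outcome_fit(th0=0.0, th1=0.5, th2=0.3, th3=0.0, cov=None):
    return mk_fit({"intercept": th0, "A": th1, "M": th2, "A:M": th3}, cov)


def mediator_fit(b0=0.0, b1=0.4, cov=None):
    return mk_fit({"intercept": b0, "A": b1}, cov)


class TestClosedForms:
    def test_no_interaction_reduces_to_product_of_coefficients(self):
        est = decompose(outcome_fit(), mediator_fit())
        assert est.cde == pytest.approx(0.5)
        assert est.intref == 0.0 and est.intmed == 0.0
        assert est.pie == pytest.approx(0.12)
        assert est.te == pytest.approx(0.62)

    def test_theta3_zero_kills_interaction_components_exactly(self):
        est = decompose(outcome_fit(th1=0.2, th2=0.7, th3=0.0), mediator_fit(b0=1.3, b1=-0.6),
                        DecompositionSpec(a=2.0, a_star=-1.0, m_star=0.7))
        assert est.intref == 0.0 and est.intmed == 0.0

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        th1=st.floats(-1, 1), th2=st.floats(-1, 1), th3=st.floats(-1, 1),
        b0=st.floats(-1, 1), b1=st.floats(-1, 1),
        a=st.floats(-2, 2), a_star=st.floats(-2, 2), m_star=st.floats(-1, 1),
    )
    def test_additivity_identity_for_any_parameters(self, th1, th2, th3, b0, b1, a, a_star, m_star):
        if a == a_star:
            a += 0.5
        spec = DecompositionSpec(a=a, a_star=a_star, m_star=m_star)
        est = decompose(outcome_fit(th1=th1, th2=th2, th3=th3), mediator_fit(b0=b0, b1=b1), spec)
        assert est.te == pytest.approx(est.cde + est.intref + est.intmed + est.pie, abs=1e-12)

    def test_swapping_contrast_negates_all_but_intmed(self):
        of, mf = outcome_fit(th1=0.1, th2=0.3, th3=0.2), mediator_fit(b0=0.2, b1=0.4)
        fwd = decompose(of, mf, DecompositionSpec(a=1.0, a_star=0.0, m_star=0.1))
        rev = decompose(of, mf, DecompositionSpec(a=0.0, a_star=1.0, m_star=0.1))
        assert rev.intmed == pytest.approx(fwd.intmed, abs=1e-12)
        # the other components are not simply negated (the reference exposure
        # level enters INTREF and PIE), but the total effect is
        assert rev.te == pytest.approx(-fwd.te, abs=1e-12)
        assert rev.cde == pytest.approx(-fwd.cde, abs=1e-12)

    def test_mismatched_covariate_sets_raise(self):
        of = mk_fit({"intercept": 0, "A": 0.1, "M": 0.3, "A:M": 0.2, "age": 0.01})
        mf = mk_fit({"intercept": 0, "A": 0.4, "sex": 0.2})
        with pytest.raises(ValueError, match="covariate"):
            decompose(of, mf)

    def test_same_contrast_rejected(self):
        with pytest.raises(ValueError, match="a != a_star"):
            decompose(outcome_fit(), mediator_fit(), DecompositionSpec(a=1.0, a_star=1.0))


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_components_match_counterfactual_simulation(self, seed):
        rng = np.random.default_rng(seed)
        th1, th2, th3, b0, b1 = rng.uniform(-0.5, 0.5, 5)
        th3 = th3 + np.sign(th3 or 1) * 0.2  # keep the interaction away from 0
        spec = DecompositionSpec(a=1.0, a_star=0.0, m_star=float(rng.uniform(-0.5, 0.5)))
        est = decompose(outcome_fit(th1=th1, th2=th2, th3=th3), mediator_fit(b0=b0, b1=b1), spec)
        oracle = counterfactual_oracle(
            (0.0, th1, th2, th3), (b0, b1), spec.a, spec.a_star, spec.m_star,
            n_draws=400_000, seed=seed + 100,
        )
        for comp in COMPONENTS:
            tol = max(3 * oracle.mc_se[comp], 1e-12)
            assert est.component(comp) == pytest.approx(oracle.estimates[comp], abs=tol)


class TestModelFitting:
    def test_planted_mediator_and_interaction_coefficients_recovered(self, single_mediator_cohort):
        c = single_mediator_cohort
        exp = reverse_z(c.data["le8_total"]).values.rename("le8_z_rev")
        covs = c.data[ANALYSIS_COVARIATES]
        med = c.data["prot_0000"].rename("prot_0000")
        mf = fit_mediator_model(med, exp, covs)
        assert abs(mf.params["le8_z_rev"] - c.truth["alpha"][0]) < 3 * mf.bse["le8_z_rev"]
        of = fit_outcome_model(c.latent_outcome("OD_mean"), exp, med, covs)
        assert abs(of.params["prot_0000"] - c.truth["beta"][0]) < 3 * of.bse["prot_0000"]
        assert abs(of.params["le8_z_rev:prot_0000"] - 0.0) < 3 * of.bse["le8_z_rev:prot_0000"]

    def test_permuted_exposure_gives_null_slope(self, single_mediator_cohort):
        c = single_mediator_cohort
        rng = np.random.default_rng(0)
        exp = reverse_z(c.data["le8_total"]).values.rename("le8_z_rev")
        perm = pd.Series(rng.permutation(exp.to_numpy()), index=exp.index, name="le8_z_rev")
        mf = fit_mediator_model(c.data["prot_0000"].rename("prot_0000"), perm, c.data[ANALYSIS_COVARIATES])
        assert abs(mf.params["le8_z_rev"]) < 4 * mf.bse["le8_z_rev"]

    def test_theta3_recovered_when_planted(self):
        from proteoscreen import CohortSpec, generate_cohort

        c = generate_cohort(CohortSpec(
            n_subjects=20000, n_proteins=2, n_true_mediators=1, interaction_theta3=0.2, seed=5,
        ))
        exp = reverse_z(c.data["le8_total"]).values.rename("le8_z_rev")
        of = fit_outcome_model(
            c.latent_outcome("OD_mean"), exp, c.data["prot_0000"].rename("prot_0000"),
            c.data[ANALYSIS_COVARIATES],
        )
        name = "le8_z_rev:prot_0000"
        assert abs(of.params[name] - 0.2) < 3 * of.bse[name]


class TestDeltaMethod:
    def test_zero_covariance_gives_zero_ses(self):
        est = decompose(outcome_fit(th3=0.2), mediator_fit())
        est = delta_se(est, outcome_fit(th3=0.2), mediator_fit())
        assert all(se == 0.0 for se in est.se.values())

    def test_analytic_gradients_match_numeric(self, single_mediator_cohort):
        c = single_mediator_cohort
        exp = reverse_z(c.data["le8_total"]).values.rename("le8_z_rev")
        covs = c.data[ANALYSIS_COVARIATES]
        med = c.data["prot_0000"].rename("prot_0000")
        of = fit_outcome_model(c.latent_outcome("OD_mean"), exp, med, covs)
        mf = fit_mediator_model(med, exp, covs)
        spec = DecompositionSpec(covariate_values={k: float(covs[k].mean()) for k in covs})
        assert numeric_gradient_check(of, mf, spec) < 1e-6

    def test_pie_se_reduces_to_product_delta_form_when_theta3_fixed_zero(self):
        rng = np.random.default_rng(0)
        var_th2, var_b1 = 0.01, 0.02
        th2, b1 = 0.3, 0.4
        cov_of = pd.DataFrame(0.0, index=["intercept", "A", "M", "A:M"], columns=["intercept", "A", "M", "A:M"])
        cov_of.loc["M", "M"] = var_th2
        cov_mf = pd.DataFrame(0.0, index=["intercept", "A"], columns=["intercept", "A"])
        cov_mf.loc["A", "A"] = var_b1
        of = outcome_fit(th2=th2, th3=0.0, cov=cov_of)
        mf = mediator_fit(b1=b1, cov=cov_mf)
        est = delta_se(decompose(of, mf), of, mf)
        expected = np.sqrt(th2**2 * var_b1 + b1**2 * var_th2)
        assert est.se["pie"] == pytest.approx(expected, rel=1e-12)

    def test_delta_ses_agree_with_bootstrap(self):
        from proteoscreen import CohortSpec, generate_cohort

        c = generate_cohort(CohortSpec(
            n_subjects=4000, n_proteins=2, n_true_mediators=1, interaction_theta3=0.15, seed=13,
        ))
        exp = reverse_z(c.data["le8_total"]).values.rename("le8_z_rev")
        covs = c.data[ANALYSIS_COVARIATES]
        med = c.data["prot_0000"].rename("prot_0000")
        y = c.latent_outcome("OD_mean").rename("y")
        spec = DecompositionSpec(covariate_values={k: float(covs[k].mean()) for k in covs})
        of = fit_outcome_model(y, exp, med, covs)
        mf = fit_mediator_model(med, exp, covs)
        est = delta_se(decompose(of, mf, spec), of, mf, spec)
        boot = bootstrap_se(y, exp, med, covs, spec, n_boot=600, seed=1)
        for comp in ("te", "cde", "intmed", "pie"):
            assert est.se[comp] == pytest.approx(boot[comp], rel=0.15)


class TestProportionsAndClassification:
    def test_proportions_sum_to_one(self):
        est = proportions(decompose(outcome_fit(th3=0.2), mediator_fit(b0=0.3)))
        assert sum(est.prop.values()) == pytest.approx(1.0)

    def test_cde_equals_te_gives_prop_one(self):
        est = proportions(decompose(outcome_fit(th1=0.5, th2=0.0, th3=0.0), mediator_fit(b1=0.0)))
        assert est.prop["cde"] == pytest.approx(1.0)
        assert est.prop["pie"] == pytest.approx(0.0)

    def test_zero_te_flagged(self):
        est = proportions(decompose(outcome_fit(th1=0.0, th2=0.0, th3=0.0), mediator_fit(b1=0.0)))
        assert est.te_is_zero
        assert np.isnan(est.prop["pie"])

    def test_published_leptin_row_classifies_consistent(self):
        est = reference_estimate("LEP", "OD_mean")
        assert classify_mediation(est).label == "consistent"

    def test_published_rows_all_classify_consistent_on_both_outcomes(self):
        tab = load_reference_table()
        for protein in REFERENCE_PROTEINS:
            for outcome in ("FA_mean", "OD_mean"):
                est = reference_estimate(protein, outcome, tab)
                assert classify_mediation(est).label == "consistent", (protein, outcome)

    def test_insignificant_total_effect_gates_to_none(self):
        est = reference_estimate("LEP", "OD_mean")
        est.p["te"] = 0.20
        assert classify_mediation(est).label == "none"

    def test_opposing_significant_pie_with_larger_cde_is_inconsistent(self):
        from proteoscreen import FourWayEstimate

        est = FourWayEstimate(te=0.05, cde=0.09, intref=0.0, intmed=0.0, pie=-0.04)
        est.p = {"te": 0.01, "cde": 0.001, "intref": 0.9, "intmed": 0.9, "pie": 0.01}
        est = proportions(est)
        assert classify_mediation(est).label == "inconsistent"

    def test_pie_share_alone_can_carry_consistency(self):
        from proteoscreen import FourWayEstimate

        # PIE not individually significant but >20% of a significant TE
        est = FourWayEstimate(te=0.10, cde=0.07, intref=0.0, intmed=0.0, pie=0.03)
        est.p = {"te": 0.001, "cde": 0.01, "intref": 0.9, "intmed": 0.9, "pie": 0.30}
        est = proportions(est)
        assert classify_mediation(est).label == "consistent"

    def test_requires_inference_before_classification(self):
        est = decompose(outcome_fit(), mediator_fit())
        with pytest.raises(ValueError, match="p-values"):
            classify_mediation(est)


def test_end_to_end_additivity_on_fitted_models(analysis_frame):
    cohort, exposure, covs = analysis_frame
    est, _ = fourway_analysis(
        cohort.latent_outcome("OD_mean").rename("y"), exposure,
        cohort.data["prot_0000"].rename("prot_0000"), covs,
    )
    assert est.te == pytest.approx(est.cde + est.intref + est.intmed + est.pie, abs=1e-12)
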