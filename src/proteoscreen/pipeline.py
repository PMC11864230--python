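"""End-to-end orchestration of the mediation-moderation analysis.

Seven stages, mirroring how a cohort analysis of cardiovascular health and
white-matter microstructure proceeds:

1. descriptive statistics by sex;
2. covariate-adjusted exposure-outcome models on the raw outcome scales, with
   sex and polygenic-risk-tertile heterogeneity tests and sex stratification;
3. the proteome-wide exposure-mediator screen (Bonferroni + effect-size
   selection, with a configurable gate: the effect-size filter engages only
   when the Bonferroni-significant set is large);
4. four-way decomposition of each selected mediator against each z-scored
   outcome, with mediation classification;
5. intersection of consistent mediators across outcomes;
6. PCA aggregation of the shared consistent mediators and decomposition of
   the component scores, overall and within strata;
7. association of each shared mediator with the reverse-z-coded exposure
   sub-scores and components (heatmap-ready long table).

Every artifact is a plain TSV/CSV/JSON file under ``output_dir``; the run is
a pure function of (inputs, config, seed). Each fitted model receives a
sequential model id recorded both in the output tables and in ``models.log``.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import le8_scoring
from .fourway import DecompositionSpec, fourway_analysis
from .linear_screen import fit_adjusted_ols, heterogeneity_test, mediator_screen
from .mediator_pca import decompose_pc, fit_pca
from .synthetic_cohort import Cohort

__all__ = ["PipelineConfig", "run_pipeline", "shared_consistent_mediators"]

DEFAULT_COVARIATES = [
    "age", "sex", "race_minority", "household_size", "ses_z", "time_elapsed_days",
]
DEFAULT_OUTCOMES = ["FA_mean", "MD_mean", "ISOVF_mean", "ICVF_mean", "OD_mean"]


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline` (loadable from YAML/JSON)."""

    cohort_csv: str | None = None
    truth_json: str | None = None
    output_dir: str = "proteoscreen_out"
    exposure_column: str = "le8_total"
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    outcomes: list[str] = field(default_factory=lambda: list(DEFAULT_OUTCOMES))
    primary_outcomes: list[str] = field(default_factory=lambda: ["FA_mean", "OD_mean"])
    alpha: float = 0.05
    effect_threshold: float = 0.20
    screen_gate: int = 500
    a: float = 1.0
    a_star: float = 0.0
    m_star: float = 0.0
    mode: str = "selected"  # or "proteome-wide"
    restandardize_within_stratum: bool = False
    min_stratum_n: int = 50
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.mode not in ("selected", "proteome-wide"):
            raise ValueError("mode must be 'selected' or 'proteome-wide'")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)


class _ModelLog:
    def __init__(self) -> None:
        self.rows: list[dict] = []

    def record(self, stage: str, description: str, n_obs: int) -> str:
        mid = f"m{len(self.rows):04d}"
        self.rows.append({"model_id": mid, "stage": stage, "description": description, "n": n_obs})
        return mid


def _zscore(s: pd.Series) -> pd.Series:
    return (s - s.mean()) / s.std(ddof=1)


def _descriptives(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Means +/- SE overall and by sex, with a sex-difference p-value from a
    bivariate linear model (continuous) or a proportion comparison (binary)."""
    rows = []
    men = df[df["sex"] == 0]
    women = df[df["sex"] == 1]
    for col in columns:
        s = df[col].dropna()
        fit = fit_adjusted_ols(df[col], df["sex"].rename("sex_indicator"))
        rows.append(
            {
                "variable": col,
                "mean_overall": s.mean(),
                "se_overall": s.std(ddof=1) / np.sqrt(len(s)),
                "mean_men": men[col].mean(),
                "mean_women": women[col].mean(),
                "p_sex": fit.pvalues["sex_indicator"],
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, cohort: Cohort | None = None) -> dict:
    """Execute all stages; returns the run report (also written as JSON)."""
    config.validate()
    t0 = time.time()
    if cohort is None:
        if config.cohort_csv is None or config.truth_json is None:
            raise ValueError("either pass a Cohort or set cohort_csv + truth_json")
        cohort = Cohort.from_files(config.cohort_csv, config.truth_json)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _ModelLog()
    df = cohort.data
    report: dict = {"seed": config.seed, "stages": {}}

    # --- exposure -------------------------------------------------------
    rz = le8_scoring.reverse_z(df[config.exposure_column])
    exposure = rz.values.rename("le8_z_rev")
    covs = df[config.covariates]

    # --- stage 1: descriptives ------------------------------------------
    stage1_cols = [config.exposure_column] + config.covariates + config.outcomes
    stage1_cols = [c for c in dict.fromkeys(stage1_cols) if c != "sex"]
    desc = _descriptives(df, stage1_cols)
    desc.to_csv(out / "descriptives.tsv", sep="\t", index=False)
    report["stages"]["descriptives"] = {"n_subjects": int(len(df)), "n_variables": len(desc)}

    # --- stage 2: exposure-outcome models (raw scale) -------------------
    rows = []
    sex = df["sex"].rename("sex")
    prs = df["prs_tertile"].rename("prs_tertile")
    for y in config.outcomes:
        fit = fit_adjusted_ols(df[y], exposure, covs)
        mid = log.record("exposure_outcome", f"{y} ~ le8_z_rev + covariates", fit.n_obs)
        het_sex = heterogeneity_test(df[y], exposure, covs, sex)
        het_prs = heterogeneity_test(df[y], exposure, covs, prs, categorical=True)
        row = {
            "outcome": y,
            "stratum": "overall",
            "beta": fit.params["le8_z_rev"],
            "se": fit.bse["le8_z_rev"],
            "p": fit.pvalues["le8_z_rev"],
            "n": fit.n_obs,
            "p_sex_interaction": het_sex["p_value"],
            "p_prs_interaction": het_prs["p_value"],
            "model_id": mid,
        }
        rows.append(row)
        for label, mask in (("men", df["sex"] == 0), ("women", df["sex"] == 1)):
            sub = df[mask]
            sub_exp = exposure[mask]
            sfit = fit_adjusted_ols(sub[y], sub_exp, sub[[c for c in config.covariates if c != "sex"]])
            mid = log.record("exposure_outcome", f"{y} ~ le8_z_rev | {label}", sfit.n_obs)
            rows.append(
                {
                    "outcome": y,
                    "stratum": label,
                    "beta": sfit.params["le8_z_rev"],
                    "se": sfit.bse["le8_z_rev"],
                    "p": sfit.pvalues["le8_z_rev"],
                    "n": sfit.n_obs,
                    "model_id": mid,
                }
            )
    exp_out = pd.DataFrame(rows)
    exp_out.to_csv(out / "exposure_outcome.tsv", sep="\t", index=False)
    report["stages"]["exposure_outcome"] = {"n_models": len(rows)}

    # --- stage 3: mediator screen ---------------------------------------
    proteins = df[cohort.protein_columns]
    screen = mediator_screen(
        exposure, proteins, covs, alpha=config.alpha, effect_threshold=config.effect_threshold
    )
    n_bonf = int((screen["p_bonferroni"] < config.alpha).sum())
    if n_bonf <= config.screen_gate:
        # modest Bonferroni-significant set: skip the effect-size filter
        screen["selected"] = screen["p_bonferroni"] < config.alpha
    selected = list(screen.index[screen["selected"]])
    screen.to_csv(out / "screen.tsv", sep="\t")
    screen[["effect", "neg_log10_p", "selected"]].to_csv(out / "volcano.csv")
    report["stages"]["screen"] = {
        "proteins_tested": int(screen.shape[0]),
        "bonferroni_significant": n_bonf,
        "effect_filter_applied": n_bonf > config.screen_gate,
        "selected": len(selected),
    }

    # --- stage 4: four-way decomposition --------------------------------
    spec = DecompositionSpec(a=config.a, a_star=config.a_star, m_star=config.m_star)
    decompose_set = list(proteins.columns) if config.mode == "proteome-wide" else selected
    fw_rows = []
    for y in config.outcomes:
        y_z = _zscore(df[y]).rename(f"{y}_z")
        for prot in decompose_set:
            est, cls = fourway_analysis(
                y_z, exposure, df[prot].rename(prot), covs, spec=spec, alpha=config.alpha
            )
            mid = log.record("fourway", f"{y}_z ~ le8_z_rev * {prot}", int(len(df)))
            row = {"outcome": y, "protein": prot, "label": cls.label, "model_id": mid}
            if config.mode == "proteome-wide":
                row["te_pie_significant"] = bool(
                    est.p["te"] < config.alpha and est.p["pie"] < config.alpha
                )
            row.update(est.to_series().to_dict())
            fw_rows.append(row)
    fourway_table = pd.DataFrame(
        fw_rows, columns=None if fw_rows else ["outcome", "protein", "label", "prop_pie"]
    )
    fourway_table.to_csv(out / "fourway.tsv", sep="\t", index=False)
    class_counts = (
        fourway_table.groupby("outcome")["label"].value_counts().unstack(fill_value=0)
        if len(fourway_table)
        else pd.DataFrame()
    )
    report["stages"]["fourway"] = {
        "n_decompositions": len(fw_rows),
        "class_counts": {k: v.to_dict() for k, v in class_counts.iterrows()} if len(class_counts) else {},
    }

    # --- stage 5: shared consistent mediators ---------------------------
    class_by_outcome = {
        y: fourway_table[fourway_table["outcome"] == y] for y in config.primary_outcomes
    }
    shared = shared_consistent_mediators(class_by_outcome, primary=config.primary_outcomes[0])
    pd.Series(shared, name="protein").to_csv(out / "shared_consistent.tsv", sep="\t", index=False)
    report["stages"]["shared_consistent"] = {"n_shared": len(shared), "proteins": shared}

    # --- stage 6: PCA + PC decomposition --------------------------------
    strata = {
        "men": df["sex"] == 0,
        "women": df["sex"] == 1,
        **{f"prs_t{t}": df["prs_tertile"] == t for t in (1, 2, 3)},
    }
    if len(shared) >= 2:
        pca = fit_pca(df[shared])
        pd.DataFrame(
            {"eigenvalue": pca.eigenvalues},
            index=pd.RangeIndex(1, len(pca.eigenvalues) + 1, name="component"),
        ).to_csv(out / "pca_eigenvalues.csv")
        pca.loadings.to_csv(out / "pca_loadings.tsv", sep="\t")
        pca.scores.to_csv(out / "pca_scores.csv")
        if pca.n_retained > 0:
            pc_rows = []
            for y in config.primary_outcomes:
                y_z = _zscore(df[y]).rename(f"{y}_z")
                tab = decompose_pc(
                    pca.scores, exposure, y_z, covs, spec=spec, strata=strata,
                    restandardize_within_stratum=config.restandardize_within_stratum,
                    min_stratum_n=config.min_stratum_n, alpha=config.alpha,
                )
                tab.insert(0, "outcome", y)
                pc_rows.append(tab)
            pc_table = pd.concat(pc_rows, ignore_index=True)
            pc_table.to_csv(out / "pca_fourway.tsv", sep="\t", index=False)
            report["stages"]["pca"] = {
                "n_retained": int(pca.n_retained),
                "variance_explained": [float(v) for v in pca.variance_explained],
            }
        else:
            report["stages"]["pca"] = {"n_retained": 0}
    else:
        report["stages"]["pca"] = {"skipped": True, "reason": "fewer than 2 shared mediators"}

    # --- stage 7: mediator vs LE8 components/sub-scores -----------------
    comp_rows = []
    if shared:
        scores = le8_scoring.score_components(df)
        targets = {"total": scores["total"],
                   "lifestyle": scores["lifestyle_subscore"],
                   "biological": scores["biological_subscore"]}
        targets.update({c: scores[c] for c in le8_scoring.COMPONENTS})
        for name, series in targets.items():
            try:
                rzc = le8_scoring.reverse_z(series)
            except ValueError:
                continue
            for prot in shared:
                fit = fit_adjusted_ols(df[prot], rzc.values.rename(f"{name}_z_rev"), covs)
                mid = log.record("component_assoc", f"{prot} ~ {name}_z_rev", fit.n_obs)
                comp_rows.append(
                    {
                        "protein": prot,
                        "exposure_component": name,
                        "beta": fit.params[f"{name}_z_rev"],
                        "se": fit.bse[f"{name}_z_rev"],
                        "p": fit.pvalues[f"{name}_z_rev"],
                        "model_id": mid,
                    }
                )
    pd.DataFrame(comp_rows).to_csv(out / "component_assoc.tsv", sep="\t", index=False)
    report["stages"]["component_assoc"] = {"n_models": len(comp_rows)}

    # --- report + audit log ---------------------------------------------
    pd.DataFrame(log.rows).to_csv(out / "models.log", sep="\t", index=False)
    report["wall_clock_s"] = round(time.time() - t0, 3)
    (out / "run_report.json").write_text(json.dumps(report, indent=1))
    return report


def shared_consistent_mediators(
    classifications: dict[str, pd.DataFrame], primary: str | None = None
) -> list[str]:
    """Intersection of 'consistent' mediator sets across outcomes.

    ``classifications`` maps outcome name to a table with ``protein``,
    ``label`` and ``prop_pie`` columns. The result is ordered by |PIE share
    of TE| on the primary outcome (descending); requires >= 2 outcomes.
    """
    if len(classifications) < 2:
        raise ValueError("shared_consistent_mediators requires >= 2 classified outcomes")
    sets = []
    for tab in classifications.values():
        sets.append(set(tab.loc[tab["label"] == "consistent", "protein"]))
    shared = set.intersection(*sets)
    if primary is None:
        primary = next(iter(classifications))
    ptab = classifications[primary].set_index("protein")
    return sorted(
        shared,
        key=lambda prot: (-abs(ptab.loc[prot, "prop_pie"]), prot),
    )
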