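"""Synthetic cohort generator with planted confounding and mediation structure.

Emulates the analysis surface of a population cohort with plasma-proteomic
mediators and global white-matter dMRI outcomes: a cardiovascular-health
exposure on the Life's Essential 8 total scale (0-800, later reverse-z coded),
covariates that confound the exposure-mediator-outcome paths, a matrix of
standardized protein levels (NPX-like, block-correlated), and five continuous
imaging outcomes on their raw scales.

The structural model is linear with optional exposure-mediator interaction.
With standardized exposure A, confounder composite U and planted coefficients
(alpha, beta, gamma, theta3):

    M_j = alpha_j * A + c_m * U + noise_j              (alpha_j = alpha for true mediators)
    L   = gamma * A + sum_j beta_j * M_j + theta3 * A * M_0 + c_y * U + eps

Each raw outcome is an affine map of its own copy of L (shared structural
part, independent noise) onto a realistic raw scale with a health direction
(fractional anisotropy and neurite density fall with poorer CVH; mean
diffusivity, isotropic water fraction and orientation dispersion rise).
Every planted coefficient is stored verbatim in ``Cohort.truth`` so that
downstream estimators can be tested for recovery.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CohortSpec", "Cohort", "generate_cohort", "inject_missingness", "OUTCOME_SCALES"]

#: raw-scale mean, SD and health direction for each global dMRI outcome.
#: direction = sign of the raw-scale change per unit increase of the
#: standardized latent (poorer CVH pushes the latent up).
OUTCOME_SCALES: dict[str, tuple[float, float, float]] = {
    "FA_mean": (0.5615, 0.0189, -1.0),
    "MD_mean": (7.925e-4, 3.37e-5, +1.0),
    "ISOVF_mean": (0.0943, 0.0126, +1.0),
    "ICVF_mean": (0.6120, 0.0314, -1.0),
    "OD_mean": (0.1277, 0.0126, +1.0),
}

OUTCOME_NAMES = tuple(OUTCOME_SCALES)

#: LE8-total scale used to place the standardized latent exposure on 0-800
#: (population mean and the points-per-SD conversion of the exposure).
LE8_TOTAL_MEAN = 531.1
LE8_TOTAL_SD = 93.1

COVARIATE_COLUMNS = (
    "age",
    "sex",
    "race_minority",
    "household_size",
    "education",
    "income",
    "deprivation",
    "time_elapsed_days",
    "prs_tertile",
)


@dataclass
class CohortSpec:
    """Parameters of the planted data-generating process.

    ``confounder_strengths`` is (on_exposure, on_mediator, on_outcome): the
    coefficients of the standardized confounder composite U (built from age
    and the SES summary) in the exposure, mediator and outcome equations.
    ``noise_sd_mediator=None`` auto-balances each mediator's noise so the
    planted mediators have unit population variance (so planted per-SD
    coefficients survive within-sample standardization).
    """

    n_subjects: int = 1000
    n_proteins: int = 20
    n_true_mediators: int = 5
    alpha_exposure_on_mediator: float = 0.4
    beta_mediator_on_outcome: float = 0.3
    gamma_direct: float = 0.1
    interaction_theta3: float = 0.0
    confounder_strengths: tuple[float, float, float] = (0.3, 0.2, 0.2)
    noise_sd_mediator: float | None = None
    noise_sd_outcome: float = 1.0
    protein_block_correlation: float = 0.3
    protein_block_size: int = 5
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be at least 1")
        if not 0 <= self.n_true_mediators <= self.n_proteins:
            raise ValueError("n_true_mediators must lie in [0, n_proteins]")
        if self.noise_sd_mediator is not None and self.noise_sd_mediator <= 0:
            raise ValueError("noise_sd_mediator must be positive")
        if self.noise_sd_outcome <= 0:
            raise ValueError("noise_sd_outcome must be positive")
        if not abs(self.protein_block_correlation) < 1:
            raise ValueError("protein_block_correlation must satisfy |rho| < 1")
        if self.protein_block_correlation < 0:
            raise ValueError("protein_block_correlation must be non-negative")
        if self.protein_block_size < 1:
            raise ValueError("protein_block_size must be at least 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass
class Cohort:
    """A generated cohort: tidy subject table plus the planted truth."""

    data: pd.DataFrame
    truth: dict
    spec: CohortSpec

    @property
    def protein_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("prot_")]

    @property
    def outcome_columns(self) -> list[str]:
        return [c for c in OUTCOME_NAMES if c in self.data.columns]

    def latent_outcome(self, name: str) -> pd.Series:
        """Invert the raw-scale affine map: outcome on the planted latent scale.

        Returns ``direction * (raw - mean) / sd`` so that the planted
        structural coefficients (gamma, beta, theta3) apply directly.
        """
        mean, sd, direction = (self.truth["outcome_scales"][name][k] for k in ("mean", "sd", "direction"))
        return direction * (self.data[name] - mean) / sd

    def to_files(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write the cohort as tidy CSV plus a JSON sidecar with spec + truth."""
        prefix = Path(prefix)
        csv_path = prefix.with_suffix(".csv")
        json_path = prefix.with_suffix(".truth.json")
        self.data.to_csv(csv_path, index=False)
        sidecar = {"spec": asdict(self.spec), "truth": self.truth}
        json_path.write_text(json.dumps(sidecar, indent=1))
        return csv_path, json_path

    @classmethod
    def from_files(cls, csv_path: str | Path, json_path: str | Path) -> "Cohort":
        data = pd.read_csv(csv_path)
        sidecar = json.loads(Path(json_path).read_text())
        spec = CohortSpec(**{**sidecar["spec"], "confounder_strengths": tuple(sidecar["spec"]["confounder_strengths"])})
        return cls(data=data, truth=sidecar["truth"], spec=spec)


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a cohort per the planted structural model (reproducible by seed)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_subjects, spec.n_proteins
    k = spec.n_true_mediators

    # --- covariates -------------------------------------------------------
    age = rng.uniform(40.0, 70.0, n)
    sex = rng.binomial(1, 0.531, n)
    race_minority = rng.binomial(1, 0.032, n)
    household_size = 1 + rng.poisson(1.6, n)
    education = rng.integers(0, 3, n)
    income = rng.integers(1, 6, n)
    deprivation = rng.normal(-1.77, 2.8, n)
    time_elapsed_days = np.round(rng.normal(2900.0, 700.0, n)).clip(min=365)
    prs_tertile = rng.integers(1, 4, n)

    # confounder composite: age and socio-economic position, standardized
    ses = _standardize(
        _standardize(income.astype(float)) + _standardize(education.astype(float)) - _standardize(deprivation)
    )
    confounder = _standardize(_standardize(age) + ses) / np.sqrt(1.0)
    confounder = _standardize(confounder)

    c_e, c_m, c_y = spec.confounder_strengths
    if abs(c_e) >= 1:
        raise ValueError("confounder_strengths[0] (on exposure) must satisfy |c| < 1")

    # --- exposure on the standardized latent scale, then LE8 total --------
    a_latent = c_e * confounder + np.sqrt(1.0 - c_e**2) * rng.standard_normal(n)
    le8_total = np.clip(LE8_TOTAL_MEAN - LE8_TOTAL_SD * a_latent, 0.0, 800.0)

    # --- proteins: block-equicorrelated noise plus structural terms -------
    rho = spec.protein_block_correlation
    n_blocks = int(np.ceil(m / spec.protein_block_size))
    block_of = np.repeat(np.arange(n_blocks), spec.protein_block_size)[:m]
    factors = rng.standard_normal((n, n_blocks))
    eps = rng.standard_normal((n, m))
    noise = np.sqrt(rho) * factors[:, block_of] + np.sqrt(1.0 - rho) * eps  # unit variance

    alpha = np.zeros(m)
    alpha[:k] = spec.alpha_exposure_on_mediator
    structural_var = alpha**2 + c_m**2 + 2.0 * alpha * c_m * c_e
    if spec.noise_sd_mediator is None:
        resid_var = 1.0 - structural_var
        if (resid_var <= 0).any():
            raise ValueError(
                "planted effects imply mediator variance > 1; "
                "set noise_sd_mediator explicitly or reduce alpha/confounder strength"
            )
        s_j = np.sqrt(resid_var)
    else:
        s_j = np.full(m, spec.noise_sd_mediator)
    proteins = alpha * a_latent[:, None] + c_m * confounder[:, None] + s_j * noise

    # --- outcomes ---------------------------------------------------------
    beta = np.zeros(m)
    beta[:k] = spec.beta_mediator_on_outcome
    structural = (
        spec.gamma_direct * a_latent
        + proteins @ beta
        + spec.interaction_theta3 * a_latent * (proteins[:, 0] if m else 0.0)
        + c_y * confounder
    )
    data = {
        "subject_id": np.arange(n),
        "age": age,
        "sex": sex,
        "race_minority": race_minority,
        "household_size": household_size,
        "education": education,
        "income": income,
        "deprivation": deprivation,
        "time_elapsed_days": time_elapsed_days,
        "prs_tertile": prs_tertile,
        "ses_z": ses,
        "le8_total": le8_total,
    }
    outcome_scales = {}
    for name, (mean, sd, direction) in OUTCOME_SCALES.items():
        latent = structural + spec.noise_sd_outcome * rng.standard_normal(n)
        data[name] = mean + sd * direction * latent
        outcome_scales[name] = {"mean": mean, "sd": sd, "direction": direction}

    # raw LE8 component inputs with realistic marginals (scoring-path
    # exercise only; the analysis exposure is the planted le8_total)
    data.update(_raw_le8_components(rng, n))

    protein_frame = pd.DataFrame(
        proteins, columns=[f"prot_{j:04d}" for j in range(m)]
    )
    df = pd.concat([pd.DataFrame(data), protein_frame], axis=1)

    truth = {
        "alpha": alpha.tolist(),
        "beta": beta.tolist(),
        "gamma": spec.gamma_direct,
        "theta3": spec.interaction_theta3,
        "confounder_strengths": list(spec.confounder_strengths),
        "true_mediators": [f"prot_{j:04d}" for j in range(k)],
        "interaction_mediator": "prot_0000" if spec.interaction_theta3 != 0 and m else None,
        "outcome_scales": outcome_scales,
        "le8_total_mean": LE8_TOTAL_MEAN,
        "le8_total_sd": LE8_TOTAL_SD,
    }
    cohort = Cohort(data=df, truth=truth, spec=spec)
    if spec.missing_rate > 0:
        cohort = inject_missingness(cohort, spec.missing_rate, seed=spec.seed + 1)
    return cohort


def _raw_le8_components(rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    return {
        "diet_quantile": rng.integers(1, 11, n),
        "pa_minutes_per_week": np.round(rng.gamma(1.4, 90.0, n)),
        "smoking_status": rng.choice(5, n, p=[0.55, 0.25, 0.08, 0.02, 0.10]),
        "secondhand_flag": rng.binomial(1, 0.05, n),
        "sleep_hours": np.clip(rng.normal(7.2, 1.0, n), 3.0, 12.0),
        "bmi_kg_m2": np.clip(rng.normal(27.0, 4.5, n), 15.0, 60.0),
        "nonhdl_mg_dl": np.clip(rng.normal(145.0, 35.0, n), 60.0, 400.0),
        "glucose_mg_dl": np.clip(rng.normal(95.0, 15.0, n), 60.0, 350.0),
        "diabetes_flag": rng.binomial(1, 0.05, n),
        "lipid_med_flag": rng.binomial(1, 0.15, n),
        "sbp_mmhg": np.clip(rng.normal(135.0, 18.0, n), 85.0, 220.0),
        "dbp_mmhg": np.clip(rng.normal(80.0, 10.0, n), 45.0, 130.0),
        "bp_med_flag": rng.binomial(1, 0.18, n),
    }


def inject_missingness(
    cohort: Cohort,
    rate: float,
    seed: int,
    columns: list[str] | None = None,
) -> Cohort:
    """Set cells missing completely at random (MCAR) at the given rate.

    Applies to every analysis column except ``subject_id`` by default;
    complete-case filtering downstream then reproduces listwise deletion.
    Deterministic in ``seed``. ``rate=0`` returns the cohort unchanged.
    """
    if not 0 <= rate < 1:
        raise ValueError("missingness rate must lie in [0, 1)")
    if rate == 0:
        return cohort
    rng = np.random.default_rng(seed)
    df = cohort.data.copy()
    cols = columns if columns is not None else [c for c in df.columns if c != "subject_id"]
    mask = rng.random((len(df), len(cols))) < rate
    for i, c in enumerate(cols):
        col = df[c].astype(float)
        col[mask[:, i]] = np.nan
        df[c] = col
    return Cohort(data=df, truth=cohort.truth, spec=cohort.spec)
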