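"""Life's Essential 8 (LE8) cardiovascular-health scoring.

The LE8 composite summarizes cardiovascular health (CVH) from four lifestyle
components (diet, physical activity, nicotine exposure, sleep health) and four
biological components (BMI, blood lipids, blood glucose, blood pressure). Each
component is scored 0-100 against the American Heart Association point
schedule; the total here is the plain sum over the eight components and ranges
0-800, with higher values indicating better CVH.

For use as an exposure in risk models the total (or a sub-score, or a single
component) is z-standardized within the analysis sample and multiplied by -1
(`reverse_z`), so that one unit of the resulting ``le8_z_rev`` exposure
corresponds to a one-SD *decrement* in cardiovascular health.

The component gradations between the printed optimal anchors and zero are data,
not code: they ship as a YAML breakpoint table (``data/le8_defaults.yaml``) and
can be overridden per cohort (e.g., a different diet-quantile mapping).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LE8Config",
    "ReverseZExposure",
    "load_default_config",
    "score_components",
    "reverse_z",
    "ses_composite",
]

LIFESTYLE_COMPONENTS = ("diet", "physical_activity", "nicotine", "sleep")
BIOLOGICAL_COMPONENTS = ("bmi", "lipids", "glucose", "blood_pressure")
COMPONENTS = LIFESTYLE_COMPONENTS + BIOLOGICAL_COMPONENTS

#: raw input columns required by :func:`score_components`
RAW_COLUMNS = (
    "diet_quantile",
    "pa_minutes_per_week",
    "smoking_status",
    "secondhand_flag",
    "sleep_hours",
    "bmi_kg_m2",
    "nonhdl_mg_dl",
    "glucose_mg_dl",
    "diabetes_flag",
    "lipid_med_flag",
    "sbp_mmhg",
    "dbp_mmhg",
    "bp_med_flag",
)

# physiological plausibility bounds (inclusive) for validation
_PLAUSIBLE = {
    "pa_minutes_per_week": (0.0, 10080.0),
    "sleep_hours": (0.0, 24.0),
    "bmi_kg_m2": (10.0, 80.0),
    "nonhdl_mg_dl": (40.0, 500.0),
    "glucose_mg_dl": (40.0, 600.0),
    "sbp_mmhg": (60.0, 260.0),
    "dbp_mmhg": (30.0, 160.0),
}


def load_default_config() -> dict:
    """Load the default LE8 breakpoint tables shipped with the package."""
    text = resources.files("proteoscreen.data").joinpath("le8_defaults.yaml").read_text()
    return yaml.safe_load(text)


@dataclass
class LE8Config:
    """Breakpoint tables for component scoring; defaults to the AHA schedule."""

    tables: dict = field(default_factory=load_default_config)

    def __getitem__(self, key: str) -> dict:
        return self.tables[key]


def _interval_points(values: np.ndarray, bands: list) -> np.ndarray:
    """Score values against [lo, hi, points) interval bands."""
    out = np.full(values.shape, np.nan)
    for lo, hi, pts in bands:
        mask = (values >= lo) & (values < hi)
        out[mask] = pts
    return out


def _threshold_points(values: np.ndarray, bands: list) -> np.ndarray:
    """Score values against descending [minimum, points] threshold bands."""
    out = np.full(values.shape, np.nan)
    for lo, pts in sorted(bands, key=lambda b: b[0], reverse=True):
        mask = np.isnan(out) & (values >= lo)
        out[mask] = pts
    return out


def _validate_ranges(raw: pd.DataFrame) -> None:
    for col, (lo, hi) in _PLAUSIBLE.items():
        vals = raw[col].to_numpy(dtype=float)
        bad = (vals < lo) | (vals > hi)
        bad &= ~np.isnan(vals)
        if bad.any():
            idx = raw.index[bad][0]
            raise ValueError(
                f"{col} outside plausible range [{lo}, {hi}] "
                f"(first offending row index {idx}: {raw.loc[idx, col]})"
            )


def score_components(raw: pd.DataFrame, config: LE8Config | None = None) -> pd.DataFrame:
    """Score the eight LE8 components plus sub-scores and the 0-800 total.

    Parameters
    ----------
    raw
        One row per subject with the columns in :data:`RAW_COLUMNS`. Diet enters
        as a precomputed DASH-adherence quantile (1-based, 1 = lowest adherence).
    config
        Breakpoint tables; the shipped AHA-schedule defaults when omitted.

    Returns
    -------
    DataFrame indexed like ``raw`` with one column per component (points in
    [0, 100]), ``lifestyle_subscore``, ``biological_subscore`` (each 0-400) and
    ``total`` (0-800). Rows with any missing raw component propagate NaN so
    that listwise deletion downstream reproduces complete-case behaviour.
    """
    cfg = config or LE8Config()
    missing_cols = [c for c in RAW_COLUMNS if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"missing raw LE8 component columns: {missing_cols}")
    _validate_ranges(raw)

    out = pd.DataFrame(index=raw.index)

    # --- lifestyle ---
    nq = int(cfg["diet"]["n_quantiles"])
    q = raw["diet_quantile"].to_numpy(dtype=float)
    valid = ~np.isnan(q)
    if ((q[valid] < 1) | (q[valid] > nq) | (q[valid] != np.round(q[valid]))).any():
        raise ValueError(f"diet_quantile must be an integer in [1, {nq}]")
    out["diet"] = (q - 1.0) / (nq - 1.0) * 100.0

    out["physical_activity"] = _threshold_points(
        raw["pa_minutes_per_week"].to_numpy(dtype=float), cfg["physical_activity"]["bands"]
    )

    status = raw["smoking_status"].to_numpy(dtype=float)
    pts = np.asarray(cfg["nicotine"]["status_points"], dtype=float)
    valid = ~np.isnan(status)
    if ((status[valid] < 0) | (status[valid] >= len(pts))).any():
        raise ValueError(f"smoking_status must be an integer code in [0, {len(pts) - 1}]")
    nic = np.where(np.isnan(status), np.nan, pts[np.nan_to_num(status).astype(int)])
    secondhand = raw["secondhand_flag"].to_numpy(dtype=float)
    nic = nic - secondhand * cfg["nicotine"]["secondhand_deduction"]
    out["nicotine"] = np.clip(nic, 0.0, 100.0)

    out["sleep"] = _interval_points(
        raw["sleep_hours"].to_numpy(dtype=float), cfg["sleep"]["bands"]
    )

    # --- biological ---
    out["bmi"] = _interval_points(raw["bmi_kg_m2"].to_numpy(dtype=float), cfg["bmi"]["bands"])

    lip = _interval_points(raw["nonhdl_mg_dl"].to_numpy(dtype=float), cfg["lipids"]["bands"])
    lip = lip - raw["lipid_med_flag"].to_numpy(dtype=float) * cfg["lipids"]["treatment_deduction"]
    out["lipids"] = np.clip(lip, 0.0, 100.0)

    glu_raw = raw["glucose_mg_dl"].to_numpy(dtype=float)
    diab = raw["diabetes_flag"].to_numpy(dtype=float)
    glu_no = _interval_points(glu_raw, cfg["glucose"]["no_diabetes_bands"])
    glu_yes = _interval_points(glu_raw, cfg["glucose"]["diabetes_bands"])
    out["glucose"] = np.where(np.isnan(diab), np.nan, np.where(diab > 0, glu_yes, glu_no))

    bp_cfg = cfg["blood_pressure"]
    sbp = raw["sbp_mmhg"].to_numpy(dtype=float)
    dbp = raw["dbp_mmhg"].to_numpy(dtype=float)
    sbp_cat = np.searchsorted(np.asarray(bp_cfg["sbp_cuts"], dtype=float), sbp, side="right")
    dbp_idx = np.searchsorted(np.asarray(bp_cfg["dbp_cuts"], dtype=float), dbp, side="right")
    dbp_cat = np.asarray(bp_cfg["dbp_cats"], dtype=int)[dbp_idx]
    cat = np.maximum(sbp_cat, dbp_cat)
    bp = np.asarray(bp_cfg["category_points"], dtype=float)[cat]
    bp = np.where(np.isnan(sbp) | np.isnan(dbp), np.nan, bp)
    bp = bp - raw["bp_med_flag"].to_numpy(dtype=float) * bp_cfg["treatment_deduction"]
    out["blood_pressure"] = np.clip(bp, 0.0, 100.0)

    out["lifestyle_subscore"] = out[list(LIFESTYLE_COMPONENTS)].sum(axis=1, skipna=False)
    out["biological_subscore"] = out[list(BIOLOGICAL_COMPONENTS)].sum(axis=1, skipna=False)
    out["total"] = out["lifestyle_subscore"] + out["biological_subscore"]
    return out


@dataclass
class ReverseZExposure:
    """Reverse-coded standardized exposure: higher value = poorer CVH.

    ``values`` is the within-sample z-score of the supplied totals multiplied
    by -1, so one unit is one sample-SD decrement of the underlying score.
    """

    values: pd.Series
    sample_mean: float
    sample_sd: float


def reverse_z(totals: pd.Series | np.ndarray) -> ReverseZExposure:
    """z-standardize a score within the supplied sample, then negate.

    Uses the n-1 (sample) SD. Missing values are excluded from the mean/SD and
    propagate as NaN in the output. Raises on zero variance or fewer than two
    distinct values.
    """
    s = pd.Series(np.asarray(totals, dtype=float)) if not isinstance(totals, pd.Series) else totals.astype(float)
    valid = s.dropna()
    if valid.nunique() < 2:
        raise ValueError("reverse_z requires at least 2 distinct non-missing values")
    mu = float(valid.mean())
    sd = float(valid.std(ddof=1))
    if sd == 0.0:
        raise ValueError("reverse_z undefined for zero-variance input")
    return ReverseZExposure(values=-(s - mu) / sd, sample_mean=mu, sample_sd=sd)


def ses_composite(education: pd.Series, income: pd.Series, deprivation: pd.Series) -> pd.Series:
    """Socio-economic status summary: z(education) + z(income) + z(-deprivation).

    The deprivation index (higher = more deprived) is z-scored then negated so
    the composite increases with socio-economic advantage; the sum is
    re-standardized to mean 0, SD 1 within the sample.
    """
    parts = []
    for s in (education, income):
        s = pd.Series(s, dtype=float)
        parts.append((s - s.mean()) / s.std(ddof=1))
    d = pd.Series(deprivation, dtype=float)
    parts.append(-(d - d.mean()) / d.std(ddof=1))
    total = parts[0] + parts[1] + parts[2]
    return (total - total.mean()) / total.std(ddof=1)
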