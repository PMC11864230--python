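"""Published reference estimates for the ten shared consistent mediators.

The UK Biobank analysis (N = 3953) reported four-way decomposition estimates
for ten plasma proteins that consistently mediated the effect of poor
cardiovascular health on both tract-averaged fractional anisotropy (FA_mean)
and orientation dispersion (OD_mean), both z-scored. Those published numbers
ship here as a plain CSV and serve as numeric input for arithmetic-identity
checks (component additivity, proportion-of-TE recomputation) and for
exercising the mediation classifier on real-world magnitudes.

Printed significance values of "<0.001" are stored as 0.001 with
``p_is_upper_bound = 1``; all classification thresholds used downstream
(0.05) are unaffected by this censoring.
"""

from __future__ import annotations

from importlib import resources
from io import StringIO

import pandas as pd

from .fourway import FourWayEstimate

__all__ = ["load_reference_table", "reference_estimate", "REFERENCE_PROTEINS"]

REFERENCE_PROTEINS = (
    "LEP", "CPM", "F9", "FGF21", "PRSS8", "LILRA5", "CA14", "VWA1", "BAIAP2", "WFIKKN2",
)


def load_reference_table() -> pd.DataFrame:
    """Long-format table: protein, outcome, quantity, estimate, se, p."""
    text = resources.files("proteoscreen.data").joinpath("ukb_fourway_reference.csv").read_text()
    return pd.read_csv(StringIO(text))


def reference_estimate(protein: str, outcome: str, table: pd.DataFrame | None = None) -> FourWayEstimate:
    """Assemble a :class:`FourWayEstimate` from the published row of one
    protein-outcome pair (estimates, SEs, p-values, and printed proportions)."""
    tab = table if table is not None else load_reference_table()
    sub = tab[(tab.protein == protein) & (tab.outcome == outcome)].set_index("quantity")
    if sub.empty:
        raise KeyError(f"no reference row for {protein} / {outcome}")
    comps = {c: float(sub.loc[c, "estimate"]) for c in ("te", "cde", "intref", "intmed", "pie")}
    est = FourWayEstimate(**comps)
    est.se = {c: float(sub.loc[c, "se"]) for c in comps}
    est.p = {c: float(sub.loc[c, "p"]) for c in comps}
    est.prop = {
        c: float(sub.loc[f"prop_{c}", "estimate"]) for c in ("cde", "intref", "intmed", "pie")
    }
    return est
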