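"""Drug-response summaries: survival fraction, dose-response AUC, and
High- vs Low-CEA group comparison.

Survival fraction is the day-6 luminescence of a drug-treated well over
its vehicle (DMSO) control, × 100.  The dose-response AUC is the
trapezoidal mean of percent survival over log10(concentration),
normalized by the log-concentration span — a flat 100% curve scores 100
and the value is invariant to rescaling all concentrations by a common
factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DoseResponseCurve",
    "survival_fraction",
    "auc_drc",
    "compare_group_auc",
    "summarize_plate",
]

PLATE_CSV_COLUMNS = [
    "sample_id",
    "patient_id",
    "platform",
    "concentration_uM",
    "lum_drug",
    "lum_control",
]


def survival_fraction(lum_drug: float, lum_control: float) -> float:
    """Percent survival: 100 × drug luminescence / control luminescence."""
    if lum_control <= 0:
        raise ValueError("control luminescence must be > 0")
    if lum_drug < 0:
        raise ValueError("drug luminescence must be >= 0")
    return 100.0 * lum_drug / lum_control


def auc_drc(concentrations, survival) -> float:
    """Normalized dose-response AUC in percent units.

    Trapezoidal integral of survival over log10(concentration), divided
    by the log10 span, so min(survival) ≤ AUC ≤ max(survival).
    """
    c = np.asarray(concentrations, dtype=float)
    s = np.asarray(survival, dtype=float)
    if c.shape != s.shape or c.ndim != 1:
        raise ValueError("concentrations and survival must be 1-D, equal length")
    if c.size < 2:
        raise ValueError("need at least two concentrations")
    if np.any(c <= 0):
        raise ValueError("concentrations must be > 0")
    if np.any(np.diff(c) <= 0):
        raise ValueError("concentrations must be strictly increasing")
    if np.any(s < 0):
        raise ValueError("survival must be >= 0")
    x = np.log10(c)
    return float(np.trapezoid(s, x) / (x[-1] - x[0]))


@dataclass(frozen=True)
class DoseResponseCurve:
    """One sample's dose-response curve and its normalized AUC."""

    concentrations: tuple[float, ...]  # µM, strictly increasing
    survival: tuple[float, ...]  # percent
    auc: float

    @classmethod
    def from_points(cls, concentrations, survival) -> "DoseResponseCurve":
        auc = auc_drc(concentrations, survival)
        return cls(tuple(float(c) for c in concentrations),
                   tuple(float(s) for s in survival), auc)


def compare_group_auc(aucs_by_class: dict) -> dict:
    """Group means ± SEM and a Welch two-sample t comparison.

    ``aucs_by_class`` maps a class label (e.g. "High"/"Low") to a list of
    per-sample AUCs.  Exactly two groups; each needs n ≥ 2.  Descriptive
    only — no multiplicity correction.
    """
    if len(aucs_by_class) != 2:
        raise ValueError("expected exactly two groups")
    summary = {}
    arrays = {}
    for cls, values in aucs_by_class.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {cls!r} needs at least 2 samples")
        arrays[cls] = arr
        summary[cls] = {
            "n": int(arr.size),
            "mean": float(arr.mean()),
            "sem": float(arr.std(ddof=1) / np.sqrt(arr.size)),
        }
    (cls_a, a), (cls_b, b) = arrays.items()
    t, p = stats.ttest_ind(a, b, equal_var=False)
    summary["comparison"] = {
        "groups": (cls_a, cls_b),
        "mean_difference": float(a.mean() - b.mean()),
        "welch_t": float(t),
        "p_value": float(p),
    }
    return summary


def summarize_plate(plate: pd.DataFrame) -> pd.DataFrame:
    """Per-sample dose-response AUCs from a raw luminescence plate table.

    Expects columns ``sample_id, patient_id, platform, concentration_uM,
    lum_drug, lum_control``; returns one row per sample with its AUC.
    """
    missing = set(PLATE_CSV_COLUMNS) - set(plate.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    rows = []
    for sample_id, grp in plate.groupby("sample_id", sort=True):
        grp = grp.sort_values("concentration_uM")
        surv = [survival_fraction(d, c)
                for d, c in zip(grp["lum_drug"], grp["lum_control"])]
        auc = auc_drc(grp["concentration_uM"].to_numpy(), np.asarray(surv))
        rows.append({
            "sample_id": sample_id,
            "patient_id": grp["patient_id"].iloc[0],
            "platform": grp["platform"].iloc[0],
            "n_doses": len(grp),
            "auc": auc,
        })
    return pd.DataFrame(rows)
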