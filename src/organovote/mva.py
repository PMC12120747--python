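"""Majority voting aggregation of per-organoid predictions.

A patient's organoid panel is first cleaned with Tukey fences (any record
with any filtered feature outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR] is
dropped; quartiles by linear interpolation between order statistics),
truncated to at most ``max_panel`` organoids (49 by default) by a seeded
uniform shuffle, classified organoid by organoid, and resolved by strict
majority.  An exact tie is reported as Indeterminate and scored as an
incorrect call; with an odd panel a tie is impossible.

Filtering applies at prediction time to the panel.  An alternative
percentile-trimming mode (``trim_tails``) removes a fixed fraction of
each tail of every feature instead of using the 1.5·IQR fences; on
near-normal data the fences remove well under 1% of records, so a
trimming fraction as large as 12.5% per tail cannot arise from them and
must be requested explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import FEATURE_COLUMNS, ClassifierModel
from .synthgen import records_to_frame

__all__ = [
    "PatientPrediction",
    "iqr_filter",
    "trim_tails_filter",
    "majority_vote",
    "predict_patient",
    "predict_cohort",
]

DEFAULT_MAX_PANEL = 49
IQR_FENCE_FACTOR = 1.5


@dataclass(frozen=True)
class PatientPrediction:
    """Audit trail of one patient-level majority-vote call."""

    patient_id: str
    n_input: int
    n_after_filter: int
    votes_high: int
    votes_low: int
    call: str  # High | Low | Indeterminate

    def __post_init__(self) -> None:
        if self.votes_high + self.votes_low != self.n_after_filter:
            raise ValueError("votes must sum to the filtered panel size")
        if self.n_after_filter > self.n_input:
            raise ValueError("filtered panel cannot exceed input panel")
        expected = _call_from_votes(self.votes_high, self.votes_low)
        if self.call != expected:
            raise ValueError(f"call {self.call!r} inconsistent with votes")


def _call_from_votes(votes_high: int, votes_low: int) -> str:
    if votes_high > votes_low:
        return "High"
    if votes_low > votes_high:
        return "Low"
    return "Indeterminate"


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table.reset_index(drop=True)
    return records_to_frame(table)


def iqr_filter(table, features=FEATURE_COLUMNS) -> pd.DataFrame:
    """Drop records outside the Tukey fences of any named feature.

    Quartiles use linear interpolation between order statistics; fences
    are Q1 − 1.5·IQR and Q3 + 1.5·IQR per feature.  Row order preserved.
    Requires at least 4 rows for meaningful quartiles.
    """
    frame = _as_frame(table)
    if len(frame) < 4:
        raise ValueError("need at least 4 records for quartile fences")
    keep = np.ones(len(frame), dtype=bool)
    for name in features:
        values = frame[name].to_numpy(dtype=float)
        q1, q3 = np.percentile(values, [25, 75])  # linear interpolation
        iqr = q3 - q1
        lo, hi = q1 - IQR_FENCE_FACTOR * iqr, q3 + IQR_FENCE_FACTOR * iqr
        keep &= (values >= lo) & (values <= hi)
    return frame.loc[keep].reset_index(drop=True)


def trim_tails_filter(table, fraction: float = 0.125, features=FEATURE_COLUMNS) -> pd.DataFrame:
    """Percentile trimming: drop records in the outer ``fraction`` of each
    tail of any named feature (e.g. 0.125 keeps the central 75% band per
    feature)."""
    if not 0 < fraction < 0.5:
        raise ValueError("fraction must lie in (0, 0.5)")
    frame = _as_frame(table)
    if len(frame) < 4:
        raise ValueError("need at least 4 records for percentile trimming")
    keep = np.ones(len(frame), dtype=bool)
    for name in features:
        values = frame[name].to_numpy(dtype=float)
        lo, hi = np.percentile(values, [100 * fraction, 100 * (1 - fraction)])
        keep &= (values >= lo) & (values <= hi)
    return frame.loc[keep].reset_index(drop=True)


def majority_vote(votes) -> str:
    """Strict-majority winner of High/Low votes; tie → Indeterminate."""
    votes = list(votes)
    if not votes:
        raise ValueError("empty vote list")
    unknown = set(votes) - {"High", "Low"}
    if unknown:
        raise ValueError(f"votes must be High or Low, got {sorted(unknown)}")
    high = sum(v == "High" for v in votes)
    return _call_from_votes(high, len(votes) - high)


def predict_patient(
    model: ClassifierModel,
    panel,
    max_panel: int = DEFAULT_MAX_PANEL,
    seed: int = 0,
    features=FEATURE_COLUMNS,
    outlier_filter=iqr_filter,
) -> PatientPrediction:
    """One patient-level call from a panel of that patient's organoids.

    Pipeline: outlier filter → seeded-shuffle truncation to ``max_panel``
    → per-organoid predictions → strict majority vote.
    """
    frame = _as_frame(panel)
    patients = frame["patient_id"].unique()
    if len(patients) != 1:
        raise ValueError(f"panel spans multiple patients: {sorted(map(str, patients))}")
    n_input = len(frame)
    filtered = outlier_filter(frame, features=features) if outlier_filter else frame
    if len(filtered) == 0:
        raise ValueError("no organoids left after outlier filtering")
    if len(filtered) > max_panel:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.permutation(len(filtered))[:max_panel])
        filtered = filtered.iloc[idx].reset_index(drop=True)
    pred = model.predict(filtered)
    votes_high = int(np.sum(pred == "High"))
    votes_low = len(pred) - votes_high
    return PatientPrediction(
        patient_id=str(patients[0]),
        n_input=n_input,
        n_after_filter=len(filtered),
        votes_high=votes_high,
        votes_low=votes_low,
        call=_call_from_votes(votes_high, votes_low),
    )


def predict_cohort(model, table, max_panel: int = DEFAULT_MAX_PANEL, seed: int = 0,
                   outlier_filter=iqr_filter) -> pd.DataFrame:
    """Per-patient majority-vote calls over a labeled cohort table.

    Returns one row per patient: the PatientPrediction fields plus the
    true class and whether the call is correct (Indeterminate counts as
    incorrect).
    """
    frame = _as_frame(table)
    rows = []
    for patient_id, panel in frame.groupby("patient_id", sort=True):
        pp = predict_patient(model, panel.reset_index(drop=True),
                             max_panel=max_panel, seed=seed,
                             outlier_filter=outlier_filter)
        truth = panel["cea_class"].iloc[0] if "cea_class" in panel else None
        rows.append({
            "patient_id": pp.patient_id,
            "n_input": pp.n_input,
            "n_after_filter": pp.n_after_filter,
            "votes_high": pp.votes_high,
            "votes_low": pp.votes_low,
            "call": pp.call,
            "truth": truth,
            "correct": (pp.call == truth) if truth is not None else None,
        })
    return pd.DataFrame(rows)
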