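"""Per-organoid High-/Low-CEA classification.

A random-forest ensemble on the three morphometric features (area,
perimeter, circularity).  Defaults: 100 trees, unlimited depth, √p
features per split, balanced class weighting, seed 0 — recorded in the
model metadata so a saved model is fully reproducible.  Trees are
scale-invariant so no feature scaling is applied.  Evaluation reports
per-class accuracy (recall) with High-CEA as the positive class,
mirroring a confusion-matrix readout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .synthgen import records_to_frame

__all__ = [
    "FEATURE_COLUMNS",
    "CLASS_LABELS",
    "ClassifierModel",
    "ConfusionSummary",
    "train_classifier",
    "evaluate",
    "predict_labels",
    "save_model",
    "load_model",
]

FEATURE_COLUMNS = ("area_um2", "perimeter_um", "circularity")
CLASS_LABELS = ("High", "Low")

DEFAULT_HYPERPARAMETERS = {
    "n_estimators": 100,
    "max_depth": None,
    "max_features": "sqrt",
    "class_weight": "balanced",
}


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    return records_to_frame(table)


@dataclass
class ClassifierModel:
    """A fitted ensemble plus the metadata needed to reproduce it."""

    estimator: RandomForestClassifier
    feature_names: tuple[str, ...] = FEATURE_COLUMNS
    class_labels: tuple[str, ...] = CLASS_LABELS
    hyperparameters: dict = field(default_factory=lambda: dict(DEFAULT_HYPERPARAMETERS))
    seed: int = 0

    def predict(self, table) -> np.ndarray:
        frame = _as_frame(table)
        missing = set(self.feature_names) - set(frame.columns)
        if missing:
            raise ValueError(f"missing feature columns: {sorted(missing)}")
        X = frame.loc[:, list(self.feature_names)].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise ValueError("feature table contains missing values")
        return self.estimator.predict(X)


@dataclass(frozen=True)
class ConfusionSummary:
    """Confusion counts with High-CEA positive, plus per-class accuracy."""

    tp: int  # High called High
    fn: int  # High called Low
    fp: int  # Low called High
    tn: int  # Low called Low

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def high_accuracy(self) -> float:
        """Fraction of High-CEA organoids called High (sensitivity)."""
        total = self.tp + self.fn
        return self.tp / total if total else float("nan")

    @property
    def low_accuracy(self) -> float:
        """Fraction of Low-CEA organoids called Low (specificity)."""
        total = self.tn + self.fp
        return self.tn / total if total else float("nan")

    @property
    def overall_accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else float("nan")

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
            "high_accuracy": self.high_accuracy,
            "low_accuracy": self.low_accuracy,
            "overall_accuracy": self.overall_accuracy,
        }


def train_classifier(table, seed: int = 0, **hyperparameters) -> ClassifierModel:
    """Fit the random forest on (area, perimeter, circularity) vs class.

    ``hyperparameters`` override the defaults (n_estimators, max_depth,
    max_features, class_weight).  Deterministic given ``seed``.
    """
    frame = _as_frame(table)
    missing = set(FEATURE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"missing feature columns: {sorted(missing)}")
    if "cea_class" not in frame.columns or frame["cea_class"].isna().any():
        raise ValueError("every training row needs a cea_class label")
    y = frame["cea_class"].to_numpy(dtype=object)
    present = set(np.unique(y))
    if not present >= set(CLASS_LABELS):
        raise ValueError(f"training table must contain both classes, got {sorted(present)}")
    X = frame.loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("feature table contains missing values")
    hyper = dict(DEFAULT_HYPERPARAMETERS)
    hyper.update(hyperparameters)
    estimator = RandomForestClassifier(random_state=seed, n_jobs=1, **hyper)
    estimator.fit(X, y)
    return ClassifierModel(estimator=estimator, hyperparameters=hyper, seed=seed)


def predict_labels(model: ClassifierModel, table) -> np.ndarray:
    return model.predict(table)


def evaluate(model: ClassifierModel, table) -> ConfusionSummary:
    """Tally per-organoid predictions on a labeled table."""
    frame = _as_frame(table)
    if "cea_class" not in frame.columns or frame["cea_class"].isna().any():
        raise ValueError("evaluation rows must be labeled")
    truth = frame["cea_class"].to_numpy(dtype=object)
    unknown = set(truth) - set(CLASS_LABELS)
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")
    pred = model.predict(frame)
    high, pred_high = truth == "High", pred == "High"
    return ConfusionSummary(
        tp=int(np.sum(high & pred_high)),
        fn=int(np.sum(high & ~pred_high)),
        fp=int(np.sum(~high & pred_high)),
        tn=int(np.sum(~high & ~pred_high)),
    )


def save_model(model: ClassifierModel, path) -> None:
    """Serialize estimator to ``path`` with a JSON metadata sidecar."""
    path = Path(path)
    joblib.dump(model.estimator, path)
    meta = {
        "format_version": 1,
        "feature_names": list(model.feature_names),
        "class_labels": list(model.class_labels),
        "hyperparameters": {k: v for k, v in model.hyperparameters.items()},
        "seed": model.seed,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_model(path) -> ClassifierModel:
    path = Path(path)
    estimator = joblib.load(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    if meta.get("format_version") != 1:
        raise ValueError("unsupported model format version")
    return ClassifierModel(
        estimator=estimator,
        feature_names=tuple(meta["feature_names"]),
        class_labels=tuple(meta["class_labels"]),
        hyperparameters=meta["hyperparameters"],
        seed=meta["seed"],
    )
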