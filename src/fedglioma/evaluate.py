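"""Slice-to-patient decisions and confusion-matrix evaluation.

The classifier predicts single 2D slices; a patient's scan-level diagnosis is
the majority vote over their M slice predictions (class 1 — the
IDH-mutation/LGG analogue — iff strictly more than M/2 slices are class 1, so
even-M ties resolve to class 0).  Metrics are accuracy, sensitivity and
specificity with class 1 as positive; multi-run experiments report the mean
and sample standard deviation across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import ModelConfig, forward
from .preprocess import preprocess_scan, SliceDataset

__all__ = [
    "PatientPrediction", "ConfusionCounts", "MetricsReport", "majority_vote",
    "confusion", "metrics", "predict_slices", "evaluate_slice_level",
    "evaluate_patient_level", "aggregate_runs",
]


@dataclass
class PatientPrediction:
    patient_id: str
    slice_predictions: list
    decision: int
    label: int | None = None


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/TN/FN with positive class = IDH-mutation/LGG-analogue (label 1)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricsReport:
    """Accuracy / sensitivity / specificity; ``None`` marks an undefined value
    (zero denominator), never silently 0."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    level: str = "slice-2D"
    n_runs: int = 1
    accuracy_std: float | None = None
    sensitivity_std: float | None = None
    specificity_std: float | None = None

    def as_dict(self) -> dict:
        return {"level": self.level, "n_runs": self.n_runs,
                "accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "accuracy_std": self.accuracy_std,
                "sensitivity_std": self.sensitivity_std,
                "specificity_std": self.specificity_std}


def majority_vote(slice_preds) -> int:
    """1 iff strictly more than half of the slice predictions are 1."""
    preds = np.asarray(slice_preds)
    if preds.size == 0:
        raise ValueError("majority_vote requires at least one slice prediction")
    return int(preds.sum() > preds.size / 2.0)


def confusion(predictions, labels, positive_class: int = 1) -> ConfusionCounts:
    preds = np.asarray(predictions)
    labs = np.asarray(labels)
    if preds.shape != labs.shape:
        raise ValueError("predictions and labels must have equal length")
    pos = labs == positive_class
    ppos = preds == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pos & ppos)), fp=int(np.sum(~pos & ppos)),
        tn=int(np.sum(~pos & ~ppos)), fn=int(np.sum(pos & ~ppos)))


def metrics(counts: ConfusionCounts, level: str = "slice-2D") -> MetricsReport:
    """Accuracy, sensitivity, specificity from confusion counts."""
    if counts.total == 0:
        raise ValueError("cannot compute metrics from all-zero counts")

    def _ratio(num, den):
        return num / den if den > 0 else None

    return MetricsReport(
        accuracy=_ratio(counts.tp + counts.tn, counts.total),
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn),
        specificity=_ratio(counts.tn, counts.fp + counts.tn),
        level=level)


def predict_slices(params, config: ModelConfig, images: np.ndarray,
                   threshold: float = 0.5, batch_size: int = 256):
    """Per-slice class decisions (and class-1 probabilities) for an image stack."""
    probs = np.concatenate([
        forward(params, config, images[i:i + batch_size])
        for i in range(0, len(images), batch_size)])
    p1 = probs[:, 1]
    return (p1 >= threshold).astype(int), p1


def evaluate_slice_level(params, config: ModelConfig, dataset: SliceDataset,
                         threshold: float = 0.5) -> MetricsReport:
    """Pooled 2D slice accuracy/sensitivity/specificity over a slice dataset."""
    preds, _ = predict_slices(params, config, dataset.images, threshold)
    return metrics(confusion(preds, dataset.labels), level="slice-2D")


def evaluate_patient_level(params, config: ModelConfig, test_scans,
                           n_per_view: int = 5, out_size: int | None = None,
                           threshold: float = 0.5):
    """Scan-level evaluation: preprocess each test patient (no augmentation),
    predict every slice, majority-vote the patient decision.

    Patients whose mask cannot supply the required slices are skipped with a
    warning.  Returns (patient predictions, patient-level report,
    slice-level report).
    """
    out_size = config.input_size if out_size is None else out_size
    patient_preds: list[PatientPrediction] = []
    slice_preds_all, slice_labels_all = [], []
    for scan in test_scans:
        try:
            records = preprocess_scan(scan, n_per_view=n_per_view,
                                      out_size=out_size)
        except ValueError as exc:
            warnings.warn(f"skipping patient {scan.patient_id}: {exc}")
            continue
        images = np.stack([r.image for r in records])
        preds, _ = predict_slices(params, config, images, threshold)
        patient_preds.append(PatientPrediction(
            patient_id=scan.patient_id, slice_predictions=list(map(int, preds)),
            decision=majority_vote(preds), label=scan.label))
        slice_preds_all.append(preds)
        slice_labels_all.append(np.full(len(preds), scan.label))
    if not patient_preds:
        raise ValueError("no evaluable test patients")
    patient_report = metrics(confusion(
        [p.decision for p in patient_preds],
        [p.label for p in patient_preds]), level="patient-3D")
    slice_report = metrics(confusion(
        np.concatenate(slice_preds_all), np.concatenate(slice_labels_all)),
        level="slice-2D")
    return patient_preds, patient_report, slice_report


def aggregate_runs(reports: list[MetricsReport]) -> MetricsReport:
    """Mean and sample (n-1) standard deviation across repeated runs.

    An undefined (None) entry in any run makes the aggregate undefined.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    levels = {r.level for r in reports}
    level = levels.pop() if len(levels) == 1 else "mixed"
    out = {"level": level, "n_runs": len(reports)}
    for name in ("accuracy", "sensitivity", "specificity"):
        vals = [getattr(r, name) for r in reports]
        if any(v is None for v in vals):
            out[name] = None
            out[f"{name}_std"] = None
        else:
            arr = np.asarray(vals, dtype=float)
            out[name] = float(arr.mean())
            out[f"{name}_std"] = (float(arr.std(ddof=1)) if len(arr) > 1
                                  else None)
    return MetricsReport(**out)


def reports_to_frame(rows: dict) -> pd.DataFrame:
    """Flatten {name: MetricsReport} into a tidy DataFrame for CSV output."""
    return pd.DataFrame([{"name": k, **v.as_dict()} for k, v in rows.items()])
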