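"""Patient-level aggregation, cohort balancing, cross-validation and
metrics.

Per-image death probabilities are combined per patient by their
arithmetic mean; the patient is classified non-survivor when that mean
reaches the decision threshold (ties classify positive). The evaluation
protocol is a 10-fold rotation over patient-level groups: each fold uses
one group for testing, the next two (cyclically) for validation and the
remaining seven for training, so every patient is tested exactly once
and a patient's three images never straddle roles.

Metrics (positive class = non-survivor):

    sensitivity = TP / (TP + FN) * 100
    specificity = TN / (FP + TN) * 100
    accuracy    = (TP + TN) / (TP + TN + FP + FN) * 100

plus the ROC curve (false-positive rate vs sensitivity over all score
cutoffs) and its trapezoidal area.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import (
    EmptyInputError,
    LeakageError,
    ProtocolError,
    SamplingError,
    ShapeError,
    UndefinedMetricError,
)
from .model import ImageDataset, TrainConfig, build_classifier, train


@dataclass(frozen=True)
class PredictionResult:
    """Patient-level prediction: three per-image scores and their mean."""

    patient_id: str
    per_image_probs: tuple[float, ...]
    aggregated_prob: float
    predicted_label: int
    true_label: int


@dataclass(frozen=True)
class FoldAssignment:
    """Patient-level k-group split with a rotating 7/2/1 role schedule."""

    k: int
    group_of: dict[str, int]
    role_schedule: list[dict[str, list[int]]]

    def patients_in_groups(self, groups) -> list[str]:
        wanted = set(groups)
        return [p for p, g in self.group_of.items() if g in wanted]

    def fold_patients(self, fold: int) -> dict[str, list[str]]:
        roles = self.role_schedule[fold]
        return {role: self.patients_in_groups(groups)
                for role, groups in roles.items()}


@dataclass(frozen=True)
class MetricsReport:
    """Confusion counts, the three rate metrics (percent) and ROC/AUC.

    A rate whose denominator is zero is None and named in
    ``undefined_metrics`` (never silently reported as 0).
    """

    tps: int
    tns: int
    fps: int
    fns: int
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    auc: float | None = None
    undefined_metrics: tuple[str, ...] = ()

    @property
    def n_patients(self) -> int:
        return self.tps + self.tns + self.fps + self.fns


def undersample_majority(ids_major: list[str], n_minor: int,
                         seed: int) -> list[str]:
    """Uniform random sample of ``n_minor`` majority-class patients.

    Deterministic for a given seed; used to balance the cohort before
    training (e.g. 291 survivors kept out of 9457).
    """
    if n_minor > len(ids_major):
        raise SamplingError(
            f"cannot sample {n_minor} from {len(ids_major)} ids")
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(ids_major), size=n_minor, replace=False)
    return [ids_major[i] for i in picked]


def make_folds(patient_ids: list[str], k: int = 10,
               seed: int = 0) -> FoldAssignment:
    """Deal shuffled patients into k balanced groups and build the
    rotating role schedule: fold f tests group f, validates on groups
    (f+1, f+2) mod k, trains on the rest.
    """
    if k < 3:
        raise ProtocolError(
            f"k must be >= 3 (train/val/test roles need 3 groups), got {k}")
    if len(patient_ids) < k:
        raise ProtocolError(
            f"{len(patient_ids)} patients cannot fill {k} groups")
    if len(set(patient_ids)) != len(patient_ids):
        raise ProtocolError("duplicate patient ids")
    rng = np.random.default_rng(seed)
    order = [patient_ids[i] for i in rng.permutation(len(patient_ids))]
    group_of = {pid: i % k for i, pid in enumerate(order)}
    schedule = []
    for f in range(k):
        val = [(f + 1) % k, (f + 2) % k]
        schedule.append({
            "test": [f],
            "val": val,
            "train": [g for g in range(k) if g != f and g not in val],
        })
    return FoldAssignment(k=k, group_of=group_of, role_schedule=schedule)


def aggregate_patient(per_image_probs, threshold: float = 0.5,
                      patient_id: str = "", true_label: int = 0,
                      n_segments: int = 3) -> PredictionResult:
    """Mean of the per-image death probabilities, thresholded (ties -> 1)."""
    probs = tuple(float(p) for p in per_image_probs)
    if len(probs) != n_segments:
        raise ShapeError(
            f"expected {n_segments} per-image probabilities, got {len(probs)}")
    if any(not 0.0 <= p <= 1.0 for p in probs):
        raise ShapeError("probabilities must lie in [0, 1]")
    mean = float(np.mean(probs))
    return PredictionResult(patient_id=patient_id, per_image_probs=probs,
                            aggregated_prob=mean,
                            predicted_label=int(mean >= threshold),
                            true_label=int(true_label))


def confusion_and_rates(results: list[PredictionResult]) -> MetricsReport:
    """Confusion counts and the three percentage metrics.

    Positive class is non-survivor (label 1). Undefined rates are
    reported as None and flagged.
    """
    if not results:
        raise EmptyInputError("no prediction results to score")
    tps = sum(1 for r in results if r.true_label == 1 and r.predicted_label == 1)
    fns = sum(1 for r in results if r.true_label == 1 and r.predicted_label == 0)
    tns = sum(1 for r in results if r.true_label == 0 and r.predicted_label == 0)
    fps = sum(1 for r in results if r.true_label == 0 and r.predicted_label == 1)
    undefined = []
    sensitivity = specificity = None
    if tps + fns > 0:
        sensitivity = tps / (tps + fns) * 100.0
    else:
        undefined.append("sensitivity")
    if fps + tns > 0:
        specificity = tns / (fps + tns) * 100.0
    else:
        undefined.append("specificity")
    accuracy = (tps + tns) / len(results) * 100.0
    return MetricsReport(tps=tps, tns=tns, fps=fps, fns=fns,
                         sensitivity=sensitivity, specificity=specificity,
                         accuracy=accuracy,
                         undefined_metrics=tuple(undefined))


def roc_auc(aggregated_probs, true_labels) -> tuple[list[tuple[float, float]], float]:
    """ROC curve (FPR, sensitivity) over all score cutoffs, and its
    trapezoidal area. Equal scores collapse into a single ROC step.

    Raises
    ------
    UndefinedMetricError
        If only one class is present.
    """
    scores = np.asarray(aggregated_probs, dtype=np.float64)
    labels = np.asarray(true_labels, dtype=np.int64)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ShapeError("scores and labels must be equal-length 1-D arrays")
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError(
            "ROC/AUC needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(labels, scores)
    points = list(zip(fpr.tolist(), tpr.tolist()))
    return points, float(_sk_auc(fpr, tpr))


def score_report(results: list[PredictionResult]) -> MetricsReport:
    """Full report: confusion counts, rates, ROC points and AUC."""
    report = confusion_and_rates(results)
    labels = [r.true_label for r in results]
    if len(set(labels)) == 2:
        points, area = roc_auc([r.aggregated_prob for r in results], labels)
        report = replace(report, roc_points=points, auc=area)
    else:
        report = replace(
            report,
            undefined_metrics=report.undefined_metrics + ("auc",))
    return report


@dataclass
class CrossValidationResult:
    fold_reports: list[MetricsReport]
    pooled_report: MetricsReport
    fold_results: list[list[PredictionResult]]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([r.accuracy for r in self.fold_reports]))

    @property
    def mean_auc(self) -> float | None:
        aucs = [r.auc for r in self.fold_reports if r.auc is not None]
        return float(np.mean(aucs)) if aucs else None


def predict_patients(model, dataset: ImageDataset,
                     threshold: float = 0.5) -> list[PredictionResult]:
    """Per-image death probabilities aggregated to patient level."""
    by_patient: dict[str, list] = {}
    for it in dataset.items:
        by_patient.setdefault(it.patient_id, []).append(it)
    results = []
    for pid in sorted(by_patient):
        items = sorted(by_patient[pid], key=lambda it: it.segment_index)
        probs = model.predict_proba(np.stack([it.image for it in items]))[:, 1]
        results.append(aggregate_patient(
            probs, threshold=threshold, patient_id=pid,
            true_label=items[0].label, n_segments=len(items)))
    return results


def _check_no_leakage(splits: dict[str, ImageDataset]) -> None:
    roles = list(splits)
    for i, a in enumerate(roles):
        for b in roles[i + 1:]:
            shared = splits[a].patient_ids & splits[b].patient_ids
            if shared:
                raise LeakageError(
                    f"patients in both {a} and {b}: {sorted(shared)[:5]}")


def run_cross_validation(dataset: ImageDataset,
                         config: TrainConfig | None = None,
                         k: int = 10, seed: int = 0,
                         backbone: str = "tiny2d",
                         model_factory=None) -> CrossValidationResult:
    """The full k-fold protocol on a labelled image dataset.

    For each fold a *fresh* model is built (parameters re-initialized),
    trained on the 7 train groups, monitored on the 2 validation groups
    and scored on the single test group; the pooled report concatenates
    the per-fold test predictions (every patient tested exactly once).

    ``model_factory(fold_index) -> model`` overrides the default
    build-and-train path's model construction; it exists so protocol
    behaviour can be exercised with inexpensive models.
    """
    config = config or TrainConfig()
    folds = make_folds(sorted(dataset.patient_ids), k=k, seed=seed)
    fold_reports, fold_results = [], []
    for f in range(k):
        roles = folds.fold_patients(f)
        splits = {role: dataset.subset(pids) for role, pids in roles.items()}
        _check_no_leakage(splits)
        if model_factory is not None:
            model = model_factory(f)
        else:
            fold_config = replace(config, seed=config.seed + f)
            model = build_classifier(backbone, fold_config)
        model, _history = train(model, splits["train"], splits["val"],
                                getattr(model, "config", config))
        results = predict_patients(model, splits["test"],
                                   threshold=config.threshold)
        fold_results.append(results)
        fold_reports.append(score_report(results))
    pooled = score_report([r for fold in fold_results for r in fold])
    return CrossValidationResult(fold_reports=fold_reports,
                                 pooled_report=pooled,
                                 fold_results=fold_results)
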