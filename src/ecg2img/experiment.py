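"""End-to-end synthetic experiments: cohort -> images -> training ->
patient-level evaluation on a held-out split.

The single-split experiment mirrors one fold of the full protocol at
desk scale: a balanced synthetic cohort is generated, encoded into
stacked-lead images, split 7/2/1 at patient level (stratified by
outcome), a fresh tiny2d classifier is trained end-to-end, and the
held-out patients are scored by mean-of-three-images aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ProtocolError
from .evaluation import (
    MetricsReport,
    PredictionResult,
    predict_patients,
    score_report,
)
from .imaging import ECGImagePanel, RenderConfig, encode_patient
from .leads import select_panel
from .model import ImageDataset, TrainConfig, build_classifier, train
from .signal_io import WaveformRecord
from .synthetic import SynthParams, gen_cohort

#: Train/validation/test fractions matching the 7/2/1 protocol.
DEFAULT_SPLIT = (0.7, 0.2, 0.1)


def encode_cohort(records: list[WaveformRecord],
                  config: RenderConfig | None = None) -> list[ECGImagePanel]:
    """Lead selection + image encoding for every record."""
    config = config or RenderConfig()
    return [encode_patient(select_panel(rec), config) for rec in records]


def split_patients(dataset: ImageDataset, seed: int,
                   fractions: tuple[float, float, float] = DEFAULT_SPLIT
                   ) -> dict[str, ImageDataset]:
    """Patient-level stratified train/val/test split.

    Within each outcome class, patients are shuffled and dealt so each
    split keeps the cohort's class balance; splits are patient-disjoint
    by construction.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ProtocolError(f"split fractions must sum to 1, got {fractions}")
    label_of = {it.patient_id: it.label for it in dataset.items}
    rng = np.random.default_rng(seed)
    roles: dict[str, list[str]] = {"train": [], "val": [], "test": []}
    for label in sorted(set(label_of.values())):
        pids = sorted(p for p, l in label_of.items() if l == label)
        pids = [pids[i] for i in rng.permutation(len(pids))]
        n = len(pids)
        n_train = int(round(fractions[0] * n))
        n_val = int(round(fractions[1] * n))
        roles["train"].extend(pids[:n_train])
        roles["val"].extend(pids[n_train:n_train + n_val])
        roles["test"].extend(pids[n_train + n_val:])
    if not all(roles.values()):
        raise ProtocolError("a split role received zero patients")
    return {role: dataset.subset(pids) for role, pids in roles.items()}


@dataclass
class ExperimentResult:
    model: object
    history: list[dict]
    splits: dict[str, ImageDataset]
    test_results: list[PredictionResult]
    report: MetricsReport


def run_split_experiment(panels: list[ECGImagePanel],
                         train_config: TrainConfig,
                         split_seed: int,
                         backbone: str = "tiny2d") -> ExperimentResult:
    """Train on pre-encoded panels with a stratified 7/2/1 split."""
    dataset = ImageDataset.from_panels(panels)
    splits = split_patients(dataset, seed=split_seed)
    model = build_classifier(backbone, train_config)
    model, history = train(model, splits["train"], splits["val"], train_config)
    results = predict_patients(model, splits["test"],
                               threshold=train_config.threshold)
    return ExperimentResult(model=model, history=history, splits=splits,
                            test_results=results,
                            report=score_report(results))


def heldout_predictions(result: ExperimentResult,
                        include_val: bool = False) -> list[PredictionResult]:
    """Patient-level predictions on held-out patients.

    With ``include_val`` the validation patients are included: they
    receive no gradient updates (validation only monitors the loss and
    there is no early stopping), so they are held out in the sense that
    matters for an unbiased score — useful when the 10% test split alone
    is too small for a stable AUC.
    """
    items = list(result.splits["test"].items)
    if include_val:
        items += result.splits["val"].items
    ds = ImageDataset(items=items)
    threshold = getattr(result.model, "config", TrainConfig()).threshold
    return predict_patients(result.model, ds, threshold=threshold)


def run_single_split_experiment(n_per_class: int = 100,
                                seed: int = 0,
                                params: SynthParams | None = None,
                                train_config: TrainConfig | None = None,
                                render_config: RenderConfig | None = None
                                ) -> ExperimentResult:
    """Generate, encode, train and evaluate in one call.

    ``seed`` drives cohort generation, the patient split and model
    initialization/training (all derived deterministically).
    """
    params = params or SynthParams()
    train_config = train_config or TrainConfig(freeze_backbone=False,
                                               seed=seed)
    records = gen_cohort(n_per_class, seed=seed, params=params)
    panels = encode_cohort(records, render_config)
    return run_split_experiment(panels, train_config, split_seed=seed + 17)
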