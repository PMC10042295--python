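"""Binary classifier harness: backbones, heads, training, prediction.

The harness is backbone-agnostic in the transfer-learning sense: a
backbone is a convolutional feature extractor whose classification head
is discarded and replaced by two freshly initialized fully connected
layers (hidden ReLU layer, then a 2-way softmax-normalized output). With
``freeze_backbone`` only the new head receives gradient updates.

The built-in ``tiny2d`` backbone (three conv+pool blocks) trains from
scratch in minutes on a CPU and is the default for tests and synthetic
experiments. A four-branch 1-D CNN over the raw leads (four conv+pool
blocks per lead, branch features fused in one fully connected layer) is
provided as the conventional-waveform-analysis baseline.

Class convention everywhere: 0 = survivor, 1 = non-survivor; the
"death probability" is the softmax score of class 1.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .errors import (
    ConfigurationError,
    EmptyInputError,
    LeakageError,
    ShapeError,
)
from .imaging import ECGImagePanel

#: Hyperparameters used in the original GPU-scale protocol.
PAPER_LEARNING_RATE = 1e-6
PAPER_EPOCHS = 50

IMAGE_SIZE = 224
LEAD_SAMPLES = 5000
N_PANEL_LEADS = 4


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    Defaults are desk-scale (Adam at 1e-3, 10 epochs); the original
    protocol used a learning rate of 1e-6 for 50 epochs with batch size 8
    on pretrained backbones (see ``PAPER_LEARNING_RATE``/``PAPER_EPOCHS``).
    """

    learning_rate: float = 1e-3
    epochs: int = 10
    batch_size: int = 8
    seed: int = 0
    freeze_backbone: bool = True
    head_hidden_units: int = 256
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ConfigurationError("epochs and batch_size must be >= 1")
        if not 0.0 < self.threshold < 1.0:
            raise ConfigurationError("threshold must lie in (0, 1)")


@dataclass(frozen=True)
class ImageItem:
    """One training/evaluation image: a segment of one patient's panel."""

    image: np.ndarray  # (224, 224) uint8
    patient_id: str
    segment_index: int
    label: int


@dataclass
class ImageDataset:
    """Per-image dataset where every patient contributes one item per
    segment (three by default) and labels are constant within a patient."""

    items: list[ImageItem]
    segments_per_patient: int = 3

    def __post_init__(self) -> None:
        counts: dict[str, int] = {}
        labels: dict[str, int] = {}
        for it in self.items:
            counts[it.patient_id] = counts.get(it.patient_id, 0) + 1
            if labels.setdefault(it.patient_id, it.label) != it.label:
                raise ShapeError(
                    f"patient {it.patient_id!r} has inconsistent labels")
        bad = {p: c for p, c in counts.items()
               if c != self.segments_per_patient}
        if bad:
            raise ShapeError(
                f"patients with != {self.segments_per_patient} images: {bad}")

    @classmethod
    def from_panels(cls, panels: list[ECGImagePanel]) -> "ImageDataset":
        items = []
        for panel in panels:
            if panel.label is None:
                raise ShapeError(f"panel {panel.patient_id!r} has no label")
            for k, img in enumerate(panel.images):
                items.append(ImageItem(image=img, patient_id=panel.patient_id,
                                       segment_index=k, label=panel.label))
        segs = len(panels[0].images) if panels else 3
        return cls(items=items, segments_per_patient=segs)

    @property
    def patient_ids(self) -> set[str]:
        return {it.patient_id for it in self.items}

    def subset(self, patient_ids) -> "ImageDataset":
        wanted = set(patient_ids)
        return ImageDataset(
            items=[it for it in self.items if it.patient_id in wanted],
            segments_per_patient=self.segments_per_patient)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        x = np.stack([it.image for it in self.items])[:, None, :, :]
        y = np.array([it.label for it in self.items], dtype=np.int64)
        return x, y


@dataclass(frozen=True)
class WaveformItem:
    """One patient's (4, L) lead array for the 1-D baseline."""

    leads: np.ndarray
    patient_id: str
    label: int


@dataclass
class WaveformDataset:
    """Per-patient raw-lead dataset consumed by the 1-D baseline."""

    items: list[WaveformItem]

    @property
    def patient_ids(self) -> set[str]:
        return {it.patient_id for it in self.items}

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        x = np.stack([it.leads for it in self.items])
        y = np.array([it.label for it in self.items], dtype=np.int64)
        return x, y


def _normalize_images(images: np.ndarray) -> np.ndarray:
    """uint8 grids -> float in [0, 1] with the trace as the high signal."""
    return ((255.0 - images.astype(nn.DTYPE)) / np.asarray(255.0, nn.DTYPE))


class ImageClassifier:
    """2-D CNN: frozen-or-trainable backbone plus a two-layer head."""

    def __init__(self, backbone_layers: list[nn.Layer], feature_channels: int,
                 gradcam_layer_index: int, config: TrainConfig,
                 backbone_name: str):
        rng = np.random.default_rng(config.seed + 1_000_003)
        if config.freeze_backbone:
            for layer in backbone_layers:
                if layer.params():
                    layer.trainable = False
        head = [nn.GlobalAvgPool(),
                nn.Dense(feature_channels, config.head_hidden_units, rng),
                nn.ReLU(),
                nn.Dense(config.head_hidden_units, 2, rng)]
        self.net = nn.Sequential(backbone_layers + head)
        self.gradcam_layer_index = gradcam_layer_index
        self.config = config
        self.backbone_name = backbone_name
        self.n_backbone_layers = len(backbone_layers)

    # -- array plumbing ----------------------------------------------------
    def prepare(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        if x.shape[-2:] != (IMAGE_SIZE, IMAGE_SIZE):
            raise ShapeError(
                f"expected {IMAGE_SIZE}x{IMAGE_SIZE} images, got {x.shape[-2:]}")
        return _normalize_images(x)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return self.net.backward(grad)

    def predict_proba(self, images: np.ndarray,
                      batch_size: int = 32) -> np.ndarray:
        """(n, 2) class scores (survivor, non-survivor), rows sum to 1."""
        x = self.prepare(images)
        outs = [nn.softmax(self.net.forward(x[i:i + batch_size]))
                for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(outs, axis=0)

    def trainable_parameter_count(self) -> int:
        return self.net.trainable_parameter_count()

    def backbone_params(self) -> list[np.ndarray]:
        return [p for l in self.net.layers[:self.n_backbone_layers]
                for p in l.params()]


def _tiny2d_backbone(rng: np.random.Generator) -> tuple[list[nn.Layer], int, int]:
    layers = [
        nn.Conv2D(1, 8, 3, rng, stride=2), nn.ReLU(), nn.MaxPool2D(2),  # 224 -> 56
        nn.Conv2D(8, 16, 3, rng), nn.ReLU(), nn.MaxPool2D(2),           # 56 -> 28
        nn.Conv2D(16, 32, 3, rng), nn.ReLU(), nn.MaxPool2D(2),          # 28 -> 14
    ]
    # GradCAM target: output of the ReLU after the final convolution
    # (index 7), spatial resolution 28x28, 32 channels.
    return layers, 32, 7


_BACKBONES = {"tiny2d": _tiny2d_backbone}


def build_classifier(backbone: str = "tiny2d",
                     config: TrainConfig | None = None) -> ImageClassifier:
    """Construct a classifier with a replaced two-layer head.

    Raises
    ------
    ConfigurationError
        For an unknown backbone identifier.
    """
    config = config or TrainConfig()
    if backbone not in _BACKBONES:
        raise ConfigurationError(
            f"unknown backbone {backbone!r}; available: {sorted(_BACKBONES)}")
    rng = np.random.default_rng(config.seed)
    layers, channels, cam_index = _BACKBONES[backbone](rng)
    return ImageClassifier(layers, channels, cam_index, config,
                           backbone_name=backbone)


class LeadSignalClassifier:
    """Four-branch 1-D CNN baseline over raw (4, 5000) lead arrays."""

    def __init__(self, config: TrainConfig):
        rng = np.random.default_rng(config.seed)
        self.branches = []
        for _ in range(N_PANEL_LEADS):
            self.branches.append(nn.Sequential([
                nn.Conv1D(1, 8, 7, rng), nn.ReLU(), nn.MaxPool1D(4),
                nn.Conv1D(8, 16, 7, rng), nn.ReLU(), nn.MaxPool1D(4),
                nn.Conv1D(16, 32, 5, rng), nn.ReLU(), nn.MaxPool1D(4),
                nn.Conv1D(32, 32, 5, rng), nn.ReLU(), nn.MaxPool1D(4),
                nn.GlobalAvgPool(),
            ]))
        self.head = nn.Sequential([nn.Dense(32 * N_PANEL_LEADS, 2, rng)])
        self.config = config

    def prepare(self, leads: np.ndarray) -> np.ndarray:
        x = np.asarray(leads, dtype=nn.DTYPE)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[1] != N_PANEL_LEADS:
            raise ShapeError(
                f"expected (n, {N_PANEL_LEADS}, L) lead arrays, got {x.shape}")
        return x

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 3 or x.shape[1] != N_PANEL_LEADS:
            raise ShapeError(
                f"expected (n, {N_PANEL_LEADS}, L) input, got {x.shape}")
        feats = [b.forward(x[:, i:i + 1, :])
                 for i, b in enumerate(self.branches)]
        return self.head.forward(np.concatenate(feats, axis=1))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dfeats = self.head.backward(grad)
        outs = []
        for i, b in enumerate(self.branches):
            outs.append(b.backward(dfeats[:, i * 32:(i + 1) * 32]))
        return np.concatenate(outs, axis=1)

    def predict_proba(self, leads: np.ndarray,
                      batch_size: int = 32) -> np.ndarray:
        x = self.prepare(leads)
        outs = [nn.softmax(self.forward(x[i:i + batch_size]))
                for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(outs, axis=0)

    def trainable_parameter_count(self) -> int:
        return (sum(b.trainable_parameter_count() for b in self.branches)
                + self.head.trainable_parameter_count())

    # train() accesses parameters through these two methods
    def _all_nets(self):
        return self.branches + [self.head]

    def trainable_params(self):
        return [p for net in self._all_nets() for p in net.trainable_params()]

    def trainable_grads(self):
        return [g for net in self._all_nets() for g in net.trainable_grads()]


def build_1d_baseline(config: TrainConfig | None = None) -> LeadSignalClassifier:
    """The conventional 1-D CNN baseline (four conv+pool blocks per lead)."""
    return LeadSignalClassifier(config or TrainConfig())


def _model_params(model) -> tuple[list[np.ndarray], list[np.ndarray]]:
    if isinstance(model, ImageClassifier):
        return model.net.trainable_params(), model.net.trainable_grads()
    return model.trainable_params(), model.trainable_grads()


def train(model, train_set, val_set, config: TrainConfig | None = None):
    """Train ``model`` on per-image items with Adam + cross-entropy.

    Both sets must be :class:`ImageDataset`-like (``items``, ``arrays()``,
    ``patient_ids``) and patient-disjoint; history has one entry per epoch
    with train/validation loss and accuracy. The model at the final epoch
    is the returned model (no early stopping).

    Raises
    ------
    LeakageError
        If any patient appears in both train and validation sets.
    EmptyInputError
        If either split is empty.
    """
    config = config or (model.config if hasattr(model, "config") else TrainConfig())
    if not train_set.items or not val_set.items:
        raise EmptyInputError("train and validation sets must be non-empty")
    overlap = train_set.patient_ids & val_set.patient_ids
    if overlap:
        raise LeakageError(
            f"patients in both train and validation: {sorted(overlap)[:5]}")

    x_train_raw, y_train = train_set.arrays()
    x_val_raw, y_val = val_set.arrays()
    x_train = model.prepare(x_train_raw[:, 0] if x_train_raw.ndim == 4
                            else x_train_raw)
    x_val = model.prepare(x_val_raw[:, 0] if x_val_raw.ndim == 4
                          else x_val_raw)

    params, _ = _model_params(model)
    optimizer = nn.Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history = []
    n = x_train.shape[0]
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, epoch_correct = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x_train[idx], y_train[idx]
            logits = model.forward(xb)
            loss, dlogits = nn.softmax_cross_entropy(logits, yb)
            model.backward(dlogits)
            _, grads = _model_params(model)
            optimizer.step(grads)
            epoch_loss += loss * len(idx)
            epoch_correct += int((logits.argmax(axis=1) == yb).sum())
        val_loss, val_acc = _evaluate(model, x_val, y_val,
                                      config.batch_size * 4)
        history.append({
            "train_loss": epoch_loss / n,
            "train_accuracy": epoch_correct / n,
            "val_loss": val_loss,
            "val_accuracy": val_acc,
        })
    return model, history


def _evaluate(model, x: np.ndarray, y: np.ndarray,
              batch_size: int) -> tuple[float, float]:
    total_loss, correct = 0.0, 0
    for start in range(0, x.shape[0], batch_size):
        xb, yb = x[start:start + batch_size], y[start:start + batch_size]
        logits = model.forward(xb)
        loss, _ = nn.softmax_cross_entropy(logits, yb)
        total_loss += loss * len(yb)
        correct += int((logits.argmax(axis=1) == yb).sum())
    return total_loss / x.shape[0], correct / x.shape[0]


def predict_image(model: ImageClassifier, image: np.ndarray) -> float:
    """Death probability (class 1 score) for one 224x224 8-bit image."""
    img = np.asarray(image)
    if img.shape != (IMAGE_SIZE, IMAGE_SIZE):
        raise ShapeError(
            f"expected a {IMAGE_SIZE}x{IMAGE_SIZE} image, got {img.shape}")
    return float(model.predict_proba(img[None])[0, 1])


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: ImageClassifier, path: str | Path) -> None:
    """Save parameters as .npz with a JSON sidecar recording the config."""
    path = Path(path)
    arrays = {f"p{i}": p for i, p in enumerate(model.net.all_params())}
    np.savez(path, **arrays)
    sidecar = {"backbone": model.backbone_name,
               "train_config": asdict(model.config)}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(path: str | Path) -> ImageClassifier:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = TrainConfig(**sidecar["train_config"])
    model = build_classifier(sidecar["backbone"], config)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with np.load(npz_path) as data:
        for i, p in enumerate(model.net.all_params()):
            p[...] = data[f"p{i}"]
    return model
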