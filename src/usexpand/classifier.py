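"""The fixed five-conv-stage CNN and its class-weighted training loop.

Architecture: five 3x3 'same' convolutions (32, 64, 128, 128, 128
filters by default), each followed by ReLU, 20% dropout and 2x2/stride-2
max pooling; then 50% dropout, flatten, a 512-unit ReLU layer with 50%
dropout, and a 3-way softmax. With a 180-pixel input the spatial trace
is 180→90→45→22→11→5 (floor pooling) and the flatten width 3200, giving
2,028,291 trainable parameters.

Inputs are scaled to [0, 1] before entering the network. Training uses
Adam (lr 1e-4), class-weighted categorical cross-entropy (weights
N/(K·n_c), so each class has equal total impact), 50 epochs and batch
size 32 at paper scale; a reduced desk preset supports fast experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _nn
from .augment import AugmentPolicy, augment_stream
from .records import CLASSES, CohortManifest

__all__ = ["CnnSpec", "TrainConfig", "ScoreSet", "build_cnn", "class_weights",
           "weighted_cross_entropy", "train_classifier", "predict"]


@dataclass(frozen=True)
class CnnSpec:
    input_side: int = 180
    conv_filters: tuple[int, ...] = (32, 64, 128, 128, 128)
    kernel: int = 3
    conv_dropout: float = 0.20
    post_pool_dropout: float = 0.50
    post_fc_dropout: float = 0.50
    fc_width: int = 512
    n_classes: int = 3

    def spatial_trace(self) -> list[int]:
        side = self.input_side
        trace = [side]
        for _ in self.conv_filters:
            side = side // 2
            trace.append(side)
        return trace

    def flatten_width(self) -> int:
        final = self.spatial_trace()[-1]
        return final * final * self.conv_filters[-1]


def desk_cnn_spec(side: int = 64) -> CnnSpec:
    """Narrow five-stage variant for small synthetic images.

    Width and dropout are reduced together: at desk width the full-size
    regularisation (20%/50%) leaves the network unable to fit even the
    training set, so the preset keeps the same structure with lighter
    dropout.
    """
    return CnnSpec(input_side=side, conv_filters=(16, 32, 64, 64, 64), fc_width=128,
                   conv_dropout=0.10, post_pool_dropout=0.25, post_fc_dropout=0.25)


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0
    augment_policy: AugmentPolicy | None = None
    lr_decay: bool = False   # linear decay to ~0 over the final third

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class ScoreSet:
    """Per-image class probabilities with truth and patient ids."""

    probabilities: np.ndarray          # (N, 3) rows over CLASSES order
    true_classes: list[str]
    patient_ids: list[str]
    combination_id: int | None = None

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        if self.probabilities.ndim != 2 or self.probabilities.shape[1] != len(CLASSES):
            raise ValueError("probabilities must be (N, 3)")
        if (self.probabilities < 0).any():
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.probabilities.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")
        if len(self.true_classes) != len(self.probabilities):
            raise ValueError("length mismatch between probabilities and labels")

    def __len__(self):
        return len(self.true_classes)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({
            "patient_id": self.patient_ids,
            "true_class": self.true_classes,
            "p_normal": self.probabilities[:, 0],
            "p_benign": self.probabilities[:, 1],
            "p_malignant": self.probabilities[:, 2],
        })
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, combination_id=None) -> "ScoreSet":
        df = pd.read_csv(path)
        probs = df[["p_normal", "p_benign", "p_malignant"]].to_numpy()
        return cls(probs, df["true_class"].tolist(),
                   df["patient_id"].astype(str).tolist(), combination_id)


def build_cnn(spec: CnnSpec = CnnSpec(), seed: int = 0) -> _nn.Sequential:
    if spec.input_side // 2 ** len(spec.conv_filters) < 1:
        raise ValueError(
            f"input side {spec.input_side} too small for {len(spec.conv_filters)} halvings")
    rng = np.random.default_rng(seed)
    layers: list[_nn.Layer] = []
    cin = 1
    for f in spec.conv_filters:
        layers += [_nn.Conv2d(cin, f, spec.kernel, stride=1, rng=rng),
                   _nn.ReLU(), _nn.Dropout(spec.conv_dropout), _nn.MaxPool2()]
        cin = f
    layers += [_nn.Dropout(spec.post_pool_dropout), _nn.Flatten(),
               _nn.Dense(spec.flatten_width(), spec.fc_width, rng=rng), _nn.ReLU(),
               _nn.Dropout(spec.post_fc_dropout),
               _nn.Dense(spec.fc_width, spec.n_classes, rng=rng, gain=1.0)]
    return _nn.Sequential(*layers)


def parameter_count(model: _nn.Sequential) -> int:
    return sum(p.size for p in model.params())


def class_weights(labels: list[str]) -> dict[str, float]:
    """w_c = N / (K * n_c): every class contributes equal total loss weight."""
    counts = {c: 0 for c in CLASSES}
    for lab in labels:
        counts[lab] += 1
    missing = [c for c, n in counts.items() if n == 0]
    if missing:
        raise ValueError(f"class(es) absent from training labels: {missing}")
    n = len(labels)
    k = len(CLASSES)
    return {c: n / (k * counts[c]) for c in CLASSES}


def weighted_cross_entropy(probabilities: np.ndarray, true_classes: list[str],
                           weights: dict[str, float]) -> float:
    """Batch-averaged -w_true * log p_true with a 1e-7 probability floor."""
    probs = np.asarray(probabilities, dtype=np.float64)
    idx = np.array([CLASSES.index(c) for c in true_classes])
    ptrue = np.clip(probs[np.arange(len(idx)), idx], 1e-7, None)
    w = np.array([weights[c] for c in true_classes])
    return float(np.mean(-w * np.log(ptrue)))


def _batch_arrays(records, weights):
    x = np.stack([r.pixels.astype(np.float64) / 255.0 for r in records])[:, None, :, :]
    y = np.zeros((len(records), len(CLASSES)))
    w = np.zeros(len(records))
    for i, r in enumerate(records):
        y[i, CLASSES.index(r.class_label)] = 1.0
        w[i] = weights[r.class_label]
    return x, y, w


def train_classifier(train_manifest: CohortManifest, config: TrainConfig = TrainConfig(),
                     spec: CnnSpec = CnnSpec()) -> tuple[_nn.Sequential, list[float]]:
    """Train the CNN; returns the final model and the per-epoch loss history."""
    labels = [r.class_label for r in train_manifest]
    weights = class_weights(labels)
    for r in train_manifest:
        if r.pixels.shape != (spec.input_side, spec.input_side):
            raise ValueError("training images must be preprocessed to the input side")
    model = build_cnn(spec, seed=config.seed)
    opt = _nn.Adam(model.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    stream = augment_stream(train_manifest, config.augment_policy, seed=config.seed + 2)
    history: list[float] = []
    n = len(train_manifest)
    for _epoch in range(config.epochs):
        if config.lr_decay:
            frac = max(0.0, (_epoch - config.epochs * 2 / 3) / (config.epochs / 3))
            opt.lr = config.learning_rate * (1.0 - frac) + 1e-5
        epoch_records = next(stream)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            batch = [epoch_records[i] for i in order[start: start + config.batch_size]]
            x, y, w = _batch_arrays(batch, weights)
            logits, caches = model.forward(x, rng=rng, train=True)
            loss, dlogits = _nn.softmax_cross_entropy(logits, y, w)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {_epoch}; history={history}")
            opt.zero_grad()
            model.backward(dlogits, caches)
            opt.step()
            epoch_loss += loss * len(batch)
        history.append(epoch_loss / n)
    return model, history


def predict(model: _nn.Sequential, manifest: CohortManifest, spec: CnnSpec = CnnSpec(),
            combination_id: int | None = None, batch_size: int = 64) -> ScoreSet:
    """Deterministic inference (dropout inactive); one probability row per record."""
    probs = []
    recs = manifest.records
    for start in range(0, len(recs), batch_size):
        batch = recs[start: start + batch_size]
        x = np.stack([r.pixels.astype(np.float64) / 255.0 for r in batch])[:, None, :, :]
        logits, _ = model.forward(x, train=False)
        probs.append(_nn.softmax(logits))
    probabilities = np.vstack(probs) if probs else np.zeros((0, len(CLASSES)))
    return ScoreSet(probabilities, [r.class_label for r in recs],
                    [r.patient_id for r in recs], combination_id)
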