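"""Binary tumor/normal classification via transfer-style training.

The classifier is a feature backbone with a replaceable 2-way head
(dropout + fully connected + softmax).  The bundled backbone is a small
inception-style network trained from scratch — two inception blocks of
parallel 1x1 / 3x3 / 5x5 convolution branches — so the whole transfer
recipe (replace head, optionally freeze the feature extractor, fine-tune)
runs in seconds on CPU with no pretrained-weight download.  An externally
pretrained backbone can be plugged in through the same protocol: any
object with ``features`` (a Sequential), ``feature_dim``, ``input_size``
and ``in_channels`` attributes.

Training uses plain cross-entropy on the 2-way head (class imbalance is a
pixel-level concern handled by the segmenter's focal loss, not an
image-level one here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.transform import resize

from .errors import DegenerateInputError, TumorsegError
from .nn import (
    Adam,
    BatchNorm2D,
    Concat,
    Conv2D,
    Dense,
    Dropout,
    GlobalAvgPool2D,
    MaxPool2D,
    ReLU,
    Sequential,
)
from .phantom import PhantomDataset

LABELS = ("normal", "tumor")  # index 0 / 1


@dataclass
class TransferConfig:
    backbone: str = "mini_inception_scratch"
    freeze_through: str | None = None  # None | "features" (= all but head)
    input_size: int = 32
    fine_tune_lr: float = 1e-3
    epochs: int = 15
    batch_size: int = 16
    seed: int = 0
    validation_fraction: float = 0.1
    dropout: float = 0.4

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.fine_tune_lr <= 0:
            raise TumorsegError("invalid transfer-training configuration")


@dataclass
class MiniInceptionBackbone:
    """Scratch inception-style feature extractor (protocol implementation)."""

    features: Sequential
    feature_dim: int
    input_size: int
    in_channels: int


def _conv_bn_relu(c_in, c_out, kernel, rng):
    return Sequential(
        [Conv2D(c_in, c_out, kernel=kernel, stride=1, pad=kernel // 2, rng=rng),
         BatchNorm2D(c_out), ReLU()]
    )


def _inception_block(c_in, widths, rng):
    """Parallel 1x1 / 3x3 / 5x5 conv branches concatenated on channels."""
    w1, w3, w5 = widths
    return Concat(
        [_conv_bn_relu(c_in, w1, 1, rng),
         _conv_bn_relu(c_in, w3, 3, rng),
         _conv_bn_relu(c_in, w5, 5, rng)]
    )


def build_mini_inception(
    in_channels: int = 1, input_size: int = 32, seed: int = 0
) -> MiniInceptionBackbone:
    rng = np.random.default_rng(seed)
    features = Sequential(
        [
            _conv_bn_relu(in_channels, 8, 3, rng),
            MaxPool2D(),
            _inception_block(8, (4, 8, 4), rng),   # -> 16 channels
            MaxPool2D(),
            _inception_block(16, (8, 16, 8), rng),  # -> 32 channels
        ]
    )
    return MiniInceptionBackbone(
        features=features, feature_dim=32, input_size=input_size, in_channels=in_channels
    )


class ClassifierModel:
    """Backbone + dropout + 2-way dense head with softmax output."""

    def __init__(self, backbone, head: Sequential, seed: int):
        self.backbone = backbone
        self.head = head
        self.seed = seed
        self.net = Sequential([backbone.features, head])
        self.normalize = True

    def prepare(self, image: np.ndarray) -> np.ndarray:
        x = prepare_input(image, self.backbone.input_size, channels=self.backbone.in_channels)
        if self.normalize:
            sd = x.std()
            if sd > 0:
                x = (x - x.mean()) / sd
        if x.ndim == 2:
            return x[None]  # (C=1, H, W)
        return x.transpose(2, 0, 1)

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return self.net.forward(x, train=train)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        z = self.forward_logits(x, train=False)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


def adapt_backbone(
    backbone="mini_inception_scratch",
    n_classes: int = 2,
    freeze_through: str | None = None,
    dropout: float = 0.4,
    seed: int = 0,
) -> ClassifierModel:
    """Attach a fresh dropout + dense head to a backbone; optionally freeze.

    ``backbone`` is either the name of the bundled scratch backbone or any
    object satisfying the backbone protocol (e.g. an externally pretrained
    feature extractor).
    """
    if n_classes < 2:
        raise TumorsegError("n_classes must be >= 2")
    if isinstance(backbone, str):
        if backbone == "mini_inception_scratch":
            backbone = build_mini_inception(seed=seed)
        elif backbone == "googlenet_pretrained":
            raise TumorsegError(
                "no pretrained weights are bundled; pass a backbone object "
                "implementing the backbone protocol instead"
            )
        else:
            raise TumorsegError(f"unknown backbone {backbone!r}")
    rng = np.random.default_rng(seed + 1)
    head = Sequential(
        [GlobalAvgPool2D(), Dropout(p=dropout, seed=seed + 2),
         Dense(backbone.feature_dim, n_classes, rng=rng)]
    )
    model = ClassifierModel(backbone, head, seed)
    if freeze_through in ("features", "all_but_head"):
        for layer in backbone.features.iter_layers():
            layer.trainable = False
    elif freeze_through is not None:
        raise TumorsegError(f"unknown freeze_through {freeze_through!r}")
    return model


def prepare_input(image: np.ndarray, input_size: int, channels: int = 1) -> np.ndarray:
    """Bilinear-resize to ``input_size`` square; replicate gray to 3 channels
    when a 3-channel backbone requires it."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if arr.shape[:2] != (input_size, input_size):
        arr = resize(arr, (input_size, input_size), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    if channels == 3 and arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    return arr


def _cross_entropy_and_grad(logits: np.ndarray, y: np.ndarray):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = len(y)
    pt = np.clip(p[np.arange(n), y], 1e-12, 1.0)
    loss = float(-np.log(pt).mean())
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    acc = float((p.argmax(axis=1) == y).mean())
    return loss, grad / n, acc


def train_classifier(
    model: ClassifierModel, data: PhantomDataset, config: TransferConfig
) -> tuple[ClassifierModel, pd.DataFrame]:
    """Seeded minibatch Adam training of the 2-way head (and any unfrozen
    backbone layers) with cross-entropy."""
    if len(data) == 0:
        raise TumorsegError("empty dataset")
    y = np.array([LABELS.index(lab) for lab in data.labels])
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("dataset contains a single class")
    x = np.stack([model.prepare(img) for img in data.images])

    rng = np.random.default_rng(config.seed)
    n = len(x)
    order = rng.permutation(n)
    n_val = int(round(config.validation_fraction * n))
    val_idx, train_idx = order[:n_val], order[n_val:]

    optim = Adam(model.net, lr=config.fine_tune_lr)
    history = []
    for epoch in range(1, config.epochs + 1):
        idx = train_idx.copy()
        rng.shuffle(idx)
        losses, accs, sizes = [], [], []
        for start in range(0, len(idx), config.batch_size):
            batch = idx[start : start + config.batch_size]
            logits = model.forward_logits(x[batch], train=True)
            loss, dz, acc = _cross_entropy_and_grad(logits, y[batch])
            model.net.backward(dz)
            optim.step()
            losses.append(loss)
            accs.append(acc)
            sizes.append(len(batch))
        sizes = np.asarray(sizes, dtype=np.float64)
        row = {
            "epoch": epoch,
            "train_loss": float(np.average(losses, weights=sizes)),
            "train_acc": float(np.average(accs, weights=sizes)),
        }
        if n_val:
            logits = model.forward_logits(x[val_idx], train=False)
            vloss, _, vacc = _cross_entropy_and_grad(logits, y[val_idx])
            row["val_loss"], row["val_acc"] = vloss, vacc
        else:
            row["val_loss"], row["val_acc"] = np.nan, np.nan
        history.append(row)
    return model, pd.DataFrame(history)


def predict_label(model: ClassifierModel, image: np.ndarray) -> tuple[str, dict[str, float]]:
    """Classify one image; returns the label and both class probabilities."""
    x = model.prepare(image)[None]
    p = model.predict_proba(x)[0]
    label = LABELS[int(p.argmax())]
    return label, {"normal": float(p[0]), "tumor": float(p[1])}


def predict_labels(model: ClassifierModel, images) -> list[str]:
    x = np.stack([model.prepare(img) for img in images])
    p = model.predict_proba(x)
    return [LABELS[i] for i in p.argmax(axis=1)]
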