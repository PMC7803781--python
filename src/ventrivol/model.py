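"""Per-slice semantic segmentation model and its training recipe.

An encoder-decoder convolutional network maps a 200x200x3 thickened
slice to a 200x200 3-class map (background / brain / ventricle).  The
training recipe: class-weighted cross-entropy with median-frequency
weights, SGD with learning rate 0.01, momentum 0.9, L2 regularisation
0.0005, mini-batches of 2 chosen by an epoch-wise reshuffle so every
image is used exactly once per epoch, ten epochs, and optional affine
augmentation (translation, rotation, scale, shear).

Two model sizes are provided.  ``tiny`` is a 3-level symmetric
encoder-decoder trained from scratch -- the size used throughout the test
suite.  ``vgg16`` reproduces a VGG16-shaped encoder with a mirrored
decoder; it is constructable (and a pretrained-initialisation hook
exists) but is far too large to train on a laptop-class CPU.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import nn
from .dataset import (
    AffineParams,
    ClassWeights,
    SliceDataset,
    SliceLabel,
    ThickSlice,
    apply_augmentation,
    augmentation_sample,
)
from .volume_io import CANVAS, VENTRICLE


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    momentum: float = 0.9
    weight_decay: float = 0.0005
    batch_size: int = 2
    epochs: int = 10
    augment: bool = False
    model_size: str = "tiny"  # "tiny" | "vgg16"
    pretrained_init: Optional[str] = None  # path to saved weights (hook)
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training configuration")
        if self.model_size not in ("tiny", "vgg16"):
            raise ValueError(f"unknown model_size {self.model_size!r}")


# encoder channel plans; 'P' = 2x2 max-pool.  The decoder mirrors the
# encoder with nearest-neighbour upsampling.
_PLANS = {
    "tiny": [8, "P", 16, "P", 32],
    # VGG16-shaped encoder, truncated to three pooling stages so the
    # 200-pixel canvas stays divisible by the pooling factor
    "vgg16": [64, 64, "P", 128, 128, "P", 256, 256, 256, "P", 512, 512, 512],
}


def _build(plan: list, rng: np.random.Generator, n_classes: int = 3) -> nn.Sequential:
    """Symmetric encoder-decoder from a channel plan.

    The decoder mirrors the encoder but reduces channels *before* each
    upsampling step (conv at the coarse resolution, then upsample), which
    keeps the expensive full-resolution convolutions narrow.
    """
    layers: list[nn.Layer] = []
    c = 3
    enc_widths = []  # conv widths per resolution level, shallow -> deep
    level = [3]
    for item in plan:
        if item == "P":
            layers.append(nn.MaxPool2())
            enc_widths.append(level)
            level = []
        else:
            layers.append(nn.Conv2d(c, item, 3, rng))
            layers.append(nn.ReLU())
            c = item
            level.append(item)
    enc_widths.append(level)
    # decoder: at each level conv down to the next-shallower width, upsample
    for target_level in reversed(enc_widths[:-1]):
        target = target_level[-1] if target_level else c
        layers.append(nn.Conv2d(c, target, 3, rng))
        layers.append(nn.ReLU())
        layers.append(nn.Upsample2())
        c = target
    layers.append(nn.Conv2d(c, c, 3, rng))
    layers.append(nn.ReLU())
    layers.append(nn.Conv2d(c, n_classes, 1, rng))
    return nn.Sequential(layers)


@dataclass
class EpochMetrics:
    epoch: int
    train_loss: float
    test_ventricle_iou: float


@dataclass
class SliceSegmenter:
    """A trained per-slice segmenter over the fixed 3-class list."""

    net: nn.Sequential
    classes: tuple[int, ...] = (0, 1, 2)
    canvas: tuple[int, int] = CANVAS
    config: Optional[TrainConfig] = None
    fingerprint: dict = field(default_factory=dict)

    def predict(self, image: ThickSlice) -> SliceLabel:
        """Argmax class map for one thickened slice; deterministic."""
        if image.pixels.shape[:2] != self.canvas:
            raise ValueError(
                f"input {image.pixels.shape[:2]} does not match canvas {self.canvas}"
            )
        x = _to_batch([image])
        logits = self.net.forward(x, train=False)
        pred = logits.argmax(axis=1)[0].astype(np.uint8)
        return SliceLabel(
            pixels=pred,
            centre_index=image.centre_index,
            source_id=image.source_id,
            pad_info=image.pad_info,
        )

    def predict_batch(self, images: Sequence[ThickSlice]) -> list[SliceLabel]:
        out = []
        for i in range(0, len(images), 8):
            chunk = list(images[i : i + 8])
            logits = self.net.forward(_to_batch(chunk), train=False)
            preds = logits.argmax(axis=1).astype(np.uint8)
            for img, pred in zip(chunk, preds):
                out.append(
                    SliceLabel(pred, img.centre_index, img.source_id, img.pad_info)
                )
        return out

    def save(self, path: str) -> str:
        arrays = {f"p{i}": a for i, a in enumerate(self.net.state_arrays())}
        meta = {
            "model_size": self.config.model_size if self.config else "tiny",
            "classes": list(self.classes),
            "fingerprint": self.fingerprint,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)
        return path

    @classmethod
    def load(cls, path: str) -> "SliceSegmenter":
        data = np.load(path if str(path).endswith(".npz") else path + ".npz")
        meta = json.loads(bytes(data["__meta__"]).decode())
        net = _build(_PLANS[meta["model_size"]], np.random.default_rng(0))
        for i, arr in enumerate(net.state_arrays()):
            arr[...] = data[f"p{i}"]
        cfg = TrainConfig(model_size=meta["model_size"])
        return cls(net=net, classes=tuple(meta["classes"]), config=cfg,
                   fingerprint=meta.get("fingerprint", {}))


def _to_batch(images: Sequence[ThickSlice]) -> np.ndarray:
    x = np.stack([im.pixels for im in images]).astype(np.float32) / 255.0
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))


def _alpha_array(weights: ClassWeights | None) -> np.ndarray:
    alpha = np.ones(3, dtype=np.float32)
    if weights is not None:
        for c, a in weights.alpha.items():
            alpha[c] = a
    return alpha


def corpus_hash(labels: Sequence[SliceLabel]) -> str:
    h = hashlib.sha256()
    for lab in labels:
        h.update(lab.pixels.tobytes())
    return h.hexdigest()


def train(
    dataset: SliceDataset, config: TrainConfig
) -> tuple[SliceSegmenter, list[EpochMetrics]]:
    """Train a slice segmenter; deterministic given the config seed.

    Class weights come from the dataset (training split only).  Each epoch
    reshuffles the training set and forms mini-batches without
    replacement so every image is used exactly once per epoch.  Logged
    metrics: mean training loss and test-split ventricle IoU per epoch.
    """
    if not dataset.train_images:
        raise ValueError("empty training set")
    rng = np.random.default_rng(config.seed)
    net = _build(_PLANS[config.model_size], rng)
    model = SliceSegmenter(net=net, config=config)
    if config.pretrained_init:
        init = SliceSegmenter.load(config.pretrained_init)
        for dst, src in zip(net.state_arrays(), init.net.state_arrays()):
            if dst.shape == src.shape:
                dst[...] = src
    alpha = _alpha_array(dataset.class_weights)
    opt = nn.SGD(net.layers, config.learning_rate, config.momentum,
                 config.weight_decay)
    xs = _to_batch(dataset.train_images)
    ys = np.stack([l.pixels for l in dataset.train_labels])
    n = len(dataset.train_images)
    metrics: list[EpochMetrics] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for i in range(0, n, config.batch_size):
            sel = order[i : i + config.batch_size]
            xb, yb = xs[sel], ys[sel]
            if config.augment:
                xb, yb = _augment_batch(xb, yb, rng)
            logits = net.forward(xb, train=True)
            loss, dlogits = nn.weighted_softmax_ce(logits, yb, alpha)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, step {i // config.batch_size}: "
                    f"learning rate {config.learning_rate} too high for this corpus"
                )
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        iou, _ = evaluate_slices(model, dataset.test_images, dataset.test_labels)
        metrics.append(EpochMetrics(epoch, float(np.mean(losses)), iou))
    model.fingerprint = {
        "config": json.dumps(vars(config), default=str, sort_keys=True),
        "corpus": corpus_hash(dataset.train_labels),
    }
    return model, metrics


def _augment_batch(xb: np.ndarray, yb: np.ndarray, rng: np.random.Generator):
    """Apply an independent affine draw to each (image, label) pair."""
    out_x = np.empty_like(xb)
    out_y = np.empty_like(yb)
    for i in range(len(xb)):
        img8 = np.clip(np.round(xb[i].transpose(1, 2, 0) * 255.0), 0, 255).astype(
            np.uint8
        )
        ts = ThickSlice(img8, centre_index=0)
        sl = SliceLabel(yb[i].astype(np.uint8), centre_index=0)
        ats, asl = apply_augmentation(ts, sl, augmentation_sample(rng))
        out_x[i] = ats.pixels.astype(np.float32).transpose(2, 0, 1) / 255.0
        out_y[i] = asl.pixels
    return out_x, out_y


def evaluate_slices(
    model: SliceSegmenter,
    images: Sequence[ThickSlice],
    labels: Sequence[SliceLabel],
) -> tuple[float, float]:
    """Mean per-slice ventricle IoU and DSC over a test set.

    Slices where both prediction and truth have no ventricle pixels are
    skipped (the ratio is undefined); slices where the truth is empty but
    the prediction is not count as 0.  DSC comes from per-slice pixel
    counts, 2|A&B| / (|A|+|B|), not from the IoU.
    """
    if not images:
        raise ValueError("empty evaluation set")
    preds = model.predict_batch(images)
    ious, dscs = [], []
    for pred, truth in zip(preds, labels):
        a = pred.pixels == VENTRICLE
        b = truth.pixels == VENTRICLE
        na, nb = int(a.sum()), int(b.sum())
        if na == 0 and nb == 0:
            continue
        inter = int((a & b).sum())
        ious.append(inter / (na + nb - inter))
        dscs.append(2.0 * inter / (na + nb))
    if not ious:
        return float("nan"), float("nan")
    return float(np.mean(ious)), float(np.mean(dscs))
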