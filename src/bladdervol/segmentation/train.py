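"""Training loop and data augmentation for the segmentation network.

Training follows the plain recipe for this architecture: pixel-wise
softmax cross-entropy, stochastic gradient descent with momentum, and a
step learning-rate schedule

    lr(epoch) = initial_lr / 10 ** floor(epoch / step)

with ``step`` = 50 epochs by default.  Augmentation applies brightness
and contrast jitter (photometric, image only) and random horizontal
flips (geometric, image and mask together), then resizes both to the
network input size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from skimage.transform import resize as _sk_resize

from ..frames import UltrasoundFrame
from .fcn import FCNQuarterVGG, SegmentationModelSpec
from .nn import SGDMomentum, softmax_cross_entropy


@dataclass
class AugmentationConfig:
    """Random photometric + flip augmentation, with a fixed final resize."""

    brightness_range: Tuple[float, float] = (-0.08, 0.08)
    contrast_range: Tuple[float, float] = (0.85, 1.15)
    horizontal_flip_probability: float = 0.5
    resize_to: Tuple[int, int] = (512, 384)  # (width, height)

    def __post_init__(self):
        if not 0.0 <= self.horizontal_flip_probability <= 1.0:
            raise ValueError("flip probability must lie in [0, 1]")


@dataclass
class TrainingConfig:
    """Optimisation settings; defaults follow the reference recipe."""

    epochs: int = 200
    initial_lr: float = 1e-4
    lr_step_epochs: int = 50
    momentum: float = 0.9
    batch_size: int = 4
    seed: int = 0
    class_weights: Optional[Tuple[float, float]] = None
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if self.lr_step_epochs < 1:
            raise ValueError("lr_step_epochs must be >= 1")

    def learning_rate(self, epoch: int) -> float:
        """Closed-form step schedule: initial_lr / 10^floor(epoch/step)."""
        return self.initial_lr / 10.0 ** math.floor(epoch / self.lr_step_epochs)


def augment(
    frame: UltrasoundFrame,
    mask: np.ndarray,
    config: AugmentationConfig,
    seed: int,
) -> Tuple[UltrasoundFrame, np.ndarray]:
    """Apply one random augmentation draw to an aligned frame/mask pair.

    Geometric transforms (horizontal flip, resize) hit frame and mask
    identically; photometric transforms (brightness, contrast) hit the
    frame only.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    img = frame.image.astype(np.float64)
    m = np.asarray(mask, dtype=bool)

    if rng.random() < config.horizontal_flip_probability:
        img = img[:, ::-1]
        m = m[:, ::-1]

    brightness = rng.uniform(*config.brightness_range)
    contrast = rng.uniform(*config.contrast_range)
    mean = img.mean()
    img = np.clip(mean + contrast * (img - mean) + brightness, 0.0, 1.0)

    w, h = config.resize_to
    rows, cols = img.shape
    if (rows, cols) != (h, w):
        img = _sk_resize(img, (h, w), order=1, anti_aliasing=True)
        m = _sk_resize(m.astype(np.float64), (h, w), order=0) > 0.5
        sr, sc = frame.spacing
        spacing = (sr * rows / h, sc * cols / w)
    else:
        spacing = frame.spacing

    out = UltrasoundFrame(image=np.clip(img, 0.0, 1.0), section=frame.section, spacing=spacing)
    return out, m


def _dice(pred: np.ndarray, truth: np.ndarray) -> float:
    inter = np.logical_and(pred, truth).sum()
    denom = pred.sum() + truth.sum()
    return 1.0 if denom == 0 else 2.0 * inter / denom


def train(
    dataset: Sequence[Tuple[UltrasoundFrame, np.ndarray]],
    config: TrainingConfig,
    validation: Optional[Sequence[Tuple[UltrasoundFrame, np.ndarray]]] = None,
    model: Optional[FCNQuarterVGG] = None,
) -> Tuple[FCNQuarterVGG, Dict[str, List[float]]]:
    """Train the segmentation network on (frame, mask) pairs.

    Returns the trained model and a history dict with per-epoch ``loss``,
    ``dice`` (training, from the forward passes of the epoch), ``lr``
    and, when a validation set is given, ``val_dice``.
    """
    if len(dataset) == 0:
        raise ValueError("training dataset is empty")
    for f, m in dataset:
        if f.shape != np.asarray(m).shape:
            raise ValueError("frame and mask shapes differ")

    w, h = config.augmentation.resize_to
    if model is None:
        spec = SegmentationModelSpec(input_size=(w, h))
        model = FCNQuarterVGG(spec, seed=config.seed)
    optimizer = SGDMomentum(model.parameters(), momentum=config.momentum)
    weights = None if config.class_weights is None else np.asarray(config.class_weights)

    rng = np.random.default_rng(config.seed)
    history: Dict[str, List[float]] = {"loss": [], "dice": [], "lr": []}
    if validation is not None:
        history["val_dice"] = []

    val_batch = None
    if validation is not None:
        val_batch = _prepare_batch(validation, config.augmentation, augment_seed=None)

    n = len(dataset)
    for epoch in range(config.epochs):
        lr = config.learning_rate(epoch)
        order = rng.permutation(n)
        seeds = rng.integers(0, 2**31 - 1, size=n)
        losses, dices = [], []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = [augment(*dataset[i], config.augmentation, int(seeds[i])) for i in idx]
            x, y = _stack_batch(batch)
            logits = model.forward(x)
            loss, grad = softmax_cross_entropy(logits, y, class_weights=weights)
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged: non-finite loss at epoch {epoch}")
            losses.append(loss)
            pred = logits.argmax(axis=1) == 1
            dices.extend(_dice(pred[k], y[k] == 1) for k in range(len(idx)))
            model.backward(grad)
            optimizer.step(lr)
        history["loss"].append(float(np.mean(losses)) if losses else float(loss))
        history["dice"].append(float(np.mean(dices)))
        history["lr"].append(lr)
        if val_batch is not None:
            xv, yv = val_batch
            dv = []
            for k in range(0, len(xv), config.batch_size):
                pv = model.predict_proba(xv[k : k + config.batch_size]) >= 0.5
                dv.extend(_dice(pv[j], yv[k + j] == 1) for j in range(len(pv)))
            history["val_dice"].append(float(np.mean(dv)))
    return model, history


def _prepare_batch(pairs, aug: AugmentationConfig, augment_seed):
    """Resize pairs to the network size without random augmentation."""
    fixed = AugmentationConfig(
        brightness_range=(0.0, 0.0),
        contrast_range=(1.0, 1.0),
        horizontal_flip_probability=0.0,
        resize_to=aug.resize_to,
    )
    batch = [augment(f, m, fixed, 0) for f, m in pairs]
    return _stack_batch(batch)


def _stack_batch(batch):
    x = np.stack([f.image - 0.5 for f, _ in batch])[:, None].astype(np.float32)
    y = np.stack([m.astype(np.int64) for _, m in batch])
    return x, y
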