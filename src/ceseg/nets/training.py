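"""Training loops for the two networks.

Both networks minimise a cross-entropy loss with a pixel-wise soft-max
over the two classes, with the probabilistic label (p, 1 - p) as the soft
target.  The optimiser is Adam with initial learning rate 0.001 and the
decaying schedule lr_i = lr_{i-1} / (1 + 0.001 * i).  Flip augmentation
(factor 4) is applied to the training pool.  The U-net trains on whole
images (batch of 4); the SW-net trains on class-balanced 64x64 patch
batches (batch of 128, 64 per class, the class being the binarised label
of the central pixel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .. import labels as _labels
from ..preprocess import augment_flips
from . import engine as eng
from .models import SWNet, UNet

__all__ = ["TrainConfig", "sample_patches", "train"]

#: edge:body pixel imbalance in the clinical images, used for optional weighting
CLASS_WEIGHTS = (1.0, 4.0)  # (body, edge)


@dataclass
class TrainConfig:
    lr0: float = 1e-3
    decay: float = 1e-3
    iterations: int = 500
    batch_images: int = 4      # U-net
    batch_patches: int = 128   # SW-net
    seed: int = 0
    class_weighting: bool = False
    label_mode: str = "probabilistic"   # "probabilistic" | "binary"
    eval_every: int = 0        # 0 = no periodic accuracy evaluation

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.batch_images < 1 or self.batch_patches < 1:
            raise ValueError("batch sizes must be positive")
        if self.label_mode not in ("probabilistic", "binary"):
            raise ValueError("label_mode must be 'probabilistic' or 'binary'")


def sample_patches(
    image: np.ndarray,
    label: np.ndarray,
    count: int,
    patch: int = 64,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Class-balanced patch batch centred on edge/body pixels.

    The image is mirror-padded by half a patch so every pixel is a valid
    centre.  Returns (patches [count, patch, patch, 1], target edge
    probability at each centre, centre class, centre (row, col) pairs).
    ``count`` must be even; exactly count/2 patches per class are drawn.
    """
    if count % 2:
        raise ValueError("patch count must be even for exact class balance")
    rng = rng or np.random.default_rng()
    image = np.asarray(image, dtype=float)
    label = np.asarray(label, dtype=float)
    if image.shape != label.shape:
        raise ValueError("image and label shapes differ")
    classes = _labels.binarize_labels(label)
    edge_idx = np.flatnonzero(classes.ravel() == 1)
    body_idx = np.flatnonzero(classes.ravel() == 0)
    if len(edge_idx) == 0 or len(body_idx) == 0:
        raise ValueError("need both classes present to balance the batch")
    half = count // 2
    centers = np.concatenate(
        [
            rng.choice(edge_idx, half, replace=len(edge_idx) < half),
            rng.choice(body_idx, half, replace=len(body_idx) < half),
        ]
    )
    ys, xs = np.unravel_index(centers, image.shape)
    pad = patch // 2
    padded = np.pad(image, pad, mode="reflect")
    patches = np.stack([padded[y : y + patch, x : x + patch] for y, x in zip(ys, xs)])
    return (
        patches[..., None],
        label.ravel()[centers],
        classes.ravel()[centers],
        np.column_stack([ys, xs]),
    )


def _target(label: np.ndarray, mode: str) -> np.ndarray:
    if mode == "binary":
        return _labels.binarize_labels(label).astype(float)
    return np.asarray(label, dtype=float)


def train(
    model: UNet | SWNet,
    data: list[tuple[np.ndarray, np.ndarray]],
    tcfg: TrainConfig,
) -> pd.DataFrame:
    """Train on (preprocessed image, probabilistic label) pairs.

    Returns the history as a DataFrame with columns iteration, lr, loss
    (and accuracy every ``eval_every`` iterations when requested).
    Deterministic for a fixed seed on one device.
    """
    if not data:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(tcfg.seed)
    pool: list[tuple[np.ndarray, np.ndarray]] = []
    for image, label in data:
        pool.extend(augment_flips(np.asarray(image, float), np.asarray(label, float)))

    weights = CLASS_WEIGHTS if tcfg.class_weighting else None
    opt = eng.Adam(model.parameters(), lr0=tcfg.lr0, decay=tcfg.decay)
    rows = []
    for _ in range(tcfg.iterations):
        if isinstance(model, UNet):
            picks = rng.integers(0, len(pool), size=tcfg.batch_images)
            xs = np.stack([pool[i][0] for i in picks])[..., None]
            ts = np.stack([_target(pool[i][1], tcfg.label_mode) for i in picks])
        else:
            i = int(rng.integers(0, len(pool)))
            xs, centre_p, _, _ = sample_patches(
                pool[i][0], pool[i][1], tcfg.batch_patches, model.cfg.patch_size, rng
            )
            ts = _target(centre_p, tcfg.label_mode)
        opt.zero_grad()
        logits = model.forward(xs, train=True)
        loss, grad = eng.cross_entropy_soft(logits, ts, class_weights=weights)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite loss at iteration {opt.i + 1}; lr={opt.lr:.2e}"
            )
        model.backward(grad)
        lr = opt.step()
        row = {"iteration": opt.i, "lr": lr, "loss": loss}
        if tcfg.eval_every and opt.i % tcfg.eval_every == 0:
            row["accuracy"] = evaluate_accuracy(model, pool[:4], tcfg)
        rows.append(row)
    return pd.DataFrame(rows)


def evaluate_loss(
    model: UNet | SWNet,
    data: list[tuple[np.ndarray, np.ndarray]],
    *,
    patches_per_image: int = 128,
    seed: int = 0,
) -> float:
    """Mean soft-target cross-entropy on held-out pairs (inference mode)."""
    rng = np.random.default_rng(seed)
    losses = []
    for image, label in data:
        if isinstance(model, UNet):
            logits = model.forward(np.asarray(image, float)[None, :, :, None], train=False)
            loss, _ = eng.cross_entropy_soft(logits, np.asarray(label, float)[None])
        else:
            xs, centre_p, _, _ = sample_patches(
                image, label, patches_per_image, model.cfg.patch_size, rng
            )
            logits = model.forward(xs, train=False)
            loss, _ = eng.cross_entropy_soft(logits, centre_p)
        losses.append(loss)
    return float(np.mean(losses))


def evaluate_accuracy(
    model: UNet | SWNet,
    data: list[tuple[np.ndarray, np.ndarray]],
    tcfg: TrainConfig,
) -> float:
    """Pixel (or patch-centre) accuracy in percent, inference mode."""
    rng = np.random.default_rng(tcfg.seed + 1)
    correct, total = 0, 0
    for image, label in data:
        if isinstance(model, UNet):
            logits = model.forward(np.asarray(image, float)[None, :, :, None], train=False)
            pred = eng.softmax(logits)[0, :, :, 1] > 0.5
            truth = _labels.binarize_labels(label).astype(bool)
        else:
            xs, centre_p, _, _ = sample_patches(
                image, label, tcfg.batch_patches, model.cfg.patch_size, rng
            )
            pred = eng.softmax(model.forward(xs, train=False))[:, 1] > 0.5
            truth = centre_p > 0.5
        correct += int(np.sum(pred == truth))
        total += truth.size
    return 100.0 * correct / total
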