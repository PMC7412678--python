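"""Intensity preprocessing scenarios and flip augmentation.

Five scenarios are supported for network input: raw, per-image
normalisation to [0, 1], per-image standardisation to zero mean / unit
variance, CLAHE (contrast limited adaptive histogram equalisation with a
24x24 kernel, roughly one average cell), and CLAHE followed by
standardisation.  Augmentation is restricted to horizontal/vertical flips:
specular images carry small horizontal/vertical distortion patterns that
rotations or elastic deformations would corrupt.
"""

from __future__ import annotations

import numpy as np
from skimage import exposure

__all__ = [
    "MODES",
    "DegenerateImageError",
    "standardize",
    "normalize",
    "clahe",
    "apply_mode",
    "augment_flips",
]

MODES = ("raw", "normalize", "standardize", "clahe", "clahe+standardize")

DEFAULT_CLAHE_KERNEL = 24
DEFAULT_CLAHE_CLIP = 0.01


class DegenerateImageError(ValueError):
    """Raised when a constant image makes a transform undefined."""


def standardize(image: np.ndarray) -> np.ndarray:
    """(image - mean) / std, per image."""
    image = np.asarray(image, dtype=float)
    std = image.std()
    if std == 0.0:
        raise DegenerateImageError("cannot standardize a constant image (std = 0)")
    return (image - image.mean()) / std


def normalize(image: np.ndarray) -> np.ndarray:
    """(image - min) / (max - min), per image."""
    image = np.asarray(image, dtype=float)
    lo, hi = image.min(), image.max()
    if hi == lo:
        raise DegenerateImageError("cannot normalize a constant image (max = min)")
    return (image - lo) / (hi - lo)


def clahe(
    image: np.ndarray,
    kernel: int = DEFAULT_CLAHE_KERNEL,
    clip: float = DEFAULT_CLAHE_CLIP,
) -> np.ndarray:
    """Contrast limited adaptive histogram equalisation, output in [0, 1].

    The kernel defaults to 24 px, approximately the diameter of an average
    endothelial cell at 1.038 um/px; the clip limit is a conservative
    fraction-of-tile default exposed in the run configuration.
    """
    image = np.asarray(image, dtype=float)
    if kernel < 2:
        raise ValueError(f"CLAHE kernel must be >= 2 px, got {kernel}")
    if image.shape[0] < kernel or image.shape[1] < kernel:
        raise ValueError(
            f"CLAHE kernel {kernel} exceeds image dimensions {image.shape}"
        )
    if image.min() < 0.0 or image.max() > 1.0:
        image = normalize(image)
    out = exposure.equalize_adapthist(image, kernel_size=kernel, clip_limit=clip)
    return np.clip(out, 0.0, 1.0)


def apply_mode(image: np.ndarray, mode: str, *, clahe_kernel: int = DEFAULT_CLAHE_KERNEL,
               clahe_clip: float = DEFAULT_CLAHE_CLIP) -> np.ndarray:
    """Apply one of the five preprocessing scenarios."""
    if mode not in MODES:
        raise ValueError(f"unknown preprocessing mode {mode!r}; expected one of {MODES}")
    if mode == "raw":
        return np.asarray(image, dtype=float)
    if mode == "normalize":
        return normalize(image)
    if mode == "standardize":
        return standardize(image)
    out = clahe(image, kernel=clahe_kernel, clip=clahe_clip)
    if mode == "clahe+standardize":
        out = standardize(out)
    return out


def augment_flips(image: np.ndarray, label: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Return the four flip-augmented (image, label) pairs.

    Order: identity, horizontal flip, vertical flip, both.  Flips are
    applied identically to image and label so the geometric correspondence
    is preserved.
    """
    image = np.asarray(image)
    label = np.asarray(label)
    if image.shape != label.shape:
        raise ValueError(f"image {image.shape} and label {label.shape} shapes differ")
    return [
        (image, label),
        (image[:, ::-1], label[:, ::-1]),
        (image[::-1, :], label[::-1, :]),
        (image[::-1, ::-1], label[::-1, ::-1]),
    ]
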