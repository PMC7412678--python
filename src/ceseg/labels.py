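"""Probabilistic edge labels for training.

The expert gold standard marks cell borders as 1-pixel-wide, 8-connected
lines.  Training on those hard labels penalises the network for predicting
edge probability mass on the pixels immediately adjacent to the traced line,
even though those pixels are visually indistinguishable from the line
itself.  The probabilistic label spreads each traced edge with an
unnormalised isotropic Gaussian (sigma = 1 px, 7x7 support) so that traced
pixels keep probability 1 and probability decays smoothly into the cell
body.  Binarising the result at p > 0.5 accepts exactly a 1-pixel error in
edge localisation.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["gaussian_structuring_function", "make_probabilistic_labels", "binarize_labels"]

#: half-width of the 7x7 kernel support, in pixels
SUPPORT_RADIUS = 3
#: standard deviation of the label Gaussian, in pixels
SIGMA = 1.0


def gaussian_structuring_function(sigma: float = SIGMA, radius: int = SUPPORT_RADIUS) -> np.ndarray:
    """Unnormalised isotropic Gaussian on a (2*radius+1)^2 support, peak value 1."""
    ax = np.arange(-radius, radius + 1, dtype=float)
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    return np.exp(-(yy**2 + xx**2) / (2.0 * sigma**2))


def _validate_binary(gold: np.ndarray) -> np.ndarray:
    gold = np.asarray(gold)
    if gold.ndim != 2:
        raise ValueError(f"gold standard must be 2-D, got shape {gold.shape}")
    if not np.isin(gold, (0, 1)).all():
        raise ValueError("gold standard must be binary (values 0 and 1)")
    return gold.astype(float)


def make_probabilistic_labels(gold: np.ndarray, *, method: str = "dilation") -> np.ndarray:
    """Spread a binary gold standard into per-pixel edge probabilities.

    Parameters
    ----------
    gold
        Binary 2-D array, 1 on traced cell edges.
    method
        ``"dilation"`` (default): grayscale dilation of the edge indicator
        with the Gaussian structuring function,
        ``p(x) = max_e exp(-||x - e||^2 / 2)`` over edge pixels ``e`` within
        the 7x7 support.  This guarantees p = 1 exactly on edges and
        p <= 1 everywhere, for any input.
        ``"convolution"``: plain linear convolution with the unnormalised
        kernel, clipped to [0, 1].  Kept for comparison; for dense edge
        lines it saturates a band around the line instead of preserving the
        single-pixel crest.

    Returns
    -------
    np.ndarray
        Float array in [0, 1], same shape as ``gold``.
    """
    g = _validate_binary(gold)
    kernel = gaussian_structuring_function()
    if method == "convolution":
        out = ndimage.convolve(g, kernel, mode="constant", cval=0.0)
        return np.clip(out, 0.0, 1.0)
    if method != "dilation":
        raise ValueError(f"unknown method {method!r}")
    r = SUPPORT_RADIUS
    h, w = g.shape
    padded = np.pad(g, r)
    out = np.zeros_like(g)
    for dy in range(2 * r + 1):
        for dx in range(2 * r + 1):
            # padded window shifted by (dy-r, dx-r); weight = Gaussian at that offset
            np.maximum(out, padded[dy : dy + h, dx : dx + w] * kernel[dy, dx], out=out)
    return out


def binarize_labels(label: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Binarise a probabilistic label: edge class is any pixel with p > threshold."""
    label = np.asarray(label, dtype=float)
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    if label.min() < 0.0 or label.max() > 1.0:
        raise ValueError("probabilistic label values must lie in [0, 1]")
    return (label > threshold).astype(np.uint8)
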