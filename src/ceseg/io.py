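"""Image, label and report IO, plus the run configuration.

Conventions: 8-bit grayscale PNG/TIFF in (scaled to [0, 1] in memory),
16-bit label TIFF out for segmentations (0 = edge skeleton), 32-bit float
TIFF for probabilistic labels and network outputs, CSV reports.
Coordinates are 0-based (row, col) with row 0 at the image top.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import tifffile
import yaml
from PIL import Image as PILImage

from .postprocess import DEFAULT_K_SIGMA, CellSegmentation

__all__ = [
    "ImageFormatError",
    "RunConfig",
    "read_image",
    "write_image",
    "read_prob_map",
    "write_prob_map",
    "read_segmentation",
    "write_segmentation",
    "DEFAULT_PIXEL_PITCH",
]

DEFAULT_PIXEL_PITCH = 1.038


class ImageFormatError(ValueError):
    """Input file is not an 8-bit single-channel grayscale image."""


@dataclass
class RunConfig:
    """Flat run configuration; CLI flags override file values."""

    preprocess: str = "raw"       # raw | normalize | standardize | clahe | clahe+standardize
    net: str = "unet"             # unet | swnet
    alpha: float = 1.0
    k_sigma: float = DEFAULT_K_SIGMA
    pixel_pitch: float = DEFAULT_PIXEL_PITCH
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        from .preprocess import MODES

        if self.preprocess not in MODES:
            raise ValueError(f"preprocess must be one of {MODES}, got {self.preprocess!r}")
        if self.net not in ("unet", "swnet"):
            raise ValueError(f"net must be 'unet' or 'swnet', got {self.net!r}")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit grayscale PNG/TIFF, scaled to [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with PILImage.open(path) as im:
        if im.mode != "L":
            raise ImageFormatError(
                f"{path.name}: expected 8-bit grayscale (mode 'L'), got mode {im.mode!r}"
            )
        arr = np.asarray(im, dtype=np.float64)
    return arr / 255.0


def write_image(image: np.ndarray, path: str | Path) -> Path:
    """Write a [0, 1] float image as 8-bit grayscale PNG/TIFF."""
    path = Path(path)
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    PILImage.fromarray(np.round(arr * 255.0).astype(np.uint8), mode="L").save(path)
    return path


def read_prob_map(path: str | Path) -> np.ndarray:
    """Read a 32-bit float TIFF probability map."""
    arr = tifffile.imread(Path(path)).astype(np.float64)
    if arr.ndim != 2:
        raise ImageFormatError(f"{Path(path).name}: probability map must be single-channel 2-D")
    return arr


def write_prob_map(prob: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(prob, dtype=np.float32))
    return path


def _overlay_rgb(labels: np.ndarray) -> np.ndarray:
    """Deterministic colour rendering of a label grid, black edge skeleton."""
    rng = np.random.default_rng(12345)
    n = int(labels.max())
    palette = rng.integers(60, 255, size=(n + 1, 3), dtype=np.uint8)
    palette[0] = 0
    return palette[labels]


def write_segmentation(
    seg: CellSegmentation | np.ndarray,
    path: str | Path,
    *,
    overlay: bool = True,
) -> Path:
    """Write a segmentation as 16-bit label TIFF (plus an overlay PNG)."""
    labels = seg.labels if isinstance(seg, CellSegmentation) else np.asarray(seg)
    if labels.min() < 0:
        raise ValueError("labels must be >= 0")
    if labels.max() > 65535:
        raise ValueError(f"{labels.max()} labels exceed the 16-bit TIFF range")
    path = Path(path)
    tifffile.imwrite(path, labels.astype(np.uint16))
    if overlay:
        PILImage.fromarray(_overlay_rgb(labels), mode="RGB").save(
            path.with_suffix("").with_name(path.stem + "_overlay.png")
        )
    return path


def read_segmentation(path: str | Path) -> CellSegmentation:
    labels = tifffile.imread(Path(path)).astype(np.int32)
    return CellSegmentation(labels=labels)
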