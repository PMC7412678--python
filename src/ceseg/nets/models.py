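"""U-net and sliding-window CNN architectures.

U-net: a contraction path of ``steps`` resolution steps (per step: two
k x k 'same' convolutions with ReLU, dropout between them, then 2x2 max
pooling with stride 2) and a mirrored expansion path (per step: k x k
transposed convolution with stride 2, concatenation with the
same-resolution contraction features, two convolutions with dropout
between).  Channels double on the way down from ``base_channels`` and the
expansion conv channels halve at each upsampling step; a final 1x1
convolution maps to the two classes (cell body, cell edge) under a
pixel-wise soft-max.  Defaults: 4x4 kernels, 4 steps, 32 base channels,
dropout 0.5.

SW-net: the same contraction path (3x3 kernels, no dropout by default)
applied to a 64x64 patch, followed by global average pooling and a
two-neuron fully connected layer that classifies the patch's central
pixel.

The receptive field of the deepest contraction feature is computed with
max-pooling contributing stride only (no kernel extent):
RF = 1 + sum over conv layers of (k - 1) * (cumulative stride).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import engine as eng

__all__ = [
    "NetConfig",
    "UNet",
    "SWNet",
    "build_unet",
    "build_swnet",
    "receptive_field",
    "receptive_field_probe",
    "predict_unet",
    "predict_swnet",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class NetConfig:
    kind: str = "unet"                       # "unet" | "swnet"
    kernel: int = 4                          # swnet default: 3
    steps: int = 4                           # resolution steps
    convs_per_step: int | tuple[int, ...] = 2
    base_channels: int = 32
    dropout: float = 0.5                     # swnet default: 0
    patch_size: int = 64                     # swnet input size
    in_channels: int = 1
    classes: int = 2

    def __post_init__(self):
        if self.kind not in ("unet", "swnet"):
            raise ValueError(f"kind must be 'unet' or 'swnet', got {self.kind!r}")
        if self.kernel < 1 or self.steps < 1 or self.base_channels < 1:
            raise ValueError("kernel, steps and base_channels must be >= 1")
        cs = self.conv_counts
        if len(cs) != self.steps or any(c < 1 for c in cs):
            raise ValueError("convs_per_step must be >= 1 for each of the steps")
        if self.kind == "swnet" and self.patch_size % (2**self.steps):
            raise ValueError(
                f"patch size {self.patch_size} not divisible by 2^{self.steps}"
            )

    @property
    def conv_counts(self) -> tuple[int, ...]:
        cs = self.convs_per_step
        return tuple(cs) if isinstance(cs, (tuple, list)) else (cs,) * self.steps

    @classmethod
    def unet(cls, **kw) -> "NetConfig":
        return cls(kind="unet", **kw)

    @classmethod
    def swnet(cls, **kw) -> "NetConfig":
        kw.setdefault("kernel", 3)
        kw.setdefault("dropout", 0.0)
        return cls(kind="swnet", **kw)


def receptive_field(cfg: NetConfig | int, steps: int | None = None,
                    convs_per_step: int | tuple[int, ...] = 2) -> int:
    """Receptive field (px) of the deepest contraction-path feature.

    Each convolution adds (k - 1) * (cumulative stride before it); each
    2x2 max-pool doubles the cumulative stride and adds no kernel extent.
    May be called with a NetConfig or with (kernel, steps[, convs_per_step]),
    where convs_per_step is an int or a per-step tuple.
    """
    if isinstance(cfg, NetConfig):
        k, counts = cfg.kernel, cfg.conv_counts
    else:
        if steps is None:
            raise TypeError("steps required when passing a bare kernel size")
        k = int(cfg)
        counts = (
            tuple(convs_per_step)
            if isinstance(convs_per_step, (tuple, list))
            else (int(convs_per_step),) * steps
        )
        if len(counts) != steps:
            raise ValueError("convs_per_step tuple length must equal steps")
    rf, stride = 1, 1
    for c in counts:
        rf += c * (k - 1) * stride
        stride *= 2
    return rf


class _ConvBlock:
    """convs_per_step convolutions with activation, dropout between convs."""

    def __init__(self, cin, cout, k, n_convs, dropout, rng, activation="relu"):
        act = eng.ReLU if activation == "relu" else eng.Identity
        self.layers: list = []
        for j in range(n_convs):
            if j > 0 and dropout > 0:
                self.layers.append(eng.Dropout(dropout, rng))
            self.layers.append(eng.Conv2d(cin if j == 0 else cout, cout, k, rng))
            self.layers.append(act())

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, g):
        for l in reversed(self.layers):
            g = l.backward(g)
        return g


class _Contraction:
    """Shared contraction path: per step a conv block then a 2x2 pool."""

    def __init__(self, cfg: NetConfig, rng, activation="relu", pool="max"):
        self.cfg = cfg
        pool_cls = eng.MaxPool2 if pool == "max" else eng.SubsamplePool2
        self.blocks, self.pools = [], []
        cin = cfg.in_channels
        for s, n_convs in enumerate(cfg.conv_counts):
            cout = cfg.base_channels * 2**s
            self.blocks.append(
                _ConvBlock(cin, cout, cfg.kernel, n_convs, cfg.dropout, rng, activation)
            )
            self.pools.append(pool_cls())
            cin = cout
        self.out_channels = cin

    def params(self):
        return [p for b in self.blocks for p in b.params()]

    def forward(self, x, train=False):
        skips = []
        for block, pool in zip(self.blocks, self.pools):
            x = block.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        return x, skips

    def backward(self, g, skip_grads=None):
        for s in reversed(range(len(self.blocks))):
            g = self.pools[s].backward(g)
            if skip_grads is not None and skip_grads[s] is not None:
                g = g + skip_grads[s]
            g = self.blocks[s].backward(g)
        return g


class UNet:
    """Fully convolutional U-net; forward produces per-pixel 2-class logits."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        if cfg.kind != "unet":
            raise ValueError("NetConfig.kind must be 'unet'")
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.contraction = _Contraction(cfg, rng)
        self.upconvs, self.up_blocks, self._up_channels = [], [], []
        cin = self.contraction.out_channels
        n = cfg.steps
        for j in range(n):
            up_out = max(cin // 2, 1)
            skip_ch = cfg.base_channels * 2 ** (n - 1 - j)
            self.upconvs.append(eng.ConvTranspose2d(cin, up_out, cfg.kernel, rng))
            self.up_blocks.append(
                _ConvBlock(up_out + skip_ch, up_out, cfg.kernel, 2, cfg.dropout, rng)
            )
            self._up_channels.append(up_out)
            cin = up_out
        self.final = eng.Conv2d(cin, cfg.classes, 1, rng)

    def parameters(self) -> list[eng.Param]:
        ps = self.contraction.params()
        for up, blk in zip(self.upconvs, self.up_blocks):
            ps += up.params() + blk.params()
        return ps + self.final.params()

    def _check_size(self, h, w):
        d = 2**self.cfg.steps
        if h % d or w % d:
            raise ValueError(f"input {h}x{w} not divisible by 2^{self.cfg.steps} = {d}")

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._check_size(x.shape[1], x.shape[2])
        h, skips = self.contraction.forward(x, train)
        self._skip_count = len(skips)
        for j, (up, blk) in enumerate(zip(self.upconvs, self.up_blocks)):
            h = up.forward(h, train)
            h = np.concatenate([h, skips[self.cfg.steps - 1 - j]], axis=-1)
            h = blk.forward(h, train)
        return self.final.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        g = self.final.backward(dlogits)
        skip_grads = [None] * self.cfg.steps
        for j in reversed(range(self.cfg.steps)):
            g = self.up_blocks[j].backward(g)
            c = self._up_channels[j]
            g_up, g_skip = g[..., :c], g[..., c:]
            s = self.cfg.steps - 1 - j
            skip_grads[s] = g_skip if skip_grads[s] is None else skip_grads[s] + g_skip
            g = self.upconvs[j].backward(g_up)
        return self.contraction.backward(g, skip_grads)


class SWNet:
    """Patch classifier: contraction path + global average pool + dense 2-way."""

    def __init__(self, cfg: NetConfig, seed: int = 0):
        if cfg.kind != "swnet":
            raise ValueError("NetConfig.kind must be 'swnet'")
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.contraction = _Contraction(cfg, rng)
        self.gap = eng.GlobalAvgPool()
        self.fc = eng.Dense(self.contraction.out_channels, cfg.classes, rng)

    def parameters(self) -> list[eng.Param]:
        return self.contraction.params() + self.fc.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[1] != self.cfg.patch_size or x.shape[2] != self.cfg.patch_size:
            raise ValueError(
                f"expected {self.cfg.patch_size}x{self.cfg.patch_size} patches, got {x.shape[1:3]}"
            )
        h, _ = self.contraction.forward(x, train)
        return self.fc.forward(self.gap.forward(h, train), train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        g = self.gap.backward(self.fc.backward(dlogits))
        return self.contraction.backward(g)


def build_unet(cfg: NetConfig | None = None, seed: int = 0) -> UNet:
    return UNet(cfg or NetConfig.unet(), seed)


def build_swnet(cfg: NetConfig | None = None, seed: int = 0) -> SWNet:
    return SWNet(cfg or NetConfig.swnet(), seed)


def receptive_field_probe(cfg: NetConfig, input_size: int | None = None) -> int:
    """Measure the deepest contraction feature's receptive field empirically.

    Builds a linear probe of the contraction path — identity activations,
    stride-2 subsampling in place of max pooling (the receptive-field
    convention counts pooling as stride only), all-positive weights so
    that gradient support is not pruned by ReLU dead zones or argmax
    selection — backpropagates a unit gradient from the centre of the
    deepest feature map, and returns the spatial extent of the nonzero
    input gradient.
    """
    rf = receptive_field(cfg)
    size = input_size or 2 ** int(np.ceil(np.log2(2 * rf)))
    d = 2**cfg.steps
    size = int(np.ceil(size / d)) * d
    probe = _Contraction(
        replace(cfg, dropout=0.0, in_channels=1),
        np.random.default_rng(0),
        activation="identity",
        pool="subsample",
    )
    for p in probe.params():
        p.value = np.abs(p.value) + 1e-3
    x = np.zeros((1, size, size, 1))
    deepest, _ = probe.forward(x)
    g = np.zeros_like(deepest)
    cy, cx = deepest.shape[1] // 2, deepest.shape[2] // 2
    g[0, cy, cx, 0] = 1.0
    dx = probe.backward(g)
    ys, xs = np.nonzero(np.abs(dx[0, :, :, 0]) > 0)
    return int(max(ys.max() - ys.min(), xs.max() - xs.min()) + 1)


def predict_unet(model: UNet, image: np.ndarray) -> np.ndarray:
    """Edge-probability map from a preprocessed image (dropout disabled)."""
    image = np.asarray(image, dtype=float)
    logits = model.forward(image[None, :, :, None], train=False)
    return eng.softmax(logits)[0, :, :, 1]


def predict_swnet(model: SWNet, image: np.ndarray, batch: int = 512) -> np.ndarray:
    """Per-pixel edge probability: one centred patch per pixel.

    The image is mirror-padded by half a patch so that every pixel —
    including the borders — has a full patch; patches are evaluated in
    batches.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    half = model.cfg.patch_size // 2
    padded = np.pad(image, half, mode="reflect")
    windows = np.lib.stride_tricks.sliding_window_view(
        padded, (model.cfg.patch_size, model.cfg.patch_size)
    )[:h, :w]
    flat = windows.reshape(h * w, model.cfg.patch_size, model.cfg.patch_size)
    out = np.empty(h * w)
    for start in range(0, h * w, batch):
        chunk = flat[start : start + batch][..., None]
        out[start : start + batch] = eng.softmax(model.forward(chunk))[:, 1]
    return out.reshape(h, w)


def save_model(model: UNet | SWNet, path: str | Path) -> Path:
    """Checkpoint as .npz with a JSON config sidecar."""
    path = Path(path)
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.parameters())}
    np.savez_compressed(path, **arrays)
    cfg = model.cfg.__dict__.copy()
    cfg["convs_per_step"] = list(model.cfg.conv_counts)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(cfg, fh, indent=2)
    return path


def load_model(path: str | Path) -> UNet | SWNet:
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        cfg_dict = json.load(fh)
    cfg_dict["convs_per_step"] = tuple(cfg_dict["convs_per_step"])
    cfg = NetConfig(**cfg_dict)
    model = UNet(cfg) if cfg.kind == "unet" else SWNet(cfg)
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
        for i, p in enumerate(model.parameters()):
            p.value[...] = data[f"param_{i}"]
    return model
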