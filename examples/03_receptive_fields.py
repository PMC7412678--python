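"""Receptive fields of the published network configurations.

The receptive field (RF) of the deepest contraction feature is computed
with 2x2 max-pooling contributing stride only:
RF = 1 + sum over conv layers of (k - 1) * (cumulative stride).
An average endothelial cell spans 25-30 px, so an RF of 75-90 px covers
a cell and its direct neighbours - the 4x4/4-step U-net (RF 91) sits in
that band, which is why it is the default.
"""

from ceseg.nets import receptive_field

rows = [
    ("3x3 kernels, 4 steps", 3, 4, 2),
    ("4x4 kernels, 4 steps (default U-net)", 4, 4, 2),
    ("5x5 kernels, 4 steps", 5, 4, 2),
    ("4x4 kernels, 3 steps", 4, 3, 2),
    ("4x4 kernels, 5 steps", 4, 5, 2),
    ("3x3 kernels, 5 steps", 3, 5, 2),
    ("5x5 kernels, 4 steps, last conv removed", 5, 4, (2, 2, 2, 1)),
]
print(f"{'configuration':<42} RF (px)")
for name, k, n, c in rows:
    print(f"{name:<42} {receptive_field(k, n, c):>5}")
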