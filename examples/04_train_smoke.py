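"""Short U-net training run on one synthetic image.

Uses the published optimiser settings - Adam, initial learning rate
0.001 with the decay schedule lr_i = lr_{i-1} / (1 + 0.001 * i) - on a
reduced network (2 resolution steps, 8 base channels) so the run takes
seconds on a CPU.  Flip augmentation multiplies the one image by four.
"""

from ceseg import MosaicSpec, RenderSpec, generate_mosaic, make_probabilistic_labels
from ceseg import render_intensity
from ceseg.nets import NetConfig, TrainConfig, build_unet, train

truth, gold = generate_mosaic(MosaicSpec(height=64, width=64, n_cells=16, seed=3))
image = render_intensity(truth, RenderSpec(seed=3))
label = make_probabilistic_labels(gold)

model = build_unet(NetConfig.unet(kernel=3, steps=2, base_channels=8), seed=0)
history = train(model, [(image, label)], TrainConfig(iterations=200, batch_images=2, seed=0))

for i in (0, 49, 99, 149, 199):
    row = history.iloc[i]
    print(f"iteration {int(row.iteration):>3}: loss {row.loss:.4f}  lr {row.lr:.6f}")
print(
    f"\nloss fell from {history.loss.iloc[0]:.4f} to {history.loss.iloc[-1]:.4f} "
    "(soft-target cross-entropy); the learning rate follows the stated decay."
)
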