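# ceseg — corneal endothelium cell segmentation and morphometry

The corneal endothelium (CE) is a monolayer of predominantly hexagonal
cells on the posterior cornea, imaged in vivo by non-contact specular
microscopy.  Three morphometric biomarkers summarise its health —
endothelial cell density (ECD, cells/mm²), polymegethism (CV, the
coefficient of variation of cell areas, %), and pleomorphism (HEX, the
percentage of six-sided cells) — and all three require an accurate
instance segmentation of the low-contrast, unevenly lit specular images.
`ceseg` implements an end-to-end pipeline for that task, aimed at
researchers in ophthalmic image analysis:

1. **Probabilistic edge labels.**  Expert tracings are 1-px, 8-connected
   edge lines.  Each line is spread with an unnormalised isotropic
   Gaussian (σ = 1 px, 7×7 support) as a grayscale dilation, so traced
   pixels keep p = 1 and binarising at p > 0.5 accepts exactly a 1-px
   localisation error.
2. **Two CNN architectures**, built on a small self-contained NumPy
   layer/backprop engine: a U-net (two 4×4 padded convolutions per
   resolution step with dropout 0.5 between them, 2×2 max pooling, four
   steps at 32→256 channels, transposed-convolution expansion with skip
   concatenations, pixel-wise soft-max over two classes) and a
   sliding-window network, SW-net (the same contraction path with 3×3
   kernels on 64×64 patches, global average pooling, and a two-neuron
   dense layer classifying the central pixel).  Training uses soft-target
   cross-entropy and Adam with lr₀ = 0.001 and
   lr_i = lr_{i−1}/(1 + 0.001·i), flip-only augmentation, and
   class-balanced patch batches for SW-net.  A receptive-field calculator
   (pooling counted as stride only) reproduces the RF of every published
   configuration: 61, 91, 121, 43, 187, 125 and 89 px.
3. **Fourier/watershed postprocessing.**  The 2-D Fourier magnitude of a
   CE edge map shows a ring whose radius f* (the characteristic
   frequency) is the reciprocal of the most common cell size l = 1/f*.
   After removing the low-frequency background by grayscale
   reconstruction by dilation, the angularly averaged radial magnitude
   F_RM(f) = (1/2π)∫|F(f,θ)|dθ is peak-picked inside the physiological
   band; the edge map is smoothed with σ = k_σ/(α·f*), k_σ = 0.20, and
   the classic watershed floods every regional minimum into one cell.
   No per-image parameter is tuned.
4. **Biomarkers.**  Per cell, S_i = B_i + E_i/2 (body pixels plus half
   of the adjacent shared edge pixels); ECD = 10⁶/(S̄·pitch²) at
   1.038 µm/px, CV = 100·sd(S)/S̄ (population form), HEX = 100·n_hex/n
   with sides counted as region-adjacency neighbours sharing ≥ 2 edge
   pixels.  Cells touching the frame or outside the region of interest
   are excluded from all three identically.
5. **Evaluation.**  Pixel metrics (accuracy, AUC, and PRE*/SEN*/SPE*
   restricted to pixels with label exactly 0 or 1); the modified
   Hausdorff distance MHD(U,V) = max(hd(U,V), hd(V,U)) with
   hd(U,V) = (1/|U|)Σ min‖a−b‖₂ between edge skeletons; per-cell
   DICE = 2TP/(2TP+FP+FN) against the largest-overlap superpixel; and
   the 0.80 rule (a cell is correct iff TP > 0.80·max(|C_i|,|S_j|),
   otherwise under- or over-segmented), plus the α robustness sweep over
   0.60…1.40 in steps of 0.05.
6. **Synthetic mosaics.**  Lloyd-relaxed Voronoi phantoms with exact
   ground truth emulate the reported image statistics (240×528 px,
   ~240 cells, ECD 1100–2800 cells/mm², CV 18–36 %), so the entire
   pipeline is testable without clinical data.

## Worked example

`python examples/05_segment_and_biomarkers.py` builds a 240×528 phantom
with 240 cells, derives the ideal edge-probability map from its gold
standard, and runs the full postprocessing and morphometry:

```
characteristic frequency f* = 0.0477 cycles/px -> cell size l = 21.0 px, sigma = 4.19 px
cells found: 244 (truth: 240)
correct 100.00%  oversegmented 0.00%  undersegmented 0.00%
image DICE 0.973   MHD 0.377 px

ECD 1804 vs truth 1800 cells/mm^2
CV  24.6 vs truth 22.7 %
HEX 44.1 vs truth 44.0 %
```

The Fourier step recovers the mean cell size, every interior truth cell
is matched by exactly one watershed cell (the four extras are border
slivers outside the evaluated region), and the three biomarkers agree
with the generator's ground truth to a few percent.
`python examples/06_alpha_sweep.py` degrades the edge maps the way a
trained network would (faded edge segments, correlated noise) and shows
the U-shaped error curve of the smoothing scale with its minimum near
α = 1 — the automatic cell-size estimate needs no manual tuning.

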