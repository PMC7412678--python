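# Methods

## Scope and model

`ceseg` segments corneal-endothelium (CE) specular-microscopy images
into cells and estimates the three clinical biomarkers (ECD, CV, HEX).
The pipeline has four stages — probabilistic labels, a CNN edge
detector, Fourier/watershed postprocessing, morphometry — plus the
evaluation metrics and a synthetic-mosaic generator that supplies ground
truth.  The clinical dataset the method was designed around (50 images,
240×528 px at 1.038 µm/px, ~240 cells per image) is not public, so all
empirical statements in this repository are about synthetic phantoms;
the tests and `scripts/acceptance.py` compute every number they assert.

## Probabilistic labels

The gold standard is a binary image of 1-px, 8-connected edge lines.
The probabilistic label is the grayscale dilation of that indicator with
the unnormalised Gaussian structuring function exp(−‖x−e‖²/2) on a 7×7
support: p(x) = max over edge pixels e of the kernel value.  The max
form (rather than a linear convolution) is what guarantees the two
stated label properties for *every* input — traced pixels keep exactly
p = 1 and p ≤ 1 holds globally — because a convolution with a kernel of
central weight 1 exceeds 1 wherever edge pixels are adjacent, which is
everywhere along a line.  A convolution-then-clip variant is available
behind `method="convolution"` for comparison.  Binarising at p > 0.5
marks the traced pixel and its 4-neighbours as edge: an explicit 1-px
tolerance on edge localisation, tested against a morphological-dilation
oracle.

## Networks

No deep-learning framework is used: the two architectures run on a
purpose-built NumPy engine (`ceseg.nets.engine`) with explicit forward
and backward passes for k×k 'same' convolutions (asymmetric padding for
even kernels), 2×2 max pooling, stride-2 transposed convolutions
implemented as zero-insertion upsampling followed by a convolution,
inverted dropout, global average pooling, dense layers, soft-target
cross-entropy with pixel-wise soft-max, and Adam.  Gradients are
verified against finite differences in the test suite (to ~1e−8 on a
linear probe; directionally on the ReLU networks, where kink crossings
bound the attainable agreement).

* **U-net** (default): 4 resolution steps, each two 4×4 convolutions
  with ReLU, dropout 0.5 between them, then a 2×2/stride-2 max pool;
  channels 32, 64, 128, 256.  The expansion path mirrors it with 4×4
  stride-2 transposed convolutions (kernel divisible by the stride, so
  filter footprints overlap evenly and no checkerboard artefact arises),
  concatenation with the same-resolution contraction features, and two
  convolutions per step whose channel count halves at each upsampling
  (128, 64, 32, 16); a 1×1 convolution maps to the two classes.  Inputs
  must be divisible by 2⁴ (240×528 is).
* **SW-net**: the same contraction path with 3×3 kernels and no dropout
  (dropout made the patch classifier collapse to the majority class in
  the original experiments; it remains available but off), applied to a
  64×64 patch, then global average pooling and a two-neuron dense layer
  classifying the patch centre.  Prediction assembles one patch per
  pixel from a mirror-padded image; the assembly is tested against an
  explicit per-pixel loop.
* **Training**: Adam with lr₀ = 0.001 and the compounding decay
  lr_i = lr_{i−1}/(1 + 0.001·i) (the schedule is asserted in closed
  form; note it decays quickly — by iteration ~150 the rate is below
  1e−8, which matches its published form).  Batches: 4 whole images for
  U-net, 128 patches for SW-net with exactly 64 per class, the class
  being the binarised label of the central pixel.  Augmentation is
  horizontal/vertical flips only (rotations and elastic deformations
  would fabricate noise patterns the sensor never produces).  Optional
  class weighting uses edge:body = 4:1, reflecting the ~4× pixel
  imbalance; it is off by default.  Soft targets (p, 1−p) are the
  default; `label_mode="binary"` reproduces the hard-label ablation,
  and a seeded comparison in the tests checks it evaluates no better
  than soft labels.
* **Receptive field**: RF = 1 + Σ_convs (k−1)·(cumulative stride), with
  pooling contributing stride only.  This convention reproduces all
  seven published values (61, 91, 121, 43, 187, 125, 89).  A
  gradient-probe cross-check builds a linear version of the contraction
  path (identity activations, stride-2 subsampling in place of pooling,
  positive weights) and measures the nonzero-gradient extent, which must
  equal the calculator exactly.  For the 3×3 variant with a third
  convolution per step the convention yields 91 rather than the
  published 93; that configuration is therefore not used as a reference
  value.

## Postprocessing

1. **Radial magnitude.**  2-D FFT without windowing; the centred
   magnitude's low-frequency background is removed by grayscale
   reconstruction by dilation with the marker equal to the global
   minimum everywhere except the DC pixel, which keeps its value.  The
   reconstruction is then the monotone descending hull of the DC lobe,
   and subtracting it leaves the features that rise above it — the
   cell-size ring.  (A marker that instead keeps the spectrum's boundary
   values was considered and rejected: boundary magnitudes are
   negligible, so that reconstruction is ~0 and removes nothing.)  The
   cleaned spectrum is angularly averaged into radial bins of width
   1/max(H, W) cycles/px, with each axis's frequency in cycles/pixel so
   non-square frames stay isotropic; the DC bin is excluded.  A constant
   map yields an all-zero spectrum and is flagged degenerate.
2. **Characteristic frequency.**  The dominant bin inside
   [1/60, 1/12] cycles/px — cell diameters of 12–60 px, a generous
   margin around the physiological 25–30 px — refined by a 3-point
   quadratic fit (the full parametric peak model of the prior literature
   is deliberately out of scope).  The peak must exceed twice the
   in-band median; otherwise an estimation-failure error is raised.
3. **Smoothing.**  Isotropic Gaussian with σ = k_σ/(α·f*), k_σ = 0.20,
   mirrored boundaries, truncation at 4σ.  Mirror boundaries conserve
   the image mean only approximately (relative drift ≲ 1e−3 on random
   images); the tests assert that bound rather than exactness.
4. **Watershed.**  Unseeded flooding from every regional minimum
   (8-connected minima plateaus, 4-connected basins, watershed lines as
   label 0).  A relief with no regional minimum (constant input) is one
   basin.  The line construction can strand one or two pixels of a basin
   behind the line; a cleanup keeps each label's largest 4-connected
   component so that "one cell = one 4-connected region" is an invariant.
   Cell count is non-increasing in σ (smoothing merges minima), which is
   property-tested.

## Biomarkers

S_i = B_i + E_i/2, where B_i is the body pixel count and E_i the number
of edge pixels whose 8-neighbourhood touches cell i — shared borders are
split evenly, and the package's vectorised accounting is tested against
a per-pixel scan.  ECD = 10⁶/(S̄·pitch²) cells/mm² (pitch default
1.038 µm/px); CV is the population coefficient of variation in percent;
HEX counts cells with exactly six region-adjacency neighbours, two cells
being neighbours iff they share a boundary run of at least
`min_adjacency_run` = 2 edge pixels (corner contacts are not sides; the
threshold is exposed because it must scale with any resampling).  Cells
touching the frame border, or with any body pixel outside the
region-of-interest mask, are excluded from all three estimators
identically.  Whether side counting should use region adjacency or
polygon-vertex detection is not fixed by the definitions; region
adjacency was chosen as the robust reading and is what the tests
specify.

## Evaluation

Accuracy and AUC are computed over all pixels with the ground truth
binarised at p > 0.5 (strict inequality); PRE*/SEN*/SPE* use only pixels
whose label is exactly 0 or 1, edge positive.  MHD uses the two 1-px
edge skeletons restricted to the gold-standard region.  Per-cell DICE
matches each truth cell with its largest-overlap superpixel (ties broken
towards the smaller label for determinism).  The 0.80 rule classifies a
failing cell as undersegmented when its best superpixel is larger than
the cell and oversegmented otherwise; a superpixel that is best match
for two or more truth cells marks all its failing matches
undersegmented.  The α sweep re-segments each map over
α = 0.60…1.40 (17 points) reusing the per-map f*, since the spectrum
does not depend on α.

## Synthetic data

A mosaic is a Voronoi tessellation of n random seed points, regularised
by Lloyd relaxation; the labelled truth is produced by flooding the
distance-to-nearest-seed relief with one marker per seed
(4-connectivity, watershed lines), which guarantees exactly n
4-connected cells separated by 1-px lines.  Junction pixels are thinned
where a unique 4-adjacent cell can absorb them; a 2×2 edge block remains
only at exact four-cell cross junctions, where it is geometrically
unavoidable under the 8-connected-line convention.  Defaults emulate the
reported acquisition: 240×528 px at 1.038 µm/px and 240 cells
(≈1800 cells/mm²).  Four Lloyd iterations were chosen once so that the
emergent statistics sit inside the reported clinical ranges — CV ≈ 21–26 %
(range 18–36) and HEX ≈ 42–50 % (range 44–74; the generator sits at the
lower edge, since Lloyd relaxation trades CV against HEX and cannot
reach high HEX at mid-range CV).  More relaxation lowers CV and raises
HEX monotonically, which is the generator's single regularity knob and
is property-tested.

The intensity model (per-cell brightness jitter, darkened borders, a
quadratic illumination field, Gaussian blur and noise) is qualitative:
it reproduces the features the pipeline depends on — dark 1–2 px
borders, non-uniform luminosity, a visible Fourier ring — and none of
the instrument-specific artefacts (Descemet folds, guttae, defocus
gradients).  Passing tests on these phantoms therefore validate the
algorithmic chain, not clinical-grade performance.

`simulate_network_output` emulates a trained network's imperfect edge
map for postprocessing robustness studies: the probabilistic label is
attenuated by a smooth random field (faded/missing edge segments,
attenuation 0.35 at correlation length 12 px) plus correlated additive
noise (σ = 0.08, correlation 1.5 px) and a 0.06 baseline.  These levels
were set so that the degradations match their qualitative descriptions
(some edges locally fade below threshold; interiors fluctuate visibly
but well below edge strength).  On such maps the α sweep is U-shaped
with its minimum near α = 1, reproducing the behaviour that motivates
the k_σ calibration.

## Numerical choices and degenerate inputs

* Constant images raise explicit degenerate-input errors in
  standardisation/normalisation; constant probability maps are flagged
  in the spectrum and raise at frequency estimation.
* CLAHE uses a 24×24 kernel (≈ one average cell) with clip limit 0.01 —
  the clip limit and interpolation scheme are not fixed by the published
  description, so a conservative standard construction (scikit-image's)
  is used and both knobs are exposed in the configuration.
* Coordinates are 0-based (row, col), row 0 at the top; segmentations
  are 16-bit label TIFFs (0 = edge skeleton), probability maps 32-bit
  float TIFFs, images 8-bit grayscale PNG/TIFF scaled to [0, 1].
* All randomness flows through seeded `numpy.random.Generator`s carried
  in the spec/config objects; identical seeds give byte-identical
  manifests and reports.

## Problem sizes used in tests

Unit and property tests run on 64–128 px mosaics with 10–40 cells and on
≤32×32 metric instances so the whole suite stays in tens of seconds on
one CPU; the pipeline-level checks (perfect-input recovery, the α sweep)
use full-frame 240×528 mosaics with 240 cells, and the training smoke
test uses a reduced U-net (2 steps, 8 base channels, 3×3 kernels) on a
64×64 image for 200 iterations — chosen as the smallest sizes at which
the measured properties are stable.

## Known limitations

* The synthetic phantoms cannot certify clinical accuracy; the
  published headline numbers on the 50-image dataset (pixel AUC ≈ 0.99,
  DICE ≈ 0.98, sub-percent biomarker errors) require that dataset and
  GPU-scale training and are not reproduced here.
* The NumPy engine is single-threaded per operation and intended for
  desk-scale experiments; full-resolution default-width U-net training
  is possible but slow.
* HEX of the generator sits at the low edge of the clinical range, and
  4-cell cross junctions keep a 2×2 edge block.
* The oversegment-then-merge refinement stage and stochastic/seeded
  watershed variants are intentionally out of scope.
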