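# Methods

## The mapping procedure

`reedcover` estimates the areal fraction of common-reed cover in an RGB
scene by patch classification. The classification unit is a square tile
of side `tile_size` (default 32 px). Training data are tiles cropped from
pure-class photographs — scenes fully covered by reed, and scenes free of
it — so every crop carries its source image's binary label without any
manual delineation. Crops are taken on a regular grid with an overlap
fraction of 0.5 along both axes (stride = `round(tile_size × (1 −
overlap))`), and if the last regular window does not sit flush with the
image edge one extra window is placed at `dimension − tile_size`
(shift-to-fit), so no margin is ever left uncovered. Windows are 0-based,
half-open, and listed row-major.

At inference the same tiling runs over the full scene; each tile gets a
softmax reed probability, and each pixel's probability is the unweighted
arithmetic mean over every window covering it (four windows for interior
pixels at 50 % overlap). The mask is `probability ≥ threshold` (ties
count as reed; default threshold 0.5) and the coverage fraction is the
mask mean. A `vote` mode that hard-thresholds each tile before stitching
is provided for comparison. Because trained tile probabilities saturate,
the mean-then-threshold rule behaves like a majority vote of the covering
windows; its effective spatial resolution is the stride (16 px by
default), which is the granularity limit discussed under *Limitations*.

## The classifier

The network is deliberately small: `conv(3×3, same padding, ReLU) → pool
2×2 → conv(3×3, same padding, ReLU) → pool 2×2 → flatten → fully
connected → softmax(2)`. Channel widths are (8, 16); pooling is max by
default with average selectable — both reduce positional sensitivity of
the learned features, and on a constant feature field they coincide. For
the default 32-px tile the flattened feature vector has 16 × 8 × 8 = 1024
entries and the whole model holds 3442 parameters.

Weights are initialised from U(−1/√fan_in, +1/√fan_in) with a seeded
generator (draw order conv1, conv2, FC; biases zero), so two builds from
the same spec are bit-identical. Training minimises categorical
cross-entropy with Adam (learning rate 1e−3, batch size 32) for a fixed
30-epoch schedule; batch order is drawn from the run seed and all
arithmetic is plain NumPy, making runs exactly reproducible on a fixed
platform. Per-epoch train loss, validation loss and validation accuracy
are recorded; there is no early stopping, learning-rate schedule, or
augmentation. The implementation is pure NumPy (im2col convolutions with
explicit backprop); at this scale a full 30-epoch run takes a few seconds
on one CPU core.

Splitting follows the field protocol: all tiles are shuffled and 70 %
(round-half-up) train the network. Note that with 50 %-overlapping crops
this leaks pixels between train and validation tiles cut from the same
photograph; the `group_by_source` split mode assigns whole source images
to one side and is the leakage-safe alternative. Validation metrics on
the synthetic benchmark are insensitive to the choice because the corpus
is cleanly separable.

## The synthetic benchmark

The generator replaces drone photographs with statistical caricatures
that keep exactly the properties the pipeline exploits:

* **reed**: vertical striations (sinusoid of period 6 px across columns,
  with a slowly wobbling phase) in a green-brown palette, plus Gaussian
  pixel noise (σ = 8 on the 8-bit scale). Its within-row variance exceeds
  its within-column variance by a wide margin (ratio > 1.5 for ≥ 99 % of
  seeds at both 32 and 64 px).
* **water**: an isotropic low-frequency field (Gaussian-filtered noise,
  σ = 3 px, small amplitude) in a blue-grey palette, dominated by shared
  isotropic pixel noise so its axis-variance ratio stays within
  [0.67, 1.5] at the same seed rates.

A frozen linear probe on (mean colour, log axis-variance ratio) separates
the two classes at ≥ 99 % on 32-px tiles; this certifies that classifier
benchmarks on the generator are well-posed rather than measuring an
accident of initialisation.

Scenes are a reed mask composited from full-size reed and water textures.
Two geometries exist. The default thresholds a correlated Gaussian random
field (σ = 32 px structure scale) at the quantile matching the target
coverage: both phases form contiguous belts and lagoons at a stated
characteristic scale — the morphology of real reed margins — and the
coverage target is met exactly to one pixel. The alternative `patches`
mode places axis-aligned ellipses/rectangles (a pixel is reed iff the
patch covers its centre, minimum ~30 px across) until the mask mean is
within 0.02 of the target, erroring if the patch budget cannot reach it.
The field geometry is the default because unions of randomly placed
patches inevitably leave slivers and crescents thinner than a tile, which
no tile-majority classifier can resolve — planted coverage would then be
unrecoverable for reasons unrelated to the method under test. Default
scenes are 256×256: the coverage estimate changes in units of one stride
cell, so a 128-px scene quantises the fraction at ~1/64 while 256 px
gives 16× finer granularity.

What the generator does **not** emulate: perspective and lens distortion,
sun glint and shadows, seasonal spectral variation, mixed vegetation
classes, sensor noise correlated across channels, and georeferencing.
Passing benchmarks here therefore demonstrate that the pipeline's
geometry, training loop and coverage estimator are correct — not that the
classifier would transfer to arbitrary field imagery without retraining
on real photographs.

## Evaluation

Tile predictions are summarised as the TP/FP/TN/FN confusion matrix with
reed as the positive class, plus accuracy, precision, recall, specificity
and F1. Ratios with a zero denominator are reported as *missing*, never
coerced to 0, so degenerate validation splits cannot silently inflate a
metric. The `risk_flag` report marks scenes whose coverage fraction
reaches a configurable threshold (default 0.6, ≥ convention); the value
is an explicit heuristic placeholder — no field-validated criterion
exists for when reed expansion threatens open-water biodiversity.

## Chemistry fixtures

The packaged tables hold the reed-stem measurements made alongside the
imaging survey: EDX weight-percent compositions of four samples (control
reed and water-kept reed, epidermis and cross-section; each column sums
to 100 ± 0.5 wt %, checked on load), and pH / electrical conductivity /
soluble salts for three aqueous extracts. Analytes for which only
concentration ranges were published (total nitrogen, nitrate, nitrite,
sulphate, sulphide, phosphate) are stored strictly as (lo, hi) metadata —
per-sample values are not invented. Two ranges were published in
descending order; they are stored normalised with the original order
recorded in a note field. The conductometric cell constant is
k = ½ Σ kᵢ with kᵢ = γᵢ/cᵢ over the two KCl standards (0.1 n and
0.01 n); γᵢ is the standard's specific conductivity (cm⁻¹) and cᵢ the
measured conductivity. No conversion from conductivity to soluble-salt
mass is implemented: the published extract values are inconsistent with
any single linear factor, so the table stores both columns as measured.

## Numerical and design choices

* Tile size, kernel size, channel widths, activations, pooling kind and
  learning hyperparameters are all configuration with the defaults above;
  none is canonical to the mapping recipe itself.
* Round-half-up for the 70 % training count (`floor(0.7·n + 0.5)`).
* Softmax head with two units rather than a single-logit sigmoid, so the
  per-class probability vector is explicit.
* Max-pool gradients are split equally among tied maxima, keeping
  training deterministic on constant regions.
* Probability fields are written as 32-bit float TIFF, or ×255 8-bit PNG.
* Degenerate inputs fail loudly: rasters smaller than one tile, overlap
  producing a stride below one pixel, single-class training partitions,
  non-finite losses, and unreachable patch-mode coverage targets all
  raise with actionable messages.

## Problem sizes

The default study conditions — 20 + 20 source images of 64×64 (360 tiles,
252 train / 108 validation), 30 epochs, 256×256 scenes — were chosen so
the full pipeline, including five independently seeded training runs in
the acceptance script, completes in well under a minute on a single CPU
core while leaving the classifier's task non-trivial (the corpus spans
400 distinct seeded textures).

## Known limitations

* Coverage resolution is bounded by the stride: stands or lagoons
  narrower than ~one tile are systematically eroded or filled. The
  measured coverage error on default scenes is ≲ 0.04; it grows as scene
  structure approaches the tile scale.
* The default tile-shuffle split leaks overlapping pixels between
  partitions (see above); validation accuracy on real photographs should
  be read from `group_by_source` splits.
* The classifier is a texture discriminator; it has no notion of species
  and will call any striated green-brown texture "reed".
* Thresholding at 0.5 is uncalibrated for scenes whose class mixture
  differs strongly from the training corpus.
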