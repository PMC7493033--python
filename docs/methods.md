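# Methods

## Model

`octfmap` classifies an OCT volume `X_i` (an ordered stack of `|X_i|`
grayscale B-scans, one volume-level label) in three stages.

**B-scan feature extraction.** A convolutional backbone maps each B-scan to
a length-`L` vector taken at the global average pooling of the last
convolutional stage, after the nonlinearity and before the classification
head. Training uses *label inheritance*: every B-scan receives its volume's
label, giving a large but noisy slice-level training set (a diseased volume
contains normal-looking slices). The head is trained with softmax
cross-entropy and momentum SGD; a configurable set of early stages can be
frozen, in which case their parameters are excluded from the optimizer and
their batch-norm layers stay in inference mode, so frozen state is
bit-identical before and after training.

**2-D feature map.** The `|X_i|` vectors are stacked row-by-row in
acquisition order into the matrix `F_i` of shape `(|X_i|, L)`. Row order is
meaningful: adjacent B-scans are anatomically correlated, so `F_i` has
row-to-row correlation that a 2-D classifier can exploit. Flattening for
the linear model is row-major ("lexicographic"): element `(i, j)` lands at
index `i·L + j`. For the reference geometry (100 B-scans of 1000×512,
`L = 2048`) the map holds 204,800 values against 51,200,000 voxels, a
250:1 reduction.

**Volume-level classifiers.**

- *LSVM*: linear SVM with L2 penalty and squared hinge loss (scikit-learn's
  `LinearSVC`) on flattened maps; `C = 1` by default.
- *CNN*: `n` convolution blocks — 3×3 convolution to 4 channels with "same"
  zero padding, batch normalization, LeakyReLU (slope 0.01), 2×2 max
  pooling with stride 2 and floor semantics — followed by one fully
  connected layer and softmax. Same padding means pooling alone controls
  downsampling, which is what produces the printed activation chain
  (100×2048 → 50×1024 → 25×512 → 12×256 → 6×128, flattened FC input
  4·6·128 = 3072). The constraint `2^n < |X_i|` guarantees every block has
  rows left to pool; it is validated at construction.
- *CNN_CBAM*: the CNN with a convolutional block attention module after the
  last block. Channel attention: global average- and max-pooled channel
  descriptors pass through a shared two-layer bottleneck (reduction `r`,
  ReLU between, biases included, following the reference implementation);
  the two outputs are summed and sigmoid-squashed into per-channel gates in
  (0,1). Spatial attention: channel-wise mean and max maps, concatenated
  and convolved with a 7×7 filter, sigmoid-squashed into a spatial gate.
  `r = 2` by default because the network has only 4 channels.

All neural parts run on `octfmap.nn`, a ~500-line NumPy reverse-mode
autodiff engine (float64, CPU). Convolution is im2col + matmul with a
strided-view forward and a slice-scatter backward; runs are bit-reproducible
for a fixed seed.

## Default hyperparameters

| stage | lr | momentum | batch | epochs | notes |
|---|---|---|---|---|---|
| extractor fine-tuning | 5e-4 | 0.95 | 64 | 3 | freeze conv1–conv3; online crop/flip augmentation |
| volume CNN / CNN_CBAM | 1e-3 | 0.9 | 64 | 150 | softmax CE, momentum SGD |

B-scans are standardized per pixel as `(x − 0.45)/0.23` after rescaling to
[0, 1], and replicated across input channels where the backbone expects
more than one. Augmentation is the standard random-resized-crop (area
fraction uniform in [0.7, 1.0], aspect ratio uniform in [3/4, 4/3], 10
attempts then the full centered frame) followed by bilinear resize to the
backbone's input size and a horizontal flip iff a uniform draw is < 0.5.
The crop fraction is interpreted as an *area* fraction — the convention of
standard augmentation stacks.

## Design choices made where the design was open

- **Joint rather than alternating updates.** The reference protocol trains
  the last two backbone stages and the head "alternately"; no schedule is
  specified, so all unfrozen parameters are updated jointly at every step —
  the conventional reading.
- **Open-gate CBAM initialization.** Sigmoid gates at a random init output
  ≈ 0.5, so an untrained CBAM multiplies activations by ≈ 0.25 and shrinks
  gradients before it has learned anything. The gate output layers
  therefore start with bias +2 (gates ≈ 0.88), making the fresh module
  approximately the identity — highway-style gate initialization. This
  affects optimization speed only, not expressiveness.
- **Tie-breaks.** Equal class scores resolve to the lowest class index;
  the voting rule uses a strict inequality, so a positive fraction exactly
  equal to ε yields the negative class.
- **Partitioning.** "Approximately equal" k-fold parts: a class of size
  `qk + r` yields `r` parts of `q+1` and `k−r` of `q`, assigned to folds in
  shuffled order. The repeated-split protocol rounds the per-class training
  size half-up (classes of 448 and 462 at 40% train as 179 and 185).
- **Fold dispersion** is the sample standard deviation (ddof = 1), recorded
  in the report metadata; a single repeat reports sd 0 and is flagged.
- **Metrics** with empty denominators (no positive or no negative test
  volumes) are reported as absent, never silently 0.

## Synthetic data: what it emulates and what it does not

`generate_volumes` renders each B-scan as a dark background plus one bright
horizontal band of Gaussian depth profile; band depth varies smoothly
across columns (tilt) and across B-scans (sinusoidal drift), with i.i.d.
Gaussian pixel noise, clipped to [0, 1]. Positive-class volumes carry, in a
contiguous 30–70% stretch of their B-scans, a Gaussian bump (width
`lesion_width`) that pushes the band upward and deposits a fluid-like
bright pocket beneath it, both scaled by `lesion_amplitude`. Setting
`lesion_amplitude = 0` makes the classes identical in distribution. Because
only a subset of slices is lesioned, inherited B-scan labels are genuinely
noisy — the same label-noise structure the real task has.

`generate_feature_maps` emulates the class contrast of real feature maps
directly: class mean pattern + AR(1)-correlated row offsets (coefficient
`row_corr`) + i.i.d. noise, clipped to [0, 5]; the normal-like class has the
higher mean and smaller row variance, both gaps scaling with
`class_mean_shift` so a zero shift is the exact null.

Not emulated: OCT speckle statistics, multiple retinal layers, vendor
intensity profiles, segmentation ground truth. Passing tests therefore show
that the pipeline recovers volume labels from band-deformation signal under
label-inheritance noise at desk scale — not that it reaches any particular
accuracy on clinical data.

## Desk-scale study conditions

Chosen once for CPU-scale testing and used by the test suite:

- synthetic volumes: 50 + 50 per class, 16 B-scans of 24×24, lesion
  amplitude 0.5, lesion width 6 px, noise sd 0.05 (the "high separability"
  regime: a learning-free band-deviation threshold already separates the
  classes);
- backbone: `tiny-cnn` (stages of 8/16/64 channels, input 24×24,
  `L = 64`), trained from random init — hence no frozen stages and a
  from-scratch learning rate of 1e-2 (the 5e-4 default is a fine-tuning
  rate for a pretrained backbone) — and without crop augmentation: a
  0.7-area crop of a 24×24 B-scan routinely excises the entire lesion,
  which at this resolution only injects label noise;
- volume classifier: `cnn_cbam` with `n = 2`, 30 epochs, minibatch 16 —
  the training folds hold only 80 maps, and a minibatch of 16 preserves
  roughly the reference protocol's steps-per-epoch ratio.

Under these conditions stratified fivefold CV over three seeds yields a
mean accuracy of 96% (computed by `tests/test_acceptance.py`).

## Numerical notes and limitations

- Max pooling drops odd trailing rows/columns (floor); gradients of tied
  maxima are split equally.
- Batch-norm uses eps 1e-5 and running-stat momentum 0.1; inference always
  uses running statistics.
- The im2col convolution is O(k²·C·H·W) memory; fine at desk scale, not
  meant for 224×224×2048-channel workloads.
- `LinearSVC` may emit convergence warnings on perfectly separable
  high-dimensional flattenings; the decision function is still exact enough
  for classification.
- Voting is implemented for two classes (the use case of the baseline);
  multi-class plurality voting is out of scope.
- MAT-container volumes: one 3-D array per file, axis order configurable,
  default (height, width, B-scan); both classic and HDF5-based MAT formats
  are read.
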