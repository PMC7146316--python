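# Methods

## The classification problem

A hyperspectral cube assigns every pixel of an agricultural scene a
reflectance spectrum over N narrow bands (~200 for the public crop
benchmarks). Ground truth labels a subset of pixels with one of M crop
classes (label 0 = unlabeled background, excluded from all metrics).
The task is per-pixel classification; the difficulty is that several
crop classes (e.g. untrained grapes versus untrained vineyard) have
nearly identical mean spectra and can only be told apart by spatial
context.

Four pipelines attack this with a shared CNN core and different input
representations: the raw pixel spectrum; the spectrum after CNN-guided
band selection; the spectrum concatenated with the vectorized first Q
principal components of the R×R neighborhood (length N + R²Q); and the
R×R×Q principal-component stack fed to a 2D-CNN.

## Network and training

Both architectures cascade `depth` (default 4) convp blocks of 20
filters: convolution of kernel size 2 (1D) or 2×2 (2D), batch
normalization, ReLU, maxpooling of window and stride 2. The head is a
fully connected layer into a softmax, with FC input 20·N″ (1D) or
20·R″² (2D), where N″/R″ is the spatial size after the pooling cascade.

Numerical choices that the block structure leaves open, all configurable:

* **Padding.** Convolutions produce same-size output via edge-replicate
  padding (one column on the right / bottom). With kernel 2 and four
  stride-2 pools this makes the shape arithmetic exact: each block
  floor-halves the spatial size, so e.g. 204 → 102 → 51 → 25 → 12 and
  645 → 322 → 161 → 80 → 40; a 21×21 patch collapses to 1×1. A builder
  refuses geometries that collapse below 1 and names the offending block.
* **Pooling** floor-truncates a trailing partial window.
* **Batch normalization** uses mini-batch mean and *population* variance
  per feature (per channel for conv maps), guard constant eps = 1e-5,
  and running statistics with momentum 0.1 for inference — batch
  statistics at test time would make predictions depend on batch
  composition. Training-mode batches must hold at least 2 samples; a
  trailing mini-batch of size 1 is merged into the previous batch, so 33
  samples at batch size 16 yield batches of 16 and 17.
* **Optimizer.** Adam, learning rate 1e-3, on softmax cross-entropy
  (the loss implied by the softmax head). Weight init is small-variance
  Gaussian (He scaling) from a seed-derived stream; training is
  deterministic given the seed. Defaults follow the benchmark protocol:
  mini-batches of M′ = 16, 200 epochs, 50% of labeled pixels drawn at
  random for training (a stratified per-class option exists; whether the
  original protocol stratified is not stated, so simple random is the
  default). Non-finite loss raises a divergence error naming the epoch.
* **Ties** in the argmax break toward the lowest class index.
* **Gradients** are hand-derived per layer and verified against central
  differences in the test suite (including through the batch statistics,
  the replicate padding and the pooling argmax).

All computation is float64 numpy; the model sizes involved (tens of
thousands of parameters) make this comfortably fast on one CPU core.

## Input construction

* **Band removal** drops listed 1-based band ids (e.g.
  `108-112,154-167,224`); survivors keep their original ids so removal
  composes and spectra remain traceable to physical bands.
* **Standardization.** Spectra and PCA scores are standardized per
  feature with training-pixel statistics before entering the network or
  being concatenated. The original protocol does not state whether
  inputs were standardized (the first BN layer partially compensates),
  but the augmented vector concatenates reflectance and PCA scores of
  very different scales, so a common scale is the safer default; it is a
  config flag.
* **PCA** is fitted on all pixels of the cube by default, matching a
  transductive reading of "applied to each pixel" (a train-only scope
  exists for leakage-sensitive use). Component signs are fixed so each
  component's largest-magnitude loading is positive — PCA signs are
  arbitrary and determinism requires a rule.
* **Patches** are centered windows; out-of-image positions are filled by
  mirror reflection at the border, which keeps patch statistics
  scene-like and every labeled pixel usable. Patch vectorization is
  row-major with the component index fastest.
* **Band selection (BSCNN)** scores each candidate subset by zero-masking
  the evaluation inputs outside the subset and running the frozen
  full-band network; the input keeps its full length N. Scoring uses a
  validation split held out from the *training* pixels (default 20%) —
  the original description says only "overall accuracy" without naming
  the set, and scoring on the test set would leak it into model
  selection. L (the number of trials) is never stated; the default is
  100. Subsets are sampled independently per trial without
  deduplication, the simplest reading of "randomly selected". Ties
  break toward the earliest trial.

## Evaluation

OA = trace / total of the confusion matrix over test pixels. "Producer
accuracy" is implemented exactly as defined by the protocol this package
follows: the class diagonal divided by the *column* sum (pixels
classified to the class). Column normalization is conventionally called
user's accuracy or precision; the name is kept, the discrepancy is
documented here and in the module docstring. An empty column reports
PA = 0 with a warning.

## Synthetic scenes

The generator emulates the statistical shape of the public crop scenes,
not their physics:

* **Signatures** are sums of random Gaussian bumps over the band axis
  (default 6 bumps, width 8% of the axis, baseline 0.15), giving smooth
  non-negative mean spectra like real vegetation curves.
* **Layout** is a rectangular grid of contiguous single-class fields
  (16 classes → 4×4 fields) or Voronoi cells; ~10% of pixels are
  relabeled 0 to mimic unlabeled background (each class keeps at least
  one pixel). Background pixels get their own dimmed signature so maps
  look scene-like.
* **Noise** per pixel is an equal-variance mix of white noise and a
  spatially correlated field (white noise smoothed over a 3-pixel
  moving-average window, the simplest model of the neighbor correlation
  that motivates spatial features), scaled by a per-class standard
  deviation (default 0.05 against signatures of order 0.2–2).
* **Corrupted bands** are overwritten with N(0.5, 2.0²) noise. The scale
  is chosen so these bands' across-scene variance dominates clean bands'
  (whose variance is mostly between-class signature spread, ~0.3²) by
  well over the 5× the generator promises — emulating water-vapor
  absorption channels that carry no usable signal.
* **The confusable pair** gives two designated classes mean spectra a
  controlled L2 distance delta apart (delta = 0 → identical); their
  fields sit in different places with different neighboring crops, so
  only spatial context separates them. For the pair experiments the
  correlated-noise length is set to 1 (iid noise): with correlated
  texture and a random 50% split, a pixelwise network can partially
  separate even identical classes by memorizing local noise shared
  between neighboring train and test pixels, which would blur the
  mechanism the scene exists to isolate.

Default scene size is 40×40 pixels with 60 bands and 16 classes — large
enough that every class has ~90 labeled pixels and a 21×21 window
reaches neighboring fields, small enough that a full train/evaluate
cycle takes seconds on one CPU.

What passing on these scenes does and does not show: the synthetic
scenes have piecewise-constant class structure, stationary Gaussian
noise and no sensor artifacts beyond the corrupted bands, so results
here demonstrate the *mechanisms* (spatial context rescues spectrally
confusable classes; masking-based selection finds informative bands;
removing garbage bands helps a pixelwise classifier) rather than
absolute accuracies transferable to real sensors.

## Experiment scales

The recovery experiments in the test suite run scaled down from the
published protocol — 40×40×60 scenes, 40 training epochs, and for band
selection 40 bands with 200 trials — sizes chosen so each experiment
completes in well under two minutes on a single core while leaving the
measured effects (pair-PA improvement ≥ 0.2, informative-band overlap
above the hypergeometric mean of 2.5) far from their thresholds. The
full-size protocol (50% split, M′ = 16, 200 epochs, R = 21, N′ = 70 of
204 bands) is the package default and runs unchanged on the public
scenes if the user supplies them.

## Known limitations

* No GPU path; very large scenes (10⁵ labeled pixels at input length
  645+) train in hours, like any single-core implementation.
* The ENVI reader covers the standard header fields (samples, lines,
  bands, data type, interleave, byte order, offset, wavelength) only.
* Reflectance scaling of on-disk scenes is never assumed; cubes load in
  native scale and standardization happens in preprocessing.
* `producer_accuracy` is precision-like by design (see Evaluation); use
  the confusion matrix directly if recall-style per-class accuracy is
  wanted.
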