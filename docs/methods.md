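# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, what the synthetic data
emulate, and the problem sizes the test suite runs at.

## Live-frames and preprocessing

Videos are treated as ordered stacks of grayscale frames (frames are the
time unit; no wall-clock anywhere).  Preprocessing subtracts the per-pixel
mean frame of the whole video, zeroes residuals below an intensity
threshold of 25, median-filters with a 5-px kernel, and applies global
histogram equalization.  The equalization uses the cdf-minimum convention
(the most common value — the dark background — maps to 0), which keeps
background pixels black; a plain cdf mapping would lift the background to
mid-gray.  Background removal is only approximately idempotent: a second
application changes a small fraction of pixels (the mean of the processed
video is no longer exactly zero); the suite asserts < 2 % of pixels change.

A live-frame stacks frames `c−s, c, c+s` into R/G/B.  Stride `s = 1` suits
fast (fly-like) dynamics, `s = 2` slower (mouse-like) dynamics.  Rows of
every embedding matrix align to the *center* index, so label tables and
smoothing windows stay symmetric; a video of `n` frames yields exactly
`n − 2s` live-frames.

The single-animal tracker thresholds at 150, median-filters the mask
(kernel 5), keeps the largest connected component and returns its center
of gravity; empty frames yield missing values (NaN), not errors.  Wall
distances are the two smallest of the four side distances of the (clamped)
centroid, converted to cm.

## Augmentation

Two views per live-frame, pipeline order crop → rotation → vertical flip →
horizontal flip → Turbo → color jitter:

* crop side fractions drawn independently per axis from [0.7, 1] (so at
  least 49 % of pixels survive), placement uniform, resized back bilinearly;
* rotation angle uniform in ±arctan(W/H) — the acute angle between the
  image diagonal and the vertical (45° for square frames); exposed corners
  fill with black, the background color after preprocessing;
* flips and the Turbo lookup each fire with probability 0.5;
* Turbo maps each 8-bit channel through the published 256-entry Turbo
  colormap and keeps channel *i* of Turbo(channel *i*), preserving the
  motion-coloring structure while giving color jitter real leverage on
  grayscale data.  The LUT is taken from matplotlib's `turbo` colormap
  (the same published table; verified to contain 256 distinct rows);
* brightness and contrast jitter ±10 % always; hue and saturation jitter
  only after a Turbo transform (they are meaningless on grayscale channels).

An alternative reading of the per-channel Turbo composition — averaging the
three full RGB images — is noted but not implemented.  Note the per-channel
lookup uses a *different* LUT column per channel, so the transform does not
literally commute with channel permutations; what holds (and is tested) is
that each output channel depends only on its own input channel.

## Network

One weight-shared network, two passes per step.  Backbone choices:

* `resnet50` (default): the standard 50-layer bottleneck residual CNN
  without its classification head (23 508 032 parameters, verified against
  the canonical count), global average pooling → 2048-d features;
* `small`: four stride-2 conv-BN-ReLU blocks for CPU-scale work.

Heads (defaults match the published architecture; widths are configurable
so desk-scale runs can shrink them):

* projector: 3-layer MLP, width 2048, hidden layers BN+ReLU, output BN
  only; its output `z` is the Meta-representation at inference;
* predictor: bottleneck MLP 2048 → 512 → 2048 (BN+ReLU on the hidden layer
  only);
* group discriminator: one *weight-normalized* linear map 2048 → 1024
  (rows of the weight matrix scaled to unit norm every forward pass)
  followed by L2 normalization of each output vector.  The discriminator
  acts on the projector output.

`forward_train` concatenates the two views into a single batch, so
batch-norm statistics are computed and updated exactly once per optimizer
step; this also makes "identical views ⇒ identical branch outputs" exact.
Initialization is He-random; loading a pretrained checkpoint is supported
but no pretraining is bundled.

## Objective

`Loss = Loss1 + λ·Loss2` with λ = 2 and temperature θ = 0.07.

* `Loss1` is the symmetric stop-gradient cosine loss.  The implementation
  returns analytic gradients for the predictor outputs and *exactly zero*
  for the projector outputs; the suite verifies the predictor gradients by
  finite differences and that the loss value (which genuinely depends on
  z) receives no gradient through it.
* `Loss2` clusters each branch's discriminator outputs with spherical
  k-means (cosine similarity, centroids re-normalized each Lloyd
  iteration, hard assignments; an emptied cluster is re-seeded from the
  farthest point).  Sample *i* of branch A produces affinities
  `(vᵢ/θ)·M_Bᵀ` trained by cross-entropy toward the cluster label of its
  counterpart in branch B — the cross-branch pairing is what makes the
  term "cross-level": instance-level representations are compared against
  group-level structure of the twin branch.  Assignments are constants;
  gradients flow through v and through the centroids (normalized means of
  their members).  Cross-entropy is averaged, not summed, over the batch so
  λ is batch-size independent.
* k for the in-batch k-means defaults to 10 and is logged per run.

The collapse level is `1 − mean_c(std_c)·√C` with *population* (ddof 0)
standard deviations — this makes the analytic zero case exact: rows of
`[H; −H]/√C` (H a Hadamard matrix) are unit-norm with per-channel mean 0
and std exactly `C^{−1/2}`.  A plain Hadamard matrix does **not** work (its
first column is constant).  During training the monitor is computed on the
L2-normalized train-mode projector outputs each step; note that the
projector's final batch-norm standardizes channels *within* the batch, so
train-mode collapse readings understate degeneracy — eval-mode embeddings
of a fixed probe batch are the sharper diagnostic (used in the end-to-end
ablation below).

## Training

SGD, momentum 0.9, weight decay 1e-4 (excluded from batch-norm parameters
and biases), one-cycle learning rate with pct_start 0.025, div_factor 25
and final_div 1e4 (the latter two are this policy's customary defaults),
max_lr = base_lr · batch/256 with base 0.025 (0.05 for
fine-tuning).  Default 20 000 steps, batch 256.  Samplers: `cross_video`
(global shuffle) and `within_video` (each batch from one video; videos
shorter than a batch are sampled with replacement, with a warning).  All
per-step randomness derives from (seed, step), so resuming from a
checkpoint reproduces the original run bit-for-bit.  A warning is logged
when the train-mode collapse level exceeds 0.95 for 500 consecutive steps.

## Embeddings and downstream analyses

Embeddings are stored unnormalized; every cosine computation normalizes on
the fly.  A centered 3-frame moving average (`smooth_embeddings`) is the
standard noise-reduction step before nearest-neighbor use.

* **k-NN**: neighbors by cosine similarity; class score
  `Σ exp(sim/τ)·1[class]`; defaults k = 20, τ = 0.07, the standard values
  of the weighted-kNN construction this classifier follows, both exposed
  as parameters.  Temporal vote windows: 21 (fly), 81 (mouse/rat); ties keep the
  frame's own label; the vote is an unweighted majority.
* **Temporal features**: per dimension, centered moving mean and std plus
  the dominant short-time-Fourier frequency and its magnitude (window 81,
  reflect padding).  On 2048-d embeddings an optional PCA step (default 16
  components) precedes the sliding features.  The boosted learner is
  injected (default LightGBM) behind a fit/predict contract with early
  stopping; ensembles vote by majority and propagate no scores.
* **Anomaly**: IES − IAS with k = 1; the ±50-frame exclusion applies only
  within the same video (frames of other query videos are always eligible
  intra-group partners).  The exclusion is inclusive (`|j−i| ≤ 50`) and
  the radius is a parameter.  Distances are chunked; results
  are independent of chunk size.  A single one-off novel frame scores ≈ 0
  by construction — only recurring anomalies are flaggable, which is the
  intended false-positive suppression.
* **DTW**: symmetric step pattern with weights (1, 2, 1), no open ends;
  cosine costs for embeddings, absolute difference for scalar series.  The
  delay curve is `mean(matched i) − j` per reference index; positive means
  the query leads.  Group curves resample each pair's delay curve onto a
  common relative-position grid and report mean ± SEM.  The DP inner loop
  is quadratic and intended for desk-scale series (≤ a few thousand frames).
* **AR-HMM**: a finite-K EM fit (forward-backward E-step; weighted
  least-squares M-step; multi-restart best-likelihood; Viterbi decoding)
  **replaces the weak-limit Gibbs samplers used by nonparametric
  behavior-segmentation pipelines** — K is an explicit module cap
  (default 10), AR lag default 1 (configurable).  The
  log-likelihood is non-decreasing across EM iterations by construction
  and asserted in tests.  Zero-occupancy states are pruned with a warning.
  PCA-95: components fitted on the control group only, smallest count
  reaching 95 % cumulative explained variance; state usages compared by
  two-sided Mann-Whitney tests with Benjamini-Hochberg correction.

## Synthetic data: what it emulates and what it does not

`generate_scene_video` renders one or two Gaussian-smoothed oriented
ellipses (brightness gradient toward the "head", giving rotation-sensitive
texture) on a dark arena.  States follow a user-supplied Markov chain; the
default 3-state ethogram (idle / chase / contact) uses sticky transitions
(self-probabilities 0.92–0.95, mean bouts of ~15 frames) and
arena-relative target distances.  The follower's corrective speed is large
enough that a state switch settles within a few frames — otherwise
"idle" frames linger with overlapping blobs and the per-state pixel
statistics blur into each other.  The scenes emulate: two-agent top-view
grayscale recordings, distinct per-state motion statistics, Markov bout
structure.  They do not emulate: postural detail (wings, limbs), occlusion
beyond blob overlap, illumination drift, camera noise, or multi-arena
recordings — so passing tests show the pipeline's machinery is correct and
that it can discover blob-level behavioral structure, not that it matches
human annotation quality on real animals.

`generate_embedding_clusters` draws unit-norm vectors around random
orthonormal centroids (dispersion ∝ 1/separation) — a geometry fixture for
classifier and anomaly tests.  `generate_arhmm_series` simulates the exact
generative model of the AR-HMM fitter, enabling parameter-recovery tests;
it warns when an AR matrix's companion spectral radius reaches 1.05.

## Desk-scale test sizes

The full published recipe (ResNet-50, batch 256, 20 000 steps) is a
GPU-scale computation; the test suite exercises the identical code paths at
sizes chosen for a single CPU core:

* end-to-end benchmark: 48×48 arenas, four 1000-frame videos (3 train,
  1 additional for cross-validation), small backbone (width 8), projector
  128-d, batch 48, 2000 steps, base LR 0.1/256; leave-one-video-out 1-NN
  macro-F1 on 3-frame-smoothed embeddings.  Video length matters more than
  step count here: too-short videos under-supply data diversity and cap
  the representation quality well below what the same training reaches
  with longer recordings.
* collapse ablation (λ = 2 vs λ = 0): three of the same videos, 64-d
  projector, batch 16, 1250 steps, five paired seeds; "final collapse
  level" is computed on eval-mode embeddings of a fixed probe batch,
  because the train-mode monitor is partially masked by the projector's
  final batch-norm.  The ablation needs enough optimization for the λ = 0
  arm's drift toward degeneracy to express itself: at a few hundred steps
  the λ = 2 arm is *higher* (the cluster loss concentrates representations
  transiently) and the comparison inverts only as training proceeds.  The
  onset of the λ = 0 drift is strongly seed-dependent at this scale, so
  the paired comparison is the least stable part of the suite; the horizon
  used is the longest the desk-scale budget allows.
* AR-HMM recovery: 2 states, 3 dims, 20 000 frames, 5 seeds.
* oracle-equivalence suites (anomaly, k-NN, DTW) run on random instances
  of tens-to-hundreds of frames, sizes in the tests.

## Known limitations

* No video-container decoding: inputs are frame directories or in-memory
  stacks (the environment provides no FFmpeg bindings); container
  extraction is an upstream step.
* The numpy layer framework is single-threaded and eager; it is meant for
  correctness and desk-scale training, not production GPU training.
* The finite-K EM AR-HMM is a deliberate methodological substitution for
  the nonparametric Gibbs machinery (see above); with K well above the
  number of distinct dynamical regimes, surplus states go unused and are
  pruned, but the two fits are not numerically interchangeable.
* t-SNE visualization of embeddings is out of scope (any off-the-shelf
  reducer works on the exported matrices).
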