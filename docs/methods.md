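# Methods

## Problem and model

The package reconstructs naturalistic video frames from fMRI voxel
responses in early visual cortex (V1, V2, V3). Its core idea is that these
areas are retinotopic: each voxel has a receptive-field (RF) center
`RF(r1, r2, r3) = (x, y)` in stimulus coordinates, so voxel activity can be
*transported* into pixel space before any learning happens. With point-like
RFs the transported image is

    n(x', y') = (1 / M(x', y')) * sum over voxels with RF center at (x', y') of n(r1, r2, r3),

where `M(x', y')` counts the voxels mapping to pixel `(x', y')`; pixels no
voxel maps to stay zero. This per-pixel mean is equivalently a sparse linear
operator `W` of shape `[H*W, V]` with entries `1/M` (`rf_transport`), which
admits a learnable generalization: multiplying each voxel's masked entry by
a trainable weight `V_v`, initialized to 1 so the learned variant coincides
with the fixed transport before training (`networks.LearnableRFLayer`).
Because the delta mask assigns each voxel to exactly one pixel, only one
scalar per voxel is free; the weights are stored as a length-V vector.

Temporal structure is modeled by lag stacking, not deconvolution: for each
stimulus frame the transported images of the response volumes at a set of TR
offsets are stacked channelwise (ROI-major, lag-minor). The default lagset
is {3, 4, 5, 6, 7} TRs — five volumes centered on a 5-TR (3.5 s at
TR = 0.7 s) hemodynamic delay. Published descriptions of this window are
internally inconsistent (a "5 TR fixed delay" vs a "2.1–4.2 s window of 5
TRs", which spans only 4 TRs at 0.7 s); centering five lags on 5 TR and
making the set configurable is the package's resolution.

The stack of RF-signal images (15 channels for 3 ROIs x 5 lags) is
translated to a `[3, H, W]` frame in [-1, 1] by a U-Net generator (first
convolution, four stride-2 skip-connected encoder/decoder pairs, final
transposed convolution, tanh). A five-layer convolutional PatchGAN
discriminator with batch normalization and leaky ReLU (slope 0.2) scores
patches of the candidate frame concatenated with its conditioning RFS
images. Channel widths and strides follow the standard conditional
image-to-image plan (encoder widths base*{2,4,8,8}, kernel 4; discriminator
strides 2,2,2,1,1, so 96x96 in gives a 10x10 patch grid); only the depth of
both networks is fixed by design, the widths are free configuration.

## Losses and optimization

The generator minimizes `1*L1 + 100*feature + 1*adversarial`:

- **L1**: mean absolute pixel difference.
- **Feature**: Euclidean distance between extractor features of target and
  reconstruction. The distance is RMS-normalized over the feature dimension
  (`sqrt(mean((f_t - f_r)^2))`) so the weight of 100 acts on an O(1)
  quantity regardless of extractor width; whether the original formulation
  summed or averaged over feature dimensions is unstated, and this is the
  package's choice.
- **Adversarial**: BCE of the discriminator's patch logits against the
  "real" label — the inverse of the discriminator's objective.

The discriminator minimizes `BCE(real->1) + BCE(fake->0)`, each term
averaged over the patch grid. Fakes pass through a history buffer of
capacity 50: while filling, reconstructions pass through unchanged and are
stored; once full, each incoming reconstruction is swapped with a uniformly
drawn stored one with probability 0.5 (the candidate replaces the sampled
entry), so the discriminator keeps revisiting the generator's past errors.

Optimization is Adam (lr 2e-4, beta1 0.5, beta2 0.999), one discriminator
step then one generator step per batch (update order is a convention; the
alternative was not explored). Batch size defaults to 16 and epochs to 50;
the condition of the discriminator is detached so only the generator (plus
any trainable frontend: the learnable RF layer, or the linear layer of the
voxel-input baseline) receives the composite gradient. Training runs in
float32 — adversarial training does not benefit from double precision and
CPU matmuls are about twice as fast; all analytical code paths default to
float64. Training aborts with a diagnostic on non-finite loss. Seeded end to
end: same seed, same loss log, bit for bit.

## Feature extractors

Both the training feature loss and the evaluation metrics are computed
against a pluggable extractor interface. The shipped extractor is a
fixed-seed random-weight convolutional network exposing the canonical
`pool2 / pool5 / fc6` layers; two instances (`alexnet_like`, and a wider
`c3d_like` standing in for a spatiotemporal clip network applied per frame)
form the evaluation pair. Random convolutional features are a standard
perceptual basis and keep the package self-contained; absolute published
correlation/distance values require the original pretrained AlexNet/C3D/VGG
activations and are out of scope. Any object with
`features(images, layer) -> [N, D]` (and differentiable `__call__` for the
loss) can be substituted.

## Baselines

1. **Identification**: ridge-regularized closed-form linear encoding model
   (default lambda 1.0 — deterministic, unlike an SGD-trained dense layer)
   from stimulus features to voxels; training stimuli are forward-passed and
   each test voxel pattern is Pearson-correlated against all predicted
   training patterns; the reconstruction is the pixelwise mean of the top-10
   frames (ties break toward the lower index; "clips" are single frames at
   this scale).
2. **Voxel-input GAN**: identical generator/discriminator and losses, but
   the input is the raw z-scored lag-stacked voxel vector through a learned
   linear layer reshaped onto the generator grid — no topography.
3. **Fully connected control**: all convolutions replaced by dense layers;
   documented as an expected-to-fail control with far more parameters than
   the convolutional model.

## Evaluation

Per test frame and per extractor-layer combination (2 x 3 = 6), Pearson
correlation and Euclidean distance between reconstruction and target
features, then averaged over frames. Constant feature vectors make the
correlation undefined; it is recorded as 0 with a warning. Statistics:

- one-sided one-sample t-test of a per-frame metric against a chance level;
  chance is built by shuffled pairing (reconstruction i vs target j != i),
  since no canonical chance construction exists for these metrics;
- one-sided binomial test against p = 0.5 counting wins across all frames
  and all 12 metric columns — higher correlation wins, *lower* distance wins
  (a "higher metric" can only mean "better"), ties count as failures.

## Synthetic data generator

`synthetic_data` emulates the structure of a single-participant naturalistic
video fMRI session: three pseudo-ROIs (V1s/V2s/V3s) whose RF centers tile
the canvas with Gaussian jitter increasing along the hierarchy (sd 0.5, 1.0,
1.5 pixels), TR = 0.7 s, and voxel responses equal to the video luminance at
each voxel's RF center delayed by a fixed 5 TR, plus Gaussian noise
(default sd 0.1), z-scored per voxel. The luminance (grayscale) response
model is the simplest generative structure consistent with early visual
areas; color in the reconstructions must then come from the generator's
learned statistics of the toy video. A fixed point delay matches the
model's own temporal assumption (lag stacking). The generator deliberately
omits an HRF shape, physiological noise spectra, head motion, and
between-run nonstationarity — so passing tests show that the pipeline
recovers what its own forward model encodes, not that it would reach any
particular accuracy on real BOLD data.

The pass-through experiment (`passthrough_rfs`) replaces voxel responses by
the stimulus's own values at the RF centers: it measures how much stimulus
information the RF pixel budget carries, independent of brain data, and is
the package's feasibility/hyperparameter harness.

The toy video contains a moving bright disc, bar, and face-like blob on a
dark background, deterministic per seed.

## Study-scale experiment and numerical choices

`pipeline.run_synthetic_experiment` is the desk-scale end-to-end recovery
run: 32x32 canvas, three pseudo-ROIs with one voxel per pixel each, lagset
{3,4,5,6,7}, 500 training frames, noise sd 0.1, 30 epochs, batch 16,
base width 16 (about 5-6 minutes on one CPU core; width is the package's
size choice, scaled so a single-core run stays comfortable). Held-out
reconstruction quality is the mean per-frame pixel Pearson r; the control
pairs each reconstruction with the target half the test set away — adjacent
frames of a smooth video are near-duplicates, so a one-frame shift would not
be a control. At these defaults the matched correlation lands above 0.9 and
the control near 0.

Other numerical conventions: coordinates are 0-based with (x, y) =
(column, row); pixel (x', y') covers [x', x'+1); continuous RF centers are
assigned by nearest-pixel rounding with exact halves toward the lower index,
and in-canvas coordinates within half a pixel of the upper border stay on
the edge pixel. Voxels whose centers fall outside the canvas are dropped at
load time with a logged count. Z-scoring is per voxel over the full run,
before lag stacking; constant voxels become zeros. The fish-eye warp — cited
in the literature without a formula — is fixed here as the power-law radial
map `r_src = R * (r_dst / R)^(1+strength)` about the canvas center with R
the half-width, bilinear sampling, out-of-bounds reading 0, default strength
0.5; it magnifies the center and compresses the periphery, and strength 0 is
the identity up to interpolation. Video resampling picks the nearest source
frame at each target timestamp k*TR and resizes bilinearly; frame count is
floor(duration/TR) with a 1e-9 guard on the float ratio. Data-fraction
splits are contiguous prefixes of size floor(n * fraction) — for a 119,000
frame corpus: 95,200 / 71,400 / 47,600 / 23,800 at 4/5 … 1/5.

## Dependencies and self-authored components

numpy/scipy/pandas carry the numerics (sparse transport operator, bilinear
sampling, statistics via scipy.stats); h5py, nibabel, imageio and yaml/json
carry the formats. The neural networks run on a small reverse-mode autodiff
engine written for this package (`voxel2pixel.autodiff`): broadcast-aware
arithmetic, strided (transposed) convolution decomposed over kernel
positions into BLAS matmuls, batch norm, Adam. Every gradient is verified
against central finite differences in the test suite.

## Known limitations

- Random-feature metrics rank models consistently but are not numerically
  comparable to pretrained-network scores.
- The synthetic generator's noise is white and Gaussian; real BOLD noise is
  temporally autocorrelated and structured, so the recovery thresholds here
  say nothing quantitative about real-data performance.
- RF centers are inputs throughout; estimating them from data is explicitly
  out of scope.
- Training is CPU-oriented and single-device; no mixed precision or
  learning-rate schedules.
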