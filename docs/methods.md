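# Methods

`braggcam` re-creates, at desk scale, an explainability study of CNN-based
hit finding for serial femtosecond crystallography (SFX): simulate diffraction
frames with known Bragg-peak ground truth, train small CNN classifiers on
them, and then interrogate the trained networks with two standard
visualization tools — gradient-weighted class activation mapping (Grad-CAM,
with guided backpropagation) and per-layer representation inversion —
alongside a classical radial-threshold spot-finding baseline.  This note
documents the models, the parameters that matter, the numerical choices, and
what the synthetic setting does and does not establish.

## Synthetic frames

A frame is a non-negative `H x W` intensity image (arbitrary detector units,
ADU) composed additively:

```
frame = Bragg peaks + amorphous rings + noise,  clipped at 0
```

* **Bragg peaks** are isotropic 2-D Gaussians (width `peak_sigma`, default
  1.5 px) at integer pixel centres, truncated at 4 sigma.  Integer centres
  make every planted peak a strict local maximum of the noise-free image, so
  brute-force oracles can count them unambiguously.  Centres are
  rejection-sampled with a minimum pairwise separation (default
  `7 * peak_sigma`); at that spacing the above-threshold footprints of even
  the brightest default peaks can never merge under 8-connectivity, which is
  what makes the spot-finder's exact-recovery property a theorem of the
  design rather than a statistical accident.  Up to 25 greedy placement
  passes (1000 candidate draws per peak) are attempted before a scene is
  declared overcrowded.
* **Amorphous rings** model scattering from non-crystalline material: a sum
  of radial Gaussian profiles (width 3 px) centred on the frame centre, at
  radii scaling with the frame size.
* **Noise** is additive Gaussian read noise (default sigma 1 ADU), optionally
  preceded by Poisson resampling of the noise-free mean image (photon
  counting).  Poisson resampling is off by default so that oracle properties
  of the mean image are exact.

The five classes emulate the DiffraNet taxonomy.  Defaults (64 x 64 frames;
peak counts scale with frame area for other sizes):

| class     | peaks   | amplitude (ADU) | rings | binarized |
|-----------|---------|-----------------|-------|-----------|
| Blank     | 0       | —               | 0     | miss      |
| NoCrystal | 0       | —               | 6 ADU | miss      |
| Weak      | 3–6     | 8–14            | 3 ADU | hit       |
| Good      | 7–12    | 16–30           | 3 ADU | hit       |
| Strong    | 13–20   | 34–60           | 3 ADU | hit       |

The ranges are disjoint and ordered, realising the taxonomy's "increasingly
higher intensity" definition in a form whose class boundaries are sharp.
Note what this implies: the five-class problem is *easier* than its
real-data counterpart (see Limitations).  The hit/miss merge maps
{Blank, NoCrystal} to miss and the rest to hit.

Datasets carry a deterministic, per-class stratified train/test split; all
per-frame randomness derives from `numpy.random.SeedSequence` children of a
single dataset seed.

## Classifiers

Two size-parameterized architectures are built on an in-package CNN engine
(`braggcam.nn`) with explicit forward/backward passes — explicit backprop is
what gives the explanation methods uniform access to any layer's activations
`A^k`, to class-score gradients, and to the modified guided-ReLU backward
rule:

* **alexnet_style** — five convolution blocks (conv + ReLU, max-pooling after
  blocks 1, 2 and 5) followed by three fully connected layers.  The desk
  preset uses 64 x 64 single-channel input with reduced filter counts
  (16/32/48/48/32, FC 128/64/n); the classic full-size filter plan
  (96/256/384/384/256, FC 4096/4096/n, 11 px stride-4 stem) exists as the
  `full` preset.  The desk preset omits dropout and local-response
  normalization so every pass is a deterministic function of the weights.
* **resnet_style** — a 3 x 3 stem, configurable residual stages of 3 x 3
  basic blocks (1 x 1 projection on shape change), global average pooling
  and a linear head.  Tests exercise a two-stage variant; explanations
  default to the last residual stage.

Preprocessing standardizes each frame ((x − mean)/(std + 1e-8)) and
replicates grayscale to the required channel count; the generator's absolute
intensity scale is therefore irrelevant to the classifier.  Activations
reported for a named layer are the post-ReLU feature maps, taken before any
pooling.

Training uses Adam with cross-entropy on raw scores and an exponentially
decaying learning rate `lr(t) = lr_init * decay^t`.  The reference recipe
(50 epochs, batch 128, lr 1e-5) targets full-scale 512² training and is kept
as the `full` preset; the desk preset (15 epochs, batch 32, lr 1e-3, decay
0.9) uses the standard Adam rate appropriate for the small networks and
datasets the test suite trains.  Desk study size: 500 training and 100 test
frames per class — chosen so the whole study runs in minutes on one CPU
core.  Predicted labels are score argmaxes; exact ties break toward the
lowest class index.

## Grad-CAM, guided backpropagation

For class score `y^c` (raw pre-softmax classifier score) and conv-layer
feature maps `A^k`:

1. `∂y^c/∂A^k` by backprop;
2. neuron importance `α_k^c` = spatial mean of that gradient;
3. `L^c = ReLU(Σ_k α_k^c A^k)`;
4. bilinear upsampling of `L^c` to the input size, then per-map min-max
   normalization to [0, 1] (an all-zero map stays zero);
5. jet-colormap alpha blend for presentation.

Guided backpropagation re-runs the backward pass with every ReLU passing
gradient only where its forward input and the incoming gradient are both
positive; guided Grad-CAM is the elementwise product of the upsampled heat
map with the guided pixel gradient.  On a network whose head is global
average pooling plus a linear layer, steps 1–3 reduce exactly to the classic
class activation map — the test suite uses this identity as an oracle.

Quantitative localization uses ground truth: `localization_score` is the
fraction of total heat-map mass inside a dilated mask (default radius 3 px)
around the planted peak centres; a uniform heat map scores exactly the mask
area fraction, which is the natural baseline.

## Representation inversion

Given `Φ_0 = Φ(x_0)` at a chosen layer, the reconstruction minimizes

```
l(Φ(σx), Φ_0) + λ_α R_α(x) + λ_TV R_TV(x)
```

with `l` the squared Euclidean distance normalized by ‖Φ_0‖², the α-norm
prior `R_α = Σ_i |x_i − x̄|^α` (α = 6) penalizing a wide spread of pixel
values, and the total-variation prior with exponent β = 1 on forward
differences favouring piecewise-smooth images.  β is fixed by the study
design; the α exponent, the normalized distance and the default weights
(λ_α = 1e-5, λ_TV = 1e-3) follow the classic inversion formulation the study
builds on.  σ is the mean Euclidean norm of preprocessed training images
(√(H·W) for standardized frames, ≈ 64 at desk scale), so the optimizer works
on unit-scale pixels.

Optimizer numerics (all declared choices): gradient descent with momentum
0.9 from a seeded Gaussian-noise start; the step is auto-calibrated once so
the first update moves the worst pixel by `step_size` (default 0.05)
normalized units, then decays x0.5 every ceil(iterations/3); the iterate is
clipped to ±6 normalized units per iteration — wide enough that Bragg-peak
intensities many standard deviations above background stay representable —
and the best-objective iterate is returned with a full per-iteration trace
of all three components.  With an identity representation and zero priors
the problem is a convex quadratic whose minimizer is `x_0`; the suite checks
the optimizer recovers it to numerical precision.  TV gradients use an 1e-8
smoothing inside the square root at β = 1.

## Spot-finding baseline

A Peakfinder8-style threshold scheme, per frame:

1. equal-width annuli (2 px) around the frame centre; per-annulus background
   mean/std estimated with upper-sigma-clipping iterated to convergence
   (pixels more than 3 std above the mean are discarded and the statistics
   recomputed), pooled over ±2 neighbouring bins — the innermost annuli of a
   64² frame contain fewer pixels than one peak footprint, so unpooled
   estimates would be signal-dominated;
2. candidate pixels exceed `mean + max(snr_min*std, min_intensity)`; the
   2 ADU absolute floor plays the role of a photon/ADC threshold and keeps
   the rule defined on noise-free frames;
3. 8-connected components, kept iff `n_min < size < n_max` (strict, per the
   scheme's "more than / fewer than" wording), intensity-weighted centroids,
   integrated intensities, SNR against the local annulus;
4. a frame is a hit iff at least `n_peaks` components survive.

Background is estimated per frame (frames are independent here), not from a
running average across frames.

## What passing tests show — and what they do not

The generator emulates the *statistical structure* of the five-class
taxonomy, not diffraction physics: no Ewald-sphere geometry, polarization,
panel gaps, mosaicity or realistic background textures (all out of scope, as
is the nanoBragg simulator that produced the original synthetic set).
Consequences worth stating plainly:

* Desk-scale classification accuracies (≈100% five-class) exceed the
  full-scale reference values (98.1/98.3) because the synthetic classes have
  sharp boundaries; they are property substitutes ("the pipeline trains and
  generalizes"), not reproductions of the published numbers.
* Because the five-class task is solvable from global intensity statistics,
  the five-class model's Grad-CAM heat need not concentrate on peaks — we
  observe it mostly does not.  The *hit/miss-merged* model, whose class
  evidence is the presence of Bragg peaks, does localize above the uniform
  baseline for every hit class, and that is the model the localization
  property and the study report score — consistent with the merged-class
  setting the original visualizations use for discriminative regions.
* Inversion faithfulness (conv1 reconstructions correlating with the input
  far more strongly than conv5) is a robust trend here (≈0.99 vs ≈0.1
  Pearson), matching the qualitative expectation that early layers keep a
  photographically faithful copy.

## Reproducibility

Every stochastic stage takes an explicit seed; the study driver derives
per-stage seeds from one global seed by fixed offsets (simulate +1,
five-class training +2, hit/miss training +3, explanation sampling +4,
inversion +5).  Training histories, predictions and report metrics are
bitwise-reproducible for a fixed seed on a fixed BLAS; across platforms,
floating-point reduction order may perturb late-epoch weights without
affecting the reported properties.  Model weights default to single
precision (double the CPU throughput; classification and explanation are
insensitive to it) — gradient-checking tests build double-precision
networks.
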