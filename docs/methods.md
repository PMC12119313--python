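# Methods

This note documents the models, numerical choices and limitations of
`dualdistill`, in the order a user meets them: the synthetic data, the
staged-backbone adapter, the three distillation signals, the training
protocol, the metrics, and the introspection tools.

## Conventions

All video arrays use the axis order **(channel, time, height, width)**,
with a leading batch axis inside models and losses.  The literature
alternates between T×C×W×H and C×T×H×W conventions; this package fixes
one and converts on ingest.  Flattening a stage feature to frame rows
orders each row channel-fastest, then width, then height; the inverse
operation restores the feature exactly.

Losses are averaged over the batch axis.  Models train in single
precision (`float32`); all analytic operations preserve the dtype of
their inputs, so oracle tests run in double precision.

## Synthetic plaque-like videos

The generator emulates the *statistical* structure of B-mode
carotid-plaque clips, not their physics:

* **Background and blob.** A constant mid-gray background (0.40) with
  one disk-shaped blob whose edge is softened by a ~1.5 px sigmoid
  profile.  Class 0 renders the blob bright (0.78), class 1 dark
  (0.10), class 2 half-bright/half-dark split at the blob centre.
  Radius is drawn per clip from `blob_radius_range` (default 6–12 px at
  64×64).
* **Speckle.** Multiplicative Rayleigh-like noise with unit mean,
  strength `speckle_sigma` (default 0.30), clipped to [0, 1].  This
  gives first-order B-mode texture; there is no beamforming,
  attenuation, or depth-dependent point-spread function, so passing
  tests show the *method* works on speckle-like statistics, not that it
  transfers to clinical data.
* **Drift.** The blob centre random-walks with per-frame Euclidean step
  ≤ `drift_step` (default 1 px/frame).
* **Probe jumps.** With per-clip probability `jump_rate` (default 0.5)
  the blob is abruptly displaced mid-clip by one third of the image
  side, then returns linearly to the undisturbed path by the last
  frame, with fresh speckle after the jump.  This reproduces the
  clinical phenomenon in which two adjacent frames are less similar
  than two distant ones.  `inject_probe_jump` applies the same
  transformation to an existing generated clip; re-rendering with the
  clip's own noise seed and zero displacement is an exact identity.
* **Scale.** Default clips are 24 frames of 64×64 — a deliberate
  desk-scale stand-in for full-length 120-frame studies, which remain
  available through `SynthParams(n_frames=120)`.

Per-frame speckle streams derive from `(noise_seed, frame_index)` seed
sequences, so datasets are bit-reproducible and individual frames can
be re-rendered independently.  Clip metadata carries the blob masks and
centres, which the tests use as ground-truth oracles.  Contrast levels
are free parameters chosen for a clear but not trivial signal; they are
not calibrated against clinical imagery.

## The autodiff engine

No deep-learning framework is a dependency: `dualdistill.nn` is a small
reverse-mode automatic-differentiation engine over numpy arrays with
exactly the primitives the package needs (elementwise arithmetic,
matmul, reductions, argmax-routed channel max, slicing/concat, a 3-D
convolution, and fixed-matrix axis resampling).  The convolution is
computed by im2col: one strided gather per kernel offset into a column
buffer, then a single GEMM; the buffer is reused in the backward pass
for the weight gradient, and the input gradient is scattered back
through the same slices.  Gradients accumulate on every node that
requires them, which is what lets Grad-CAM read gradients at
intermediate feature maps.  Numeric-differentiation tests pin the
gradients of every composite operation.

## Staged backbones and auxiliary heads

A backbone exposes its stages as ordered module attributes plus a
`classify(feature)` method.  `register_stages` validates the stage list
and adds **zero** parameters; `attach_aux_heads` adds one auxiliary
classifier per selected student stage and the shared attention module;
`strip_auxiliaries` returns the original backbone object, so the
stripped model's parameter multiset and outputs are bitwise identical
to the teacher branch — distillation costs nothing at inference.

The auxiliary head is deliberately minimal: global average pooling over
(time, height, width) followed by one affine map.  Published
self-distillation implementations sometimes insert bottleneck
convolutions before the pool; a `bottleneck_conv` variant is provided,
but the default keeps the head architecture-independent since nothing
in the method constrains it.  The bundled `ToyVideoNet` (4 stages of
3×3×3 convolution + ReLU, stride 2 in time/height/width from stage 2,
widths 4-8-16-32) exists for tests and desk-scale experiments; real
backbones integrate through the same adapter.

## Relation-matrix distillation

`R = G·Gᵗ / ‖G‖²_F` is the literal normalised Gram matrix
(`frobenius` mode): symmetric, trace 1, scale-invariant, but its
entries are **not** confined to [−1, 1].  A `cosine` mode (row-pairwise
cosine similarity: unit diagonal, entries in [−1, 1], also
scale-invariant) is provided because frame-relation *coefficients* are
conventionally reported on the [−1, 1] scale; the two normalisations
genuinely differ and both are exposed.  The loss defaults to the
Frobenius mode and to the plain Frobenius norm of the difference per
stage ("element-wise Euclidean distance" read literally); squared and
mean reductions are config options for scale tuning.

Stages disagree in temporal extent in strided backbones, so student
matrices are bilinearly resampled (half-pixel centres) to the teacher's
T×T and re-symmetrised as `(R + Rᵗ)/2`.  Resampling the small matrix
rather than the features keeps the module stateless and cheap.  For
zero frames in cosine mode the affected rows and columns (including the
diagonal) are zeroed with a warning; an all-zero feature tensor in
Frobenius mode is an error, since the normalisation is undefined.

The teacher matrix is detached by default: distillation should not drag
the teacher toward its students.  This is configurable.

## Attention-map distillation

Channel mean- and max-pooled maps are concatenated (2 channels) and
convolved with a shared 2-in/1-out kernel of spatial size 7×7 applied
per frame (temporal extent 1).  Three open design points are resolved
as documented defaults, each switchable: the kernel is *shared* across
stages (it is resolution-agnostic; per-stage kernels would add
unmatched parameters), the temporal extent is 1 (a (3,7,7) variant is
available), and no squashing nonlinearity follows the convolution (a
sigmoid flag exists).

Unlike the relation loss, the attention loss does **not** detach the
teacher by default: the attention kernel's only gradient source is this
loss, so full detachment would leave it untrained.  To prevent the
trivial collapse of scaling all maps toward zero, each map is divided
by its own Frobenius norm before the distance (normalisation on by
default).  Student maps are trilinearly resampled to the teacher's
(time, height, width) before comparison.

All resampling in the package (relation matrices, attention maps,
Grad-CAM volumes, frame resizing) uses one half-pixel-centre separable
linear interpolation; downsampling by exactly 2× then equals block
averaging.

## The combined objective

`L = L_SD + β·L_RGSD + γ·L_AGSD`, with
`L_SD = Σ CE + α·Σ τ²·KL(p_K ‖ p_i)`.  Choices:

* **KL direction** — teacher as reference distribution,
  `KL(p_teacher ‖ p_student)`, the common distillation convention; the
  direction is switchable since the base formulation does not fix it.
* **Temperature** — default τ = 3 with the standard τ² gradient
  compensation; τ = 1 recovers the unsoftened loss.
* **Weights** — α = 0.3, β = 0.1, γ = 0.1, chosen once so the three
  components have comparable magnitude on the synthetic smoke setup.
* **Components** — `{SD, RGSD, AGSD}` each toggle independently; a
  disabled component contributes exactly 0, and with SD disabled the
  classification part reduces to the teacher's cross-entropy alone, so
  the 8 on/off combinations are additively consistent on frozen
  weights.
* **Feature hints** — an optional L2 feature-matching term appears in
  some self-distillation variants; it is stubbed behind a flag and off
  by default, as the base objective here does not include it.

## Training protocol

SGD with momentum 0.9 and weight decay 1e-4; linear warmup
`lr(e) = base_lr·(e+1)/warmup` over the first `warmup_epochs` epochs
(default 10), then tenfold step decay at the milestones (defaulting to
50% and 75% of total epochs, since no canonical epochs are mandated);
global gradient-norm clipping at 1.0.  Preprocessing: uniform-stride
temporal sampling to `frames_per_clip` (looping short clips), clip-
consistent random resized crop (area fraction U[0.5, 1.0], aspect
U[3/4, 4/3]) and horizontal flip with probability 0.5 in training,
centre crop in evaluation, and channel standardisation with Kinetics400
statistics (averaged to a scalar pair for grayscale input).  Everything
derives from the config seed, so histories are reproducible on one
device.

Cross-validation is stratified (the clinical class mix is imbalanced,
roughly 124/80/113, so plain splits risk starving a fold of one class);
fold aggregation reports mean ± *sample* standard deviation formatted
on the percent scale.

Two problem-size profiles exist: the reference defaults (100 epochs,
224 px, 16 frames) and the desk-scale **smoke profile** (15 epochs,
32 px, 8 frames, 3-epoch warmup) used by the test suite, the examples
and the acceptance script.  The smoke sizes are the package's choice of
a configuration that a toy 4-stage CNN can learn on a CPU in about a
minute; nothing in the method depends on them.

## Metrics

Confusion counts are one-vs-rest per class.  Sensitivity, specificity,
precision and F1 are computed per class and macro-averaged; 0/0 ratios
are reported as 0 and flagged.  **Accuracy is the fraction of correct
predictions** (headline), while the macro average of the per-class
one-vs-rest accuracy `(TP+TN)/n` is also exposed — the two differ for
more than two classes, and published three-class tables rarely state
which is meant.  ROC curves are one-vs-rest with tied thresholds
merged; AUC is the trapezoidal integral, equal to the tie-averaged
rank statistic (verified against both a Mann–Whitney oracle and
scikit-learn).  The false positive rate is `FP/(FP+TN)` =
1 − specificity; a source formula equating FPR with sensitivity is a
typographical error and is not implemented.

## Introspection

`frame_relation_coefficients` reuses the relation module's cosine path
verbatim (single code path, bit-identical matrices) at any registered
stage.  `gradcam_3d` weights each channel of a tapped layer by the
spatial-temporal mean of the target-class score's gradient, rectifies
the weighted sum, trilinearly upsamples to input resolution and
normalises the maximum to 1; an everywhere-zero gradient yields a
flagged all-zero volume with a warning.  The input tensor itself
carries gradients, so the analysis also works through parameter-free
stages.

## Known limitations

* The speckle model is first-order; no claim is made about transfer to
  clinical ultrasound.
* The toy backbone is small by design; integrating published video
  backbones requires wrapping them in this package's module system (the
  adapter contract is the stage-attribute + `classify` convention).
* Bilinear resampling of relation matrices is exact block averaging
  only for integer 2× ratios; larger ratios lose high-frequency
  structure, which is acceptable for the smooth Gram matrices seen in
  practice.
* Directional-benefit results on the synthetic data are stochastic at
  this scale: the acceptance check asserts a non-inferiority margin
  over seeds, not a fixed improvement.
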