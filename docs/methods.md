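# Methods

`segpretext` implements and compares three strategies for training 2D semantic
segmentation models when labeled data are scarce: **contrastive patch-pair
pretraining**, **entropy-guided inpainting pretraining** (self-learning), and
**registration-based deformable data augmentation**, together with the metric
and statistical machinery needed to compare them fairly. Everything runs on a
synthetic deformable-phantom cohort, so the full pipeline is testable on one
CPU with no external data.

## Preprocessing model

Volumes are resampled to an isotropic 1 mm grid (linear for images, nearest
neighbor for masks, so masks stay binary). CT volumes are min–max rescaled to
[0, 1] per volume; the min–max is per-volume rather than a fixed HU window
because the input phantoms and cropped ROIs carry no calibrated unit. MR
volumes are divided by the intensity at the 90% point of the cumulative
histogram of their **nonzero** voxels and clipped at 2× that level; background
air is excluded because it otherwise dominates the histogram, and the clip
bounds the influence of hyperintense outliers. Degenerate inputs follow fixed
rules: a constant CT volume maps to all zeros, an all-equal MR foreground maps
to all ones, and a zero reference level raises an error. Training operates on
2D slices; by default only slices containing foreground are kept.

## Evaluation metrics

Six metrics on binary masks: Jaccard `|R∩T|/|R∪T|`, Dice `2|R∩T|/(|R|+|T|)`,
sensitivity, relative volume difference `100(|T|−|R|)/|R|` (signed percent),
Hausdorff distance and mean absolute surface distance. Two conventions are
worth flagging:

* **Sensitivity** defaults to `|R∩T|/|T|` — the denominator is the *predicted*
  mask, matching the evaluation protocol this package mirrors rather than the
  conventional `|R∩T|/|R|`; a `conventional` flag provides the latter.
* **Hausdorff** defaults to the directed form (reference → prediction);
  `mode="symmetric"` gives the max of both directions.

Surfaces are foreground voxels with a face-adjacent background neighbor
(4-connectivity in 2D, 6 in 3D); the image border counts as background.
Distances are Euclidean in physical mm. When both masks are empty the overlap
metrics are undefined and raise rather than silently returning 0/0; callers
filter empty slices. Nearest-surface queries use a k-d tree; the tests verify
every metric against exhaustive brute-force oracles.

## Contrastive pretraining

Proxy task: do two 30×30 px (3×3 cm at 1 mm) patches come from the same
subject? Patch centers are drawn half from the mask interior and half from a
10 mm band just outside it, so the encoder sees the organ and its periphery.
Batches are balanced (half positive, half negative); positive pairs are two
independent patches of one subject, possibly from different slices. The two
encoder branches are literally one object, so weight sharing is exact and
gradients from both branches accumulate in the same parameters.

The loss uses the Euclidean embedding distance `Dis = ‖p1 − p2‖`. The default
`corrected` mode is `Σ [L·Dis² + (1−L)·max(0, margin−Dis)²]` with margin 1.0 —
the standard contrastive hinge, which is the behavior the method description
implies (minimize distance for same-subject pairs, maximize for
different-subject pairs). An `as_printed` mode computing
`Σ [L·Dis² + (1−L)·Dis²]` is retained deliberately: that form is
label-independent (it reduces to `Σ Dis²`), and keeping it executable
documents the degeneracy instead of silently "fixing" it. Embedding dimension
defaults to 64 through a global-average-pool + linear head, which makes the
embedding independent of patch size.

After pretraining, the encoder is copied into a segmentation network; the
decoder and head are freshly initialized and **nothing is frozen** — the whole
model fine-tunes.

## Self-learning (entropy-guided inpainting)

Square patches are removed from each slice and a residual network regresses
the missing intensities, with RMSE computed **over the hole voxels only**
(over the full image the identity mapping would dominate the objective).

Patch placement is guided by a local Shannon-entropy map: per-pixel entropy
(bits) of the intensity histogram in a sliding 9 px window with 32 bins over
[0, clip_max] and reflective borders. A light Gaussian prefilter (σ = 1.5 px)
precedes the binning: without it, sensor noise in flat regions carries almost
as much *histogram* entropy as real structure, and the adaptive scheme loses
its discriminative power. Pipelines for real data denoise before analysis;
the prefilter plays that role here and can be disabled.

Centers are sampled with probability ∝ entropy plus a floor of 0.1·H_max —
informative regions receive many patches, flat regions still receive their
share (of large ones); with a strictly proportional rule a zero-entropy region
would never be corrupted at all. Patch size maps linearly from 25 mm at zero
entropy to 3 mm at the image's entropy maximum, clamped to [3, 25] mm; the
linear form is the simplest map consistent with the stated direction and
range. Sampling stops when the planned union covers 15% of the image area
(a budget under which ample context survives; configurable). Holes are filled
with 0, the post-normalization background value.

After pretraining, the sigmoid regression head is replaced by a fresh
two-channel per-pixel softmax head; trunk weights carry over bit-exactly and
remain trainable.

The **mean-fill baseline** used to certify learnability fills holes with the
mean intensity of the uncorrupted remainder; beating it shows the network
exploits spatial context rather than intensity statistics. Note the ceiling:
on these phantoms the additive noise is unpredictable by construction, so the
best achievable hole-RMSE is roughly the local noise-plus-texture standard
deviation.

## Deformable data augmentation

Each source subject is nonrigidly registered onto the coordinates of other
subjects: B-spline free-form deformation (control-point spacing 16 mm) under
Mattes mutual information, multi-resolution (2 levels by default at this image
scale), optimized by gradient descent with physical-shift parameter scaling
through SimpleITK's registration framework, full-grid metric sampling
(deterministic for fixed inputs and configuration) and a 0.5 mm cap on
per-iteration motion. The step cap matters at the near-identity end:
without it, the automatically estimated step size explodes when the initial
metric gradient is tiny (e.g. self-registration) and the optimizer drifts.
Quasi-Newton alternatives proved fragile here — on these images the MI values
are small enough in magnitude that relative function-tolerance tests fire
after a single iteration, silently returning near-identity fields. The resulting
dense displacement field warps the source image (linear) and its mask
(nearest-neighbor, re-binarized) identically; provenance (source id, target
id, field) rides along on every synthetic subject. With `policy="all"` an
n-subject cohort yields n(n−1) synthetic subjects; `k_random` caps targets per
source for bounded runtime. Registration targets may come from a separate
cohort — they need not be training subjects themselves, though the experiment
driver restricts them to the training fold to guarantee leak-free evaluation.

This package registers 2D slices (one field per subject pair, estimated on
middle slices and applied to all slices); the contract would equally admit a
3D engine. A conventional-augmentation baseline (rotation ±15°, isotropic
scale 0.9–1.1, horizontal flip p = 0.5, shear ±5°) is provided for
comparison.

## Network core

No deep-learning framework is used: `segpretext.nn` is a compact CPU layer
library (im2col convolution, ReLU, nearest-neighbor upsampling, global average
pooling, linear, sigmoid and channel-softmax heads, residual blocks, Adam)
with explicit backpropagation, written for the small networks these
experiments need. The backbone counts convolutional layers explicitly: the
default `layers=20` gives a twenty-convolution residual network (stem,
stride-2 downsampling, residual blocks at half resolution, a half-resolution
decoder convolution, 2× upsampling, 1×1 head). Layers are functional
(`forward` returns a cache consumed by `backward`), which is what makes the
weight-shared siamese pair exact. The learning-rate schedule decays
geometrically between the configured endpoints (contrastive proxy 0.01→0.0005,
inpainting proxy 0.005→0.0005, fine-tuning 0.005→0.0001, augmented training
0.01→0.0001; batch sizes 50/40 per task).

Fine-tuning minimizes the hybrid loss: soft Dice (smoothing ε = 1 in numerator
and denominator) plus mean per-pixel cross-entropy, summed with unit weights.

## Synthetic cohort: what it emulates, and what it does not

Each subject is an elliptical "organ" (24×16 mm base radii at intensity 0.5
over a 0.35 background) cut into 3 slices of an ellipsoid, deformed by a
subject-specific smooth random warp (Gaussian-smoothed white noise scaled to a
6 mm peak), with per-subject size jitter (lognormal, σ = 0.15), center jitter
(±4 mm), intensity jitter (σ = 0.04), band-limited interior texture
(amplitude 0.10) and additive Gaussian noise (σ = 0.08); an optional lesion
blob lies strictly inside the organ. The low contrast-to-noise ratio
(0.15 contrast against 0.08 noise) is deliberate: soft-tissue boundaries in CT
and MR are not high-contrast edges, and with a cleaner phantom the
segmentation task saturates and the frameworks become indistinguishable.
The mask is evaluated analytically at warped coordinates, so it is exactly
binary with no interpolation artifacts. Subject warps come from the same
family of smooth displacement fields the registration module estimates —
which is precisely what makes registration-based augmentation meaningfully
testable here.

Not emulated: imaging physics (beam hardening, bias fields, coil profiles,
partial-volume effects), multi-organ context, and pathology diversity. Tests
passing on these phantoms certify the pipeline's mechanics and relative
behavior, not clinical performance.

## Experiment design and statistics

Splits are patient-wise: subjects, never slices, are assigned to folds, and a
hard leakage assertion rejects any synthetic subject whose source *or* target
falls outside the training fold. Five frameworks share one k-fold split per
seed; inpainting pretraining and augmentation are computed once per training
fold and shared between the frameworks that use them (the artifacts are
identical either way). The full run is reproducible bit-for-bit given a seed
on one CPU thread.

Desk-scale defaults (`StudyScale`): 6-layer, 8-channel backbones, batch 8,
random 64×64 training crops, 150 fine-tuning steps, 100 inpainting-proxy
steps, 60 contrastive steps, and `k_random` augmentation with k = 3. These
sizes were chosen once as the package's one-CPU study conditions; every knob
is configurable and the full-scale schedules remain the defaults of the
underlying training functions. Optional plateau early stopping (patience on
the monotone-smoothed loss curve) replaces fixed epoch budgets when loss
plateaus are the stopping rule of interest. Per-subject evaluation stacks predicted slices into a volume and
scores it against the stacked reference.

Statistics follow the protocol the package mirrors: pairwise **paired**
t-tests per metric on per-subject scores (the pairing unit is the subject
within matched folds), significance at α = 0.05, plus one-way ANOVA across
frameworks with Tukey-HSD simultaneous confidence intervals. No further
multiple-testing correction is applied beyond Tukey HSD. Comparing a
framework with itself yields p = 1 by convention (zero differences).

## Numerical choices and edge rules

* Mask warping/resampling: nearest-neighbor, re-binarized at 0.5; linear
  interpolation on masks is available behind a flag but never the default.
* Both-empty mask pairs raise; empty predictions give Dice/Jaccard = 0 and
  NaN surface distances in reports.
* Entropy maps clip tiny negative round-off to 0 and are bounded by
  log2(bins).
* RMSE gradients guard the √ at zero with a 1e-12 floor; cross-entropy clips
  probabilities at 1e-7.
* The second conv of each residual block is initialized at 0.1× He scale so
  blocks start near the identity.
* Registration uses full-grid metric sampling specifically to keep fields
  deterministic; sampled strategies are faster but noisy.

## Known limitations

* The numpy training core is single-threaded and desk-scale; it is not a
  substitute for GPU-scale experiments, and absolute Dice values on phantoms
  do not transfer to clinical data.
* 2D registration of matched sections stands in for the 3D registration a
  clinical pipeline would use.
* The inpainting ceiling on noisy phantoms is the irreducible noise floor;
  improvements beyond the mean-fill baseline are necessarily modest there.
* Entropy-map parameters (window, bins, prefilter σ) interact with the noise
  level; the defaults target the phantom regime and are logged so real-data
  users can retune them.
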