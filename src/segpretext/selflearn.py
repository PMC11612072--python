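"""Entropy-guided inpainting pretraining (self-learning).

Proxy task: square patches are removed from each slice and a residual network
is trained to predict the missing voxels from their surroundings (object
completion), under an RMSE loss evaluated over the holes only.  Patch
placement is guided by a local Shannon-entropy map of the image: centers are
sampled with probability proportional to entropy — more patches land on
informative regions — while patch size shrinks linearly with entropy from
25 mm (flat regions) down to 3 mm (most informative pixel), so enough context
always survives to make the holes predictable.

After pretraining, the sigmoid regression head is swapped for a fresh per-pixel
softmax head and the whole network fine-tunes on segmentation; trunk weights
carry over bit-exactly and nothing is frozen.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np
from scipy import ndimage

from .contrastive import TrainingFailureError
from .io_preprocess import InvalidInputError, SliceSample
from .nn import Adam, SegmentationNet, copy_weights, lr_schedule

__all__ = [
    "EntropyMap",
    "InpaintPatchSpec",
    "CorruptedSample",
    "local_entropy",
    "plan_inpainting_patches",
    "corrupt_image",
    "rmse_loss",
    "rmse_loss_grad",
    "build_backbone",
    "pretrain_inpainting",
    "adapt_head",
    "mean_fill_rmse",
    "monotone_smoothed",
    "plateau_reached",
]

logger = logging.getLogger(__name__)

SIZE_MIN_MM = 3.0
SIZE_MAX_MM = 25.0


@dataclasses.dataclass
class EntropyMap:
    values: np.ndarray  # bits, same shape as the source image
    window_px: int
    bins: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if (self.values < -1e-9).any() or (self.values > np.log2(self.bins) + 1e-9).any():
            raise InvalidInputError("entropy values must lie in [0, log2(bins)]")


@dataclasses.dataclass
class InpaintPatchSpec:
    center: tuple[int, int]
    size_mm: float

    def __post_init__(self) -> None:
        if not (SIZE_MIN_MM <= self.size_mm <= SIZE_MAX_MM):
            raise InvalidInputError(f"patch size {self.size_mm} mm outside [{SIZE_MIN_MM}, {SIZE_MAX_MM}]")


@dataclasses.dataclass
class CorruptedSample:
    corrupted: np.ndarray
    hole_mask: np.ndarray
    original: np.ndarray

    def __post_init__(self) -> None:
        self.hole_mask = np.asarray(self.hole_mask).astype(np.uint8)
        keep = self.hole_mask == 0
        if not np.array_equal(self.corrupted[keep], self.original[keep]):
            raise InvalidInputError("corrupted image differs from original outside holes")
        if self.hole_mask.any() and not np.all(self.corrupted[self.hole_mask == 1] == 0):
            raise InvalidInputError("hole voxels must be zeroed")


def local_entropy(image: np.ndarray, window_px: int = 9, bins: int = 32,
                  clip_max: float | None = None,
                  smooth_sigma: float = 1.5) -> EntropyMap:
    """Per-pixel Shannon entropy (bits) of the intensity histogram in a
    sliding window, with reflective border handling.

    Intensities are binned on ``[0, clip_max]`` (default: the image max, or 1
    for near-constant images); per-bin occupancy fractions come from a uniform
    filter over bin-indicator images, which is exact for a square window.
    ``smooth_sigma`` applies a light Gaussian prefilter so that pixel noise
    does not masquerade as information — upstream pipelines denoise before
    this kind of analysis, and without it the entropy of a noisy flat region
    rivals that of real structure.  Set to 0 to disable.
    """
    image = np.asarray(image, dtype=np.float64)
    if window_px % 2 == 0 or window_px < 1:
        raise InvalidInputError(f"window must be odd and positive, got {window_px}")
    if min(image.shape) < window_px:
        raise InvalidInputError(f"window {window_px} does not fit image {image.shape}")
    if smooth_sigma > 0:
        image = ndimage.gaussian_filter(image, smooth_sigma)
    if clip_max is None:
        clip_max = float(image.max()) if image.max() > 0 else 1.0
    idx = np.clip((image / clip_max * bins).astype(int), 0, bins - 1)
    ent = np.zeros(image.shape, dtype=np.float64)
    for b in range(bins):
        p = ndimage.uniform_filter((idx == b).astype(np.float64), size=window_px, mode="reflect")
        nz = p > 0
        ent[nz] -= p[nz] * np.log2(p[nz])
    # tiny negatives from float round-off
    np.clip(ent, 0.0, np.log2(bins), out=ent)
    return EntropyMap(ent, window_px, bins)


def patch_size_mm(entropy: float, h_max: float) -> float:
    """Linear entropy→size map: 25 mm at zero entropy, 3 mm at the image
    maximum, clamped to [3, 25]."""
    if h_max <= 0:
        return SIZE_MAX_MM
    size = SIZE_MAX_MM - (SIZE_MAX_MM - SIZE_MIN_MM) * (entropy / h_max)
    return float(np.clip(size, SIZE_MIN_MM, SIZE_MAX_MM))


def plan_inpainting_patches(emap: EntropyMap, coverage: float = 0.15,
                            rng: np.random.Generator | int | None = None,
                            floor_frac: float = 0.1,
                            max_patches: int = 10_000) -> list[InpaintPatchSpec]:
    """Sample removal patches until their union covers ``coverage`` of the
    image area.

    Centers are drawn with probability proportional to local entropy plus a
    floor of ``floor_frac``·H_max (uniform fallback on zero-entropy images):
    informative regions receive many patches, but flat regions still receive
    their share of large ones — without the floor a zero-entropy region would
    never be corrupted at all.  Overlaps are permitted; the planned footprint
    is the union.
    """
    if not (0.0 < coverage < 0.5):
        raise InvalidInputError(f"coverage must be in (0, 0.5), got {coverage}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    values = emap.values
    h, w = values.shape
    if values.max() <= 0:
        logger.info("zero-entropy image: sampling patch centers uniformly")
        prob = np.full(values.size, 1.0 / values.size)
    else:
        weighted = values + floor_frac * values.max()
        prob = (weighted / weighted.sum()).ravel()
    h_max = float(values.max())
    footprint = np.zeros((h, w), dtype=bool)
    target = coverage * h * w
    plan: list[InpaintPatchSpec] = []
    for _ in range(max_patches):
        flat = rng.choice(values.size, p=prob)
        r, c = divmod(int(flat), w)
        size = patch_size_mm(float(values[r, c]), h_max)
        plan.append(InpaintPatchSpec((r, c), size))
        half = int(round(size)) // 2
        n = int(round(size))
        r0, c0 = r - half, c - half
        footprint[max(r0, 0):min(r0 + n, h), max(c0, 0):min(c0 + n, w)] = True
        if footprint.sum() >= target:
            break
    return plan


def corrupt_image(sample: SliceSample | np.ndarray, plan: list[InpaintPatchSpec]) -> CorruptedSample:
    """Zero out the planned square patches; the hole mask records exactly the
    removed voxels (overlaps are a plain union)."""
    if not plan:
        raise InvalidInputError("empty inpainting plan")
    image = sample.image if isinstance(sample, SliceSample) else np.asarray(sample, dtype=np.float64)
    h, w = image.shape
    hole = np.zeros((h, w), dtype=np.uint8)
    for spec in plan:
        n = int(round(spec.size_mm))  # 1 mm voxels
        half = n // 2
        r0, c0 = spec.center[0] - half, spec.center[1] - half
        hole[max(r0, 0):min(r0 + n, h), max(c0, 0):min(c0 + n, w)] = 1
    corrupted = image.copy()
    corrupted[hole == 1] = 0.0
    return CorruptedSample(corrupted, hole, image.copy())


def rmse_loss(predicted: np.ndarray, original: np.ndarray, hole_mask: np.ndarray) -> float:
    """Root mean square error over hole voxels only."""
    return _rmse(predicted, original, hole_mask, with_grad=False)[0]


def rmse_loss_grad(predicted, original, hole_mask):
    """RMSE over holes plus its gradient with respect to the prediction."""
    return _rmse(predicted, original, hole_mask, with_grad=True)


def _rmse(predicted, original, hole_mask, with_grad):
    predicted = np.asarray(predicted, dtype=np.float64)
    original = np.asarray(original, dtype=np.float64)
    hole = np.asarray(hole_mask).astype(bool)
    if predicted.shape != original.shape or predicted.shape != hole.shape:
        raise InvalidInputError("predicted/original/hole_mask shapes must match")
    n = int(hole.sum())
    if n == 0:
        raise InvalidInputError("hole mask is empty")
    diff = (predicted - original) * hole
    mse = float((diff**2).sum() / n)
    rmse = math.sqrt(mse)
    if not with_grad:
        return rmse, None
    grad = diff / (n * max(rmse, 1e-12))
    return rmse, grad


def monotone_smoothed(history: list[float], window: int = 10) -> np.ndarray:
    """Monotone-smoothed loss curve: running minimum of the moving average."""
    h = np.asarray(history, dtype=np.float64)
    if h.size == 0:
        return h
    kernel = np.ones(min(window, h.size)) / min(window, h.size)
    avg = np.convolve(h, kernel, mode="valid")
    return np.minimum.accumulate(avg)


def plateau_reached(history: list[float], patience: int, window: int = 10,
                    min_delta: float = 1e-4) -> bool:
    """True when the smoothed loss has not improved by ``min_delta`` for
    ``patience`` consecutive steps."""
    curve = monotone_smoothed(history, window)
    if curve.size <= patience:
        return False
    return curve[-1] > curve[-1 - patience] - min_delta


def build_backbone(layers: int = 20, in_ch: int = 1, out_ch: int | None = None,
                   head: str = "sigmoid", width: int = 16,
                   rng: np.random.Generator | int | None = None) -> SegmentationNet:
    """The residual backbone (default twenty convolutional layers) with the
    selected output head; the trunk is identical regardless of head choice."""
    if layers < 2:
        raise InvalidInputError(f"need at least 2 layers, got {layers}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if out_ch is None:
        out_ch = 1 if head == "sigmoid" else 2
    return SegmentationNet(layers=layers, width=width, in_ch=in_ch,
                           out_ch=out_ch, head=head, rng=rng)


def mean_fill_rmse(samples: list[SliceSample], coverage: float = 0.15,
                   window_px: int = 9, bins: int = 32,
                   rng: np.random.Generator | int | None = None) -> float:
    """Baseline: RMSE of filling holes with the corrupted image's mean
    intensity (computed outside the holes)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    errs = []
    for s in samples:
        emap = local_entropy(s.image, window_px, bins)
        plan = plan_inpainting_patches(emap, coverage, rng)
        cor = corrupt_image(s, plan)
        fill = float(cor.original[cor.hole_mask == 0].mean())
        pred = np.where(cor.hole_mask == 1, fill, cor.original)
        errs.append(rmse_loss(pred, cor.original, cor.hole_mask))
    return float(np.mean(errs))


def pretrain_inpainting(model: SegmentationNet, samples: list[SliceSample],
                        steps: int | None = None, epochs: int = 15, batch: int = 40,
                        lr_start: float = 0.005, lr_end: float = 0.0005,
                        coverage: float = 0.15, window_px: int = 9, bins: int = 32,
                        crop_px: int | None = None, patience: int | None = None,
                        rng: np.random.Generator | int | None = None):
    """Train the sigmoid-headed backbone on entropy-guided object completion.

    Defaults follow the proxy schedule: batch 40, learning rate decayed from
    0.005 to 0.0005, plateau around 15 epochs.  Entropy maps are computed once
    per slice and cached.  ``patience`` enables early stopping once the
    smoothed loss plateaus.  Returns ``(model, history)`` with per-step RMSE.
    """
    if model.head_kind != "sigmoid":
        raise InvalidInputError("inpainting pretraining requires the sigmoid regression head")
    if not samples:
        raise InvalidInputError("no training samples")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if steps is None:
        steps = max(1, epochs * math.ceil(len(samples) / batch))
    emaps = [local_entropy(s.image, window_px, bins) for s in samples]
    opt = Adam(model.params(), lr=lr_start)
    lrs = lr_schedule(lr_start, lr_end, steps)
    history: list[float] = []
    for t in range(steps):
        idx = rng.integers(len(samples), size=batch)
        corrupted = []
        for i in idx:
            image, emap = samples[i].image, emaps[i]
            if crop_px is not None and min(image.shape) > crop_px:
                r0 = int(rng.integers(0, image.shape[0] - crop_px + 1))
                c0 = int(rng.integers(0, image.shape[1] - crop_px + 1))
                image = image[r0:r0 + crop_px, c0:c0 + crop_px]
                emap = EntropyMap(emap.values[r0:r0 + crop_px, c0:c0 + crop_px],
                                  emap.window_px, emap.bins)
            plan = plan_inpainting_patches(emap, coverage, rng)
            corrupted.append(corrupt_image(image, plan))
        x = np.stack([c.corrupted for c in corrupted])[:, None]
        pred, cache = model.forward(x)
        step_loss = 0.0
        grads = np.zeros_like(pred)
        for j, c in enumerate(corrupted):
            loss_j, g_j = rmse_loss_grad(pred[j, 0], c.original, c.hole_mask)
            step_loss += loss_j
            grads[j, 0] = g_j
        step_loss /= len(corrupted)
        if not np.isfinite(step_loss):
            raise TrainingFailureError(f"inpainting loss diverged at step {t}")
        opt.zero_grad()
        model.backward(grads / len(corrupted), cache)
        opt.step(lr=lrs[t])
        history.append(step_loss)
        if patience is not None and plateau_reached(history, patience):
            break
    return model, history


def adapt_head(model: SegmentationNet, out_ch: int = 2,
               rng: np.random.Generator | int | None = None) -> SegmentationNet:
    """Swap the sigmoid regression head for a fresh per-pixel softmax head.

    The trunk (encoder + decoder) weights are retained bit-exactly and remain
    trainable; only the 1×1 head convolution is newly initialized.
    """
    if model.head_kind == "softmax":
        logger.warning("model already has a softmax head; adapt_head is a no-op")
        return model
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    new = SegmentationNet(layers=model.layers_spec, width=model.width,
                          in_ch=model.in_ch, out_ch=out_ch, head="softmax", rng=rng)
    copy_weights(model.trunk_params(), new.trunk_params())
    return new
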