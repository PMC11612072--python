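"""Contrastive patch-pair pretraining.

Proxy task: decide whether two 3×3 cm image patches come from the same
subject.  Patches are drawn from within the reference mask and from a band
just outside it, so the encoder sees both the organ and its periphery.  A
siamese pair of weight-shared encoder branches embeds each patch; the
contrastive loss pulls same-subject embeddings together and (in the default
``corrected`` mode) pushes different-subject embeddings apart up to a margin.
The ``as_printed`` mode reproduces the label-independent sum of squared
distances exactly as the printed loss reads, kept to document its degeneracy.

After pretraining the encoder branch is transplanted into a segmentation
network whose decoder starts from fresh random weights; nothing is frozen by
default so the whole model fine-tunes on the target task.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import ndimage

from .io_preprocess import InvalidInputError, SliceSample
from .nn import Adam, ContrastiveEncoder, SegmentationNet, copy_weights, lr_schedule

__all__ = [
    "RoiPatch",
    "PatchPair",
    "EmbeddingPair",
    "sample_roi_patch",
    "build_pair_batch",
    "contrastive_loss",
    "contrastive_loss_grad",
    "pretrain_contrastive",
    "transfer_encoder",
    "CannotFormNegativePairsError",
    "TrainingFailureError",
]

PATCH_PX = 30  # 3 cm at 1 mm voxels


class CannotFormNegativePairsError(ValueError):
    pass


class TrainingFailureError(RuntimeError):
    pass


@dataclasses.dataclass
class RoiPatch:
    pixels: np.ndarray  # (30, 30)
    subject_id: str
    center: tuple[int, int]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.shape != (PATCH_PX, PATCH_PX):
            raise InvalidInputError(f"patch must be {PATCH_PX}x{PATCH_PX}, got {self.pixels.shape}")


@dataclasses.dataclass
class PatchPair:
    a: RoiPatch
    b: RoiPatch
    label: int

    def __post_init__(self) -> None:
        expected = int(self.a.subject_id == self.b.subject_id)
        if self.label != expected:
            raise InvalidInputError("pair label inconsistent with subject identities")


@dataclasses.dataclass
class EmbeddingPair:
    p1: np.ndarray
    p2: np.ndarray

    def __post_init__(self) -> None:
        self.p1 = np.asarray(self.p1, dtype=np.float64).ravel()
        self.p2 = np.asarray(self.p2, dtype=np.float64).ravel()
        if self.p1.shape != self.p2.shape:
            raise InvalidInputError(f"embedding dimension mismatch: {self.p1.shape} vs {self.p2.shape}")

    @property
    def dimension(self) -> int:
        return self.p1.size


def _crop_padded(image: np.ndarray, center: tuple[int, int], size: int = PATCH_PX) -> np.ndarray:
    """Crop a size×size window centered at ``center``, zero-padding beyond borders."""
    h, w = image.shape
    half = size // 2
    r0, c0 = center[0] - half, center[1] - half
    out = np.zeros((size, size), dtype=np.float64)
    rs, re = max(r0, 0), min(r0 + size, h)
    cs, ce = max(c0, 0), min(c0 + size, w)
    if rs < re and cs < ce:
        out[rs - r0:re - r0, cs - c0:ce - c0] = image[rs:re, cs:ce]
    return out


def sample_roi_patch(sample: SliceSample, rng: np.random.Generator,
                     band_mm: float = 10.0) -> RoiPatch:
    """Draw one 30×30 patch centered inside the mask (p=0.5) or in a band of
    width ``band_mm`` just outside it (p=0.5)."""
    mask = sample.mask.astype(bool)
    if not mask.any():
        raise InvalidInputError("cannot sample a patch from an empty mask")
    take_interior = rng.random() < 0.5
    if not take_interior:
        dist = ndimage.distance_transform_edt(~mask, sampling=sample.spacing)
        band = (~mask) & (dist <= band_mm)
        if band.any():
            candidates = np.argwhere(band)
        else:  # mask fills the image; fall back to interior
            candidates = np.argwhere(mask)
    else:
        candidates = np.argwhere(mask)
    r, c = candidates[rng.integers(len(candidates))]
    return RoiPatch(_crop_padded(sample.image, (int(r), int(c))), sample.subject_id, (int(r), int(c)))


def build_pair_batch(cohort: list[SliceSample] | dict[str, list[SliceSample]],
                     batch: int, rng: np.random.Generator,
                     band_mm: float = 10.0) -> list[PatchPair]:
    """A batch of patch pairs, half labeled 1 (same subject) and half 0."""
    if isinstance(cohort, dict):
        by_subject = {k: v for k, v in cohort.items() if v}
    else:
        by_subject = {}
        for s in cohort:
            by_subject.setdefault(s.subject_id, []).append(s)
    subjects = sorted(by_subject)
    if len(subjects) < 2:
        raise CannotFormNegativePairsError("need >= 2 distinct subjects for negative pairs")
    n_pos = batch // 2
    pairs: list[PatchPair] = []
    for i in range(batch):
        if i < n_pos:
            sid = subjects[rng.integers(len(subjects))]
            slices = by_subject[sid]
            sa = slices[rng.integers(len(slices))]
            sb = slices[rng.integers(len(slices))]
            label = 1
        else:
            ia, ib = rng.choice(len(subjects), size=2, replace=False)
            sa = by_subject[subjects[ia]][rng.integers(len(by_subject[subjects[ia]]))]
            sb = by_subject[subjects[ib]][rng.integers(len(by_subject[subjects[ib]]))]
            label = 0
        pairs.append(PatchPair(sample_roi_patch(sa, rng, band_mm),
                               sample_roi_patch(sb, rng, band_mm), label))
    return pairs


def _pair_arrays(p1, p2, labels):
    if isinstance(p1, (list, tuple)) and len(p1) and isinstance(p1[0], EmbeddingPair):
        # called as (pairs, labels): unpack the embedding pairs
        pairs, labels = p1, p2
        p1 = np.stack([p.p1 for p in pairs])
        p2 = np.stack([p.p2 for p in pairs])
    p1 = np.asarray(p1, dtype=np.float64)
    p2 = np.asarray(p2, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64).ravel()
    if p1.shape != p2.shape:
        raise InvalidInputError(f"embedding shape mismatch: {p1.shape} vs {p2.shape}")
    if p1.ndim == 1:
        p1, p2 = p1[None], p2[None]
    if len(labels) != len(p1):
        raise InvalidInputError("one label per pair required")
    if not np.all(np.isfinite(p1)) or not np.all(np.isfinite(p2)):
        raise InvalidInputError("embeddings must be finite")
    return p1, p2, labels


def contrastive_loss(p1, p2, labels=None, margin: float = 1.0, mode: str = "corrected") -> float:
    """Contrastive loss over embedding pairs.

    ``corrected`` (default): Σ [L·Dis² + (1−L)·max(0, margin−Dis)²] with
    Dis = ‖p1−p2‖.  ``as_printed``: Σ [L·Dis² + (1−L)·Dis²], i.e. Σ Dis²
    regardless of labels.

    Accepts either two embedding stacks plus labels, or
    ``contrastive_loss(pairs, labels)`` with a list of :class:`EmbeddingPair`.
    """
    return _contrastive(p1, p2, labels, margin, mode, with_grad=False)[0]


def contrastive_loss_grad(p1, p2, labels=None, margin: float = 1.0, mode: str = "corrected"):
    """Loss plus gradients with respect to both embedding stacks."""
    return _contrastive(p1, p2, labels, margin, mode, with_grad=True)


def _contrastive(p1, p2, labels, margin, mode, with_grad):
    if margin <= 0:
        raise InvalidInputError(f"margin must be positive, got {margin}")
    if mode not in ("corrected", "as_printed"):
        raise InvalidInputError(f"mode must be 'corrected' or 'as_printed', got {mode!r}")
    p1, p2, labels = _pair_arrays(p1, p2, labels)
    diff = p1 - p2
    dis = np.sqrt((diff**2).sum(axis=1))
    if mode == "as_printed":
        loss = float((dis**2).sum())
        if not with_grad:
            return loss, None, None
        g1 = 2.0 * diff
        return loss, g1, -g1
    hinge = np.maximum(0.0, margin - dis)
    loss = float((labels * dis**2 + (1.0 - labels) * hinge**2).sum())
    if not with_grad:
        return loss, None, None
    safe = np.where(dis > 0, dis, 1.0)
    unit = diff / safe[:, None]
    g1 = 2.0 * labels[:, None] * diff - 2.0 * ((1.0 - labels) * hinge)[:, None] * unit
    return loss, g1, -g1


def pretrain_contrastive(encoder: ContrastiveEncoder,
                         cohort: dict[str, list[SliceSample]] | list[SliceSample],
                         steps: int | None = None, epochs: int = 5, batch: int = 50,
                         lr_start: float = 0.01, lr_end: float = 0.0005,
                         margin: float = 1.0, mode: str = "corrected",
                         band_mm: float = 10.0,
                         rng: np.random.Generator | int | None = None):
    """Train the siamese encoder on the patch-pair proxy task.

    Defaults follow the proxy schedule: batch 50, learning rate decayed from
    0.01 to 0.0005, about 5 epochs to plateau.  Returns ``(encoder, history)``
    where ``history`` is the per-step loss (per pair, so comparable across
    batch sizes).
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if isinstance(cohort, dict):
        n_samples = sum(len(v) for v in cohort.values())
    else:
        n_samples = len(cohort)
    if steps is None:
        steps = max(1, epochs * math.ceil(n_samples / batch))
    opt = Adam(encoder.params(), lr=lr_start)
    lrs = lr_schedule(lr_start, lr_end, steps)
    history: list[float] = []
    for t in range(steps):
        pairs = build_pair_batch(cohort, batch, rng, band_mm)
        a = np.stack([p.a.pixels for p in pairs])[:, None]
        b = np.stack([p.b.pixels for p in pairs])[:, None]
        labels = np.array([p.label for p in pairs], dtype=np.float64)
        za, ca = encoder.forward(a)
        zb, cb = encoder.forward(b)
        loss, g1, g2 = contrastive_loss_grad(za, zb, labels, margin, mode)
        if not np.isfinite(loss):
            raise TrainingFailureError(f"contrastive loss diverged at step {t}")
        opt.zero_grad()
        encoder.backward((g1 / len(pairs)).astype(np.float32), ca)
        encoder.backward((g2 / len(pairs)).astype(np.float32), cb)
        opt.step(lr=lrs[t])
        history.append(loss / len(pairs))
    return encoder, history


def transfer_encoder(encoder: ContrastiveEncoder, out_ch: int = 2,
                     head: str = "softmax", freeze: bool = False,
                     rng: np.random.Generator | int | None = None) -> SegmentationNet:
    """Insert the pretrained encoder into a segmentation model.

    Encoder weights are copied; the decoder and head start from fresh random
    weights.  With ``freeze=False`` (the default) every parameter stays
    trainable during fine-tuning.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    model = SegmentationNet(layers=encoder.layers_spec, width=encoder.width,
                            in_ch=encoder.in_ch, out_ch=out_ch, head=head, rng=rng)
    copy_weights(encoder.encoder.params(), model.encoder.params())
    if freeze:
        for p in model.encoder.params():
            p.trainable = False
    return model
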