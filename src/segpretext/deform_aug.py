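"""Registration-based deformable data augmentation.

New training subjects are synthesized by nonrigidly registering one subject's
image onto the coordinates of another (B-spline free-form deformation under a
mutual-information similarity metric, multi-resolution) and pushing the
source's segmentation mask through the identical deformation.  With ``n``
subjects and the ``all`` pair policy this yields ``n(n−1)`` synthetic
subjects; registration targets may also come from a separate cohort.  A
conventional augmentation baseline (rotation, scaling, flipping, shear) is
provided for comparison.

The registration engine is a replaceable component behind the
:func:`register_deformable` contract; the default engine is SimpleITK's
registration framework with full-grid metric sampling, which makes fields
deterministic for fixed inputs and configuration.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .io_preprocess import InvalidInputError, SliceSample

__all__ = [
    "DeformationField",
    "SyntheticSubject",
    "RegistrationConfig",
    "ConventionalAugConfig",
    "register_deformable",
    "warp",
    "augment_dataset",
    "conventional_augment",
    "RegistrationFailureError",
]


class RegistrationFailureError(RuntimeError):
    pass


@dataclasses.dataclass
class DeformationField:
    """Dense per-pixel displacement in mm on the fixed image's grid.

    ``displacement[r, c]`` is ``(d_row, d_col)``: the warped image at pixel
    ``(r, c)`` samples the moving image at physical position
    ``(r, c)·spacing + displacement[r, c]``.
    """

    displacement: np.ndarray  # (H, W, 2), mm
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=np.float64)
        if self.displacement.ndim != 3 or self.displacement.shape[2] != 2:
            raise InvalidInputError(f"displacement must be (H, W, 2), got {self.displacement.shape}")
        if not np.all(np.isfinite(self.displacement)):
            raise InvalidInputError("displacement field contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.displacement.shape[:2]

    def mean_magnitude_mm(self) -> float:
        return float(np.sqrt((self.displacement**2).sum(axis=2)).mean())


@dataclasses.dataclass
class SyntheticSubject:
    """A warped subject with provenance: all slices share one field."""

    samples: list[SliceSample]
    source_id: str
    target_id: str
    field: DeformationField

    def __post_init__(self) -> None:
        if self.source_id == self.target_id:
            raise InvalidInputError("synthetic subject must come from two distinct subjects")

    @property
    def subject_id(self) -> str:
        return f"syn:{self.source_id}->{self.target_id}"


@dataclasses.dataclass
class RegistrationConfig:
    grid_spacing_mm: float = 16.0
    levels: int = 2
    iterations: int = 40
    histogram_bins: int = 32
    learning_rate: float = 2.0
    max_step_mm: float = 0.5  # caps per-iteration motion; keeps near-identity stable


def _to_sitk(arr: np.ndarray, spacing: tuple[float, float]) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr, dtype=np.float64))
    img.SetSpacing((spacing[1], spacing[0]))  # sitk order is (x, y) = (col, row)
    return img


def register_deformable(moving: np.ndarray, fixed: np.ndarray,
                        spacing: tuple[float, float] = (1.0, 1.0),
                        config: RegistrationConfig | None = None) -> DeformationField:
    """Estimate the dense displacement aligning ``moving`` to ``fixed``.

    B-spline free-form deformation (control-point spacing
    ``config.grid_spacing_mm``) optimized by gradient descent with
    physical-shift parameter scaling under Mattes mutual information,
    multi-resolution with ``config.levels`` levels and full-grid metric
    sampling (deterministic); the resulting transform is sampled to a dense
    field on the fixed grid.
    """
    config = config or RegistrationConfig()
    moving = np.asarray(moving, dtype=np.float64)
    fixed = np.asarray(fixed, dtype=np.float64)
    if moving.shape != fixed.shape:
        raise InvalidInputError(f"grid mismatch: moving {moving.shape} vs fixed {fixed.shape}")
    if moving.ndim != 2:
        raise InvalidInputError("register_deformable operates on 2D slices")
    f_img = _to_sitk(fixed, spacing)
    m_img = _to_sitk(moving, spacing)

    extent = [sz * sp for sz, sp in zip(f_img.GetSize(), f_img.GetSpacing())]
    mesh = [max(1, int(round(e / config.grid_spacing_mm))) for e in extent]
    tx = sitk.BSplineTransformInitializer(f_img, mesh)

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=config.histogram_bins)
    reg.SetMetricSamplingStrategy(reg.NONE)  # full sampling: deterministic
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsGradientDescent(learningRate=config.learning_rate,
                                      numberOfIterations=config.iterations,
                                      convergenceMinimumValue=1e-7,
                                      convergenceWindowSize=10,
                                      maximumStepSizeInPhysicalUnits=config.max_step_mm)
    reg.SetOptimizerScalesFromPhysicalShift()
    shrink = [2**l for l in range(config.levels - 1, -1, -1)]
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel([float(s // 2) for s in shrink])
    reg.SetInitialTransform(tx, inPlace=True)
    try:
        reg.Execute(f_img, m_img)
        metric = reg.GetMetricValue()
    except RuntimeError as exc:  # ITK signals optimizer failure this way
        raise RegistrationFailureError(str(exc)) from exc
    if not math.isfinite(metric):
        raise RegistrationFailureError(f"non-finite similarity metric: {metric}")

    disp_img = sitk.TransformToDisplacementField(
        tx, sitk.sitkVectorFloat64, f_img.GetSize(), f_img.GetOrigin(),
        f_img.GetSpacing(), f_img.GetDirection())
    disp = sitk.GetArrayFromImage(disp_img)  # (H, W, 2) with (dx, dy) components
    field = np.stack([disp[..., 1], disp[..., 0]], axis=-1)  # -> (d_row, d_col)
    return DeformationField(field, spacing)


def warp(grid: np.ndarray, field: DeformationField, interpolation: str | None = None,
         is_mask: bool = False) -> np.ndarray:
    """Apply a deformation field to an image or mask.

    Images default to linear interpolation; masks to nearest-neighbor and are
    re-binarized (``interpolation="linear"`` on a mask thresholds at 0.5).
    """
    grid = np.asarray(grid, dtype=np.float64)
    if grid.shape != field.grid_shape:
        raise InvalidInputError(f"grid {grid.shape} does not match field {field.grid_shape}")
    if is_mask and not np.isin(np.unique(grid), (0, 1)).all():
        raise InvalidInputError("input labeled as mask is not binary")
    if interpolation is None:
        interpolation = "nearest" if is_mask else "linear"
    if interpolation not in ("linear", "nearest"):
        raise InvalidInputError(f"interpolation must be 'linear' or 'nearest', got {interpolation!r}")
    rows, cols = np.meshgrid(np.arange(grid.shape[0]), np.arange(grid.shape[1]), indexing="ij")
    coords = np.stack([
        rows + field.displacement[..., 0] / field.spacing[0],
        cols + field.displacement[..., 1] / field.spacing[1],
    ])
    order = 0 if interpolation == "nearest" else 1
    out = ndimage.map_coordinates(grid, coords, order=order, mode="nearest")
    if is_mask:
        out = (out > 0.5).astype(np.uint8)
    return out


def _middle_slice(samples: list[SliceSample]) -> SliceSample:
    return samples[len(samples) // 2]


def warp_subject(samples: list[SliceSample], field: DeformationField,
                 source_id: str, target_id: str) -> SyntheticSubject:
    """Warp every slice of a subject (image linearly, mask nearest) with one
    shared field."""
    out = []
    syn_id = f"syn:{source_id}->{target_id}"
    for s in samples:
        img = warp(s.image, field, "linear")
        msk = warp(s.mask.astype(np.float64), field, is_mask=True)
        out.append(SliceSample(img, msk, syn_id, s.slice_index, s.spacing))
    return SyntheticSubject(out, source_id, target_id, field)


def augment_dataset(cohort: dict[str, list[SliceSample]],
                    policy: str = "all", k: int = 3,
                    rng: np.random.Generator | int | None = None,
                    config: RegistrationConfig | None = None,
                    targets: dict[str, list[SliceSample]] | None = None
                    ) -> list[SyntheticSubject]:
    """Expand a cohort by registering each subject onto others' coordinates.

    ``policy="all"`` produces one synthetic subject per ordered (source,
    target) pair — ``n(n−1)`` of them; ``policy="k_random"`` draws ``k``
    distinct targets per source.  ``targets`` may name a separate
    registration-target cohort (targets need not be training subjects).
    """
    if len(cohort) < 2 and targets is None:
        raise InvalidInputError("need at least 2 subjects to augment")
    if policy not in ("all", "k_random"):
        raise InvalidInputError(f"policy must be 'all' or 'k_random', got {policy!r}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    target_pool = targets if targets is not None else cohort
    sources = sorted(cohort)
    all_targets = sorted(target_pool)
    out: list[SyntheticSubject] = []
    for src in sources:
        candidates = [t for t in all_targets if t != src]
        if not candidates:
            raise InvalidInputError(f"no registration targets available for {src}")
        if policy == "all":
            chosen = candidates
        else:
            kk = min(k, len(candidates))
            chosen = [candidates[i] for i in rng.choice(len(candidates), size=kk, replace=False)]
        src_mid = _middle_slice(cohort[src])
        for tgt in chosen:
            tgt_mid = _middle_slice(target_pool[tgt])
            field = register_deformable(src_mid.image, tgt_mid.image,
                                        spacing=src_mid.spacing, config=config)
            out.append(warp_subject(cohort[src], field, src, tgt))
    return out


@dataclasses.dataclass
class ConventionalAugConfig:
    rotate_deg: float = 15.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    flip_p: float = 0.5
    shear_deg: float = 5.0


def conventional_augment(sample: SliceSample, rng: np.random.Generator | int | None = None,
                         config: ConventionalAugConfig | None = None) -> SliceSample:
    """Classic augmentation: random rotation, isotropic scale, horizontal flip
    and a small shear, applied identically to image and mask."""
    config = config or ConventionalAugConfig()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    angle = math.radians(rng.uniform(-config.rotate_deg, config.rotate_deg))
    scale = rng.uniform(*config.scale_range)
    shear = math.radians(rng.uniform(-config.shear_deg, config.shear_deg))
    do_flip = rng.random() < config.flip_p

    image = sample.image[:, ::-1] if do_flip else sample.image
    mask = sample.mask[:, ::-1] if do_flip else sample.mask

    rot = np.array([[math.cos(angle), -math.sin(angle)],
                    [math.sin(angle), math.cos(angle)]])
    sh = np.array([[1.0, math.tan(shear)], [0.0, 1.0]])
    fwd = scale * rot @ sh  # content transform about the image center
    inv = np.linalg.inv(fwd)
    center = (np.asarray(image.shape) - 1) / 2.0
    offset = center - inv @ center
    img_out = ndimage.affine_transform(image, inv, offset=offset, order=1, mode="nearest")
    msk_out = ndimage.affine_transform(mask.astype(np.float64), inv, offset=offset,
                                       order=0, mode="constant", cval=0.0)
    return SliceSample(img_out, (msk_out > 0.5).astype(np.uint8),
                       sample.subject_id, sample.slice_index, sample.spacing)
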