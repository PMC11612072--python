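"""Volume I/O, resampling, intensity normalization and 2D slice extraction.

Volumes are held as plain numpy arrays indexed ``(i, j, k)`` with a per-axis
voxel size in mm.  All downstream training operates on 2D slices taken along a
chosen axis (default: the last, through-plane, axis), so every loader here ends
in :func:`extract_slices`.

Normalization is modality-specific: CT volumes are min–max rescaled to
``[0, 1]``; MR volumes are divided by the intensity at a chosen point of the
cumulative histogram of their nonzero voxels (default the 90% point) and
clipped, which makes intensities comparable across scanners without assuming a
calibrated unit like HU.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Literal

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Volume",
    "SliceSample",
    "load_volume",
    "save_volume",
    "resample_isotropic",
    "normalize_ct",
    "normalize_mr",
    "extract_slices",
    "read_manifest",
    "write_manifest",
]

Modality = Literal["CT", "MR"]


class InvalidInputError(ValueError):
    """Raised when an operation's preconditions are violated."""


class DegenerateNormalizationError(InvalidInputError):
    """Raised when a normalization reference level is zero."""


@dataclasses.dataclass
class Volume:
    """A 3D scalar grid with voxel spacing, modality tag and subject identity.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Scalar intensities in arbitrary units.
    spacing : tuple of float
        Per-axis voxel size in mm; strictly positive.
    modality : {"CT", "MR"}
    subject_id : str
        Opaque identifier; propagated to every slice cut from this volume.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    modality: Modality = "CT"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise InvalidInputError(f"expected a 3D grid, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise InvalidInputError(f"spacing must be 3 strictly positive values, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise InvalidInputError("volume contains non-finite voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]


@dataclasses.dataclass
class SliceSample:
    """One 2D image/mask pair: the unit of training.

    ``image`` holds normalized intensities, ``mask`` a binary grid of the same
    shape.  ``subject_id`` keeps patient identity so splits can be made
    patient-wise, never slice-wise.
    """

    image: np.ndarray
    mask: np.ndarray
    subject_id: str
    slice_index: int
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        self.mask = np.asarray(self.mask)
        if self.image.shape != self.mask.shape:
            raise InvalidInputError(
                f"image/mask shape mismatch: {self.image.shape} vs {self.mask.shape}"
            )
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise InvalidInputError("mask must be binary (values in {0, 1})")
        self.mask = self.mask.astype(np.uint8)


def load_volume(path: str | Path, modality: Modality = "CT", subject_id: str = "") -> Volume:
    """Read a NIfTI volume; spacing is taken from the header zooms."""
    img = nib.load(str(path))
    voxels = np.asarray(img.get_fdata(), dtype=np.float64)
    if voxels.ndim == 4 and voxels.shape[3] == 1:
        voxels = voxels[..., 0]
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    vol = Volume(voxels=voxels, spacing=spacing, modality=modality, subject_id=subject_id)
    return vol


def save_volume(volume: Volume, path: str | Path, as_mask: bool = False) -> None:
    """Write a volume to NIfTI; masks are stored as unsigned 8-bit labels."""
    data = volume.voxels
    if as_mask:
        data = data.astype(np.uint8)
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def resample_isotropic(volume: Volume, target_mm: float = 1.0, is_mask: bool = False) -> Volume:
    """Resample a volume to an isotropic grid of ``target_mm`` voxels.

    Images use linear interpolation, masks nearest-neighbor (binarity is
    preserved exactly).  The physical extent is preserved to within one voxel
    per axis; the output grid size is ``round(n * spacing / target_mm)``.
    """
    if target_mm <= 0:
        raise InvalidInputError(f"target_mm must be positive, got {target_mm}")
    factors = tuple(s / target_mm for s in volume.spacing)
    if all(abs(f - 1.0) < 1e-12 for f in factors):
        return Volume(volume.voxels.copy(), (target_mm,) * 3, volume.modality, volume.subject_id)
    order = 0 if is_mask else 1
    out = ndimage.zoom(volume.voxels, factors, order=order, mode="nearest", grid_mode=True)
    if is_mask:
        out = (out > 0.5).astype(np.uint8)
    return Volume(out, (target_mm,) * 3, volume.modality, volume.subject_id)


def normalize_ct(volume: Volume) -> Volume:
    """Min–max rescale a CT volume to [0, 1].

    A constant volume maps to all-zeros (degenerate rule: there is no contrast
    to preserve).
    """
    if volume.modality != "CT":
        raise InvalidInputError(f"normalize_ct requires modality CT, got {volume.modality}")
    v = volume.voxels
    if v.size == 0:
        raise InvalidInputError("empty volume")
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        out = np.zeros_like(v, dtype=np.float64)
    else:
        out = (v - lo) / (hi - lo)
    return Volume(out, volume.spacing, volume.modality, volume.subject_id)


def normalize_mr(volume: Volume, pct: float = 0.90, clip_max: float = 2.0) -> Volume:
    """Normalize an MR volume by the intensity at ``pct`` of the cumulative
    histogram of its nonzero voxels, then clip to ``[0, clip_max]``.

    Only nonzero voxels enter the histogram: background air dominates the raw
    histogram and would drag the reference level toward zero.
    """
    if volume.modality != "MR":
        raise InvalidInputError(f"normalize_mr requires modality MR, got {volume.modality}")
    if not (0.0 < pct < 1.0):
        raise InvalidInputError(f"pct must be in (0, 1), got {pct}")
    v = volume.voxels
    nz = v[v != 0]
    if nz.size == 0:
        raise DegenerateNormalizationError("volume has no nonzero voxels")
    ref = float(np.quantile(nz, pct))
    if ref == 0:
        raise DegenerateNormalizationError("reference intensity level is zero")
    out = np.clip(v / ref, 0.0, clip_max)
    return Volume(out, volume.spacing, volume.modality, volume.subject_id)


def extract_slices(
    volume: Volume,
    mask_volume: Volume,
    axis: int = 2,
    keep: Literal["all", "mask_only"] = "mask_only",
) -> list[SliceSample]:
    """Cut a volume and its mask into per-slice training samples.

    ``keep="mask_only"`` retains only slices with at least one foreground
    voxel, which is how segmentation training sets are usually assembled.
    """
    if volume.voxels.shape != mask_volume.voxels.shape:
        raise InvalidInputError(
            f"volume/mask shape mismatch: {volume.voxels.shape} vs {mask_volume.voxels.shape}"
        )
    if volume.spacing != mask_volume.spacing:
        raise InvalidInputError("volume and mask spacing differ")
    if axis not in (0, 1, 2):
        raise InvalidInputError(f"axis must be 0, 1 or 2, got {axis}")
    in_plane = tuple(s for a, s in enumerate(volume.spacing) if a != axis)
    samples: list[SliceSample] = []
    for idx in range(volume.voxels.shape[axis]):
        img = np.take(volume.voxels, idx, axis=axis)
        msk = (np.take(mask_volume.voxels, idx, axis=axis) > 0.5).astype(np.uint8)
        if keep == "mask_only" and not msk.any():
            continue
        samples.append(
            SliceSample(
                image=img,
                mask=msk,
                subject_id=volume.subject_id,
                slice_index=idx,
                spacing=in_plane,  # type: ignore[arg-type]
            )
        )
    return samples


# ---------------------------------------------------------------------------
# Cohort manifests


def write_manifest(rows: Iterable[dict], path: str | Path) -> pd.DataFrame:
    """Write a cohort manifest (subject_id, image_path, mask_path, modality, ...)."""
    df = pd.DataFrame(list(rows))
    required = {"subject_id", "image_path", "mask_path", "modality"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"manifest missing columns: {sorted(missing)}")
    df.to_csv(path, sep="\t", index=False)
    return df


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str})
    required = {"subject_id", "image_path", "mask_path", "modality"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"manifest missing columns: {sorted(missing)}")
    return df


def load_cohort_slices(
    manifest: pd.DataFrame | str | Path,
    axis: int = 2,
    keep: Literal["all", "mask_only"] = "mask_only",
    normalize: bool = False,
) -> list[SliceSample]:
    """Load every subject in a manifest and return the pooled slice samples."""
    if not isinstance(manifest, pd.DataFrame):
        manifest = read_manifest(manifest)
    samples: list[SliceSample] = []
    for row in manifest.itertuples():
        vol = load_volume(row.image_path, modality=row.modality, subject_id=row.subject_id)
        msk = load_volume(row.mask_path, modality=row.modality, subject_id=row.subject_id)
        if normalize:
            vol = normalize_ct(vol) if row.modality == "CT" else normalize_mr(vol)
        samples.extend(extract_slices(vol, msk, axis=axis, keep=keep))
    return samples
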