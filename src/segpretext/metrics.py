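"""Segmentation evaluation metrics on binary masks.

Six metrics: Jaccard index, Dice coefficient, sensitivity, relative volume
difference (RVD, signed percent), Hausdorff distance (HD) and mean absolute
surface distance (MASD).  Overlap metrics are exact integer voxel counts;
surface distances are Euclidean in physical mm, with boundary voxels defined
by face connectivity (4-neighborhood in 2D, 6 in 3D) and the image border
treated as background.

Note on sensitivity: the conventional definition divides the true-positive
count by the reference volume |R|; the form implemented here as the default
divides by the predicted volume |T| (matching the evaluation protocol this
package mirrors).  Set ``conventional=True`` for |R∩T|/|R|.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "BinaryMask",
    "overlap_counts",
    "dice",
    "jaccard",
    "sensitivity_as_printed",
    "rvd",
    "extract_surface",
    "hausdorff",
    "masd",
    "evaluate_pair",
    "UndefinedMetricError",
]


class InvalidInputError(ValueError):
    pass


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given masks (e.g. 0/0)."""


@dataclasses.dataclass
class BinaryMask:
    """A 2D or 3D binary grid with per-axis spacing in mm."""

    grid: np.ndarray
    spacing: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim not in (2, 3):
            raise InvalidInputError(f"mask must be 2D or 3D, got ndim={self.grid.ndim}")
        if not np.isin(np.unique(self.grid), (0, 1)).all():
            raise InvalidInputError("mask values must be in {0, 1}")
        self.grid = self.grid.astype(np.uint8)
        if self.spacing is None:
            self.spacing = (1.0,) * self.grid.ndim
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.grid.ndim or any(s <= 0 for s in self.spacing):
            raise InvalidInputError(f"bad spacing {self.spacing} for ndim={self.grid.ndim}")


def _as_mask(m) -> BinaryMask:
    return m if isinstance(m, BinaryMask) else BinaryMask(np.asarray(m))


def _check_pair(R: BinaryMask, T: BinaryMask) -> None:
    if R.grid.shape != T.grid.shape:
        raise InvalidInputError(f"shape mismatch: {R.grid.shape} vs {T.grid.shape}")
    if R.spacing != T.spacing:
        raise InvalidInputError(f"spacing mismatch: {R.spacing} vs {T.spacing}")


def overlap_counts(R, T) -> tuple[int, int, int, int]:
    """Exact voxel counts ``(|R∩T|, |R∪T|, |R|, |T|)``."""
    R, T = _as_mask(R), _as_mask(T)
    _check_pair(R, T)
    r = R.grid.astype(bool)
    t = T.grid.astype(bool)
    inter = int(np.count_nonzero(r & t))
    union = int(np.count_nonzero(r | t))
    return inter, union, int(np.count_nonzero(r)), int(np.count_nonzero(t))


def dice(R, T) -> float:
    """Dice coefficient 2|R∩T| / (|R|+|T|)."""
    inter, _, nr, nt = overlap_counts(R, T)
    if nr + nt == 0:
        raise UndefinedMetricError("Dice undefined: both masks empty")
    return 2.0 * inter / (nr + nt)


def jaccard(R, T) -> float:
    """Jaccard index |R∩T| / |R∪T|."""
    inter, union, nr, nt = overlap_counts(R, T)
    if union == 0:
        raise UndefinedMetricError("Jaccard undefined: both masks empty")
    return inter / union


def sensitivity_as_printed(R, T, conventional: bool = False) -> float:
    """|R∩T| / |T| by default; ``conventional=True`` gives |R∩T| / |R|."""
    inter, _, nr, nt = overlap_counts(R, T)
    denom = nr if conventional else nt
    if denom == 0:
        raise UndefinedMetricError("sensitivity undefined: denominator mask empty")
    return inter / denom


def rvd(R, T) -> float:
    """Relative volume difference, signed percent: 100 (|T| − |R|) / |R|."""
    _, _, nr, nt = overlap_counts(R, T)
    if nr == 0:
        raise UndefinedMetricError("RVD undefined: reference mask empty")
    return 100.0 * (nt - nr) / nr


def extract_surface(mask) -> np.ndarray:
    """Physical coordinates (mm) of boundary voxels of a nonempty mask.

    A boundary voxel is foreground with at least one face-adjacent background
    neighbor; voxels on the image border always qualify (the outside counts
    as background).  Coordinates are voxel centers scaled by spacing.
    """
    mask = _as_mask(mask)
    g = mask.grid.astype(bool)
    if not g.any():
        raise UndefinedMetricError("cannot extract the surface of an empty mask")
    structure = ndimage.generate_binary_structure(g.ndim, 1)  # face connectivity
    interior = ndimage.binary_erosion(g, structure=structure, border_value=0)
    boundary = g & ~interior
    coords = np.argwhere(boundary).astype(np.float64)
    coords *= np.asarray(mask.spacing)
    return coords


def hausdorff(R, T, mode: str = "directed") -> float:
    """Hausdorff distance between mask surfaces, in mm.

    ``directed`` returns max over reference-surface points of the distance to
    the nearest target-surface point; ``symmetric`` the max of both
    directions.
    """
    R, T = _as_mask(R), _as_mask(T)
    _check_pair(R, T)
    if mode not in ("directed", "symmetric"):
        raise InvalidInputError(f"mode must be 'directed' or 'symmetric', got {mode!r}")
    sr = extract_surface(R)
    st = extract_surface(T)
    d_rt = float(cKDTree(st).query(sr)[0].max())
    if mode == "directed":
        return d_rt
    d_tr = float(cKDTree(sr).query(st)[0].max())
    return max(d_rt, d_tr)


def masd(R, T) -> float:
    """Mean absolute surface distance: the two directed mean nearest-surface
    distances, averaged."""
    R, T = _as_mask(R), _as_mask(T)
    _check_pair(R, T)
    sr = extract_surface(R)
    st = extract_surface(T)
    d_rt = float(cKDTree(st).query(sr)[0].mean())
    d_tr = float(cKDTree(sr).query(st)[0].mean())
    return 0.5 * (d_rt + d_tr)


def evaluate_pair(R, T, hd_mode: str = "directed") -> dict[str, float]:
    """All six metrics for one mask pair; distance metrics are NaN when the
    prediction is empty (they are undefined there)."""
    out: dict[str, float] = {}
    _, _, nr, nt = overlap_counts(R, T)
    out["dice"] = dice(R, T) if nr + nt > 0 else float("nan")
    out["jc"] = jaccard(R, T) if nr + nt > 0 else float("nan")
    out["sensitivity"] = sensitivity_as_printed(R, T) if nt > 0 else float("nan")
    out["rvd_pct"] = rvd(R, T) if nr > 0 else float("nan")
    if nr > 0 and nt > 0:
        out["hd_mm"] = hausdorff(R, T, mode=hd_mode)
        out["masd_mm"] = masd(R, T)
    else:
        out["hd_mm"] = float("nan")
        out["masd_mm"] = float("nan")
    return out
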