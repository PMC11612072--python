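"""Seeded deformable-phantom cohorts for end-to-end testing of the pipeline.

Each subject is a template organ (an ellipsoid cross-sectioned into a few 2D
slices) pushed through a subject-specific smooth random warp, given a textured
interior, organ/background intensity contrast, additive Gaussian noise and an
optional lesion blob.  The warps are drawn from the same family of smooth
displacement fields that deformable registration is expected to recover, which
is what makes registration-based augmentation meaningfully testable on these
cohorts.

Every subject is fully reproducible from ``(config.seed, subject_seed)``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .io_preprocess import InvalidInputError, SliceSample, Volume, extract_slices, save_volume, write_manifest

__all__ = ["LesionConfig", "PhantomConfig", "generate_subject", "generate_cohort", "cohort_slices"]


@dataclasses.dataclass
class LesionConfig:
    """An elliptical blob inside the organ, offset from its center.

    ``offset_frac`` is the lesion center in units of the organ radii, so any
    offset with |offset| + radius/organ-radius < 1 keeps the blob inside the
    organ; containment is additionally enforced by intersection.
    """

    radii_mm: tuple[float, float] = (4.0, 3.0)
    offset_frac: tuple[float, float] = (0.3, 0.2)
    contrast: float = -0.25


@dataclasses.dataclass
class PhantomConfig:
    """Study conditions of the synthetic cohort.

    Defaults: 96×96 px slices at 1 mm, a 24×16 mm elliptical organ at
    intensity 0.5 over a 0.35 background (a deliberately low
    contrast-to-noise regime, as in soft-tissue CT/MR), interior texture of
    amplitude 0.10, subject warps of up to 6 mm, noise sigma 0.08 and 3
    slices per subject.
    """

    image_px: tuple[int, int] = (96, 96)
    organ_center_mm: tuple[float, float] = (0.0, 0.0)
    organ_radii_mm: tuple[float, float] = (24.0, 16.0)
    organ_intensity: float = 0.5
    background: float = 0.35
    texture_amp: float = 0.10
    warp_scale_mm: float = 6.0
    warp_smooth_mm: float = 12.0
    noise_sigma: float = 0.08
    radius_jitter: float = 0.15
    intensity_jitter: float = 0.04
    center_jitter_mm: float = 4.0
    n_slices: int = 3
    lesion: LesionConfig | None = None
    seed: int = 0


def _subject_rng(config: PhantomConfig, subject_seed: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed) % (2**31), int(subject_seed) % (2**31)])


def _smooth_warp(shape: tuple[int, int], scale_mm: float, smooth_mm: float,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-smoothed random displacement with peak magnitude ``scale_mm``."""
    if scale_mm == 0:
        z = np.zeros(shape)
        return z, z.copy()
    dy = ndimage.gaussian_filter(rng.standard_normal(shape), smooth_mm)
    dx = ndimage.gaussian_filter(rng.standard_normal(shape), smooth_mm)
    mag = np.sqrt(dy**2 + dx**2)
    peak = mag.max()
    if peak > 0:
        dy *= scale_mm / peak
        dx *= scale_mm / peak
    return dy, dx


def generate_subject(config: PhantomConfig, subject_seed: int,
                     subject_id: str | None = None) -> tuple[Volume, Volume]:
    """One phantom subject: image volume and binary mask volume.

    The warped organ support is evaluated analytically (the ellipse equation is
    sampled at displaced coordinates), so the mask needs no interpolation and
    is exactly binary.
    """
    h, w = config.image_px
    a, b = config.organ_radii_mm
    if min(a, b) <= 2.0:
        raise InvalidInputError(f"degenerate organ: radii {config.organ_radii_mm} (need > 2 mm)")
    if config.noise_sigma < 0 or config.warp_scale_mm < 0:
        raise InvalidInputError("noise_sigma and warp_scale_mm must be non-negative")
    rng = _subject_rng(config, subject_seed)
    sid = subject_id if subject_id is not None else f"phantom-{subject_seed:03d}"

    # per-subject anatomy: organ size, position and mean intensity vary
    # across the cohort, on top of the smooth shape warp
    size_factor = float(np.exp(rng.normal(0.0, config.radius_jitter)))
    a = a * size_factor
    b = b * size_factor
    center = (config.organ_center_mm[0] + rng.uniform(-1, 1) * config.center_jitter_mm,
              config.organ_center_mm[1] + rng.uniform(-1, 1) * config.center_jitter_mm)
    organ_level = config.organ_intensity + rng.normal(0.0, config.intensity_jitter)

    yy, xx = np.meshgrid(np.arange(h) - (h - 1) / 2.0, np.arange(w) - (w - 1) / 2.0, indexing="ij")
    dy, dx = _smooth_warp((h, w), config.warp_scale_mm, config.warp_smooth_mm, rng)
    ywarp = yy + dy - center[0]
    xwarp = xx + dx - center[1]

    texture = ndimage.gaussian_filter(rng.standard_normal((h, w)), 2.0)
    tstd = texture.std()
    if tstd > 0:
        texture *= config.texture_amp / tstd

    # through-plane radius modulation: slices cut an ellipsoid off-equator
    z_norm = np.linspace(-0.6, 0.6, config.n_slices) if config.n_slices > 1 else np.array([0.0])
    factors = np.sqrt(np.clip(1.0 - z_norm**2, 0.0, None))

    images = np.empty((h, w, config.n_slices))
    masks = np.empty((h, w, config.n_slices), dtype=np.uint8)
    for k, f in enumerate(factors):
        organ = (ywarp / (a * f)) ** 2 + (xwarp / (b * f)) ** 2 <= 1.0
        img = np.full((h, w), config.background)
        img[organ] = organ_level + texture[organ]
        if config.lesion is not None:
            les = config.lesion
            ly = ywarp - les.offset_frac[0] * a * f
            lx = xwarp - les.offset_frac[1] * b * f
            lesion = (ly / les.radii_mm[0]) ** 2 + (lx / les.radii_mm[1]) ** 2 <= 1.0
            lesion &= organ  # blobs never leave the organ
            img[lesion] += les.contrast
        img += rng.normal(0.0, config.noise_sigma, size=(h, w))
        images[:, :, k] = np.clip(img, 0.0, 2.0)
        masks[:, :, k] = organ.astype(np.uint8)

    vol = Volume(images, (1.0, 1.0, 1.0), modality="CT", subject_id=sid)
    msk = Volume(masks, (1.0, 1.0, 1.0), modality="CT", subject_id=sid)
    return vol, msk


def generate_cohort(config: PhantomConfig, n: int,
                    outdir: str | Path | None = None) -> tuple[list[tuple[Volume, Volume]], pd.DataFrame]:
    """Generate ``n`` subjects with distinct seeds; optionally write NIfTI +
    a manifest compatible with :mod:`segpretext.io_preprocess`."""
    if n < 1:
        raise InvalidInputError(f"cohort size must be >= 1, got {n}")
    subjects = [generate_subject(config, s) for s in range(n)]
    rows = []
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for s, (vol, msk) in enumerate(subjects):
            img_path = outdir / f"{vol.subject_id}_image.nii.gz"
            msk_path = outdir / f"{vol.subject_id}_mask.nii.gz"
            save_volume(vol, img_path)
            save_volume(msk, msk_path, as_mask=True)
            rows.append(dict(subject_id=vol.subject_id, image_path=str(img_path),
                             mask_path=str(msk_path), modality="CT",
                             config_seed=config.seed, subject_seed=s))
        manifest = write_manifest(rows, outdir / "manifest.tsv")
    else:
        manifest = pd.DataFrame(
            [dict(subject_id=vol.subject_id, image_path="", mask_path="", modality="CT",
                  config_seed=config.seed, subject_seed=s)
             for s, (vol, _) in enumerate(subjects)]
        )
    return subjects, manifest


def cohort_slices(config: PhantomConfig, n: int) -> dict[str, list[SliceSample]]:
    """In-memory cohort as per-subject slice samples (foreground slices only)."""
    subjects, _ = generate_cohort(config, n)
    out: dict[str, list[SliceSample]] = {}
    for vol, msk in subjects:
        out[vol.subject_id] = extract_slices(vol, msk, axis=2, keep="mask_only")
    return out
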