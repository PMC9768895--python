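"""Image preprocessing: pons-ratio normalization, resizing, standardization,
paired geometric augmentation and the train/validation split.

Intensity normalization follows the SUVR convention for amyloid PET: every
voxel is divided by the mean uptake of the pons reference region, so the pons
ends up at a ratio of exactly 1 and cortical uptake is expressed relative to
it.  The pons statistic is the arithmetic mean, the convention for
reference-region normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import affine_transform, map_coordinates

from .phantom import PetVolume, ZoneMask

__all__ = [
    "NormalizationReport",
    "AugmentationParams",
    "normalize_to_pons",
    "resize_volume",
    "standardize",
    "augment",
    "sample_augmentation",
    "split_dataset",
]

ROTATION_RANGE_DEG = (-10.0, 10.0)
TRANSLATE_RANGE_FRAC = (-0.1, 0.1)
SHEAR_RANGE_DEG = (-10.0, 10.0)


@dataclass(frozen=True)
class NormalizationReport:
    """Record of a pons-ratio normalization: scale_applied = 1 / pons_mean."""

    pons_mean: float
    scale_applied: float
    method: str = "pons-ratio"


@dataclass(frozen=True)
class AugmentationParams:
    """A single sampled geometric augmentation.

    Rotation and shear in degrees within [-10, +10]; translations as a
    fraction of image width/height within [-0.1, 0.1].
    """

    rotation_deg: float = 0.0
    translate_frac_x: float = 0.0
    translate_frac_y: float = 0.0
    shear_deg: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = ROTATION_RANGE_DEG
        if not lo <= self.rotation_deg <= hi:
            raise ValueError(f"rotation_deg outside [{lo}, {hi}]")
        lo, hi = SHEAR_RANGE_DEG
        if not lo <= self.shear_deg <= hi:
            raise ValueError(f"shear_deg outside [{lo}, {hi}]")
        lo, hi = TRANSLATE_RANGE_FRAC
        for t in (self.translate_frac_x, self.translate_frac_y):
            if not lo <= t <= hi:
                raise ValueError(f"translation fraction outside [{lo}, {hi}]")


def normalize_to_pons(
    vol: PetVolume, pons_mask: ZoneMask
) -> tuple[PetVolume, NormalizationReport]:
    """Divide the volume by the mean uptake inside the pons mask.

    After normalization the mean of the output under the pons mask is exactly
    1.  Idempotent: applying it twice is the identity (to rounding).
    """
    mask = pons_mask.data
    if mask.shape != vol.data.shape:
        raise ValueError("pons mask shape does not match volume")
    if not mask.any():
        raise ValueError("pons mask is empty")
    pons_mean = float(vol.data[mask].mean())
    if pons_mean <= 0:
        raise ValueError(f"pons mean must be positive, got {pons_mean}")
    scale = 1.0 / pons_mean
    out = PetVolume(vol.data * scale, vol.voxel_size_mm)
    return out, NormalizationReport(pons_mean=pons_mean, scale_applied=scale)


def resize_volume(vol: PetVolume, target_shape: tuple[int, int, int]) -> PetVolume:
    """Resize by separable linear interpolation to ``target_shape``.

    Sample points are placed at ``linspace(0, n-1, m)`` per axis, so the first
    and last samples coincide with the original edge voxels and a [0, 1] ramp
    upsampled to 3 samples yields [0, 0.5, 1].
    """
    target_shape = tuple(int(n) for n in target_shape)
    if len(target_shape) != vol.data.ndim or any(n < 2 for n in target_shape):
        raise ValueError(f"degenerate target shape {target_shape}")
    if target_shape == vol.data.shape:
        return PetVolume(vol.data.copy(), vol.voxel_size_mm)
    coords = np.meshgrid(
        *(np.linspace(0, n - 1, m) for n, m in zip(vol.data.shape, target_shape)),
        indexing="ij",
    )
    data = map_coordinates(vol.data, coords, order=1, mode="nearest")
    new_voxel = vol.voxel_size_mm * vol.data.shape[0] / target_shape[0]
    return PetVolume(data, new_voxel)


def standardize(
    vol: PetVolume | np.ndarray, mean: float, std: float
) -> PetVolume | np.ndarray:
    """Shift/scale to dataset statistics: (x - mean) / std."""
    if std <= 0:
        raise ValueError("std must be positive")
    if isinstance(vol, PetVolume):
        # bypass the nonnegativity carrier: standardized values are z-scores
        out = PetVolume.__new__(PetVolume)
        out.data = (vol.data - mean) / std
        out.voxel_size_mm = vol.voxel_size_mm
        return out
    return (np.asarray(vol, dtype=float) - mean) / std


def _affine_matrix(params: AugmentationParams, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Compose rotation, shear and translation about the image center.

    Returns (matrix, offset) in the output->input convention used by
    ``scipy.ndimage.affine_transform``: input_coords = matrix @ output + offset.
    """
    h_axis, w_axis = shape  # rows = x (left-right), cols = y
    theta = np.deg2rad(params.rotation_deg)
    shear = np.deg2rad(params.shear_deg)
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    shr = np.array([[1.0, np.tan(shear)], [0.0, 1.0]])
    fwd = rot @ shr
    t = np.array(
        [params.translate_frac_x * shape[0], params.translate_frac_y * shape[1]]
    )
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    inv = np.linalg.inv(fwd)
    # forward: out = fwd @ (in - center) + center + t  =>  in = inv @ (out - center - t) + center
    offset = center - inv @ (center + t)
    return inv, offset


def augment(
    image: np.ndarray, mask: np.ndarray, params: AugmentationParams
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one geometric transform identically to a slice and its mask.

    The image is resampled with linear interpolation and the mask with
    nearest-neighbour so it stays binary; pixels transformed in from outside
    the frame are filled with 0.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    if image.ndim != 2:
        raise ValueError("augment operates on 2D slices")
    if (
        params.rotation_deg == 0
        and params.shear_deg == 0
        and params.translate_frac_x == 0
        and params.translate_frac_y == 0
    ):
        return image.copy(), mask.astype(bool).copy()
    matrix, offset = _affine_matrix(params, image.shape)
    img_out = affine_transform(image, matrix, offset=offset, order=1, mode="constant", cval=0.0)
    msk_out = affine_transform(
        mask.astype(np.uint8), matrix, offset=offset, order=0, mode="constant", cval=0
    )
    return img_out, msk_out.astype(bool)


def sample_augmentation(rng: np.random.Generator) -> AugmentationParams:
    """Draw augmentation parameters uniformly from the stated ranges."""
    return AugmentationParams(
        rotation_deg=rng.uniform(*ROTATION_RANGE_DEG),
        translate_frac_x=rng.uniform(*TRANSLATE_RANGE_FRAC),
        translate_frac_y=rng.uniform(*TRANSLATE_RANGE_FRAC),
        shear_deg=rng.uniform(*SHEAR_RANGE_DEG),
    )


def split_dataset(items, train_frac: float = 0.8, seed: int = 0):
    """Random, seeded partition of ``items`` into (train, val).

    ``|train| = round(train_frac * n)``, clamped so neither side is empty.
    """
    items = list(items)
    n = len(items)
    if n < 2:
        raise ValueError("need at least 2 items to split")
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    n_train = int(round(train_frac * n))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    train = [items[i] for i in sorted(perm[:n_train])]
    val = [items[i] for i in sorted(perm[n_train:])]
    return train, val
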