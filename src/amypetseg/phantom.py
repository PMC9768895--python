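"""Synthetic amyloid-PET brain phantoms.

Generates seeded, brain-shaped 3D tracer-uptake volumes with five disjoint
amyloid target zones (frontal lobe, posterior cingulate cortex + precuneus,
lateral temporal lobe, inferolateral parietal lobe, striatum), a midline pons
reference region and a cerebellar-surrogate background region.  Positive zones
carry elevated uptake relative to background; the scene is smoothed with a
Gaussian point-spread function and corrupted with additive Gaussian noise.

Geometries are simplified parametric shapes (ellipsoids and boxes), not
anatomy: the downstream pipeline only needs regions with the right topology —
bilateral cortical zones for the hemispheric swap and a midline pons.

Coordinate convention: 0-based voxel indices, axes ``(x, y, z)`` with
left-right along ``x`` (the hemispheric-swap mirror axis), anterior-posterior
along ``y`` and inferior-superior along ``z``.  Slicing planes: axial = fixed
``z``, coronal = fixed ``y``, sagittal = fixed ``x``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "ZONE_IDS",
    "Ellipsoid",
    "Box",
    "ZoneDef",
    "PetVolume",
    "ZoneMask",
    "PhantomSpec",
    "Phantom",
    "default_spec",
    "generate_phantom",
    "extract_slices",
    "stack_slices",
    "FWHM_TO_SIGMA",
]

#: The five visually rated amyloid accumulation zones.
ZONE_IDS = ("frontal", "pcc_precuneus", "lateral_temporal", "parietal", "striatum")

#: Gaussian FWHM = sigma * 2*sqrt(2*ln 2).
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class PhantomValidationError(ValueError):
    """Raised when a phantom specification violates its invariants."""


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in fractional volume coordinates (0..1 per axis)."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]

    def rasterize(self, shape: tuple[int, int, int]) -> np.ndarray:
        grids = np.ogrid[tuple(slice(0, n) for n in shape)]
        acc = np.zeros(shape, dtype=float)
        for g, n, c, r in zip(grids, shape, self.center, self.radii):
            if r <= 0:
                raise PhantomValidationError(f"nonpositive ellipsoid radius {r}")
            # voxel centers at (i + 0.5)/n in fractional coordinates
            acc = acc + (((g + 0.5) / n - c) / r) ** 2
        return acc <= 1.0


@dataclass(frozen=True)
class Box:
    """Axis-aligned box in fractional volume coordinates."""

    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def rasterize(self, shape: tuple[int, int, int]) -> np.ndarray:
        grids = np.ogrid[tuple(slice(0, n) for n in shape)]
        mask = np.ones(shape, dtype=bool)
        for g, n, lo, hi in zip(grids, shape, self.lo, self.hi):
            if hi <= lo:
                raise PhantomValidationError("degenerate box extent")
            frac = (g + 0.5) / n
            mask = mask & (frac >= lo) & (frac <= hi)
        return mask


@dataclass(frozen=True)
class ZoneDef:
    """One amyloid target zone: a union of parametric shapes plus its state.

    ``uptake_ratio`` is the tracer uptake inside the zone relative to
    background; a negative (amyloid-free) zone has ratio exactly 1.
    """

    zone_id: str
    geometry: tuple[Ellipsoid | Box, ...]
    positive: bool = True
    uptake_ratio: float = 2.0

    def __post_init__(self) -> None:
        if self.zone_id not in ZONE_IDS:
            raise PhantomValidationError(
                f"unknown zone_id {self.zone_id!r}; expected one of {ZONE_IDS}"
            )
        if not self.geometry:
            raise PhantomValidationError("zone geometry is empty")
        if self.positive and self.uptake_ratio <= 1.0:
            raise PhantomValidationError("positive zone requires uptake_ratio > 1")
        if not self.positive and self.uptake_ratio != 1.0:
            raise PhantomValidationError("negative zone requires uptake_ratio == 1")

    def rasterize(self, shape: tuple[int, int, int]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        for shp in self.geometry:
            mask |= shp.rasterize(shape)
        if not mask.any():
            raise PhantomValidationError(
                f"zone {self.zone_id!r} rasterizes to an empty mask at {shape}"
            )
        return mask


@dataclass
class PetVolume:
    """A 3D nonnegative tracer-uptake volume with isotropic voxel size in mm."""

    data: np.ndarray
    voxel_size_mm: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class ZoneMask:
    """A binary mask labelled with the zone it delineates (or 'pons' etc.)."""

    zone_id: str
    data: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.dtype != bool:
            vals = np.unique(arr)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError("mask values must be in {0, 1}")
            arr = arr.astype(bool)
        self.data = arr

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def count(self) -> int:
        return int(self.data.sum())


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of a synthetic brain/uptake scene.

    Defaults follow the acquisition this generator emulates: 2.0 mm voxels and
    a 3.0 mm FWHM post-reconstruction Gaussian filter.  The default matrix is
    desk-scale (64 x 64 x 40); the clinical-scale 256 x 256 x 159 matrix is
    supported by passing ``matrix_size`` explicitly.
    """

    matrix_size: tuple[int, int, int] = (64, 64, 40)
    voxel_size_mm: float = 2.0
    zones: tuple[ZoneDef, ...] = ()
    brain: Ellipsoid = Ellipsoid((0.5, 0.5, 0.5), (0.44, 0.46, 0.44))
    pons: Ellipsoid = Ellipsoid((0.5, 0.40, 0.22), (0.06, 0.06, 0.06))
    background_region: Ellipsoid = Ellipsoid((0.5, 0.22, 0.18), (0.14, 0.10, 0.09))
    background_uptake: float = 1.0
    noise_sigma: float = 0.05
    psf_fwhm_mm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.matrix_size) != 3 or any(n < 4 for n in self.matrix_size):
            raise PhantomValidationError("matrix_size must be a triple of ints >= 4")
        if self.background_uptake <= 0:
            raise PhantomValidationError("background_uptake must be positive")
        if self.noise_sigma < 0 or self.psf_fwhm_mm < 0:
            raise PhantomValidationError("noise_sigma and psf_fwhm_mm must be >= 0")
        if self.voxel_size_mm <= 0:
            raise PhantomValidationError("voxel_size_mm must be positive")
        seen = [z.zone_id for z in self.zones]
        if len(seen) != len(set(seen)):
            raise PhantomValidationError("duplicate zone_id in spec")


@dataclass
class Phantom:
    """Output of :func:`generate_phantom`."""

    volume: PetVolume
    zone_masks: dict[str, ZoneMask]
    pons_mask: ZoneMask
    background_mask: ZoneMask
    brain_mask: ZoneMask
    spec: PhantomSpec


# Bilateral zone layouts in fractional coordinates.  Chosen to be pairwise
# disjoint, inside the brain ellipsoid, and mirror-symmetric about x = 0.5
# where the anatomy is bilateral.
_ZONE_LAYOUT: dict[str, tuple[Ellipsoid, ...]] = {
    "frontal": (
        Ellipsoid((0.35, 0.74, 0.62), (0.10, 0.10, 0.12)),
        Ellipsoid((0.65, 0.74, 0.62), (0.10, 0.10, 0.12)),
    ),
    "pcc_precuneus": (Ellipsoid((0.5, 0.24, 0.62), (0.08, 0.08, 0.12)),),
    "lateral_temporal": (
        Ellipsoid((0.17, 0.50, 0.42), (0.07, 0.13, 0.10)),
        Ellipsoid((0.83, 0.50, 0.42), (0.07, 0.13, 0.10)),
    ),
    "parietal": (
        Ellipsoid((0.32, 0.32, 0.76), (0.09, 0.09, 0.08)),
        Ellipsoid((0.68, 0.32, 0.76), (0.09, 0.09, 0.08)),
    ),
    "striatum": (
        Ellipsoid((0.37, 0.55, 0.50), (0.06, 0.09, 0.08)),
        Ellipsoid((0.63, 0.55, 0.50), (0.06, 0.09, 0.08)),
    ),
}


def default_spec(
    matrix_size: tuple[int, int, int] = (64, 64, 40),
    positive_zones: tuple[str, ...] = ZONE_IDS,
    uptake_ratio: float = 2.0,
    noise_sigma: float = 0.05,
    psf_fwhm_mm: float = 3.0,
    seed: int = 0,
    lateralize: dict[str, int] | None = None,
) -> PhantomSpec:
    """Build the standard five-zone phantom specification.

    Parameters
    ----------
    positive_zones
        Zone ids carrying amyloid-elevated uptake; the rest are negative.
    uptake_ratio
        Uptake of positive zones relative to background (>= 1).
    lateralize
        Optional ``{zone_id: side}`` with side ``0`` or ``1``: keep only that
        component of a bilateral zone, producing an asymmetric lesion (useful
        for exercising the hemispheric-swap threshold).
    """
    zones = []
    for zid in ZONE_IDS:
        geom = _ZONE_LAYOUT[zid]
        if lateralize and zid in lateralize and len(geom) == 2:
            geom = (geom[lateralize[zid]],)
        positive = zid in positive_zones
        zones.append(
            ZoneDef(
                zone_id=zid,
                geometry=geom,
                positive=positive,
                uptake_ratio=uptake_ratio if positive else 1.0,
            )
        )
    return PhantomSpec(
        matrix_size=tuple(matrix_size),
        zones=tuple(zones),
        noise_sigma=noise_sigma,
        psf_fwhm_mm=psf_fwhm_mm,
        seed=seed,
    )


def _validate_disjoint(masks: dict[str, np.ndarray]) -> None:
    total = np.zeros(next(iter(masks.values())).shape, dtype=np.int64)
    for m in masks.values():
        total += m
    if total.max() > 1:
        overlapping = [
            (a, b)
            for i, (a, ma) in enumerate(masks.items())
            for b, mb in list(masks.items())[i + 1 :]
            if (ma & mb).any()
        ]
        raise PhantomValidationError(f"overlapping regions: {overlapping}")


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Render a :class:`PhantomSpec` into a noisy uptake volume plus masks.

    The noiseless scene is piecewise constant: 0 outside the brain,
    ``background_uptake`` inside, ``uptake_ratio x background`` inside positive
    zones, background level inside the pons (no specific binding).  The scene
    is then blurred with a Gaussian of ``psf_fwhm_mm`` and white Gaussian
    noise of standard deviation ``noise_sigma`` is added (clipped at zero to
    keep uptake nonnegative).  Deterministic for a fixed ``spec.seed``.
    """
    shape = tuple(spec.matrix_size)
    brain = spec.brain.rasterize(shape)

    region_masks: dict[str, np.ndarray] = {}
    for zone in spec.zones:
        region_masks[zone.zone_id] = zone.rasterize(shape) & brain
        if not region_masks[zone.zone_id].any():
            raise PhantomValidationError(
                f"zone {zone.zone_id!r} lies entirely outside the brain"
            )
    region_masks["pons"] = spec.pons.rasterize(shape) & brain
    region_masks["background_ref"] = spec.background_region.rasterize(shape) & brain
    _validate_disjoint(region_masks)

    scene = np.zeros(shape, dtype=float)
    scene[brain] = spec.background_uptake
    for zone in spec.zones:
        scene[region_masks[zone.zone_id]] = spec.background_uptake * zone.uptake_ratio

    if spec.psf_fwhm_mm > 0:
        sigma_vox = spec.psf_fwhm_mm * FWHM_TO_SIGMA / spec.voxel_size_mm
        scene = gaussian_filter(scene, sigma=sigma_vox, mode="constant")
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        scene = scene + rng.normal(0.0, spec.noise_sigma, size=shape)
        np.clip(scene, 0.0, None, out=scene)

    zone_masks = {
        z.zone_id: ZoneMask(z.zone_id, region_masks[z.zone_id]) for z in spec.zones
    }
    return Phantom(
        volume=PetVolume(scene, spec.voxel_size_mm),
        zone_masks=zone_masks,
        pons_mask=ZoneMask("pons", region_masks["pons"]),
        background_mask=ZoneMask("background_ref", region_masks["background_ref"]),
        brain_mask=ZoneMask("brain", brain),
        spec=spec,
    )


_PLANE_AXIS = {"axial": 2, "coronal": 1, "sagittal": 0}


def extract_slices(
    vol: PetVolume | np.ndarray, plane: str, indices
) -> list[np.ndarray]:
    """Extract 2D slices along one of the three orthogonal planes.

    ``axial`` slices at fixed z (shape nx x ny), ``coronal`` at fixed y
    (nx x nz), ``sagittal`` at fixed x (ny x nz).
    """
    data = vol.data if isinstance(vol, PetVolume) else np.asarray(vol)
    if plane not in _PLANE_AXIS:
        raise ValueError(f"unknown plane {plane!r}; expected one of {list(_PLANE_AXIS)}")
    axis = _PLANE_AXIS[plane]
    n = data.shape[axis]
    out = []
    for idx in np.atleast_1d(indices):
        idx = int(idx)
        if not 0 <= idx < n:
            raise IndexError(f"{plane} index {idx} out of range [0, {n})")
        out.append(np.take(data, idx, axis=axis).copy())
    return out


def stack_slices(slices: list[np.ndarray], plane: str) -> np.ndarray:
    """Inverse of :func:`extract_slices` over all indices of a plane."""
    if plane not in _PLANE_AXIS:
        raise ValueError(f"unknown plane {plane!r}")
    return np.stack(slices, axis=_PLANE_AXIS[plane])


def replace_spec(spec: PhantomSpec, **kwargs) -> PhantomSpec:
    """Return a copy of ``spec`` with the given fields replaced."""
    return replace(spec, **kwargs)
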