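"""File I/O: NIfTI volumes and masks, PNG slice rendering, YAML phantom specs."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import yaml

from .phantom import Box, Ellipsoid, PetVolume, PhantomSpec, ZoneDef, ZoneMask

__all__ = [
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
    "save_slice_png",
    "spec_to_yaml",
    "spec_from_yaml",
]


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


def save_volume(vol: PetVolume, path) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), _affine(vol.voxel_size_mm))
    nib.save(img, str(path))


def load_volume(path) -> PetVolume:
    img = nib.load(str(path))
    voxel = float(img.header.get_zooms()[0])
    return PetVolume(np.asarray(img.dataobj, dtype=np.float64), voxel)


def save_mask(mask: ZoneMask, path, voxel_size_mm: float = 2.0) -> None:
    """Write a binary mask; the zone id goes in the NIfTI description field."""
    img = nib.Nifti1Image(mask.data.astype(np.uint8), _affine(voxel_size_mm))
    img.header["descrip"] = mask.zone_id.encode()[:79]
    nib.save(img, str(path))


def load_mask(path) -> ZoneMask:
    img = nib.load(str(path))
    zone_id = bytes(img.header["descrip"]).decode(errors="ignore").rstrip("\x00")
    return ZoneMask(zone_id or "unknown", np.asarray(img.dataobj) > 0)


def save_slice_png(slice2d: np.ndarray, path, cmap: str | None = None) -> None:
    """Render a 2D slice to PNG, grayscale by default or via a colormap name
    (the clinical reads use color scales such as rainbow/spectrum)."""
    arr = np.asarray(slice2d, dtype=float)
    lo, hi = float(arr.min()), float(arr.max())
    scaled = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
    if cmap is None:
        iio.imwrite(Path(path), (scaled * 255).astype(np.uint8))
    else:
        import matplotlib

        rgba = matplotlib.colormaps[cmap](scaled)
        iio.imwrite(Path(path), (rgba[..., :3] * 255).astype(np.uint8))


def _shape_to_dict(shape) -> dict:
    d = asdict(shape)
    d["kind"] = "ellipsoid" if isinstance(shape, Ellipsoid) else "box"
    return d


def _shape_from_dict(d: dict):
    d = dict(d)
    kind = d.pop("kind")
    if kind == "ellipsoid":
        return Ellipsoid(tuple(d["center"]), tuple(d["radii"]))
    if kind == "box":
        return Box(tuple(d["lo"]), tuple(d["hi"]))
    raise ValueError(f"unknown shape kind {kind!r}")


def spec_to_yaml(spec: PhantomSpec, path=None) -> str:
    """Serialize a phantom specification; returns the YAML text."""
    payload = {
        "matrix_size": list(spec.matrix_size),
        "voxel_size_mm": spec.voxel_size_mm,
        "background_uptake": spec.background_uptake,
        "noise_sigma": spec.noise_sigma,
        "psf_fwhm_mm": spec.psf_fwhm_mm,
        "seed": spec.seed,
        "brain": _shape_to_dict(spec.brain),
        "pons": _shape_to_dict(spec.pons),
        "background_region": _shape_to_dict(spec.background_region),
        "zones": [
            {
                "zone_id": z.zone_id,
                "positive": z.positive,
                "uptake_ratio": z.uptake_ratio,
                "geometry": [_shape_to_dict(s) for s in z.geometry],
            }
            for z in spec.zones
        ],
    }
    text = yaml.safe_dump(payload, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def spec_from_yaml(source) -> PhantomSpec:
    """Load a phantom specification from YAML text or a file path."""
    text = str(source)
    if "\n" not in text:
        p = Path(text)
        if p.exists():
            text = p.read_text()
    d = yaml.safe_load(text)
    zones = tuple(
        ZoneDef(
            zone_id=z["zone_id"],
            geometry=tuple(_shape_from_dict(s) for s in z["geometry"]),
            positive=z["positive"],
            uptake_ratio=z["uptake_ratio"],
        )
        for z in d["zones"]
    )
    return PhantomSpec(
        matrix_size=tuple(d["matrix_size"]),
        voxel_size_mm=d["voxel_size_mm"],
        zones=zones,
        brain=_shape_from_dict(d["brain"]),
        pons=_shape_from_dict(d["pons"]),
        background_region=_shape_from_dict(d["background_region"]),
        background_uptake=d["background_uptake"],
        noise_sigma=d["noise_sigma"],
        psf_fwhm_mm=d["psf_fwhm_mm"],
        seed=d["seed"],
    )
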