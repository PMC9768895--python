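"""Threshold-derived ground-truth masks.

Emulates the semi-automatic labelling procedure used for amyloid PET reads:
within a manually delineated zone, voxels of the pons-normalized image are
labelled positive when they exceed a factor (default 1.5) times the mean
uptake of a designated amyloid-free background region (a cerebellar-gray
surrogate in the phantoms).  The comparison is a strict inequality; ties at
exactly ``factor x background`` are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import PetVolume, ZoneMask

__all__ = ["ThresholdRule", "background_level", "make_ground_truth"]

#: Ground-truth threshold relative to background uptake.
DEFAULT_TRUTH_FACTOR = 1.5


@dataclass(frozen=True)
class ThresholdRule:
    """Threshold at ``factor`` times a background mean."""

    factor: float = DEFAULT_TRUTH_FACTOR

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("threshold factor must be positive")


def background_level(vol: PetVolume, background_mask: ZoneMask) -> float:
    """Arithmetic mean of the volume under the background mask."""
    mask = background_mask.data
    if mask.shape != vol.data.shape:
        raise ValueError("background mask shape does not match volume")
    if not mask.any():
        raise ValueError("background mask is empty")
    return float(vol.data[mask].mean())


def make_ground_truth(
    vol: PetVolume,
    zone: ZoneMask,
    rule: ThresholdRule = ThresholdRule(),
    background: float | ZoneMask | None = None,
) -> ZoneMask:
    """Zone-restricted thresholding: ``zone AND (voxel > factor * background)``.

    ``background`` is either a precomputed background level or a background
    mask from which the level is taken; the result is always a subset of the
    zone mask (the manual-delineation surrogate) and shrinks monotonically as
    the factor rises.
    """
    if zone.data.shape != vol.data.shape:
        raise ValueError("zone mask shape does not match volume")
    if not zone.data.any():
        raise ValueError("zone mask is empty")
    if isinstance(background, ZoneMask):
        level = background_level(vol, background)
    elif background is None:
        raise ValueError("a background level or mask is required")
    else:
        level = float(background)
    if level <= 0:
        raise ValueError(f"background level must be positive, got {level}")
    hot = vol.data > rule.factor * level
    return ZoneMask(zone.zone_id, zone.data & hot)
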