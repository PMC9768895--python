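"""Probability-map to lesion-mask post-processing.

Binarization at foreground probability > 0.5, morphological dilation with
square connectivity, and the hemispheric-swap fixed threshold: the predicted
mask is mirrored left-right, the mean image intensity under the mirrored mask
gives a subject-internal contralateral reference, and predicted pixels are
kept only where the intensity exceeds ``factor`` (default 1.3) times that
reference.  On a perfectly symmetric image the lesion equals its own
reference and the mask empties — asymmetry is what the test detects.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

__all__ = ["binarize", "dilate", "hemispheric_swap_threshold", "DEFAULT_SWAP_FACTOR"]

#: Post-threshold relative to the contralateral (hemispheric-swap) mean.
DEFAULT_SWAP_FACTOR = 1.3


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Foreground probability strictly above ``threshold`` -> 1."""
    prob = np.asarray(prob, dtype=float)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probability map values must lie in [0, 1]")
    return prob > threshold


def dilate(mask: np.ndarray, size: int = 3) -> np.ndarray:
    """Binary dilation with a square (2D) or cube (3D) structuring element.

    ``size`` x ``size`` (x ``size``) full connectivity; the output always
    contains the input.
    """
    mask = np.asarray(mask).astype(bool)
    if size < 1 or size % 2 == 0:
        raise ValueError("structuring element size must be odd and >= 1")
    if size == 1 or not mask.any():
        return mask.copy()
    structure = np.ones((size,) * mask.ndim, dtype=bool)
    return ndimage.binary_dilation(mask, structure=structure)


def hemispheric_swap_threshold(
    image: np.ndarray,
    pred_mask: np.ndarray,
    factor: float = DEFAULT_SWAP_FACTOR,
    mirror_axis: int = 0,
) -> np.ndarray:
    """Keep predicted pixels exceeding ``factor`` x the contralateral mean.

    The reference level is the mean of ``image`` under the left-right mirror
    of ``pred_mask`` (mirroring along ``mirror_axis``, x by convention).  The
    output is always a subset of ``pred_mask``; raising ``factor`` never adds
    pixels.  If the mirrored mask is empty the prediction is returned
    unchanged with a warning.
    """
    image = np.asarray(image, dtype=float)
    pred_mask = np.asarray(pred_mask).astype(bool)
    if image.shape != pred_mask.shape:
        raise ValueError("image and mask shapes differ")
    if factor < 0:
        raise ValueError("factor must be nonnegative")
    mirrored = np.flip(pred_mask, axis=mirror_axis)
    if not mirrored.any():
        warnings.warn(
            "mirrored mask is empty; hemispheric-swap threshold skipped", stacklevel=2
        )
        return pred_mask.copy()
    reference = float(image[mirrored].mean())
    return pred_mask & (image > factor * reference)
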