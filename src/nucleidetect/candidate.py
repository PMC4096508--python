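"""Candidate-region extraction by Otsu global thresholding.

Foreground (nucleus) voxels are separated from the dark background with
Otsu's method, which maximizes between-class variance over the intensity
histogram.  Retaining the preprocessed intensities on the binary mask and
zeroing the background gives the candidate-region image; downstream
enhancement and size filtering absorb mask imperfections, so no
morphological cleanup is applied.
"""

from __future__ import annotations

import numpy as np
from skimage.filters import threshold_otsu

from .image_io import Volume

DEFAULT_NBINS = 256


def otsu_threshold(v: Volume, nbins: int = DEFAULT_NBINS) -> float:
    """Otsu threshold of a volume's intensity histogram.

    Returns the threshold maximizing between-class variance over an
    ``nbins`` histogram spanning [min, max] of the frame.  A constant
    volume has no bimodality and raises ``ValueError``.
    """
    data = np.asarray(v.data)
    if data.min() == data.max():
        raise ValueError("cannot threshold a constant volume (no bimodality)")
    return float(threshold_otsu(data, nbins=int(nbins)))


def threshold_mask(v: Volume, threshold: float) -> np.ndarray:
    """Boolean foreground mask: voxels strictly above the threshold."""
    return v.data > threshold


def candidate_mask(v: Volume, nbins: int = DEFAULT_NBINS) -> np.ndarray:
    """Otsu foreground mask of a preprocessed frame."""
    return threshold_mask(v, otsu_threshold(v, nbins))


def candidate_image(v: Volume, mask: np.ndarray) -> Volume:
    """Retain intensities on the mask, zero elsewhere."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != v.data.shape:
        raise ValueError(f"mask shape {mask.shape} != volume shape {v.data.shape}")
    out = np.where(mask, v.data.astype(np.float64), 0.0)
    return Volume(out, v.voxel_size, v.t)
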