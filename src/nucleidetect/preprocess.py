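"""Per-frame preprocessing: impulsive-noise removal and z-isotropization.

Confocal stacks carry impulsive bright spots (chromatin texture, shot
noise) and are sampled more coarsely along z than in-plane.  Each frame is
median filtered with a small 3D window and then resampled along z by cubic
interpolation so that voxels become approximately isotropic; the result is
the preprocessed image on which all later stages operate.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from scipy.interpolate import make_interp_spline

from .image_io import Volume

DEFAULT_MEDIAN_WINDOW = (5, 5, 3)


def median_filter_3d(v: Volume, size: tuple[int, int, int] = DEFAULT_MEDIAN_WINDOW) -> Volume:
    """Apply a 3D median filter with edge replication at the borders.

    Parameters
    ----------
    v : Volume
    size : (nx, ny, nz)
        Window extents; each must be odd and >= 1.  The default (5, 5, 3)
        reflects the coarser native z sampling.
    """
    size = tuple(int(s) for s in size)
    if len(size) != 3 or any(s < 1 or s % 2 == 0 for s in size):
        raise ValueError(f"median window dimensions must be odd and >= 1, got {size}")
    out = ndimage.median_filter(v.data.astype(np.float64), size=size, mode="nearest")
    return Volume(out, v.voxel_size, v.t)


def interpolate_z(v: Volume) -> Volume:
    """Resample the z axis by cubic interpolation to ~isotropic voxels.

    The new z extent is ``round(nz * dz / dx)`` and the voxel size becomes
    ``(dx, dy, dx)``; x and y are untouched.  If the volume is already
    isotropic the input is returned unchanged; if dz < dx the frame is
    already finer than the target and a warning is issued.
    """
    dx, dy, dz = v.voxel_size
    if dz == dx:
        return v
    if dz < dx:
        warnings.warn(
            f"z spacing {dz} already finer than in-plane spacing {dx}; skipping "
            "z interpolation", stacklevel=2,
        )
        return v
    nz = v.shape[2]
    new_nz = int(round(nz * dz / dx))
    if nz == 1:
        # degenerate: replicate the single slice
        data = np.repeat(v.data, new_nz, axis=2)
        return Volume(data, (dx, dy, dx), v.t)
    zq = np.arange(new_nz) * (dx / dz)
    zq = np.clip(zq, 0.0, nz - 1.0)
    k = min(3, nz - 1)
    spline = make_interp_spline(np.arange(nz), v.data.astype(np.float64), k=k, axis=2)
    data = spline(zq)
    return Volume(data, (dx, dy, dx), v.t)


def preprocess_frame(
    v: Volume,
    median_window: tuple[int, int, int] = DEFAULT_MEDIAN_WINDOW,
    isotropic: bool = True,
) -> Volume:
    """Median filter then (optionally) z-isotropize: the preprocessed image."""
    out = median_filter_3d(v, median_window)
    if isotropic:
        out = interpolate_z(out)
    return out
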