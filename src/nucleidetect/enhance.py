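"""Adaptive Gaussian enhancement of the candidate-region image.

Nuclei behave as bright quasi-spherical blobs; convolving with an isotropic
Gaussian whose support length matches a nucleus diameter acts as a matched
filter that homogenizes the interior texture and produces one clean
intensity peak per nucleus.  Two modes are provided:

* single-scale: one Gaussian of length ``L_avg`` (the mean diameter);
* multiscale: a ladder of lengths between ``L_min`` and ``L_max`` (the
  minimum and maximum diameters) with fixed increment ``dL``, whose
  per-voxel responses are combined by taking the maximum.

Filter lengths are supplied by the temporal feedback state: the diameters
estimated on frame t become the lengths used to enhance frame t+1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import Volume


def round_up_odd(x: float) -> int:
    """Round to nearest integer, then up to the next odd integer if even.

    Symmetric discrete kernels need odd support, so even feedback lengths
    are promoted to the next odd value.
    """
    n = int(np.floor(float(x) + 0.5))
    if n % 2 == 0:
        n += 1
    return n


@dataclass(frozen=True)
class FilterConfig:
    """Gaussian filter lengths (voxels) driving the enhancement of one frame.

    ``L_min``/``L_max`` bound the multiscale ladder, ``L_avg`` is the
    single-scale length, ``dL`` the ladder increment and ``w`` the weight
    factor applied to fed-back diameters (1.0 for Gaussian filters).
    """

    L_min: int
    L_max: int
    L_avg: int | None = None
    dL: int = 3
    w: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "L_min", round_up_odd(self.L_min))
        object.__setattr__(self, "L_max", round_up_odd(self.L_max))
        if self.L_avg is not None:
            object.__setattr__(self, "L_avg", round_up_odd(self.L_avg))
        if self.L_min > self.L_max:
            raise ValueError(f"L_min={self.L_min} exceeds L_max={self.L_max}")
        if self.dL < 1:
            raise ValueError(f"dL must be >= 1, got {self.dL}")
        if not (0.0 < self.w <= 1.0):
            raise ValueError(f"w must lie in (0, 1], got {self.w}")

    @property
    def K(self) -> int:
        """Number of ladder scales (excluding an appended cap)."""
        return (self.L_max - self.L_min) // self.dL + 1

    def scales(self) -> list[int]:
        """Ladder of odd filter lengths L_min, L_min+dL, ...; L_max appended
        if the fixed-increment ladder stops short of it."""
        ls = [self.L_min + s * self.dL for s in range(self.K)]
        if ls[-1] < self.L_max:
            ls.append(self.L_max)
        return [round_up_odd(l) for l in ls]

    @property
    def single_length(self) -> int:
        return self.L_avg if self.L_avg is not None else round_up_odd((self.L_min + self.L_max) / 2)


def gaussian_kernel_1d(L: int) -> np.ndarray:
    """Length-L discrete Gaussian, sigma = (L - 1) / 6, normalized to unit sum.

    The support spans ±3 sigma, so the endpoint taps are ~1% of the center.
    """
    L = int(L)
    if L < 3 or L % 2 == 0:
        raise ValueError(f"kernel length must be odd and >= 3, got {L}")
    sigma = (L - 1) / 6.0
    x = np.arange(L, dtype=np.float64) - (L - 1) / 2.0
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def enhance_single(I_c: Volume, L: int) -> Volume:
    """Separable isotropic Gaussian enhancement at one filter length.

    The 1D kernel is applied along x, y and z in turn (edge replication at
    the borders), which equals dense convolution with the 3D outer-product
    kernel.
    """
    L = int(L)
    if L > min(I_c.shape):
        raise ValueError(f"filter length {L} exceeds smallest image dimension {min(I_c.shape)}")
    k = gaussian_kernel_1d(L)
    out = I_c.data.astype(np.float64)
    for axis in range(3):
        out = ndimage.convolve1d(out, k, axis=axis, mode="nearest")
    return Volume(out, I_c.voxel_size, I_c.t)


def scale_weight(L: int, L_ref: int) -> float:
    """Matched-filter weight of scale L relative to the reference scale.

    Responses are computed with unit-sum (mean-preserving) kernels, whose
    amplitude at a blob center decreases with sigma even at the matched
    scale; weighting each response by (sigma / sigma_ref)^(3/2) restores
    unit-energy (matched-filter) comparability, so the voxelwise maximum
    genuinely selects the scale matched to the local object size instead
    of always preferring the smallest scale.
    """
    s = (L - 1) / 6.0
    s_ref = (L_ref - 1) / 6.0
    return (s / s_ref) ** 1.5


def enhance_multiscale(I_c: Volume, cfg: FilterConfig) -> Volume:
    """Voxelwise maximum of matched-filter-weighted responses over the
    ladder of lengths (collapses to ``enhance_single`` when K = 1)."""
    scales = cfg.scales()
    out = None
    for L in scales:
        resp = enhance_single(I_c, L).data * scale_weight(L, scales[0])
        out = resp if out is None else np.maximum(out, resp)
    return Volume(out, I_c.voxel_size, I_c.t)


def enhance(I_c: Volume, cfg: FilterConfig, mode: str = "multi") -> Volume:
    """Dispatch between multiscale and single-scale enhancement."""
    if mode == "multi":
        return enhance_multiscale(I_c, cfg)
    if mode == "single":
        return enhance_single(I_c, cfg.single_length)
    raise ValueError(f"unknown enhancement mode {mode!r}")
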