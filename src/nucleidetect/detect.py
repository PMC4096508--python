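"""Centroid extraction from the enhanced image.

Stage-1 finds local-maxima voxels via the characteristic ratio (the
percentage of 26-neighbors with strictly lower intensity), groups them by
26-connectivity and averages each component into one initial centroid.
Stage-2 keeps only candidates whose intensity profiles along the three
orthogonal axes are concave at the center (true blob peaks).  Stage-3
merges fragmented detections closer than a distance threshold by
single-linkage grouping.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage

from .enhance import round_up_odd
from .image_io import Volume

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class NucleusDetection:
    """One detected nucleus: centroid position plus its estimated size.

    ``position`` may be fractional (component averaging); ``radius`` and
    ``diameter`` are filled by the radial-gradient size optimizer and are 0
    until then.  ``valid`` is cleared when size optimization fails.
    """

    position: tuple[float, float, float]
    label: int = 0
    radius: float = 0.0
    diameter: float = 0.0
    valid: bool = True

    def rounded(self) -> tuple[int, int, int]:
        return tuple(int(np.floor(p + 0.5)) for p in self.position)  # type: ignore[return-value]


@dataclass(frozen=True)
class DetectParams:
    """Thresholds of the three extraction stages.

    tau_r : characteristic-ratio threshold in percent (100 = strict local
        maxima).
    tau_s : minimum fraction of the three orthogonal profiles that must be
        concave at the candidate (default 2/3).
    tau_d : merge distance in voxels; when None it is set per frame to half
        the previous frame's mean diameter.
    profile_length : orthogonal-profile length in voxels; fed back as the
        previous frame's mean diameter.
    """

    tau_r: float = 100.0
    tau_s: float = 2.0 / 3.0
    tau_d: float | None = None
    profile_length: int = 15

    def __post_init__(self) -> None:
        if not (0.0 < self.tau_r <= 100.0):
            raise ValueError(f"tau_r must lie in (0, 100], got {self.tau_r}")
        if self.tau_d is not None and self.tau_d < 0:
            raise ValueError(f"tau_d must be >= 0, got {self.tau_d}")
        if self.profile_length < 3:
            raise ValueError(f"profile_length must be >= 3, got {self.profile_length}")


def characteristic_ratio_maxima(E: Volume, tau_r: float) -> np.ndarray:
    """Boolean grid of voxels passing the characteristic-ratio test.

    The ratio of a voxel is the percentage of its (in-bounds) 26-neighbors
    with strictly lower intensity.  At tau_r = 100 exact plateaus would
    fail the strict test, so a voxel is accepted when it is >= all
    neighbors and > at least one; below 100 the plain ratio threshold
    applies.
    """
    data = E.data.astype(np.float64)
    n_lower = np.zeros(data.shape, dtype=np.int16)
    n_leq = np.zeros(data.shape, dtype=np.int16)
    n_valid = np.zeros(data.shape, dtype=np.int16)
    nx, ny, nz = data.shape
    for dx, dy, dz in itertools.product((-1, 0, 1), repeat=3):
        if dx == dy == dz == 0:
            continue
        src = tuple(slice(max(d, 0), s + min(d, 0)) for d, s in zip((dx, dy, dz), (nx, ny, nz)))
        dst = tuple(slice(max(-d, 0), s + min(-d, 0)) for d, s in zip((dx, dy, dz), (nx, ny, nz)))
        center = data[dst]
        neigh = data[src]
        n_lower[dst] += center > neigh
        n_leq[dst] += center >= neigh
        n_valid[dst] += 1
    if tau_r >= 100.0:
        return (n_leq == n_valid) & (n_lower >= 1)
    ratio = 100.0 * n_lower / n_valid
    return ratio >= tau_r


def stage1_initial_centroids(E: Volume, mask: np.ndarray, tau_r: float = 100.0) -> list[NucleusDetection]:
    """Initial centroids: averaged 26-connected components of maxima voxels."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != E.data.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {E.data.shape}")
    if not mask.any():
        return []
    maxima = characteristic_ratio_maxima(E, tau_r) & mask
    labels, n = ndimage.label(maxima, structure=_STRUCT_26)
    if n == 0:
        return []
    centers = ndimage.center_of_mass(maxima, labels, index=np.arange(1, n + 1))
    return [
        NucleusDetection(position=tuple(float(c) for c in pos), label=i + 1)
        for i, pos in enumerate(centers)
    ]


def _axis_profile(data: np.ndarray, center: tuple[int, int, int], axis: int, length: int):
    """1D intensity profile of ``length`` voxels about ``center`` along an
    axis, clipped to the image bounds.  Returns (profile, center index)."""
    half = length // 2
    c = center[axis]
    lo = max(0, c - half)
    hi = min(data.shape[axis] - 1, c + half)
    if axis == 0:
        prof = data[lo:hi + 1, center[1], center[2]]
    elif axis == 1:
        prof = data[center[0], lo:hi + 1, center[2]]
    else:
        prof = data[center[0], center[1], lo:hi + 1]
    return np.asarray(prof, dtype=np.float64), c - lo


def _profile_concave(prof: np.ndarray, ci: int) -> bool:
    """Concavity check at the profile center: central value >= both
    endpoints (strictly above at least one, so flat plateaus fail) and
    second central difference <= 0."""
    if len(prof) < 3 or ci == 0 or ci == len(prof) - 1:
        return False
    center = prof[ci]
    if center < prof[0] or center < prof[-1]:
        return False
    if not (center > prof[0] or center > prof[-1]):
        return False
    return prof[ci - 1] + prof[ci + 1] - 2.0 * center <= 0.0


def stage2_convexity_filter(
    E: Volume,
    cands: list[NucleusDetection],
    tau_s: float = 2.0 / 3.0,
    profile_length: int = 15,
) -> list[NucleusDetection]:
    """Retain candidates whose orthogonal profiles are concave at the center.

    For each candidate, three profiles of ``profile_length`` voxels are
    extracted along x, y and z (clipped at the image bounds); the candidate
    survives iff at least a fraction ``tau_s`` of the profiles passes the
    concavity test.
    """
    if profile_length < 3:
        raise ValueError(f"profile_length must be >= 3, got {profile_length}")
    length = round_up_odd(profile_length)
    data = E.data.astype(np.float64)
    out = []
    for det in cands:
        c = tuple(np.clip(det.rounded(), 0, np.array(data.shape) - 1))
        n_ok = 0
        for axis in range(3):
            prof, ci = _axis_profile(data, c, axis, length)
            if _profile_concave(prof, ci):
                n_ok += 1
        if n_ok / 3.0 >= tau_s - 1e-12:
            out.append(det)
    return out


def stage3_merge(cands: list[NucleusDetection], tau_d: float) -> list[NucleusDetection]:
    """Merge fragmented detections by single-linkage grouping.

    Groups of candidates whose single-linkage distance is <= tau_d are
    replaced by their unweighted mean position.
    """
    if tau_d < 0:
        raise ValueError(f"tau_d must be >= 0, got {tau_d}")
    if len(cands) <= 1 or tau_d == 0:
        return list(cands)
    pos = np.array([d.position for d in cands], dtype=np.float64)
    Z = linkage(pos, method="single")
    groups = fcluster(Z, t=tau_d, criterion="distance")
    out = []
    for label in np.unique(groups):
        members = pos[groups == label]
        out.append(NucleusDetection(position=tuple(members.mean(axis=0)), label=int(label)))
    return out
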