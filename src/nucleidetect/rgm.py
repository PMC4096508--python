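"""Radial-gradient-magnitude (RGM) nucleus sizing and temporal feedback.

Nuclei are modelled as bright spheres.  Around each candidate centroid two
radial functions are computed on the enhanced image: F(r), the mean
intensity inside the concentric sphere of radius r, and A(r), the mean
intensity of the annulus between r-1 and r.  Their absolute difference
RGM(r) = |F(r) - A(r)| rises from the center, peaks at the object
boundary, then decays; the argmax radius estimates the nucleus radius and
the diameter is D = 2 * r_opt.

The minimum/maximum/mean diameters of the retained nuclei of frame t are
fed back as the Gaussian filter lengths enhancing frame t+1, which is what
makes the whole method self-calibrating with respect to object size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .detect import DetectParams, NucleusDetection
from .enhance import FilterConfig, round_up_odd
from .image_io import Volume

DEFAULT_SIZE_THRESHOLD = 10.0  # voxels, on the diameter
DEFAULT_RMAX_FACTOR = 1.5


@dataclass
class RGMProfile:
    """Radial profile of one candidate: F, A and RGM per integer radius."""

    r: np.ndarray       # integer radii 1..r_max
    F: np.ndarray       # mean intensity within sphere of radius r
    A: np.ndarray       # mean intensity of annulus (r-1, r]
    rgm: np.ndarray     # |F - A|
    Ns: np.ndarray      # voxel count of each sphere
    Na: np.ndarray      # voxel count of each annulus


@dataclass(frozen=True)
class FeedbackState:
    """Diameter statistics of one frame, the payload fed to frame t+1."""

    D_min: float
    D_max: float
    D_mean: float
    T_s: float = DEFAULT_SIZE_THRESHOLD
    frame_index: int = 0
    n_retained: int = 0

    def __post_init__(self) -> None:
        if self.n_retained and not (self.D_min <= self.D_mean <= self.D_max):
            raise ValueError(
                f"inconsistent diameter stats: {self.D_min}, {self.D_mean}, {self.D_max}"
            )
        if self.T_s <= 0:
            raise ValueError(f"T_s must be > 0, got {self.T_s}")


def rgm_profile(E: Volume, center: tuple[float, float, float], r_max: int) -> RGMProfile:
    """Compute F, A and RGM for integer radii 1..r_max about a centroid.

    The center is rounded to the voxel lattice; voxels outside the image
    are excluded from every mean.  Shell membership uses the Euclidean
    distance d to the center: sphere(r) is d <= r, annulus(r) is
    r-1 < d <= r.
    """
    r_max = int(r_max)
    if r_max < 2:
        raise ValueError(f"r_max must be >= 2, got {r_max}")
    data = E.data
    cx, cy, cz = (int(np.floor(c + 0.5)) for c in center)
    nx, ny, nz = data.shape
    if not (0 <= cx < nx and 0 <= cy < ny and 0 <= cz < nz):
        raise ValueError(f"center {center} outside image of shape {data.shape}")
    x0, x1 = max(0, cx - r_max), min(nx, cx + r_max + 1)
    y0, y1 = max(0, cy - r_max), min(ny, cy + r_max + 1)
    z0, z1 = max(0, cz - r_max), min(nz, cz + r_max + 1)
    box = np.asarray(data[x0:x1, y0:y1, z0:z1], dtype=np.float64)
    gx, gy, gz = np.meshgrid(
        np.arange(x0, x1) - cx, np.arange(y0, y1) - cy, np.arange(z0, z1) - cz,
        indexing="ij",
    )
    d = np.sqrt(gx**2 + gy**2 + gz**2)
    shell = np.ceil(d).astype(np.int64).ravel()  # center voxel -> shell 0
    within = shell <= r_max
    shell = shell[within]
    vals = box.ravel()[within]

    counts = np.bincount(shell, minlength=r_max + 1).astype(np.float64)
    sums = np.bincount(shell, weights=vals, minlength=r_max + 1)
    cum_counts = np.cumsum(counts)
    cum_sums = np.cumsum(sums)

    r = np.arange(1, r_max + 1)
    Ns = cum_counts[1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        F = np.where(Ns > 0, cum_sums[1:] / Ns, 0.0)
        A = np.where(counts[1:] > 0, sums[1:] / counts[1:], 0.0)
    rgm = np.abs(F - A)
    return RGMProfile(r=r, F=F, A=A, rgm=rgm, Ns=Ns.astype(np.int64), Na=counts[1:].astype(np.int64))


def optimal_radius(p: RGMProfile) -> int:
    """Optimal radius: the inner radius of the annulus maximizing RGM.

    RGM(r) compares the annulus (r-1, r] against the sphere of radius r;
    when it peaks, r-1 bounds the object surface while r already lies in
    the background, so the inner radius r-1 of the maximizing annulus is
    returned (ties broken to the smallest r).  On an ideal binary sphere
    of radius R the maximizing annulus is (R, R+1] and the estimate is
    exactly R.  An all-zero profile carries no boundary information and
    yields 0 (flagged invalid by the caller).
    """
    if p.rgm.size == 0:
        raise ValueError("empty RGM profile")
    if not np.any(p.rgm > 0):
        return 0
    return int(p.r[int(np.argmax(p.rgm))]) - 1


def size_detections(
    E: Volume,
    dets: list[NucleusDetection],
    r_max: int,
) -> list[NucleusDetection]:
    """Fill radius/diameter of each detection by RGM optimization on E.

    The per-detection search range is capped by the distance to the
    nearest image border.
    """
    out = []
    nx, ny, nz = E.shape
    for det in dets:
        cx, cy, cz = det.rounded()
        border = min(cx, nx - 1 - cx, cy, ny - 1 - cy, cz, nz - 1 - cz)
        rm = max(2, min(int(r_max), border)) if border >= 1 else 2
        prof = rgm_profile(E, det.position, rm)
        r_opt = optimal_radius(prof)
        out.append(replace(det, radius=float(r_opt), diameter=2.0 * r_opt, valid=r_opt > 0))
    return out


def eliminate_spurious(
    dets: list[NucleusDetection], T_s: float = DEFAULT_SIZE_THRESHOLD
) -> list[NucleusDetection]:
    """Drop detections with estimated diameter below the minimum size
    threshold (boundary inclusive: D >= T_s is retained)."""
    return [d for d in dets if d.valid and d.diameter >= T_s]


def feedback_params(
    dets: list[NucleusDetection],
    prev_cfg: FilterConfig,
    prev_dp: DetectParams,
    frame_index: int = 0,
    T_s: float = DEFAULT_SIZE_THRESHOLD,
) -> tuple[FeedbackState, FilterConfig, DetectParams]:
    """Diameter statistics of the retained nuclei and the derived
    filter/detection parameters for the next frame.

    Multiscale lengths: L_min = w * D_min, L_max = w * D_max (odd-rounded);
    single-scale length: L_avg = w * D_mean.  The profile length of the
    Stage-2 convexity test becomes D_mean and the merge distance tau_d half
    of it.  With zero retained detections the previous parameters are
    carried forward unchanged.
    """
    if not dets:
        warnings.warn(
            f"frame {frame_index}: no retained detections; carrying previous "
            "filter parameters forward", stacklevel=2,
        )
        state = FeedbackState(0.0, 0.0, 0.0, T_s=T_s, frame_index=frame_index, n_retained=0)
        return state, prev_cfg, prev_dp
    diam = np.array([d.diameter for d in dets], dtype=np.float64)
    w = prev_cfg.w
    state = FeedbackState(
        D_min=float(diam.min()),
        D_max=float(diam.max()),
        D_mean=float(diam.mean()),
        T_s=T_s,
        frame_index=frame_index,
        n_retained=len(dets),
    )
    cfg = FilterConfig(
        L_min=round_up_odd(w * state.D_min),
        L_max=round_up_odd(w * state.D_max),
        L_avg=round_up_odd(w * state.D_mean),
        dL=prev_cfg.dL,
        w=w,
    )
    dp = replace(
        prev_dp,
        profile_length=max(3, round_up_odd(state.D_mean)),
        tau_d=state.D_mean / 2.0,
    )
    return state, cfg, dp
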