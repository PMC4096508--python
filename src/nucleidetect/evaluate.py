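"""Detection scoring and the robustness harnesses.

Scoring follows the ground-truth-centric protocol: a spherical window of
radius ``d_eval`` (10 voxels by default) is centered at each GT centroid;
the closest unconsumed estimated centroid inside the window counts as a
true positive, each estimate matching at most one GT.  Sensitivity,
precision and F-measure follow from TP, FP = n_est - TP and
FN = n_gt - TP.

The robustness harnesses rerun the pipeline over a grid of initial filter
lengths (parameter sweep) or over a ladder of additive-Gaussian-noise
levels (noise sweep) and tabulate the scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detect import DetectParams, NucleusDetection
from .enhance import FilterConfig
from .image_io import Volume
from .pipeline import FrameResult, Variant, process_frame, process_sequence

DEFAULT_EVAL_DISTANCE = 10.0


@dataclass(frozen=True)
class DetectionScore:
    """TP/FP/FN counts and the derived detection metrics of one frame."""

    TP: int
    FP: int
    FN: int

    @property
    def sensitivity(self) -> float:
        d = self.TP + self.FN
        return self.TP / d if d else 0.0

    @property
    def precision(self) -> float:
        d = self.TP + self.FP
        return self.TP / d if d else 0.0

    @property
    def f_measure(self) -> float:
        se, pr = self.sensitivity, self.precision
        return 2.0 * se * pr / (se + pr) if (se + pr) > 0 else 0.0


def _positions(est) -> np.ndarray:
    if len(est) == 0:
        return np.empty((0, 3))
    if isinstance(est[0], NucleusDetection):
        return np.array([d.position for d in est], dtype=np.float64)
    return np.asarray(est, dtype=np.float64).reshape(len(est), 3)


def _gt_positions(gt) -> np.ndarray:
    if isinstance(gt, pd.DataFrame):
        if len(gt) == 0:
            return np.empty((0, 3))
        return gt[["x", "y", "z"]].to_numpy(dtype=np.float64)
    arr = np.asarray(gt, dtype=np.float64)
    return arr.reshape(len(arr), 3)


def score_frame(est, gt, d_eval: float = DEFAULT_EVAL_DISTANCE) -> DetectionScore:
    """Score estimated centroids against ground truth for one frame.

    ``est`` is a list of detections or an (n, 3) array; ``gt`` a centroid
    DataFrame (columns x, y, z) or an (m, 3) array.  GT centroids are
    visited in ascending index order; each takes the nearest unconsumed
    estimate within ``d_eval`` (ties to the lowest estimate index).
    """
    if d_eval <= 0:
        raise ValueError(f"d_eval must be > 0, got {d_eval}")
    pe = _positions(est)
    pg = _gt_positions(gt)
    used = np.zeros(len(pe), dtype=bool)
    tp = 0
    for g in pg:
        if len(pe) == 0:
            break
        d = np.sqrt(((pe - g) ** 2).sum(axis=1))
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= d_eval:
            used[j] = True
            tp += 1
    return DetectionScore(TP=tp, FP=len(pe) - tp, FN=len(pg) - tp)


def mean_f_measure(results: list[FrameResult], gts: list[pd.DataFrame],
                   d_eval: float = DEFAULT_EVAL_DISTANCE) -> float:
    """Time-averaged F-measure of a processed sequence."""
    return float(np.mean([
        score_frame(fr.detections, gt, d_eval).f_measure
        for fr, gt in zip(results, gts)
    ]))


def add_noise(v: Volume, sigma_n: float, seed: int = 0) -> tuple[Volume, float]:
    """Additive white Gaussian noise at spread ``sigma_n``.

    Returns the noisy volume (clipped to non-negative intensities) and the
    realized SNR in dB: 10 log10(mean(v^2) / sigma_n^2), the clean-image
    mean square power over the noise variance.
    """
    if sigma_n <= 0:
        raise ValueError(f"sigma_n must be > 0, got {sigma_n}")
    rng = np.random.default_rng(seed)
    clean = v.data.astype(np.float64)
    noisy = clean + rng.normal(0.0, sigma_n, clean.shape)
    noisy = np.clip(noisy, 0.0, None)
    snr_db = 10.0 * np.log10(np.mean(clean**2) / sigma_n**2)
    return Volume(noisy, v.voxel_size, v.t), float(snr_db)


def default_parameter_grid(multiscale: bool = True) -> list:
    """The standard sweep grid: L_min 5..50 step 5, with L_max = L_min + 12
    for multiscale; bare lengths 5..50 for single-scale."""
    lmins = list(range(5, 51, 5))
    if multiscale:
        return [(l, l + 12) for l in lmins]
    return lmins


def parameter_sweep(
    frames: list[Volume],
    gts: list[pd.DataFrame],
    grid: list,
    variant: Variant | str = Variant.proposed,
    *,
    feedback: bool = True,
    dL: int = 3,
    d_eval: float = DEFAULT_EVAL_DISTANCE,
    dp0: DetectParams | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Run the sequence once per initial filter setting; tidy score table.

    ``grid`` entries are (L_min, L_max) pairs for multiscale variants or
    bare lengths for single-scale ones.  Columns: setting, frame, TP, FP,
    FN, sensitivity, precision, f_measure.
    """
    variant = Variant(variant)
    rows = []
    for setting in grid:
        if variant.multiscale:
            lmin, lmax = setting
            cfg0 = FilterConfig(L_min=lmin, L_max=lmax, dL=dL)
        else:
            cfg0 = FilterConfig(L_min=setting, L_max=setting, L_avg=setting, dL=dL)
        results = process_sequence(frames, cfg0, dp0, variant, feedback=feedback, **kwargs)
        for fr, gt in zip(results, gts):
            s = score_frame(fr.detections, gt, d_eval)
            rows.append(dict(
                setting=str(setting), frame=fr.t, TP=s.TP, FP=s.FP, FN=s.FN,
                sensitivity=s.sensitivity, precision=s.precision,
                f_measure=s.f_measure,
            ))
    return pd.DataFrame(rows)


def noise_sweep(
    v: Volume,
    gt: pd.DataFrame,
    sigmas: list[float],
    cfg0: FilterConfig,
    variant: Variant | str = Variant.proposed,
    *,
    feedback: bool = True,
    d_eval: float = DEFAULT_EVAL_DISTANCE,
    dp0: DetectParams | None = None,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Detection counts of one frame under increasing additive noise.

    The clean frame stands in for the tail of a long recording: when
    feedback is enabled it is processed once first so the filter lengths
    are the self-calibrated ones (as they would be by this stage of a
    sequence), and the estimates then keep adapting from one noise level
    to the next.  The non-adaptive baseline keeps ``cfg0`` throughout.
    Columns: sigma, snr_db, n_detected, TP, FP, FN, sensitivity,
    precision, f_measure.
    """
    variant = Variant(variant)
    dp = dp0 or DetectParams()
    cfg = cfg0
    if feedback:
        # the clean frame stands in for the long adapted recording that
        # precedes it: iterate the feedback loop on it until the filter
        # lengths stop changing (a few passes at most)
        for _ in range(5):
            warm = process_frame(v, cfg, dp, variant, feedback=True, **kwargs)
            if not warm.feedback.n_retained:
                break
            new_cfg, new_dp = warm.next_config, warm.next_params
            if (new_cfg.L_min, new_cfg.L_max) == (cfg.L_min, cfg.L_max):
                cfg, dp = new_cfg, new_dp
                break
            cfg, dp = new_cfg, new_dp
    rows = []
    for k, sigma in enumerate(sigmas):
        noisy, snr_db = add_noise(v, sigma, seed=(seed, 5, k))
        fr = process_frame(noisy, cfg, dp, variant, feedback=feedback, **kwargs)
        if feedback and fr.feedback.n_retained:
            cfg, dp = fr.next_config, fr.next_params
        s = score_frame(fr.detections, gt, d_eval)
        rows.append(dict(
            sigma=sigma, snr_db=snr_db, n_detected=len(fr.detections),
            TP=s.TP, FP=s.FP, FN=s.FN, sensitivity=s.sensitivity,
            precision=s.precision, f_measure=s.f_measure,
        ))
    return pd.DataFrame(rows)
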