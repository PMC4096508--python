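"""Frame-to-frame nearest-neighbor association of detections.

Detections of consecutive frames are linked greedily by ascending pairwise
Euclidean distance; each detection is used at most once and links longer
than a distance threshold (25 voxels by default, roughly the inter-frame
nuclear displacement bound in early embryos) are rejected.  Chains of
links form nuclear trajectories; the population is assumed fixed (no
division handling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .detect import NucleusDetection
from .pipeline import FrameResult

DEFAULT_LINK_DISTANCE = 25.0


@dataclass
class TrackSet:
    """Per-nucleus chains of (frame, detection index, position)."""

    tracks: list[list[tuple[int, int, tuple[float, float, float]]]]
    distance_threshold: float = DEFAULT_LINK_DISTANCE

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for ti, chain in enumerate(self.tracks):
            for t, _idx, pos in chain:
                rows.append(dict(track_id=ti + 1, t=t, x=pos[0], y=pos[1], z=pos[2]))
        return pd.DataFrame(rows, columns=["track_id", "t", "x", "y", "z"])


def link_frames(
    a: list[NucleusDetection],
    b: list[NucleusDetection],
    d_max: float = DEFAULT_LINK_DISTANCE,
) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of detections by ascending distance.

    Returns index pairs (i, j) with ``a[i]`` linked to ``b[j]``; pairs
    farther apart than ``d_max`` are never formed.
    """
    if d_max <= 0:
        raise ValueError(f"d_max must be > 0, got {d_max}")
    if not a or not b:
        return []
    pa = np.array([d.position for d in a], dtype=np.float64)
    pb = np.array([d.position for d in b], dtype=np.float64)
    dist = cdist(pa, pb)
    order = np.argsort(dist, axis=None, kind="stable")
    used_a = np.zeros(len(a), dtype=bool)
    used_b = np.zeros(len(b), dtype=bool)
    pairs: list[tuple[int, int]] = []
    for flat in order:
        i, j = divmod(int(flat), len(b))
        if dist[i, j] > d_max:
            break
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = used_b[j] = True
        pairs.append((i, j))
    return pairs


def build_tracks(
    results: list[FrameResult],
    d_max: float = DEFAULT_LINK_DISTANCE,
) -> TrackSet:
    """Chain consecutive-frame links into trajectories.

    Unmatched detections start new tracks; a detection that finds no
    partner in the next frame ends its track.
    """
    tracks: list[list[tuple[int, int, tuple[float, float, float]]]] = []
    open_by_det: dict[int, int] = {}  # detection index in current frame -> track index
    for k, fr in enumerate(results):
        dets = fr.detections
        if k == 0:
            for i, d in enumerate(dets):
                tracks.append([(fr.t, i, d.position)])
                open_by_det[i] = len(tracks) - 1
            continue
        prev = results[k - 1]
        pairs = link_frames(prev.detections, dets, d_max)
        new_open: dict[int, int] = {}
        matched_b = set()
        for i, j in pairs:
            ti = open_by_det.get(i)
            if ti is None:  # previous detection was itself unmatched earlier
                tracks.append([(prev.t, i, prev.detections[i].position)])
                ti = len(tracks) - 1
            tracks[ti].append((fr.t, j, dets[j].position))
            new_open[j] = ti
            matched_b.add(j)
        for j, d in enumerate(dets):
            if j not in matched_b:
                tracks.append([(fr.t, j, d.position)])
                new_open[j] = len(tracks) - 1
        open_by_det = new_open
    return TrackSet(tracks=tracks, distance_threshold=d_max)
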