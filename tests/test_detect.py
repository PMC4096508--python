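import numpy as np
import pytest

from nucleidetect import detect, enhance
from nucleidetect.detect import DetectParams, NucleusDetection
from nucleidetect.image_io import Volume

from conftest import make_multi_sphere_volume, make_sphere_volume


def enhanced_spheres(centers, radii, n=64):
    v = make_multi_sphere_volume(centers, radii, n=n, background=0.0)
    mask = v.data > 50.0
    E = enhance.enhance_single(Volume(v.data * mask), 9)
    return E, mask


class TestStage1:
    def test_single_sphere_yields_one_centroid(self):
        E, mask = enhanced_spheres([(24, 24, 24)], [8], n=48)
        dets = detect.stage1_initial_centroids(E, mask)
        assert len(dets) == 1
        assert np.linalg.norm(np.array(dets[0].position) - 24.0) <= 1.0

    def test_two_separated_spheres_yield_two(self):
        E, mask = enhanced_spheres([(18, 18, 18), (46, 46, 40)], [7, 8], n=64)
        dets = detect.stage1_initial_centroids(E, mask)
        assert len(dets) == 2

    def test_constant_masked_region_has_no_maxima(self):
        E = Volume(np.full((10, 10, 10), 5.0))
        mask = np.ones((10, 10, 10), bool)
        assert detect.stage1_initial_centroids(E, mask, tau_r=100.0) == []

    def test_empty_mask_gives_empty_list(self):
        E = Volume(np.random.default_rng(0).random((8, 8, 8)))
        assert detect.stage1_initial_centroids(E, np.zeros((8, 8, 8), bool)) == []

    def test_plateau_tie_break_accepts_single_component(self):
        # a 2-voxel plateau strictly above its surroundings survives as one cluster
        data = np.zeros((9, 9, 9))
        data[4, 4, 4] = data[4, 4, 5] = 10.0
        dets = detect.stage1_initial_centroids(
            Volume(data), np.ones((9, 9, 9), bool), tau_r=100.0)
        assert len(dets) == 1
        assert dets[0].position[2] == pytest.approx(4.5)

    def test_ratio_threshold_below_100_relaxes(self):
        # center voxel higher than 25 of its 26 neighbors: fails at 100, passes at 90
        data = np.zeros((7, 7, 7))
        data[3, 3, 3] = 10.0
        data[3, 3, 4] = 10.0  # one equal neighbor
        data[3, 3, 2] = 12.0  # make the other voxel non-maximal
        m = np.ones((7, 7, 7), bool)
        at100 = detect.characteristic_ratio_maxima(Volume(data), 100.0)
        at90 = detect.characteristic_ratio_maxima(Volume(data), 90.0)
        assert not at100[3, 3, 3]
        assert at90[3, 3, 3]


class TestStage2:
    def test_true_sphere_center_retained_and_plateau_rejected(self):
        E, mask = enhanced_spheres([(24, 24, 24)], [8], n=48)
        good = NucleusDetection(position=(24.0, 24.0, 24.0))
        flat = NucleusDetection(position=(5.0, 5.0, 5.0))  # background corner
        kept = detect.stage2_convexity_filter(E, [good, flat], tau_s=2 / 3, profile_length=15)
        assert kept == [good]

    def test_empty_candidate_list(self):
        E = Volume(np.zeros((8, 8, 8)))
        assert detect.stage2_convexity_filter(E, [], 2 / 3, 9) == []

    def test_profile_clipped_at_bounds(self):
        # centroid near the border must not raise
        E, mask = enhanced_spheres([(7, 24, 24)], [6], n=48)
        det_near_edge = NucleusDetection(position=(7.0, 24.0, 24.0))
        kept = detect.stage2_convexity_filter(E, [det_near_edge], 2 / 3, 21)
        assert kept  # still a concave peak

    def test_never_increases_count(self, rng):
        E = Volume(rng.random((16, 16, 16)))
        cands = [NucleusDetection(position=tuple(p)) for p in rng.random((10, 3)) * 15]
        kept = detect.stage2_convexity_filter(E, cands, 2 / 3, 9)
        assert len(kept) <= len(cands)


def brute_force_single_linkage(points, tau):
    """Reference grouping: transitive closure of the <=tau relation."""
    n = len(points)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(points[i] - points[j]) <= tau:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(sorted(g) for g in groups.values())


class TestStage3:
    def test_close_pair_merged_to_midpoint(self):
        a = NucleusDetection(position=(10.0, 10.0, 10.0))
        b = NucleusDetection(position=(12.0, 10.0, 10.0))
        out = detect.stage3_merge([a, b], tau_d=5.0)
        assert len(out) == 1
        assert out[0].position == pytest.approx((11.0, 10.0, 10.0))

    def test_distant_pair_kept(self):
        a = NucleusDetection(position=(0.0, 0.0, 0.0))
        b = NucleusDetection(position=(20.0, 0.0, 0.0))
        assert len(detect.stage3_merge([a, b], tau_d=5.0)) == 2

    def test_chain_merges_by_single_linkage(self):
        # a-b and b-c each exactly tau apart: one merged centroid
        pts = [(0.0, 0, 0), (5.0, 0, 0), (10.0, 0, 0)]
        dets = [NucleusDetection(position=p) for p in pts]
        out = detect.stage3_merge(dets, tau_d=5.0)
        assert len(out) == 1
        assert out[0].position[0] == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_grouping(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.random((12, 3)) * 30
        dets = [NucleusDetection(position=tuple(p)) for p in pts]
        tau = 6.0
        merged = detect.stage3_merge(dets, tau)
        expected_groups = brute_force_single_linkage(pts, tau)
        assert len(merged) == len(expected_groups)
        got = sorted(tuple(np.round(d.position, 6)) for d in merged)
        want = sorted(tuple(np.round(pts[g].mean(axis=0), 6)) for g in expected_groups)
        assert got == want

    def test_never_increases_count(self, rng):
        pts = rng.random((8, 3)) * 20
        dets = [NucleusDetection(position=tuple(p)) for p in pts]
        assert len(detect.stage3_merge(dets, 4.0)) <= 8


class TestDetectParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            DetectParams(tau_r=0.0)
        with pytest.raises(ValueError):
            DetectParams(tau_d=-1.0)
        with pytest.raises(ValueError):
            DetectParams(profile_length=2)
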