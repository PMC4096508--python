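import numpy as np
import pytest

from nucleidetect import rgm
from nucleidetect.detect import DetectParams, NucleusDetection
from nucleidetect.enhance import FilterConfig
from nucleidetect.image_io import Volume
from nucleidetect.rgm import RGMProfile

from conftest import make_sphere_volume


def brute_force_fa(data, center, r_max):
    """Per-voxel distance classification oracle for F(r) and A(r)."""
    nx, ny, nz = data.shape
    F, A = [], []
    cx, cy, cz = center
    d = np.sqrt(
        (np.arange(nx)[:, None, None] - cx) ** 2
        + (np.arange(ny)[None, :, None] - cy) ** 2
        + (np.arange(nz)[None, None, :] - cz) ** 2
    )
    for r in range(1, r_max + 1):
        sphere = d <= r
        annulus = (d > r - 1) & (d <= r)
        F.append(data[sphere].mean())
        A.append(data[annulus].mean() if annulus.any() else 0.0)
    return np.array(F), np.array(A)


class TestRGMProfile:
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_classification(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.random((15, 15, 15)) * 100
        center = tuple(rng.integers(4, 11, 3))
        p = rgm.rgm_profile(Volume(data), center, r_max=5)
        F, A = brute_force_fa(data, center, 5)
        np.testing.assert_allclose(p.F, F, rtol=1e-12)
        np.testing.assert_allclose(p.A, A, rtol=1e-12)
        np.testing.assert_allclose(p.rgm, np.abs(F - A), rtol=1e-12)

    def test_ideal_sphere_peaks_at_boundary_annulus(self):
        v, c = make_sphere_volume(8, n=40)
        p = rgm.rgm_profile(v, c, r_max=16)
        peak_annulus = int(p.r[np.argmax(p.rgm)])
        assert peak_annulus in (8, 9)
        # RGM rises from the center to the boundary region
        assert p.rgm[0] < p.rgm.max()

    def test_constant_volume_is_all_zero(self):
        p = rgm.rgm_profile(Volume(np.full((15, 15, 15), 9.0)), (7, 7, 7), 5)
        np.testing.assert_allclose(p.rgm, 0.0, atol=1e-12)

    def test_counts_monotone_and_annuli_nonempty(self):
        p = rgm.rgm_profile(Volume(np.zeros((21, 21, 21))), (10, 10, 10), 8)
        assert np.all(np.diff(p.Ns) > 0)
        assert np.all(p.Na >= 1)

    def test_border_voxels_excluded(self):
        # center at the corner: means are still well defined
        v, _ = make_sphere_volume(5, n=20, center=(2, 2, 2))
        p = rgm.rgm_profile(v, (2, 2, 2), 6)
        assert np.all(np.isfinite(p.F))

    def test_invalid_inputs(self):
        v = Volume(np.zeros((9, 9, 9)))
        with pytest.raises(ValueError):
            rgm.rgm_profile(v, (4, 4, 4), 0)
        with pytest.raises(ValueError):
            rgm.rgm_profile(v, (20, 4, 4), 3)


class TestOptimalRadius:
    def test_ideal_sphere_radius_recovered_exactly(self):
        for R in (5, 8, 11):
            v, c = make_sphere_volume(R, n=2 * R + 16)
            p = rgm.rgm_profile(v, c, r_max=R + 6)
            assert rgm.optimal_radius(p) == R

    def test_tie_broken_to_smallest(self):
        prof = RGMProfile(
            r=np.arange(1, 6), F=np.zeros(5), A=np.zeros(5),
            rgm=np.array([0.0, 1.0, 3.0, 3.0, 1.0]),
            Ns=np.arange(1, 6), Na=np.ones(5),
        )
        assert rgm.optimal_radius(prof) == 2  # annulus 3 wins the tie, inner radius 2

    def test_all_zero_profile_flags_invalid(self):
        prof = RGMProfile(
            r=np.arange(1, 4), F=np.zeros(3), A=np.zeros(3),
            rgm=np.zeros(3), Ns=np.arange(1, 4), Na=np.ones(3),
        )
        assert rgm.optimal_radius(prof) == 0

    def test_noisy_enhanced_sphere_within_one_voxel(self):
        from nucleidetect import candidate, enhance

        hits = 0
        for seed in range(10):
            v, c = make_sphere_volume(6, n=36, soft=True, background=20,
                                      peak=180, noise=0.10, seed=seed)
            mask = candidate.candidate_mask(v)
            ic = candidate.candidate_image(v, mask)
            E = enhance.enhance_multiscale(ic, FilterConfig(9, 15))
            Ec = Volume(E.data * mask)
            p = rgm.rgm_profile(Ec, tuple(int(x) for x in c), 12)
            if abs(rgm.optimal_radius(p) - 6) <= 1:
                hits += 1
        assert hits >= 9


class TestEliminateSpurious:
    def _det(self, D):
        return NucleusDetection(position=(5, 5, 5), diameter=D, radius=D / 2, valid=D > 0)

    def test_small_removed_boundary_retained(self):
        dets = [self._det(4), self._det(10), self._det(16)]
        out = rgm.eliminate_spurious(dets, T_s=10)
        assert [d.diameter for d in out] == [10, 16]

    def test_empty_list(self):
        assert rgm.eliminate_spurious([], 10) == []

    def test_monotone_in_threshold(self):
        dets = [self._det(D) for D in (4, 8, 10, 12, 20)]
        for lo, hi in [(4, 8), (8, 12), (12, 25)]:
            assert len(rgm.eliminate_spurious(dets, hi)) <= len(rgm.eliminate_spurious(dets, lo))


class TestFeedbackParams:
    def _dets(self, diams):
        return [NucleusDetection(position=(0, 0, 0), diameter=d, radius=d / 2) for d in diams]

    def test_min_max_become_filter_lengths(self):
        state, cfg, dp = rgm.feedback_params(
            self._dets([11, 20, 31]), FilterConfig(5, 17), DetectParams())
        assert (state.D_min, state.D_max) == (11, 31)
        assert (cfg.L_min, cfg.L_max) == (11, 31)

    def test_single_detection_collapses_lengths(self):
        state, cfg, _ = rgm.feedback_params(
            self._dets([15]), FilterConfig(5, 17), DetectParams())
        assert cfg.L_min == cfg.L_max == cfg.L_avg == 15

    def test_weight_half_with_odd_rounding(self):
        state, cfg, _ = rgm.feedback_params(
            self._dets([12, 20]), FilterConfig(5, 17, w=0.5), DetectParams())
        assert (cfg.L_min, cfg.L_max) == (7, 11)  # 6 -> 7, 10 -> 11

    def test_zero_retained_carries_previous(self):
        prev_cfg = FilterConfig(9, 21)
        prev_dp = DetectParams(profile_length=13)
        with pytest.warns(UserWarning):
            state, cfg, dp = rgm.feedback_params([], prev_cfg, prev_dp, frame_index=4)
        assert cfg is prev_cfg and dp is prev_dp
        assert state.n_retained == 0

    def test_profile_length_follows_mean_diameter(self):
        _, _, dp = rgm.feedback_params(
            self._dets([14, 18]), FilterConfig(5, 17), DetectParams())
        assert dp.profile_length == 17  # round_up_odd(16)
        assert dp.tau_d == pytest.approx(8.0)

    def test_state_invariants(self):
        with pytest.raises(ValueError):
            rgm.FeedbackState(D_min=10, D_max=5, D_mean=7, n_retained=2)
        with pytest.raises(ValueError):
            rgm.FeedbackState(D_min=1, D_max=2, D_mean=1.5, T_s=0)
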