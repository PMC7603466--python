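"""Synthetic textures, patch pairs and sequences: exact ground truth by construction."""

import numpy as np
import pytest

from fetomosaic import (
    ArtifactConfig,
    FeatureEstimator,
    TrajectorySpec,
    apply_homography,
    compose_relative,
    decompose,
    fourpt_to_matrix,
    generate_controlled_pair,
    generate_perturbed_pair,
    generate_sequence,
    generate_texture,
    photometric_error,
    rigid_matrix,
)
from fetomosaic.synth import PlacementError, TrajectoryError, sample_patch


class TestTexture:
    def test_zero_density_zero_contrast_is_constant(self):
        tex = generate_texture(64, 64, vessel_density=0, contrast=0,
                               rng=np.random.default_rng(0))
        assert np.ptp(tex) == 0.0

    def test_deterministic_per_seed(self):
        a = generate_texture(128, 128, rng=np.random.default_rng(7))
        b = generate_texture(128, 128, rng=np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_range_and_structure(self):
        tex = generate_texture(256, 256, rng=np.random.default_rng(1))
        assert tex.min() >= 0.0 and tex.max() <= 1.0
        assert tex.std() > 0.02  # visible structure

    def test_invalid_dimensions(self):
        with pytest.raises(ValueError):
            generate_texture(0, 10)

    def test_registrable_by_feature_estimator(self, texture256):
        # a known rigid shift between two crops must be recoverable
        shift = (8.0, -5.0)
        h = rigid_matrix(0.0, *shift)
        pa = texture256[50:178, 40:168]
        pb = sample_patch(texture256, h, (40, 50), 128)
        fp = FeatureEstimator(seed=0).estimate(pa, pb)
        err = np.abs(fp.displacements - np.array(shift)).max()
        assert np.median(np.abs(fp.displacements - np.array(shift))) < 0.5, err


class TestControlledPair:
    def test_zero_transform_gives_identical_patches(self, texture256):
        pair = generate_controlled_pair(texture256, beta_range_deg=(0, 0),
                                        d_range_px=(0, 0), rng=np.random.default_rng(0))
        np.testing.assert_allclose(pair.patch_b, pair.patch_a, atol=1e-12)
        np.testing.assert_array_equal(pair.gt.displacements, 0.0)

    def test_pure_translation_displacements(self, texture256):
        pair = generate_controlled_pair(texture256, beta_range_deg=(0, 0),
                                        d_range_px=(16, 16), rng=np.random.default_rng(1))
        np.testing.assert_allclose(pair.gt.du, 16.0)
        np.testing.assert_allclose(pair.gt.dv, 16.0)
        # patch_b is the exactly shifted resampling of the source
        oy = int(pair.gt.corners[0, 1])
        ox = int(pair.gt.corners[0, 0])
        np.testing.assert_allclose(
            pair.patch_b, texture256[oy + 16 : oy + 144, ox + 16 : ox + 144], atol=1e-12)

    def test_corner_map_matches_rigid_formula(self, texture256):
        # every displaced corner must equal R(beta) c + d for the sampled
        # (beta, d), recovered from the pair's own ground truth
        pair = generate_controlled_pair(texture256, rng=np.random.default_rng(2))
        d = decompose(fourpt_to_matrix(pair.gt))
        h = rigid_matrix(d.theta, d.t_x, d.t_y)
        expected = apply_homography(h, pair.gt.corners)
        np.testing.assert_allclose(pair.gt.displaced_corners, expected, atol=1e-8)

    def test_no_scale_or_shear_in_gt(self, texture256):
        # the controlled model is rigid: decomposition gives unit scales
        # and no second rotation
        for i in range(20):
            pair = generate_controlled_pair(texture256, rng=np.random.default_rng(i))
            d = decompose(fourpt_to_matrix(pair.gt))
            assert abs(d.s_g - 1) < 1e-10 and abs(d.s_h - 1) < 1e-10
            assert abs(d.gamma) < 1e-10

    def test_deterministic_per_seed(self, texture256):
        a = generate_controlled_pair(texture256, rng=np.random.default_rng(3))
        b = generate_controlled_pair(texture256, rng=np.random.default_rng(3))
        np.testing.assert_array_equal(a.patch_b, b.patch_b)
        np.testing.assert_array_equal(a.gt.displacements, b.gt.displacements)

    def test_placement_error_when_transform_too_large(self, texture256):
        with pytest.raises(PlacementError):
            generate_controlled_pair(texture256, d_range_px=(400, 400),
                                     rng=np.random.default_rng(0))

    def test_image_too_small_rejected(self):
        with pytest.raises(ValueError):
            generate_controlled_pair(np.zeros((100, 100)))


class TestPerturbedPair:
    def test_zero_perturbation(self, texture256):
        pair = generate_perturbed_pair(texture256, max_perturb=0,
                                       rng=np.random.default_rng(0))
        np.testing.assert_array_equal(pair.gt.displacements, 0.0)
        np.testing.assert_allclose(pair.patch_b, pair.patch_a, atol=1e-12)

    def test_displacements_bounded_and_integer(self, texture256):
        for i in range(10):
            pair = generate_perturbed_pair(texture256, max_perturb=32,
                                           rng=np.random.default_rng(i))
            d = pair.gt.displacements
            assert np.abs(d).max() <= 32
            np.testing.assert_array_equal(d, np.round(d))

    def test_continuous_flag(self, texture256):
        pair = generate_perturbed_pair(texture256, max_perturb=10, integer=False,
                                       rng=np.random.default_rng(4))
        assert not np.allclose(pair.gt.displacements, np.round(pair.gt.displacements))

    def test_deterministic_per_seed(self, texture256):
        a = generate_perturbed_pair(texture256, rng=np.random.default_rng(5))
        b = generate_perturbed_pair(texture256, rng=np.random.default_rng(5))
        np.testing.assert_array_equal(a.patch_b, b.patch_b)


class TestSequence:
    def test_two_frames_zero_step(self, texture_large):
        spec = TrajectorySpec(kind="exploratory", n_frames=2, step_px=0.0,
                              step_deg=0.0, seed=0)
        seq = generate_sequence(texture_large, spec)
        np.testing.assert_array_equal(seq.frames[0], seq.frames[1])
        np.testing.assert_allclose(seq.gt_pairwise[0], np.eye(3), atol=1e-12)

    def test_circular_loop_closes(self, texture_large):
        spec = TrajectorySpec(kind="circular", n_frames=36, step_px=6.0, seed=1)
        seq = generate_sequence(texture_large, spec)
        assert len(seq.gt_pairwise) == 35
        rel = compose_relative(seq.gt_pairwise)
        assert np.abs(rel[-1] - np.eye(3)).max() < 1e-6
        # last frame coincides with the first
        np.testing.assert_allclose(seq.frames[-1], seq.frames[0], atol=1e-9)

    def test_gt_photometric_residue_is_interpolation_only(self, texture_large):
        spec = TrajectorySpec(kind="spiral", n_frames=8, step_px=6.0, seed=2)
        seq = generate_sequence(texture_large, spec)
        for k in range(len(seq.frames) - 1):
            pe = photometric_error(seq.frames[k], seq.frames[k + 1], seq.gt_pairwise[k])
            assert pe < 0.01

    def test_deterministic(self, texture_large):
        spec = TrajectorySpec(kind="exploratory", n_frames=5, seed=9)
        a = generate_sequence(texture_large, spec)
        b = generate_sequence(texture_large, spec)
        for fa, fb in zip(a.frames, b.frames):
            np.testing.assert_array_equal(fa, fb)
        for ha, hb in zip(a.gt_pairwise, b.gt_pairwise):
            np.testing.assert_array_equal(ha, hb)

    def test_trajectory_exit_names_frame(self, texture256):
        spec = TrajectorySpec(kind="circular", n_frames=10, orbit_radius=300.0, seed=0)
        with pytest.raises(TrajectoryError, match="frame"):
            generate_sequence(texture256, spec)

    def test_circular_mask_applied(self, texture_large):
        spec = TrajectorySpec(kind="exploratory", n_frames=3, seed=4)
        seq = generate_sequence(texture_large, spec, mask_radius=100.0)
        (cx, cy), r = seq.mask
        assert r == 100.0
        assert seq.frames[0][0, 0] == 0.0  # corner outside the circle
        yy, xx = np.mgrid[0:256, 0:256]
        outside = (xx - cx) ** 2 + (yy - cy) ** 2 > r**2
        assert all(np.all(f[outside] == 0.0) for f in seq.frames)

    def test_artifacts_do_not_touch_gt(self, texture_large):
        spec = TrajectorySpec(kind="exploratory", n_frames=4, seed=6)
        clean = generate_sequence(texture_large, spec)
        noisy = generate_sequence(texture_large, spec,
                                  artifacts=ArtifactConfig(specular_level=1.0,
                                                           blur_sigma=1.0,
                                                           occlusion_prob=1.0))
        for hc, hn in zip(clean.gt_pairwise, noisy.gt_pairwise):
            np.testing.assert_array_equal(hc, hn)
        assert any(np.abs(c - n).max() > 1e-3
                   for c, n in zip(clean.frames, noisy.frames))

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            TrajectorySpec(kind="zigzag", n_frames=5)
        with pytest.raises(ValueError):
            TrajectorySpec(kind="circular", n_frames=1)
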