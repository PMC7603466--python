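"""Homography algebra: conversions, decomposition, composition, mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fetomosaic import (
    DecomposedHomography,
    DecompositionError,
    DegenerateGeometryError,
    FourPointHomography,
    ProjectiveDegeneracyError,
    apply_homography,
    compose_relative,
    decompose,
    default_corners,
    fourpt_to_matrix,
    matrix_to_fourpt,
    recompose,
    rigid_matrix,
    rotation_angle,
    translation_matrix,
)
from fetomosaic.homography import rotation2d, wrap_angle

from conftest import random_near_affine

C128 = default_corners(128, 128)


class TestFourPointToMatrix:
    def test_pure_translation(self):
        fp = FourPointHomography(corners=C128, displacements=np.tile([5.0, 3.0], (4, 1)))
        h = fourpt_to_matrix(fp)
        np.testing.assert_allclose(h, translation_matrix(5, 3), atol=1e-9)

    def test_zero_displacement_is_identity(self):
        h = fourpt_to_matrix(FourPointHomography.zero(C128))
        np.testing.assert_allclose(h, np.eye(3), atol=1e-10)

    def test_rigid_corner_map_recovers_constructed_matrix(self):
        # displacements generated by the rigid corner model must DLT back
        # to the directly constructed rotation+translation matrix
        h_true = rigid_matrix(5.0, 10.0, -4.0, degrees=True)
        disp = apply_homography(h_true, C128) - C128
        h = fourpt_to_matrix(FourPointHomography(corners=C128, displacements=disp))
        b = np.deg2rad(5.0)
        np.testing.assert_allclose(h[:2, :2], [[np.cos(b), np.sin(b)],
                                               [-np.sin(b), np.cos(b)]], atol=1e-8)
        np.testing.assert_allclose(h[:, 2], [10.0, -4.0, 1.0], atol=1e-8)
        np.testing.assert_allclose(h[2, :2], [0.0, 0.0], atol=1e-8)

    def test_collinear_corners_raise(self):
        corners = np.array([[0.0, 0.0], [1, 1], [2, 2], [0, 5]])
        with pytest.raises(DegenerateGeometryError):
            fourpt_to_matrix(FourPointHomography.zero(corners))

    def test_coincident_corners_raise(self):
        with pytest.raises(DegenerateGeometryError):
            FourPointHomography.zero(np.array([[0.0, 0], [0, 0], [5, 5], [0, 5]]))


class TestMatrixToFourPoint:
    def test_identity_gives_zero(self):
        fp = matrix_to_fourpt(np.eye(3), C128)
        np.testing.assert_allclose(fp.displacements, 0.0, atol=1e-12)

    def test_translation(self):
        fp = matrix_to_fourpt(translation_matrix(7, -2), C128)
        np.testing.assert_allclose(fp.du, 7.0)
        np.testing.assert_allclose(fp.dv, -2.0)

    def test_roundtrip_1000_random_near_affine(self):
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(1000):
            h = random_near_affine(rng)
            fp = matrix_to_fourpt(h, C128)
            h2 = fourpt_to_matrix(fp)
            # compare by corner reprojection, the metric that matters
            err = np.abs(apply_homography(h2, C128) - apply_homography(h, C128)).max()
            worst = max(worst, err)
        assert worst < 1e-8

    def test_corner_at_infinity_raises(self):
        h = np.eye(3)
        h[2, 0] = -1.0 / 127.0  # sends x=127 corners to infinity
        with pytest.raises(ProjectiveDegeneracyError):
            matrix_to_fourpt(h, C128)


class TestComposeRelative:
    def test_identities(self):
        rel = compose_relative([np.eye(3)] * 5)
        assert len(rel) == 6
        for h in rel:
            np.testing.assert_allclose(h, np.eye(3))

    def test_translation_chain(self):
        rel = compose_relative([translation_matrix(1, 0)] * 9, reference_index=0)
        for k, h in enumerate(rel):
            np.testing.assert_allclose(h, translation_matrix(k, 0), atol=1e-12)

    def test_matches_naive_left_product(self):
        rng = np.random.default_rng(3)
        pairwise = [rigid_matrix(rng.uniform(-5, 5), rng.uniform(-10, 10),
                                 rng.uniform(-10, 10), degrees=True) for _ in range(10)]
        rel = compose_relative(pairwise, reference_index=0)
        acc = np.eye(3)
        for k, p in enumerate(pairwise):
            acc = acc @ p  # independent accumulation
            np.testing.assert_allclose(rel[k + 1], acc / acc[2, 2], atol=1e-10)

    def test_nonzero_reference(self):
        rng = np.random.default_rng(4)
        pairwise = [rigid_matrix(rng.uniform(-5, 5), rng.uniform(-10, 10),
                                 rng.uniform(-10, 10), degrees=True) for _ in range(6)]
        ref = 3
        rel = compose_relative(pairwise, reference_index=ref)
        np.testing.assert_allclose(rel[ref], np.eye(3))
        # frame ref-1 into ref: inverse of pairwise[ref-1]
        np.testing.assert_allclose(rel[ref - 1] @ pairwise[ref - 1], np.eye(3), atol=1e-10)
        # consistency: rel[j] = rel[j-1] @ pairwise[j-1] for j > ref
        for j in range(ref + 1, 7):
            np.testing.assert_allclose(rel[j], rel[j - 1] @ pairwise[j - 1], atol=1e-10)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            compose_relative([])

    def test_singular_member_raises(self):
        bad = np.eye(3)
        bad[0, 0] = 0.0
        bad[0, 1] = 0.0
        with pytest.raises(ValueError):
            compose_relative([np.eye(3), bad])


class TestDecompose:
    def test_identity(self):
        d = decompose(np.eye(3))
        assert d.theta == 0 and d.gamma == 0
        assert d.s_g == 1 and d.s_h == 1
        assert d.t_x == 0 and d.t_y == 0

    def test_pure_anisotropic_scale(self):
        h = np.diag([2.0, 0.5, 1.0])
        d = decompose(h)
        assert abs(d.theta) < 1e-12 and abs(d.gamma) < 1e-12
        assert d.s_g == pytest.approx(2.0) and d.s_h == pytest.approx(0.5)

    def test_constructed_rsr_recovered(self):
        a = rotation2d(0.2) @ np.diag([2.0, 1.0]) @ rotation2d(-0.1)
        h = np.eye(3)
        h[:2, :2] = a
        h[0, 2], h[1, 2] = 3.0, 4.0
        d = decompose(h)
        assert d.theta == pytest.approx(0.2, abs=1e-8)
        assert d.gamma == pytest.approx(-0.1, abs=1e-8)
        assert d.s_g == pytest.approx(2.0, abs=1e-8)
        assert d.s_h == pytest.approx(1.0, abs=1e-8)
        assert (d.t_x, d.t_y) == (3.0, 4.0)

    def test_roundtrip_1000_random_parameter_tuples(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            s_g = rng.uniform(0.5, 2.0)
            d = DecomposedHomography(
                theta=rng.uniform(-np.pi / 2 + 1e-6, np.pi / 2),
                gamma=rng.uniform(-np.pi + 1e-6, np.pi),
                s_g=s_g,
                s_h=s_g * rng.uniform(0.3, 0.999),  # anisotropic, canonical order
                t_x=rng.uniform(-50, 50),
                t_y=rng.uniform(-50, 50),
            )
            d2 = decompose(recompose(d))
            np.testing.assert_allclose(d2.as_array(), d.as_array(), atol=1e-8)

    def test_matrix_roundtrip_on_random_near_affine(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            h = random_near_affine(rng, max_proj=0.0)
            h2 = recompose(decompose(h))
            np.testing.assert_allclose(h2[:2, :], h[:2, :], atol=1e-8)

    def test_singular_block_raises(self):
        with pytest.raises((DecompositionError, ValueError)):
            decompose(np.diag([1e-15, 1.0, 1.0]))

    def test_reflection_raises(self):
        h = np.diag([-1.0, 1.0, 1.0])
        with pytest.raises(DecompositionError):
            decompose(h)

    def test_non_affine_warns(self):
        h = rigid_matrix(2.0, 1.0, 1.0, degrees=True)
        h[2, 0] = 5e-3
        with pytest.warns(UserWarning, match="non-affine"):
            decompose(h)

    def test_isotropic_rule_puts_rotation_in_theta(self):
        h = rigid_matrix(100.0, 0.0, 0.0, degrees=True)  # beyond pi/2
        d = decompose(h)
        assert d.gamma == 0.0
        assert d.theta == pytest.approx(np.deg2rad(100.0), abs=1e-10)


class TestRecompose:
    def test_identity_params(self):
        np.testing.assert_allclose(
            recompose(DecomposedHomography(0, 0, 1, 1, 0, 0)), np.eye(3))

    def test_pure_translation_params(self):
        np.testing.assert_allclose(
            recompose(DecomposedHomography(0, 0, 1, 1, 7, -2)), translation_matrix(7, -2))

    def test_nonpositive_scale_rejected(self):
        with pytest.raises((DecompositionError, ValueError)):
            DecomposedHomography(0, 0, -1.0, 1.0, 0, 0)


class TestApply:
    def test_identity(self):
        np.testing.assert_allclose(apply_homography(np.eye(3), [3.0, 4.0]), [3.0, 4.0])

    def test_translation(self):
        np.testing.assert_allclose(
            apply_homography(translation_matrix(5, 3), [0.0, 0.0]), [5.0, 3.0])

    def test_projective_division_hand_computed(self):
        h = rigid_matrix(3.0, 2.0, -1.0, degrees=True)
        h[2, 0] = 0.001
        x, y = 100.0, 100.0
        denom = 0.001 * x + h[2, 1] * y + 1.0
        expected = [(h[0, 0] * x + h[0, 1] * y + h[0, 2]) / denom,
                    (h[1, 0] * x + h[1, 1] * y + h[1, 2]) / denom]
        np.testing.assert_allclose(apply_homography(h, [x, y]), expected, rtol=1e-12)

    def test_point_at_infinity_names_index(self):
        h = np.eye(3)
        h[2, 0] = -0.01
        with pytest.raises(ProjectiveDegeneracyError, match="index 1"):
            apply_homography(h, [[0.0, 0.0], [100.0, 0.0]])

    def test_inverse_roundtrip(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            h = random_near_affine(rng)
            pts = rng.uniform(0, 128, size=(5, 2))
            back = apply_homography(np.linalg.inv(h), apply_homography(h, pts))
            np.testing.assert_allclose(back, pts, atol=1e-8)


class TestRotationAngle:
    def test_matches_rigid_input(self):
        for deg in (-170.0, -45.0, 0.0, 3.0, 120.0):
            h = rigid_matrix(deg, 5.0, -2.0, degrees=True)
            assert rotation_angle(h) == pytest.approx(np.deg2rad(deg), abs=1e-12)

    def test_stable_under_near_isotropy(self):
        # theta/gamma split is ill-conditioned near isotropy; the total
        # rotation must stay put
        rng = np.random.default_rng(9)
        for _ in range(100):
            h = rigid_matrix(4.0, 1.0, 1.0, degrees=True)
            h[:2, :2] += rng.normal(0, 1e-3, size=(2, 2))
            assert abs(rotation_angle(h) - np.deg2rad(4.0)) < 5e-3


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    theta=st.floats(-np.pi / 2 + 1e-3, np.pi / 2 - 1e-3),
    gamma=st.floats(-np.pi + 1e-3, np.pi - 1e-3),
    s_g=st.floats(0.5, 2.0),
    ratio=st.floats(0.3, 0.95),
    t_x=st.floats(-100, 100),
    t_y=st.floats(-100, 100),
)
def test_decompose_recompose_identity_property(theta, gamma, s_g, ratio, t_x, t_y):
    """recompose then decompose returns the canonical parameters exactly."""
    d = DecomposedHomography(theta=theta, gamma=gamma, s_g=s_g, s_h=s_g * ratio,
                             t_x=t_x, t_y=t_y)
    d2 = decompose(recompose(d))
    np.testing.assert_allclose(d2.as_array(), d.as_array(), atol=1e-8)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    beta=st.floats(-np.pi, np.pi),
    t_x=st.floats(-50, 50),
    t_y=st.floats(-50, 50),
    px=st.floats(0, 255),
    py=st.floats(0, 255),
)
def test_apply_inverse_roundtrip_property(beta, t_x, t_y, px, py):
    """H^-1 (H x) = x for rigid homographies and any finite point."""
    h = rigid_matrix(beta, t_x, t_y)
    out = apply_homography(np.linalg.inv(h), apply_homography(h, [px, py]))
    np.testing.assert_allclose(out, [px, py], atol=1e-9)


def test_wrap_angle_branch():
    assert wrap_angle(np.pi) == pytest.approx(np.pi)
    assert wrap_angle(-np.pi) == pytest.approx(np.pi)
    assert wrap_angle(3 * np.pi / 2) == pytest.approx(-np.pi / 2)
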