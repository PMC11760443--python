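import numpy as np
import pytest

from mritexture.geometry import (
    ImageGeometry,
    RigidTransform,
    RoiPropagationError,
    RoiSpec,
    apply_transform,
    compose,
    propagate_roi,
    rasterize_circle,
    resample_to_frame,
)


def random_rigid_2d(rng):
    ang = rng.uniform(0, 2 * np.pi)
    return RigidTransform.from_angle_2d(ang, rng.uniform(-20, 20, size=2))


class TestRigidTransform:
    def test_rejects_non_rotation(self):
        with pytest.raises(ValueError):
            RigidTransform(np.array([[1.0, 0.0], [0.0, 2.0]]), np.zeros(2))
        with pytest.raises(ValueError):  # reflection: det -1
            RigidTransform(np.array([[1.0, 0.0], [0.0, -1.0]]), np.zeros(2))

    def test_identity_fixes_points(self, rng):
        T = RigidTransform.identity(2)
        pts = rng.normal(size=(10, 2))
        assert np.allclose(T.apply(pts), pts)

    def test_pure_translation(self):
        T = RigidTransform(np.eye(3), np.array([0.0, 5.0, 0.0]))
        assert np.allclose(apply_transform([0.0, 0.0, 0.0], T), [0.0, 5.0, 0.0])

    def test_90deg_rotation_about_z_maps_x_to_y(self):
        # axes ordered (z, y, x): rotate in the (y, x) plane
        R = np.array([[1, 0, 0], [0, 0, 1], [0, -1, 0]], dtype=float)
        T = RigidTransform(R, np.zeros(3))
        out = apply_transform([0.0, 0.0, 1.0], T)
        assert np.allclose(out, [0.0, 1.0, 0.0], atol=1e-12)

    def test_json_roundtrip(self, rng):
        T = random_rigid_2d(rng)
        T2 = RigidTransform.from_dict(T.to_dict())
        assert np.allclose(T.rotation, T2.rotation)
        assert np.allclose(T.translation, T2.translation)

    def test_homogeneous_roundtrip(self, rng):
        T = random_rigid_2d(rng)
        T2 = RigidTransform.from_homogeneous(T.to_homogeneous())
        assert np.allclose(T.rotation, T2.rotation)


class TestCompose:
    def test_identity_composes_to_identity(self):
        T = compose([RigidTransform.identity(2)])
        assert np.allclose(T.rotation, np.eye(2))

    def test_two_quarter_turns_make_a_half_turn(self):
        q = RigidTransform.from_angle_2d(np.pi / 2)
        T = compose([q, q])
        assert np.allclose(T.rotation, -np.eye(2), atol=1e-12)

    def test_matches_pointwise_application(self, rng):
        # compose([T1, T2]) applied to points == T2(T1(x)) pointwise
        T1, T2 = random_rigid_2d(rng), random_rigid_2d(rng)
        T = compose([T1, T2])
        pts = rng.uniform(-50, 50, size=(100, 2))
        assert np.allclose(T.apply(pts), T2.apply(T1.apply(pts)), atol=1e-12)

    def test_inverse_cancels(self, rng):
        T = random_rigid_2d(rng)
        I = compose([T, T.inverse()])
        assert np.allclose(I.rotation, np.eye(2), atol=1e-9)
        assert np.allclose(I.translation, 0.0, atol=1e-9)

    def test_mixed_dimensionality_rejected(self):
        with pytest.raises(ValueError):
            compose([RigidTransform.identity(2), RigidTransform.identity(3)])
        with pytest.raises(ValueError):
            compose([])


class TestResample:
    def test_identity_reproduces_input(self, rng):
        img = rng.normal(size=(12, 10))
        geom = ImageGeometry(img.shape)
        out, valid = resample_to_frame(img, geom, RigidTransform.identity(2), geom)
        assert np.allclose(out, img)
        assert valid.all()

    def test_integer_translation_nearest_is_index_shift(self, rng):
        img = rng.normal(size=(10, 10))
        geom = ImageGeometry(img.shape)
        T = RigidTransform(np.eye(2), np.array([3.0, 0.0]))  # +3 rows
        out, valid = resample_to_frame(img, geom, T, geom, "nearest")
        # oracle: target row r samples moving row r-3; first 3 rows invalid
        assert np.allclose(out[3:], img[:-3])
        assert not valid[:3].any() and (out[:3] == 0).all()
        assert valid[3:].all()

    def test_nearest_keeps_binary_values(self, rng):
        mask = (rng.uniform(size=(15, 15)) > 0.5).astype(float)
        geom = ImageGeometry(mask.shape)
        T = RigidTransform.from_angle_2d(0.3, (1.2, -0.7))
        out, valid = resample_to_frame(mask, geom, T, geom, "nearest")
        assert set(np.unique(out)).issubset({0.0, 1.0})


class TestRoi:
    def test_invariants(self):
        with pytest.raises(ValueError):
            RoiSpec("circle", "cancerous", "l0", center=(2, 2), radius=0)
        with pytest.raises(ValueError):
            RoiSpec("mask", "cancerous", "l0", mask=np.zeros((4, 4), bool))

    def test_identity_propagation_is_noop(self):
        roi = RoiSpec("circle", "cancerous", "l0", center=(10.0, 12.0), radius=4.0)
        geom = ImageGeometry((32, 32))
        out = propagate_roi(roi, RigidTransform.identity(2), geom, geom)
        assert out.center == roi.center and out.radius == roi.radius
        assert out.frame == "lowfield"

    def test_translation_shifts_center_by_spacing(self):
        # +10 mm along rows at 1 mm/px -> +10 px
        roi = RoiSpec("circle", "cancerous", "l0", center=(5.0, 5.0), radius=3.0)
        geom = ImageGeometry((32, 32), (1.0, 1.0))
        T = RigidTransform(np.eye(2), np.array([10.0, 0.0]))
        out = propagate_roi(roi, T, geom, geom)
        assert np.allclose(out.center, (15.0, 5.0))

    def test_radius_converts_with_target_spacing(self):
        # radius 10 px at 1 mm/px -> 10 mm -> 5 px at 2 mm/px
        roi = RoiSpec("circle", "cancerous", "l0", center=(16.0, 16.0), radius=10.0)
        src = ImageGeometry((64, 64), (1.0, 1.0))
        tgt = ImageGeometry((32, 32), (2.0, 2.0))
        out = propagate_roi(roi, RigidTransform.identity(2), src, tgt)
        assert np.isclose(out.radius, 5.0)

    def test_matched_pair_radii_survive_propagation(self, rng):
        geom = ImageGeometry((64, 64))
        # small in-plane wobble, as a manual registration would produce
        T = RigidTransform.from_angle_2d(rng.uniform(-0.2, 0.2), rng.uniform(-3, 3, 2))
        pair = [
            RoiSpec("circle", "cancerous", "l0", center=(30.0, 30.0), radius=6.0),
            RoiSpec("circle", "non_suspicious", "l0", center=(40.0, 20.0), radius=6.0),
        ]
        out = [propagate_roi(r, T, geom, geom) for r in pair]
        assert out[0].radius == out[1].radius

    def test_propagation_out_of_grid_errors(self):
        roi = RoiSpec("circle", "cancerous", "l0", center=(5.0, 5.0), radius=2.0)
        geom = ImageGeometry((16, 16))
        T = RigidTransform(np.eye(2), np.array([1000.0, 0.0]))
        with pytest.raises(RoiPropagationError):
            propagate_roi(roi, T, geom, geom)

    def test_mask_roi_propagates_nearest(self):
        mask = np.zeros((20, 20), bool)
        mask[8:12, 8:12] = True
        roi = RoiSpec("mask", "cancerous", "l0", mask=mask)
        geom = ImageGeometry((20, 20))
        T = RigidTransform(np.eye(2), np.array([2.0, 0.0]))
        out = propagate_roi(roi, T, geom, geom)
        assert out.mask[10:14, 8:12].all()

    def test_circle_rasterization_uses_center_inclusion(self):
        m = rasterize_circle((5, 5), (2, 2), 1.0)
        assert m.sum() == 5  # plus-shaped: ties at distance == radius included
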