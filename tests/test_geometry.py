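"""Sensor-array geometry: transforms, VMH assembly, clash tests, catalog."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vmhsim import (
    RigidTransform,
    SensorArray,
    apply_transform,
    build_vmh,
    check_clash,
    counter_transform,
    helmet_catalog,
    read_sensor_layout,
    synthetic_helmet,
    write_sensor_layout,
)

angles = st.floats(-180, 180, allow_nan=False)
shifts = st.floats(-50, 50, allow_nan=False)


def one_sensor_array(pos=(100.0, 0.0, 0.0), ori=(1.0, 0.0, 0.0)):
    return SensorArray(
        labels=("A1",), positions=np.array([pos]), orientations=np.array([ori])
    )


class TestRigidTransform:
    def test_identity_leaves_array_unchanged(self, base_small):
        out = apply_transform(base_small, RigidTransform())
        np.testing.assert_allclose(out.positions, base_small.positions, atol=1e-12)
        np.testing.assert_allclose(out.orientations, base_small.orientations, atol=1e-12)
        assert out.labels == base_small.labels

    def test_explicit_z_rotation_and_translation(self):
        # cos20 = 0.9397, sin20 = 0.3420: position rotates about z about the
        # origin, then translates; the orientation only rotates.
        arr = one_sensor_array()
        t = RigidTransform(rotation_deg=(0, 0, 20), translation_mm=(-15, -15, 0))
        out = apply_transform(arr, t)
        np.testing.assert_allclose(out.positions[0], [78.969, 19.202, 0.0], atol=1e-3)
        np.testing.assert_allclose(out.orientations[0], [0.9397, 0.3420, 0.0], atol=1e-4)

    def test_rotation_composition_is_rz_ry_rx(self):
        t = RigidTransform(rotation_deg=(10, 20, 30))
        rx, ry, rz = (math.radians(a) for a in (10, 20, 30))

        def rot(axis, a):
            c, s = math.cos(a), math.sin(a)
            mats = {
                "x": [[1, 0, 0], [0, c, -s], [0, s, c]],
                "y": [[c, 0, s], [0, 1, 0], [-s, 0, c]],
                "z": [[c, -s, 0], [s, c, 0], [0, 0, 1]],
            }
            return np.array(mats[axis])

        expected = rot("z", rz) @ rot("y", ry) @ rot("x", rx)
        np.testing.assert_allclose(t.matrix(), expected, atol=1e-12)

    @given(rx=angles, ry=angles, rz=angles, tx=shifts, ty=shifts, tz=shifts)
    @settings(max_examples=25, deadline=None)
    def test_inverse_recovers_original(self, rx, ry, rz, tx, ty, tz):
        arr = synthetic_helmet(n_channels=16)
        t = RigidTransform(rotation_deg=(rx, ry, rz), translation_mm=(tx, ty, tz))
        back = apply_transform(apply_transform(arr, t), t.inverse())
        np.testing.assert_allclose(back.positions, arr.positions, atol=1e-9)
        np.testing.assert_allclose(back.orientations, arr.orientations, atol=1e-9)

    @given(rx=angles, ry=angles, rz=angles)
    @settings(max_examples=25, deadline=None)
    def test_rotation_preserves_distances_and_norms(self, rx, ry, rz):
        arr = synthetic_helmet(n_channels=16)
        out = apply_transform(arr, RigidTransform(rotation_deg=(rx, ry, rz)))
        np.testing.assert_allclose(
            np.linalg.norm(out.positions, axis=1),
            np.linalg.norm(arr.positions, axis=1),
            atol=1e-9,
        )
        d_in = np.linalg.norm(arr.positions[:, None] - arr.positions[None], axis=-1)
        d_out = np.linalg.norm(out.positions[:, None] - out.positions[None], axis=-1)
        np.testing.assert_allclose(d_out, d_in, atol=1e-9)
        np.testing.assert_allclose(
            np.linalg.norm(out.orientations, axis=1), 1.0, atol=1e-9
        )

    def test_non_finite_parameters_rejected(self):
        with pytest.raises(ValueError):
            RigidTransform(rotation_deg=(np.nan, 0, 0))
        with pytest.raises(ValueError):
            RigidTransform(translation_mm=(np.inf, 0, 0))

    def test_counter_transform_inverts_head_motion(self):
        head_motion = RigidTransform(rotation_deg=(20, 20, 20), translation_mm=(15, 15, 15))
        counter = counter_transform(head_motion)
        arr = synthetic_helmet(n_channels=8)
        back = apply_transform(apply_transform(arr, head_motion), counter)
        np.testing.assert_allclose(back.positions, arr.positions, atol=1e-9)


class TestVirtualHelmet:
    def test_standard_helmet_has_one_array(self, base_full):
        vmh = build_vmh(base_full)
        assert vmh.n_arrays == 1
        assert vmh.n_channels == 248

    @pytest.mark.parametrize("n_transforms,channels", [(1, 496), (2, 744)])
    def test_channel_count_scales_with_arrays(self, base_full, n_transforms, channels):
        transforms = [
            RigidTransform(rotation_deg=(0, 0, 10 * (i + 1))) for i in range(n_transforms)
        ]
        vmh = build_vmh(base_full, transforms)
        assert vmh.n_channels == channels

    def test_vmhb_combines_three_arrays(self, base_small):
        vmh = build_vmh(
            base_small,
            [
                RigidTransform((20, 20, 20), (15, 15, 15)),
                RigidTransform((-20, -20, -20), (-15, -15, 0)),
            ],
        )
        assert vmh.n_arrays == 3
        # first array is the untransformed base
        np.testing.assert_array_equal(vmh.arrays[0].positions, base_small.positions)

    def test_construction_is_deterministic(self, base_small):
        t = [RigidTransform((20, 0, 0), (-15, 15, 0))]
        a = build_vmh(base_small, t)
        b = build_vmh(base_small, t)
        np.testing.assert_array_equal(a.positions, b.positions)
        assert a.labels == b.labels


class TestClash:
    def test_sensor_inside_sphere_clashes(self, head):
        arr = one_sensor_array(pos=(90.0, 0.0, 0.0))
        assert check_clash(build_vmh(arr), head) is True

    def test_all_sensors_outside_do_not_clash(self, head, base_small):
        assert base_small.radial_distances().min() >= 120 - 1e-9
        assert check_clash(build_vmh(base_small), head) is False

    def test_downward_translation_through_scalp_clashes(self, head, base_small):
        # the vertex standoff is 120 - 95.5 = 24.5 mm; pushing further drives
        # the top sensors into the sphere
        vmh = build_vmh(base_small, [RigidTransform(translation_mm=(0, 0, -30))])
        assert check_clash(vmh, head) is True

    def test_clash_monotone_in_margin(self, head, base_small):
        vmh = build_vmh(base_small)
        margins = [0.0, 10.0, 20.0, 30.0, 40.0]
        flags = [check_clash(vmh, head, m) for m in margins]
        # once clashing at some margin, clashing at every larger margin
        assert flags == sorted(flags)


class TestCatalog:
    def test_catalog_has_fourteen_helmets(self, base_small, head):
        catalog = helmet_catalog(base_small, head)
        assert [h.serial for h in catalog] == list(range(1, 15))

    def test_serial_one_is_standard(self, catalog_small):
        assert catalog_small[1].n_arrays == 1
        assert catalog_small[1].transforms[0].is_identity

    def test_serial_three_transform(self, catalog_small):
        h = catalog_small[3]
        assert h.n_arrays == 2
        assert h.transforms[1].rotation_deg == (0, 20, 0)
        assert h.transforms[1].translation_mm == (-15, 15, 0)

    def test_serial_fourteen_is_three_array_vmhb(self, catalog_small):
        h = catalog_small[14]
        assert h.name == "VMHb"
        assert h.n_arrays == 3
        assert h.transforms[1].rotation_deg == (20, 20, 20)
        assert h.transforms[2].rotation_deg == (-20, -20, -20)

    def test_no_catalog_helmet_clashes(self, catalog_small, head):
        for h in catalog_small.values():
            assert check_clash(h, head) is False


class TestLayoutIO:
    def test_round_trip_lossless_to_six_decimals(self, base_small, tmp_path):
        path = tmp_path / "layout.tsv"
        write_sensor_layout(base_small, path)
        back = read_sensor_layout(path)
        assert back.labels == base_small.labels
        np.testing.assert_allclose(back.positions, base_small.positions, atol=1e-6)
        np.testing.assert_allclose(back.orientations, base_small.orientations, atol=1e-6)


class TestSyntheticHelmet:
    def test_default_has_248_unit_orientations(self, base_full, head):
        assert base_full.n_channels == 248
        np.testing.assert_allclose(
            np.linalg.norm(base_full.orientations, axis=1), 1.0, atol=1e-9
        )
        # whole shell outside the head with a realistic standoff
        assert base_full.radial_distances().min() > head.radius

    def test_orientations_point_radially_inward(self, base_full):
        r_hat = base_full.positions / np.linalg.norm(
            base_full.positions, axis=1, keepdims=True
        )
        np.testing.assert_allclose(base_full.orientations, -r_hat, atol=1e-12)
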