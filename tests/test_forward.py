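"""Forward model: closed-form dipole fields, gains, effective rank."""

import numpy as np
import pytest

from vmhsim import (
    DipoleSet,
    RigidTransform,
    apply_transform,
    dipole_field,
    effective_rank,
    forward_project,
    gain_matrix,
    synthetic_helmet,
)


def sarvas_oracle(r0, q, pos, ori):
    """Independent, literal transcription of the spherical-conductor field.

    B(r) = (F (Q x r0) - ((Q x r0) . r) grad F) / F^2 with
    F = a (r a + r^2 - r0 . r),
    grad F = (a^2/r + (a.r)/a + 2a + 2r) r - (a + 2r + (a.r)/a) r0.
    Scalar loop over sensors; no vectorization shared with the package.
    """
    r0 = np.asarray(r0, float)
    q = np.asarray(q, float)
    out = np.empty(len(pos))
    for i, (r, o) in enumerate(zip(pos, ori)):
        a_vec = r - r0
        a = np.linalg.norm(a_vec)
        rn = np.linalg.norm(r)
        F = a * (rn * a + rn**2 - np.dot(r0, r))
        gradF = (
            (a**2 / rn + np.dot(a_vec, r) / a + 2 * a + 2 * rn) * r
            - (a + 2 * rn + np.dot(a_vec, r) / a) * r0
        )
        qxr0 = np.cross(q, r0)
        B = (F * qxr0 - np.dot(qxr0, r) * gradF) / F**2
        out[i] = np.dot(B, o)
    return out


class TestDipoleField:
    def test_radial_moment_is_silent(self, base_small, head):
        loc = np.array([30.0, 40.0, 20.0])
        field = dipole_field(loc, 2.5 * loc, base_small, head)
        assert np.max(np.abs(field)) < 1e-12 * np.linalg.norm(loc)

    def test_linearity_in_moment(self, base_small, head):
        loc = np.array([0.0, 0.0, 50.0])
        mom = np.array([1.0, 0.5, 0.0])
        f1 = dipole_field(loc, mom, base_small, head)
        f2 = dipole_field(loc, 2.0 * mom, base_small, head)
        np.testing.assert_allclose(f2, 2.0 * f1, rtol=1e-12)

    def test_matches_independent_transcription(self, base_small, head, rng):
        for _ in range(5):
            loc = rng.uniform(-40, 40, 3)
            mom = rng.uniform(-1, 1, 3)
            got = dipole_field(loc, mom, base_small, head)
            want = sarvas_oracle(loc, mom, base_small.positions, base_small.orientations)
            np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_tangential_dipole_on_axis_sensor_ring(self, head):
        # tangential dipole at (0, 0, 50) mm observed by a ring at 120 mm
        theta = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        pos = 120.0 * np.column_stack(
            [np.cos(theta) * np.sin(1.0), np.sin(theta) * np.sin(1.0),
             np.full_like(theta, np.cos(1.0))]
        )
        ori = -pos / np.linalg.norm(pos, axis=1, keepdims=True)
        from vmhsim import SensorArray

        ring = SensorArray(
            labels=tuple(f"R{i}" for i in range(12)), positions=pos, orientations=ori
        )
        loc = np.array([0.0, 0.0, 50.0])
        mom = np.array([1.0, 0.0, 0.0])
        got = dipole_field(loc, mom, ring, head)
        want = sarvas_oracle(loc, mom, pos, ori)
        np.testing.assert_allclose(got, want, rtol=1e-10)
        assert np.max(np.abs(got)) > 0

    def test_location_outside_sphere_rejected(self, base_small, head):
        with pytest.raises(ValueError):
            dipole_field([0, 0, 96.0], [1, 0, 0], base_small, head)

    def test_rotation_equivariance(self, head, rng):
        # rotating sensors, source and moment jointly leaves the projected
        # field unchanged
        base = synthetic_helmet(n_channels=32)
        t = RigidTransform(rotation_deg=(25, -40, 60))
        R = t.matrix()
        rotated = apply_transform(base, t)
        loc = np.array([20.0, -30.0, 40.0])
        mom = np.array([0.3, -1.1, 0.7])
        f0 = dipole_field(loc, mom, base, head)
        f1 = dipole_field(R @ loc, R @ mom, rotated, head)
        np.testing.assert_allclose(f1, f0, atol=1e-9 * np.max(np.abs(f0)))

    def test_field_decays_moving_dipole_inward(self, head):
        # fixed tangential dipole moved inward along the axis toward the
        # origin under a fixed sensor: the pickup magnitude decays
        from vmhsim import SensorArray

        sensor = SensorArray(
            labels=("S",),
            positions=np.array([[0.0, 0.0, 120.0]]),
            orientations=np.array([[1.0, 0.0, 0.0]]),
        )
        depths = [80.0, 60.0, 40.0, 20.0]
        mags = [
            abs(dipole_field([0, 0, z], [0, 1, 0], sensor, head)[0]) for z in depths
        ]
        assert all(m1 > m2 for m1, m2 in zip(mags, mags[1:]))


class TestGainMatrix:
    def test_standard_shape_is_channels_by_2p(self, gain_small, small_grid):
        assert gain_small.shape == (64, 2 * small_grid.n_points)

    def test_three_array_vmh_has_triple_rows(self, catalog_small, small_grid, head):
        g = gain_matrix(catalog_small[14], small_grid, head)
        assert g.shape[0] == 3 * 64
        assert g.n_arrays == 3

    def test_columns_are_unit_basis_fields(self, catalog_small, small_grid, head, gain_small):
        i = 7
        for b in range(2):
            want = dipole_field(
                small_grid.points[i],
                small_grid.basis[i, b],
                catalog_small[1].arrays[0],
                head,
            )
            np.testing.assert_allclose(gain_small.values[:, 2 * i + b], want, rtol=1e-12)

    def test_projection_matches_per_dipole_superposition(
        self, gain_small, small_grid, head, catalog_small, rng
    ):
        from vmhsim import random_dipoles

        d = random_dipoles(small_grid, 3, rng)
        via_gain = forward_project(gain_small, d)
        direct = sum(
            dipole_field(loc, mom, catalog_small[1].arrays[0], head)
            for loc, mom in zip(d.locations(small_grid), d.moments(small_grid))
        )
        np.testing.assert_allclose(via_gain, direct, rtol=1e-10)


class TestForwardProject:
    def test_empty_set_gives_zero_field(self, gain_small):
        d = DipoleSet(indices=(), coefficients=np.empty((0, 2)))
        np.testing.assert_array_equal(forward_project(gain_small, d), 0.0)

    def test_unit_coefficient_selects_column(self, gain_small):
        d = DipoleSet(indices=(5,), coefficients=np.array([[1.0, 0.0]]))
        np.testing.assert_array_equal(
            forward_project(gain_small, d), gain_small.values[:, 10]
        )

    def test_two_dipoles_superpose(self, gain_small):
        d1 = DipoleSet(indices=(3,), coefficients=np.array([[0.7, 0.6]]))
        d2 = DipoleSet(indices=(9,), coefficients=np.array([[0.5, 0.9]]))
        both = DipoleSet(
            indices=(3, 9), coefficients=np.array([[0.7, 0.6], [0.5, 0.9]])
        )
        np.testing.assert_allclose(
            forward_project(gain_small, both),
            forward_project(gain_small, d1) + forward_project(gain_small, d2),
            atol=1e-12,
        )

    def test_index_out_of_range_rejected(self, gain_small):
        d = DipoleSet(
            indices=(gain_small.n_points,), coefficients=np.array([[1.0, 0.0]])
        )
        with pytest.raises(ValueError):
            forward_project(gain_small, d)


class TestEffectiveRank:
    def test_counts_singular_values_above_tolerance(self):
        m = np.diag([1.0, 0.5, 5e-4])
        assert effective_rank(m, 1e-3) == 2

    def test_duplicate_rows_leave_rank_unchanged(self, gain_small):
        doubled = np.vstack([gain_small.values, gain_small.values])
        assert effective_rank(doubled) == effective_rank(gain_small)

    def test_two_array_vmh_exceeds_standard(self, catalog_small, small_grid, head, gain_small):
        g2 = gain_matrix(catalog_small[3], small_grid, head)
        assert effective_rank(g2) > effective_rank(gain_small)

    def test_monotone_nonincreasing_in_tolerance(self, gain_small):
        tols = [1e-4, 1e-3, 1e-2, 1e-1]
        ranks = [effective_rank(gain_small, t) for t in tols]
        assert ranks == sorted(ranks, reverse=True)
        assert ranks[0] <= min(gain_small.shape)

    def test_invalid_tolerance_rejected(self, gain_small):
        with pytest.raises(ValueError):
            effective_rank(gain_small, 0.0)
        with pytest.raises(ValueError):
            effective_rank(gain_small, 1.0)


class TestGainCache:
    def test_round_trip_with_grid_hash_guard(self, gain_small, small_grid, tmp_path, head):
        from vmhsim.forward import load_gain, save_gain

        save_gain(gain_small, tmp_path / "gain", grid=small_grid)
        back = load_gain(tmp_path / "gain", grid=small_grid)
        np.testing.assert_array_equal(back.values, gain_small.values)
        assert back.n_arrays == gain_small.n_arrays

        from vmhsim import build_grid

        other = build_grid(head, subdivisions=1)
        with pytest.raises(ValueError):
            load_gain(tmp_path / "gain", grid=other)
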