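"""Quaternion algebra against independent oracles.

The multiplication is checked against its 4x4 matrix representation,
axis-angle construction against the Rodrigues rotation formula, the
gyro integration/differentiation pair against closed forms and each
other, and the swing-twist decomposition against a brute-force grid
search over twist angles.
"""

import numpy as np
import pytest

from equigait import quat as Q
from equigait.signals import AngVelSignal, QuatSignal

Z = np.array([0.0, 0.0, 1.0])
X = np.array([1.0, 0.0, 0.0])


def quat_as_matrix(q):
    """Left-multiplication matrix of a quaternion: q (x) p == M(q) p."""
    w, x, y, z = q
    return np.array([[w, -x, -y, -z],
                     [x, w, -z, y],
                     [y, z, w, -x],
                     [z, -y, x, w]])


def random_unit_quats(rng, n):
    q = rng.normal(size=(n, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)


class TestMultiply:
    def test_identity(self, rng):
        q = random_unit_quats(rng, 5)
        np.testing.assert_allclose(Q.multiply(Q.IDENTITY, q), q)
        np.testing.assert_allclose(Q.multiply(q, Q.IDENTITY), q)

    def test_basis_products(self):
        i = np.array([0.0, 1.0, 0.0, 0.0])
        j = np.array([0.0, 0.0, 1.0, 0.0])
        k = np.array([0.0, 0.0, 0.0, 1.0])
        np.testing.assert_allclose(Q.multiply(i, j), k)
        np.testing.assert_allclose(Q.multiply(j, i), -k)

    def test_matrix_representation_oracle(self, rng):
        for _ in range(50):
            q1, q2 = random_unit_quats(rng, 2)
            np.testing.assert_allclose(Q.multiply(q1, q2),
                                       quat_as_matrix(q1) @ q2, atol=1e-14)

    def test_unit_norm_preserved(self, rng):
        q1 = random_unit_quats(rng, 1000)
        q2 = random_unit_quats(rng, 1000)
        norms = np.linalg.norm(Q.multiply(q1, q2), axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)


class TestAxisAngle:
    def test_half_turn_about_z(self):
        np.testing.assert_allclose(Q.from_axis_angle(Z, np.pi),
                                   [0, 0, 0, 1], atol=1e-12)

    def test_zero_angle_is_identity(self):
        np.testing.assert_allclose(Q.from_axis_angle(X, 0.0), Q.IDENTITY)

    def test_rodrigues_oracle(self, rng):
        axis = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
        theta = 0.7
        q = Q.from_axis_angle(axis, theta)
        for v in rng.normal(size=(10, 3)):
            rodrigues = (v * np.cos(theta) + np.cross(axis, v) * np.sin(theta)
                         + axis * (axis @ v) * (1 - np.cos(theta)))
            np.testing.assert_allclose(Q.rotate_vector(q, v), rodrigues, atol=1e-12)

    def test_non_unit_axis_warns(self):
        with pytest.warns(UserWarning, match="normalized"):
            q = Q.from_axis_angle(np.array([0.0, 0.0, 2.0]), np.pi / 2)
        np.testing.assert_allclose(q, Q.from_axis_angle(Z, np.pi / 2), atol=1e-12)

    def test_zero_axis_raises(self):
        with pytest.raises(ValueError):
            Q.from_axis_angle(np.zeros(3), 0.3)

    def test_round_trip_to_axis_angle(self, rng):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        q = Q.from_axis_angle(axis, 1.1)
        ax, ang = Q.to_axis_angle(q)
        np.testing.assert_allclose(ax * ang, axis * 1.1, atol=1e-12)


class TestGyroIntegration:
    def test_zero_rate_is_identity_step(self, rng):
        q = random_unit_quats(rng, 1)[0]
        np.testing.assert_allclose(Q.integrate_gyro(q, np.zeros(3), 0.005), q)

    def test_constant_rate_closed_form(self):
        omega = AngVelSignal(np.tile([0.0, 0.0, 90.0], (201, 1)), 200.0)
        qs = Q.integrate_gyro_signal(omega)
        axis, angle = Q.to_axis_angle(qs.quats[-1])
        assert abs(np.degrees(angle) - 90.0) < 0.1
        np.testing.assert_allclose(axis, Z, atol=1e-9)

    def test_differentiate_inverts_integration(self):
        # small dt and moderate rate: renormalization error is negligible
        rng = np.random.default_rng(7)
        w = rng.normal(0, 5, size=3)  # deg/s
        omega = AngVelSignal(np.tile(w, (51, 1)), 2000.0)
        qs = Q.integrate_gyro_signal(omega)
        back = Q.differentiate_quats(qs)
        np.testing.assert_allclose(back.omega[1:], np.tile(w, (50, 1)), atol=1e-6)

    def test_differentiate_constant_signal_is_zero(self):
        q = Q.from_axis_angle(Z, 0.4)
        qs = QuatSignal(np.tile(q, (20, 1)), 100.0)
        np.testing.assert_allclose(Q.differentiate_quats(qs).omega, 0.0, atol=1e-12)

    def test_recovers_rate_within_relative_tolerance(self):
        omega = AngVelSignal(np.tile([40.0, -25.0, 60.0], (401, 1)), 200.0)
        qs = Q.integrate_gyro_signal(omega)
        back = Q.differentiate_quats(qs)
        rel = np.abs(back.omega[1:] - omega.omega[1:]) / np.linalg.norm(omega.omega[0])
        assert rel.max() < 1e-4

    def test_sign_flip_repaired_no_spike(self):
        omega = AngVelSignal(np.tile([0.0, 0.0, 45.0], (101, 1)), 200.0)
        q = Q.integrate_gyro_signal(omega).quats.copy()
        q[50:] *= -1.0  # inject the q/-q ambiguity; QuatSignal must repair it
        back = Q.differentiate_quats(QuatSignal(q, 200.0))
        assert np.abs(back.omega[1:, 2] - 45.0).max() < 0.01


class TestSwingTwist:
    def test_pure_twist(self):
        qr = Q.from_axis_angle(Z, np.radians(30))
        tw, sw = Q.swing_twist(qr, Z)
        np.testing.assert_allclose(tw, qr, atol=1e-12)
        np.testing.assert_allclose(sw, Q.IDENTITY, atol=1e-12)

    def test_pure_swing(self):
        qr = Q.from_axis_angle(X, np.radians(30))
        tw, sw = Q.swing_twist(qr, Z)
        np.testing.assert_allclose(tw, Q.IDENTITY, atol=1e-12)
        np.testing.assert_allclose(sw, qr, atol=1e-12)

    def test_recomposition_many_random_pairs(self, rng):
        q = rng.normal(size=(10000, 4))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        axes = rng.normal(size=3)
        axes /= np.linalg.norm(axes)
        tw, sw = Q.swing_twist(q, axes)
        recomposed = Q.multiply(tw, sw)
        err = np.minimum(np.abs(recomposed - q).max(axis=1),
                         np.abs(recomposed + q).max(axis=1))
        assert err.max() < 1e-9
        # twist parallel, swing perpendicular to the axis
        assert np.abs(np.cross(tw[:, 1:], axes)).max() < 1e-9
        assert np.abs(sw[:, 1:] @ axes).max() < 1e-9

    def test_grid_search_oracle(self, rng):
        """The twist minimizes the residual swing angle over all
        candidate twist angles (1e-4 rad grid)."""
        for _ in range(3):
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            tw, sw = Q.swing_twist(q, axis)
            grid = np.arange(-np.pi, np.pi, 1e-4)
            cand_tw = Q.from_axis_angle(axis, grid)
            cand_sw = Q.multiply(Q.conjugate(cand_tw), q)
            swing_angles = 2 * np.arccos(np.clip(np.abs(cand_sw[:, 0]), -1, 1))
            best = swing_angles.min()
            mine = 2 * np.arccos(np.clip(abs(sw[0]), -1, 1))
            assert mine <= best + 1e-7

    def test_degenerate_half_turn(self):
        qr = Q.from_axis_angle(X, np.pi)  # 180 deg swing, w == 0
        tw, sw = Q.swing_twist(qr, Z)
        np.testing.assert_allclose(tw, Q.IDENTITY, atol=1e-12)
        np.testing.assert_allclose(Q.multiply(tw, sw), qr, atol=1e-12)


class TestTwistAngle:
    def test_identity_is_zero(self):
        assert Q.twist_angle(Q.IDENTITY, Z) == 0.0

    @pytest.mark.parametrize("axis,expected", [(Z, 28.64788975654116),
                                               (-Z, -28.64788975654116)])
    def test_sign_follows_axis(self, axis, expected):
        tw = Q.from_axis_angle(Z, 0.5)
        assert Q.twist_angle(tw, axis) == pytest.approx(expected, abs=1e-9)

    def test_non_parallel_vector_part_raises(self):
        with pytest.raises(ValueError, match="parallel"):
            Q.twist_angle(Q.from_axis_angle(X, 0.5), Z)

    def test_wraps_into_half_open_interval(self):
        tw = Q.from_axis_angle(Z, np.radians(350.0))
        assert Q.twist_angle(tw, Z) == pytest.approx(-10.0, abs=1e-9)
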