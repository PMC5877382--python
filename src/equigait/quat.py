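"""Quaternion algebra for orientation processing.

Quaternions are stored scalar-first ``(w, x, y, z)`` as numpy arrays of
shape ``(4,)`` or ``(n, 4)``; all binary operations broadcast over leading
dimensions.  The Hamilton product convention is used throughout.

Frame convention: a quaternion ``q`` maps body-frame vectors into the
global (navigation) frame, ``v_nav = q (0, v_body) q*``; viewed passively
it is the frame rotation from the global frame to the sensor body frame.
Under this convention the kinematic equation driven by the body-frame
angular rate is ``q_dot = 1/2 q (0, omega_body)``.

Public angular quantities are in degrees; internal math is in radians.
"""

from __future__ import annotations

import warnings

import numpy as np

from .signals import AngVelSignal, QuatSignal

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])

DEG = np.pi / 180.0


class DegenerateSwingError(ValueError):
    """Raised when a swing-twist decomposition has no usable twist/swing."""


def multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product ``q1 (x) q2``, broadcasting over leading dims."""
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    w1, v1 = q1[..., :1], q1[..., 1:]
    w2, v2 = q2[..., :1], q2[..., 1:]
    w = w1 * w2 - np.sum(v1 * v2, axis=-1, keepdims=True)
    v = w1 * v2 + w2 * v1 + np.cross(v1, v2)
    return np.concatenate([w, v], axis=-1)


def conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n < 1e-15):
        raise ValueError("cannot normalize zero quaternion")
    return q / n


def from_axis_angle(axis: np.ndarray, theta: float | np.ndarray) -> np.ndarray:
    """Rotation quaternion ``(cos(theta/2), axis sin(theta/2))``, theta in rad."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis, axis=-1, keepdims=True)
    if np.any(n < 1e-12):
        raise ValueError("rotation axis must be non-zero")
    if np.any(np.abs(n - 1.0) > 1e-9):
        warnings.warn("non-unit rotation axis normalized", stacklevel=2)
        axis = axis / n
    half = np.asarray(theta, dtype=float)[..., None] / 2.0
    v = axis * np.sin(half)
    w = np.broadcast_to(np.cos(half), v.shape[:-1] + (1,))
    return np.concatenate([w, v], axis=-1)


def to_axis_angle(q: np.ndarray) -> tuple[np.ndarray, float]:
    """Inverse of :func:`from_axis_angle`; angle in [0, pi] rad."""
    q = normalize(np.asarray(q, dtype=float))
    if q[0] < 0:
        q = -q
    s = np.linalg.norm(q[1:])
    angle = 2.0 * np.arctan2(s, q[0])
    axis = q[1:] / s if s > 1e-12 else np.array([0.0, 0.0, 1.0])
    return axis, float(angle)


def rotate_vector(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Apply the rotation: body -> global under the module convention."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    qv = np.concatenate([np.zeros(v.shape[:-1] + (1,)), v], axis=-1)
    return multiply(multiply(q, qv), conjugate(q))[..., 1:]


def geodesic_angle(q1: np.ndarray, q2: np.ndarray) -> float | np.ndarray:
    """Rotation angle (rad) between two orientations, sign-insensitive."""
    d = np.abs(np.sum(np.asarray(q1) * np.asarray(q2), axis=-1))
    return 2.0 * np.arccos(np.clip(d, -1.0, 1.0))


def shortest_arc(v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector ``v_from`` onto ``v_to``."""
    a = np.asarray(v_from, dtype=float)
    b = np.asarray(v_to, dtype=float)
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    c = float(np.dot(a, b))
    if c < -1.0 + 1e-12:
        # 180 deg: any axis perpendicular to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        return from_axis_angle(axis / np.linalg.norm(axis), np.pi)
    q = np.concatenate([[1.0 + c], np.cross(a, b)])
    return normalize(q)


def integrate_gyro(q_prev: np.ndarray, omega_dps: np.ndarray, dt: float) -> np.ndarray:
    """One first-order integration step of the body-rate kinematics.

    ``q(tk) = normalize(q(tk-1) + q_dot dt)`` with
    ``q_dot = 1/2 q(tk-1) (0, omega)``; ``omega_dps`` in deg/s.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    omega = np.asarray(omega_dps, dtype=float) * DEG
    qdot = 0.5 * multiply(q_prev, np.concatenate([[0.0], omega]))
    return normalize(np.asarray(q_prev, dtype=float) + qdot * dt)


def integrate_gyro_signal(omega: AngVelSignal, q0: np.ndarray | None = None) -> QuatSignal:
    """Integrate a whole angular-velocity signal into an orientation signal."""
    q0 = IDENTITY if q0 is None else normalize(np.asarray(q0, dtype=float))
    n = len(omega)
    out = np.empty((n, 4))
    out[0] = q0
    dt = omega.dt
    q = q0
    for k in range(1, n):
        w = omega.omega[k] if not omega.gap_mask[k] else np.zeros(3)
        q = integrate_gyro(q, w, dt)
        out[k] = q
    return QuatSignal(out, omega.sample_rate, omega.start_time, omega.gap_mask.copy())


def differentiate_quats(qsig: QuatSignal) -> AngVelSignal:
    """Body-frame angular velocity (deg/s) from an orientation signal.

    Algebraic inverse of the first-order integration step:
    ``(0, omega(tk)) = 2 q*(tk-1) (x) q_dot(tk)`` with
    ``q_dot = (q(tk) - q(tk-1)) / dt``.  The first sample copies the
    second; gap samples propagate into the output mask (and their
    successors, whose finite difference spans the gap).
    """
    q = qsig.quats
    if len(q) < 2:
        raise ValueError("need at least 2 samples to differentiate")
    qdot = (q[1:] - q[:-1]) * qsig.sample_rate
    omega = 2.0 * multiply(conjugate(q[:-1]), qdot)[:, 1:] / DEG
    out = np.vstack([omega[0], omega])
    mask = qsig.gap_mask.copy()
    mask[1:] |= qsig.gap_mask[:-1]
    return AngVelSignal(out, qsig.sample_rate, qsig.start_time, mask)


def swing_twist(qr: np.ndarray, axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Decompose ``qr = twist (x) swing`` about a unit ``axis``.

    The twist is the rotation component about ``axis``; the swing is the
    residual rotation, whose axis is perpendicular to ``axis``.  Works on
    single quaternions or (n, 4) stacks.

    In the fully degenerate case (a 180-degree swing exactly perpendicular
    to the axis: both the projected vector part and the scalar part vanish)
    the twist is taken as identity.
    """
    qr = np.asarray(qr, dtype=float)
    axis = np.asarray(axis, dtype=float)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
        raise ValueError("swing_twist axis must be a unit vector")
    single = qr.ndim == 1
    q = np.atleast_2d(qr)
    proj = q[:, 1:] @ axis  # component of the vector part along the axis
    tw = np.concatenate([q[:, :1], proj[:, None] * axis[None, :]], axis=1)
    norms = np.linalg.norm(tw, axis=1)
    degenerate = norms < 1e-12
    tw[degenerate] = IDENTITY
    tw[~degenerate] /= norms[~degenerate, None]
    sw = multiply(conjugate(tw), q)
    if single:
        return tw[0], sw[0]
    return tw, sw


def twist_angle(twist: np.ndarray, axis: np.ndarray) -> float | np.ndarray:
    """Signed angle (degrees, in (-180, 180]) of a twist about ``axis``.

    Positive when the twist's vector part aligns with ``+axis``.
    """
    twist = np.asarray(twist, dtype=float)
    axis = np.asarray(axis, dtype=float)
    single = twist.ndim == 1
    q = np.atleast_2d(twist)
    proj = q[:, 1:] @ axis
    residual = q[:, 1:] - proj[:, None] * axis[None, :]
    vec_norm = np.linalg.norm(q[:, 1:], axis=1)
    bad = np.linalg.norm(residual, axis=1) > 1e-6 * np.maximum(vec_norm, 1.0)
    if np.any(bad & (vec_norm > 1e-9)):
        raise ValueError("twist vector part is not parallel to the axis")
    ang = 2.0 * np.arctan2(proj, q[:, 0]) / DEG
    # wrap to (-180, 180]
    ang = np.where(ang <= -180.0, ang + 360.0, ang)
    ang = np.where(ang > 180.0, ang - 360.0, ang)
    return float(ang[0]) if single else ang


def yaw_quaternion(yaw_rad: float) -> np.ndarray:
    return from_axis_angle(np.array([0.0, 0.0, 1.0]), yaw_rad)
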