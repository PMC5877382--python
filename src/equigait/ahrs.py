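"""Complementary attitude filter: gyro integration with gravity correction.

Orientation is propagated by integrating the gyroscope and corrected each
step by rotating the estimate a small fraction ``accel_gain`` toward the
orientation implied by the accelerometer's gravity direction.  The
correction axis is always horizontal, so only pitch and roll drift are
compensated; yaw (heading) is deliberately left uncorrected — there is no
magnetometer in the pipeline, and heading is removed downstream by the
per-stride axis estimation.

With the default gain of 1e-4 per sample at 200 Hz the correction time
constant is ~50 s: slow enough that stride-level dynamics pass through
untouched, fast enough to cancel typical gyroscope bias drift in tilt.

Samples in free fall (acceleration magnitude far from 1 g carries no
usable gravity direction) skip the correction, as do gap samples, which
are bridged by gyro-only prediction (zero rate, i.e. held orientation,
when the gyro itself is the gap).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import quat
from .signals import AngVelSignal, QuatSignal, TimeSeries

Z_UP = np.array([0.0, 0.0, 1.0])

LOCATIONS = ("poll", "withers", "sternum", "sacrum", "LF", "RF", "LH", "RH")
LIMB_LOCATIONS = ("LF", "RF", "LH", "RH")


@dataclass(frozen=True)
class AhrsConfig:
    """Complementary-filter configuration."""

    accel_gain: float = 1e-4  # fraction of tilt error corrected per sample
    sample_rate: float = 200.0
    gravity: float = 9.81  # m/s^2

    def __post_init__(self) -> None:
        if not 0.0 <= self.accel_gain <= 1.0:
            raise ValueError("accel_gain must be in [0, 1]")


@dataclass
class ImuRecording:
    """One sensor location's synchronized accelerometer + gyroscope streams."""

    acc: TimeSeries  # (n, 3) m/s^2, body frame
    gyro: AngVelSignal  # (n, 3) deg/s, body frame
    location: str = "sacrum"

    def __post_init__(self) -> None:
        if self.location not in LOCATIONS:
            raise ValueError(f"unknown sensor location {self.location!r}")
        if len(self.acc) != len(self.gyro):
            raise ValueError("acc and gyro must share the time base")
        if abs(self.acc.sample_rate - self.gyro.sample_rate) > 1e-9:
            raise ValueError("acc and gyro must share the sample rate")

    def __len__(self) -> int:
        return len(self.acc)

    @property
    def sample_rate(self) -> float:
        return self.acc.sample_rate

    @property
    def gap_mask(self) -> np.ndarray:
        return self.acc.gap_mask | self.gyro.gap_mask


def _tilt_from_gravity(acc_body: np.ndarray) -> np.ndarray:
    """Yaw-free orientation whose rotation takes the measured gravity
    direction onto +z (shortest arc)."""
    g_dir = acc_body / np.linalg.norm(acc_body)
    return quat.shortest_arc(g_dir, Z_UP)


def estimate_orientation(imu: ImuRecording, cfg: AhrsConfig | None = None) -> QuatSignal:
    """Per-sample orientation (body -> navigation) from gyro + accelerometer.

    Initialized from the first valid accelerometer sample's gravity
    direction with yaw 0.  Per step: first-order gyro integration, then a
    fractional tilt correction toward the accelerometer-implied gravity
    direction about a horizontal axis (yaw preserved).
    """
    cfg = cfg or AhrsConfig(sample_rate=imu.sample_rate)
    n = len(imu)
    if n == 0:
        raise ValueError("empty recording")
    dt = 1.0 / imu.sample_rate
    acc = imu.acc.data
    gyro = imu.gyro.omega
    gaps = imu.gap_mask
    norms = np.linalg.norm(acc, axis=1)
    valid_idx = np.flatnonzero(~gaps & (norms > 0.5 * cfg.gravity))
    if len(valid_idx) == 0:
        raise ValueError("no valid sample with a usable gravity direction "
                         "to initialize the orientation")
    q = _tilt_from_gravity(acc[valid_idx[0]])
    out = np.empty((n, 4))
    out[: valid_idx[0] + 1] = q
    g = cfg.gravity
    alpha = cfg.accel_gain
    half_dt_rad = 0.5 * dt * quat.DEG
    qw, qx, qy, qz = (float(v) for v in q)
    # scalar inner loop: the per-sample state is tiny, so plain float math
    # is an order of magnitude faster than numpy here
    for k in range(valid_idx[0] + 1, n):
        if gaps[k]:
            out[k] = (qw, qx, qy, qz)  # hold through gap (gyro-only, zero rate)
            continue
        wx = gyro[k, 0] * half_dt_rad
        wy = gyro[k, 1] * half_dt_rad
        wz = gyro[k, 2] * half_dt_rad
        nw = qw - qx * wx - qy * wy - qz * wz
        nx = qx + qw * wx + qy * wz - qz * wy
        ny = qy + qw * wy + qz * wx - qx * wz
        nz = qz + qw * wz + qx * wy - qy * wx
        inv = 1.0 / np.sqrt(nw * nw + nx * nx + ny * ny + nz * nz)
        qw, qx, qy, qz = nw * inv, nx * inv, ny * inv, nz * inv
        ax, ay, az = acc[k, 0], acc[k, 1], acc[k, 2]
        anorm = np.sqrt(ax * ax + ay * ay + az * az)
        if alpha > 0.0 and anorm > 0.5 * g:
            ax, ay, az = ax / anorm, ay / anorm, az / anorm
            # measured gravity direction in the navigation frame: R(q) a
            gx = (1.0 - 2.0 * (qy * qy + qz * qz)) * ax \
                + 2.0 * (qx * qy - qw * qz) * ay + 2.0 * (qx * qz + qw * qy) * az
            gy = 2.0 * (qx * qy + qw * qz) * ax \
                + (1.0 - 2.0 * (qx * qx + qz * qz)) * ay + 2.0 * (qy * qz - qw * qx) * az
            gz = 2.0 * (qx * qz - qw * qy) * ax \
                + 2.0 * (qy * qz + qw * qx) * ay + (1.0 - 2.0 * (qx * qx + qy * qy)) * az
            # horizontal correction axis = g_nav x z_up
            cx, cy = gy, -gx
            s = np.sqrt(cx * cx + cy * cy)
            if s > 1e-12:
                angle = np.arctan2(s, min(max(gz, -1.0), 1.0))
                half = 0.5 * alpha * angle
                dw = np.cos(half)
                sin_scaled = np.sin(half) / s
                dx, dy = cx * sin_scaled, cy * sin_scaled
                nw = dw * qw - dx * qx - dy * qy
                nx = dw * qx + dx * qw + dy * qz
                ny = dw * qy + dy * qw - dx * qz
                nz = dw * qz + dx * qy - dy * qx
                inv = 1.0 / np.sqrt(nw * nw + nx * nx + ny * ny + nz * nz)
                qw, qx, qy, qz = nw * inv, nx * inv, ny * inv, nz * inv
        out[k, 0] = qw
        out[k, 1] = qx
        out[k, 2] = qy
        out[k, 3] = qz
    return QuatSignal(out, imu.sample_rate, imu.acc.start_time, gaps.copy())


def rotate_to_navigation(imu: ImuRecording, qsig: QuatSignal,
                         gravity: float = 9.81) -> TimeSeries:
    """Motion acceleration in the navigation frame (gravity removed, z up)."""
    if len(qsig) != len(imu):
        raise ValueError("orientation signal must match the IMU time base")
    acc_nav = quat.rotate_vector(qsig.quats, imu.acc.data)
    acc_nav[:, 2] -= gravity
    return TimeSeries(acc_nav, imu.sample_rate, imu.acc.start_time,
                      (imu.gap_mask | qsig.gap_mask))
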