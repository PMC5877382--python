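"""Synthetic horse-gait trials with paired inertial and optical streams.

The simulator prescribes kinematics (no force model): cannon-bone
orientation trajectories for the four limbs and vertical-displacement
waveforms for the upper-body locations, all analytic functions of the
stride phase, then renders them into the two measurement modalities:

* **IMU streams** — the ideal gyroscope is the numerical derivative of
  the truth orientation (so that re-integrating it reproduces the truth
  exactly up to round-off), plus a constant bias and white noise; the
  ideal accelerometer is the gravity vector (plus, for the upper body,
  the second derivative of the vertical position; for the limbs, short
  hoof-impact transients) rotated into the sensor frame, plus noise.
* **OMC-like streams** — truth positions/orientations expressed in a
  rotated camera frame, with the rigid-body frame rotated from the IMU
  body frame by a fixed mounting rotation, delayed by a known lag,
  with position/orientation noise and random short occlusion gaps.

Limb kinematics per stride (phase 0 = hoof-on, ``d`` = duty factor):
the sagittal angle starts at the configured protraction at hoof-on,
drops smoothly to zero over the first part of stance, stays on a quiet
vertical plateau, descends to the configured retraction just at
hoof-off, and swings smoothly back up to protraction by the next
hoof-on.  The coronal angle is a smooth low-amplitude lobe confined to
the swing phase.  The upper body oscillates vertically twice per stride
with configurable peak/trough differences for asymmetry studies.

Everything is deterministic under the configured seed, and the ground
truth (orientations, angles, events, displacements, extrema, lag,
relative rotation) is returned alongside the rendered sensor data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import quat
from .ahrs import ImuRecording, LIMB_LOCATIONS
from .events import StrideSet
from .signals import AngVelSignal, QuatSignal, TimeSeries
from .vertical import StrideExtrema, symmetry_parameters

UPPER_BODY_LOCATIONS = ("withers", "sternum", "sacrum", "poll")

GRAVITY = 9.81

#: stride-phase offsets per limb, lateral-sequence walk and diagonal trot
GAIT_PHASE_OFFSETS = {
    "walk": {"LH": 0.0, "LF": 0.25, "RH": 0.5, "RF": 0.75},
    "trot": {"LH": 0.5, "LF": 0.0, "RH": 0.0, "RF": 0.5},
}

#: fraction of stance spent in each fast transition at the stance edges
STANCE_TRANSITION_FRACTION = 0.15


def _default_relative_rotation() -> np.ndarray:
    axis = np.array([0.15, -0.10, 0.98])
    return quat.from_axis_angle(axis / np.linalg.norm(axis), np.radians(35.0))


@dataclass
class GaitConfig:
    """Prescribed gait kinematics.

    Defaults follow straight-line overground conditions: walk near
    0.85 strides/s with a 0.6 duty factor, trot near 1.28 strides/s with
    0.4; sagittal swing of about +/-25 degrees, a few degrees of coronal
    motion, and 40 mm of twice-per-stride vertical range at the upper
    body.  ``asymmetry`` maps a location to injected peak/trough
    differences in mm, e.g. ``{"sacrum": (10.0, 0.0)}`` for a 10 mm
    max_diff.
    """

    gait: str = "walk"
    stride_freq: float = 0.85  # Hz
    duty_factor: float = 0.6  # stance fraction of stride
    protraction_deg: float = 25.0
    retraction_deg: float = -25.0
    coronal_amp_deg: float = 4.0
    vert_range_mm: float = 40.0
    asymmetry: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_strides: int = 20
    heading_deg: float = 0.0
    forward_speed: float = 1.5  # m/s, used for optical marker x-position

    def __post_init__(self) -> None:
        if not 0.0 < self.duty_factor < 1.0:
            raise ValueError("duty_factor must be in (0, 1)")
        if self.stride_freq <= 0:
            raise ValueError("stride_freq must be positive")
        if self.protraction_deg <= self.retraction_deg:
            raise ValueError("protraction must exceed retraction")
        if self.coronal_amp_deg > self.protraction_deg - self.retraction_deg:
            warnings.warn("coronal amplitude exceeds the sagittal range; "
                          "unusual configuration", stacklevel=2)

    @classmethod
    def walk(cls, **kw) -> "GaitConfig":
        return cls(gait="walk", **kw)

    @classmethod
    def trot(cls, **kw) -> "GaitConfig":
        defaults = dict(gait="trot", stride_freq=1.275, duty_factor=0.4,
                        protraction_deg=30.0, retraction_deg=-30.0,
                        forward_speed=3.0)
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class SensorConfig:
    """Sensor imperfections and the inter-system transform."""

    sample_rate: float = 200.0  # Hz
    gyro_noise_sd: float = 0.2  # deg/s
    # residual bias of a startup-calibrated gyroscope, deg/s
    gyro_bias: tuple[float, float, float] = (0.01, -0.008, 0.02)
    acc_noise_sd: float = 0.05  # m/s^2
    omc_pos_noise_sd: float = 1.9  # mm, optical relative precision
    omc_quat_noise_deg: float = 0.3
    omc_gap_rate: float = 2.0  # gaps per minute
    omc_gap_len: int = 20  # samples per gap
    lag: float = 0.3735  # s, OMC stream delayed relative to IMU
    relative_rotation: np.ndarray = field(default_factory=_default_relative_rotation)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gyro_noise_sd", "acc_noise_sd", "omc_pos_noise_sd",
                     "omc_quat_noise_deg", "omc_gap_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        self.relative_rotation = quat.normalize(np.asarray(self.relative_rotation,
                                                           dtype=float))

    @classmethod
    def noiseless(cls, **kw) -> "SensorConfig":
        defaults = dict(gyro_noise_sd=0.0, gyro_bias=(0.0, 0.0, 0.0),
                        acc_noise_sd=0.0, omc_pos_noise_sd=0.0,
                        omc_quat_noise_deg=0.0, omc_gap_rate=0.0)
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class OmcRecording:
    """Optical stream for one location: marker position (mm) and, for the
    limb rigid bodies, orientation."""

    positions: TimeSeries
    quats: QuatSignal | None = None


@dataclass
class SyntheticTrial:
    imu: dict[str, ImuRecording]
    omc: dict[str, OmcRecording]
    truth: dict
    gait_config: GaitConfig
    sensor_config: SensorConfig


# ---------------------------------------------------------------------------
# analytic per-phase waveforms

def _sagittal_angle(phase: np.ndarray, g: GaitConfig) -> np.ndarray:
    """Sagittal cannon angle (deg) as a function of limb stride phase."""
    p = np.mod(phase, 1.0)
    d = g.duty_factor
    f = STANCE_TRANSITION_FRACTION
    P, R = g.protraction_deg, g.retraction_deg
    out = np.zeros_like(p)
    in_stance = p < d
    u = p[in_stance] / d
    stance = np.zeros_like(u)
    early = u < f
    stance[early] = P * (1.0 + np.cos(np.pi * u[early] / f)) / 2.0
    late = u > 1.0 - f
    stance[late] = R * (1.0 - np.cos(np.pi * (u[late] - (1.0 - f)) / f)) / 2.0
    out[in_stance] = stance
    v = (p[~in_stance] - d) / (1.0 - d)
    out[~in_stance] = R + (P - R) * (1.0 - np.cos(np.pi * v)) / 2.0
    return out


def _coronal_angle(phase: np.ndarray, g: GaitConfig) -> np.ndarray:
    """Coronal cannon angle (deg): a smooth swing-phase lobe, zero in stance."""
    p = np.mod(phase, 1.0)
    d = g.duty_factor
    out = np.zeros_like(p)
    swing = p >= d
    v = (p[swing] - d) / (1.0 - d)
    out[swing] = g.coronal_amp_deg * np.sin(2.0 * np.pi * v) * np.sin(np.pi * v)
    return out


def _vertical_waveform_mm(phase: np.ndarray, vert_range: float,
                          max_diff: float, min_diff: float) -> np.ndarray:
    """Twice-per-stride vertical displacement (mm) with injected asymmetry.

    Troughs near phase 0.125/0.625, peaks near 0.375/0.875; the
    first-harmonic terms shift the two peaks apart by ``max_diff`` and
    the two troughs by ``min_diff``.
    """
    psi = 2.0 * np.pi * (np.mod(phase, 1.0) - 0.125)
    return (-(vert_range / 2.0) * np.cos(2.0 * psi)
            + (max_diff / 2.0) * np.sin(psi)
            + (min_diff / 2.0) * np.cos(psi))


def _vertical_accel(phase: np.ndarray, stride_freq: float, vert_range: float,
                    max_diff: float, min_diff: float) -> np.ndarray:
    """Second time-derivative of the vertical waveform, in m/s^2."""
    psi = 2.0 * np.pi * (np.mod(phase, 1.0) - 0.125)
    w = 2.0 * np.pi * stride_freq
    d2_mm = (2.0 * vert_range * np.cos(2.0 * psi) * w ** 2
             - (max_diff / 2.0) * np.sin(psi) * w ** 2
             - (min_diff / 2.0) * np.cos(psi) * w ** 2)
    return d2_mm / 1000.0


def _limb_orientation(phase: np.ndarray, g: GaitConfig, limb: str) -> np.ndarray:
    """Truth orientation quaternions (body -> navigation) for one limb."""
    sag = np.radians(_sagittal_angle(phase, g))
    side = 1.0 if limb.startswith("L") else -1.0
    cor = side * np.radians(_coronal_angle(phase, g))
    n = len(phase)
    qz = quat.from_axis_angle(np.array([0.0, 0.0, 1.0]), np.full(n, np.radians(g.heading_deg)))
    qx = quat.from_axis_angle(np.array([1.0, 0.0, 0.0]), cor)
    qy = quat.from_axis_angle(np.array([0.0, 1.0, 0.0]), -sag)
    return quat.multiply(qz, quat.multiply(qx, qy))


def _event_times(g: GaitConfig, offset: float, t_end: float) -> tuple[np.ndarray, np.ndarray]:
    """Hoof-on / hoof-off times for a limb with the given phase offset."""
    T = 1.0 / g.stride_freq
    ons, offs = [], []
    i = -1
    while True:
        t_on = (i + offset) * T
        t_off = (i + offset + g.duty_factor) * T
        if t_on > t_end:
            break
        if t_on >= 0.0:
            ons.append(t_on)
        if 0.0 <= t_off <= t_end:
            offs.append(t_off)
        i += 1
    return np.array(ons), np.array(offs)


def _impact_train(times: np.ndarray, events: np.ndarray, amp: float,
                  width: float) -> np.ndarray:
    """Sum of Gaussian transients centred on the event times."""
    out = np.zeros_like(times)
    for t0 in events:
        sel = np.abs(times - t0) < 5.0 * width
        out[sel] += amp * np.exp(-0.5 * ((times[sel] - t0) / width) ** 2)
    return out


def _occlusion_mask(rng: np.random.Generator, n: int, fs: float,
                    rate_per_min: float, gap_len: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    if rate_per_min <= 0 or gap_len <= 0:
        return mask
    expected = rate_per_min * n / fs / 60.0
    n_gaps = rng.poisson(expected)
    for start in rng.integers(0, max(n - gap_len, 1), size=n_gaps):
        mask[start:start + gap_len] = True
    return mask


def _noisy_quats(rng: np.random.Generator, quats: np.ndarray,
                 noise_deg: float) -> np.ndarray:
    if noise_deg <= 0:
        return quats.copy()
    n = len(quats)
    axes = rng.normal(size=(n, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)
    angles = np.radians(rng.normal(0.0, noise_deg, size=n))
    dq = quat.from_axis_angle(axes, angles)
    return quat.multiply(dq, quats)


def simulate_trial(g: GaitConfig | None = None,
                   s: SensorConfig | None = None) -> SyntheticTrial:
    """Render one synthetic trial: IMU + OMC streams plus ground truth."""
    g = g or GaitConfig()
    s = s or SensorConfig()
    rng = np.random.default_rng(s.seed)
    fs = s.sample_rate
    T = 1.0 / g.stride_freq
    t_end = (g.n_strides + 1.5) * T
    n = int(round(t_end * fs)) + 1
    t = np.arange(n) / fs
    t_omc = t - s.lag  # the OMC stream reports the world `lag` seconds late
    # start the trial mid-cycle so no hoof event is cut by the record start
    phase0 = 0.37
    phase = t * g.stride_freq + phase0
    phase_omc = t_omc * g.stride_freq + phase0
    offsets = GAIT_PHASE_OFFSETS[g.gait]
    q_rel_conj = quat.conjugate(s.relative_rotation)
    q_room = quat.from_axis_angle(np.array([0.0, 0.0, 1.0]), np.radians(15.0))

    imu: dict[str, ImuRecording] = {}
    omc: dict[str, OmcRecording] = {}
    truth: dict = {
        "lag": s.lag,
        "relative_rotation": s.relative_rotation.copy(),
        "events": {},
        "orientation": {},
        "sagittal_deg": {},
        "coronal_deg": {},
        "vertical_disp_mm": {},
        "stride_extrema": {},
        "sample_rate": fs,
        "times": t,
    }

    impact_amp = 30.0  # m/s^2
    impact_width = 0.004  # s

    for limb in LIMB_LOCATIONS:
        off = offsets[limb]
        lphase = phase - off
        q_truth = QuatSignal(_limb_orientation(lphase, g, limb), fs)
        ons, offs = _event_times(g, off - phase0, t[-1])
        truth["events"][limb] = (ons, offs)
        truth["orientation"][limb] = q_truth
        truth["sagittal_deg"][limb] = _sagittal_angle(lphase, g)
        side = 1.0 if limb.startswith("L") else -1.0
        truth["coronal_deg"][limb] = _coronal_angle(lphase, g)

        omega_ideal = quat.differentiate_quats(q_truth)
        gyro = omega_ideal.omega + np.asarray(s.gyro_bias, dtype=float)
        gyro = gyro + rng.normal(0.0, s.gyro_noise_sd, size=gyro.shape)
        events = np.concatenate([ons, offs])
        acc_nav = np.zeros((n, 3))
        acc_nav[:, 2] = GRAVITY
        # hoof impacts: short vertical transients at both event types
        acc_nav[:, 2] += _impact_train(t, events, impact_amp, impact_width)
        acc_body = quat.rotate_vector(quat.conjugate(q_truth.quats), acc_nav)
        acc_body = acc_body + rng.normal(0.0, s.acc_noise_sd, size=acc_body.shape)
        imu[limb] = ImuRecording(
            acc=TimeSeries(acc_body, fs), gyro=AngVelSignal(gyro, fs), location=limb,
        )

        # optical rigid body: delayed, re-framed, noisy, with occlusions
        q_omc_truth = quat.multiply(
            quat.multiply(q_room, _limb_orientation(phase_omc - off, g, limb)),
            q_rel_conj)
        q_omc = _noisy_quats(rng, q_omc_truth, s.omc_quat_noise_deg)
        gaps = _occlusion_mask(rng, n, fs, s.omc_gap_rate, s.omc_gap_len)
        pos_nav = np.column_stack([
            g.forward_speed * t_omc * 1000.0,
            np.zeros(n),
            np.full(n, 300.0),  # cannon marker height, mm
        ])
        pos_room = quat.rotate_vector(q_room, pos_nav / 1000.0) * 1000.0
        pos_room += rng.normal(0.0, s.omc_pos_noise_sd, size=pos_room.shape)
        omc[limb] = OmcRecording(
            positions=TimeSeries(pos_room, fs, gap_mask=gaps.copy()),
            quats=QuatSignal(q_omc, fs, gap_mask=gaps.copy()),
        )

    ref_ons, ref_offs = truth["events"]["RF"]
    for loc in UPPER_BODY_LOCATIONS:
        max_diff, min_diff = g.asymmetry.get(loc, (0.0, 0.0))
        # upper-body oscillation is phase-locked to the reference limb
        ub_phase = phase - offsets["RF"]
        z_mm = _vertical_waveform_mm(ub_phase, g.vert_range_mm, max_diff, min_diff)
        z_acc = _vertical_accel(ub_phase, g.stride_freq, g.vert_range_mm,
                                max_diff, min_diff)
        truth["vertical_disp_mm"][loc] = TimeSeries(z_mm, fs)
        truth["stride_extrema"][loc] = _true_extrema(
            g, max_diff, min_diff)
        # constant mounting tilt plus a gentle stride-locked pitch sway
        tilt = quat.from_axis_angle(np.array([1.0, 0.0, 0.0]), np.radians(6.0))
        sway = quat.from_axis_angle(np.array([0.0, 1.0, 0.0]),
                                    np.radians(3.0) * np.sin(2.0 * np.pi * ub_phase))
        q_ub = QuatSignal(quat.multiply(sway, tilt[None, :]), fs)
        omega_ideal = quat.differentiate_quats(q_ub)
        gyro = (omega_ideal.omega + np.asarray(s.gyro_bias, dtype=float)
                + rng.normal(0.0, s.gyro_noise_sd, size=(n, 3)))
        acc_nav = np.zeros((n, 3))
        acc_nav[:, 2] = GRAVITY + z_acc
        acc_body = quat.rotate_vector(quat.conjugate(q_ub.quats), acc_nav)
        acc_body = acc_body + rng.normal(0.0, s.acc_noise_sd, size=acc_body.shape)
        imu[loc] = ImuRecording(
            acc=TimeSeries(acc_body, fs), gyro=AngVelSignal(gyro, fs), location=loc,
        )

        z_omc = _vertical_waveform_mm(phase_omc - offsets["RF"], g.vert_range_mm,
                                      max_diff, min_diff)
        pos_nav = np.column_stack([
            g.forward_speed * t_omc * 1000.0,
            np.zeros(n),
            z_omc + 1500.0,  # marker height above the floor, mm
        ])
        pos_room = quat.rotate_vector(q_room, pos_nav / 1000.0) * 1000.0
        pos_room += rng.normal(0.0, s.omc_pos_noise_sd, size=pos_room.shape)
        gaps = _occlusion_mask(rng, n, fs, s.omc_gap_rate, s.omc_gap_len)
        omc[loc] = OmcRecording(positions=TimeSeries(pos_room, fs, gap_mask=gaps))

    return SyntheticTrial(imu=imu, omc=omc, truth=truth,
                          gait_config=g, sensor_config=s)


def _true_extrema(g: GaitConfig, max_diff: float, min_diff: float) -> StrideExtrema:
    """Exact extrema of the analytic vertical waveform over one stride."""
    phi = np.linspace(0.0, 1.0, 20001, endpoint=False)
    z = _vertical_waveform_mm(phi, g.vert_range_mm, max_diff, min_diff)
    half1 = (phi >= 0.0) & (phi < 0.5)
    half2 = ~half1
    # trough/peak pairs in temporal order (trough near .125, peak near .375, ...)
    min1 = float(z[half1].min())
    max1 = float(z[half1].max())
    min2 = float(z[half2].min())
    max2 = float(z[half2].max())
    return StrideExtrema(max1=max1, max2=max2, min1=min1, min2=min2)


class MemoryBundle:
    """In-memory stand-in for an on-disk trial bundle (same interface)."""

    def __init__(self, trial: SyntheticTrial, subject_id: str = "sim"):
        self._trial = trial
        self.subject_id = subject_id
        self.gait = trial.gait_config.gait
        self.sample_rate = trial.sensor_config.sample_rate

    @property
    def locations(self):
        return list(self._trial.imu)

    def imu(self, location: str):
        return self._trial.imu[location]

    def has_omc(self, location: str) -> bool:
        return location in self._trial.omc

    def omc(self, location: str):
        rec = self._trial.omc[location]
        return rec.positions, rec.quats


def reference_strides(trial: SyntheticTrial, limb: str = "RF") -> StrideSet:
    """Truth stride segmentation for the given (reference) limb."""
    ons, offs = trial.truth["events"][limb]
    return StrideSet(limb, ons, offs)


def truth_parameters(trial: SyntheticTrial) -> dict[str, pd.DataFrame]:
    """Ground-truth per-stride parameter tables for direct comparison.

    Returns ``{"limb_angles": ..., "symmetry": ...}`` with the same
    columns as the pipeline's own output tables.
    """
    g = trial.gait_config
    limb_rows = []
    for limb in LIMB_LOCATIONS:
        strides = StrideSet(limb, *trial.truth["events"][limb])
        sag = trial.truth["sagittal_deg"][limb]
        cor = trial.truth["coronal_deg"][limb]
        fs = trial.truth["sample_rate"]
        for i, st in enumerate(strides.strides):
            sl = slice(int(round(st.on * fs)), int(round(st.next_on * fs)) + 1)
            limb_rows.append({
                "limb": limb,
                "stride_index": i,
                "protraction_deg": g.protraction_deg,
                "retraction_deg": g.retraction_deg,
                "abduction_deg": float(np.max(cor[sl])),
                "adduction_deg": float(np.min(cor[sl])),
                "sag_rom_deg": g.protraction_deg - g.retraction_deg,
                "cor_rom_deg": float(np.max(cor[sl]) - np.min(cor[sl])),
            })
    sym_rows = []
    ref = reference_strides(trial)
    for loc in UPPER_BODY_LOCATIONS:
        e = trial.truth["stride_extrema"][loc]
        p = symmetry_parameters(e)
        for i in range(len(ref)):
            sym_rows.append({
                "location": loc, "stride_index": i,
                "min_diff_mm": p.min_diff, "max_diff_mm": p.max_diff,
                "range_diff_up_mm": p.range_diff_up,
                "range_diff_down_mm": p.range_diff_down,
                "si_up": p.si_up, "si_down": p.si_down,
            })
    return {"limb_angles": pd.DataFrame(limb_rows),
            "symmetry": pd.DataFrame(sym_rows)}
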