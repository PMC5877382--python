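"""Hoof-on / hoof-off detection and stride segmentation.

Strides are delimited by successive hoof-on events of the same limb; each
stride splits into a stance phase (hoof-on to hoof-off) and a swing phase
(hoof-off to the next hoof-on).  All downstream timing — mid-stance zero
references, stride windows for the symmetry analysis — derives from one
limb-mounted IMU so that both measurement systems share identical stride
segmentation.

The default detector is a deliberately simple baseline that works well on
signals with a quiet stance phase: stance candidates are contiguous
regions where the low-pass-filtered angular-velocity magnitude stays
below a threshold for a minimum duration.  The stance end is taken as
hoof-off directly; the stance start is refined backwards to the nearest
preceding acceleration-magnitude impact peak (hoof impact), and the
stance end forwards to the nearest following impact peak when one exists
(breakover transient).  Detectors are pluggable: anything callable with
the same signature can replace the baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import signal as sps

from .ahrs import ImuRecording


@dataclass(frozen=True)
class Stride:
    """One stride: hoof-on, hoof-off, next hoof-on (seconds)."""

    on: float
    off: float
    next_on: float

    def __post_init__(self) -> None:
        if not (self.on < self.off < self.next_on):
            raise ValueError("stride events must satisfy on < off < next on")

    @property
    def stance(self) -> float:
        return self.off - self.on

    @property
    def swing(self) -> float:
        return self.next_on - self.off

    @property
    def duration(self) -> float:
        return self.next_on - self.on


@dataclass
class StrideSet:
    """Ordered hoof events and the complete strides they delimit."""

    limb: str
    hoof_on: np.ndarray  # sorted times, s
    hoof_off: np.ndarray  # sorted times, s

    def __post_init__(self) -> None:
        self.hoof_on = np.asarray(self.hoof_on, dtype=float)
        self.hoof_off = np.asarray(self.hoof_off, dtype=float)
        if np.any(np.diff(self.hoof_on) <= 0) or np.any(np.diff(self.hoof_off) <= 0):
            raise ValueError("event times must be strictly increasing")
        self.strides: list[Stride] = []
        offs = self.hoof_off
        for i in range(len(self.hoof_on) - 1):
            on, next_on = self.hoof_on[i], self.hoof_on[i + 1]
            inside = offs[(offs > on) & (offs < next_on)]
            if len(inside) == 1:
                self.strides.append(Stride(on, float(inside[0]), next_on))

    def __len__(self) -> int:
        return len(self.strides)

    def stance_durations(self) -> np.ndarray:
        return np.array([s.stance for s in self.strides])

    def swing_durations(self) -> np.ndarray:
        return np.array([s.swing for s in self.strides])

    def stride_durations(self) -> np.ndarray:
        return np.array([s.duration for s in self.strides])

    def midstance_times(self, sample_rate: float, start_time: float = 0.0) -> np.ndarray:
        return np.array([midstance_time(s, sample_rate, start_time)
                         for s in self.strides])


def midstance_time(stride: Stride, sample_rate: float | None = None,
                   start_time: float = 0.0) -> float:
    """50%-of-stance instant, snapped to the nearest sample when a rate is given.

    Snapping guarantees both measurement systems use the identical sample
    index as the zero-angle reference.
    """
    t = stride.on + 0.5 * stride.stance
    if sample_rate is None:
        return t
    return start_time + round((t - start_time) * sample_rate) / sample_rate


@dataclass(frozen=True)
class ThresholdStanceDetector:
    """Baseline detector: quiet-gyro stance regions refined by impact peaks.

    Parameters are configuration, not constants: the angular-rate
    threshold separates the stance plateau from the swing arc, and the
    minimum stance duration rejects brief quiet moments mid-swing.
    """

    omega_threshold: float = 20.0  # deg/s on the low-passed |omega|
    min_stance: float = 0.08  # s
    smoothing_window: float = 0.05  # s; centred moving average (ring-free FIR)
    impact_search: float = 0.2  # s window for impact-peak refinement

    def __call__(self, imu: ImuRecording) -> tuple[np.ndarray, np.ndarray]:
        fs = imu.sample_rate
        omega_mag = np.linalg.norm(imu.gyro.omega, axis=1)
        # a boxcar keeps the smoothed magnitude non-negative and free of the
        # ringing an IIR low-pass produces around the impact transients
        win = max(1, int(round(self.smoothing_window * fs)) | 1)
        kernel = np.ones(win) / win
        filled = np.where(imu.gap_mask, np.nan, omega_mag)
        smooth = np.convolve(np.nan_to_num(filled, nan=0.0), kernel, mode="same")
        quiet = np.where(imu.gap_mask, False, smooth < self.omega_threshold)
        min_len = max(1, int(round(self.min_stance * fs)))
        edges = np.diff(quiet.astype(int))
        starts = np.flatnonzero(edges == 1) + 1
        ends = np.flatnonzero(edges == -1) + 1
        if quiet[0]:
            starts = np.concatenate([[0], starts])
        if quiet[-1]:
            ends = np.concatenate([ends, [len(quiet)]])
        acc_mag = np.linalg.norm(imu.acc.data, axis=1)
        srch = max(1, int(round(self.impact_search * fs)))
        t0 = imu.acc.start_time
        ons, offs = [], []
        for s, e in zip(starts, ends):
            if e - s < min_len:
                continue
            if s < srch or e > len(quiet) - srch:
                continue  # partial stance at a recording boundary
            on_idx = self._refine_to_peak(acc_mag, s, -srch)
            off_idx = self._refine_to_peak(acc_mag, e - 1, srch)
            ons.append(t0 + on_idx / fs)
            offs.append(t0 + off_idx / fs)
        return np.asarray(ons), np.asarray(offs)

    @staticmethod
    def _refine_to_peak(acc_mag: np.ndarray, idx: int, span: int) -> int:
        """Move ``idx`` to the strongest acceleration peak within ``span``
        samples (negative span searches backwards); keep ``idx`` if the
        window holds no interior maximum."""
        n = len(acc_mag)
        lo, hi = (max(0, idx + span), idx + 1) if span < 0 else (idx, min(n, idx + span + 1))
        if hi - lo < 3:
            return idx
        window = acc_mag[lo:hi]
        peaks, _ = sps.find_peaks(window)
        if len(peaks) == 0:
            return idx
        best = peaks[np.argmax(window[peaks])]
        return lo + int(best)


def detect_hoof_events(imu: ImuRecording,
                       detector: Callable[[ImuRecording], tuple[np.ndarray, np.ndarray]] | None = None,
                       ) -> StrideSet:
    """Run a hoof-event detector on a limb-mounted recording.

    Raises if fewer than two complete strides are found.
    """
    if imu.location not in ("LF", "RF", "LH", "RH"):
        raise ValueError("hoof events require a limb-mounted recording")
    detector = detector or ThresholdStanceDetector()
    ons, offs = detector(imu)
    if len(ons) < 3 or len(offs) < 2:
        raise ValueError("fewer than 2 complete strides detected")
    ss = StrideSet(imu.location, ons, offs)
    if len(ss) < 2:
        raise ValueError("fewer than 2 complete strides detected")
    return ss
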