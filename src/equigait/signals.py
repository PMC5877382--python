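"""Uniformly sampled signal containers shared by all processing stages.

Three containers cover everything the pipeline moves around:

``TimeSeries``
    A uniformly sampled scalar or vector signal (acceleration, position,
    displacement, angular-velocity magnitude, ...).
``QuatSignal``
    A unit-quaternion orientation trajectory, scalar-first storage,
    kept sign-continuous so it can be differentiated sample-to-sample.
``AngVelSignal``
    A 3-axis angular-velocity trajectory in deg/s, body frame.

All three carry a sample rate, an absolute start time and a boolean
``gap_mask`` marking placeholder samples (missing data, e.g. marker
occlusions).  Gap samples hold placeholder values and must be ignored by
any numeric consumer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _as_gap_mask(mask, n: int) -> np.ndarray:
    if mask is None:
        return np.zeros(n, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (n,):
        raise ValueError(f"gap_mask shape {mask.shape} does not match {n} samples")
    return mask


@dataclass
class TimeSeries:
    """Uniformly sampled signal; ``data`` is (n,) scalar or (n, c) vector."""

    data: np.ndarray
    sample_rate: float
    start_time: float = 0.0
    gap_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (1, 2):
            raise ValueError("TimeSeries data must be 1-D or 2-D (samples x channels)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.gap_mask = _as_gap_mask(self.gap_mask, len(self.data))

    def __len__(self) -> int:
        return len(self.data)

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def duration(self) -> float:
        return (len(self.data) - 1) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.data)) / self.sample_rate

    @property
    def n_channels(self) -> int:
        return 1 if self.data.ndim == 1 else self.data.shape[1]

    def copy_with(self, data: np.ndarray, gap_mask: np.ndarray | None = None) -> "TimeSeries":
        if gap_mask is None:
            gap_mask = self.gap_mask.copy()
        return TimeSeries(np.asarray(data, dtype=float), self.sample_rate,
                          self.start_time, gap_mask)

    def index_of(self, t: float) -> int:
        """Nearest sample index for absolute time ``t``."""
        return int(round((t - self.start_time) * self.sample_rate))


def enforce_sign_continuity(quats: np.ndarray) -> np.ndarray:
    """Flip quaternion signs so consecutive samples have non-negative dot.

    q and -q encode the same rotation; differentiation requires picking the
    continuous branch.
    """
    q = np.array(quats, dtype=float)
    dots = np.einsum("ij,ij->i", q[1:], q[:-1])
    # cumulative parity of sign flips
    flips = np.cumprod(np.where(dots < 0, -1.0, 1.0))
    q[1:] *= flips[:, None]
    return q


@dataclass
class QuatSignal:
    """Unit-quaternion orientation trajectory, scalar-first (w, x, y, z).

    Convention: each quaternion maps body-frame vectors into the global /
    navigation frame, ``v_nav = q (0, v_body) q*`` — equivalently it is the
    frame rotation from the global frame to the sensor body frame.
    Normalized and sign-continuous after construction.
    """

    quats: np.ndarray
    sample_rate: float
    start_time: float = 0.0
    gap_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        q = np.asarray(self.quats, dtype=float)
        if q.ndim != 2 or q.shape[1] != 4:
            raise ValueError("quats must have shape (n, 4)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.gap_mask = _as_gap_mask(self.gap_mask, len(q))
        norms = np.linalg.norm(q, axis=1)
        valid = ~self.gap_mask
        if np.any(norms[valid] < 1e-12):
            raise ValueError("zero-norm quaternion in valid samples")
        q = q / np.where(norms < 1e-12, 1.0, norms)[:, None]
        self.quats = enforce_sign_continuity(q)

    def __len__(self) -> int:
        return len(self.quats)

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.quats)) / self.sample_rate

    def index_of(self, t: float) -> int:
        return int(round((t - self.start_time) * self.sample_rate))

    def copy_with(self, quats: np.ndarray, gap_mask: np.ndarray | None = None) -> "QuatSignal":
        if gap_mask is None:
            gap_mask = self.gap_mask.copy()
        return QuatSignal(quats, self.sample_rate, self.start_time, gap_mask)


@dataclass
class AngVelSignal:
    """3-axis angular velocity in deg/s, expressed in the sensor body frame."""

    omega: np.ndarray
    sample_rate: float
    start_time: float = 0.0
    gap_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        if self.omega.ndim != 2 or self.omega.shape[1] != 3:
            raise ValueError("omega must have shape (n, 3)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        self.gap_mask = _as_gap_mask(self.gap_mask, len(self.omega))

    def __len__(self) -> int:
        return len(self.omega)

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.omega)) / self.sample_rate
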