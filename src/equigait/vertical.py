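"""Upper-body vertical displacement and per-stride symmetry parameters.

Displacement comes from the navigation-frame vertical acceleration by
cyclic integration: a plain double integral of accelerometer data drifts
without bound, so at each integration step (acceleration -> velocity,
velocity -> displacement) the mean over the previous, current and next
stride is subtracted from each stride's samples before integrating.
Any residual drift and floor-slope trend is then removed by the
stride-frequency-tuned high-pass filter from :mod:`equigait.filters`.

At walk and trot the upper body rises and falls twice per stride (one
oscillation per diagonal step), so each stride window holds two maxima
and two minima.  The symmetry parameters compare the two halves:

* ``min_diff`` / ``max_diff`` — difference between the two troughs /
  the two peaks;
* ``range_diff_up`` / ``range_diff_down`` — difference between the two
  upward (trough-to-peak) / downward (peak-to-trough) ranges;
* ``si_up`` / ``si_down`` — symmetry index
  ``(R1 - R2) / max(R1, R2)``: 0 for perfect symmetry, +/-1 for maximal
  asymmetry (one range absent).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate as spi
from scipy import signal as sps

from .events import StrideSet
from .signals import TimeSeries

M_TO_MM = 1000.0


@dataclass(frozen=True)
class StrideExtrema:
    """Two peaks and two troughs of one stride's vertical displacement (mm),
    in temporal order anchored at the stride start."""

    max1: float
    max2: float
    min1: float
    min2: float

    @property
    def range_up1(self) -> float:
        """Trough 1 to the following peak."""
        return self.max1 - self.min1

    @property
    def range_up2(self) -> float:
        return self.max2 - self.min2

    @property
    def range_down1(self) -> float:
        """Peak 1 to the following trough (cyclic within the stride)."""
        return self.max1 - self.min2

    @property
    def range_down2(self) -> float:
        return self.max2 - self.min1


@dataclass(frozen=True)
class SymmetryResult:
    """Per-stride symmetry parameters (mm; symmetry indices dimensionless)."""

    min_diff: float
    max_diff: float
    range_diff_up: float
    range_diff_down: float
    si_up: float
    si_down: float


def _stride_sample_slices(strides: StrideSet, sig: TimeSeries) -> list[slice]:
    n = len(sig)
    out = []
    for st in strides.strides:
        a = max(0, sig.index_of(st.on))
        b = min(n, sig.index_of(st.next_on))
        out.append(slice(a, b))
    return out


def _cyclic_detrend(x: np.ndarray, slices: list[slice]) -> np.ndarray:
    """Subtract, per stride, the mean over the previous/current/next stride."""
    out = x.copy()
    for i, sl in enumerate(slices):
        lo = slices[max(0, i - 1)].start
        hi = slices[min(len(slices) - 1, i + 1)].stop
        out[sl] = x[sl] - np.mean(x[lo:hi])
    return out


def cyclic_integrate(nav_acc_z: TimeSeries, strides: StrideSet) -> TimeSeries:
    """Vertical displacement (mm) by drift-suppressed double integration.

    Requires at least three complete strides (the detrending mean needs
    adjacent strides).  Samples outside the stride-covered span are
    masked in the output.
    """
    if len(strides) < 3:
        raise ValueError("cyclic integration needs at least 3 complete strides")
    z = np.asarray(nav_acc_z.data, dtype=float)
    if z.ndim != 1:
        raise ValueError("expected the scalar vertical acceleration channel")
    dt = nav_acc_z.dt
    slices = _stride_sample_slices(strides, nav_acc_z)
    span = slice(slices[0].start, slices[-1].stop)
    acc = _cyclic_detrend(z, slices)
    vel = np.zeros_like(z)
    vel[span] = spi.cumulative_trapezoid(acc[span], dx=dt, initial=0.0)
    vel = _cyclic_detrend(vel, slices)
    disp = np.zeros_like(z)
    disp[span] = spi.cumulative_trapezoid(vel[span], dx=dt, initial=0.0)
    mask = np.ones(len(z), dtype=bool)
    mask[span] = nav_acc_z.gap_mask[span]
    return TimeSeries(disp * M_TO_MM, nav_acc_z.sample_rate,
                      nav_acc_z.start_time, mask)


def stride_extrema(vdisp: TimeSeries, strides: StrideSet,
                   min_separation: float = 0.1) -> dict[int, StrideExtrema]:
    """Two most prominent peaks and troughs inside each stride window.

    ``vdisp`` must already be drift-removed (high-pass) and denoised.
    Strides with fewer than two peaks or two troughs are skipped; the
    returned dict maps stride index -> extrema for usable strides.
    """
    x = np.asarray(vdisp.data, dtype=float)
    fs = vdisp.sample_rate
    dist = max(1, int(round(min_separation * fs)))
    results: dict[int, StrideExtrema] = {}
    for i, sl in enumerate(_stride_sample_slices(strides, vdisp)):
        seg = x[sl]
        if vdisp.gap_mask[sl].any() or len(seg) < 2 * dist + 3:
            continue
        peaks = _top_two(seg, dist)
        troughs = _top_two(-seg, dist)
        if peaks is None or troughs is None:
            continue
        results[i] = StrideExtrema(
            max1=float(seg[peaks[0]]), max2=float(seg[peaks[1]]),
            min1=float(seg[troughs[0]]), min2=float(seg[troughs[1]]),
        )
    return results


def _top_two(seg: np.ndarray, dist: int) -> tuple[int, int] | None:
    """Indices of the two most prominent local maxima, in temporal order."""
    idx, props = sps.find_peaks(seg, distance=dist, prominence=0.0)
    if len(idx) < 2:
        return None
    best = np.argsort(props["prominences"])[-2:]
    pair = np.sort(idx[best])
    return int(pair[0]), int(pair[1])


def _symmetry_index(r1: float, r2: float) -> float:
    m = max(r1, r2)
    if m <= 0.0:
        return math.nan
    return (r1 - r2) / m


def symmetry_parameters(e: StrideExtrema) -> SymmetryResult:
    """Symmetry parameters from one stride's extrema.

    The symmetry index is undefined (NaN) when both ranges are zero.
    """
    return SymmetryResult(
        min_diff=e.min1 - e.min2,
        max_diff=e.max1 - e.max2,
        range_diff_up=e.range_up1 - e.range_up2,
        range_diff_down=e.range_down1 - e.range_down2,
        si_up=_symmetry_index(e.range_up1, e.range_up2),
        si_down=_symmetry_index(e.range_down1, e.range_down2),
    )


def symmetry_table(vdisp: TimeSeries, strides: StrideSet,
                   location: str) -> pd.DataFrame:
    """Per-stride symmetry parameters for one upper-body location."""
    rows = []
    for i, e in stride_extrema(vdisp, strides).items():
        s = symmetry_parameters(e)
        rows.append({
            "location": location,
            "stride_index": i,
            "min_diff_mm": s.min_diff,
            "max_diff_mm": s.max_diff,
            "range_diff_up_mm": s.range_diff_up,
            "range_diff_down_mm": s.range_diff_down,
            "si_up": s.si_up,
            "si_down": s.si_down,
        })
    if not rows:
        raise ValueError(f"no usable strides for symmetry at {location}")
    return pd.DataFrame(rows)
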