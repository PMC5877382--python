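"""Sagittal / coronal limb angles from cannon-bone orientation.

Because neither system carries an absolute heading reference, the forward
(sagittal) direction is estimated per stride from the rotation between
the orientations at that stride's hoof-off and the following hoof-on
(the swing rotation).  Removing the z-twist of that rotation leaves a
swing about a horizontal axis: the unit vector perpendicular to the
sagittal plane.  Rotating it by 90 degrees about z gives the coronal
axis (mirrored for left-side limbs so "outward" is positive on both
sides).

Each sample's orientation is then expressed relative to the orientation
at mid-stance — the stride's zero-angle reference — and decomposed about
the two axes by successive swing-twist decompositions; the twist angles
are the sagittal and coronal angle signals.  Protraction (forward) is
positive sagittal, abduction (outward) positive coronal.

Per-stride parameters: protraction = sagittal angle at hoof-on,
retraction = sagittal at hoof-off, abduction / adduction = coronal
extrema over the stride, and the two ranges of motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

import pandas as pd

from . import quat
from .filters import DENOISE_SPEC, FilterSpec, _apply_filtfilt
from .events import StrideSet, midstance_time
from .signals import QuatSignal, TimeSeries

Z = np.array([0.0, 0.0, 1.0])

#: maximum fraction of gap samples tolerated inside a stride
MAX_GAP_FRACTION = 0.25


@dataclass
class LimbAngleSignals:
    """Per-sample sagittal / coronal angle signals with stride bookkeeping."""

    sagittal: TimeSeries  # degrees
    coronal: TimeSeries  # degrees
    stride_id: np.ndarray  # per-sample stride index, -1 outside strides
    sagittal_axes: np.ndarray  # (n_strides, 3), unit, horizontal
    coronal_axes: np.ndarray  # (n_strides, 3)
    skipped_strides: list[int]


def stride_rotation(q_on: np.ndarray, q_off: np.ndarray) -> np.ndarray:
    """Rotation between the hoof-off and hoof-on orientations: ``q_on (x) q_off*``."""
    return quat.multiply(q_on, quat.conjugate(q_off))


def stride_axes(qr: np.ndarray, left_side: bool = False,
                min_swing_deg: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Sagittal and coronal axes from a stride's swing rotation.

    The z-twist (heading) of ``qr`` is discarded; the residual swing's
    rotation axis is horizontal and perpendicular to the sagittal plane.
    The coronal axis is the sagittal axis rotated +90 deg about z
    (-90 deg for left-side limbs, keeping outward tilt positive).
    """
    _, sw = quat.swing_twist(qr, Z)
    v = sw[1:]
    norm = np.linalg.norm(v)
    if 2.0 * np.degrees(np.arctan2(norm, abs(sw[0]))) < min_swing_deg:
        raise ValueError("stride rotation has no usable sagittal swing "
                         "(near-pure rotation about z)")
    sagittal_axis = v / norm
    s = -1.0 if left_side else 1.0
    coronal_axis = np.array([-s * sagittal_axis[1], s * sagittal_axis[0], 0.0])
    coronal_axis /= np.linalg.norm(coronal_axis)
    return sagittal_axis, coronal_axis


def limb_angle_signals(qsig: QuatSignal, strides: StrideSet,
                       denoise: bool = True,
                       denoise_spec: FilterSpec = DENOISE_SPEC) -> LimbAngleSignals:
    """Sagittal / coronal angle signals for every complete stride.

    Angles are zero at each stride's mid-stance sample by construction;
    after the optional zero-phase denoising they are re-zeroed there so
    the reference is preserved exactly.  Strides whose windows contain
    more than 25% gap samples are skipped and reported.
    """
    fs = qsig.sample_rate
    t0 = qsig.start_time
    n = len(qsig)
    left = strides.limb.startswith("L")
    sag = np.full(n, np.nan)
    cor = np.full(n, np.nan)
    stride_id = np.full(n, -1, dtype=int)
    sag_axes = np.full((len(strides), 3), np.nan)
    cor_axes = np.full((len(strides), 3), np.nan)
    skipped: list[int] = []
    mid_idx = np.full(len(strides), -1, dtype=int)
    for i, st in enumerate(strides.strides):
        i_on = qsig.index_of(st.on)
        i_next = qsig.index_of(st.next_on)
        i_off = qsig.index_of(st.off)
        if i_on < 0 or i_next >= n:
            skipped.append(i)
            continue
        window = slice(i_on, i_next + 1)
        if qsig.gap_mask[window].mean() > MAX_GAP_FRACTION:
            skipped.append(i)
            continue
        try:
            axes = stride_axes(stride_rotation(qsig.quats[i_next], qsig.quats[i_off]),
                               left_side=left)
        except ValueError:
            # no measurable swing this stride (e.g. standing still): the
            # relative rotation is near-identity, so angles about any
            # horizontal axis pair are well-defined and near zero
            axes = (np.array([0.0, 1.0, 0.0]), np.array([-1.0, 0.0, 0.0]))
        sag_axes[i], cor_axes[i] = axes
        im = qsig.index_of(midstance_time(st, fs, t0))
        mid_idx[i] = im
        q_rel = quat.multiply(qsig.quats[window], quat.conjugate(qsig.quats[im]))
        tw_s, _ = quat.swing_twist(q_rel, sag_axes[i])
        tw_c, _ = quat.swing_twist(q_rel, cor_axes[i])
        sag[window] = quat.twist_angle(tw_s, sag_axes[i])
        cor[window] = quat.twist_angle(tw_c, cor_axes[i])
        stride_id[window] = i
    if not np.any(stride_id >= 0):
        raise ValueError("no usable strides for limb-angle extraction")
    if denoise:
        covered = stride_id >= 0
        gap = qsig.gap_mask | ~covered
        sag_f = _apply_filtfilt(denoise_spec, TimeSeries(np.nan_to_num(sag), fs, t0, gap)).data
        cor_f = _apply_filtfilt(denoise_spec, TimeSeries(np.nan_to_num(cor), fs, t0, gap)).data
        sag = np.where(covered, sag_f, np.nan)
        cor = np.where(covered, cor_f, np.nan)
        # restore the exact mid-stance zero reference
        for i in range(len(strides)):
            if mid_idx[i] >= 0 and np.isfinite(sag[mid_idx[i]]):
                sag[stride_id == i] -= sag[mid_idx[i]]
                cor[stride_id == i] -= cor[mid_idx[i]]
    gap_out = qsig.gap_mask | (stride_id < 0)
    return LimbAngleSignals(
        sagittal=TimeSeries(np.nan_to_num(sag), fs, t0, gap_out),
        coronal=TimeSeries(np.nan_to_num(cor), fs, t0, gap_out),
        stride_id=stride_id,
        sagittal_axes=sag_axes,
        coronal_axes=cor_axes,
        skipped_strides=skipped,
    )


def extract_limb_parameters(sig: LimbAngleSignals, strides: StrideSet) -> pd.DataFrame:
    """Per-stride angle parameters as a table.

    Columns: limb, stride_index, protraction_deg, retraction_deg,
    abduction_deg, adduction_deg, sag_rom_deg, cor_rom_deg.
    """
    fs = sig.sagittal.sample_rate
    t0 = sig.sagittal.start_time
    rows = []
    for i, st in enumerate(strides.strides):
        sel = sig.stride_id == i
        if not sel.any():
            continue
        i_on = sig.sagittal.index_of(st.on)
        i_off = sig.sagittal.index_of(st.off)
        prot = sig.sagittal.data[i_on]
        retr = sig.sagittal.data[i_off]
        valid = sel & ~sig.coronal.gap_mask
        abd = float(np.max(sig.coronal.data[valid]))
        add = float(np.min(sig.coronal.data[valid]))
        rows.append({
            "limb": strides.limb,
            "stride_index": i,
            "protraction_deg": float(prot),
            "retraction_deg": float(retr),
            "abduction_deg": abd,
            "adduction_deg": add,
            "sag_rom_deg": float(abs(prot - retr)),
            "cor_rom_deg": abd - add,
        })
    if not rows:
        raise ValueError("no strides with usable angle signals")
    return pd.DataFrame(rows)
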