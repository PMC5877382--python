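"""End-to-end processing: sensors in, gait-parameter tables out.

Processing order mirrors the measurement chain: orientation estimation
per sensor, stride segmentation from a reference limb, limb angles for
each limb, cyclic integration and symmetry extraction for the upper
body, and — when a paired optical stream is present — time
synchronization, rigid alignment, the same parameter extraction on the
optical data with identical stride timing, and per-parameter agreement
statistics.

Every stage logs the parameters it used; re-running with the same
inputs and configuration reproduces outputs exactly.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ahrs, filters, limbs, quat, sync, vertical
from .agreement import PairedMeasurements, bland_altman, icc_mixed
from .ahrs import AhrsConfig, ImuRecording, LIMB_LOCATIONS
from .events import StrideSet, ThresholdStanceDetector, detect_hoof_events
from .io import TrialBundle
from .signals import AngVelSignal, QuatSignal, TimeSeries

log = logging.getLogger("equigait")

UPPER_BODY = ("withers", "sternum", "sacrum", "poll")

LIMB_PARAMS = ("protraction_deg", "retraction_deg", "abduction_deg",
               "adduction_deg", "sag_rom_deg", "cor_rom_deg")
SYMMETRY_PARAMS = ("min_diff_mm", "max_diff_mm", "range_diff_up_mm",
                   "range_diff_down_mm", "si_up", "si_down")


@dataclass
class PipelineConfig:
    """Every number the pipeline depends on, overridable from YAML."""

    sample_rate: float = 200.0
    accel_gain: float = 1e-4
    gravity: float = 9.81
    denoise_cutoff: float = 30.0
    denoise_order: int = 4
    highpass_stride_fraction: float = 2.0 / 3.0
    reference_limb: str = "RF"
    stride_freq_location: str = "sacrum"
    omega_threshold: float = 20.0
    min_stance: float = 0.08
    sync_max_lag: float = 0.5
    variance_window: int = 10
    variance_threshold: float = 1.0e-3
    variance_robust_multiple: float = 10.0
    loa_multiplier: float = 1.96

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class TrialResult:
    subject_id: str
    gait: str
    limb_params: pd.DataFrame  # per limb and stride, "system" column imu/omc
    symmetry: pd.DataFrame  # per location and stride, "system" column
    stride_sets: dict[str, StrideSet]
    sync_report: dict | None = None  # lag, peak_corr, rotation, residual

    def imu_only(self, table: str) -> pd.DataFrame:
        df = getattr(self, table)
        return df[df.system == "imu"].drop(columns="system")


def _vertical_displacement(nav_acc: TimeSeries, ref: StrideSet,
                           stride_freq: float, cfg: PipelineConfig) -> TimeSeries:
    acc_z = TimeSeries(nav_acc.data[:, 2], nav_acc.sample_rate,
                       nav_acc.start_time, nav_acc.gap_mask.copy())
    disp = vertical.cyclic_integrate(acc_z, ref)
    hp = filters.highpass_drift_removal(disp, stride_freq)
    return filters.lowpass_denoise(hp)


def _displacement_from_positions(pos: TimeSeries, ref: StrideSet,
                                 stride_freq: float, cfg: PipelineConfig) -> TimeSeries:
    z = TimeSeries(pos.data[:, 2], pos.sample_rate, pos.start_time,
                   pos.gap_mask.copy())
    hp = filters.highpass_drift_removal(z, stride_freq)
    return filters.lowpass_denoise(hp)


def run_pipeline(bundle: TrialBundle, cfg: PipelineConfig | None = None) -> TrialResult:
    """Process one trial bundle into per-stride parameter tables."""
    cfg = cfg or PipelineConfig()
    t_start = time.perf_counter()
    ahrs_cfg = AhrsConfig(accel_gain=cfg.accel_gain,
                          sample_rate=bundle.sample_rate, gravity=cfg.gravity)
    detector = ThresholdStanceDetector(omega_threshold=cfg.omega_threshold,
                                       min_stance=cfg.min_stance)

    limbs_present = [l for l in LIMB_LOCATIONS if l in bundle.locations]
    upper_present = [l for l in UPPER_BODY if l in bundle.locations]
    if cfg.reference_limb not in limbs_present:
        raise ValueError(f"reference limb {cfg.reference_limb} missing from bundle")

    # --- orientation + stride segmentation (IMU is the timing reference)
    imu_recs: dict[str, ImuRecording] = {}
    orientations: dict[str, QuatSignal] = {}
    stride_sets: dict[str, StrideSet] = {}
    for loc in limbs_present + upper_present:
        rec = bundle.imu(loc)
        imu_recs[loc] = rec
        orientations[loc] = ahrs.estimate_orientation(rec, ahrs_cfg)
        log.info("orientation estimated for %s (%d samples)", loc, len(rec))
    for limb in limbs_present:
        stride_sets[limb] = detect_hoof_events(imu_recs[limb], detector)
        log.info("%s: %d strides", limb, len(stride_sets[limb]))
    ref = stride_sets[cfg.reference_limb]

    # --- synchronization + alignment against the optical stream
    sync_report = None
    lag = 0.0
    if bundle.has_omc(cfg.reference_limb):
        _, q_omc_ref = bundle.omc(cfg.reference_limb)
        if q_omc_ref is None:
            raise ValueError("reference-limb optical stream has no orientation")
        om_imu = imu_recs[cfg.reference_limb].gyro
        om_omc = quat.differentiate_quats(q_omc_ref)
        sres = sync.estimate_lag(sync.angvel_magnitude(om_imu),
                                 sync.angvel_magnitude(om_omc),
                                 max_lag=cfg.sync_max_lag)
        lag = sres.lag
        om_al_ts = sync.resample_to_lag(
            TimeSeries(om_omc.omega, om_omc.sample_rate, om_omc.start_time,
                       om_omc.gap_mask), lag)
        om_al = AngVelSignal(om_al_ts.data, om_al_ts.sample_rate,
                             om_al_ts.start_time, om_al_ts.gap_mask)
        mag_i = sync.angvel_magnitude(om_imu)
        mag_o = sync.angvel_magnitude(om_al)
        # the printed exclusion threshold assumes near-noiseless magnitudes;
        # guard it with a robust multiple of the typical variance mismatch
        dv = np.abs(sync._sliding_variance(mag_i.data, cfg.variance_window)
                    - sync._sliding_variance(mag_o.data, cfg.variance_window))
        thr = max(cfg.variance_threshold,
                  cfg.variance_robust_multiple * float(np.median(dv)))
        mask = sync.variance_exclusion_mask(mag_i, mag_o, threshold=thr,
                                            window=cfg.variance_window)
        align = sync.kabsch_align(om_imu, om_al, mask)
        sync_report = {
            "lag_s": lag, "peak_corr": sres.peak_corr,
            "rotation_quat_wxyz": [float(x) for x in align.rotation],
            "residual_rmsd_dps": align.residual_rmsd,
            "excluded_fraction": align.excluded_fraction,
        }
        log.info("sync: lag %.4f s (r=%.3f), alignment residual %.1f deg/s",
                 lag, sres.peak_corr, align.residual_rmsd)

    # --- limb angles, both systems on identical stride timing
    limb_rows = []
    for limb in limbs_present:
        ss = stride_sets[limb]
        sig = limbs.limb_angle_signals(orientations[limb], ss)
        df = limbs.extract_limb_parameters(sig, ss)
        df.insert(0, "system", "imu")
        limb_rows.append(df)
        if bundle.has_omc(limb):
            _, q_omc = bundle.omc(limb)
            if q_omc is not None:
                q_al = sync.resample_to_lag(q_omc, lag)
                sig_o = limbs.limb_angle_signals(q_al, ss)
                df_o = limbs.extract_limb_parameters(sig_o, ss)
                df_o.insert(0, "system", "omc")
                limb_rows.append(df_o)
    limb_params = pd.concat(limb_rows, ignore_index=True)

    # --- upper-body vertical displacement and symmetry
    sym_rows = []
    if upper_present:
        freq_loc = (cfg.stride_freq_location
                    if cfg.stride_freq_location in upper_present else upper_present[0])
        nav = ahrs.rotate_to_navigation(imu_recs[freq_loc], orientations[freq_loc],
                                        cfg.gravity)
        acc_z = TimeSeries(nav.data[:, 2], nav.sample_rate, nav.start_time,
                           nav.gap_mask.copy())
        raw_disp = vertical.cyclic_integrate(acc_z, ref)
        stride_freq = filters.estimate_stride_frequency(raw_disp)
        log.info("stride frequency %.3f Hz (high-pass cutoff %.3f Hz)",
                 stride_freq, stride_freq * cfg.highpass_stride_fraction)
        for loc in upper_present:
            nav = ahrs.rotate_to_navigation(imu_recs[loc], orientations[loc],
                                            cfg.gravity)
            disp = _vertical_displacement(nav, ref, stride_freq, cfg)
            df = vertical.symmetry_table(disp, ref, loc)
            df.insert(0, "system", "imu")
            sym_rows.append(df)
            if bundle.has_omc(loc):
                pos, _ = bundle.omc(loc)
                pos_al = sync.resample_to_lag(pos, lag)
                disp_o = _displacement_from_positions(pos_al, ref, stride_freq, cfg)
                df_o = vertical.symmetry_table(disp_o, ref, loc)
                df_o.insert(0, "system", "omc")
                sym_rows.append(df_o)
    symmetry = (pd.concat(sym_rows, ignore_index=True) if sym_rows
                else pd.DataFrame(columns=["system", "location", "stride_index",
                                           *SYMMETRY_PARAMS]))
    log.info("pipeline finished in %.2f s", time.perf_counter() - t_start)
    return TrialResult(subject_id=bundle.subject_id, gait=bundle.gait,
                       limb_params=limb_params, symmetry=symmetry,
                       stride_sets=stride_sets, sync_report=sync_report)


def _pair_table(df: pd.DataFrame, keys: list[str], params: tuple[str, ...],
                subject_col: str = "subject_id") -> pd.DataFrame:
    a = df[df.system == "imu"].drop(columns="system")
    b = df[df.system == "omc"].drop(columns="system")
    merged = a.merge(b, on=keys, suffixes=("_imu", "_omc"))
    return merged


def agreement_tables(results: list[TrialResult],
                     level: str = "per_stride") -> pd.DataFrame:
    """Agreement statistics across trials, in the layout of the validation
    tables: one row per (table, parameter, gait, grouping) with Upper LOA,
    Lower LOA, Bias and ICC.
    """
    frames = {"limb_angles": [], "symmetry": []}
    for i, r in enumerate(results):
        lp = r.limb_params.copy()
        lp["subject_id"] = r.subject_id
        lp["gait"] = r.gait
        lp["trial_id"] = i
        frames["limb_angles"].append(lp)
        sy = r.symmetry.copy()
        sy["subject_id"] = r.subject_id
        sy["gait"] = r.gait
        sy["trial_id"] = i
        frames["symmetry"].append(sy)
    rows = []
    for table, frame_list in frames.items():
        df = pd.concat(frame_list, ignore_index=True)
        if "omc" not in set(df.system):
            continue
        group_col = "limb" if table == "limb_angles" else "location"
        params = LIMB_PARAMS if table == "limb_angles" else SYMMETRY_PARAMS
        keys = [group_col, "stride_index", "subject_id", "gait", "trial_id"]
        merged = _pair_table(df, keys, params)
        for gait in sorted(merged.gait.unique()):
            sub_g = merged[merged.gait == gait]
            for group in sorted(sub_g[group_col].unique()):
                sub = sub_g[sub_g[group_col] == group]
                for p in params:
                    pm = PairedMeasurements(
                        sub[f"{p}_imu"].to_numpy(), sub[f"{p}_omc"].to_numpy(),
                        sub["subject_id"].to_numpy(), sub["trial_id"].to_numpy())
                    if len(pm) < 3 or len(np.unique(pm.subject_id)) < 2:
                        continue
                    ba = bland_altman(pm, level=level)
                    try:
                        icc = icc_mixed(pm, response="stacked").icc
                    except ValueError:
                        icc = np.nan
                    rows.append({
                        "table": table, "gait": gait, group_col: group,
                        "parameter": p, "level": level, "n": ba.n,
                        "upper_loa": ba.loa_upper, "lower_loa": ba.loa_lower,
                        "bias": ba.bias, "icc": icc,
                    })
    return pd.DataFrame(rows)
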