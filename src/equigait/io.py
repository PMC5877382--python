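"""Plain-text trial bundles: columnar TSV data files plus a YAML manifest.

A *trial bundle* is a directory holding one recording session:

```
trial/
  manifest.yaml          # subject, gait, sample rate, units, file map
  imu_<location>.tsv     # time_s  acc_x..acc_z [m/s^2]  gyro_x..gyro_z [deg/s]
  omc_<location>.tsv     # time_s  pos_x..pos_z [mm]  [qw qx qy qz]
  truth_*.tsv            # optional simulator ground-truth sidecars
```

Missing samples (dropouts, marker occlusions) are empty fields in the
data columns; they load as gap-masked placeholder samples so the time
base stays uniform.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ahrs import ImuRecording
from .signals import AngVelSignal, QuatSignal, TimeSeries

IMU_COLUMNS = ["time_s", "acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z"]
OMC_POS_COLUMNS = ["time_s", "pos_x_mm", "pos_y_mm", "pos_z_mm"]
OMC_QUAT_COLUMNS = ["qw", "qx", "qy", "qz"]

TIME_JITTER_TOL = 1e-6  # s


def _check_uniform_time(t: np.ndarray) -> float:
    if len(t) < 2:
        raise ValueError("data file must contain at least 2 samples")
    dt = np.diff(t)
    if np.any(np.abs(dt - dt[0]) > TIME_JITTER_TOL):
        raise ValueError("non-uniform time base (jitter beyond 1e-6 s)")
    return 1.0 / float(np.mean(dt))


def _read_table(path: str | Path, expected: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def read_imu(path: str | Path, location: str = "sacrum") -> ImuRecording:
    """Load an IMU stream from TSV; empty fields become gap samples."""
    df = _read_table(path, IMU_COLUMNS)
    t = df["time_s"].to_numpy(dtype=float)
    fs = _check_uniform_time(t)
    acc = df[["acc_x", "acc_y", "acc_z"]].to_numpy(dtype=float)
    gyro = df[["gyro_x", "gyro_y", "gyro_z"]].to_numpy(dtype=float)
    gaps = np.isnan(acc).any(axis=1) | np.isnan(gyro).any(axis=1)
    acc = np.nan_to_num(acc)
    gyro = np.nan_to_num(gyro)
    return ImuRecording(
        acc=TimeSeries(acc, fs, float(t[0]), gaps.copy()),
        gyro=AngVelSignal(gyro, fs, float(t[0]), gaps.copy()),
        location=location,
    )


def write_imu(path: str | Path, imu: ImuRecording) -> None:
    t = imu.acc.times
    data = np.column_stack([t, imu.acc.data, imu.gyro.omega])
    df = pd.DataFrame(data, columns=IMU_COLUMNS)
    df.loc[imu.gap_mask, IMU_COLUMNS[1:]] = np.nan
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_omc(path: str | Path) -> tuple[TimeSeries, QuatSignal | None]:
    """Load an optical stream: positions (mm) and optional orientation."""
    df = _read_table(path, OMC_POS_COLUMNS)
    t = df["time_s"].to_numpy(dtype=float)
    fs = _check_uniform_time(t)
    pos = df[["pos_x_mm", "pos_y_mm", "pos_z_mm"]].to_numpy(dtype=float)
    gaps = np.isnan(pos).any(axis=1)
    quats = None
    if all(c in df.columns for c in OMC_QUAT_COLUMNS):
        q = df[OMC_QUAT_COLUMNS].to_numpy(dtype=float)
        qgaps = gaps | np.isnan(q).any(axis=1)
        norms = np.linalg.norm(np.nan_to_num(q), axis=1)
        bad = (~qgaps) & (np.abs(norms - 1.0) > 0.01)
        if bad.any():
            raise ValueError(f"{path}: {int(bad.sum())} quaternion(s) deviate "
                             "from unit norm by more than 0.01")
        qn = np.nan_to_num(q)
        qn[qgaps] = [1.0, 0.0, 0.0, 0.0]
        quats = QuatSignal(qn, fs, float(t[0]), qgaps)
    positions = TimeSeries(np.nan_to_num(pos), fs, float(t[0]), gaps)
    return positions, quats


def write_omc(path: str | Path, positions: TimeSeries,
              quats: QuatSignal | None = None) -> None:
    t = positions.times
    cols = [t, positions.data]
    names = list(OMC_POS_COLUMNS)
    if quats is not None:
        cols.append(quats.quats)
        names += OMC_QUAT_COLUMNS
    df = pd.DataFrame(np.column_stack(cols), columns=names)
    df.loc[positions.gap_mask, names[1:4]] = np.nan
    if quats is not None:
        df.loc[quats.gap_mask, OMC_QUAT_COLUMNS] = np.nan
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def write_trial_bundle(path: str | Path, trial, subject_id: str = "sim") -> Path:
    """Write a simulated trial as a bundle directory (data + truth sidecars)."""
    from .simulate import truth_parameters

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    locations = {}
    for loc, imu in trial.imu.items():
        fname = f"imu_{loc}.tsv"
        write_imu(path / fname, imu)
        locations[loc] = {"imu": fname}
    for loc, rec in trial.omc.items():
        fname = f"omc_{loc}.tsv"
        write_omc(path / fname, rec.positions, rec.quats)
        locations[loc]["omc"] = fname
    manifest = {
        "subject_id": subject_id,
        "gait": trial.gait_config.gait,
        "sample_rate": trial.sensor_config.sample_rate,
        "units": {"acc": "m/s^2", "gyro": "deg/s", "pos": "mm"},
        "locations": locations,
    }
    truth = truth_parameters(trial)
    truth["limb_angles"].to_csv(path / "truth_limb_angles.tsv", sep="\t", index=False)
    truth["symmetry"].to_csv(path / "truth_symmetry.tsv", sep="\t", index=False)
    manifest["truth"] = {
        "limb_angles": "truth_limb_angles.tsv",
        "symmetry": "truth_symmetry.tsv",
        "lag_s": float(trial.truth["lag"]),
        "relative_rotation_wxyz": [float(x) for x in trial.truth["relative_rotation"]],
    }
    with open(path / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return path


class TrialBundle:
    """Lazy view over a trial bundle directory."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        with open(self.path / "manifest.yaml") as fh:
            self.manifest = yaml.safe_load(fh)
        self.subject_id = self.manifest.get("subject_id", "unknown")
        self.gait = self.manifest.get("gait", "unknown")
        self.sample_rate = float(self.manifest["sample_rate"])

    @property
    def locations(self) -> list[str]:
        return list(self.manifest["locations"])

    def imu(self, location: str) -> ImuRecording:
        entry = self.manifest["locations"][location]
        rec = read_imu(self.path / entry["imu"], location)
        if abs(rec.sample_rate - self.sample_rate) > 1e-6:
            raise ValueError(f"{location}: data sample rate differs from manifest")
        return rec

    def has_omc(self, location: str) -> bool:
        return "omc" in self.manifest["locations"][location]

    def omc(self, location: str) -> tuple[TimeSeries, QuatSignal | None]:
        entry = self.manifest["locations"][location]
        return read_omc(self.path / entry["omc"])

    def truth_table(self, kind: str) -> pd.DataFrame | None:
        info = self.manifest.get("truth")
        if not info or kind not in info:
            return None
        return pd.read_csv(self.path / info[kind], sep="\t")
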