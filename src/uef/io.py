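"""CSV/JSON readers and writers plus run configuration.

Documented CSV schemas (UTF-8, comma separator, '.' decimal, header row):

* gyro trial — ``time_s,value`` (single axis) or ``time_s,gx,gy,gz``, deg/s;
* ECG — ``time_s,mv`` or ``time_s,mv,ax,ay,az`` at the ECG rate (the
  accelerometer, natively slower, is zero-order-hold upsampled on write and
  decimated back on read);
* HR stream — ``time_s,bpm``.

A JSON sidecar (``<stem>.truth.json``) can hold generator ground truth and
parameters next to any written record.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .hr import ECGRecord, HRSeries
from .motor import GyroTrial

__all__ = [
    "RunConfig",
    "CohortManifest",
    "read_trial_csv",
    "read_gyro_csv",
    "read_ecg_csv",
    "read_hr_csv",
    "write_gyro_csv",
    "write_ecg_csv",
    "write_hr_csv",
    "write_truth_json",
]

#: numeric formatting for all CSV export (stable, round-trip-safe)
FLOAT_FORMAT = "%.10g"


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Resolved settings of one analysis run; serialises losslessly to YAML.

    The high-pass default here (0.25 Hz) is the drift-removal setting used
    for synthetic cohorts, whose flexion fundamentals sit at 0.7-1.3 Hz; a
    first-order high-pass at the conventional 2.5 Hz would attenuate such
    narrowband signals severely (zero-phase gain |H|^2 ~= 0.14 at 1 Hz).
    Set ``highpass_cutoff: 2.5`` for broadband real-device recordings.
    """

    # motor processing
    highpass_cutoff: float | None = 0.25
    lowpass_cutoff: float | None = 10.0
    min_cycle_ms: float = 200.0
    min_range_frac: float = 0.1
    naming: str = "table1"
    # weighted-condition load
    added_mass_kg: float = 0.5
    added_mass_radius_m: float = 0.25
    # HR processing
    smooth_beats: int = 5
    task_threshold_k: float = 6.0
    expected_windows: tuple[float, float, float] = (60.0, 20.0, 60.0)
    # agreement
    icc_form: str = "icc2_1"
    aggregate: str = "per_condition_mean"  # or "per_trial"
    # run
    seed: int = 0
    figures: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["expected_windows"] = list(self.expected_windows)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "expected_windows" in d:
            d["expected_windows"] = tuple(d["expected_windows"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


# --------------------------------------------------------------------------
# CSV readers/writers
# --------------------------------------------------------------------------

def _validate_time(t: np.ndarray, path) -> float:
    if len(t) < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError(f"{path}: non-monotone time column")
    return float(1.0 / np.median(dt))


def _check_rate(fs: float, expected: float | None, path) -> None:
    if expected is not None and abs(fs - expected) > 0.01 * expected:
        raise ValueError(
            f"{path}: sampling rate {fs:.2f} Hz does not match expected "
            f"{expected:.2f} Hz (+/-1%)"
        )


def write_gyro_csv(trial: GyroTrial, path: str | Path) -> None:
    cols = {"time_s": trial.time}
    if trial.is_triaxial:
        for j, name in enumerate(("gx", "gy", "gz")):
            cols[name] = trial.samples[:, j]
    else:
        cols["value"] = trial.samples
    pd.DataFrame(cols).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_gyro_csv(path: str | Path, expected_fs: float | None = None,
                  condition: str = "unweighted", device_label: str = "") -> GyroTrial:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise ValueError(f"{path}: missing required column 'time_s'")
    fs = _validate_time(df["time_s"].to_numpy(), path)
    _check_rate(fs, expected_fs, path)
    if {"gx", "gy", "gz"}.issubset(df.columns):
        samples = df[["gx", "gy", "gz"]].to_numpy()
    elif "value" in df.columns:
        samples = df["value"].to_numpy()
    else:
        raise ValueError(f"{path}: missing gyro columns ('value' or 'gx,gy,gz')")
    return GyroTrial(samples=samples, fs=fs, condition=condition,
                     device_label=device_label)


def write_ecg_csv(record: ECGRecord, path: str | Path) -> None:
    t = np.arange(len(record.ecg)) / record.fs_ecg + record.start_time
    cols = {"time_s": t, "mv": record.ecg}
    if record.accel is not None:
        ratio = record.fs_ecg / record.fs_acc
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("ECG/accel rate ratio must be integral for CSV export")
        up = np.repeat(record.accel, int(round(ratio)), axis=0)[: len(t)]
        if len(up) < len(t):  # pad the tail with the last accel sample
            up = np.vstack([up, np.repeat(up[-1:], len(t) - len(up), axis=0)])
        for j, name in enumerate(("ax", "ay", "az")):
            cols[name] = up[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def read_ecg_csv(path: str | Path, expected_fs: float | None = None,
                 fs_acc: float = 100.0) -> ECGRecord:
    df = pd.read_csv(path)
    for col in ("time_s", "mv"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    t = df["time_s"].to_numpy()
    fs = _validate_time(t, path)
    _check_rate(fs, expected_fs, path)
    accel = None
    if {"ax", "ay", "az"}.issubset(df.columns):
        step = int(round(fs / fs_acc))
        accel = df[["ax", "ay", "az"]].to_numpy()[::step]
    return ECGRecord(ecg=df["mv"].to_numpy(), fs_ecg=fs, accel=accel,
                     fs_acc=fs_acc, start_time=float(t[0]))


def write_hr_csv(series: HRSeries, path: str | Path) -> None:
    pd.DataFrame({"time_s": series.times, "bpm": series.hr}).to_csv(
        path, index=False, float_format=FLOAT_FORMAT
    )


def read_hr_csv(path: str | Path) -> HRSeries:
    df = pd.read_csv(path)
    for col in ("time_s", "bpm"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    t = df["time_s"].to_numpy()
    _validate_time(t, path)
    return HRSeries(times=t, hr=df["bpm"].to_numpy())


_SCHEMAS = {"gyro": read_gyro_csv, "ecg": read_ecg_csv, "hr": read_hr_csv}


def read_trial_csv(path: str | Path, schema: str, **kwargs):
    """Typed reader dispatch: ``schema`` in {'gyro', 'ecg', 'hr'}."""
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema '{schema}'; choose from {sorted(_SCHEMAS)}")
    return _SCHEMAS[schema](path, **kwargs)


def write_truth_json(path: str | Path, truth, params=None) -> None:
    """JSON sidecar with generator ground truth and parameters."""
    payload = {"truth": truth.as_dict() if truth is not None else None}
    if params is not None:
        payload["params"] = dataclasses.asdict(params)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


# --------------------------------------------------------------------------
# cohort manifest
# --------------------------------------------------------------------------

@dataclass
class CohortManifest:
    """File layout of a written cohort: per subject, the motor trial CSVs
    per device and condition, the ECG CSV and the watch HR CSV, plus a
    provenance block (generator seed or 'external')."""

    root: Path
    subjects: list[dict]
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        ids = [s["subject_id"] for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject ids in manifest")
        for s in self.subjects:
            for rel in _manifest_files(s):
                if not (self.root / rel).exists():
                    raise FileNotFoundError(f"manifest file missing: {rel}")

    def to_json(self, path: str | Path | None = None) -> None:
        path = Path(path) if path else self.root / "manifest.json"
        payload = {"provenance": self.provenance, "subjects": self.subjects}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortManifest":
        path = Path(path)
        payload = json.loads(path.read_text())
        m = cls(root=path.parent, subjects=payload["subjects"],
                provenance=payload.get("provenance", {}))
        m.validate()
        return m


def _manifest_files(subject: dict) -> list[str]:
    files = []
    for cond_trials in subject.get("motor", {}).values():
        for pair in cond_trials:
            files.extend(pair.values())
    if subject.get("ecg"):
        files.append(subject["ecg"])
    if subject.get("watch_hr"):
        files.append(subject["watch_hr"])
    return files
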