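"""Heart-rate dynamics around a short physical task.

Detects beats in a single-channel ECG with the Pan-Tompkins QRS detector,
locates the task interval from a synchronized accelerometer, converts RR
intervals to instantaneous heart rate, and computes five parameters over a
baseline / task / recovery layout (default 60 s / 20 s / 60 s):

* ``hr_increase`` — % rise of the task maximum HR over the baseline minimum;
* ``hr_decrease`` — % change of the recovery minimum HR from the task
  maximum (typically negative);
* ``mean_baseline``, ``mean_task``, ``mean_post`` — time-weighted mean HR
  in each window (BPM).

Per-second smartwatch HR streams enter :func:`compute_hr_params` directly;
only ECG goes through beat detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.ndimage import uniform_filter1d

__all__ = [
    "ECGRecord",
    "RRSeries",
    "HRSeries",
    "TaskWindows",
    "HRParams",
    "pan_tompkins",
    "detect_task_window",
    "rr_to_hr",
    "compute_hr_params",
]

#: physiological RR bounds (s) applied before HR conversion
RR_MIN_S = 0.25
RR_MAX_S = 3.0


@dataclass
class TaskWindows:
    """Contiguous baseline [t0, t1), task [t1, t2), post [t2, t3) bounds, s."""

    t0: float
    t1: float
    t2: float
    t3: float

    def __post_init__(self) -> None:
        if not (self.t0 < self.t1 < self.t2 < self.t3):
            raise ValueError("windows must be contiguous and non-empty")

    @property
    def baseline(self) -> tuple[float, float]:
        return (self.t0, self.t1)

    @property
    def task(self) -> tuple[float, float]:
        return (self.t1, self.t2)

    @property
    def post(self) -> tuple[float, float]:
        return (self.t2, self.t3)


@dataclass
class ECGRecord:
    """Single-channel ECG (mV) with an optional synchronized triaxial
    accelerometer (g) sharing the same start time."""

    ecg: np.ndarray
    fs_ecg: float = 1000.0
    accel: np.ndarray | None = None   # (m, 3) at fs_acc
    fs_acc: float = 100.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        if self.fs_ecg < 250:
            raise ValueError("ECG sampling rate must be >= 250 Hz")
        if self.accel is not None:
            self.accel = np.asarray(self.accel, dtype=float)
            if self.accel.ndim != 2 or self.accel.shape[1] != 3:
                raise ValueError("accelerometer must be (n, 3)")

    @property
    def duration_s(self) -> float:
        return len(self.ecg) / self.fs_ecg


@dataclass
class RRSeries:
    """Beat times (s, strictly increasing) from ECG, a generator, or a watch."""

    beat_times: np.ndarray
    source: str = "ecg"
    windows: TaskWindows | None = None

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if len(self.beat_times) >= 2 and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat times must be strictly increasing")

    @property
    def intervals(self) -> np.ndarray:
        return np.diff(self.beat_times)


@dataclass
class HRSeries:
    """Heart rate (BPM) at strictly increasing times (s); instantaneous
    beat-resolved or per-second."""

    times: np.ndarray
    hr: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        if self.times.shape != self.hr.shape:
            raise ValueError("times and hr must have the same shape")
        if len(self.times) >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.hr <= 0):
            raise ValueError("heart rate must be positive")


@dataclass
class HRParams:
    hr_increase: float      # %
    hr_decrease: float      # %, typically negative
    mean_baseline: float    # BPM
    mean_task: float        # BPM
    mean_post: float        # BPM

    def __post_init__(self) -> None:
        if min(self.mean_baseline, self.mean_task, self.mean_post) <= 0:
            raise ValueError("window means must be positive")

    def as_dict(self) -> dict[str, float]:
        return {
            "hr_increase": self.hr_increase,
            "hr_decrease": self.hr_decrease,
            "mean_baseline": self.mean_baseline,
            "mean_task": self.mean_task,
            "mean_post": self.mean_post,
        }


# --------------------------------------------------------------------------
# Pan-Tompkins QRS detection
# --------------------------------------------------------------------------

def pan_tompkins(
    record: ECGRecord,
    refractory_ms: float = 200.0,
    integration_ms: float = 150.0,
    band: tuple[float, float] = (5.0, 15.0),
) -> RRSeries:
    """Classical Pan-Tompkins beat detection.

    Stages: 5-15 Hz band-pass (zero-phase), five-point derivative, squaring,
    150 ms moving-window integration, then sequential dual adaptive
    thresholds on the integrated peaks with a 200 ms refractory period,
    T-wave rejection by slope comparison inside 360 ms, and search-back at
    1.66x the running RR average against the lower threshold.  Beat times
    are refined to the R peak of the raw ECG near each accepted integration
    peak.
    """
    fs = record.fs_ecg
    x = record.ecg
    if len(x) < 10 * fs:
        raise ValueError("need at least 10 s of ECG")

    sos = signal.butter(2, band, btype="bandpass", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos, x)
    # five-point derivative: y[n] = (2x[n] + x[n-1] - x[n-3] - 2x[n-4]) / 8
    der = signal.lfilter(np.array([2, 1, 0, -1, -2]) / 8.0, [1.0], bp)
    sq = der * der
    win = max(1, int(round(integration_ms * 1e-3 * fs)))
    mwi = uniform_filter1d(sq, size=win, mode="nearest")

    refractory = int(round(refractory_ms * 1e-3 * fs))
    peaks, _ = signal.find_peaks(mwi, distance=max(1, refractory))
    if len(peaks) == 0:
        raise RuntimeError("undetectable rhythm: no candidate peaks")

    # initial signal/noise level estimates from the learning phase (first 2 s)
    learn = mwi[: int(2 * fs)]
    spki = float(learn.max())
    npki = float(learn.mean()) * 0.5
    thr1 = npki + 0.25 * (spki - npki)

    qrs: list[int] = []
    pending_noise: list[int] = []   # sub-threshold peaks since the last QRS
    rr_recent: list[float] = []

    def rr_avg() -> float:
        return float(np.mean(rr_recent[-8:])) if rr_recent else 1.0

    def slope(idx: int) -> float:
        a = max(0, idx - int(0.075 * fs))
        b = min(len(der), idx + int(0.075 * fs))
        return float(np.max(np.abs(der[a:b])))

    def accept(idx: int, searchback: bool = False) -> None:
        nonlocal spki, thr1
        if searchback:
            spki = 0.25 * mwi[idx] + 0.75 * spki
        else:
            spki = 0.125 * mwi[idx] + 0.875 * spki
        if qrs:
            rr_recent.append((idx - qrs[-1]) / fs)
        qrs.append(idx)
        pending_noise.clear()
        thr1 = npki + 0.25 * (spki - npki)

    for p in peaks:
        amp = mwi[p]
        is_qrs = False
        if amp > thr1 and (not qrs or p - qrs[-1] > refractory):
            # T-wave discrimination: a peak inside 360 ms with less than half
            # the slope of the previous QRS is a T wave, not a beat
            if qrs and (p - qrs[-1]) < 0.36 * fs and slope(p) < 0.5 * slope(qrs[-1]):
                is_qrs = False
            else:
                is_qrs = True
        if is_qrs:
            accept(p)
        else:
            npki = 0.125 * amp + 0.875 * npki
            thr1 = npki + 0.25 * (spki - npki)
            pending_noise.append(p)
            # search-back for a missed beat when the gap exceeds 1.66 * RR
            if qrs and rr_recent and (p - qrs[-1]) / fs > 1.66 * rr_avg():
                thr2 = 0.5 * thr1
                candidates = [
                    c for c in pending_noise
                    if c - qrs[-1] > refractory and mwi[c] > thr2
                ]
                if candidates:
                    best = max(candidates, key=lambda c: mwi[c])
                    later = [c for c in pending_noise if c > best]
                    accept(best, searchback=True)
                    pending_noise.extend(later)

    if not qrs:
        raise RuntimeError("undetectable rhythm: no beats above threshold")

    # refine to the R peak of the raw ECG (zero-phase stages keep the MWI
    # peak near the R wave; search a symmetric window)
    half = int(round(0.075 * fs))
    refined = []
    for idx in qrs:
        a, b = max(0, idx - half), min(len(x), idx + half + 1)
        refined.append(a + int(np.argmax(x[a:b])))
    beats = np.unique(np.asarray(refined, dtype=float)) / fs + record.start_time
    return RRSeries(beat_times=beats, source="ecg")


# --------------------------------------------------------------------------
# task-window detection
# --------------------------------------------------------------------------

def detect_task_window(
    record: ECGRecord,
    expected: tuple[float, float, float] = (60.0, 20.0, 60.0),
    k: float = 6.0,
    rms_window_s: float = 1.0,
    task_tol_frac: float = 0.5,
) -> TaskWindows:
    """Locate the task interval from the synchronized accelerometer.

    The task is the longest contiguous run where the 1 s moving RMS of the
    (median-centred) acceleration magnitude exceeds the quiescent level by
    ``k`` robust standard deviations.  Baseline and post windows of the
    expected durations abut the task and are truncated to the available
    record with a warning.
    """
    if record.accel is None:
        raise ValueError("no accelerometer channel in record")
    base_s, task_s, post_s = expected
    fs = record.fs_acc
    mag = np.linalg.norm(record.accel, axis=1)
    mag = mag - np.median(mag)
    rms = np.sqrt(uniform_filter1d(mag * mag, size=max(1, int(rms_window_s * fs)),
                                   mode="nearest"))
    level = float(np.median(rms))
    sd = 1.4826 * float(np.median(np.abs(rms - level)))
    thr = level + k * max(sd, 1e-12)

    above = rms > thr
    # longest contiguous run
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(above))
    if not starts:
        raise RuntimeError("task not found: no supra-threshold activity")
    runs = [(s, e) for s, e in zip(starts, ends)]
    s, e = max(runs, key=lambda r: r[1] - r[0])
    # refine edges at 1/sqrt(2) of the plateau RMS: with a centred moving-RMS
    # window over a variance step this crossing sits at the true edge
    plateau = float(np.median(rms[s:e])) if e > s else thr
    half = plateau / np.sqrt(2.0)
    pad = max(1, int(rms_window_s * fs))
    a = max(0, s - pad)
    seg = rms[a : min(len(rms), s + pad)]
    hit = np.flatnonzero(seg >= half)
    if len(hit):
        s = a + int(hit[0])
    b = min(len(rms), e + pad)
    seg = rms[max(0, e - pad) : b]
    hit = np.flatnonzero(seg >= half)
    if len(hit):
        e = max(0, e - pad) + int(hit[-1]) + 1
    t1 = s / fs + record.start_time
    t2 = e / fs + record.start_time
    dur = t2 - t1
    if not (1 - task_tol_frac) * task_s <= dur <= (1 + task_tol_frac) * task_s:
        raise RuntimeError(
            f"task not found: activity run of {dur:.1f} s outside "
            f"{task_s} s +/- {task_tol_frac:.0%}"
        )

    total_end = record.start_time + len(mag) / fs
    t0 = t1 - base_s
    if t0 < record.start_time:
        if record.start_time - t0 > rms_window_s:
            warnings.warn("baseline window truncated to the available record",
                          stacklevel=2)
        t0 = record.start_time
    t3 = t2 + post_s
    if t3 > total_end:
        if t3 - total_end > rms_window_s:
            warnings.warn("post-task window truncated to the available record",
                          stacklevel=2)
        t3 = total_end
    return TaskWindows(t0=t0, t1=t1, t2=t2, t3=t3)


# --------------------------------------------------------------------------
# RR -> HR and window parameters
# --------------------------------------------------------------------------

def rr_to_hr(rr: RRSeries, smooth_beats: int = 5) -> HRSeries:
    """Instantaneous HR (60 / RR, BPM) at interval midpoints.

    Intervals outside the physiological band [0.25 s, 3 s] are discarded
    before conversion.  A centred rolling median over ``smooth_beats`` beats
    (1 disables) suppresses single-beat artifacts before any min/max
    extraction downstream.
    """
    if len(rr.beat_times) < 2:
        raise ValueError("need at least 2 beats")
    if smooth_beats < 1:
        raise ValueError("smooth_beats must be >= 1")
    iv = rr.intervals
    keep = (iv >= RR_MIN_S) & (iv <= RR_MAX_S)
    if not keep.any():
        raise ValueError("no physiological RR intervals after cleaning")
    mids = (rr.beat_times[:-1] + rr.beat_times[1:])[keep] / 2.0
    hr = 60.0 / iv[keep]
    if smooth_beats > 1:
        hr = (
            pd.Series(hr)
            .rolling(smooth_beats, center=True, min_periods=1)
            .median()
            .to_numpy()
        )
    return HRSeries(times=mids, hr=hr)


def _window_stats(series: HRSeries, lo: float, hi: float, name: str):
    m = (series.times >= lo) & (series.times < hi)
    if m.sum() < 3:
        raise ValueError(f"window '{name}' contains fewer than 3 HR samples")
    t, h = series.times[m], series.hr[m]
    span = t[-1] - t[0]
    mean = float(np.trapezoid(h, t) / span) if span > 0 else float(h.mean())
    return float(h.min()), float(h.max()), mean


def compute_hr_params(series: HRSeries, win: TaskWindows) -> HRParams:
    """Five HR parameters over the baseline/task/post layout.

    ``hr_increase = 100 * (max task - min baseline) / min baseline`` and
    ``hr_decrease = 100 * (min post - max task) / max task`` (signed, so a
    recovery below the task peak is negative).  Window means are
    time-weighted (trapezoidal) averages.
    """
    base_min, _, base_mean = _window_stats(series, *win.baseline, "baseline")
    _, task_max, task_mean = _window_stats(series, *win.task, "task")
    post_min, _, post_mean = _window_stats(series, *win.post, "post")
    return HRParams(
        hr_increase=100.0 * (task_max - base_min) / base_min,
        hr_decrease=100.0 * (post_min - task_max) / task_max,
        mean_baseline=base_mean,
        mean_task=task_mean,
        mean_post=post_mean,
    )
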