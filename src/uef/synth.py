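"""Seeded synthetic recordings for the UEF frailty analysis.

The study data (wrist gyroscope trials, chest ECG, smartwatch HR streams
from a paired two-device protocol) are not publicly deposited, so this
module generates statistically analogous records with known ground truth:

* flexion/extension angular-velocity trials built from alternating
  half-sine lobes with a linearly declining, jittered amplitude schedule,
  low-frequency drift and white noise;
* a device overlay (gain, offset, extra noise, timing jitter) that turns
  one ideal trial into a reference-sensor and a smartwatch version;
* beat series with a baseline / task / recovery heart-rate profile,
  rendered both as a template-based ECG waveform with a synchronized
  accelerometer channel and as a lagged, smoothed, noisy per-second HR
  stream emulating wrist PPG;
* paired cohorts combining all of the above.

Every generator is a pure function of its parameters including the seed,
and returns a :class:`SyntheticTruth` carrying the noise-free parameter
values the analysis should recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .hr import ECGRecord, HRSeries, RRSeries, TaskWindows
from .motor import Anthropometrics, GyroTrial

__all__ = [
    "MotorSimParams",
    "DeviceNoiseModel",
    "HRProfile",
    "SyntheticTruth",
    "MotorTrialPair",
    "SubjectRecord",
    "Cohort",
    "gen_flexion_trial",
    "apply_device",
    "gen_rr_series",
    "gen_ecg_waveform",
    "gen_ppg_hr",
    "gen_cohort",
    "DEFAULT_MOTOR_BOUNDS",
    "DEFAULT_HR_BOUNDS",
    "DEFAULT_DEVICE_MODELS",
    "DEFAULT_WATCH_HR_MODEL",
]

#: fixed frequency of the slow additive drift component (Hz)
DRIFT_FREQ_HZ = 0.1


@dataclass(frozen=True)
class MotorSimParams:
    """Parameters of one synthetic flexion/extension trial.

    ``peak_velocity`` is the nominal lobe amplitude A (deg/s) of the first
    5 s; each cycle's velocity range is 2A.  ``decline_pct`` is the signed
    percentage change of the mean per-cycle range from the first to the
    last 5 s (negative = fatigue).  ``cycle_cv`` adds multiplicative
    Gaussian cycle-to-cycle amplitude jitter (% of the scheduled
    amplitude).  If ``rom`` (deg, target excursion per flexion lobe) is
    given, the cycle frequency is derived from it as ``A / (pi * rom)``
    and overrides ``cycle_frequency``.
    """

    peak_velocity: float = 350.0   # deg/s
    cycle_frequency: float = 1.1   # Hz (one flexion+extension per cycle)
    rom: float | None = None       # deg
    decline_pct: float = -5.0      # %
    cycle_cv: float = 5.0          # %
    noise_sd: float = 5.0          # deg/s
    drift_amp: float = 0.0         # deg/s
    duration_s: float = 20.0
    fs: float = 100.0
    seed: int = 0

    def resolved_frequency(self) -> float:
        if self.rom is not None:
            if self.rom <= 0:
                raise ValueError("rom must be positive")
            return self.peak_velocity / (math.pi * self.rom)
        return self.cycle_frequency

    def validate(self) -> None:
        if self.peak_velocity <= 0:
            raise ValueError("peak_velocity must be positive")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValueError("duration and sampling rate must be positive")
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s * fs must be an integral sample count")
        f = self.resolved_frequency()
        if f <= 0:
            raise ValueError("cycle frequency must be positive")
        if f >= self.fs / 4:
            raise ValueError("cycle_frequency >= fs/4: cycles unresolvable")
        if self.peak_velocity <= self.noise_sd:
            raise ValueError("peak_velocity must exceed noise_sd")
        if self.noise_sd < 0 or self.drift_amp < 0 or self.cycle_cv < 0:
            raise ValueError("noise, drift and cv must be non-negative")


@dataclass(frozen=True)
class DeviceNoiseModel:
    """Multiplicative/additive overlay emulating inter-device discrepancies
    (calibration gain, offset, sensor noise and clock jitter)."""

    gain: float = 1.0            # unitless
    offset: float = 0.0          # deg/s
    extra_noise_sd: float = 0.0  # deg/s
    timing_jitter_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if self.extra_noise_sd < 0 or self.timing_jitter_ms < 0:
            raise ValueError("noise and jitter must be non-negative")


@dataclass(frozen=True)
class HRProfile:
    """Baseline / task / recovery heart-rate profile.

    During the task, HR ramps linearly from ``baseline_hr`` to
    ``baseline_hr * (1 + task_increase_pct/100)`` over the first
    ``task_ramp_frac`` of the task and then plateaus; during recovery it
    decays exponentially back toward baseline with time constant
    ``recovery_tau_s``.  ``hrv_sd_ms`` adds Gaussian RR jitter.
    """

    baseline_hr: float = 80.0       # BPM
    task_increase_pct: float = 36.0  # %
    recovery_tau_s: float = 25.0    # s
    hrv_sd_ms: float = 10.0         # ms
    baseline_s: float = 60.0
    task_s: float = 20.0
    recovery_s: float = 60.0
    task_ramp_frac: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not 30.0 < self.baseline_hr < 220.0:
            raise ValueError("baseline_hr must lie in (30, 220) BPM")
        if self.task_increase_pct <= -100.0:
            raise ValueError("task_increase_pct must exceed -100")
        if self.recovery_tau_s <= 0:
            raise ValueError("recovery_tau_s must be positive")
        if min(self.baseline_s, self.task_s, self.recovery_s) <= 0:
            raise ValueError("window durations must be positive")
        if not 0.0 < self.task_ramp_frac <= 1.0:
            raise ValueError("task_ramp_frac must lie in (0, 1]")
        if self.hrv_sd_ms < 0:
            raise ValueError("hrv_sd_ms must be non-negative")
        if 60.0 / self.peak_hr < 0.25:
            raise ValueError("profile yields RR < 250 ms (HR > 240 BPM)")

    @property
    def peak_hr(self) -> float:
        return self.baseline_hr * (1.0 + self.task_increase_pct / 100.0)

    @property
    def total_s(self) -> float:
        return self.baseline_s + self.task_s + self.recovery_s

    @property
    def windows(self) -> TaskWindows:
        return TaskWindows(
            0.0,
            self.baseline_s,
            self.baseline_s + self.task_s,
            self.total_s,
        )

    def instantaneous_hr(self, t: np.ndarray) -> np.ndarray:
        """Noise-free instantaneous HR (BPM) at times ``t`` (s)."""
        t = np.asarray(t, dtype=float)
        b, p = self.baseline_hr, self.peak_hr
        t1 = self.baseline_s
        t2 = t1 + self.task_s
        ramp = self.task_ramp_frac * self.task_s
        hr = np.full(t.shape, float(b))
        in_ramp = (t >= t1) & (t < t1 + ramp)
        hr[in_ramp] = b + (p - b) * (t[in_ramp] - t1) / ramp
        in_plateau = (t >= t1 + ramp) & (t < t2)
        hr[in_plateau] = p
        in_rec = t >= t2
        hr[in_rec] = b + (p - b) * np.exp(-(t[in_rec] - t2) / self.recovery_tau_s)
        return hr

    def truth_params(self) -> dict[str, float]:
        """Closed-form noise-free values of the five HR parameters."""
        b, p = self.baseline_hr, self.peak_hr
        ramp = self.task_ramp_frac * self.task_s
        hr_end = b + (p - b) * math.exp(-self.recovery_s / self.recovery_tau_s)
        tau, rec = self.recovery_tau_s, self.recovery_s
        mean_post = b + (p - b) * tau / rec * (1.0 - math.exp(-rec / tau))
        return {
            "hr_increase": 100.0 * (max(b, p) - b) / b,
            "hr_decrease": 100.0 * (min(hr_end, p) - p) / p,
            "mean_baseline": b,
            "mean_task": ((b + p) / 2.0 * ramp + p * (self.task_s - ramp)) / self.task_s,
            "mean_post": mean_post,
        }


@dataclass
class SyntheticTruth:
    """Ground-truth parameter values for one generated record.

    ``values`` holds the noise-free analysis outputs; ``per_cycle`` holds
    generator internals (e.g. scheduled per-cycle ranges) useful in tests.
    Regenerating with the same parameters reproduces it bit-for-bit.
    """

    kind: str                       # "motor" | "hr"
    values: dict[str, float]
    per_cycle: dict[str, np.ndarray] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "kind": self.kind,
            "values": {k: float(v) for k, v in self.values.items()},
            "per_cycle": {k: np.asarray(v).tolist() for k, v in self.per_cycle.items()},
        }


# --------------------------------------------------------------------------
# motor trial generation
# --------------------------------------------------------------------------

def _amplitude_schedule(params: MotorSimParams, f: float, rng: np.random.Generator):
    """Per-cycle amplitudes: linear decline (exact on the window means of
    the noise-free schedule) times multiplicative jitter."""
    n_cycles = int(math.floor(params.duration_s * f + 1e-9))
    if n_cycles < 1:
        raise ValueError("trial shorter than one cycle")
    centers = (np.arange(n_cycles) + 0.5) / f
    w = min(5.0, params.duration_s / 2.0)
    first = centers < w
    last = centers >= params.duration_s - w
    sched = np.ones(n_cycles)
    if params.decline_pct != 0.0:
        if not first.any() or not last.any():
            raise ValueError("decline schedule needs cycles in both 5 s windows")
        m1 = centers[first].mean()
        m2 = centers[last].mean()
        r = 1.0 + params.decline_pct / 100.0
        s = (r - 1.0) / (m2 - m1)
        sched = np.clip(1.0 + s * (centers - m1), 0.05, None)
    jitter = np.clip(
        1.0 + params.cycle_cv / 100.0 * rng.standard_normal(n_cycles), 0.05, None
    )
    return params.peak_velocity * sched * jitter, centers


def gen_flexion_trial(params: MotorSimParams) -> tuple[GyroTrial, SyntheticTruth]:
    """Generate one 20 s flexion/extension angular-velocity trial.

    The noise-free signal is ``A_i * sin(2 pi f t)`` with a per-cycle
    amplitude ``A_i`` from the declining, jittered schedule; a drift
    sinusoid (``drift_amp`` at 0.1 Hz, random phase) and white noise of SD
    ``noise_sd`` are added.  The truth records the noise-free per-cycle
    velocity ranges (2 A_i) and angular ranges (A_i / (pi f)).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    f = params.resolved_frequency()
    n = int(round(params.duration_s * params.fs))
    t = np.arange(n) / params.fs

    amps, centers = _amplitude_schedule(params, f, rng)
    cyc = np.minimum((t * f).astype(int), len(amps) - 1)
    clean = amps[cyc] * np.sin(2.0 * np.pi * f * t)

    drift_phase = rng.uniform(0.0, 2.0 * np.pi)
    drift = params.drift_amp * np.sin(2.0 * np.pi * DRIFT_FREQ_HZ * t + drift_phase)
    noise = params.noise_sd * rng.standard_normal(n)
    samples = clean + drift + noise

    ranges = 2.0 * amps
    excursions = amps / (np.pi * f)
    w = min(5.0, params.duration_s / 2.0)
    first = ranges[centers < w]
    last = ranges[centers >= params.duration_s - w]
    mean_r = float(ranges.mean())
    sd_r = float(ranges.std(ddof=1)) if len(ranges) > 1 else 0.0
    truth = SyntheticTruth(
        kind="motor",
        values={
            "speed": mean_r,
            "flexibility": float(excursions.mean()),
            "cv": 100.0 * sd_r / mean_r,
            "decline": (
                100.0 * (last.mean() - first.mean()) / first.mean()
                if len(first) and len(last)
                else 0.0
            ),
            "peak_alpha_rad": float(
                np.mean(2.0 * np.pi * f * amps) * np.pi / 180.0
            ),
            "n_cycles": float(len(amps)),
            "cycle_frequency": f,
        },
        per_cycle={"velocity_range": ranges, "angular_range": excursions,
                   "center_time_s": centers},
    )
    trial = GyroTrial(samples=samples, fs=params.fs, device_label="ideal")
    return trial, truth


def apply_device(trial: GyroTrial, model: DeviceNoiseModel, seed: int = 0) -> GyroTrial:
    """Overlay a device response on an ideal trial (input unmodified).

    Output is ``gain * x + offset`` resampled at jittered times (smooth
    clock error with SD ``timing_jitter_ms``) plus white noise of SD
    ``extra_noise_sd``.  The identity model returns the input samples
    bit-for-bit.
    """
    if trial.n == 0:
        raise ValueError("empty trial")
    rng = np.random.default_rng(seed)
    x = model.gain * trial.samples + model.offset
    if model.timing_jitter_ms > 0:
        t = trial.time
        knots = np.arange(0.0, trial.duration_s + 1.0, 1.0)
        delta = rng.standard_normal(len(knots)) * model.timing_jitter_ms * 1e-3
        jit = np.interp(t, knots, delta)
        if trial.is_triaxial:
            x = np.column_stack(
                [np.interp(t + jit, t, x[:, j]) for j in range(3)]
            )
        else:
            x = np.interp(t + jit, t, x)
    if model.extra_noise_sd > 0:
        x = x + model.extra_noise_sd * rng.standard_normal(x.shape)
    return replace(trial, samples=x, device_label=trial.device_label or "device")


# --------------------------------------------------------------------------
# heart-rate generation
# --------------------------------------------------------------------------

def gen_rr_series(profile: HRProfile) -> tuple[RRSeries, SyntheticTruth]:
    """Generate beat times over the baseline/task/recovery profile.

    Beats are placed by stepping the true instantaneous RR (60/HR at the
    current beat time) with additive Gaussian jitter of SD ``hrv_sd_ms``.
    The truth carries the closed-form noise-free HR parameters.
    """
    profile.validate()
    rng = np.random.default_rng(profile.seed)
    beats = [0.0]
    total = profile.total_s
    while True:
        t = beats[-1]
        rr = 60.0 / float(profile.instantaneous_hr(np.array([t]))[0])
        rr = rr + rng.standard_normal() * profile.hrv_sd_ms * 1e-3
        rr = float(np.clip(rr, RR_FLOOR_S, None))
        if t + rr >= total:
            break
        beats.append(t + rr)
    rr_series = RRSeries(
        beat_times=np.array(beats), source="synthetic", windows=profile.windows
    )
    truth = SyntheticTruth(kind="hr", values=profile.truth_params())
    return rr_series, truth


RR_FLOOR_S = 0.25


def gen_ecg_waveform(
    rr: RRSeries,
    fs: float = 1000.0,
    snr_db: float | None = None,
    include_accel: bool = True,
    fs_acc: float = 100.0,
    wander_mv: float = 0.05,
    seed: int = 0,
) -> ECGRecord:
    """Render a beat series as a template-based ECG with accelerometer.

    Each beat contributes a narrow positive Gaussian QRS (1 mV, 10 ms SD)
    with smaller P and T Gaussians; baseline wander at 0.25 Hz and,
    when ``snr_db`` is given, white noise scaled to that SNR relative to
    the clean waveform RMS are added.  The accelerometer channel is
    near-zero noise outside the task window and high-variance inside it
    (quiet record if the series carries no windows).
    """
    if fs < 250:
        raise ValueError("ECG sampling rate must be >= 250 Hz")
    if len(rr.beat_times) == 0:
        raise ValueError("empty beat series")
    total = rr.windows.t3 if rr.windows is not None else rr.beat_times[-1] + 1.0
    n = int(round(total * fs))
    t0 = rr.beat_times[0]
    ecg = np.zeros(n)

    # (amplitude mV, sd s, offset from R s)
    waves = [(1.0, 0.010, 0.0), (0.12, 0.020, -0.16), (0.25, 0.050, 0.22)]
    for beat in rr.beat_times:
        for amp, sd, off in waves:
            c = beat + off
            a = max(0, int((c - 5 * sd) * fs))
            b = min(n, int((c + 5 * sd) * fs) + 1)
            if a >= b:
                continue
            tt = np.arange(a, b) / fs
            ecg[a:b] += amp * np.exp(-0.5 * ((tt - c) / sd) ** 2)

    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    tt = np.arange(n) / fs
    clean_rms = float(np.sqrt(np.mean(ecg * ecg)))
    ecg = ecg + wander_mv * np.sin(2.0 * np.pi * 0.25 * tt + phase)
    if snr_db is not None:
        noise_sd = clean_rms / 10.0 ** (snr_db / 20.0)
        ecg = ecg + noise_sd * rng.standard_normal(n)

    accel = None
    if include_accel:
        m = int(round(total * fs_acc))
        scale = np.full(m, 0.005)
        if rr.windows is not None:
            ta = np.arange(m) / fs_acc
            scale[(ta >= rr.windows.t1) & (ta < rr.windows.t2)] = 0.4
        accel = rng.standard_normal((m, 3)) * scale[:, None]
    return ECGRecord(ecg=ecg, fs_ecg=fs, accel=accel, fs_acc=fs_acc,
                     start_time=float(min(0.0, t0)))


def gen_ppg_hr(
    rr: RRSeries,
    smooth_window_s: float = 10.0,
    lag_s: float = 5.0,
    noise_bpm: float = 2.5,
    seed: int = 0,
    dt_s: float = 1.0,
    task_noise_factor: float = 4.0,
) -> HRSeries:
    """Emulate a wrist-PPG per-second HR stream from the true beat series.

    The true instantaneous HR is sampled on a ``dt_s`` grid, averaged over
    a trailing ``smooth_window_s`` window, delayed by ``lag_s`` and
    perturbed with Gaussian noise — the mechanism by which dynamic HR
    extrema are attenuated while window means survive.  Optical HR is far
    noisier while the wrist is moving, so when the series carries task
    windows the noise SD inside the task is ``task_noise_factor`` times
    ``noise_bpm``; this selectively corrupts the task extrema that the
    dynamic parameters depend on while window means, which average the
    noise away, are barely affected.
    """
    if smooth_window_s < 0 or lag_s < 0 or noise_bpm < 0:
        raise ValueError("smoothing, lag and noise must be non-negative")
    if task_noise_factor < 1:
        raise ValueError("task_noise_factor must be >= 1")
    if len(rr.beat_times) < 2:
        raise ValueError("need at least 2 beats")
    iv = rr.intervals
    mids = (rr.beat_times[:-1] + rr.beat_times[1:]) / 2.0
    hr_inst = 60.0 / iv
    total = rr.windows.t3 if rr.windows is not None else rr.beat_times[-1]
    times = np.arange(dt_s / 2.0, total, dt_s)
    hr = np.interp(times, mids, hr_inst)

    w = int(round(smooth_window_s / dt_s))
    if w > 1:
        c = np.cumsum(np.insert(hr, 0, 0.0))
        idx = np.arange(len(hr))
        lo = np.maximum(0, idx - w + 1)
        hr = (c[idx + 1] - c[lo]) / (idx + 1 - lo)
    m = int(round(lag_s / dt_s))
    if m > 0:
        hr = np.concatenate([np.full(m, hr[0]), hr[:-m]])
    rng = np.random.default_rng(seed)
    scale = np.full(len(hr), float(noise_bpm))
    if rr.windows is not None:
        in_task = (times >= rr.windows.t1) & (times < rr.windows.t2)
        scale[in_task] *= task_noise_factor
    hr = hr + scale * rng.standard_normal(len(hr))
    hr = np.clip(hr, 1.0, None)
    return HRSeries(times=times, hr=hr)


# --------------------------------------------------------------------------
# paired cohorts
# --------------------------------------------------------------------------

#: study-condition parameter bounds for subject-level uniform draws.  The
#: weighted condition (hand-held weight) is slower, smaller in excursion
#: and declines more — emulating the frail end of the spectrum.
DEFAULT_MOTOR_BOUNDS: dict[str, dict[str, tuple[float, float]]] = {
    "unweighted": {
        "peak_velocity": (250.0, 450.0),
        "cycle_frequency": (0.9, 1.3),
        "decline_pct": (-12.0, 4.0),
        "cycle_cv": (3.0, 10.0),
        "noise_sd": (4.0, 8.0),
        "drift_amp": (5.0, 15.0),
    },
    "weighted": {
        "peak_velocity": (90.0, 250.0),
        "cycle_frequency": (0.7, 1.1),
        "decline_pct": (-25.0, -5.0),
        "cycle_cv": (5.0, 14.0),
        "noise_sd": (4.0, 8.0),
        "drift_amp": (5.0, 15.0),
    },
}

DEFAULT_HR_BOUNDS: dict[str, tuple[float, float]] = {
    "baseline_hr": (65.0, 95.0),
    "task_increase_pct": (20.0, 55.0),
    "recovery_tau_s": (15.0, 35.0),
    "hrv_sd_ms": (5.0, 20.0),
}

#: device overlays: near-transparent reference sensor vs a smartwatch with
#: a small calibration gain, offset, extra noise and clock jitter
DEFAULT_DEVICE_MODELS: dict[str, DeviceNoiseModel] = {
    "reference": DeviceNoiseModel(gain=1.0, offset=0.0, extra_noise_sd=2.0,
                                  timing_jitter_ms=0.0),
    "watch": DeviceNoiseModel(gain=1.04, offset=2.0, extra_noise_sd=6.0,
                              timing_jitter_ms=5.0),
}

#: wrist-PPG HR stream emulation used for the watch side of the HR pairing
DEFAULT_WATCH_HR_MODEL: dict[str, float] = {
    "smooth_window_s": 10.0,
    "lag_s": 5.0,
    "noise_bpm": 2.5,
    "task_noise_factor": 4.0,
}

#: added weight of the weighted condition (kg at the default radius)
WEIGHTED_ADDED_MASS_KG = 0.5

#: within-subject trial-to-trial multiplicative variation (SD)
TRIAL_VARIATION_SD = 0.04

#: ECG rendering SNR for cohort records (dB)
COHORT_ECG_SNR_DB = 20.0


@dataclass
class MotorTrialPair:
    """One trial seen by both devices, with its generator truth."""

    reference: GyroTrial
    watch: GyroTrial
    truth: SyntheticTruth
    params: MotorSimParams


@dataclass
class SubjectRecord:
    subject_id: str
    anthro: Anthropometrics
    motor: dict[str, list[MotorTrialPair]]  # condition -> trials
    ecg: ECGRecord
    watch_hr: HRSeries
    hr_truth: SyntheticTruth
    hr_windows: TaskWindows
    hr_profile: HRProfile


@dataclass
class Cohort:
    subjects: list[SubjectRecord]
    seed: int
    device_models: dict[str, DeviceNoiseModel]
    watch_hr_model: dict[str, float]


def _check_bounds(bounds: dict) -> None:
    for key, val in bounds.items():
        if isinstance(val, dict):
            _check_bounds(val)
        else:
            lo, hi = val
            if hi < lo:
                raise ValueError(f"degenerate bounds for '{key}': {val}")


def _draw(rng: np.random.Generator, bounds: tuple[float, float]) -> float:
    return float(rng.uniform(*bounds))


def gen_cohort(
    n: int = 34,
    motor_bounds: dict | None = None,
    hr_bounds: dict | None = None,
    device_models: dict[str, DeviceNoiseModel] | None = None,
    watch_hr_model: dict[str, float] | None = None,
    seed: int = 0,
    n_trials: int = 3,
    conditions: tuple[str, ...] = ("unweighted", "weighted"),
) -> Cohort:
    """Simulate a paired two-device cohort.

    Each subject performs ``n_trials`` trials per condition (weighted and
    unweighted), recorded by both the reference sensor and the smartwatch
    overlay, plus one ECG + watch-HR session.  Subject-level parameters are
    drawn uniformly within the bounds; trials vary around the subject level
    by a small multiplicative factor.  Fully reproducible from ``seed``.
    """
    if n < 2:
        raise ValueError("cohort needs at least 2 subjects")
    motor_bounds = motor_bounds or DEFAULT_MOTOR_BOUNDS
    hr_bounds = hr_bounds or DEFAULT_HR_BOUNDS
    device_models = device_models or DEFAULT_DEVICE_MODELS
    watch_hr_model = watch_hr_model or DEFAULT_WATCH_HR_MODEL
    _check_bounds(motor_bounds)
    _check_bounds(hr_bounds)

    master = np.random.default_rng(seed)
    subjects: list[SubjectRecord] = []
    for i in range(n):
        rng = np.random.default_rng(master.integers(0, 2**31 - 1))
        body_mass = float(np.clip(rng.normal(64.0, 14.0), 40.0, 120.0))
        height = float(np.clip(rng.normal(1.68, 0.09), 1.45, 2.05))
        anthro = Anthropometrics(body_mass=body_mass, height=height)

        motor: dict[str, list[MotorTrialPair]] = {}
        for cond in conditions:
            b = motor_bounds[cond]
            base = {k: _draw(rng, v) for k, v in b.items()}
            trials = []
            for _ in range(n_trials):
                fac = float(np.clip(rng.normal(1.0, TRIAL_VARIATION_SD), 0.7, 1.3))
                params = MotorSimParams(
                    peak_velocity=base["peak_velocity"] * fac,
                    cycle_frequency=base["cycle_frequency"],
                    decline_pct=base["decline_pct"],
                    cycle_cv=base["cycle_cv"],
                    noise_sd=base["noise_sd"],
                    drift_amp=base["drift_amp"],
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                ideal, truth = gen_flexion_trial(params)
                ideal = replace(ideal, condition=cond)
                ref = apply_device(ideal, device_models["reference"],
                                   seed=int(rng.integers(0, 2**31 - 1)))
                watch = apply_device(ideal, device_models["watch"],
                                     seed=int(rng.integers(0, 2**31 - 1)))
                ref = replace(ref, device_label="reference")
                watch = replace(watch, device_label="watch")
                trials.append(MotorTrialPair(ref, watch, truth, params))
            motor[cond] = trials

        profile = HRProfile(
            baseline_hr=_draw(rng, hr_bounds["baseline_hr"]),
            task_increase_pct=_draw(rng, hr_bounds["task_increase_pct"]),
            recovery_tau_s=_draw(rng, hr_bounds["recovery_tau_s"]),
            hrv_sd_ms=_draw(rng, hr_bounds["hrv_sd_ms"]),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rr, hr_truth = gen_rr_series(profile)
        ecg = gen_ecg_waveform(rr, snr_db=COHORT_ECG_SNR_DB,
                               seed=int(rng.integers(0, 2**31 - 1)))
        watch_hr = gen_ppg_hr(rr, seed=int(rng.integers(0, 2**31 - 1)),
                              **watch_hr_model)
        subjects.append(
            SubjectRecord(
                subject_id=f"S{i + 1:03d}",
                anthro=anthro,
                motor=motor,
                ecg=ecg,
                watch_hr=watch_hr,
                hr_truth=hr_truth,
                hr_windows=profile.windows,
                hr_profile=profile,
            )
        )
    return Cohort(subjects=subjects, seed=seed, device_models=device_models,
                  watch_hr_model=dict(watch_hr_model))
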