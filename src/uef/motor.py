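"""Elbow-flexion kinematics from wrist angular velocity.

The upper-extremity-function (UEF) motor test asks a participant to flex and
extend the elbow as fast as possible for 20 s while a wrist gyroscope records
angular velocity (deg/s).  This module turns one such trial into the five
motor parameters used for frailty scoring:

* **speed** — mean per-cycle angular-velocity range (max minus min), deg/s;
* **moment** — mean per-cycle peak elbow moment, ``I * alpha`` with the
  forearm+hand moment of inertia, Nm;
* **flexibility** — mean per-cycle angular excursion, the integral of
  angular velocity over the flexion lobe, deg;
* **coefficient of variation** of the per-cycle ranges, %;
* **last-vs-first** — percentage change of the mean range between the last
  and first 5 s of the trial (fatigue-related slowing), signed %;

plus a 0-100 composite frailty score (0 = fit, 100 = extremely frail)
computed by a configurable linear surrogate model.

Processing follows filter -> segment -> per-cycle statistics.  All filters
are zero-phase (forward-backward) so per-cycle extrema are not biased by
phase distortion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "GyroTrial",
    "FlexionCycle",
    "Anthropometrics",
    "FrailtyModel",
    "MotorParams",
    "DEFAULT_FRAILTY_MODEL",
    "highpass",
    "lowpass",
    "select_flexion_axis",
    "segment_cycles",
    "compute_speed",
    "compute_flexibility",
    "compute_moment",
    "compute_cv_of_ranges",
    "compute_last_vs_first",
    "compute_motor_params",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class GyroTrial:
    """One angular-velocity recording (deg/s) from one device and condition.

    ``samples`` is 1-D for a single (flexion-axis) channel or ``(n, 3)`` for
    a raw triaxial recording.  ``condition`` distinguishes the weighted and
    unweighted protocol arms.
    """

    samples: np.ndarray
    fs: float
    condition: str = "unweighted"
    device_label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim not in (1, 2):
            raise ValueError("samples must be 1-D or (n, 3)")
        if self.samples.ndim == 2 and self.samples.shape[1] != 3:
            raise ValueError("triaxial trials must have exactly 3 columns")

    @property
    def n(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n) / self.fs

    @property
    def is_triaxial(self) -> bool:
        return self.samples.ndim == 2

    def check_duration(self, expected_s: float = 20.0, tol_s: float = 1.0) -> None:
        if abs(self.duration_s - expected_s) > tol_s:
            raise ValueError(
                f"trial duration {self.duration_s:.2f} s outside "
                f"{expected_s} +/- {tol_s} s"
            )


@dataclass
class FlexionCycle:
    """One segmented flexion/extension cycle (half-open sample indices)."""

    start_idx: int
    end_idx: int
    velocity_range: float       # deg/s, max - min within the cycle
    angular_range: float        # deg, |integral| over the flexion lobe
    peak_accel: float | None = None   # deg/s^2
    peak_moment: float | None = None  # Nm

    def __post_init__(self) -> None:
        if self.end_idx <= self.start_idx:
            raise ValueError("cycle end must be after start")
        if self.velocity_range < 0 or self.angular_range < 0:
            raise ValueError("cycle ranges must be non-negative")

    def center_idx(self) -> float:
        return 0.5 * (self.start_idx + self.end_idx)


# Standard anthropometric segment proportions (Winter-style body-segment
# tables): forearm+hand mass fraction of body mass, forearm length fraction
# of stature, and radius of gyration about the elbow as a fraction of
# forearm length.
FOREARM_HAND_MASS_FRAC = 0.022
FOREARM_LENGTH_FRAC = 0.146
RADIUS_OF_GYRATION_FRAC = 0.827


@dataclass
class Anthropometrics:
    """Segment properties needed for the elbow-moment estimate.

    ``forearm_hand_inertia`` (kg m^2, about the elbow) may be given directly;
    otherwise it is derived from body mass and height using standard segment
    proportions.  ``added_mass`` models the hand-held weight of the weighted
    condition as a point mass at ``added_mass_radius`` from the elbow.
    """

    body_mass: float | None = None   # kg
    height: float | None = None      # m
    added_mass: float = 0.0          # kg
    added_mass_radius: float = 0.25  # m
    forearm_hand_inertia: float | None = None  # kg m^2

    def __post_init__(self) -> None:
        if self.added_mass < 0 or self.added_mass_radius < 0:
            raise ValueError("added mass and radius must be non-negative")
        if self.forearm_hand_inertia is None:
            if self.body_mass is None or self.height is None:
                raise ValueError(
                    "anthropometrics incomplete: give forearm_hand_inertia "
                    "or both body_mass and height"
                )
            if self.body_mass <= 0 or self.height <= 0:
                raise ValueError("body mass and height must be positive")
            m = FOREARM_HAND_MASS_FRAC * self.body_mass
            rho = RADIUS_OF_GYRATION_FRAC * FOREARM_LENGTH_FRAC * self.height
            self.forearm_hand_inertia = m * rho * rho
        if self.forearm_hand_inertia <= 0:
            raise ValueError("segment inertia must be positive")

    @property
    def total_inertia(self) -> float:
        """Segment inertia plus the point-mass contribution of added weight."""
        return self.forearm_hand_inertia + self.added_mass * self.added_mass_radius**2


# --------------------------------------------------------------------------
# frailty surrogate model
# --------------------------------------------------------------------------

#: Internal sub-parameter keys, independent of the Table-label naming switch.
SUBPARAM_KEYS = ("speed", "moment", "flexibility", "cv", "decline")


@dataclass(frozen=True)
class FrailtyModel:
    """Linear surrogate frailty-score model.

    Each sub-parameter ``x`` is normalised between a *fit* anchor (mapped to
    0) and a *frail* anchor (mapped to 1), clipped, then combined with
    non-negative weights summing to one; the score is ``100 * sum(w * norm)``.
    Anchor order encodes direction: for speed the frail anchor is *below*
    the fit anchor (slower is frailer), for cycle-to-cycle variability it is
    above.

    This is a documented surrogate with anchors spanning the plausible
    young-to-frail range of each sub-parameter; it is **not** the published
    regression-based frailty model, whose coefficients are not public.
    """

    anchors: dict[str, tuple[float, float]]  # key -> (fit_value, frail_value)
    weights: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.anchors) != set(self.weights):
            raise ValueError("anchors and weights must cover the same keys")
        w = np.array([self.weights[k] for k in self.anchors])
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        for k, (fit, frail) in self.anchors.items():
            if fit == frail:
                raise ValueError(f"anchors for '{k}' must be distinct")

    def subscore(self, key: str, value: float) -> float:
        fit, frail = self.anchors[key]
        return float(np.clip((value - fit) / (frail - fit), 0.0, 1.0))

    def score(self, subparams: dict[str, float]) -> float:
        """0-100 frailty score from the five sub-parameter values."""
        total = sum(
            self.weights[k] * self.subscore(k, subparams[k]) for k in self.anchors
        )
        return float(100.0 * np.clip(total, 0.0, 1.0))


#: Default anchors: fit/frail values spanning roughly the cohort mean +/- 2 SD
#: of each sub-parameter in a mixed weighted/unweighted protocol.
DEFAULT_FRAILTY_MODEL = FrailtyModel(
    anchors={
        "speed": (1400.0, 0.0),        # deg/s; slower -> frailer
        "moment": (3.9, 0.6),          # Nm; weaker -> frailer
        "flexibility": (166.0, 44.0),  # deg; smaller excursion -> frailer
        "cv": (0.0, 17.2),             # %; more variable -> frailer
        "decline": (19.8, -19.4),      # %; steeper slowing -> frailer
    },
    weights={k: 0.2 for k in SUBPARAM_KEYS},
)


@dataclass
class MotorParams:
    """The five motor outputs plus the composite frailty score for one trial.

    ``speed_reduction`` / ``speed_variability`` follow the ``naming`` switch:
    with ``naming="table1"`` speed_reduction is the CV of the per-cycle
    ranges and speed_variability the last-vs-first percentage change; with
    ``naming="swapped"`` the mapping is reversed.  ``cv_pct`` and
    ``decline_pct`` always hold the unambiguous underlying quantities.
    """

    speed: float
    moment: float
    flexibility: float
    speed_reduction: float
    speed_variability: float
    frailty_score: float
    cv_pct: float = 0.0
    decline_pct: float = 0.0
    n_cycles: int = 0
    naming: str = "table1"

    def __post_init__(self) -> None:
        if min(self.speed, self.moment, self.flexibility) < 0:
            raise ValueError("speed, moment and flexibility must be >= 0")
        if not 0.0 <= self.frailty_score <= 100.0:
            raise ValueError("frailty score must lie in [0, 100]")

    def as_dict(self) -> dict[str, float]:
        return {
            "speed": self.speed,
            "moment": self.moment,
            "flexibility": self.flexibility,
            "speed_reduction": self.speed_reduction,
            "speed_variability": self.speed_variability,
            "frailty_score": self.frailty_score,
        }


# --------------------------------------------------------------------------
# filtering
# --------------------------------------------------------------------------

def _apply_sos(trial: GyroTrial, sos: np.ndarray) -> GyroTrial:
    x = trial.samples
    if trial.is_triaxial:
        y = np.column_stack(
            [signal.sosfiltfilt(sos, x[:, j]) for j in range(3)]
        )
    else:
        y = signal.sosfiltfilt(sos, x)
    return replace(trial, samples=y)


def highpass(trial: GyroTrial, cutoff: float = 2.5, order: int = 1) -> GyroTrial:
    """Zero-phase Butterworth high-pass (drift and DC removal).

    Applied forward and backward, so the effective amplitude response is the
    squared single-pass magnitude and the phase is zero.  Output length
    equals input length.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff >= trial.fs / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    sos = signal.butter(order, cutoff, btype="highpass", fs=trial.fs, output="sos")
    return _apply_sos(trial, sos)


def lowpass(trial: GyroTrial, cutoff: float = 10.0, order: int = 2) -> GyroTrial:
    """Zero-phase Butterworth low-pass used to denoise before segmentation
    and differentiation; the flexion band (<3 Hz) passes essentially
    unattenuated."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff >= trial.fs / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    sos = signal.butter(order, cutoff, btype="lowpass", fs=trial.fs, output="sos")
    return _apply_sos(trial, sos)


def select_flexion_axis(trial: GyroTrial) -> GyroTrial:
    """Pick the gyroscope axis carrying the flexion/extension movement.

    During the UEF task the elbow flexion axis dominates the signal energy,
    so the maximum-variance channel is selected.  Ties resolve to the first
    axis with a warning.
    """
    if not trial.is_triaxial:
        return trial
    var = trial.samples.var(axis=0)
    if np.all(var == 0):
        raise ValueError("no dominant axis: all channels are constant")
    best = int(np.argmax(var))
    if np.sum(var == var[best]) > 1:
        warnings.warn("variance tie between axes; picking the first", stacklevel=2)
        best = int(np.flatnonzero(var == var[best])[0])
    return replace(trial, samples=trial.samples[:, best])


# --------------------------------------------------------------------------
# segmentation
# --------------------------------------------------------------------------

def _zero_crossings(v: np.ndarray) -> np.ndarray:
    """Indices i where the sign of v changes between i-1 and i (zeros keep
    the previous sign so they do not create crossings by themselves)."""
    s = np.sign(v)
    # forward-fill zero signs
    nz = s != 0
    if not nz.any():
        return np.empty(0, dtype=int)
    idx = np.where(nz, np.arange(len(s)), 0)
    np.maximum.accumulate(idx, out=idx)
    s = s[idx]
    first = np.flatnonzero(nz)[0]
    s[:first] = s[first]
    return np.flatnonzero(s[1:] != s[:-1]) + 1


def segment_cycles(
    trial: GyroTrial,
    min_cycle_ms: float = 200.0,
    min_range_frac: float = 0.1,
) -> list[FlexionCycle]:
    """Split a (filtered) single-axis trial into flexion/extension cycles.

    Cycles are delimited by alternating zero crossings of the velocity:
    a cycle is one positive (flexion) lobe followed by the next negative
    (extension) lobe.  Lobes briefer than half of ``min_cycle_ms`` are
    treated as debounce chatter and merged into their neighbours; partial
    lobes at the record edges are dropped; cycles whose velocity range is
    below ``min_range_frac`` of the median range are discarded.

    Raises ``ValueError("trial unusable ...")`` when fewer than 3 cycles
    survive.
    """
    if trial.is_triaxial:
        raise ValueError("segment a single-axis trial (see select_flexion_axis)")
    v = trial.samples
    n = len(v)
    crossings = _zero_crossings(v)
    if len(crossings) < 2:
        raise ValueError("trial unusable: fewer than 3 flexion cycles found")

    bounds = list(crossings)
    min_lobe = max(2, int(round(0.5 * min_cycle_ms * 1e-3 * trial.fs)))
    # merge debounce chatter: drop the pair of crossings bounding the
    # shortest internal lobe until all inter-crossing lobes are long enough
    while len(bounds) >= 2:
        gaps = np.diff(bounds)
        j = int(np.argmin(gaps))
        if gaps[j] >= min_lobe:
            break
        del bounds[j : j + 2]

    if len(bounds) < 2:
        raise ValueError("trial unusable: fewer than 3 flexion cycles found")

    # lobe list including edge segments; edge lobes kept only if close to
    # full length (>= 60% of the median internal lobe)
    internal = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)]
    med_len = float(np.median([b - a for a, b in internal]))
    lobes = list(internal)
    if bounds[0] >= 0.6 * med_len:
        lobes.insert(0, (0, bounds[0]))
    if n - bounds[-1] >= 0.6 * med_len:
        lobes.append((bounds[-1], n))

    def lobe_sign(a: int, b: int) -> float:
        seg = v[a:b]
        return float(np.sign(seg.sum()))

    cycles: list[FlexionCycle] = []
    i = 0
    dt = 1.0 / trial.fs
    while i < len(lobes) - 1:
        a0, a1 = lobes[i]
        if lobe_sign(a0, a1) <= 0:
            i += 1
            continue
        b0, b1 = lobes[i + 1]
        seg = v[a0:b1]
        vel_range = float(seg.max() - seg.min())
        excursion = abs(float(np.trapezoid(v[a0:a1], dx=dt)))
        cycles.append(
            FlexionCycle(
                start_idx=a0,
                end_idx=b1,
                velocity_range=vel_range,
                angular_range=excursion,
            )
        )
        i += 2

    if cycles:
        med_range = float(np.median([c.velocity_range for c in cycles]))
        kept = [c for c in cycles if c.velocity_range >= min_range_frac * med_range]
        if len(kept) < len(cycles):
            logger.debug("discarded %d low-range cycles", len(cycles) - len(kept))
        cycles = kept

    if len(cycles) < 3:
        raise ValueError("trial unusable: fewer than 3 flexion cycles found")
    return cycles


# --------------------------------------------------------------------------
# per-cycle parameters
# --------------------------------------------------------------------------

def _require_cycles(cycles: list[FlexionCycle], k: int = 3) -> None:
    if len(cycles) < k:
        raise ValueError(f"need at least {k} cycles, got {len(cycles)}")


def compute_speed(cycles: list[FlexionCycle]) -> float:
    """Mean per-cycle angular-velocity range (deg/s)."""
    _require_cycles(cycles)
    return float(np.mean([c.velocity_range for c in cycles]))


def compute_flexibility(cycles: list[FlexionCycle], trial: GyroTrial | None = None) -> float:
    """Mean per-cycle angular excursion (deg): the integral of angular
    velocity over each flexion lobe, averaged across cycles."""
    _require_cycles(cycles)
    return float(np.mean([c.angular_range for c in cycles]))


def compute_moment(
    cycles: list[FlexionCycle],
    trial: GyroTrial,
    anthro: Anthropometrics,
    accel_lowpass_hz: float | None = 10.0,
) -> float:
    """Mean per-cycle peak elbow moment (Nm), ``I_total * max |alpha|``.

    Angular acceleration is the central difference of the (optionally 10 Hz
    low-passed) velocity, converted to rad/s^2.  Gravity torque is not
    modelled — the trial gives no elbow-angle zero reference — so this is
    the inertial moment only.  Added weight enters the inertia as a point
    mass at ``anthro.added_mass_radius``.
    """
    if anthro is None:
        raise ValueError("anthropometrics are required for the moment estimate")
    _require_cycles(cycles)
    src = trial
    if accel_lowpass_hz is not None:
        src = lowpass(trial, accel_lowpass_hz)
    alpha = np.gradient(src.samples, 1.0 / trial.fs) * (np.pi / 180.0)  # rad/s^2
    inertia = anthro.total_inertia
    moments = []
    for c in cycles:
        peak = float(np.max(np.abs(alpha[c.start_idx : c.end_idx])))
        c.peak_accel = peak * 180.0 / np.pi
        c.peak_moment = inertia * peak
        moments.append(c.peak_moment)
    return float(np.mean(moments))


def compute_cv_of_ranges(cycles: list[FlexionCycle]) -> float:
    """Coefficient of variation of the per-cycle velocity ranges (%):
    100 * sample SD / mean."""
    _require_cycles(cycles)
    r = np.array([c.velocity_range for c in cycles])
    mean = r.mean()
    if mean <= 0:
        raise ValueError("mean velocity range is zero; CV undefined")
    return float(100.0 * r.std(ddof=1) / mean)


def compute_last_vs_first(
    cycles: list[FlexionCycle],
    trial: GyroTrial,
    window_s: float = 5.0,
) -> float:
    """Signed percentage change of the mean per-cycle velocity range between
    the last and first ``window_s`` seconds of the trial.

    Negative values indicate within-trial slowing (fatigue)."""
    _require_cycles(cycles)
    if trial.duration_s < 2 * window_s:
        raise ValueError(f"trial shorter than two {window_s} s windows")
    centers = np.array([c.center_idx() for c in cycles]) / trial.fs
    ranges = np.array([c.velocity_range for c in cycles])
    first = ranges[centers < window_s]
    last = ranges[centers >= trial.duration_s - window_s]
    if len(first) == 0:
        raise ValueError("no full cycle in the first window")
    if len(last) == 0:
        raise ValueError("no full cycle in the last window")
    m0 = first.mean()
    return float(100.0 * (last.mean() - m0) / m0)


# --------------------------------------------------------------------------
# full per-trial pipeline
# --------------------------------------------------------------------------

def compute_motor_params(
    trial: GyroTrial,
    anthro: Anthropometrics,
    model: FrailtyModel = DEFAULT_FRAILTY_MODEL,
    naming: str = "table1",
    highpass_cutoff: float | None = 2.5,
    lowpass_cutoff: float | None = 10.0,
    min_cycle_ms: float = 200.0,
    min_range_frac: float = 0.1,
) -> MotorParams:
    """Run filter -> segment -> per-cycle statistics on one trial.

    ``highpass_cutoff`` (Hz) removes drift/DC; ``None`` disables it (a
    first-order high-pass near the flexion fundamental attenuates genuinely
    narrowband signals, so pick the cutoff below the motion band).
    ``naming="table1"`` reports the CV as *speed reduction* and the
    last-vs-first change as *speed variability*; ``"swapped"`` reverses the
    two labels.
    """
    if naming not in ("table1", "swapped"):
        raise ValueError("naming must be 'table1' or 'swapped'")
    work = select_flexion_axis(trial) if trial.is_triaxial else trial
    if highpass_cutoff is not None:
        work = highpass(work, highpass_cutoff)
    if lowpass_cutoff is not None:
        work = lowpass(work, lowpass_cutoff)
    cycles = segment_cycles(work, min_cycle_ms=min_cycle_ms, min_range_frac=min_range_frac)

    speed = compute_speed(cycles)
    flexibility = compute_flexibility(cycles, work)
    moment = compute_moment(cycles, work, anthro)
    cv = compute_cv_of_ranges(cycles)
    decline = compute_last_vs_first(cycles, work)

    score = model.score(
        {
            "speed": speed,
            "moment": moment,
            "flexibility": flexibility,
            "cv": cv,
            "decline": decline,
        }
    )
    if naming == "table1":
        reduction, variability = cv, decline
    else:
        reduction, variability = decline, cv
    return MotorParams(
        speed=speed,
        moment=moment,
        flexibility=flexibility,
        speed_reduction=reduction,
        speed_variability=variability,
        frailty_score=score,
        cv_pct=cv,
        decline_pct=decline,
        n_cycles=len(cycles),
        naming=naming,
    )
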