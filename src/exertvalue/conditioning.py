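"""Evaluative-conditioning reward controller and interval-session simulator.

The conditioning paradigm pairs cardiovascular strain (the conditioned
stimulus) with sweet taste (the unconditioned stimulus) during treadmill
interval training.  Two syringe pumps infuse a combined 2 ml/min of liquid
into the mouth; the sweet share of that flow is driven by heart rate:

    sweet_rate = total_rate * (HR - HR_baseline)^2 / (0.85*HRmax - HR_baseline)^2

so sweetness is 0% at the heart rate of the participant's self-selected
baseline speed and reaches 100% at 85% of the age-predicted maximum
(HRmax = 220 - age).  Outside that range the rate is clamped so that both
pump rates stay in [0, total_rate] and always sum to total_rate.

A training session is six progressive interval cycles with peak targets
60..85 %HRmax: ~10 s ramp up, 2 min hold, ~10 s ramp down, 1.5 min at
baseline.  The heart-rate trace is simulated as a first-order relaxation
toward the segment target (time constant ``tau_sec``) with optional
Gaussian per-second noise, and pump commands are sampled at 1 Hz.  One
pairing event is logged per cycle when the controller is active; three
sessions per week over three weeks gives the canonical 9 sessions x 6
pairings = 54 pairings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, ValidationError

TOTAL_RATE_ML_MIN = 2.0
THRESHOLD_FRACTION = 0.85
CYCLE_TARGETS_PCT = (60, 65, 70, 75, 80, 85)


def hr_max(age: float) -> float:
    """Age-predicted maximal heart rate, 220 - age (bpm).

    Ages outside the recruited 18-50 range trigger a warning: the linear
    formula is only validated for that bracket.
    """
    if isinstance(age, bool) or not isinstance(age, (int, float, np.integer, np.floating)):
        raise ValidationError(f"age must be numeric, got {age!r}")
    if not np.isfinite(age):
        raise ValidationError(f"age must be finite, got {age!r}")
    if not 18 <= age <= 50:
        warnings.warn(
            f"age {age} outside the validated 18-50 range for 220 - age",
            stacklevel=2,
        )
    return 220.0 - float(age)


def sweet_rate(
    current_hr: float,
    baseline_hr: float,
    hr_max_bpm: float,
    total_rate: float = TOTAL_RATE_ML_MIN,
    threshold_fraction: float = THRESHOLD_FRACTION,
):
    """Sweet-solution pump rate (ml/min) for a given heart rate.

    Quadratic between the baseline heart rate (0% sweet) and
    ``threshold_fraction * hr_max_bpm`` (100% sweet), clamped outside so the
    command is physically realizable.  Accepts scalars or arrays.
    """
    if total_rate <= 0:
        raise ValidationError(f"total_rate must be positive, got {total_rate}")
    threshold = threshold_fraction * hr_max_bpm
    if baseline_hr >= threshold:
        raise ConfigurationError(
            f"baseline HR {baseline_hr} bpm is at/above the {threshold_fraction:.0%} "
            f"HRmax threshold ({threshold} bpm): controller denominator degenerate"
        )
    frac = (np.asarray(current_hr, dtype=float) - baseline_hr) / (threshold - baseline_hr)
    frac = np.clip(frac, 0.0, 1.0)
    out = total_rate * frac**2
    return out if out.ndim else float(out)


def count_pairings(sessions_per_week: int, weeks: int, pairings_per_session: int) -> int:
    """Total CS-US pairings over a training plan (simple product)."""
    for name, v in (
        ("sessions_per_week", sessions_per_week),
        ("weeks", weeks),
        ("pairings_per_session", pairings_per_session),
    ):
        if int(v) != v or v < 0:
            raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")
    return int(sessions_per_week) * int(weeks) * int(pairings_per_session)


@dataclass(frozen=True)
class Cycle:
    """One interval cycle: ramp to a %HRmax target, hold, return to baseline."""

    target_pct_hrmax: float
    ramp_up_sec: float = 10.0
    hold_sec: float = 120.0
    ramp_down_sec: float = 10.0
    baseline_sec: float = 90.0


@dataclass(frozen=True)
class SessionSchedule:
    cycles: tuple[Cycle, ...]
    warmup_sec: float = 180.0
    cooldown_sec: float = 180.0

    @property
    def duration_sec(self) -> float:
        per_cycle = sum(
            c.ramp_up_sec + c.hold_sec + c.ramp_down_sec + c.baseline_sec
            for c in self.cycles
        )
        return self.warmup_sec + per_cycle + self.cooldown_sec


def build_session_schedule() -> SessionSchedule:
    """The canonical six-cycle session with 60..85 %HRmax peak targets."""
    return SessionSchedule(cycles=tuple(Cycle(t) for t in CYCLE_TARGETS_PCT))


@dataclass(frozen=True)
class PumpCommand:
    time_sec: float
    neutral_rate: float
    sweet_rate: float


@dataclass
class PumpLog:
    """1 Hz dual-pump command log backed by arrays; iterates as PumpCommand."""

    time_sec: np.ndarray
    neutral_rate: np.ndarray
    sweet_rate: np.ndarray

    def __len__(self) -> int:
        return len(self.time_sec)

    def __iter__(self):
        for t, nr, sr in zip(self.time_sec, self.neutral_rate, self.sweet_rate):
            yield PumpCommand(float(t), float(nr), float(sr))

    @property
    def combined_rate(self) -> np.ndarray:
        return self.neutral_rate + self.sweet_rate


@dataclass(frozen=True)
class PairingEvent:
    session_index: int  # 1-based
    cycle_index: int  # 1-based
    peak_hr: float
    peak_sweet_fraction: float


@dataclass
class HRTrace:
    time_sec: np.ndarray
    hr: np.ndarray

    samples: list = field(default_factory=list, repr=False)

    def __post_init__(self):
        self.samples = list(zip(self.time_sec.tolist(), self.hr.tolist()))


def _target_profile(schedule: SessionSchedule, baseline_hr: float, hr_max_bpm: float) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Per-second HR target and the (start, end) sample window of each cycle."""
    segments: list[tuple[float, float, float]] = [(schedule.warmup_sec, baseline_hr, baseline_hr)]
    windows: list[tuple[int, int]] = []
    t = int(schedule.warmup_sec)
    for cyc in schedule.cycles:
        peak = cyc.target_pct_hrmax / 100.0 * hr_max_bpm
        start = t
        segments.append((cyc.ramp_up_sec, baseline_hr, peak))
        segments.append((cyc.hold_sec, peak, peak))
        t += int(cyc.ramp_up_sec + cyc.hold_sec)
        windows.append((start, t))  # ramp-up through end of hold
        segments.append((cyc.ramp_down_sec, peak, baseline_hr))
        segments.append((cyc.baseline_sec, baseline_hr, baseline_hr))
        t += int(cyc.ramp_down_sec + cyc.baseline_sec)
    segments.append((schedule.cooldown_sec, baseline_hr, baseline_hr))
    parts = [
        np.linspace(lo, hi, int(round(dur)), endpoint=False)
        for dur, lo, hi in segments
        if int(round(dur)) > 0
    ]
    return np.concatenate(parts), windows


def simulate_session(
    profile,
    schedule: SessionSchedule | None = None,
    controller_on: bool = True,
    seed=0,
    *,
    tau_sec: float = 30.0,
    hr_noise_sd: float = 1.0,
    total_rate: float = TOTAL_RATE_ML_MIN,
    threshold_fraction: float = THRESHOLD_FRACTION,
    session_index: int = 1,
) -> tuple[HRTrace, PumpLog, list[PairingEvent]]:
    """Simulate one interval session for a participant.

    ``profile`` needs ``baseline_hr`` and ``hr_max`` attributes (duck-typed so
    any record, e.g. a cohort ParticipantProfile, works).  Heart rate relaxes
    first-order toward the segment target; pump commands are emitted at 1 Hz
    and always conserve ``total_rate``.  With ``controller_on`` false (the
    training-only arm) the sweet pump is silent and only neutral solution
    flows.  One pairing event per cycle is logged when the controller is on.
    """
    schedule = schedule or build_session_schedule()
    baseline_hr = float(profile.baseline_hr)
    hrmax = float(profile.hr_max)
    if controller_on:
        # raises ConfigurationError early on a degenerate denominator
        sweet_rate(baseline_hr, baseline_hr, hrmax, total_rate, threshold_fraction)
    rng = np.random.default_rng(seed)

    target, windows = _target_profile(schedule, baseline_hr, hrmax)
    n = len(target)
    alpha = 1.0 / tau_sec
    noise = rng.normal(0.0, hr_noise_sd, size=n) if hr_noise_sd > 0 else np.zeros(n)
    hr = np.empty(n)
    hr[0] = baseline_hr
    for i in range(1, n):
        hr[i] = hr[i - 1] + alpha * (target[i - 1] - hr[i - 1]) + noise[i]
    np.clip(hr, 31.0, 229.0, out=hr)

    times = np.arange(n, dtype=float)
    if controller_on:
        sweet = np.asarray(sweet_rate(hr, baseline_hr, hrmax, total_rate, threshold_fraction))
    else:
        sweet = np.zeros(n)
    log = PumpLog(time_sec=times, neutral_rate=total_rate - sweet, sweet_rate=sweet)

    pairings: list[PairingEvent] = []
    if controller_on:
        for ci, (lo, hi) in enumerate(windows, start=1):
            peak = float(hr[lo:hi].max())
            frac = float(sweet_rate(peak, baseline_hr, hrmax, total_rate, threshold_fraction)) / total_rate
            pairings.append(PairingEvent(session_index, ci, peak, frac))
    return HRTrace(times, hr), log, pairings
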