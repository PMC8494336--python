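"""Synthetic participant cohorts with known ground truth.

Generates latent participant profiles (fitness, discounting constants,
conditioning susceptibility) for the three study arms — no-training (NTR),
training-only (TR), and conditioning-plus-training (COTR) — and the
observables the analysis consumes: self-paced treadmill trial records
(speed, heart rate, RPE, Feeling Scale) at the three assessment points
T0/T1/T2, and binary intertemporal choices consistent with hyperbolic
discounting for money, food, and exercise.

Speed selection model
---------------------
A participant picks the treadmill speed that maximizes modeled pleasantness

    Vp(s) = reward_scale * [gamma * g(f) + delta_m * f^2] / (1 + k_eff * RPE(f))

where f is the heart-rate reserve fraction at speed s (HR = HR/Speed * s,
rest 60 bpm), RPE(f) = 6 + 14*f, g(f) = f*(2*f_p - f)/f_p^2 is a concave
reward-availability curve peaking at reserve fraction f_p, gamma is the
fitness-relative reward (baseline HR/Speed over current HR/Speed, so
training raises it), and delta_m adds a conditioned reward that grows with
strain as f^2 — mirroring the quadratic sweetness controller it was learned
under.  Lower HR/Speed (training) shifts the optimal *speed* up at an
unchanged optimal heart rate; a positive delta_m shifts the optimal strain
itself up.  Both shifts are weakly monotone by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .conditioning import hr_max as _hr_max
from .effort import map_reward
from .errors import ValidationError

GROUPS = ("NTR", "TR", "COTR")
TIME_POINTS = ("T0", "T1", "T2")
COMMODITIES = ("money", "food", "exercise")

SPEED_GRID = np.round(np.arange(3.0, 16.0 + 1e-9, 0.1), 1)  # km/h, treadmill range
REST_HR = 60.0
RPE_MIN, RPE_SPAN = 6.0, 14.0


@dataclass(frozen=True)
class ParticipantProfile:
    """Latent ground truth for one simulated participant."""

    id: str
    group: str
    age: float  # years
    sex: str
    baseline_hr: float  # bpm at self-selected baseline speed
    hr_per_speed0: float  # bpm per km/h at T0 (inverse fitness)
    training_gain: float  # fractional HR/Speed reduction at T1
    detrain_fraction: float  # share of the gain lost again by T2
    k_money: float  # per-day discount constants
    k_food: float
    k_exercise: float
    k_effort: float  # effort-discounting constant
    conditioning_delta_m: float  # learned reward surplus (0 unless COTR)
    choice_noise: float  # logistic temperature, value units
    rating_noise_sd: float  # FS/RPE scale units

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        for name in ("k_money", "k_food", "k_exercise", "k_effort"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.group != "COTR" and self.conditioning_delta_m != 0:
            raise ValidationError("conditioning_delta_m must be 0 outside the COTR arm")
        if not 0 <= self.training_gain < 1:
            raise ValidationError("training_gain must lie in [0, 1)")
        if not 0 <= self.detrain_fraction <= 1:
            raise ValidationError("detrain_fraction must lie in [0, 1]")

    @property
    def hr_max(self) -> float:
        return 220.0 - self.age

    def hr_per_speed(self, time_point: str) -> float:
        """HR/Speed at an assessment point: T1 applies the training gain,
        T2 gives back ``detrain_fraction`` of it."""
        if time_point == "T0":
            return self.hr_per_speed0
        if time_point == "T1":
            return self.hr_per_speed0 * (1.0 - self.training_gain)
        if time_point == "T2":
            return self.hr_per_speed0 * (1.0 - self.training_gain * (1.0 - self.detrain_fraction))
        raise ValidationError(f"unknown time point {time_point!r}")

    def k_for(self, commodity: str) -> float:
        try:
            return {"money": self.k_money, "food": self.k_food, "exercise": self.k_exercise}[commodity]
        except KeyError:
            raise ValidationError(f"unknown commodity {commodity!r}") from None


@dataclass(frozen=True)
class TrialRecord:
    """One self-paced exercise assessment."""

    participant_id: str
    time_point: str
    speed: float  # km/h
    avg_hr: float  # bpm
    rpe: int  # 6-20
    fs: int  # -5..+5


@dataclass(frozen=True)
class ChoiceTrial:
    commodity: str
    immediate_amount: float
    delayed_amount: float
    delay_days: float
    chosen: str | None = None

    def __post_init__(self):
        if self.commodity not in COMMODITIES:
            raise ValidationError(f"unknown commodity {self.commodity!r}")
        if self.immediate_amount > self.delayed_amount:
            raise ValidationError("immediate amount must not exceed the delayed amount")
        if self.delay_days < 0:
            raise ValidationError("delay must be non-negative")


@dataclass(frozen=True)
class CohortConfig:
    """Latent-trait distributions for the generator.

    Defaults emulate the study sample: young adults, HR/Speed near
    22 bpm/(km/h), right-skewed (log-normal) discount constants with money
    discounted far slower than food or exercise, a ~8.5% HR/Speed training
    gain of which ~80% is lost after four detraining weeks, and an additive
    conditioned reward in the COTR arm only.
    """

    age_mean: float = 24.3
    age_sd: float = 5.2
    female_fraction: float = 0.55
    hr_per_speed_mean: float = 22.3
    hr_per_speed_sd: float = 3.5
    training_gain_mean: float = 0.085
    training_gain_sd: float = 0.04
    detrain_mean: float = 0.8
    detrain_sd: float = 0.15
    k_money_median: float = 0.02
    k_food_median: float = 0.25
    k_exercise_median: float = 0.17
    k_log_sigma: float = 1.1
    k_effort_median: float = 0.204
    k_effort_log_sigma: float = 0.15
    conditioning_delta_m_mean: float = 1.2
    conditioning_delta_m_sd: float = 0.3
    choice_noise: float = 1.0
    rating_noise_sd: float = 0.7
    reward_scale: float = 2.8  # FS amplitude of the pleasantness model
    reward_peak_fraction: float = 0.5  # HR-reserve fraction of peak reward


DEFAULT_GROUP_SPLIT = {"NTR": 10 / 58, "TR": 24 / 58, "COTR": 24 / 58}


def _split_counts(n: int, split: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n across groups."""
    props = {g: split.get(g, 0.0) for g in GROUPS}
    total = sum(props.values())
    if any(p < 0 for p in props.values()) or not np.isclose(total, 1.0, atol=1e-9):
        raise ValidationError(f"group proportions must be non-negative and sum to 1, got {split}")
    raw = {g: n * p for g, p in props.items()}
    counts = {g: int(np.floor(v)) for g, v in raw.items()}
    short = n - sum(counts.values())
    for g in sorted(GROUPS, key=lambda g: raw[g] - counts[g], reverse=True)[:short]:
        counts[g] += 1
    return counts


def expected_rpe(hr, hr_max_bpm: float):
    """Affine RPE model on the heart-rate reserve fraction, clamped to 6-20."""
    f = np.clip((np.asarray(hr, dtype=float) - REST_HR) / (hr_max_bpm - REST_HR), 0.0, 1.0)
    out = RPE_MIN + RPE_SPAN * f
    return out if out.ndim else float(out)


def pleasantness_curve(
    hr_per_speed: float,
    hr_max_bpm: float,
    k_effort: float,
    fitness_gamma: float = 1.0,
    delta_m: float = 0.0,
    reward_scale: float = 2.8,
    peak_fraction: float = 0.5,
    speeds: np.ndarray = SPEED_GRID,
) -> np.ndarray:
    """Model pleasantness Vp over a speed grid (see module docstring)."""
    hr = np.minimum(hr_per_speed * speeds, hr_max_bpm)
    f = np.clip((hr - REST_HR) / (hr_max_bpm - REST_HR), 0.0, 1.0)
    base = f * (2.0 * peak_fraction - f) / peak_fraction**2
    m = reward_scale * (fitness_gamma * np.maximum(base, 0.0) + delta_m * f**2)
    rpe = RPE_MIN + RPE_SPAN * f
    return m / (1.0 + k_effort * rpe)


def _select_speed(profile: ParticipantProfile, time_point: str, config: CohortConfig) -> tuple[float, float]:
    """Deterministic argmax speed and its model pleasantness."""
    hps = profile.hr_per_speed(time_point)
    gamma = map_reward(hps, profile.hr_per_speed0)
    delta = (
        profile.conditioning_delta_m
        if (time_point == "T2" and profile.group == "COTR")
        else 0.0
    )
    vp = pleasantness_curve(
        hps,
        profile.hr_max,
        profile.k_effort,
        fitness_gamma=gamma,
        delta_m=delta,
        reward_scale=config.reward_scale,
        peak_fraction=config.reward_peak_fraction,
    )
    i = int(np.argmax(vp))
    return float(SPEED_GRID[i]), float(vp[i])


def make_cohort(
    n: int,
    group_split: dict[str, float] | None = None,
    config: CohortConfig | None = None,
    seed=0,
) -> list[ParticipantProfile]:
    """Draw ``n`` participant profiles; identical (inputs, seed) reproduce
    byte-identical cohorts.

    The baseline heart rate is derived, not drawn: it is HR/Speed times the
    participant's deterministic T0 preferred speed, so the conditioning
    controller's zero-sweetness point coincides with the self-selected
    baseline strain.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValidationError(f"cohort size must be a positive integer, got {n!r}")
    config = config or CohortConfig()
    counts = _split_counts(int(n), group_split or DEFAULT_GROUP_SPLIT)
    rng = np.random.default_rng(seed)
    profiles: list[ParticipantProfile] = []
    idx = 0
    for group in GROUPS:
        for _ in range(counts[group]):
            idx += 1
            age = float(np.clip(np.round(rng.normal(config.age_mean, config.age_sd)), 18, 50))
            sex = "F" if rng.random() < config.female_fraction else "M"
            hps0 = float(np.clip(rng.normal(config.hr_per_speed_mean, config.hr_per_speed_sd), 14.0, 32.0))
            if group == "NTR":
                gain = 0.0
            else:
                gain = float(np.clip(rng.normal(config.training_gain_mean, config.training_gain_sd), 0.0, 0.25))
            detrain = float(np.clip(rng.normal(config.detrain_mean, config.detrain_sd), 0.0, 1.0))
            ks = {
                c: float(np.exp(rng.normal(np.log(med), config.k_log_sigma)))
                for c, med in (
                    ("money", config.k_money_median),
                    ("food", config.k_food_median),
                    ("exercise", config.k_exercise_median),
                )
            }
            k_eff = float(np.exp(rng.normal(np.log(config.k_effort_median), config.k_effort_log_sigma)))
            if group == "COTR":
                delta = float(np.clip(rng.normal(config.conditioning_delta_m_mean, config.conditioning_delta_m_sd), 0.0, None))
            else:
                delta = 0.0
            prof = ParticipantProfile(
                id=f"P{idx:03d}",
                group=group,
                age=age,
                sex=sex,
                baseline_hr=0.0,  # placeholder, derived below
                hr_per_speed0=hps0,
                training_gain=gain,
                detrain_fraction=detrain,
                k_money=ks["money"],
                k_food=ks["food"],
                k_exercise=ks["exercise"],
                k_effort=k_eff,
                conditioning_delta_m=delta,
                choice_noise=config.choice_noise,
                rating_noise_sd=config.rating_noise_sd,
            )
            s0, _ = _select_speed(prof, "T0", config)
            baseline = float(np.clip(hps0 * s0, 41.0, 0.82 * prof.hr_max))
            profiles.append(replace(prof, baseline_hr=baseline))
    return profiles


def simulate_trial_record(
    profile: ParticipantProfile,
    time_point: str,
    seed=0,
    config: CohortConfig | None = None,
    hr_noise_sd: float = 3.0,
) -> TrialRecord:
    """One self-paced assessment: argmax speed, then noisy observables.

    Noise scales are ``profile.rating_noise_sd`` (FS, RPE) and
    ``hr_noise_sd`` (heart rate); set both to zero for the deterministic
    response.
    """
    if time_point not in TIME_POINTS:
        raise ValidationError(f"unknown time point {time_point!r}")
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    speed, vp = _select_speed(profile, time_point, config)
    hps = profile.hr_per_speed(time_point)
    avg_hr = hps * speed + (rng.normal(0.0, hr_noise_sd) if hr_noise_sd > 0 else 0.0)
    avg_hr = float(np.clip(avg_hr, 41.0, profile.hr_max))
    sd = profile.rating_noise_sd
    rpe_noise = rng.normal(0.0, sd) if sd > 0 else 0.0
    fs_noise = rng.normal(0.0, sd) if sd > 0 else 0.0
    rpe = int(np.clip(round(expected_rpe(hps * speed, profile.hr_max) + rpe_noise), 6, 20))
    fs = int(np.clip(round(5.0 * vp + fs_noise), -5, 5))
    return TrialRecord(profile.id, time_point, speed, avg_hr, rpe, fs)


def simulate_choice(profile: ParticipantProfile, trial: ChoiceTrial, seed=0) -> str:
    """Hyperbolically discounted choice between an immediate and a delayed
    reward.

    With zero choice noise this is the exact value argmax (seeded fair coin
    at exact equality); otherwise the immediate option is taken with
    logistic probability on the value difference.
    """
    k = profile.k_for(trial.commodity)
    v_imm = trial.immediate_amount
    v_del = trial.delayed_amount / (1.0 + k * trial.delay_days)
    rng = np.random.default_rng(seed)
    if profile.choice_noise == 0:
        if v_imm == v_del:
            return "immediate" if rng.random() < 0.5 else "delayed"
        return "immediate" if v_imm > v_del else "delayed"
    p_imm = 1.0 / (1.0 + np.exp(-(v_imm - v_del) / profile.choice_noise))
    return "immediate" if rng.random() < p_imm else "delayed"
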