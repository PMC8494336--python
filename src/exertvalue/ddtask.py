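"""Adjusting-amount delay-discounting task engine.

Reconstructs the computerized choice task that yields per-delay
indifference points (IPs) for three commodity menus: money (£2..£50),
food (5..150 bites), and self-paced exercise (5..150 minutes, labelled in
gym sessions of 30 minutes).  Delays are 0, 1, 7, 30, 60 and 180 days,
where 0 encodes "at the end of this session" and frames the immediate
option only — it is never fitted.

For each non-zero delay the delayed reward is anchored at the menu's
largest amount and the immediate amount follows a bisection staircase on
[0, largest]: choosing the immediate option lowers the bracket's top,
choosing the delayed option raises its bottom.  The staircase stops after
six choice reversals or once the bracket is narrower than one menu step,
whichever comes first, and the IP is the midpoint of the final bracket.
Delay order is shuffled per seed and distractor trials (repeats of earlier
questions) are interleaved at a configurable rate; both leave the IPs of a
deterministic responder unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

MONEY_AMOUNTS = (2, 7, 12, 17, 22, 27, 32, 37, 42, 47, 50)  # GBP
FOOD_AMOUNTS = (5, 10, 15, 20, 30, 60, 90, 120, 150)  # bites
EXERCISE_AMOUNTS = (5, 10, 15, 20, 30, 60, 90, 120, 150)  # minutes
DELAYS_DAYS = (0, 1, 7, 30, 60, 180)


@dataclass(frozen=True)
class CommodityMenu:
    commodity: str
    amounts: tuple
    unit: str
    delays_days: tuple = DELAYS_DAYS

    @property
    def largest_reward(self) -> float:
        return float(max(self.amounts))

    @property
    def step(self) -> float:
        """One menu step: the smallest gap between adjacent amounts."""
        return float(min(np.diff(self.amounts)))


_MENUS = {
    "money": CommodityMenu("money", MONEY_AMOUNTS, "GBP"),
    "food": CommodityMenu("food", FOOD_AMOUNTS, "bites"),
    "exercise": CommodityMenu("exercise", EXERCISE_AMOUNTS, "minutes (30 min = 1 gym session)"),
}


def build_menu(commodity: str) -> CommodityMenu:
    try:
        return _MENUS[commodity]
    except KeyError:
        raise ValidationError(f"unknown commodity {commodity!r}") from None


@dataclass
class IndifferenceCurve:
    """Per-delay indifference points for one participant and commodity."""

    participant_id: str
    commodity: str
    points: dict  # delay_days -> IP, non-zero delays only
    largest_reward: float
    flagged: bool = False
    diagnostics: dict = field(default_factory=dict)

    @property
    def delays(self) -> np.ndarray:
        return np.array(sorted(self.points))

    @property
    def ips(self) -> np.ndarray:
        return np.array([self.points[d] for d in sorted(self.points)])


def hyperbolic_responder(k: float, noise: float = 0.0, seed=0):
    """A responder valuing the delayed option at A/(1+kD).

    ``noise`` is a logistic temperature on the value difference; zero gives
    the deterministic argmax (ties break toward the delayed option, the
    indifference convention).
    """
    rng = np.random.default_rng(seed)

    def responder(immediate: float, delayed: float, delay_days: float) -> str:
        v_del = delayed / (1.0 + k * delay_days)
        if noise == 0:
            return "immediate" if immediate > v_del else "delayed"
        p_imm = 1.0 / (1.0 + np.exp(-(immediate - v_del) / noise))
        return "immediate" if rng.random() < p_imm else "delayed"

    return responder


def run_adjusting_task(
    responder,
    menu: CommodityMenu,
    seed=0,
    *,
    distractor_rate: float = 0.15,
    max_reversals: int = 6,
    max_trials_per_delay: int = 40,
    participant_id: str = "anon",
) -> IndifferenceCurve:
    """Run the adjusting-amount staircase for every non-zero delay.

    ``responder(immediate, delayed, delay_days)`` must return "immediate" or
    "delayed" for any triple.  Distractor answers are recorded but never
    enter the IP computation.  A staircase that exhausts
    ``max_trials_per_delay`` without meeting a stopping rule flags the curve
    instead of failing silently.
    """
    if not 0 <= distractor_rate < 1:
        raise ValidationError(f"distractor_rate must lie in [0, 1), got {distractor_rate}")
    rng = np.random.default_rng(seed)
    big = menu.largest_reward
    step = menu.step
    delays = [d for d in menu.delays_days if d > 0]
    order = [delays[i] for i in rng.permutation(len(delays))]

    points: dict = {}
    flagged = False
    history: list[tuple[float, float, float]] = []
    n_trials = 0
    n_distractors = 0
    per_delay_reversals: dict = {}

    for delay in order:
        lo, hi = 0.0, big
        reversals = 0
        last_choice = None
        trials = 0
        chose_immediate = chose_delayed = False
        while (hi - lo) >= step and reversals < max_reversals:
            if trials >= max_trials_per_delay:
                flagged = True
                break
            if history and rng.random() < distractor_rate:
                past = history[rng.integers(len(history))]
                responder(*past)  # answer discarded by design
                n_distractors += 1
            mid = (lo + hi) / 2.0
            choice = responder(mid, big, float(delay))
            history.append((mid, big, float(delay)))
            trials += 1
            n_trials += 1
            if choice == "immediate":
                hi = mid
                chose_immediate = True
            elif choice == "delayed":
                lo = mid
                chose_delayed = True
            else:
                raise ValidationError(f"responder returned {choice!r}")
            if last_choice is not None and choice != last_choice:
                reversals += 1
            last_choice = choice
        # A one-sided staircase pins the IP to the bracket's untouched end:
        # never preferring the immediate option means the delayed reward is
        # worth its full amount, and vice versa.
        if chose_delayed and not chose_immediate:
            points[delay] = big
        elif chose_immediate and not chose_delayed:
            points[delay] = 0.0
        else:
            points[delay] = (lo + hi) / 2.0
        per_delay_reversals[delay] = reversals

    return IndifferenceCurve(
        participant_id=participant_id,
        commodity=menu.commodity,
        points=points,
        largest_reward=big,
        flagged=flagged,
        diagnostics={
            "n_trials": n_trials,
            "n_distractors": n_distractors,
            "reversals": per_delay_reversals,
            "delay_order": order,
        },
    )
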