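"""Hyperbolic (Mazur) delay-discounting fits with exclusion and transforms.

The subjective value of a reward of amount A delayed by D days is modeled
as V = A / (1 + k*D).  Fits are performed on indifference points
normalized by the largest delayed reward (IP/A against 1/(1+kD)), which
puts the differently-scaled commodity menus on one axis; k then has units
of 1/day regardless of commodity.  Goodness of fit is the usual R^2 on the
normalized points, and curves with R^2 < 0.7 are excluded from group
statistics.  Before parametric group tests, k values are log-transformed
(natural log) and RPE values squared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .ddtask import IndifferenceCurve
from .errors import ValidationError

EXCLUSION_R2 = 0.7
_EXACT_SS = 1e-12


def mazur_value(amount: float, k: float, delay_days: float) -> float:
    """V = A / (1 + k*D)."""
    if k < 0:
        raise ValidationError(f"discount constant must be non-negative, got {k}")
    if delay_days < 0:
        raise ValidationError(f"delay must be non-negative, got {delay_days}")
    return amount / (1.0 + k * delay_days)


@dataclass(frozen=True)
class HyperbolicFit:
    participant_id: str
    commodity: str
    k: float
    r_squared: float  # NaN when the curve is constant (degenerate SStot)
    included: bool
    log_k: float  # natural log; NaN at the k = 0 boundary
    residual_ss: float = float("nan")

    @property
    def degenerate(self) -> bool:
        return math.isnan(self.r_squared)


def _objective(k: float, y: np.ndarray, d: np.ndarray) -> float:
    r = y - 1.0 / (1.0 + k * d)
    return float(r @ r)


def fit_hyperbolic(curve: IndifferenceCurve) -> HyperbolicFit:
    """Least-squares k for one indifference curve.

    Minimizes sum_D (IP_D/A - 1/(1+kD))^2 over k >= 0 by a log-spaced
    multi-start scan plus bounded Brent refinement (the objective flattens
    at extreme k, so a single local search can stall).  With a constant
    curve the total sum of squares is zero and R^2 is undefined (NaN); the
    inclusion flag then reduces to whether the k = 0 hyperbola fits
    exactly.
    """
    delays = curve.delays
    if len(delays) < 3:
        raise ValidationError(
            f"need at least 3 non-zero-delay indifference points, got {len(delays)}"
        )
    y = curve.ips / curve.largest_reward
    d = delays.astype(float)

    grid = np.concatenate(([0.0], np.geomspace(1e-8, 100.0, 201)))
    vals = np.array([_objective(k, y, d) for k in grid])
    i = int(np.argmin(vals))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
    k_hat, f_hat = float(grid[i]), float(vals[i])
    if hi > lo:
        res = optimize.minimize_scalar(
            _objective, args=(y, d), bounds=(lo, hi), method="bounded", options={"xatol": 1e-12}
        )
        if res.fun < f_hat:
            k_hat, f_hat = float(res.x), float(res.fun)
    if _objective(0.0, y, d) <= f_hat:
        k_hat, f_hat = 0.0, _objective(0.0, y, d)

    ss_res = f_hat
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot < _EXACT_SS:
        r2 = float("nan")
        included = ss_res < _EXACT_SS
    else:
        r2 = 1.0 - ss_res / ss_tot
        included = r2 >= EXCLUSION_R2
    return HyperbolicFit(
        participant_id=curve.participant_id,
        commodity=curve.commodity,
        k=k_hat,
        r_squared=r2,
        included=included,
        log_k=math.log(k_hat) if k_hat > 0 else float("nan"),
        residual_ss=ss_res,
    )


def apply_exclusion(
    fits: list[HyperbolicFit], threshold: float = EXCLUSION_R2
) -> tuple[list[HyperbolicFit], list[HyperbolicFit]]:
    """Partition fits into (retained, removed) by R^2 >= threshold.

    The inequality is strict on the removal side: R^2 exactly at the
    threshold is retained.  Degenerate (constant-curve) fits carry no R^2
    and are retained only when flagged as exact.
    """
    retained, removed = [], []
    for f in fits:
        keep = f.included if math.isnan(f.r_squared) else f.r_squared >= threshold
        (retained if keep else removed).append(f)
    return retained, removed


def transform_for_stats(values, kind: str):
    """Element-wise variance-stabilizing transform: 'logK' (natural log,
    strictly positive inputs) or 'rpeSquare' (square)."""
    arr = np.asarray(values, dtype=float)
    if kind == "logK":
        bad = np.flatnonzero(arr <= 0)
        if bad.size:
            raise ValidationError(
                f"logK transform requires positive values; offending indices {bad.tolist()} "
                f"with values {arr[bad].tolist()}"
            )
        return np.log(arr)
    if kind == "rpeSquare":
        return arr**2
    raise ValidationError(f"unknown transform kind {kind!r}")
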