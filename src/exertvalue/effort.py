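"""Hyperbolic effort valuation: Vp = M / (1 + k*C).

Maps the three exercise-trial observables onto the model quantities —
pleasantness ratings (Feeling Scale, -5..+5) normalized to Vp = FS/5,
perceived exertion (Borg RPE 6-20) as the cost C, and heart rate per speed
(an inverse fitness index) as the determinant of the reward M — then fits a
single shared discounting constant k per condition by least squares and
compares model to measured subjective values with an exact sign test.

The diagnostic property of interest: when the data contain a reward
component the fitter's M does not include (e.g. a conditioned reward), the
fitted k is pushed *down* to compensate, so a group-wise drop in k flags an
unmodeled reward surplus rather than genuinely cheaper effort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .errors import ValidationError

FS_SCALE_MAX = 5.0


def normalize_fs(fs: float) -> float:
    """Feeling Scale rating -> normalized subjective value Vp = FS/5.

    Division by the scale maximum (not an affine [-5,5] -> [0,1] rescale):
    negative pleasantness maps to negative value.
    """
    if not -FS_SCALE_MAX <= fs <= FS_SCALE_MAX:
        raise ValidationError(f"Feeling Scale value {fs} outside [-5, 5]")
    return float(fs) / FS_SCALE_MAX


def map_reward(hr_per_speed: float, ref_hr_per_speed: float, delta_m: float = 0.0) -> float:
    """Default reward mapping M = ref/(HR/Speed) + delta_m.

    Lower heart rate per speed (fitter participant) yields a larger reward;
    a conditioned reward adds on top.  The mapping is deliberately simple and
    swappable — record its name alongside any fit it feeds.
    """
    if hr_per_speed <= 0 or ref_hr_per_speed <= 0:
        raise ValidationError(
            f"HR/Speed values must be positive, got {hr_per_speed} and {ref_hr_per_speed}"
        )
    return ref_hr_per_speed / hr_per_speed + delta_m


@dataclass(frozen=True)
class EffortObservation:
    participant_id: str
    time_point: str
    vp: float  # normalized Feeling Scale, in [-1, 1]
    cost: float  # RPE, 6-20
    reward: float  # unitless M, > 0
    group: str = ""

    def __post_init__(self):
        if not -1.0 <= self.vp <= 1.0:
            raise ValidationError(f"vp {self.vp} outside [-1, 1]")
        if not 6.0 <= self.cost <= 20.0:
            raise ValidationError(f"cost {self.cost} outside the RPE range [6, 20]")
        if self.reward <= 0:
            raise ValidationError(f"reward must be positive, got {self.reward}")


@dataclass
class EffortFitResult:
    condition_label: str
    k: float
    vp_model: np.ndarray
    residual_ss: float
    comparison: dict = field(default_factory=dict)
    flat_objective: bool = False
    mapping_name: str = "default"


def _minimize_scalar_multistart(objective, k_hi: float = 10.0, xatol: float = 1e-10) -> float:
    """Bounded scalar least squares over k >= 0 with a log-spaced multi-start.

    A coarse scan locates the basin (the objective can be nearly flat at the
    extremes), then Brent refinement inside the bracketing neighbours.
    """
    grid = np.concatenate(([0.0], np.geomspace(1e-8, k_hi, 161)))
    vals = np.array([objective(k) for k in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi <= lo:
        return float(grid[i])
    res = optimize.minimize_scalar(
        objective, bounds=(lo, hi), method="bounded", options={"xatol": xatol}
    )
    best = min((objective(0.0), 0.0), (vals[i], grid[i]), (res.fun, float(res.x)))
    return float(best[1])


def fit_shared_k(
    observations: list[EffortObservation],
    condition_label: str = "",
    mapping_name: str = "default",
) -> EffortFitResult:
    """Least-squares fit of one k over all observations in a condition.

    Minimizes sum_i (vp_i - M_i/(1 + k*C_i))^2 over k >= 0 and attaches an
    exact sign test (plus Wilcoxon signed-rank when n <= 25) of measured vs
    model Vp as a goodness-of-fit check.
    """
    if len(observations) < 2:
        raise ValidationError("need at least 2 observations to fit a shared k")
    vp = np.array([o.vp for o in observations])
    cost = np.array([o.cost for o in observations])
    reward = np.array([o.reward for o in observations])

    def objective(k: float) -> float:
        r = vp - reward / (1.0 + k * cost)
        return float(r @ r)

    k_hat = _minimize_scalar_multistart(objective)
    vp_model = reward / (1.0 + k_hat * cost)
    resid = vp - vp_model
    comparison = dict(sign_test(resid))
    if len(resid) <= 25 and np.any(resid != 0):
        w = stats.wilcoxon(resid[resid != 0])
        comparison["wilcoxon_statistic"] = float(w.statistic)
        comparison["wilcoxon_p_value"] = float(w.pvalue)
    flat = bool(np.ptp(cost) == 0 and np.ptp(reward) == 0)
    return EffortFitResult(
        condition_label=condition_label,
        k=k_hat,
        vp_model=vp_model,
        residual_ss=objective(k_hat),
        comparison=comparison,
        flat_objective=flat,
        mapping_name=mapping_name,
    )


def sign_test(paired_diffs) -> dict:
    """Exact two-sided sign test on paired differences.

    Zero differences are uninformative under the binomial null and are
    dropped (their count is reported); with no informative pairs the p-value
    is 1 by convention.
    """
    diffs = np.asarray(paired_diffs, dtype=float)
    if diffs.size < 1:
        raise ValidationError("sign test needs at least one pair")
    nonzero = diffs[diffs != 0]
    n_zero = int(diffs.size - nonzero.size)
    if nonzero.size == 0:
        return {"statistic": 0, "p_value": 1.0, "n": 0, "n_zero": n_zero}
    n_pos = int(np.sum(nonzero > 0))
    p = stats.binomtest(n_pos, nonzero.size, 0.5, alternative="two-sided").pvalue
    return {"statistic": n_pos, "p_value": float(p), "n": int(nonzero.size), "n_zero": n_zero}
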