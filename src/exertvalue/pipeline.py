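"""End-to-end reproducible pipeline: simulate, task, fit, summarize, report.

Stages: cohort generation -> conditioning sessions (COTR arm with the
controller on, TR arm with neutral solution only) -> self-paced trial
records at T0/T1/T2 -> adjusting-amount discounting tasks -> per-curve
Mazur fits with the R^2 exclusion rule -> shared-k effort fits per
condition -> CSV bundle plus a text report with group summary tables and
parameter-recovery diagnostics.  Every output embeds the config hash and
seed as comment headers, and re-running with the same (config, seed)
reproduces the bundle byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import conditioning, ddtask, discounting, effort
from .errors import ValidationError

logger = logging.getLogger("exertvalue")

# Assessment plan mirroring the study: the no-training arm is only assessed
# at T0/T1; money discounting is measured once, at baseline.
TIME_POINTS_BY_GROUP = {"NTR": ("T0", "T1"), "TR": ("T0", "T1", "T2"), "COTR": ("T0", "T1", "T2")}
COMMODITIES_BY_TP = {"T0": ("money", "food", "exercise"), "T1": ("food", "exercise"), "T2": ("food", "exercise")}


@dataclass(frozen=True)
class RunConfig:
    """All tunables of one pipeline run; echoed into every output."""

    seed: int = 1
    n: int = 58
    group_split: dict = field(default_factory=lambda: dict(cohort_mod.DEFAULT_GROUP_SPLIT))
    cohort: cohort_mod.CohortConfig = field(default_factory=cohort_mod.CohortConfig)
    # controller
    total_rate: float = 2.0
    threshold_fraction: float = 0.85
    tau_sec: float = 30.0
    session_hr_noise_sd: float = 1.0
    sessions_per_week: int = 3
    weeks: int = 3
    # task
    distractor_rate: float = 0.15
    max_reversals: int = 6
    # fits
    exclusion_threshold: float = 0.7
    mapping: str = "default"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["group_split"] = {k: float(v) for k, v in self.group_split.items()}
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        raw = yaml.safe_load(text) or {}
        cohort_cfg = cohort_mod.CohortConfig(**raw.pop("cohort", {}))
        return cls(cohort=cohort_cfg, **raw)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    @property
    def n_sessions(self) -> int:
        return self.sessions_per_week * self.weeks


def pooled_mean(group_stats) -> float:
    """Sample-size-weighted mean of per-group means: sum(m_i n_i)/sum(n_i)."""
    stats = list(group_stats)
    if not stats:
        raise ValidationError("pooled_mean needs at least one (mean, n) pair")
    means = np.array([m for m, _ in stats], dtype=float)
    ns = np.array([n for _, n in stats], dtype=float)
    if np.any(ns < 1):
        raise ValidationError("every group size must be >= 1")
    return float(np.sum(means * ns) / np.sum(ns))


def summarize(records: pd.DataFrame, by, variables=None) -> pd.DataFrame:
    """Per-group mean/SD/median/quartiles in the style of the study tables.

    SD uses the n-1 denominator (NaN for singleton groups); quartiles use
    linear interpolation between order statistics.  Row order is the sorted
    grouping key, so summaries are invariant to input row permutation.
    """
    by = [by] if isinstance(by, str) else list(by)
    if variables is None:
        variables = [
            c for c in records.columns
            if c not in by and pd.api.types.is_numeric_dtype(records[c])
        ]
    rows = []
    for key, grp in sorted(records.groupby(by), key=lambda kv: kv[0]):
        key = key if isinstance(key, tuple) else (key,)
        for var in variables:
            vals = grp[var].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                logger.warning("empty group %s for %s: omitted", key, var)
                continue
            rows.append(
                dict(zip(by, key))
                | {
                    "variable": var,
                    "mean": float(np.mean(vals)),
                    "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan"),
                    "median": float(np.median(vals)),
                    "p25": float(np.percentile(vals, 25)),
                    "p75": float(np.percentile(vals, 75)),
                    "n": int(vals.size),
                }
            )
    return pd.DataFrame(rows)


def profiles_to_frame(profiles) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(p) for p in profiles])


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig, note: str = "") -> None:
    buf = io.StringIO()
    buf.write(f"# exertvalue v0.1.0 {note}\n")
    buf.write(f"# config_hash: {config.config_hash}\n")
    buf.write(f"# seed: {config.seed}\n")
    df.to_csv(buf, index=False, float_format="%.10g")
    path.write_text(buf.getvalue())


def _child_seed(ss: np.random.SeedSequence) -> np.random.SeedSequence:
    return ss.spawn(1)[0]


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute every stage and write the report bundle into ``out_dir``.

    Returns a dict of the in-memory stage products (profiles, data frames,
    fit results) for programmatic use.  Any stage failure raises with the
    stage name in the message; partial outputs already written remain on
    disk for inspection.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_ss = np.random.SeedSequence(config.seed)
    ss_cohort, ss_sessions, ss_trials, ss_task = root_ss.spawn(4)
    stage = "cohort"
    try:
        profiles = cohort_mod.make_cohort(config.n, config.group_split, config.cohort, ss_cohort)
        pframe = profiles_to_frame(profiles)
        _write_csv(pframe, out / "participants.csv", config, "participants")
        (out / "config.yaml").write_text(config.to_yaml())

        stage = "conditioning"
        schedule = conditioning.build_session_schedule()
        pairing_rows = []
        example_log = None
        session_seeds = ss_sessions.spawn(len(profiles))
        for prof, pseed in zip(profiles, session_seeds):
            if prof.group == "NTR":
                continue
            on = prof.group == "COTR"
            for s_idx, sseed in enumerate(pseed.spawn(config.n_sessions), start=1):
                _, log, pairings = conditioning.simulate_session(
                    prof,
                    schedule,
                    controller_on=on,
                    seed=sseed,
                    tau_sec=config.tau_sec,
                    hr_noise_sd=config.session_hr_noise_sd,
                    total_rate=config.total_rate,
                    threshold_fraction=config.threshold_fraction,
                    session_index=s_idx,
                )
                if np.max(np.abs(log.combined_rate - config.total_rate)) > 1e-9:
                    raise AssertionError("pump conservation violated")
                for ev in pairings:
                    pairing_rows.append(
                        {
                            "participant_id": prof.id,
                            "session_index": ev.session_index,
                            "cycle_index": ev.cycle_index,
                            "peak_hr": ev.peak_hr,
                            "peak_sweet_fraction": ev.peak_sweet_fraction,
                        }
                    )
                if example_log is None and on:
                    example_log = pd.DataFrame(
                        {
                            "time_sec": log.time_sec,
                            "neutral_rate": log.neutral_rate,
                            "sweet_rate": log.sweet_rate,
                        }
                    )
        pairings_df = pd.DataFrame(pairing_rows)
        _write_csv(pairings_df, out / "pairings.csv", config, "CS-US pairing events")
        if example_log is not None:
            _write_csv(example_log, out / "pump_log.csv", config, "example session pump log")

        stage = "trials"
        trial_rows = []
        trial_seeds = ss_trials.spawn(len(profiles))
        for prof, pseed in zip(profiles, trial_seeds):
            for tp, tseed in zip(TIME_POINTS_BY_GROUP[prof.group], pseed.spawn(3)):
                rec = cohort_mod.simulate_trial_record(prof, tp, tseed, config.cohort)
                trial_rows.append(dataclasses.asdict(rec) | {"group": prof.group})
        trials_df = pd.DataFrame(trial_rows)
        _write_csv(trials_df, out / "trials.csv", config, "self-paced exercise trials")

        stage = "dd_task"
        ip_rows = []
        fits = []
        task_seeds = ss_task.spawn(len(profiles))
        for prof, pseed in zip(profiles, task_seeds):
            for tp in TIME_POINTS_BY_GROUP[prof.group]:
                for commodity in COMMODITIES_BY_TP[tp]:
                    cseed = pseed.spawn(1)[0]
                    rng = np.random.default_rng(cseed)

                    def responder(imm, dly, d, _prof=prof, _c=commodity, _rng=rng):
                        trial = cohort_mod.ChoiceTrial(_c, min(imm, dly), dly, d)
                        return cohort_mod.simulate_choice(_prof, trial, _rng)

                    curve = ddtask.run_adjusting_task(
                        responder,
                        ddtask.build_menu(commodity),
                        seed=rng,
                        distractor_rate=config.distractor_rate,
                        max_reversals=config.max_reversals,
                        participant_id=prof.id,
                    )
                    for d in sorted(curve.points):
                        ip_rows.append(
                            {
                                "participant_id": prof.id,
                                "group": prof.group,
                                "time_point": tp,
                                "commodity": commodity,
                                "delay_days": d,
                                "ip": curve.points[d],
                                "flagged": curve.flagged,
                            }
                        )
                    f = discounting.fit_hyperbolic(curve)
                    fits.append(
                        {
                            "participant_id": prof.id,
                            "group": prof.group,
                            "time_point": tp,
                            "commodity": commodity,
                            "k": f.k,
                            "r_squared": f.r_squared,
                            "included": f.included,
                            "log_k": f.log_k,
                            "k_true": prof.k_for(commodity),
                        }
                    )
        ips_df = pd.DataFrame(ip_rows)
        fits_df = pd.DataFrame(fits)
        _write_csv(ips_df, out / "ips.csv", config, "indifference points")
        _write_csv(fits_df, out / "fits.csv", config, "Mazur hyperbolic fits (normalized IPs)")

        stage = "exclusion"
        kept = fits_df[
            (fits_df.r_squared >= config.exclusion_threshold)
            | (fits_df.r_squared.isna() & fits_df.included)
        ]
        removed = fits_df.drop(kept.index)

        stage = "effort"
        ref_hps = float(
            np.mean([p.hr_per_speed0 for p in profiles if p.group in ("TR", "COTR")])
        )
        hps_by = {p.id: p for p in profiles}
        effort_rows = []
        conditions = [
            ("T0", ("TR", "COTR")),
            ("T1", ("TR", "COTR")),
            ("T2-TR", ("TR",)),
            ("T2-COTR", ("COTR",)),
        ]
        for label, groups in conditions:
            tp = label.split("-")[0]
            sub = trials_df[(trials_df.time_point == tp) & trials_df.group.isin(groups)]
            obs = [
                effort.EffortObservation(
                    participant_id=r.participant_id,
                    time_point=tp,
                    vp=effort.normalize_fs(r.fs),
                    cost=float(r.rpe),
                    reward=effort.map_reward(
                        hps_by[r.participant_id].hr_per_speed(tp), ref_hps
                    ),
                    group=r.group,
                )
                for r in sub.itertuples()
            ]
            res = effort.fit_shared_k(obs, condition_label=label, mapping_name=config.mapping)
            effort_rows.append(
                {
                    "condition": label,
                    "n": len(obs),
                    "k": res.k,
                    "residual_ss": res.residual_ss,
                    "mean_vp_measured": float(np.mean([o.vp for o in obs])),
                    "mean_vp_model": float(np.mean(res.vp_model)),
                    "sign_statistic": res.comparison["statistic"],
                    "sign_p_value": res.comparison["p_value"],
                    "mapping": res.mapping_name,
                }
            )
        effort_df = pd.DataFrame(effort_rows)
        _write_csv(effort_df, out / "effort_fit.csv", config, "shared-k effort fits")

        stage = "report"
        trial_summary = summarize(
            trials_df, ["group", "time_point"], ["speed", "avg_hr", "rpe", "fs"]
        )
        k_summary = summarize(kept, ["group", "time_point", "commodity"], ["k", "r_squared"])
        _write_csv(trial_summary, out / "summary_trials.csv", config, "trial summaries")
        _write_csv(k_summary, out / "summary_k.csv", config, "discounting summaries (retained fits)")
        report = _render_report(
            config, pframe, trials_df, trial_summary, k_summary, kept, removed, effort_df, pairings_df
        )
        (out / "report.txt").write_text(report)
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    return {
        "profiles": profiles,
        "participants": pframe,
        "trials": trials_df,
        "ips": ips_df,
        "fits": fits_df,
        "fits_retained": kept,
        "fits_removed": removed,
        "effort": effort_df,
        "pairings": pairings_df,
        "out_dir": out,
    }


def _fmt_summary(df: pd.DataFrame) -> str:
    if df.empty:
        return "  (no rows)\n"
    cols = [c for c in df.columns]
    out = []
    for _, r in df.iterrows():
        key = " ".join(str(r[c]) for c in cols if c not in ("mean", "sd", "median", "p25", "p75", "n", "variable"))
        out.append(
            f"  {key:14s} {r['variable']:10s} {r['mean']:8.3f} ({r['sd']:.3f})  "
            f"med {r['median']:.3f} ({r['p25']:.3f}|{r['p75']:.3f})  n={int(r['n'])}"
        )
    return "\n".join(out) + "\n"


def _render_report(config, pframe, trials_df, trial_summary, k_summary, kept, removed, effort_df, pairings_df) -> str:
    lines = []
    w = lines.append
    w("exertvalue pipeline report")
    w(f"config_hash: {config.config_hash}  seed: {config.seed}")
    w("")
    counts = pframe.group.value_counts().to_dict()
    w(f"cohort: n={len(pframe)} " + " ".join(f"{g}={counts.get(g, 0)}" for g in cohort_mod.GROUPS))
    n_cotr = counts.get("COTR", 0)
    w(
        f"conditioning: {config.n_sessions} sessions x 6 cycles -> "
        f"{len(pairings_df)} pairing events over {n_cotr} COTR participants "
        f"(expected {config.n_sessions * 6 * n_cotr})"
    )
    w("")
    w("exercise trial summaries (group, time point):")
    w(_fmt_summary(trial_summary))
    w("discounting constants k, retained fits (group, time point, commodity):")
    w(_fmt_summary(k_summary))
    w(f"exclusion rule R^2 < {config.exclusion_threshold}: removed {len(removed)} of {len(kept) + len(removed)} fits")
    for r in removed.itertuples():
        w(f"  removed {r.participant_id} {r.time_point} {r.commodity} R^2={r.r_squared:.3f}")
    w("")
    w("parameter recovery (median fitted vs median generating k, retained fits):")
    for commodity, grp in kept.groupby("commodity"):
        w(
            f"  {commodity:9s} k_hat={grp.k.median():.4f}  k_true={grp.k_true.median():.4f}  "
            f"n={len(grp)}"
        )
    w("")
    w("shared-k effort fits (Vp = M/(1+kC), M mapping '" + config.mapping + "'):")
    for r in effort_df.itertuples():
        w(
            f"  {r.condition:8s} n={r.n:3d} k={r.k:.4f}  Vp meas {r.mean_vp_measured:.3f} "
            f"model {r.mean_vp_model:.3f}  sign test S={r.sign_statistic} p={r.sign_p_value:.3f}"
        )
    w("")
    return "\n".join(lines)
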