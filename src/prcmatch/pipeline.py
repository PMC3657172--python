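"""End-to-end orchestration: generate -> simulate -> analyze -> report.

A single :class:`RunConfig` fully determines a run (schedules, simulated
cohorts, analysis switches), so identical configs produce byte-identical
reports.  The pipeline emulates the full study design on synthetic data:

* a gaze experiment (healthy observers, four conditions) analyzed with the
  within/between saccade ratios and the planned interaction contrast;
* a split-half patient study: one perirhinal-lesioned observer and one
  hippocampal observer (modelled with the conjunction channel intact),
  each with their own matched control group, across the four conditions;
* an interference study: the same cohorts on Low Interference 1 /
  High Interference / Low Interference 2 blocks scored on the 30
  comparison trials each.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import gaze, scheduler, sdt, simulate, singlecase
from .errors import PrcMatchError, UndefinedRatioError
from .scheduler import (BASE_CONDITIONS, HIGH_AMBIGUITY, LOW_AMBIGUITY,
                        DIFFICULT_SIZE, EASY_SIZE)

_DEFAULT_STAY_PROBS = {
    # conjunctive processing (high ambiguity) favours within-item scanning
    HIGH_AMBIGUITY: 0.75,
    LOW_AMBIGUITY: 0.55,
    DIFFICULT_SIZE: 0.60,
    EASY_SIZE: 0.60,
}


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    seed: int = 0
    out_dir: str = "prcmatch_run"
    n_controls: int = 8
    n_gaze_participants: int = 16
    trials_policy: str = "nonmatch"  # gaze trial selection
    sdt_model: str = "differencing"
    gaze_stay_probs: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_STAY_PROBS))
    gaze_stay_prob_sd: float = 0.05  # between-participant spread
    gaze_fixations_per_trial: int = 12
    observer_intact: dict[str, Any] = field(default_factory=dict)
    observer_lesioned: dict[str, Any] = field(default_factory=dict)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _seed_for(config: RunConfig, *tags: int) -> int:
    return int(np.random.SeedSequence([config.seed, *tags]).generate_state(1)[0]
               % (2 ** 31))


def _observer(config: RunConfig, kind: str, seed: int) -> simulate.ObserverParams:
    overrides = (config.observer_lesioned if kind == "lesioned"
                 else config.observer_intact)
    base = (simulate.ObserverParams.lesioned if kind == "lesioned"
            else simulate.ObserverParams.intact)
    return base(seed=seed, **overrides)


def _ttest_dict(res: gaze.TTestResult) -> dict:
    return dataclasses.asdict(res)


# ---------------------------------------------------------------------------
# stages

def _run_gaze_stage(config: RunConfig, out: Path) -> dict:
    schedules = scheduler.build_experiment_schedules(
        "exp1", _seed_for(config, 1))
    rng = np.random.default_rng(_seed_for(config, 2))
    rows = []
    flags = []
    for p in range(config.n_gaze_participants):
        pid = f"sub{p + 1:02d}"
        for ci, (cond, sched) in enumerate(schedules.items()):
            stay = float(np.clip(
                rng.normal(config.gaze_stay_probs[cond],
                           config.gaze_stay_prob_sd), 0.0, 1.0))
            params = simulate.GazeSimParams(
                stay_prob=stay,
                fixations_per_trial=config.gaze_fixations_per_trial,
                seed=_seed_for(config, 3, p, ci))
            fix = simulate.simulate_gaze_run(sched, params)
            try:
                _, summary = gaze.analyze_gaze(fix, sched,
                                               trials=config.trials_policy)
                rows.append((pid, cond, stay, summary.within_total_avg,
                             summary.between_total_avg,
                             summary.within_between, summary.n_trials_used))
            except UndefinedRatioError as err:
                flags.append({"participant": pid, "condition": cond,
                              "issue": "undefined within:between ratio",
                              "within_total_avg": err.within_total_avg})
    df = pd.DataFrame(rows, columns=[
        "participant", "condition", "true_stay_prob", "within_total_avg",
        "between_total_avg", "within_between", "n_trials_used"])
    df.to_csv(out / "exp1_gaze_ratios.csv", index=False)

    stats: dict[str, Any] = {"flags": flags}
    wide = df.pivot(index="participant", columns="condition",
                    values="within_total_avg")
    if not flags and len(wide) >= 2:
        stats["interaction"] = _ttest_dict(
            gaze.interaction_contrast(wide, tail="one"))
        stats["simple_high_vs_low"] = _ttest_dict(
            gaze.simple_effect(wide[HIGH_AMBIGUITY], wide[LOW_AMBIGUITY],
                               tail="one"))
    (out / "exp1_gaze_stats.json").write_text(
        json.dumps(stats, indent=1, sort_keys=True))
    return stats


def _write_logs(out: Path, experiment: str,
                logs: dict[str, dict[str, list[sdt.ResponseRecord]]]) -> None:
    d = out / "logs" / experiment
    d.mkdir(parents=True, exist_ok=True)
    for pid, per_cond in logs.items():
        for cond, responses in per_cond.items():
            sdt.write_responses_csv(responses, d / f"{pid}_{cond}.csv")


def _cohorts(config: RunConfig, schedules, tag: int):
    """Two single-case cohorts: a perirhinal-lesioned and a hippocampal case."""
    cohorts = {}
    for i, (case, kind) in enumerate((("MTL", "lesioned"), ("HC", "intact"))):
        cohorts[case] = simulate.make_cohort(
            config.n_controls,
            patient_params=_observer(config, kind, _seed_for(config, tag, i, 0)),
            control_params=_observer(config, "intact",
                                     _seed_for(config, tag, i, 1)),
            schedules=schedules,
            patient_id=f"{case}-patient",
        )
    return cohorts


def _run_splithalf_stage(config: RunConfig, out: Path) -> dict:
    schedules = scheduler.build_experiment_schedules(
        "exp3", _seed_for(config, 4))
    cohorts = _cohorts(config, schedules, 5)
    rows = []
    for case, logs in cohorts.items():
        _write_logs(out, f"exp3_{case}", logs)
        for pid, per_cond in logs.items():
            for cond, responses in per_cond.items():
                first, second = sdt.split_half_dprime(
                    responses, schedules[cond], model=config.sdt_model)
                rows.append((case, pid, cond, first.d_prime, second.d_prime))
    df = pd.DataFrame(rows, columns=[
        "cohort", "participant", "condition", "dprime_first_half",
        "dprime_second_half"])
    df.to_csv(out / "exp3_dprime.csv", index=False)

    crawford_rows = []
    for case in cohorts:
        sub = df[df.cohort == case]
        patient = sub[sub.participant.str.endswith("patient")]
        controls = sub[~sub.participant.str.endswith("patient")]
        for cond in BASE_CONDITIONS:
            for half in ("dprime_first_half", "dprime_second_half"):
                res = singlecase.crawford_t(
                    float(patient[patient.condition == cond][half].iloc[0]),
                    controls[controls.condition == cond][half].to_numpy())
                crawford_rows.append((case, cond, half.replace("dprime_", ""),
                                      res.t_value, res.df, res.p_value))
    cdf = pd.DataFrame(crawford_rows, columns=[
        "cohort", "condition", "half", "t", "df", "p_one_tailed"])
    cdf.to_csv(out / "exp3_crawford.csv", index=False)

    # control analyses: difficulty contrasts and group equivalence
    ctrl = df[~df.participant.str.endswith("patient")].copy()
    ctrl["dprime"] = (ctrl.dprime_first_half + ctrl.dprime_second_half) / 2
    tables = {
        case: ctrl[ctrl.cohort == case].pivot(
            index="participant", columns="condition", values="dprime")
        [list(BASE_CONDITIONS)]
        for case in cohorts
    }
    difficulty = {
        case: {k: _ttest_dict(v)
               for k, v in singlecase.control_difficulty_contrast(t).items()}
        for case, t in tables.items()
    }
    equivalence = singlecase.control_group_equivalence(tables)
    (out / "exp3_control_stats.json").write_text(json.dumps(
        {"difficulty": difficulty,
         "equivalence": dataclasses.asdict(equivalence)},
        indent=1, sort_keys=True))
    return {"crawford": cdf.to_dict("records"),
            "equivalence": dataclasses.asdict(equivalence)}


def _run_interference_stage(config: RunConfig, out: Path) -> dict:
    pools = scheduler.FeaturePools()
    blocks = {}
    for i, (label, cond) in enumerate((
            ("low_interference_1", "low_interference"),
            ("high_interference", "high_interference"),
            ("low_interference_2", "low_interference"))):
        blocks[label] = scheduler.build_condition_schedule(
            "exp4", cond, _seed_for(config, 6, i), feature_pools=pools)
    cohorts = _cohorts(config, blocks, 7)
    rows = []
    for case, logs in cohorts.items():
        _write_logs(out, f"exp4_{case}", logs)
        for pid, per_block in logs.items():
            for label, responses in per_block.items():
                res = sdt.comparison_trial_dprime(
                    responses, blocks[label], model=config.sdt_model)
                rows.append((case, pid, label, res.d_prime,
                             res.rate_pair.hit_rate, res.rate_pair.fa_rate))
    df = pd.DataFrame(rows, columns=[
        "cohort", "participant", "block", "comparison_dprime", "hit_rate",
        "fa_rate"])
    df.to_csv(out / "exp4_dprime.csv", index=False)

    crawford_rows = []
    for case in cohorts:
        sub = df[df.cohort == case]
        patient = sub[sub.participant.str.endswith("patient")]
        controls = sub[~sub.participant.str.endswith("patient")]
        for label in blocks:
            res = singlecase.crawford_t(
                float(patient[patient.block == label]
                      .comparison_dprime.iloc[0]),
                controls[controls.block == label]
                .comparison_dprime.to_numpy())
            crawford_rows.append((case, label, res.t_value, res.df,
                                  res.p_value))
    cdf = pd.DataFrame(crawford_rows,
                       columns=["cohort", "block", "t", "df", "p_one_tailed"])
    cdf.to_csv(out / "exp4_crawford.csv", index=False)
    return {"crawford": cdf.to_dict("records")}


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle under ``config.out_dir``.

    Returns the summary dictionary (also written as ``summary.json``).
    Stage contract violations surface as :class:`PrcMatchError` with the
    offending stage named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    # schedules written for audit
    sched_dir = out / "schedules"
    sched_dir.mkdir(exist_ok=True)
    for exp in ("exp1", "exp3"):
        for cond, sched in scheduler.build_experiment_schedules(
                exp, _seed_for(config, 1 if exp == "exp1" else 4)).items():
            scheduler.write_schedule_csv(sched, sched_dir / f"{exp}_{cond}.csv")
            scheduler.write_schedule_json(sched,
                                          sched_dir / f"{exp}_{cond}.json")

    summary: dict[str, Any] = {"seed": config.seed}
    for name, stage in (("gaze", _run_gaze_stage),
                        ("split_half", _run_splithalf_stage),
                        ("interference", _run_interference_stage)):
        try:
            summary[name] = stage(config, out)
        except PrcMatchError as err:
            raise type(err)(f"stage {name!r}: {err}") from err
    (out / "summary.json").write_text(json.dumps(summary, indent=1,
                                                 sort_keys=True))
    return summary
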