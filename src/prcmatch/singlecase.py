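"""Single-case inference and control-group contrasts.

A patient's score is compared with a small control sample using Crawford's
modified t test, which treats the control sample as statistics rather than
parameters:

    t = (x - m) / (s * sqrt((n + 1) / n)),  df = n - 1

where x is the patient's score and m, s, n describe the controls.  Under
the null (patient drawn from the control population, normality) t follows
a Student t distribution with n - 1 df, which keeps the type-I error at
its nominal level even for very small control samples.

Tail conventions: patient-deficit tests are one-tailed in the deficit
direction (lower score), so a patient *above* the control mean yields a
one-tailed p > 0.5, reported as-is.  The control-group difficulty analyses
are two-tailed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, DegenerateVarianceError
from .gaze import TTestResult, interaction_contrast, simple_effect  # noqa: F401
from .scheduler import (HIGH_AMBIGUITY, LOW_AMBIGUITY, DIFFICULT_SIZE,
                        EASY_SIZE)


@dataclass
class SingleCaseResult:
    t_value: float
    df: int
    p_value: float
    tail: str  # {one, two}
    patient_score: float
    control_mean: float
    control_sd: float
    n_controls: int


def crawford_t(
    patient_score: float,
    control_scores: Sequence[float],
    tail: str = "one",
) -> SingleCaseResult:
    """Crawford's modified t for one patient vs one control sample.

    One-tailed p is the probability in the deficit direction (patient below
    the control mean); a patient at the control mean gives t = 0 and
    one-tailed p = 0.5.
    """
    controls = np.asarray(control_scores, dtype=float)
    n = len(controls)
    if n < 2:
        raise ContractError(f"need at least 2 controls, got {n}")
    m = float(np.mean(controls))
    s = float(np.std(controls, ddof=1))
    if s == 0:
        raise DegenerateVarianceError("control scores are all equal")
    t = (float(patient_score) - m) / (s * math.sqrt((n + 1) / n))
    df = n - 1
    if tail == "one":
        p = float(stats.t.cdf(t, df))  # deficit direction: score below mean
    elif tail == "two":
        p = float(2 * stats.t.sf(abs(t), df))
    else:
        raise ContractError(f"unknown tail: {tail!r}")
    return SingleCaseResult(t_value=float(t), df=df, p_value=p, tail=tail,
                            patient_score=float(patient_score),
                            control_mean=m, control_sd=s, n_controls=n)


def crawford_t_many(
    patient_scores: np.ndarray, control_scores: np.ndarray
) -> tuple[np.ndarray, int]:
    """Vectorized Crawford t over simulated cases.

    ``patient_scores`` has shape (reps,), ``control_scores`` (reps, n).
    Returns the t values and the common df.  Used for calibration studies.
    """
    controls = np.asarray(control_scores, dtype=float)
    reps, n = controls.shape
    m = controls.mean(axis=1)
    s = controls.std(axis=1, ddof=1)
    t = (np.asarray(patient_scores, dtype=float) - m) / (
        s * math.sqrt((n + 1) / n))
    return t, n - 1


# ---------------------------------------------------------------------------
# control-group difficulty analyses (two-tailed by convention)

def paired_t(a: Sequence[float], b: Sequence[float],
             tail: str = "two") -> TTestResult:
    """Paired t test between two condition vectors (two-tailed default)."""
    return simple_effect(a, b, tail=tail)


def control_difficulty_contrast(
    scores: Mapping[str, Sequence[float]] | pd.DataFrame,
) -> dict[str, TTestResult]:
    """Task-difficulty analysis on a controls-by-condition table.

    Returns the planned interaction contrast (HA - LA) - (DS - ES) and the
    pairwise paired contrasts on the condition measures (d' or RT), all
    two-tailed.
    """
    if isinstance(scores, pd.DataFrame):
        scores = {c: scores[c].to_numpy() for c in scores.columns}
    needed = (HIGH_AMBIGUITY, LOW_AMBIGUITY, DIFFICULT_SIZE, EASY_SIZE)
    missing = [c for c in needed if c not in scores]
    if missing:
        raise ContractError(f"missing conditions: {missing}")
    return {
        "interaction": interaction_contrast(scores, tail="two"),
        "high_vs_low_ambiguity": paired_t(scores[HIGH_AMBIGUITY],
                                          scores[LOW_AMBIGUITY]),
        "difficult_vs_easy_size": paired_t(scores[DIFFICULT_SIZE],
                                           scores[EASY_SIZE]),
        "high_ambiguity_vs_difficult_size": paired_t(scores[HIGH_AMBIGUITY],
                                                     scores[DIFFICULT_SIZE]),
    }


# ---------------------------------------------------------------------------
# two-group equivalence (balanced two-way mixed layout)

@dataclass
class MixedAnovaResult:
    """F tests from a balanced group (between) x condition (within) layout."""

    f_group: float
    df_group: tuple[int, int]
    p_group: float
    f_condition: float
    df_condition: tuple[int, int]
    p_condition: float
    f_interaction: float
    df_interaction: tuple[int, int]
    p_interaction: float


def mixed_anova_balanced(tables: Sequence[np.ndarray]) -> MixedAnovaResult:
    """Mixed ANOVA for g groups of equal size over k within conditions.

    ``tables[i]`` is the (n x k) score matrix of group i.  The group effect
    is tested against subjects-within-groups, condition and interaction
    against the subject-by-condition residual.  Closed-form sums of squares
    for the balanced design; unbalanced input is rejected.
    """
    mats = [np.asarray(t, dtype=float) for t in tables]
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise ContractError("groups must have equal size and conditions")
    n, k = mats[0].shape
    g = len(mats)
    if n < 2 or g < 2 or k < 1:
        raise ContractError("need >=2 groups of >=2 subjects")
    if np.any([~np.isfinite(m).all() for m in mats]):
        raise ContractError("missing cells are not supported")
    y = np.stack(mats)  # (g, n, k)
    gm = y.mean()
    group_means = y.mean(axis=(1, 2))
    subj_means = y.mean(axis=2)
    cond_means = y.mean(axis=(0, 1))
    cell_means = y.mean(axis=1)  # (g, k)

    ss_group = n * k * np.sum((group_means - gm) ** 2)
    ss_subj = k * np.sum((subj_means - group_means[:, None]) ** 2)
    ss_cond = g * n * np.sum((cond_means - gm) ** 2)
    ss_inter = n * np.sum(
        (cell_means - group_means[:, None] - cond_means[None, :] + gm) ** 2)
    resid = (y - cell_means[:, None, :] - subj_means[:, :, None]
             + group_means[:, None, None])
    ss_err = np.sum(resid ** 2)

    df_group = (g - 1, g * (n - 1))
    df_cond = (k - 1, g * (n - 1) * (k - 1))
    df_inter = ((g - 1) * (k - 1), g * (n - 1) * (k - 1))

    ms_subj = ss_subj / df_group[1]
    if ms_subj == 0:
        raise DegenerateVarianceError("no subject variance")
    f_group = (ss_group / df_group[0]) / ms_subj
    if k > 1:
        ms_err = ss_err / df_cond[1]
        if ms_err == 0:
            raise DegenerateVarianceError("no within-subject residual variance")
        f_cond = (ss_cond / df_cond[0]) / ms_err
        f_inter = (ss_inter / df_inter[0]) / ms_err
        p_cond = float(stats.f.sf(f_cond, *df_cond))
        p_inter = float(stats.f.sf(f_inter, *df_inter))
    else:
        f_cond = f_inter = float("nan")
        p_cond = p_inter = float("nan")
    return MixedAnovaResult(
        f_group=float(f_group), df_group=df_group,
        p_group=float(stats.f.sf(f_group, *df_group)),
        f_condition=float(f_cond), df_condition=df_cond, p_condition=p_cond,
        f_interaction=float(f_inter), df_interaction=df_inter,
        p_interaction=p_inter,
    )


def control_group_equivalence(
    groups: Mapping[str, pd.DataFrame],
) -> MixedAnovaResult | TTestResult:
    """Test whether two control groups differ overall or across conditions.

    Each value is a participants x conditions DataFrame with identical
    condition columns.  With a single condition the design collapses to a
    two-sample t test; otherwise the group main effect and the group x
    condition interaction from the balanced mixed layout are returned.
    """
    if len(groups) != 2:
        raise ContractError(f"need exactly 2 groups, got {len(groups)}")
    frames = list(groups.values())
    cols = [tuple(f.columns) for f in frames]
    if cols[0] != cols[1]:
        raise ContractError("groups must share the same condition columns")
    if len(cols[0]) == 1:
        a = frames[0].iloc[:, 0].to_numpy(dtype=float)
        b = frames[1].iloc[:, 0].to_numpy(dtype=float)
        t, p = stats.ttest_ind(a, b)
        pooled_sd = math.sqrt(
            ((len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1))
            / (len(a) + len(b) - 2))
        return TTestResult(t=float(t), df=len(a) + len(b) - 2, p=float(p),
                           tail="two", n=len(a) + len(b),
                           mean=float(np.mean(a) - np.mean(b)), sd=pooled_sd)
    return mixed_anova_balanced([f.to_numpy(dtype=float) for f in frames])
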