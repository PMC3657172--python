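"""Within-item vs between-item saccade classification and ratio statistics.

Two stimuli occupy two invisible 500 x 500 px frames separated by an 8 px
gap.  Each consecutive pair of fixations defines a saccade: if both
endpoints fall inside the same frame it is *within-item*, if they fall in
different frames it is *between-item*.  The per-condition summary
statistics are

    (Within/Total)Av  = mean over trials of W_i / T_i
    (Between/Total)Av = mean over trials of B_i / T_i
    Within:Between    = (Within/Total)Av / (Between/Total)Av

i.e. the within:between ratio is the quotient of the two averages, not the
average of per-trial quotients.  A predominance of within-item saccades
indicates a conjunctive (whole-object) viewing strategy; alternating
between-item saccades indicate serial single-feature comparison.

Group-level inference uses the planned interaction contrast
(high_ambiguity - low_ambiguity) - (difficult_size - easy_size) and the
simple effect high vs low ambiguity, one-tailed by default (directional
hypotheses).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (ContractError, DegenerateVarianceError,
                     UndefinedRatioError)
from .scheduler import (HIGH_AMBIGUITY, LOW_AMBIGUITY, DIFFICULT_SIZE,
                        EASY_SIZE, ConditionSchedule)


@dataclass(frozen=True)
class Fixation:
    """One fixation event in screen pixel coordinates."""

    x_px: float
    y_px: float
    onset_ms: float
    duration_ms: float
    trial_index: int = 0


@dataclass(frozen=True)
class FramesGeometry:
    """Two adjacent square frames separated by a horizontal gap.

    The default origin puts the top-left corner of the left frame at
    (0, 0); the right frame then spans x in [508, 1008].
    """

    frame_size_px: float = 500.0
    gap_px: float = 8.0
    origin_x: float = 0.0
    origin_y: float = 0.0

    def which_frame(self, x: float, y: float) -> int | None:
        """0 for the left frame, 1 for the right, None if outside both."""
        if not (self.origin_y <= y <= self.origin_y + self.frame_size_px):
            return None
        rx = x - self.origin_x
        if 0 <= rx <= self.frame_size_px:
            return 0
        rx2 = rx - self.frame_size_px - self.gap_px
        if 0 <= rx2 <= self.frame_size_px:
            return 1
        return None

    def nearest_frame(self, x: float, y: float) -> int:
        centers = (self.origin_x + self.frame_size_px / 2,
                   self.origin_x + 1.5 * self.frame_size_px + self.gap_px)
        return int(abs(x - centers[1]) < abs(x - centers[0]))


DEFAULT_GEOMETRY = FramesGeometry()


@dataclass
class SaccadeCounts:
    """Within (W), between (B) and total (T) saccade counts for one trial."""

    W: int
    B: int
    T: int
    trial_index: int = 0


@dataclass
class SaccadeRatioSummary:
    within_total_avg: float
    between_total_avg: float
    within_between: float
    n_trials_used: int


@dataclass
class TTestResult:
    """A t statistic with its df, tail convention and p value."""

    t: float
    df: int
    p: float
    tail: str  # {one, two}
    n: int
    mean: float
    sd: float


# ---------------------------------------------------------------------------
# saccade classification

def classify_saccades(
    fixations: Sequence[Fixation],
    geometry: FramesGeometry = DEFAULT_GEOMETRY,
    out_of_frame: str = "exclude",
) -> SaccadeCounts:
    """Count within- and between-item saccades for one trial.

    Each consecutive fixation pair is one saccade.  Under the default
    ``out_of_frame="exclude"`` policy, pairs with either endpoint outside
    both frames are dropped from W, B and T (so W + B = T always); under
    ``"nearest"`` every fixation is assigned to the nearest frame.  An
    empty or single-fixation trial yields W = B = T = 0.
    """
    if out_of_frame not in ("exclude", "nearest"):
        raise ContractError(f"unknown out_of_frame policy: {out_of_frame!r}")
    trial_index = fixations[0].trial_index if len(fixations) else 0
    frames: list[int | None] = []
    for f in fixations:
        fr = geometry.which_frame(f.x_px, f.y_px)
        if fr is None and out_of_frame == "nearest":
            fr = geometry.nearest_frame(f.x_px, f.y_px)
        frames.append(fr)
    w = b = 0
    for a, c in zip(frames, frames[1:]):
        if a is None or c is None:
            continue
        if a == c:
            w += 1
        else:
            b += 1
    return SaccadeCounts(W=w, B=b, T=w + b, trial_index=trial_index)


def ratio_summary(counts_per_trial: Iterable[SaccadeCounts]) -> SaccadeRatioSummary:
    """Average per-trial W/T and B/T, then form the within:between quotient.

    Trials with no counted saccades (T = 0) are skipped.  If no between-item
    saccade occurred in any trial the quotient is undefined and an
    :class:`UndefinedRatioError` carrying both averages is raised.
    """
    usable = [c for c in counts_per_trial if c.T > 0]
    if not usable:
        raise ContractError("no trials with counted saccades")
    wt = float(np.mean([c.W / c.T for c in usable]))
    bt = float(np.mean([c.B / c.T for c in usable]))
    if bt == 0:
        raise UndefinedRatioError(wt, bt)
    return SaccadeRatioSummary(wt, bt, wt / bt, len(usable))


# ---------------------------------------------------------------------------
# group-level contrasts

_CONTRAST_CONDITIONS = (HIGH_AMBIGUITY, LOW_AMBIGUITY, DIFFICULT_SIZE, EASY_SIZE)


def _one_sample_t(values: np.ndarray, tail: str) -> TTestResult:
    if tail not in ("one", "two"):
        raise ContractError(f"unknown tail: {tail!r}")
    n = len(values)
    if n < 2:
        raise ContractError(f"need at least 2 participants, got {n}")
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    df = n - 1
    if sd == 0:
        if mean == 0:
            # all contrasts exactly zero: no effect, t = 0 by convention
            p = 0.5 if tail == "one" else 1.0
            return TTestResult(t=0.0, df=df, p=p, tail=tail, n=n,
                               mean=0.0, sd=0.0)
        raise DegenerateVarianceError(
            "zero variance across participants; t undefined")
    t = mean / (sd / math.sqrt(n))
    if tail == "one":
        p = float(stats.t.sf(t, df))  # H1: contrast > 0
    elif tail == "two":
        p = float(2 * stats.t.sf(abs(t), df))
    else:
        raise ContractError(f"unknown tail: {tail!r}")
    return TTestResult(t=float(t), df=df, p=p, tail=tail, n=n, mean=mean, sd=sd)


def interaction_contrast(
    values: Mapping[str, Sequence[float]] | pd.DataFrame,
    tail: str = "one",
) -> TTestResult:
    """Planned interaction (HA - LA) - (DS - ES) as a one-sample t vs 0.

    ``values`` maps each of the four condition labels to one value per
    participant (same participant order in every condition).
    """
    if isinstance(values, pd.DataFrame):
        values = {c: values[c].to_numpy() for c in values.columns}
    missing = [c for c in _CONTRAST_CONDITIONS if c not in values]
    if missing:
        raise ContractError(f"missing conditions: {missing}")
    arrs = {c: np.asarray(values[c], dtype=float) for c in _CONTRAST_CONDITIONS}
    lengths = {len(a) for a in arrs.values()}
    if len(lengths) != 1:
        raise ContractError("all conditions need the same participants")
    contrast = ((arrs[HIGH_AMBIGUITY] - arrs[LOW_AMBIGUITY])
                - (arrs[DIFFICULT_SIZE] - arrs[EASY_SIZE]))
    return _one_sample_t(contrast, tail)


def simple_effect(
    a: Sequence[float], b: Sequence[float], tail: str = "one",
) -> TTestResult:
    """Paired t test of condition a vs condition b (default one-tailed a > b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b):
        raise ContractError("paired samples must have equal length")
    return _one_sample_t(a - b, tail)


# ---------------------------------------------------------------------------
# fixation tables and end-to-end analysis

FIXATION_COLUMNS = ["trial_index", "x_px", "y_px", "onset_ms", "duration_ms"]


def read_fixations(path: str | Path) -> pd.DataFrame:
    """Read a fixation-event table (comma- or tab-delimited, with header)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in FIXATION_COLUMNS if c not in df.columns]
    if missing:
        raise ContractError(f"fixation table missing columns: {missing}")
    return df[FIXATION_COLUMNS].sort_values(["trial_index", "onset_ms"],
                                            kind="stable")


def write_fixations(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def fixations_from_frame(df: pd.DataFrame) -> dict[int, list[Fixation]]:
    out: dict[int, list[Fixation]] = {}
    for trial, grp in df.groupby("trial_index", sort=True):
        out[int(trial)] = [
            Fixation(float(r.x_px), float(r.y_px), float(r.onset_ms),
                     float(r.duration_ms), int(trial))
            for r in grp.sort_values("onset_ms").itertuples()
        ]
    return out


def analyze_gaze(
    fixations: pd.DataFrame,
    schedule: ConditionSchedule | None = None,
    geometry: FramesGeometry = DEFAULT_GEOMETRY,
    trials: str = "nonmatch",
    out_of_frame: str = "exclude",
) -> tuple[list[SaccadeCounts], SaccadeRatioSummary]:
    """Classify saccades per trial and summarize the ratios for one block.

    ``trials="nonmatch"`` (default) restricts the summary to nonmatch
    trials of the schedule — on a match trial the two stimuli are identical
    so its ambiguity level is undefined; ``trials="all"`` keeps every trial.
    """
    if trials not in ("nonmatch", "all"):
        raise ContractError(f"unknown trial policy: {trials!r}")
    keep = None
    if trials == "nonmatch":
        if schedule is None:
            raise ContractError("trials='nonmatch' requires a schedule")
        keep = {t.trial_index for t in schedule.trials if not t.is_match}
    counts = []
    for trial, fix_list in fixations_from_frame(fixations).items():
        if keep is not None and trial not in keep:
            continue
        counts.append(classify_saccades(fix_list, geometry, out_of_frame))
    return counts, ratio_summary(counts)


def counts_to_frame(counts: Iterable[SaccadeCounts]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.trial_index, c.W, c.B, c.T) for c in counts],
        columns=["trial_index", "W", "B", "T"])


# ---------------------------------------------------------------------------
# optional fixation detection from raw gaze samples

def detect_fixations(
    samples: pd.DataFrame,
    velocity_threshold_px_per_ms: float = 1.0,
    min_duration_ms: float = 50.0,
    trial_index: int = 0,
) -> list[Fixation]:
    """Simple velocity-threshold fixation detector for raw gaze samples.

    ``samples`` needs columns t_ms, x_px, y_px at a constant sampling rate.
    Consecutive samples whose point-to-point velocity stays below the
    threshold are merged into fixation episodes; episodes shorter than
    ``min_duration_ms`` are dropped.  This is a deliberately plain detector
    for simulated or pre-cleaned data — not a re-implementation of any
    vendor's event parser.
    """
    t = samples["t_ms"].to_numpy(dtype=float)
    x = samples["x_px"].to_numpy(dtype=float)
    y = samples["y_px"].to_numpy(dtype=float)
    if len(t) < 2:
        return []
    dt = np.diff(t)
    vel = np.hypot(np.diff(x), np.diff(y)) / np.where(dt > 0, dt, np.inf)
    slow = np.concatenate([[True], vel <= velocity_threshold_px_per_ms])
    fixations = []
    start = None
    for i, s in enumerate(slow):
        if s and start is None:
            start = i
        elif not s and start is not None:
            fixations.append((start, i - 1))
            start = None
    if start is not None:
        fixations.append((start, len(t) - 1))
    out = []
    for a, b in fixations:
        dur = t[b] - t[a]
        if dur >= min_duration_ms and b > a:
            out.append(Fixation(float(np.mean(x[a:b + 1])),
                                float(np.mean(y[a:b + 1])),
                                float(t[a]), float(dur), trial_index))
    return out
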