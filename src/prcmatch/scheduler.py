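"""Trial schedules and abstract stimulus records for the matching paradigm.

The paradigm is a same-different visual matching task: on each trial two
trial-unique stimuli appear side by side and the observer reports "same" or
"different".  Object stimuli are defined by a triple of features (inner
shape, outer shape, fill); size-control stimuli are rotated squares.  Four
basic conditions exist:

* ``high_ambiguity`` — nonmatch pairs differ in exactly one feature
  (ABC vs ABD), so only the feature conjunction disambiguates reliably;
* ``low_ambiguity`` — nonmatch pairs share no feature (ABC vs DEF);
* ``difficult_size`` / ``easy_size`` — squares whose side lengths differ by
  9–15 px or 16–40 px respectively, a difficulty control;
* ``filler_everyday`` — easily discriminable filler objects drawn from a
  feature namespace disjoint from the ambiguity conditions.

Schedules for four experiment designs are generated:

* ``exp1`` / ``exp3`` — 72 consecutive trials per condition (36 match,
  36 nonmatch);
* ``exp4`` — a High Interference block of 88 consecutive high-ambiguity
  trials (44/44) and a Low Interference block of 88 trials in a repeating
  [comparison, filler, filler] pattern: 30 high-ambiguity comparison trials
  (15/15) interleaved with 58 fillers (29/29).  In both blocks performance
  is scored on every third trial only (the 30 comparison trials), so the
  blocks differ in accumulated feature interference, not in what is scored;
* ``fmri`` — 108 trials per condition (72 nonmatch, 36 match) arranged in
  36 miniblocks of 3 with at least one nonmatch trial each, evenly split
  over 4 scanning sessions.

Stimuli are abstract parameter records, not rendered images: integer shape
ids stand in for trial-unique outlines.  Each shape id maps (via
:mod:`prcmatch.simulate`) to a small set of "segment" ids drawn from a
shared pool, modelling the fact that whole shapes are trial-unique while
their local segments repeat across trials.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from .errors import ConfigurationError, ContractError, PoolDepletionError

# ---------------------------------------------------------------------------
# condition / experiment vocabulary

HIGH_AMBIGUITY = "high_ambiguity"
LOW_AMBIGUITY = "low_ambiguity"
DIFFICULT_SIZE = "difficult_size"
EASY_SIZE = "easy_size"
FILLER = "filler_everyday"

OBJECT_CONDITIONS = (HIGH_AMBIGUITY, LOW_AMBIGUITY, FILLER)
SIZE_CONDITIONS = (DIFFICULT_SIZE, EASY_SIZE)
BASE_CONDITIONS = (HIGH_AMBIGUITY, LOW_AMBIGUITY, DIFFICULT_SIZE, EASY_SIZE)

EXPERIMENT_CONDITIONS = {
    "exp1": BASE_CONDITIONS,
    "exp3": BASE_CONDITIONS,
    "exp4": ("high_interference", "low_interference"),
    "fmri": BASE_CONDITIONS,
}

FEATURE_NAMES = ("inner", "outer", "fill")

N_FILLS = 8  # distinct fill patterns per experiment
FILLER_SHAPE_OFFSET = 1_000_000  # filler shapes live in a disjoint id range
FILLER_FILL_OFFSET = 100  # filler fills likewise

ROTATION_RANGE = (15.0, 165.0)

# Size-control parameters (pixels).
DIFFICULT_SIDE_RANGE = (67, 247)
DIFFICULT_DELTA_RANGE = (9, 15)
EASY_SIDE_RANGE = (40, 268)
EASY_DELTA_RANGE = (16, 40)
JITTER_MAX_PX = 10

# Timing metadata recorded with each schedule (display timing is metadata
# only; this package does not render stimuli or collect responses).
_TIMING = {
    "exp1": {"response_deadline_ms": 15_000},
    "exp3": {"response_deadline_ms": 15_000},
    "exp4": {"response_deadline_ms": 15_000},
    "fmri": {"trial_duration_s": 5.75, "stimulus_s": 5.5, "isi_s": 0.25,
             "response_deadline_ms": 5_500},
}


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class ObjectStimulusSpec:
    """One abstract object: a (inner shape, outer shape, fill) triple."""

    inner_shape_id: int
    outer_shape_id: int
    fill_id: int
    rotation_deg: float
    frame_side: str  # {left,right}

    @property
    def features(self) -> tuple[int, int, int]:
        return (self.inner_shape_id, self.outer_shape_id, self.fill_id)


@dataclass(frozen=True)
class SizeStimulusSpec:
    """One rotated square of the size-control condition."""

    side_px: int
    rotation_deg: float
    jitter_x: int
    jitter_y: int
    frame_side: str


StimulusSpec = Union[ObjectStimulusSpec, SizeStimulusSpec]


@dataclass
class TrialSpec:
    """One same-different discrimination trial."""

    trial_index: int  # 1-based position within the condition block
    condition: str
    is_match: bool
    stimuli: tuple[StimulusSpec, StimulusSpec]
    differing_feature: str  # {fill, inner, outer, all, none}
    is_comparison: bool = False
    miniblock: int | None = None  # fmri only
    session: int | None = None  # fmri only


@dataclass
class ConditionSchedule:
    """An ordered block of trials for one experiment condition."""

    experiment: str
    condition_label: str
    trials: list[TrialSpec]
    seed: int
    counterbalance_record: dict[str, int] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.trials)


# ---------------------------------------------------------------------------
# feature pools

@dataclass
class FeaturePools:
    """Trial-unique shape-id allocator with a disjoint filler namespace.

    Inner and outer shapes draw from a single incrementing counter, so no
    shape id is ever reused across trials of an experiment.  Filler shapes
    use a separate counter offset by ``FILLER_SHAPE_OFFSET``.
    """

    capacity: int = 100_000
    n_fills: int = N_FILLS
    _next_shape: int = 0
    _next_filler_shape: int = FILLER_SHAPE_OFFSET

    def take_shape(self) -> int:
        if self._next_shape >= self.capacity:
            raise PoolDepletionError(
                f"shape pool exhausted (capacity {self.capacity})")
        out = self._next_shape
        self._next_shape += 1
        return out

    def take_filler_shape(self) -> int:
        if self._next_filler_shape >= FILLER_SHAPE_OFFSET + self.capacity:
            raise PoolDepletionError(
                f"filler shape pool exhausted (capacity {self.capacity})")
        out = self._next_filler_shape
        self._next_filler_shape += 1
        return out


# ---------------------------------------------------------------------------
# trial generators

def _rotation(rng: np.random.Generator) -> float:
    return float(rng.uniform(*ROTATION_RANGE))


def _frames(rng: np.random.Generator) -> tuple[str, str]:
    if rng.integers(2):
        return ("left", "right")
    return ("right", "left")


def generate_object_trial(
    condition: str,
    is_match: bool,
    feature_pools: FeaturePools,
    rng: np.random.Generator,
    *,
    differing_feature: str | None = None,
    trial_index: int = 0,
) -> TrialSpec:
    """Generate one object trial with trial-unique shape ids.

    For a ``high_ambiguity`` nonmatch exactly one feature differs between
    the two stimuli (Hamming distance 1 on the feature triple); for a
    ``low_ambiguity`` or filler nonmatch all three differ (distance 3);
    matches share the full triple (distance 0, rotations still drawn
    independently per object).
    """
    if condition not in OBJECT_CONDITIONS:
        raise ConfigurationError(f"not an object condition: {condition!r}")

    filler = condition == FILLER
    take = (feature_pools.take_filler_shape if filler
            else feature_pools.take_shape)
    fill_offset = FILLER_FILL_OFFSET if filler else 0
    n_fills = feature_pools.n_fills

    f1, f2 = _frames(rng)

    if is_match:
        inner = take()
        outer = take()
        fill = int(rng.integers(n_fills)) + fill_offset
        triple_a = triple_b = (inner, outer, fill)
        diff = "none"
    elif condition == HIGH_AMBIGUITY:
        diff = differing_feature or str(rng.choice(FEATURE_NAMES))
        if diff not in FEATURE_NAMES:
            raise ConfigurationError(f"bad differing_feature: {diff!r}")
        inner_a = inner_b = take()
        outer_a = outer_b = take()
        fill_a = fill_b = int(rng.integers(n_fills))
        if diff == "inner":
            inner_b = take()
        elif diff == "outer":
            outer_b = take()
        else:  # fill
            fill_a, fill_b = (int(v) for v in
                              rng.choice(n_fills, size=2, replace=False))
        triple_a = (inner_a, outer_a, fill_a)
        triple_b = (inner_b, outer_b, fill_b)
    else:  # low ambiguity or filler nonmatch: no feature overlaps
        fills = rng.choice(n_fills, size=2, replace=False)
        triple_a = (take(), take(), int(fills[0]) + fill_offset)
        triple_b = (take(), take(), int(fills[1]) + fill_offset)
        diff = "all"

    s1 = ObjectStimulusSpec(*triple_a, rotation_deg=_rotation(rng), frame_side=f1)
    s2 = ObjectStimulusSpec(*triple_b, rotation_deg=_rotation(rng), frame_side=f2)
    return TrialSpec(trial_index, condition, is_match, (s1, s2), diff)


def generate_size_trial(
    difficulty: str,
    is_match: bool,
    rng: np.random.Generator,
    *,
    trial_index: int = 0,
) -> TrialSpec:
    """Generate one size-control trial (two rotated squares).

    Difficult nonmatch: sides in [67, 247] px with |Δ| in [9, 15];
    easy nonmatch: sides in [40, 268] px with |Δ| in [16, 40].  Positions
    are jittered so the square edges never align across the two frames.
    """
    if difficulty in SIZE_CONDITIONS:
        condition = difficulty
        difficulty = "difficult" if difficulty == DIFFICULT_SIZE else "easy"
    elif difficulty in ("difficult", "easy"):
        condition = DIFFICULT_SIZE if difficulty == "difficult" else EASY_SIZE
    else:
        raise ConfigurationError(f"unknown size difficulty: {difficulty!r}")

    lo, hi = DIFFICULT_SIDE_RANGE if difficulty == "difficult" else EASY_SIDE_RANGE
    dlo, dhi = (DIFFICULT_DELTA_RANGE if difficulty == "difficult"
                else EASY_DELTA_RANGE)

    if is_match:
        side_a = side_b = int(rng.integers(lo, hi + 1))
        diff = "none"
    else:
        delta = int(rng.integers(dlo, dhi + 1))
        side_a = int(rng.integers(lo, hi - delta + 1))
        side_b = side_a + delta
        if rng.integers(2):
            side_a, side_b = side_b, side_a
        diff = "all"

    # jitter each square; redraw until offsets differ on both axes so that
    # edges cannot line up horizontally or vertically
    while True:
        jx = rng.integers(-JITTER_MAX_PX, JITTER_MAX_PX + 1, size=2)
        jy = rng.integers(-JITTER_MAX_PX, JITTER_MAX_PX + 1, size=2)
        if jx[0] != jx[1] and jy[0] != jy[1]:
            break

    f1, f2 = _frames(rng)
    s1 = SizeStimulusSpec(side_a, _rotation(rng), int(jx[0]), int(jy[0]), f1)
    s2 = SizeStimulusSpec(side_b, _rotation(rng), int(jx[1]), int(jy[1]), f2)
    return TrialSpec(trial_index, condition, is_match, (s1, s2), diff)


# ---------------------------------------------------------------------------
# schedule construction helpers

def _balanced_features(n: int, rng: np.random.Generator) -> list[str]:
    """Balanced differing-feature assignment for n high-ambiguity nonmatches.

    Counts differ pairwise by at most 1 (exactly n/3 each when 3 | n); the
    remainder features and the final order are randomized.
    """
    order = [str(f) for f in rng.permutation(FEATURE_NAMES)]
    base, rem = divmod(n, 3)
    counts = {f: base + (1 if i < rem else 0) for i, f in enumerate(order)}
    out = [f for f in order for _ in range(counts[f])]
    rng.shuffle(out)
    return out


def _match_flags(n_match: int, n_nonmatch: int,
                 rng: np.random.Generator) -> list[bool]:
    flags = [True] * n_match + [False] * n_nonmatch
    rng.shuffle(flags)
    return flags


def _make_trial(condition: str, is_match: bool, pools: FeaturePools,
                rng: np.random.Generator, diff_iter, idx: int) -> TrialSpec:
    if condition in SIZE_CONDITIONS:
        return generate_size_trial(condition, is_match, rng, trial_index=idx)
    diff = None
    if condition == HIGH_AMBIGUITY and not is_match:
        diff = next(diff_iter)
    return generate_object_trial(condition, is_match, pools, rng,
                                 differing_feature=diff, trial_index=idx)


def _block(condition: str, n_match: int, n_nonmatch: int,
           pools: FeaturePools, rng: np.random.Generator,
           start_index: int = 1) -> list[TrialSpec]:
    flags = _match_flags(n_match, n_nonmatch, rng)
    n_ha_nonmatch = (n_nonmatch if condition == HIGH_AMBIGUITY else 0)
    diff_iter = iter(_balanced_features(n_ha_nonmatch, rng))
    return [
        _make_trial(condition, m, pools, rng, diff_iter, start_index + i)
        for i, m in enumerate(flags)
    ]


def every_third_indices(n_trials: int) -> list[int]:
    """1-based positions 1, 4, 7, ... within an n-trial block."""
    return list(range(1, n_trials + 1, 3))


def _exp4_high(pools, rng) -> list[TrialSpec]:
    trials = _block(HIGH_AMBIGUITY, 44, 44, pools, rng)
    for i in every_third_indices(88):
        trials[i - 1].is_comparison = True
    return trials


def _exp4_low(pools, rng) -> list[TrialSpec]:
    comp_positions = set(every_third_indices(88))
    comp_flags = iter(_match_flags(15, 15, rng))
    fill_flags = iter(_match_flags(29, 29, rng))
    diff_iter = iter(_balanced_features(15, rng))
    trials = []
    for idx in range(1, 89):
        if idx in comp_positions:
            t = _make_trial(HIGH_AMBIGUITY, next(comp_flags), pools, rng,
                            diff_iter, idx)
            t.is_comparison = True
        else:
            t = _make_trial(FILLER, next(fill_flags), pools, rng, None, idx)
        trials.append(t)
    return trials


def _fmri(condition: str, pools, rng) -> list[TrialSpec]:
    # 36 miniblocks of 3; nonmatch count per miniblock in {1,2,3}, at least
    # one nonmatch each, totalling 72 nonmatch + 36 match.  Seeded random
    # ordering; contrast-efficiency optimization of miniblock order is out
    # of scope.
    m = int(rng.integers(0, 19))  # blocks with 3 nonmatch (= blocks with 1)
    nonmatch_counts = [3] * m + [1] * m + [2] * (36 - 2 * m)
    rng.shuffle(nonmatch_counts)
    n_ha_nonmatch = 72 if condition == HIGH_AMBIGUITY else 0
    diff_iter = iter(_balanced_features(n_ha_nonmatch, rng))
    trials = []
    idx = 1
    for mb, c in enumerate(nonmatch_counts, start=1):
        flags = [False] * c + [True] * (3 - c)
        rng.shuffle(flags)
        for is_match in flags:
            t = _make_trial(condition, is_match, pools, rng, diff_iter, idx)
            t.miniblock = mb
            t.session = (mb - 1) // 9 + 1
            trials.append(t)
            idx += 1
    return trials


def build_condition_schedule(
    experiment: str,
    condition_label: str,
    seed: int,
    feature_pools: FeaturePools | None = None,
) -> ConditionSchedule:
    """Build the full trial schedule for one experiment condition.

    Pass a shared :class:`FeaturePools` to keep shape ids trial-unique
    across several conditions of the same experiment (as
    :func:`build_experiment_schedules` does).
    """
    if experiment not in EXPERIMENT_CONDITIONS:
        raise ConfigurationError(f"unknown experiment: {experiment!r}")
    if condition_label not in EXPERIMENT_CONDITIONS[experiment]:
        raise ConfigurationError(
            f"unknown condition {condition_label!r} for {experiment!r}")

    rng = np.random.default_rng(seed)
    pools = feature_pools if feature_pools is not None else FeaturePools()

    if experiment in ("exp1", "exp3"):
        trials = _block(condition_label, 36, 36, pools, rng)
    elif experiment == "fmri":
        trials = _fmri(condition_label, pools, rng)
    elif condition_label == "high_interference":
        trials = _exp4_high(pools, rng)
    else:
        trials = _exp4_low(pools, rng)

    sched = ConditionSchedule(
        experiment=experiment,
        condition_label=condition_label,
        trials=trials,
        seed=seed,
        metadata=dict(_TIMING[experiment]),
    )
    sched.counterbalance_record = counterbalance_report(sched)
    return sched


def build_experiment_schedules(
    experiment: str, seed: int,
    conditions: Sequence[str] | None = None,
) -> dict[str, ConditionSchedule]:
    """Build all condition blocks of an experiment with one shared pool.

    Each condition gets a distinct child seed derived from ``seed``; shape
    ids remain unique across the whole experiment.
    """
    conditions = tuple(conditions or EXPERIMENT_CONDITIONS[experiment])
    pools = FeaturePools()
    out = {}
    for i, label in enumerate(conditions):
        child_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0]
                         % (2 ** 31))
        out[label] = build_condition_schedule(experiment, label, child_seed,
                                              feature_pools=pools)
    return out


# ---------------------------------------------------------------------------
# schedule queries

def comparison_trial_indices(schedule: ConditionSchedule) -> list[int]:
    """1-based indices of the scored every-third trials of an exp4 block."""
    if schedule.experiment != "exp4":
        raise ContractError(
            f"comparison trials are defined for exp4 schedules, "
            f"got {schedule.experiment!r}")
    return every_third_indices(len(schedule.trials))


def counterbalance_report(
    schedule: ConditionSchedule | Iterable[TrialSpec],
) -> dict[str, int]:
    """Counts of the differing feature over high-ambiguity nonmatch trials."""
    trials = schedule.trials if isinstance(schedule, ConditionSchedule) else schedule
    counts = Counter(
        t.differing_feature for t in trials
        if t.condition == HIGH_AMBIGUITY and not t.is_match
    )
    return {f: counts.get(f, 0) for f in FEATURE_NAMES}


def unique_shape_ids(schedules: Iterable[ConditionSchedule]) -> bool:
    """True iff no inner/outer shape id is shared between two trials."""
    seen: set[int] = set()
    for sched in schedules:
        for t in sched.trials:
            ids = set()
            for s in t.stimuli:
                if isinstance(s, ObjectStimulusSpec):
                    ids.update((s.inner_shape_id, s.outer_shape_id))
            if ids & seen:
                return False
            seen |= ids
    return True


# ---------------------------------------------------------------------------
# serialization

_CSV_COLUMNS = [
    "trial_index", "condition", "is_match", "is_comparison",
    "differing_feature", "miniblock", "session",
]
_STIM_COLUMNS = ["frame", "rotation_deg", "inner", "outer", "fill",
                 "side_px", "jitter_x", "jitter_y"]


def _stim_row(s: StimulusSpec) -> dict:
    if isinstance(s, ObjectStimulusSpec):
        return {"frame": s.frame_side, "rotation_deg": repr(s.rotation_deg),
                "inner": s.inner_shape_id, "outer": s.outer_shape_id,
                "fill": s.fill_id, "side_px": "", "jitter_x": "", "jitter_y": ""}
    return {"frame": s.frame_side, "rotation_deg": repr(s.rotation_deg),
            "inner": "", "outer": "", "fill": "",
            "side_px": s.side_px, "jitter_x": s.jitter_x, "jitter_y": s.jitter_y}


def _stim_from_row(row: dict, prefix: str) -> StimulusSpec:
    g = lambda k: row[f"{prefix}_{k}"]
    if g("inner") != "":
        return ObjectStimulusSpec(int(g("inner")), int(g("outer")),
                                  int(g("fill")), float(g("rotation_deg")),
                                  g("frame"))
    return SizeStimulusSpec(int(g("side_px")), float(g("rotation_deg")),
                            int(g("jitter_x")), int(g("jitter_y")), g("frame"))


def write_schedule_csv(schedule: ConditionSchedule, path: str | Path) -> None:
    """Write one row per trial; a leading comment line keeps block metadata."""
    path = Path(path)
    cols = (_CSV_COLUMNS
            + [f"s1_{c}" for c in _STIM_COLUMNS]
            + [f"s2_{c}" for c in _STIM_COLUMNS])
    with open(path, "w", newline="") as fh:
        fh.write(f"# experiment={schedule.experiment} "
                 f"condition={schedule.condition_label} "
                 f"seed={schedule.seed}\n")
        w = csv.DictWriter(fh, fieldnames=cols)
        w.writeheader()
        for t in schedule.trials:
            row = {
                "trial_index": t.trial_index, "condition": t.condition,
                "is_match": int(t.is_match),
                "is_comparison": int(t.is_comparison),
                "differing_feature": t.differing_feature,
                "miniblock": "" if t.miniblock is None else t.miniblock,
                "session": "" if t.session is None else t.session,
            }
            row.update({f"s1_{k}": v for k, v in _stim_row(t.stimuli[0]).items()})
            row.update({f"s2_{k}": v for k, v in _stim_row(t.stimuli[1]).items()})
            w.writerow(row)


def read_schedule_csv(path: str | Path) -> ConditionSchedule:
    path = Path(path)
    with open(path, newline="") as fh:
        first = fh.readline().strip()
        meta = {}
        if first.startswith("#"):
            meta = dict(kv.split("=") for kv in first[1:].split())
        else:
            fh.seek(0)
        trials = []
        for row in csv.DictReader(fh):
            trials.append(TrialSpec(
                trial_index=int(row["trial_index"]),
                condition=row["condition"],
                is_match=bool(int(row["is_match"])),
                stimuli=(_stim_from_row(row, "s1"), _stim_from_row(row, "s2")),
                differing_feature=row["differing_feature"],
                is_comparison=bool(int(row["is_comparison"])),
                miniblock=int(row["miniblock"]) if row["miniblock"] else None,
                session=int(row["session"]) if row["session"] else None,
            ))
    experiment = meta.get("experiment", "")
    sched = ConditionSchedule(
        experiment=experiment,
        condition_label=meta.get("condition", ""),
        trials=trials,
        seed=int(meta.get("seed", -1)),
        metadata=dict(_TIMING.get(experiment, {})),
    )
    sched.counterbalance_record = counterbalance_report(sched)
    return sched


def schedule_to_dict(schedule: ConditionSchedule) -> dict:
    d = asdict(schedule)
    for trow, trial in zip(d["trials"], schedule.trials):
        trow["stimuli"] = [
            dict(kind=("object" if isinstance(s, ObjectStimulusSpec) else "size"),
                 **asdict(s))
            for s in trial.stimuli
        ]
    return d


def schedule_from_dict(d: dict) -> ConditionSchedule:
    trials = []
    for trow in d["trials"]:
        stims = []
        for srow in trow["stimuli"]:
            srow = dict(srow)
            kind = srow.pop("kind")
            cls = ObjectStimulusSpec if kind == "object" else SizeStimulusSpec
            stims.append(cls(**srow))
        trow = dict(trow)
        trow["stimuli"] = tuple(stims)
        trials.append(TrialSpec(**trow))
    return ConditionSchedule(
        experiment=d["experiment"], condition_label=d["condition_label"],
        trials=trials, seed=d["seed"],
        counterbalance_record=dict(d.get("counterbalance_record", {})),
        metadata=dict(d.get("metadata", {})),
    )


def write_schedule_json(schedule: ConditionSchedule, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(schedule_to_dict(schedule), indent=1, sort_keys=True))


def read_schedule_json(path: str | Path) -> ConditionSchedule:
    return schedule_from_dict(json.loads(Path(path).read_text()))
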