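"""Synthetic observers and gaze sequences with known ground truth.

The observer model implements a representational-hierarchical account of
feature interference in two evidence layers:

* **Feature channels** (inner shape, outer shape, fill) correspond to
  posterior visual regions that represent single features.  Because whole
  shapes are trial-unique while their local *segments* repeat across
  trials, every processed stimulus deposits activation ("trace") on the
  segments it contains.  Posterior feature representations have a finite
  capacity: comparison noise is unaffected while the accumulated load
  stays below a capacity threshold theta, and grows linearly with the
  excess once the capacity is exceeded,

      sd_c = sigma_f * (1 + lambda * max(0, load_c - theta)).

  Traces decay by a factor rho per trial, so consecutive blocks of
  perceptually similar stimuli push the load past capacity over tens of
  trials, while interleaving dissimilar filler stimuli (which live in a
  disjoint segment namespace) keeps the relevant load below threshold.
* **A conjunction channel** corresponds to perirhinal object-level
  representations: because conjunctions are unique per object, its noise
  is *independent* of the accumulated feature trace.  Observers with
  ``conjunctive_available=False`` (perirhinal lesion) lack this channel
  and must rely on the interference-prone feature channels alone.

Per trial the observer combines absolute noisy difference signals across
its channels by reliability (inverse-variance) weighting — the standard
optimal-cue-combination rule — and responds "different" when the combined
evidence exceeds a criterion.  Reliability weighting means an intact
observer automatically leans on the conjunction channel once feature
channels degrade, whereas a lesioned observer has only degraded channels
to re-weight.  With default parameters the lesioned observer starts
a consecutive high-ambiguity block near normal and deteriorates as trace
load accumulates, while the intact observer stays flat — and the lesioned
observer is rescued when the same comparison trials are interleaved with
dissimilar fillers.  The functional form (linear noise scaling, exponential
decay, equal channel weights) is this package's construction; ground-truth
parameters make the generator usable for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ContractError
from .gaze import FIXATION_COLUMNS, DEFAULT_GEOMETRY, FramesGeometry
from .scheduler import (ConditionSchedule, ObjectStimulusSpec,
                        SizeStimulusSpec, TrialSpec,
                        DIFFICULT_SIZE, EASY_SIZE)
from .sdt import ResponseRecord

# Segment vocabulary: regular object shapes draw 4 of 16 shared segments,
# filler shapes draw from a disjoint pool of 16 (ids 16..31).
SEGMENT_POOL = 16
SEGMENTS_PER_SHAPE = 4
FILLER_SEGMENT_OFFSET = 16
_FILLER_SHAPE_MIN = 1_000_000
_FILL_SLOTS = 256  # fill-id trace table size (regular 0..7, filler 100..107)
# Deposit per presented fill: chosen so the expected trace load of the fill
# channel (8 identity slots, 2 draws/trial) grows at the same rate as the
# shape channels (16 segments, 2 x 4 draws/trial), keeping the three
# feature channels exchangeable in the interference dynamics.
_FILL_DEPOSIT = 2.0
_FILL_NS_SIZE = 8  # fills per namespace (regular: ids 0..7, filler: 100..107)


def _fill_namespace(fill_id: int) -> slice:
    base = (fill_id // 100) * 100
    return slice(base, base + _FILL_NS_SIZE)


def segment_set(shape_id: int) -> np.ndarray:
    """Deterministic segment ids composing one shape.

    Regular shapes sample from the shared pool 0..15; filler shapes (ids
    offset by the scheduler's filler namespace) sample from 16..31, so
    filler trials never load the segments that object trials re-use.
    """
    filler = shape_id >= _FILLER_SHAPE_MIN
    rng = np.random.default_rng(shape_id)
    segs = rng.choice(SEGMENT_POOL, size=SEGMENTS_PER_SHAPE, replace=False)
    return segs + (FILLER_SEGMENT_OFFSET if filler else 0)


def _folded_mean(mu: float, sd: float) -> float:
    """E|mu + e| for e ~ N(0, sd^2) (folded-normal mean)."""
    from scipy import stats as _st
    return float(sd * np.sqrt(2.0 / np.pi) * np.exp(-mu ** 2 / (2 * sd ** 2))
                 + mu * (1.0 - 2.0 * _st.norm.cdf(-mu / sd)))


def _baseline_criterion(params: "ObserverParams") -> float:
    """Midpoint of expected match vs one-feature-nonmatch evidence at load 0."""
    sf, sc = params.feature_noise_sd, params.conj_noise_sd
    w_f = 1.0 / sf ** 2
    weights = [w_f] * 3
    match_terms = [w_f * _folded_mean(0.0, sf)] * 3
    nonmatch_terms = [w_f * _folded_mean(1.0, sf),
                      w_f * _folded_mean(0.0, sf),
                      w_f * _folded_mean(0.0, sf)]
    if params.conjunctive_available:
        w_c = params.conj_weight / sc ** 2
        weights.append(w_c)
        match_terms.append(w_c * _folded_mean(0.0, sc))
        nonmatch_terms.append(w_c * _folded_mean(1.0, sc))
    total_w = sum(weights)
    return 0.5 * (sum(match_terms) + sum(nonmatch_terms)) / total_w


@dataclass
class ObserverParams:
    """Generative parameters of one simulated observer.

    feature_noise_sd
        Baseline comparison noise sigma_f of each feature channel, in units
        of the feature-difference signal (a differing feature has signal 1).
    conjunctive_available
        Whether the conjunction channel (intact perirhinal representation)
        contributes evidence.
    interference_gain
        lambda: how strongly the above-capacity trace load multiplies
        feature noise.
    trace_decay
        rho in [0, 1]: per-trial retention of the feature trace.
    capacity_threshold
        theta: trace load a feature channel absorbs without cost; only the
        excess above theta adds comparison noise.
    criterion_c
        Response threshold on the reliability-weighted evidence for object
        trials (``criterion_size`` for the size control, whose evidence is
        a single normalized side-difference channel).  ``None`` (default)
        self-calibrates to the midpoint between the observer's expected
        match and nonmatch evidence at zero trace load — what a practice
        block with feedback would establish — so intact and lesioned
        observers each get a criterion matched to their own evidence scale.
    conj_weight
        Multiplier on the conjunction channel's reliability weight
        (channel weights are 1/sd^2; the conjunction channel gets
        conj_weight/conj_noise_sd^2).
    conj_noise_sd
        Noise of the conjunction channel; independent of trace load.
    criterion_adapt_rate
        Per-trial rate at which the criterion drifts toward the running
        mean of observed evidence.  Observers know the 50/50 match base
        rate, so they recalibrate as their evidence distribution shifts;
        recalibration is kept per stimulus class (condition), since the
        classes are visually distinct.  0 freezes the criterion at its
        baseline value.
    """

    feature_noise_sd: float = 0.3
    conjunctive_available: bool = True
    interference_gain: float = 2.0
    trace_decay: float = 0.975
    capacity_threshold: float = 10.0
    criterion_c: float | None = None
    criterion_size: float | None = None
    conj_weight: float = 8.0
    conj_noise_sd: float = 0.45
    criterion_adapt_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_noise_sd <= 0:
            raise ConfigurationError("feature_noise_sd must be > 0")
        if self.interference_gain < 0:
            raise ConfigurationError("interference_gain must be >= 0")
        if not 0.0 <= self.trace_decay <= 1.0:
            raise ConfigurationError("trace_decay must lie in [0, 1]")
        if self.criterion_c is None:
            self.criterion_c = _baseline_criterion(self)
        if self.criterion_size is None:
            self.criterion_size = 0.5 * (
                _folded_mean(0.0, self.feature_noise_sd)
                + _folded_mean(1.0, self.feature_noise_sd))

    @classmethod
    def intact(cls, seed: int = 0, **kw) -> "ObserverParams":
        """Control observer: conjunction channel available."""
        return cls(conjunctive_available=True, seed=seed, **kw)

    @classmethod
    def lesioned(cls, seed: int = 0, **kw) -> "ObserverParams":
        """Perirhinal-lesion observer: feature channels only."""
        return cls(conjunctive_available=False, seed=seed, **kw)


@dataclass
class InterferenceState:
    """Accumulated feature-trace activation, decayed once per trial."""

    inner_trace: np.ndarray = field(
        default_factory=lambda: np.zeros(2 * SEGMENT_POOL))
    outer_trace: np.ndarray = field(
        default_factory=lambda: np.zeros(2 * SEGMENT_POOL))
    fill_trace: np.ndarray = field(default_factory=lambda: np.zeros(_FILL_SLOTS))
    trial_counter: int = 0

    def loads(self, trial: TrialSpec) -> dict[str, float]:
        """Similarity of the current trial's features to the stored trace.

        Shape loads average the trace over the segments of the presented
        shapes; the fill load averages over the presented fill's whole
        namespace, because the small fill vocabulary repeats exactly across
        trials so interference accrues on the pool, not on one instance.
        """
        s1, s2 = trial.stimuli
        inner = np.mean([self.inner_trace[segment_set(s.inner_shape_id)].mean()
                         for s in (s1, s2)])
        outer = np.mean([self.outer_trace[segment_set(s.outer_shape_id)].mean()
                         for s in (s1, s2)])
        fill = np.mean([self.fill_trace[_fill_namespace(s.fill_id)].mean()
                        for s in (s1, s2)])
        return {"inner": float(inner), "outer": float(outer),
                "fill": float(fill)}

    def update(self, trial: TrialSpec, rho: float) -> None:
        """Deposit the presented features, then decay every trace by rho."""
        for s in trial.stimuli:
            self.inner_trace[segment_set(s.inner_shape_id)] += 1.0
            self.outer_trace[segment_set(s.outer_shape_id)] += 1.0
            self.fill_trace[s.fill_id % _FILL_SLOTS] += _FILL_DEPOSIT
        self.inner_trace *= rho
        self.outer_trace *= rho
        self.fill_trace *= rho
        self.trial_counter += 1


# ---------------------------------------------------------------------------
# observer simulation

def _object_evidence(trial: TrialSpec, params: ObserverParams,
                     state: InterferenceState,
                     rng: np.random.Generator) -> float:
    s1, s2 = trial.stimuli
    loads = state.loads(trial)
    deltas = {
        "inner": float(s1.inner_shape_id != s2.inner_shape_id),
        "outer": float(s1.outer_shape_id != s2.outer_shape_id),
        "fill": float(s1.fill_id != s2.fill_id),
    }
    evidence = 0.0
    weight = 0.0
    for ch, delta in deltas.items():
        excess = max(0.0, loads[ch] - params.capacity_threshold)
        sd = params.feature_noise_sd * (
            1.0 + params.interference_gain * excess)
        w = 1.0 / sd ** 2  # reliability weight
        evidence += w * abs(delta + rng.normal(0.0, sd))
        weight += w
    if params.conjunctive_available:
        delta_conj = float(any(d > 0 for d in deltas.values()))
        w = params.conj_weight / params.conj_noise_sd ** 2
        evidence += w * abs(
            delta_conj + rng.normal(0.0, params.conj_noise_sd))
        weight += w
    return evidence / weight


# Normalizer for the size channel: mid-range difficult |delta| maps to ~1.
_SIZE_DELTA_SCALE = 16.0


def _size_evidence(trial: TrialSpec, params: ObserverParams,
                   rng: np.random.Generator) -> float:
    s1, s2 = trial.stimuli
    delta = abs(s1.side_px - s2.side_px) / _SIZE_DELTA_SCALE
    return abs(delta + rng.normal(0.0, params.feature_noise_sd))


def _draw_rt(evidence: float, criterion: float, deadline_ms: float,
             rng: np.random.Generator) -> float:
    # Decorative latency model: lognormal whose location rises as the
    # evidence approaches the criterion (more ambiguous -> slower).
    ambiguity = np.exp(-abs(evidence - criterion) / 0.25)
    mu = np.log(900.0) + 0.9 * ambiguity
    rt = float(rng.lognormal(mean=mu, sigma=0.35))
    return min(rt, deadline_ms)


def simulate_observer_run(
    schedule: ConditionSchedule,
    params: ObserverParams,
) -> list[ResponseRecord]:
    """Simulate one observer working through one condition block.

    Deterministic given ``params.seed``.  Feature-trace interference
    accumulates over object trials exactly in schedule order; size trials
    engage a single size channel and neither read nor write the trace.
    """
    rng = np.random.default_rng(params.seed)
    state = InterferenceState()
    deadline = float(schedule.metadata.get("response_deadline_ms", 15_000))
    criteria: dict[str, float] = {}
    alpha = params.criterion_adapt_rate
    out = []
    for trial in schedule.trials:
        if isinstance(trial.stimuli[0], SizeStimulusSpec):
            if trial.condition not in (DIFFICULT_SIZE, EASY_SIZE):
                raise ContractError(
                    f"size stimuli under condition {trial.condition!r}")
            evidence = _size_evidence(trial, params, rng)
            criterion = criteria.setdefault(trial.condition,
                                            float(params.criterion_size))
        elif isinstance(trial.stimuli[0], ObjectStimulusSpec):
            evidence = _object_evidence(trial, params, state, rng)
            criterion = criteria.setdefault(trial.condition,
                                            float(params.criterion_c))
            state.update(trial, params.trace_decay)
        else:  # pragma: no cover - schedule construction prevents this
            raise ContractError("unknown stimulus type in schedule")
        criteria[trial.condition] += alpha * (evidence - criterion)
        response = "different" if evidence > criterion else "same"
        rt = _draw_rt(evidence, criterion, deadline, rng)
        out.append(ResponseRecord.make(trial.trial_index, trial.condition,
                                       trial.is_match, response, rt))
    return out


# ---------------------------------------------------------------------------
# gaze simulation

@dataclass
class GazeSimParams:
    """Ground-truth parameters of the two-state gaze process.

    The eye stays on the current item with probability ``stay_prob`` at
    each fixation-to-fixation transition and switches otherwise, so the
    long-run expected (Within/Total)Av equals stay_prob.
    """

    stay_prob: float = 0.75
    fixations_per_trial: int = 12
    fixation_duration_ms: float = 250.0
    saccade_gap_ms: float = 30.0
    margin_px: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.stay_prob <= 1.0:
            raise ConfigurationError("stay_prob must lie in [0, 1]")
        if self.fixations_per_trial < 1:
            raise ConfigurationError("fixations_per_trial must be >= 1")


def simulate_gaze_run(
    schedule: ConditionSchedule | int,
    params: GazeSimParams,
    geometry: FramesGeometry = DEFAULT_GEOMETRY,
) -> pd.DataFrame:
    """Simulate fixation sequences for every trial of a block.

    ``schedule`` may be a ConditionSchedule or a plain trial count.
    Returns a fixation-event table with the columns consumed by
    :func:`prcmatch.gaze.analyze_gaze`.
    """
    n_trials = (len(schedule.trials)
                if isinstance(schedule, ConditionSchedule) else int(schedule))
    trial_indices = ([t.trial_index for t in schedule.trials]
                     if isinstance(schedule, ConditionSchedule)
                     else list(range(1, n_trials + 1)))
    rng = np.random.default_rng(params.seed)
    size = geometry.frame_size_px
    m = min(params.margin_px, size / 2 - 1)
    x_left = (geometry.origin_x + m, geometry.origin_x + size - m)
    x_right = (geometry.origin_x + size + geometry.gap_px + m,
               geometry.origin_x + 2 * size + geometry.gap_px - m)
    rows = []
    for trial in trial_indices:
        frame = int(rng.integers(2))
        t_ms = 0.0
        for _ in range(params.fixations_per_trial):
            lo, hi = x_right if frame else x_left
            x = float(rng.uniform(lo, hi))
            y = float(rng.uniform(geometry.origin_y + m,
                                  geometry.origin_y + size - m))
            dur = float(max(50.0, rng.normal(params.fixation_duration_ms, 40.0)))
            rows.append((trial, x, y, t_ms, dur))
            t_ms += dur + params.saccade_gap_ms
            if rng.random() > params.stay_prob:
                frame = 1 - frame
    return pd.DataFrame(rows, columns=FIXATION_COLUMNS)


# ---------------------------------------------------------------------------
# cohorts

def _child_seed(base: int, index: int) -> int:
    return int(np.random.SeedSequence([base, index]).generate_state(1)[0]
               % (2 ** 31))


def make_cohort(
    n_controls: int,
    patient_params: ObserverParams,
    control_params: ObserverParams,
    schedules: Mapping[str, ConditionSchedule],
    patient_id: str = "patient",
) -> dict[str, dict[str, list[ResponseRecord]]]:
    """Simulate one patient plus ``n_controls`` controls on shared schedules.

    Every participant receives an independent child seed derived from the
    corresponding params seed, and works through every schedule in
    ``schedules``.  Returns ``{participant_id: {label: responses}}`` ready
    for :mod:`prcmatch.singlecase`.
    """
    if n_controls < 2:
        raise ContractError(f"need at least 2 controls, got {n_controls}")
    logs: dict[str, dict[str, list[ResponseRecord]]] = {}
    participants = [(patient_id, patient_params, 0)] + [
        (f"control{i + 1:02d}", control_params, i + 1)
        for i in range(n_controls)
    ]
    for pid, params, idx in participants:
        plogs = {}
        for j, (label, sched) in enumerate(schedules.items()):
            run_params = replace(
                params, seed=_child_seed(params.seed, idx * 1000 + j))
            plogs[label] = simulate_observer_run(sched, run_params)
        logs[pid] = plogs
    return logs
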