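"""Same-different signal detection: corrected rates, d', split-half scoring.

A "different" response on a nonmatch trial is a hit; a "different" response
on a match trial is a false alarm.  Perfect raw rates (0 or 1) receive the
half-trial correction — half a trial is added to or subtracted from the
count — before d' is computed, since the model inversion is unbounded at
the extremes.

The default sensitivity model is the *differencing* model for
same-different designs: the observer responds "different" when the absolute
internal difference between the two stimuli exceeds a criterion k on the
difference axis.  Its forward equations are

    fa  = 2 * Phi(-k / sqrt(2))
    hit = Phi((d' - k) / sqrt(2)) + Phi((-d' - k) / sqrt(2))

and d' is obtained from a corrected (hit, fa) pair by solving the second
equation with bracketed root finding after inverting the first in closed
form.  The differencing model is the standard choice for roving designs
with trial-unique stimuli; an independence-observer model is provided as an
alternative.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ContractError
from .scheduler import ConditionSchedule, comparison_trial_indices

_SQRT2 = math.sqrt(2.0)


@dataclass
class ResponseRecord:
    """One logged response to a same-different trial."""

    trial_index: int
    condition: str
    is_match: bool
    response: str  # {same, different}
    rt_ms: float
    correct: bool

    @staticmethod
    def make(trial_index: int, condition: str, is_match: bool,
             response: str, rt_ms: float) -> "ResponseRecord":
        if response not in ("same", "different"):
            raise ContractError(f"bad response: {response!r}")
        correct = (response == "different") == (not is_match)
        return ResponseRecord(trial_index, condition, is_match, response,
                              rt_ms, correct)


@dataclass
class RatePair:
    """Hit / false-alarm counts and (possibly corrected) rates."""

    hits: int
    n_different: int
    fas: int
    n_same: int
    hit_rate: float
    fa_rate: float
    corrected: bool


@dataclass
class DPrimeResult:
    d_prime: float
    criterion_k: float
    model: str  # {differencing, independence}
    rate_pair: RatePair


# ---------------------------------------------------------------------------
# rates

def half_trial_rate(k: int, n: int) -> tuple[float, bool]:
    """k/n with half a trial added/subtracted at the 0 and n extremes."""
    if n <= 0:
        raise ContractError("rate needs at least one trial")
    if k == n:
        return (n - 0.5) / n, True
    if k == 0:
        return 0.5 / n, True
    return k / n, False


def corrected_rates(responses: Iterable[ResponseRecord]) -> RatePair:
    """Hit and false-alarm rates with the half-trial correction.

    Requires at least one match and one nonmatch trial.
    """
    responses = list(responses)
    hits = sum(1 for r in responses
               if not r.is_match and r.response == "different")
    n_diff = sum(1 for r in responses if not r.is_match)
    fas = sum(1 for r in responses
              if r.is_match and r.response == "different")
    n_same = sum(1 for r in responses if r.is_match)
    if n_diff == 0 or n_same == 0:
        raise ContractError(
            f"need both trial types: {n_diff} nonmatch, {n_same} match")
    hr, c1 = half_trial_rate(hits, n_diff)
    fr, c2 = half_trial_rate(fas, n_same)
    return RatePair(hits, n_diff, fas, n_same, hr, fr, c1 or c2)


# ---------------------------------------------------------------------------
# differencing model

def differencing_forward(d_prime: float, k: float) -> tuple[float, float]:
    """(hit, fa) predicted by the differencing model at (d', k)."""
    fa = 2.0 * stats.norm.cdf(-k / _SQRT2)
    hit = (stats.norm.cdf((d_prime - k) / _SQRT2)
           + stats.norm.cdf((-d_prime - k) / _SQRT2))
    return float(hit), float(fa)


def _invert_differencing(hit: float, fa: float) -> tuple[float, float]:
    # closed-form criterion from the false-alarm equation
    k = -_SQRT2 * stats.norm.ppf(fa / 2.0)

    def f(d: float) -> float:
        return (stats.norm.cdf((d - k) / _SQRT2)
                + stats.norm.cdf((-d - k) / _SQRT2)) - hit

    hi = 1.0
    while f(hi) < 0 and hi < 1e3:
        hi *= 2.0
    d = optimize.brentq(f, 0.0, hi, xtol=1e-9, rtol=8.9e-16)
    return float(d), float(k)


def independence_forward(d_prime: float, c: float) -> tuple[float, float]:
    """(hit, fa) for the independence observer with interval criterion c."""
    pc = stats.norm.cdf(c)
    pcd = stats.norm.cdf(c - d_prime)
    fa = 2.0 * pc * (1.0 - pc)
    hit = pc * (1.0 - pcd) + (1.0 - pc) * pcd
    return float(hit), float(fa)


def _invert_independence(hit: float, fa: float) -> tuple[float, float]:
    if fa > 0.5:
        raise ContractError(
            "independence model cannot produce fa > 0.5; use differencing")
    # fa = 2 Phi(c)(1 - Phi(c)); take the c >= 0 branch
    pc = 0.5 * (1.0 + math.sqrt(1.0 - 2.0 * fa))
    c = float(stats.norm.ppf(pc))
    if hit >= pc:
        raise ContractError(
            f"hit rate {hit} exceeds the independence-model ceiling {pc:.4f}")

    def f(d: float) -> float:
        return independence_forward(d, c)[0] - hit

    hi = 1.0
    while f(hi) < 0 and hi < 1e3:
        hi *= 2.0
    d = optimize.brentq(f, 0.0, hi, xtol=1e-9, rtol=8.9e-16)
    return float(d), c


def dprime_same_different(rates: RatePair, model: str = "differencing") -> DPrimeResult:
    """Invert the same-different model at a corrected (hit, fa) pair.

    d' = 0 exactly when hit = fa.  When hit < fa the roles are swapped and
    the result negated, so swapping the two rates negates d'.
    Rates of exactly 0 or 1 are rejected: apply the half-trial correction
    first (see :func:`corrected_rates`).
    """
    hit, fa = rates.hit_rate, rates.fa_rate
    for name, r in (("hit", hit), ("fa", fa)):
        if not (0.0 < r < 1.0):
            raise ContractError(
                f"{name} rate {r} outside (0,1); apply the half-trial "
                "correction before inverting")
    invert = {"differencing": _invert_differencing,
              "independence": _invert_independence}.get(model)
    if invert is None:
        raise ContractError(f"unknown model: {model!r}")
    if hit == fa:
        d = 0.0
        if model == "differencing":
            k = float(-_SQRT2 * stats.norm.ppf(fa / 2.0))
        else:
            if fa > 0.5:
                raise ContractError(
                    "independence model cannot produce fa > 0.5; "
                    "use differencing")
            k = float(stats.norm.ppf(0.5 * (1.0 + math.sqrt(1.0 - 2.0 * fa))))
    elif hit > fa:
        d, k = invert(hit, fa)
    else:
        d, k = invert(fa, hit)
        d = -d
    return DPrimeResult(d_prime=d, criterion_k=k, model=model, rate_pair=rates)


def dprime_from_responses(responses: Iterable[ResponseRecord],
                          model: str = "differencing") -> DPrimeResult:
    return dprime_same_different(corrected_rates(responses), model)


# ---------------------------------------------------------------------------
# schedule-aware scoring

def split_half_dprime(
    responses: Sequence[ResponseRecord],
    schedule: ConditionSchedule | None = None,
    model: str = "differencing",
) -> tuple[DPrimeResult, DPrimeResult]:
    """Score the first and second half of a block independently.

    A 72-trial condition splits into halves of exactly 36 trials.  The
    trial count must be even.
    """
    responses = sorted(responses, key=lambda r: r.trial_index)
    if schedule is not None and len(responses) != len(schedule.trials):
        raise ContractError(
            f"{len(responses)} responses for {len(schedule.trials)} trials")
    n = len(responses)
    if n == 0 or n % 2:
        raise ContractError(f"cannot split {n} trials into equal halves")
    half = n // 2
    return (dprime_from_responses(responses[:half], model),
            dprime_from_responses(responses[half:], model))


def comparison_trial_dprime(
    responses: Sequence[ResponseRecord],
    schedule: ConditionSchedule,
    model: str = "differencing",
) -> DPrimeResult:
    """Score only the every-third comparison trials of an exp4 block."""
    if len(responses) != len(schedule.trials):
        raise ContractError(
            f"{len(responses)} responses for {len(schedule.trials)} trials")
    idx = set(comparison_trial_indices(schedule))
    scored = [r for r in responses if r.trial_index in idx]
    if len(scored) != len(idx):
        raise ContractError("response log does not cover all comparison trials")
    return dprime_from_responses(scored, model)


def rt_summary(responses: Iterable[ResponseRecord],
               stat: str = "median") -> dict[str, float]:
    """Per-condition RT summary over correct trials (median by default)."""
    agg = {"median": np.median, "mean": np.mean}.get(stat)
    if agg is None:
        raise ContractError(f"unknown RT statistic: {stat!r}")
    by_cond: dict[str, list[float]] = {}
    for r in responses:
        if r.correct:
            by_cond.setdefault(r.condition, []).append(r.rt_ms)
    return {c: float(agg(v)) for c, v in sorted(by_cond.items())}


# ---------------------------------------------------------------------------
# serialization

RESPONSE_COLUMNS = ["trial_index", "condition", "is_match", "response",
                    "rt_ms", "correct"]


def write_responses_csv(responses: Iterable[ResponseRecord],
                        path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(RESPONSE_COLUMNS)
        for r in responses:
            w.writerow([r.trial_index, r.condition, int(r.is_match),
                        r.response, repr(float(r.rt_ms)), int(r.correct)])


def read_responses_csv(path: str | Path) -> list[ResponseRecord]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(ResponseRecord(
                trial_index=int(row["trial_index"]),
                condition=row["condition"],
                is_match=bool(int(row["is_match"])),
                response=row["response"],
                rt_ms=float(row["rt_ms"]),
                correct=bool(int(row["correct"])),
            ))
    return out


def responses_to_frame(responses: Iterable[ResponseRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in responses])


def dprime_to_dict(res: DPrimeResult) -> dict:
    return asdict(res)


def write_dprime_json(res: DPrimeResult, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dprime_to_dict(res), indent=1,
                                     sort_keys=True))
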