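"""Minimum-limit-of-prediction calibration.

Easily detected ("sink") activities — Stand, Stay Seated, Walk, Walk
Backwards — tend to score spuriously high while other activities are being
performed, absorbing their samples. The countermeasure is a per-activity
barrier: a minimum similarity the sink activity must exceed to be eligible
as the prediction.

Limits are chosen from a pre-evaluation that records, per sink activity, the
similarities obtained while it truly is performed (positives) and while the
other activities are performed (negatives). The selection interval is:

* strict rule — (max(negatives), min(positives)) when those separate;
* mean fallback — (mean(negatives), mean(positives)) when the strict bounds
  overlap (the Stand situation: its highest impostor score exceeds its lowest
  genuine score);
* degenerate — flagged, never silently resolved, when even the means fail to
  separate.

The limit itself is the interval midpoint rounded to 0.1 percentage points.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import InsufficientDataError, NoSharedLimitError, UnreliableLimitError

__all__ = [
    "ScoreSamples",
    "CalibrationInterval",
    "LimitTable",
    "calibration_interval",
    "select_limit",
    "default_limits",
    "calibrate_all",
    "read_score_samples",
    "write_score_samples",
    "DEFAULT_GLOBAL_LIMIT",
]

#: Fallback threshold below which the best-scoring activity is still reported
#: as UNKNOWN. The per-activity sink limits are far stricter; this one only
#: rules out observations unlike every registered activity.
DEFAULT_GLOBAL_LIMIT = 50.0

#: Packaged per-activity limits for the four sink activities, in percent.
DEFAULT_SINK_LIMITS: dict[str, float] = {
    "Stand": 85.4,
    "Stay Seated": 78.0,
    "Walk [D]": 78.0,
    "Walk Backwards [D]": 79.0,
}


def _check_percent(values: Iterable[float], what: str) -> list[float]:
    vals = [float(v) for v in values]
    if any(not (0.0 <= v <= 100.0) for v in vals):
        raise ValueError(f"{what} must lie in [0, 100]")
    return vals


@dataclass
class ScoreSamples:
    """Similarity scores of one activity's template, split by ground truth."""

    activity: str
    positives: list[float]  # scored while the activity was truly performed
    negatives: list[float]  # scored while other activities were performed

    def __post_init__(self) -> None:
        self.positives = _check_percent(self.positives, "positives")
        self.negatives = _check_percent(self.negatives, "negatives")


@dataclass(frozen=True)
class CalibrationInterval:
    """Candidate interval (lower from negatives, upper from positives)."""

    activity: str
    lower: float
    upper: float
    rule_used: str  # "strict" | "mean"
    degenerate: bool


def calibration_interval(samples: ScoreSamples) -> CalibrationInterval:
    """Selection interval for one activity's limit.

    Strict rule first; mean fallback when the impostor maximum reaches the
    genuine minimum; degenerate flag when the means do not separate either.
    """
    if not samples.positives or not samples.negatives:
        raise InsufficientDataError(
            f"{samples.activity}: calibration needs non-empty positives and negatives"
        )
    lower, upper = max(samples.negatives), min(samples.positives)
    rule = "strict"
    if lower >= upper:
        lower = float(np.mean(samples.negatives))
        upper = float(np.mean(samples.positives))
        rule = "mean"
    return CalibrationInterval(
        activity=samples.activity,
        lower=lower,
        upper=upper,
        rule_used=rule,
        degenerate=lower >= upper,
    )


def select_limit(interval: CalibrationInterval) -> float:
    """Midpoint of a non-degenerate interval, rounded to 0.1 points."""
    if interval.degenerate:
        raise UnreliableLimitError(
            f"{interval.activity}: interval ({interval.lower:.2f}, "
            f"{interval.upper:.2f}) cannot separate genuine from impostor scores",
            interval=interval,
        )
    limit = round((interval.lower + interval.upper) / 2.0, 1)
    if not (interval.lower < limit < interval.upper):
        # midpoint rounding left no room inside a sliver-thin interval
        raise UnreliableLimitError(
            f"{interval.activity}: interval ({interval.lower:.2f}, "
            f"{interval.upper:.2f}) too narrow for a reliable limit",
            interval=interval,
        )
    return limit


@dataclass
class LimitTable:
    """Per-activity minimum limits of prediction plus the global fallback."""

    per_activity: dict[str, float] = field(default_factory=dict)
    global_limit: float = DEFAULT_GLOBAL_LIMIT

    def __post_init__(self) -> None:
        for name, v in self.per_activity.items():
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"limit for {name!r} outside [0, 100]: {v}")
        if not (0.0 <= self.global_limit <= 100.0):
            raise ValueError(f"global limit outside [0, 100]: {self.global_limit}")

    def get(self, activity: str) -> float | None:
        return self.per_activity.get(activity)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {"per_activity": self.per_activity, "global_limit": self.global_limit},
                fh,
                indent=1,
            )
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "LimitTable":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        return cls(dict(doc.get("per_activity", {})), float(doc["global_limit"]))


def default_limits(global_limit: float = DEFAULT_GLOBAL_LIMIT) -> LimitTable:
    """The packaged per-sink-activity limits (percent)."""
    return LimitTable(dict(DEFAULT_SINK_LIMITS), global_limit)


def calibrate_all(
    score_sets: Sequence[ScoreSamples],
    per_activity: bool = True,
    global_limit: float = DEFAULT_GLOBAL_LIMIT,
) -> LimitTable:
    """Derive a :class:`LimitTable` from pre-evaluation score samples.

    ``per_activity=True`` (the recommended mode) selects one limit per
    activity from its own interval. ``per_activity=False`` selects a single
    shared limit from the intersection of all non-degenerate intervals and
    fails when that intersection is empty — which is exactly what happens
    when one activity's interval (Stand's, in practice) sits apart from the
    others'.
    """
    if not score_sets:
        raise InsufficientDataError("no score samples supplied")
    intervals = [calibration_interval(s) for s in score_sets]
    if per_activity:
        table = {iv.activity: select_limit(iv) for iv in intervals}
        return LimitTable(table, global_limit)
    usable = [iv for iv in intervals if not iv.degenerate]
    if not usable:
        raise NoSharedLimitError("every calibration interval is degenerate")
    lo = max(iv.lower for iv in usable)
    hi = min(iv.upper for iv in usable)
    if lo >= hi:
        raise NoSharedLimitError(
            f"calibration intervals have empty intersection ({lo:.2f} >= {hi:.2f}); "
            "use per-activity limits"
        )
    shared = select_limit(
        CalibrationInterval("shared", lo, hi, rule_used="strict", degenerate=False)
    )
    return LimitTable({iv.activity: shared for iv in usable}, global_limit)


# ---------------------------------------------------------------------------
# Score-sample CSV: activity,truth(pos|neg),similarity
# ---------------------------------------------------------------------------

def write_score_samples(samples: Sequence[ScoreSamples], path: str | Path) -> None:
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["activity", "truth", "similarity"])
        for s in samples:
            for v in s.positives:
                writer.writerow([s.activity, "pos", repr(v)])
            for v in s.negatives:
                writer.writerow([s.activity, "neg", repr(v)])


def read_score_samples(path: str | Path) -> list[ScoreSamples]:
    pos: dict[str, list[float]] = {}
    neg: dict[str, list[float]] = {}
    order: list[str] = []
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        for row in reader:
            if not row:
                continue
            activity, truth, value = row
            if activity not in order:
                order.append(activity)
                pos[activity] = []
                neg[activity] = []
            if truth == "pos":
                pos[activity].append(float(value))
            elif truth == "neg":
                neg[activity].append(float(value))
            else:
                raise ValueError(f"truth column must be 'pos' or 'neg', got {truth!r}")
    return [ScoreSamples(a, pos[a], neg[a]) for a in order]
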