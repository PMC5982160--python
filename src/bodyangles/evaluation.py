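"""Evaluation harness: seeded trial protocols, Suc/Vic/Rate bookkeeping,
confusion matrices, limit pre-evaluation, and paired strategy comparison.

A protocol run performs, for every (participant, activity, repetition), one
synthetic repetition and classifies it under each configured joint-set
variant. Bookkeeping follows the result-table conventions:

* **Suc** — number of repetitions whose prediction matched the performed
  activity;
* **Vic** — number of repetitions in which a variant scored the true
  activity strictly higher than every other variant (exact ties award no
  victory, so Vic totals may fall short of the trial count);
* **Rate** — 100 * Suc / repetitions.

Strategy arms (variants only, limits only, combined) are compared on
identical seeded trials: every arm sees the same generated sequences, so
differences between arms are differences between strategies, not sampling
noise.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .calibration import LimitTable, ScoreSamples, default_limits
from .errors import ConfigurationError, ValidationError
from .recognizer import (
    ActivityTemplate,
    JointSetVariant,
    UNKNOWN,
    decide,
    score_all,
)
from .skeleton import SkeletonSequence
from .synthetic import (
    ACTIVITIES,
    ACTIVITY_ORDER,
    DEFAULT_FPS,
    LEG_ACTIVITIES,
    SINK_ACTIVITIES,
    ActivityScript,
    BodyModel,
    NoiseParams,
    generate_participant,
    generate_sequence,
    make_template,
    sequence_seed,
    with_balance_sway,
)

__all__ = [
    "ProtocolConfig",
    "EvalRecord",
    "ConfusionMatrix",
    "Trial",
    "ProtocolResult",
    "StrategyArm",
    "run_protocol",
    "summarize",
    "compare_strategies",
    "pre_evaluate",
    "participant_body",
    "default_arms",
]


@dataclass(frozen=True)
class ProtocolConfig:
    """Everything a reproducible evaluation run needs."""

    participants: int = 5
    activities: tuple[str, ...] = ACTIVITY_ORDER
    repetitions: int = 25
    variants: tuple[JointSetVariant, ...] = (
        JointSetVariant.vB,
        JointSetVariant.vT,
        JointSetVariant.vC,
    )
    limits: LimitTable | None = None
    master_seed: int = 0
    fps: float = DEFAULT_FPS
    noise: NoiseParams = field(default_factory=NoiseParams)

    def __post_init__(self) -> None:
        if self.participants <= 0 or self.repetitions <= 0:
            raise ValidationError("participant and repetition counts must be positive")
        if not self.variants:
            raise ValidationError("at least one joint-set variant is required")
        unknown = [a for a in self.activities if a not in ACTIVITIES]
        if unknown:
            raise ConfigurationError(f"unknown activities: {unknown}")

    @property
    def total_trials(self) -> int:
        return self.participants * len(self.activities) * self.repetitions


@dataclass
class EvalRecord:
    """One result-table cell: counts for (participant, activity, variant)."""

    participant: str
    activity: str
    variant: JointSetVariant
    Suc: int
    repetitions: int
    Vic: int | None = None  # only meaningful when >= 2 variants were compared

    @property
    def Rate(self) -> float:
        return 100.0 * self.Suc / self.repetitions


@dataclass
class ConfusionMatrix:
    """Counts of (true activity, predicted label); rows sum to trials."""

    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def add(self, true: str, predicted: str) -> None:
        key = (true, predicted)
        self.counts[key] = self.counts.get(key, 0) + 1

    def row_sum(self, true: str) -> int:
        return sum(v for (t, _), v in self.counts.items() if t == true)

    def labels(self) -> tuple[list[str], list[str]]:
        trues = sorted({t for t, _ in self.counts})
        preds = sorted({p for _, p in self.counts})
        return trues, preds

    def write_csv(self, path: str | Path) -> None:
        trues, preds = self.labels()
        with open(path, "w", newline="\n", encoding="utf-8") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["true\\predicted", *preds])
            for t in trues:
                writer.writerow([t, *(self.counts.get((t, p), 0) for p in preds)])


@dataclass
class Trial:
    """One generated repetition with its per-variant scores and decisions."""

    participant: str
    activity: str
    repetition: int
    scores: dict[JointSetVariant, dict[str, float]]
    predictions: dict[JointSetVariant, str] = field(default_factory=dict)
    gated: dict[JointSetVariant, frozenset[str]] = field(default_factory=dict)


@dataclass
class ProtocolResult:
    config: ProtocolConfig
    records: list[EvalRecord]
    confusions: dict[JointSetVariant, ConfusionMatrix]
    trials: list[Trial]


def participant_body(master_seed: int, index: int) -> BodyModel:
    """Reproducible body for participant ``index`` (0-based) of a run."""
    seed = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(0xB0D1, index))
    return generate_participant(seed=seed, participant_id=f"P{index + 1}")


def _observed_script(name: str, noise: NoiseParams) -> ActivityScript:
    script = ACTIVITIES[name]
    if noise.sway_amplitude > 0.0 and name in LEG_ACTIVITIES:
        return with_balance_sway(script, noise.sway_amplitude)
    return script


def _template_bank(
    config: ProtocolConfig, variants: Sequence[JointSetVariant]
) -> dict[str, dict[JointSetVariant, list[ActivityTemplate]]]:
    """Per-participant, per-variant template registries (own key samples)."""
    bank: dict[str, dict[JointSetVariant, list[ActivityTemplate]]] = {}
    for i in range(config.participants):
        body = participant_body(config.master_seed, i)
        bank[body.participant_id] = {
            v: [make_template(ACTIVITIES[a], body, v, fps=config.fps)
                for a in config.activities]
            for v in variants
        }
    return bank


def _run_trials(
    config: ProtocolConfig, variants: Sequence[JointSetVariant]
) -> list[Trial]:
    """Generate and score every repetition under every requested variant."""
    bank = _template_bank(config, variants)
    trials: list[Trial] = []
    for i in range(config.participants):
        pid = f"P{i + 1}"
        body = participant_body(config.master_seed, i)
        for activity in config.activities:
            script = _observed_script(activity, config.noise)
            for rep in range(config.repetitions):
                noise = replace(
                    config.noise,
                    seed=sequence_seed(config.master_seed, pid, activity, rep),
                )
                obs = generate_sequence(script, body, fps=config.fps, noise=noise)
                scores: dict[JointSetVariant, dict[str, float]] = {}
                for v in variants:
                    reports, _ = score_all(obs, bank[pid][v])
                    scores[v] = {n: r.body_similarity for n, r in reports.items()}
                trials.append(Trial(pid, activity, rep, scores))
    return trials


def _decide_trials(
    trials: Iterable[Trial],
    variants: Sequence[JointSetVariant],
    limits: LimitTable | None,
    order: Sequence[str],
) -> None:
    for trial in trials:
        for v in variants:
            label, gated = decide(trial.scores[v], limits, order)
            trial.predictions[v] = label
            trial.gated[v] = gated


def _tabulate(
    config: ProtocolConfig,
    trials: Sequence[Trial],
    variants: Sequence[JointSetVariant],
) -> tuple[list[EvalRecord], dict[JointSetVariant, ConfusionMatrix]]:
    suc: dict[tuple[str, str, JointSetVariant], int] = {}
    vic: dict[tuple[str, str, JointSetVariant], int] = {}
    confusions = {v: ConfusionMatrix() for v in variants}
    compare = len(variants) >= 2
    for t in trials:
        for v in variants:
            key = (t.participant, t.activity, v)
            suc.setdefault(key, 0)
            vic.setdefault(key, 0)
            if t.predictions[v] == t.activity:
                suc[key] += 1
            confusions[v].add(t.activity, t.predictions[v])
        if compare:
            true_scores = {v: t.scores[v].get(t.activity, float("-inf"))
                           for v in variants}
            best = max(true_scores.values())
            winners = [v for v, s in true_scores.items() if s == best]
            if len(winners) == 1:  # exact ties award no victory
                vic[(t.participant, t.activity, winners[0])] += 1
    records = [
        EvalRecord(
            participant=p,
            activity=a,
            variant=v,
            Suc=suc[(p, a, v)],
            repetitions=config.repetitions,
            Vic=vic[(p, a, v)] if compare else None,
        )
        for i in range(config.participants)
        for p in [f"P{i + 1}"]
        for a in config.activities
        for v in variants
    ]
    return records, confusions


def run_protocol(config: ProtocolConfig) -> ProtocolResult:
    """Run the full protocol: generate, classify, and tabulate every trial."""
    trials = _run_trials(config, config.variants)
    _decide_trials(trials, config.variants, config.limits, config.activities)
    records, confusions = _tabulate(config, trials, config.variants)
    return ProtocolResult(config, records, confusions, trials)


# ---------------------------------------------------------------------------
# Totals
# ---------------------------------------------------------------------------

@dataclass
class Summary:
    by_activity: dict[tuple[JointSetVariant, str], dict]
    by_participant: dict[tuple[JointSetVariant, str], dict]
    overall: dict[JointSetVariant, dict]

    def to_json(self, path: str | Path) -> None:
        def fmt(d: Mapping) -> dict:
            return {
                "/".join(str(getattr(k, "value", k)) for k in key): v
                for key, v in d.items()
            } if isinstance(next(iter(d), None), tuple) else {
                str(getattr(k, "value", k)): v for k, v in d.items()
            }

        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "by_activity": fmt(self.by_activity),
                    "by_participant": fmt(self.by_participant),
                    "overall": fmt(self.overall),
                },
                fh,
                indent=1,
            )
            fh.write("\n")


def summarize(records: Sequence[EvalRecord], allow_mixed: bool = False) -> Summary:
    """Pool Suc/Vic over activities, participants, and overall.

    Pooled rates are 100 * sum(Suc) / sum(trials). Mixed repetition counts
    are rejected unless ``allow_mixed`` (pooling across unequal cells is then
    explicitly requested).
    """
    if not records:
        raise ValidationError("no records to summarize")
    reps = {r.repetitions for r in records}
    if len(reps) > 1 and not allow_mixed:
        raise ValidationError(
            f"mixed repetition counts {sorted(reps)}; pass allow_mixed=True to pool"
        )

    def pool(keyfn) -> dict:
        out: dict = {}
        for r in records:
            k = keyfn(r)
            cell = out.setdefault(
                k, {"Suc": 0, "Vic": 0 if r.Vic is not None else None, "trials": 0}
            )
            cell["Suc"] += r.Suc
            cell["trials"] += r.repetitions
            if r.Vic is not None and cell["Vic"] is not None:
                cell["Vic"] += r.Vic
        for cell in out.values():
            cell["Rate"] = 100.0 * cell["Suc"] / cell["trials"]
        return out

    return Summary(
        by_activity=pool(lambda r: (r.variant, r.activity)),
        by_participant=pool(lambda r: (r.variant, r.participant)),
        overall=pool(lambda r: r.variant),
    )


def write_records_csv(records: Sequence[EvalRecord], path: str | Path) -> None:
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["participant", "activity", "variant", "Suc", "Vic", "Rate"])
        for r in records:
            writer.writerow(
                [r.participant, r.activity, r.variant.value, r.Suc,
                 "" if r.Vic is None else r.Vic, f"{r.Rate:.2f}"]
            )


# ---------------------------------------------------------------------------
# Strategy comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrategyArm:
    """One strategy under comparison: which variants, and which limits."""

    name: str
    variants: tuple[JointSetVariant, ...]
    limits: LimitTable | None


def default_arms(config: ProtocolConfig) -> tuple[StrategyArm, ...]:
    """Variants-only, limits-only, and combined, with the packaged limits."""
    limits = default_limits()
    return (
        StrategyArm("variants", tuple(config.variants), None),
        StrategyArm("limits", (JointSetVariant.vB,), limits),
        StrategyArm("combined", tuple(config.variants), limits),
    )


@dataclass
class StrategyComparison:
    config: ProtocolConfig
    arms: tuple[StrategyArm, ...]
    records: dict[str, list[EvalRecord]]
    confusions: dict[str, dict[JointSetVariant, ConfusionMatrix]]
    summaries: dict[str, Summary]


def compare_strategies(
    config: ProtocolConfig, arms: Sequence[StrategyArm] | None = None
) -> StrategyComparison:
    """Evaluate strategy arms on identical seeded trials (paired design).

    Sequences are generated and scored once for the union of all arms'
    variants; each arm then applies its own gating. Arms with a single
    variant report no Vic (there is nothing to compare against).
    """
    if arms is None:
        arms = default_arms(config)
    if len(arms) < 2:
        raise ConfigurationError("strategy comparison needs at least two arms")
    all_variants: list[JointSetVariant] = []
    for arm in arms:
        for v in arm.variants:
            if v not in all_variants:
                all_variants.append(v)
    trials = _run_trials(config, all_variants)
    records: dict[str, list[EvalRecord]] = {}
    confusions: dict[str, dict[JointSetVariant, ConfusionMatrix]] = {}
    summaries: dict[str, Summary] = {}
    for arm in arms:
        arm_trials = [
            Trial(t.participant, t.activity, t.repetition,
                  {v: t.scores[v] for v in arm.variants})
            for t in trials
        ]
        _decide_trials(arm_trials, arm.variants, arm.limits, config.activities)
        recs, confs = _tabulate(config, arm_trials, arm.variants)
        records[arm.name] = recs
        confusions[arm.name] = confs
        summaries[arm.name] = summarize(recs)
    return StrategyComparison(config, tuple(arms), records, confusions, summaries)


# ---------------------------------------------------------------------------
# Limit pre-evaluation
# ---------------------------------------------------------------------------

def pre_evaluate(
    master_seed: int = 0,
    participants: int = 5,
    repetitions: int = 10,
    variant: JointSetVariant = JointSetVariant.vB,
    noise: NoiseParams | None = None,
    fps: float = DEFAULT_FPS,
    sink_activities: Sequence[str] = SINK_ACTIVITIES,
) -> list[ScoreSamples]:
    """Collect the score samples the limit calibration needs.

    Positives for a sink activity are its template's scores while it is
    truly performed; negatives are its template's scores while each of the
    non-sink activities is performed. Repetition count is a parameter (the
    protocol only calls for "several" performances).
    """
    noise = NoiseParams() if noise is None else noise
    config = ProtocolConfig(
        participants=participants,
        activities=ACTIVITY_ORDER,
        repetitions=repetitions,
        variants=(variant,),
        master_seed=master_seed,
        fps=fps,
        noise=noise,
    )
    trials = _run_trials(config, (variant,))
    samples = []
    for sink in sink_activities:
        positives = [t.scores[variant][sink] for t in trials if t.activity == sink]
        negatives = [
            t.scores[variant][sink]
            for t in trials
            if t.activity not in sink_activities
        ]
        samples.append(ScoreSamples(sink, positives, negatives))
    return samples
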