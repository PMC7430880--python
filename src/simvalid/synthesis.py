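"""Synthetic cohort generation from published group summaries.

The study's raw per-participant data is not redistributed; instead, every
metric is emulated by a normal location-scale model truncated at zero whose
pre-truncation mean and SD equal the published group mean and SD.  Count
metrics are rounded to the nearest integer after truncation.  Likert scores
are drawn from a normal, rounded and clipped to the 1..5 scale.

Seeding: one global seed expands into an independent substream per
(task, metric, group) via a stable hash, so adding or removing one metric
never perturbs the draws of another.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .cohort import (
    TOTAL_GROUP,
    CohortTable,
    GroupLabel,
    GroupSummary,
    MetricDefinition,
    ParticipantRecord,
    ValidationError,
    default_registry,
)

__all__ = [
    "GenerationSpec",
    "LikertSpec",
    "sample_metric",
    "generate_cohort",
    "generate_likert",
    "attach_likert",
    "count_metrics_from_registry",
]

#: Age mean/SD per group used for synthetic demographics.
_AGE = {
    GroupLabel.ROBOTIC: (43.0, 10.8),
    GroupLabel.LAPAROSCOPIC: (35.0, 5.5),
    GroupLabel.NOVICE: (24.0, 2.4),
}
#: Of the 15 robotic-experienced participants, 7 report > 50 advanced
#: (intracorporal-suturing) procedures; the rest report 0-50.
_ADVANCED_SPLIT = 7 / 15


@dataclass(frozen=True)
class GenerationSpec:
    """What to generate: summaries to emulate, group sizes, count set, seed."""

    summaries: Sequence[GroupSummary]
    group_sizes: Mapping[GroupLabel, int]
    count_metrics: frozenset[str] = frozenset()
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ValidationError(f"group size for {g} must be >= 1, got {n}")
        object.__setattr__(self, "count_metrics", frozenset(self.count_metrics))


@dataclass(frozen=True)
class LikertSpec:
    """Target mean/SD for a Likert item set on the 1..5 scale."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if not 1.0 <= self.mean <= 5.0:
            raise ValidationError(f"Likert mean must lie in [1, 5], got {self.mean}")
        if self.sd < 0:
            raise ValidationError(f"Likert sd must be >= 0, got {self.sd}")
        if self.n < 1:
            raise ValidationError(f"Likert n must be >= 1, got {self.n}")


def _substream(seed: int, *key: str) -> np.random.Generator:
    """Independent generator for a (seed, key...) pair, stable across runs."""
    digest = hashlib.sha256("|".join(key).encode()).digest()
    words = np.frombuffer(digest[:16], dtype=np.uint32)
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, words)]))


def sample_metric(
    mean: float,
    sd: float,
    n: int,
    count_valued: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n`` nonnegative metric values from N(mean, sd) truncated at 0.

    The truncation keeps the *pre-truncation* location and scale equal to the
    published mean and SD (the rejection construction); for the published
    metrics mean/sd is almost always >= 1, so the induced bias is small.
    Count-valued metrics are rounded to the nearest integer afterwards.
    """
    if sd < 0:
        raise ValidationError(f"sd must be >= 0, got {sd}")
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if rng is None:
        rng = np.random.default_rng()
    if sd == 0:
        if mean < 0:
            raise ValidationError("degenerate metric with negative mean")
        out = np.full(n, float(mean))
    else:
        a = (0.0 - mean) / sd  # lower bound at zero in standard units
        out = stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)
    if count_valued:
        out = np.round(out)
    return out


def generate_likert(spec: LikertSpec, rng: np.random.Generator) -> list[int]:
    """Draw ``spec.n`` Likert scores: normal draw, rounded, clipped to 1..5."""
    if spec.sd == 0:
        raw = np.full(spec.n, spec.mean)
    else:
        raw = rng.normal(spec.mean, spec.sd, size=spec.n)
    return [int(s) for s in np.clip(np.round(raw), 1, 5)]


def count_metrics_from_registry(registry: Iterable[MetricDefinition]) -> frozenset[str]:
    """Metric names declared with a ``count`` unit (rounded when generated)."""
    return frozenset(d.name for d in registry if d.unit == "count")


def generate_cohort(
    spec: GenerationSpec,
    registry: Sequence[MetricDefinition] | None = None,
    pid_prefix: str = "",
) -> CohortTable:
    """Generate one synthetic participant per subject described by ``spec``.

    Every (task, metric) in ``spec.summaries`` must carry a summary for each
    generated group.  Reproducible: the same spec and seed yield an identical
    cohort.  Synthetic demographics (age, advanced-procedure count) are
    attached so that subgroup analyses have something to filter on.
    """
    registry = list(registry) if registry is not None else default_registry()
    by_key: dict[tuple[str, str, GroupLabel], GroupSummary] = {}
    tasks: dict[str, list[str]] = {}
    for s in spec.summaries:
        if s.group == TOTAL_GROUP or not isinstance(s.group, GroupLabel):
            continue  # pooled pseudo-group rows parameterize nothing
        by_key[(s.task, s.metric, s.group)] = s
        metrics = tasks.setdefault(s.task, [])
        if s.metric not in metrics:
            metrics.append(s.metric)

    records: list[ParticipantRecord] = []
    for group in GroupLabel:  # fixed order: novice, laparoscopic, robotic
        size = int(spec.group_sizes.get(group, 0))
        if size == 0:
            continue
        demo_rng = _substream(spec.seed, "demographics", group.value)
        ages = np.round(demo_rng.normal(*_AGE[group], size=size)).clip(18, None)
        n_expert = round(size * _ADVANCED_SPLIT) if group is GroupLabel.ROBOTIC else 0
        advanced = np.zeros(size, dtype=int)
        if n_expert:
            advanced[:n_expert] = demo_rng.integers(51, 150, size=n_expert)
            advanced[n_expert:] = demo_rng.integers(0, 51, size=size - n_expert)
        for i in range(size):
            records.append(
                ParticipantRecord(
                    pid=f"{pid_prefix}{group.value}_{i + 1:03d}",
                    group=group,
                    demographics={
                        "age": float(ages[i]),
                        "advanced_procedures": int(advanced[i]),
                    },
                )
            )

    index = {g: [r for r in records if r.group == g] for g in GroupLabel}
    for task, metrics in tasks.items():
        for metric in metrics:
            for group in GroupLabel:
                size = int(spec.group_sizes.get(group, 0))
                if size == 0:
                    continue
                summary = by_key.get((task, metric, group))
                if summary is None:
                    raise ValidationError(
                        f"no summary for (metric={metric!r}, group={group.value!r})"
                        f" in task {task!r}"
                    )
                rng = _substream(spec.seed, task, metric, group.value)
                values = sample_metric(
                    summary.mean,
                    summary.sd,
                    size,
                    count_valued=metric in spec.count_metrics,
                    rng=rng,
                )
                for rec, value in zip(index[group], values):
                    rec.metrics.setdefault(task, {})[metric] = float(value)

    return CohortTable(records=records, registry=registry)


def attach_likert(
    table: CohortTable,
    likert_summaries: Sequence[GroupSummary],
    seed: int,
    items: int = 1,
) -> CohortTable:
    """Attach synthetic Likert responses drawn from questionnaire summaries.

    One participant-level response of ``items`` scores per (task, domain) is
    drawn from the participant's group summary.  With ``items=1`` the group
    mean and SD of participant domain means match the fixture directly; more
    items per domain shrink the between-participant SD of domain means (the
    published tables do not identify item-level variance, so 1 is the
    faithful default).
    """
    by_group: dict[tuple[str, str, GroupLabel], GroupSummary] = {}
    for s in likert_summaries:
        if isinstance(s.group, GroupLabel):
            by_group[(s.task, s.metric, s.group)] = s
    for rec in table.records:
        for (task, domain, group), summary in by_group.items():
            if group is not rec.group:
                continue
            rng = _substream(seed, "likert", task, domain, group.value, rec.pid)
            spec = LikertSpec(mean=summary.mean, sd=summary.sd, n=items)
            rec.likert.setdefault(task, {})[domain] = generate_likert(spec, rng)
    table.validate()
    return table
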