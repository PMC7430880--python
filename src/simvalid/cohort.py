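"""Data model and I/O for simulator validation cohorts.

The study design behind this package compares three experience groups
(novice, laparoscopic-experienced, robotic-experienced) on a set of
per-task simulator performance metrics, plus a Likert questionnaire with
three opinion domains (realism, didactic value, usability).  This module
holds the typed containers for that design and the plain-CSV readers and
writers:

* a *metric registry* declaring, per task, each metric's domain
  (movement / safety / task-specific), its benefit direction (is a lower
  or a higher raw value better?) and its unit;
* long-format cohort tables (one row per participant x task x metric);
* Likert response tables (one row per participant x task x domain x item);
* group summary fixtures (mean, SD, n per task x metric x group) which
  transcribe the published group tables and parameterize the synthetic
  cohort generator.
"""
from __future__ import annotations

import csv
import enum
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CohortError",
    "ParseError",
    "ValidationError",
    "GroupLabel",
    "Domain",
    "Direction",
    "MetricDefinition",
    "GroupSummary",
    "ParticipantRecord",
    "CohortTable",
    "TOTAL_GROUP",
    "LIKERT_DOMAINS",
    "load_registry",
    "default_registry",
    "load_cohort",
    "write_cohort",
    "load_likert",
    "write_likert",
    "load_summary_fixture",
    "fixture_path",
    "SUMMARY_FIXTURES",
    "LIKERT_FIXTURE",
]


class CohortError(ValueError):
    """Base class for cohort model errors."""


class ParseError(CohortError):
    """Malformed input file (bad header, unparsable row)."""


class ValidationError(CohortError):
    """Structurally parsable input violating a model invariant."""


class GroupLabel(enum.Enum):
    """Experience group; ordering encodes expected proficiency."""

    NOVICE = "novice"
    LAPAROSCOPIC = "laparoscopic"
    ROBOTIC = "robotic"

    @property
    def rank(self) -> int:
        return _GROUP_RANK[self]

    def __lt__(self, other: "GroupLabel") -> bool:
        if not isinstance(other, GroupLabel):
            return NotImplemented
        return self.rank < other.rank

    @classmethod
    def parse(cls, text: str) -> "GroupLabel":
        """Normalize a group label case-insensitively (accepts plural forms)."""
        key = str(text).strip().lower()
        key = _GROUP_SYNONYMS.get(key, key)
        try:
            return cls(key)
        except ValueError:
            allowed = ", ".join(g.value for g in cls)
            raise ValidationError(
                f"unknown group label {text!r}; allowed labels: {allowed}"
            ) from None


_GROUP_RANK = {GroupLabel.NOVICE: 0, GroupLabel.LAPAROSCOPIC: 1, GroupLabel.ROBOTIC: 2}
_GROUP_SYNONYMS = {"novices": "novice", "lap": "laparoscopic", "robot": "robotic"}

#: Pseudo-group used in summary fixtures for the pooled "total group" column.
TOTAL_GROUP = "total"

LIKERT_DOMAINS = ("realism", "didactic_value", "usability")


class Domain(enum.Enum):
    MOVEMENT = "movement"
    SAFETY = "safety"
    TASK_SPECIFIC = "task_specific"


class Direction(enum.Enum):
    LOWER_BETTER = "lower_better"
    HIGHER_BETTER = "higher_better"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class MetricDefinition:
    """A performance metric with its benefit direction and domain."""

    name: str
    task: str
    domain: Domain
    direction: Direction
    unit: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("metric name must be nonempty")
        if not self.unit:
            raise ValidationError(f"metric {self.name!r}: unit must be nonempty")
        if not isinstance(self.domain, Domain):
            object.__setattr__(self, "domain", Domain(self.domain))
        if not isinstance(self.direction, Direction):
            object.__setattr__(self, "direction", Direction(self.direction))


@dataclass(frozen=True)
class GroupSummary:
    """Published per-group summary: mean, SD and n for one task x metric."""

    task: str
    metric: str
    group: GroupLabel | str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError(
                f"{self.task}/{self.metric}/{_group_name(self.group)}: sd must be >= 0, got {self.sd}"
            )
        if self.n < 2:
            raise ValidationError(
                f"{self.task}/{self.metric}/{_group_name(self.group)}: n must be >= 2, got {self.n}"
            )
        if not math.isfinite(self.mean):
            raise ValidationError(f"{self.task}/{self.metric}: mean must be finite")


def _group_name(group: GroupLabel | str) -> str:
    return group.value if isinstance(group, GroupLabel) else str(group)


@dataclass
class ParticipantRecord:
    """One participant: metric values and Likert responses keyed by task."""

    pid: str
    group: GroupLabel
    metrics: dict[str, dict[str, float]] = field(default_factory=dict)
    likert: dict[str, dict[str, list[int]]] = field(default_factory=dict)
    demographics: dict[str, float] | None = None

    def validate(self, registry_index: Mapping[tuple[str, str], MetricDefinition]) -> None:
        for task, values in self.metrics.items():
            for metric, value in values.items():
                if (task, metric) not in registry_index:
                    known = sorted(m for t, m in registry_index if t == task)
                    raise ValidationError(
                        f"participant {self.pid}: unknown metric {metric!r} for {task!r};"
                        f" known metrics: {known}"
                    )
                if not math.isfinite(value) or value < 0:
                    raise ValidationError(
                        f"participant {self.pid}: metric {task}/{metric} must be a"
                        f" nonnegative finite number, got {value}"
                    )
        for task, domains in self.likert.items():
            for domain, scores in domains.items():
                if domain not in LIKERT_DOMAINS:
                    raise ValidationError(
                        f"participant {self.pid}: unknown Likert domain {domain!r};"
                        f" allowed: {LIKERT_DOMAINS}"
                    )
                for s in scores:
                    if int(s) != s or not 1 <= int(s) <= 5:
                        raise ValidationError(
                            f"participant {self.pid}: Likert score {s!r} outside 1..5"
                        )


@dataclass
class CohortTable:
    """A validated cohort: participant records plus the metric registry."""

    records: list[ParticipantRecord]
    registry: list[MetricDefinition]

    def __post_init__(self) -> None:
        self.validate()

    # -- registry helpers -------------------------------------------------
    @property
    def registry_index(self) -> dict[tuple[str, str], MetricDefinition]:
        return {(d.task, d.name): d for d in self.registry}

    def task_metrics(self, task: str) -> list[str]:
        """Registry-ordered metric names for a task."""
        return [d.name for d in self.registry if d.task == task]

    def definition(self, task: str, metric: str) -> MetricDefinition:
        try:
            return self.registry_index[(task, metric)]
        except KeyError:
            raise ValidationError(f"no metric definition for {task}/{metric}") from None

    # -- structure helpers ------------------------------------------------
    @property
    def tasks(self) -> list[str]:
        seen: dict[str, None] = {}
        for rec in self.records:
            for task in rec.metrics:
                seen.setdefault(task, None)
            for task in rec.likert:
                seen.setdefault(task, None)
        return list(seen)

    def group_sizes(self, task: str | None = None) -> dict[GroupLabel, int]:
        sizes = {g: 0 for g in GroupLabel}
        for rec in self.records:
            if task is None or task in rec.metrics or task in rec.likert:
                sizes[rec.group] += 1
        return sizes

    def metric_frame(self, task: str) -> tuple[pd.DataFrame, pd.Series]:
        """Participants x metrics matrix for a task plus the group labels.

        Participants without any value for the task are omitted; missing
        individual metrics become NaN (downstream policy decides drops).
        """
        rows, groups, index = [], [], []
        for rec in self.records:
            if task not in rec.metrics:
                continue
            rows.append(rec.metrics[task])
            groups.append(rec.group)
            index.append(rec.pid)
        frame = pd.DataFrame(rows, index=index, columns=self.task_metrics(task))
        return frame, pd.Series(groups, index=index, name="group")

    def likert_frame(self, task: str) -> tuple[pd.DataFrame, pd.Series]:
        """Per-participant Likert *domain means* for a task plus group labels."""
        rows, groups, index = [], [], []
        for rec in self.records:
            if task not in rec.likert:
                continue
            domains = rec.likert[task]
            rows.append(
                {d: (sum(s) / len(s) if s else math.nan) for d, s in domains.items()}
            )
            groups.append(rec.group)
            index.append(rec.pid)
        frame = pd.DataFrame(rows, index=index)
        return frame, pd.Series(groups, index=index, name="group")

    def validate(self) -> None:
        index = self.registry_index
        seen: set[str] = set()
        for rec in self.records:
            if rec.pid in seen:
                raise ValidationError(f"duplicate participant id {rec.pid!r}")
            seen.add(rec.pid)
            rec.validate(index)


# ---------------------------------------------------------------------------
# Registry I/O
# ---------------------------------------------------------------------------

def load_registry(path: str | Path) -> list[MetricDefinition]:
    """Read a metric registry CSV (task,metric,domain,direction,unit)."""
    defs: list[MetricDefinition] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _require_header(reader, {"task", "metric", "domain", "direction", "unit"}, path)
        for lineno, row in enumerate(reader, start=2):
            try:
                defs.append(
                    MetricDefinition(
                        name=row["metric"].strip(),
                        task=row["task"].strip(),
                        domain=Domain(row["domain"].strip()),
                        direction=Direction(row["direction"].strip()),
                        unit=row["unit"].strip(),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
    names = [(d.task, d.name) for d in defs]
    if len(names) != len(set(names)):
        raise ValidationError(f"{path}: duplicate (task, metric) entries")
    return defs


def default_registry() -> list[MetricDefinition]:
    """The packaged registry covering the three suturing tasks."""
    return load_registry(fixture_path("metric_registry.csv"))


# ---------------------------------------------------------------------------
# Cohort I/O (long CSV: participant_id,group,task,metric,value)
# ---------------------------------------------------------------------------

COHORT_COLUMNS = ("participant_id", "group", "task", "metric", "value")
LIKERT_COLUMNS = ("participant_id", "group", "task", "domain", "item", "score")


def _require_header(reader: csv.DictReader, required: set[str], path) -> None:
    fields = set(reader.fieldnames or ())
    missing = required - fields
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")


def load_cohort(path: str | Path, registry: Sequence[MetricDefinition]) -> CohortTable:
    """Load a long-format cohort CSV against a metric registry.

    Rows with unknown metrics, unknown group labels or negative values are
    rejected with an error naming the offending line.
    """
    records: dict[str, ParticipantRecord] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _require_header(reader, set(COHORT_COLUMNS), path)
        for lineno, row in enumerate(reader, start=2):
            try:
                pid = row["participant_id"].strip()
                group = GroupLabel.parse(row["group"])
                task = row["task"].strip()
                metric = row["metric"].strip()
                value = float(row["value"])
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from None
            except (KeyError, TypeError, ValueError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            rec = records.setdefault(pid, ParticipantRecord(pid=pid, group=group))
            if rec.group is not group:
                raise ValidationError(
                    f"{path}: line {lineno}: participant {pid!r} appears under two groups"
                )
            rec.metrics.setdefault(task, {})[metric] = value
    try:
        return CohortTable(records=list(records.values()), registry=list(registry))
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_cohort(table: CohortTable, path: str | Path) -> None:
    """Write the long cohort CSV (inverse of :func:`load_cohort`)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for rec in table.records:
            for task, values in rec.metrics.items():
                for metric, value in values.items():
                    writer.writerow([rec.pid, rec.group.value, task, metric, repr(value)])


def load_likert(
    path: str | Path,
    registry: Sequence[MetricDefinition] | None = None,
    table: CohortTable | None = None,
) -> CohortTable:
    """Load Likert responses; merge into ``table`` when given, else build one."""
    records: dict[str, ParticipantRecord] = (
        {r.pid: r for r in table.records} if table is not None else {}
    )
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _require_header(reader, set(LIKERT_COLUMNS), path)
        for lineno, row in enumerate(reader, start=2):
            try:
                pid = row["participant_id"].strip()
                group = GroupLabel.parse(row["group"])
                task = row["task"].strip()
                domain = row["domain"].strip()
                score = int(row["score"])
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from None
            except (KeyError, TypeError, ValueError) as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from None
            rec = records.setdefault(pid, ParticipantRecord(pid=pid, group=group))
            rec.likert.setdefault(task, {}).setdefault(domain, []).append(score)
    reg = list(registry) if registry is not None else (
        list(table.registry) if table is not None else default_registry()
    )
    return CohortTable(records=list(records.values()), registry=reg)


def write_likert(table: CohortTable, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(LIKERT_COLUMNS)
        for rec in table.records:
            for task, domains in rec.likert.items():
                for domain, scores in domains.items():
                    for item, score in enumerate(scores, start=1):
                        writer.writerow(
                            [rec.pid, rec.group.value, task, domain, item, score]
                        )


# ---------------------------------------------------------------------------
# Summary fixtures (task,metric,group,mean,sd,n)
# ---------------------------------------------------------------------------

def load_summary_fixture(
    path: str | Path, allow_total: bool = True
) -> list[GroupSummary]:
    """Load a summary-statistic fixture (CSV or JSON).

    ``total`` rows (the pooled all-groups column of the questionnaire table)
    are accepted only when ``allow_total`` is true.
    """
    path = Path(path)
    rows: Iterable[Mapping[str, object]]
    if path.suffix.lower() == ".json":
        with open(path, encoding="utf-8") as fh:
            rows = json.load(fh)
    else:
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            _require_header(reader, {"task", "metric", "group", "mean", "sd", "n"}, path)
            rows = list(reader)
    summaries: list[GroupSummary] = []
    for lineno, row in enumerate(rows, start=2):
        raw_group = str(row["group"]).strip().lower()
        group: GroupLabel | str
        if raw_group == TOTAL_GROUP:
            if not allow_total:
                raise ValidationError(
                    f"{path}: line {lineno}: pseudo-group 'total' not allowed here"
                )
            group = TOTAL_GROUP
        else:
            try:
                group = GroupLabel.parse(raw_group)
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from None
        try:
            summaries.append(
                GroupSummary(
                    task=str(row["task"]).strip(),
                    metric=str(row["metric"]).strip(),
                    group=group,
                    mean=float(row["mean"]),
                    sd=float(row["sd"]),
                    n=int(row["n"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: line {lineno}: {exc}") from None
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return summaries


#: Packaged per-task performance summary fixtures.
SUMMARY_FIXTURES = {
    "task1": "table4_task1.csv",
    "task2": "table5_task2.csv",
    "task3": "table6_task3.csv",
}

#: Packaged questionnaire (Likert) summary fixture.
LIKERT_FIXTURE = "table3_likert.csv"


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(str(resources.files("simvalid.data") / name))
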