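"""Content- and construct-validity screening.

Construct screening runs pairwise two-sample t-tests per metric between the
three experience groups.  The equal-variance (Student) and unequal-variance
(Welch) forms are both computed; on record-level data the reported form is
gated by a mean-centered Levene test at alpha = 0.05 (reject homogeneity ->
Welch), the convention SPSS users apply when reading the standard t-test
output.  Tests built from summary statistics alone default to Welch, the
conservative choice.  A Shapiro-Wilk normality p-value is logged per sample
but does not alter the test pathway.

Content screening aggregates Likert items to per-participant domain means,
summarizes per group and overall, and flags a domain positive when the
overall mean exceeds 3.5 on the 1..5 scale (boundary excluded).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .cohort import (
    TOTAL_GROUP,
    CohortTable,
    Direction,
    GroupLabel,
    GroupSummary,
    MetricDefinition,
    ValidationError,
)

__all__ = [
    "TestReport",
    "ConstructResult",
    "ContentResult",
    "LeveneResult",
    "CONTRASTS",
    "student_t_summary",
    "welch_t_summary",
    "levene_test",
    "normality_check",
    "gated_t_test",
    "compare_groups",
    "likert_content",
    "select_construct_parameters",
    "overall_content_means",
    "POSITIVITY_THRESHOLD",
]

#: A Likert domain is judged positive when its overall mean exceeds this.
POSITIVITY_THRESHOLD = 3.5

#: Pairwise contrasts in published column order: R vs N, L vs N, R vs L.
CONTRASTS: tuple[tuple[GroupLabel, GroupLabel], ...] = (
    (GroupLabel.ROBOTIC, GroupLabel.NOVICE),
    (GroupLabel.LAPAROSCOPIC, GroupLabel.NOVICE),
    (GroupLabel.ROBOTIC, GroupLabel.LAPAROSCOPIC),
)


def contrast_key(a: GroupLabel, b: GroupLabel) -> str:
    return f"{a.value}_vs_{b.value}"


@dataclass(frozen=True)
class TestReport:
    """Two-sided two-sample t-test outcome."""

    t: float
    df: float
    p: float
    method: str  # "student" | "welch"
    levene_p: float | None = None
    normality_p: tuple[float | None, float | None] | None = None

    def __post_init__(self) -> None:
        if self.df <= 0:
            raise ValidationError(f"df must be > 0, got {self.df}")
        if not 0.0 <= self.p <= 1.0:
            raise ValidationError(f"p must lie in [0, 1], got {self.p}")


class LeveneResult(NamedTuple):
    statistic: float
    pvalue: float


@dataclass
class ConstructResult:
    """Per-metric construct screen over the three pairwise contrasts."""

    metric: str
    task: str
    direction: Direction
    group_stats: dict[GroupLabel, tuple[float, float, int]]
    tests: dict[str, TestReport]
    advantage: dict[str, GroupLabel | None]
    alpha: float = 0.05

    @property
    def p_rvn(self) -> float:
        return self.tests[contrast_key(GroupLabel.ROBOTIC, GroupLabel.NOVICE)].p

    @property
    def p_lvn(self) -> float:
        return self.tests[contrast_key(GroupLabel.LAPAROSCOPIC, GroupLabel.NOVICE)].p

    @property
    def p_rvl(self) -> float:
        return self.tests[contrast_key(GroupLabel.ROBOTIC, GroupLabel.LAPAROSCOPIC)].p

    @property
    def significant_rvn(self) -> bool:
        return self.p_rvn < self.alpha


@dataclass
class ContentResult:
    """Per-domain Likert aggregation for one task."""

    task: str
    domain: str
    group_stats: dict[GroupLabel, tuple[float, float, int]]
    total_mean: float
    total_sd: float
    total_n: int
    pairwise: dict[str, TestReport]

    @property
    def positive(self) -> bool:
        return self.total_mean > POSITIVITY_THRESHOLD


# ---------------------------------------------------------------------------
# Elementary tests
# ---------------------------------------------------------------------------

def _check_summary_args(m1, s1, n1, m2, s2, n2) -> None:
    if n1 < 2 or n2 < 2:
        raise ValidationError(f"each group needs n >= 2, got n1={n1}, n2={n2}")
    if s1 < 0 or s2 < 0:
        raise ValidationError("standard deviations must be >= 0")
    if s1 == 0 and s2 == 0:
        raise ValidationError("both groups have zero variance; t-test undefined")


def student_t_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> TestReport:
    """Pooled-variance two-sided t-test from summary statistics."""
    _check_summary_args(m1, s1, n1, m2, s2, n2)
    res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return TestReport(t=float(res.statistic), df=float(n1 + n2 - 2), p=float(res.pvalue), method="student")


def welch_t_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> TestReport:
    """Welch (unequal-variance) two-sided t-test from summary statistics."""
    _check_summary_args(m1, s1, n1, m2, s2, n2)
    res = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=False)
    v1, v2 = s1**2 / n1, s2**2 / n2
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return TestReport(t=float(res.statistic), df=float(df), p=float(res.pvalue), method="welch")


def levene_test(x: Sequence[float], y: Sequence[float]) -> LeveneResult:
    """Mean-centered Levene test for equality of variances."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("Levene test needs n >= 2 per sample")
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # near-constant samples
        stat, p = stats.levene(x, y, center="mean")
    if not math.isfinite(stat):  # all absolute deviations equal across groups
        return LeveneResult(0.0, 1.0)
    return LeveneResult(float(stat), float(p))


def normality_check(x: Sequence[float]) -> float:
    """Shapiro-Wilk normality p-value (logged, never gating)."""
    x = np.asarray(x, float)
    if len(x) < 3:
        raise ValidationError("normality check needs n >= 3")
    if np.ptp(x) == 0:
        return 0.0  # a constant sample is degenerate, not normal
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # near-constant samples
        return float(stats.shapiro(x).pvalue)


def gated_t_test(
    x: Sequence[float], y: Sequence[float], levene_alpha: float = 0.05
) -> TestReport:
    """Record-level independent t-test with the Levene variance gate.

    Levene (mean-centered) at ``levene_alpha`` decides between the Student
    and the Welch form.  Shapiro-Wilk p-values for both samples are attached
    for the screen log.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("t-test needs n >= 2 per sample")
    if np.ptp(x) == 0 and np.ptp(y) == 0 and x[0] == y[0]:
        raise ValidationError("both samples constant and equal; t-test undefined")
    lev = levene_test(x, y)
    equal_var = lev.pvalue >= levene_alpha
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # near-constant samples
        res = stats.ttest_ind(x, y, equal_var=equal_var)
    norm_p = tuple(
        normality_check(s) if len(s) >= 3 and np.ptp(s) > 0 else None for s in (x, y)
    )
    return TestReport(
        t=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        method="student" if equal_var else "welch",
        levene_p=lev.pvalue,
        normality_p=norm_p,  # type: ignore[arg-type]
    )


# ---------------------------------------------------------------------------
# Cohort-level screens
# ---------------------------------------------------------------------------

def _gated_or_null(xa: np.ndarray, xb: np.ndarray) -> TestReport:
    """Gated t-test; both groups constant at one value counts as no difference."""
    if np.ptp(xa) == 0 and np.ptp(xb) == 0 and xa[0] == xb[0]:
        return TestReport(
            t=0.0, df=float(len(xa) + len(xb) - 2), p=1.0,
            method="student", levene_p=1.0,
        )
    return gated_t_test(xa, xb)


def _better_group(
    a: GroupLabel, ma: float, b: GroupLabel, mb: float, direction: Direction
) -> GroupLabel | None:
    if direction is Direction.AMBIGUOUS or ma == mb:
        return None
    if direction is Direction.LOWER_BETTER:
        return a if ma < mb else b
    return a if ma > mb else b


def compare_groups(
    cohort: CohortTable, task: str, metric: str, alpha: float = 0.05
) -> ConstructResult:
    """Screen one metric: three pairwise gated t-tests plus advantage calls."""
    definition = cohort.definition(task, metric)
    frame, groups = cohort.metric_frame(task)
    if metric not in frame.columns:
        raise ValidationError(f"metric {metric!r} not observed for task {task!r}")
    values = frame[metric].dropna()
    groups = groups.loc[values.index]
    samples = {g: values[groups == g].to_numpy() for g in GroupLabel}
    group_stats: dict[GroupLabel, tuple[float, float, int]] = {}
    for g, sample in samples.items():
        if len(sample) < 2:
            raise ValidationError(
                f"{task}/{metric}: group {g.value!r} has {len(sample)} records; need >= 2"
            )
        group_stats[g] = (
            float(np.mean(sample)),
            float(np.std(sample, ddof=1)),
            int(len(sample)),
        )
    tests: dict[str, TestReport] = {}
    advantage: dict[str, GroupLabel | None] = {}
    for a, b in CONTRASTS:
        key = contrast_key(a, b)
        tests[key] = _gated_or_null(samples[a], samples[b])
        advantage[key] = _better_group(
            a, group_stats[a][0], b, group_stats[b][0], definition.direction
        )
    return ConstructResult(
        metric=metric,
        task=task,
        direction=definition.direction,
        group_stats=group_stats,
        tests=tests,
        advantage=advantage,
        alpha=alpha,
    )


def screen_task(
    cohort: CohortTable, task: str, alpha: float = 0.05
) -> list[ConstructResult]:
    """Run :func:`compare_groups` for every registry metric observed in the task."""
    frame, _ = cohort.metric_frame(task)
    return [
        compare_groups(cohort, task, metric, alpha=alpha)
        for metric in cohort.task_metrics(task)
        if metric in frame.columns and frame[metric].notna().any()
    ]


def screen_summaries(
    summaries: Sequence[GroupSummary],
    registry: Sequence[MetricDefinition],
    task: str,
    alpha: float = 0.05,
) -> list[ConstructResult]:
    """Construct screen from printed group summaries (no record-level data).

    Without records there is nothing for Levene to gate on, so the Welch form
    is used throughout (the conservative summary-only default).
    """
    by_metric: dict[str, dict[GroupLabel, GroupSummary]] = {}
    for s in summaries:
        if s.task == task and isinstance(s.group, GroupLabel):
            by_metric.setdefault(s.metric, {})[s.group] = s
    order = [d.name for d in registry if d.task == task]
    results: list[ConstructResult] = []
    for metric in order:
        groups = by_metric.get(metric)
        if groups is None:
            continue
        missing = [g.value for g in GroupLabel if g not in groups]
        if missing:
            raise ValidationError(f"{task}/{metric}: missing summaries for {missing}")
        definition = next(d for d in registry if d.task == task and d.name == metric)
        group_stats = {g: (s.mean, s.sd, s.n) for g, s in groups.items()}
        tests: dict[str, TestReport] = {}
        advantage: dict[str, GroupLabel | None] = {}
        for a, b in CONTRASTS:
            sa, sb = groups[a], groups[b]
            key = contrast_key(a, b)
            if sa.sd == 0 and sb.sd == 0 and sa.mean == sb.mean:
                tests[key] = TestReport(
                    t=0.0, df=float(sa.n + sb.n - 2), p=1.0,
                    method="student", levene_p=1.0,
                )
            else:
                tests[key] = welch_t_summary(sa.mean, sa.sd, sa.n, sb.mean, sb.sd, sb.n)
            advantage[key] = _better_group(
                a, sa.mean, b, sb.mean, definition.direction
            )
        results.append(
            ConstructResult(
                metric=metric,
                task=task,
                direction=definition.direction,
                group_stats=group_stats,
                tests=tests,
                advantage=advantage,
                alpha=alpha,
            )
        )
    return results


def likert_content(
    cohort: CohortTable, task: str, alpha: float = 0.05
) -> list[ContentResult]:
    """Aggregate Likert domains: participant domain mean -> group and total stats."""
    frame, groups = cohort.likert_frame(task)
    if frame.empty:
        raise ValidationError(f"no Likert responses recorded for task {task!r}")
    results: list[ContentResult] = []
    for domain in frame.columns:
        values = frame[domain].dropna()
        if values.empty:
            raise ValidationError(f"{task}/{domain}: domain has zero scored items")
        dgroups = groups.loc[values.index]
        samples = {g: values[dgroups == g].to_numpy() for g in GroupLabel}
        group_stats = {
            g: (float(np.mean(s)), float(np.std(s, ddof=1)) if len(s) > 1 else 0.0, len(s))
            for g, s in samples.items()
            if len(s)
        }
        pairwise: dict[str, TestReport] = {}
        for a, b in CONTRASTS:
            if len(samples[a]) >= 2 and len(samples[b]) >= 2:
                pairwise[contrast_key(a, b)] = _gated_or_null(samples[a], samples[b])
        results.append(
            ContentResult(
                task=task,
                domain=str(domain),
                group_stats=group_stats,
                total_mean=float(values.mean()),
                total_sd=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
                total_n=int(len(values)),
                pairwise=pairwise,
            )
        )
    return results


def select_construct_parameters(
    results: Sequence[ConstructResult],
    registry: Sequence[MetricDefinition],
    include: Iterable[str] = (),
    exclude: Iterable[str] = (),
) -> list[str]:
    """Pick the composite-eligible metric set for one task.

    A metric qualifies when the robotic-vs-novice contrast is significant,
    the advantage lies with the robotic group, and its benefit direction is
    not ambiguous.  Explicit ``exclude`` removes metrics; ``include`` adds
    them regardless (the override hook for judgment calls).  Output follows
    registry order.
    """
    tasks = {r.task for r in results}
    if len(tasks) != 1:
        raise ValidationError(f"results must cover exactly one task, got {sorted(tasks)}")
    task = tasks.pop()
    order = [d.name for d in registry if d.task == task]
    known = set(order)
    include, exclude = list(include), list(exclude)
    for name in (*include, *exclude):
        if name not in known:
            raise ValidationError(
                f"override names unknown metric {name!r} for task {task!r}"
            )
    rvn = contrast_key(GroupLabel.ROBOTIC, GroupLabel.NOVICE)
    eligible = {
        r.metric
        for r in results
        if r.significant_rvn
        and r.advantage.get(rvn) is GroupLabel.ROBOTIC
        and r.direction is not Direction.AMBIGUOUS
    }
    chosen = (eligible - set(exclude)) | set(include)
    return [m for m in order if m in chosen]


def overall_content_means(
    summaries: Sequence[GroupSummary], ndigits: int | None = 1
) -> dict[str, float]:
    """Average the pooled 'total' column across tasks per Likert domain."""
    per_domain: dict[str, list[float]] = {}
    for s in summaries:
        if s.group == TOTAL_GROUP:
            per_domain.setdefault(s.metric, []).append(s.mean)
    if not per_domain:
        raise ValidationError("no 'total' rows found in the summaries")
    out = {d: float(np.mean(v)) for d, v in per_domain.items()}
    if ndigits is not None:
        out = {d: round(v, ndigits) for d, v in out.items()}
    return out
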