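import numpy as np
import pytest

from simvalid.cohort import (
    LIKERT_FIXTURE,
    SUMMARY_FIXTURES,
    CohortTable,
    Direction,
    Domain,
    GroupLabel,
    MetricDefinition,
    ParticipantRecord,
    default_registry,
    fixture_path,
    load_summary_fixture,
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def task1_summaries():
    return load_summary_fixture(fixture_path(SUMMARY_FIXTURES["task1"]))


@pytest.fixture(scope="session")
def likert_summaries():
    return load_summary_fixture(fixture_path(LIKERT_FIXTURE))


def toy_cohort(values_by_metric, directions=None, task="task1", likert=None):
    """Build a small cohort from {metric: {GroupLabel: [values]}}.

    ``directions`` maps metric -> Direction (default lower_better).
    ``likert`` maps {GroupLabel: {domain: [[scores per participant], ...]}}.
    """
    directions = directions or {}
    metrics = list(values_by_metric)
    registry = [
        MetricDefinition(
            name=m,
            task=task,
            domain=Domain.MOVEMENT,
            direction=directions.get(m, Direction.LOWER_BETTER),
            unit="count",
        )
        for m in metrics
    ]
    sizes = {
        g: max(len(per_group.get(g, ())) for per_group in values_by_metric.values())
        for g in GroupLabel
    }
    records = []
    for g in GroupLabel:
        for i in range(sizes[g]):
            rec = ParticipantRecord(pid=f"{g.value}_{i}", group=g)
            for m in metrics:
                vals = values_by_metric[m].get(g, ())
                if i < len(vals):
                    rec.metrics.setdefault(task, {})[m] = float(vals[i])
            if likert and g in likert:
                for domain, per_part in likert[g].items():
                    if i < len(per_part):
                        rec.likert.setdefault(task, {})[domain] = list(per_part[i])
            records.append(rec)
    return CohortTable(records=records, registry=registry)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
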