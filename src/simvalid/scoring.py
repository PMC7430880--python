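"""Direction-aware 0-100 composite scoring.

Each selected metric is min-max normalized over the pooled cohort of a task
(all three groups together, so every participant lives on one comparable
0-100 axis) and oriented so that 100 is always the favorable end: with raw
value v and pooled bounds (lo, hi),

    higher-better:  100 * (v - lo) / (hi - lo)
    lower-better:   100 * (hi - v) / (hi - lo)

The composite is the (weighted) mean of the normalized metrics.  Values seen
at predict time outside the fitted bounds are clipped, keeping composites in
[0, 100] when a fitted map is reused on new participants.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import CohortTable, Direction, GroupLabel, ValidationError

__all__ = [
    "ZeroRangeError",
    "NormalizationMap",
    "CompositeScoreSet",
    "MinMaxCompositeScorer",
    "fit_normalization",
    "normalize",
    "composite_scores",
    "sensitivity_weights",
    "separation",
]

logger = logging.getLogger(__name__)


class ZeroRangeError(ValidationError):
    """A metric is constant over the normalization population."""


@dataclass(frozen=True)
class NormalizationMap:
    """Fitted per-metric (min, max, direction); population is the pooled task cohort."""

    bounds: Mapping[str, tuple[float, float]]
    directions: Mapping[str, Direction]
    population: str = "pooled_all_groups"

    def __post_init__(self) -> None:
        for metric, (lo, hi) in self.bounds.items():
            if not hi > lo:
                raise ZeroRangeError(
                    f"metric {metric!r}: max ({hi}) must exceed min ({lo})"
                )


@dataclass
class CompositeScoreSet:
    """Per-participant composite scores with group summaries."""

    scores: pd.Series  # index: participant id, values in [0, 100]
    groups: pd.Series  # index: participant id -> GroupLabel
    included_metrics: list[str]
    weights: dict[str, float]
    group_summaries: dict[GroupLabel, tuple[float, float, int]]
    dropped: list[str] = field(default_factory=list)

    def group_scores(self, label: GroupLabel) -> np.ndarray:
        return self.scores[self.groups == label].to_numpy()


class MinMaxCompositeScorer(BaseEstimator, TransformerMixin):
    """Direction-aware min-max normalizer and composite aggregator.

    Parameters
    ----------
    directions : mapping metric -> Direction (or its string value).  The keys
        define the included metrics and their column order.
    weights : optional mapping metric -> nonnegative weight (default: all 1).
    clip : clip transform-time values to the fitted bounds (default True).

    Fitted attributes: ``data_min_``, ``data_max_`` (per included metric) and
    ``feature_names_in_``.
    """

    def __init__(
        self,
        directions: Mapping[str, Direction | str],
        weights: Mapping[str, float] | None = None,
        clip: bool = True,
    ) -> None:
        self.directions = directions
        self.weights = weights
        self.clip = clip

    # -- sklearn API -------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None) -> "MinMaxCompositeScorer":
        metrics = list(self.directions)
        if not metrics:
            raise ValidationError("no metrics to score")
        X = self._as_frame(X, metrics)
        directions = {m: Direction(d) for m, d in self.directions.items()}
        if any(d is Direction.AMBIGUOUS for d in directions.values()):
            bad = [m for m, d in directions.items() if d is Direction.AMBIGUOUS]
            raise ValidationError(
                f"cannot normalize metrics with ambiguous direction: {bad}"
            )
        mins, maxs = {}, {}
        for m in metrics:
            col = X[m].dropna()
            if len(col) < 2:
                raise ValidationError(f"metric {m!r}: needs >= 2 observed values")
            lo, hi = float(col.min()), float(col.max())
            if hi == lo:
                raise ZeroRangeError(
                    f"metric {m!r} is constant ({lo}) over the normalization population"
                )
            mins[m], maxs[m] = lo, hi
        self.feature_names_in_ = np.asarray(metrics, dtype=object)
        self.data_min_ = mins
        self.data_max_ = maxs
        self.directions_ = directions
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-metric oriented 0-100 scores (participants x metrics)."""
        self._check_fitted()
        metrics = list(self.directions_)
        X = self._as_frame(X, metrics)
        out = {}
        for m in metrics:
            lo, hi = self.data_min_[m], self.data_max_[m]
            v = X[m].astype(float)
            if self.clip:
                v = v.clip(lo, hi)
            z = 100.0 * (v - lo) / (hi - lo)
            if self.directions_[m] is Direction.LOWER_BETTER:
                z = 100.0 - z
            out[m] = z
        return pd.DataFrame(out, index=X.index)

    def composite(self, X: pd.DataFrame) -> pd.Series:
        """Weighted mean of the normalized metric scores, in [0, 100]."""
        Z = self.transform(X)
        w = self._weight_vector()
        return Z.mul(w, axis=1).sum(axis=1) / w.sum()

    # -- internals ---------------------------------------------------------
    def _weight_vector(self) -> pd.Series:
        metrics = list(self.directions_)
        if self.weights is None:
            w = pd.Series(1.0, index=metrics)
        else:
            w = pd.Series({m: float(self.weights.get(m, 0.0)) for m in metrics})
        if (w < 0).any():
            raise ValidationError("weights must be nonnegative")
        if w.sum() <= 0:
            raise ValidationError("weights must sum to a positive value")
        return w

    def _check_fitted(self) -> None:
        if not hasattr(self, "data_min_"):
            raise ValidationError("scorer is not fitted; call fit() first")

    @staticmethod
    def _as_frame(X, metrics: list[str]) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, float), columns=metrics)
        missing = [m for m in metrics if m not in X.columns]
        if missing:
            raise ValidationError(f"input lacks metric columns {missing}")
        return X


# ---------------------------------------------------------------------------
# Cohort-level wrappers
# ---------------------------------------------------------------------------

def _directions_for(cohort: CohortTable, task: str, metrics: Sequence[str]):
    return {m: cohort.definition(task, m).direction for m in metrics}


def fit_normalization(
    cohort: CohortTable, task: str, metrics: Sequence[str]
) -> NormalizationMap:
    """Fit pooled min-max bounds for the selected metrics of a task."""
    frame, _ = cohort.metric_frame(task)
    scorer = MinMaxCompositeScorer(_directions_for(cohort, task, metrics)).fit(frame)
    return NormalizationMap(
        bounds={m: (scorer.data_min_[m], scorer.data_max_[m]) for m in metrics},
        directions=scorer.directions_,
    )


def normalize(value: float, metric: str, nmap: NormalizationMap) -> float:
    """Map one raw value onto the oriented 0-100 scale (out-of-range clipped)."""
    if metric not in nmap.bounds:
        raise ValidationError(f"metric {metric!r} absent from normalization map")
    lo, hi = nmap.bounds[metric]
    v = min(max(float(value), lo), hi)
    z = 100.0 * (v - lo) / (hi - lo)
    if nmap.directions[metric] is Direction.LOWER_BETTER:
        z = 100.0 - z
    return z


def composite_scores(
    cohort: CohortTable,
    task: str,
    metrics: Sequence[str],
    weights: Mapping[str, float] | None = None,
) -> CompositeScoreSet:
    """Composite 0-100 scores for every task participant with complete metrics.

    Participants missing any selected metric are dropped for this task with a
    logged warning (mirroring the study's task-level exclusions); nothing is
    imputed.
    """
    if not metrics:
        raise ValidationError("metric set must be nonempty")
    frame, groups = cohort.metric_frame(task)
    missing_cols = [m for m in metrics if m not in frame.columns]
    if missing_cols:
        raise ValidationError(f"task {task!r} has no observations for {missing_cols}")
    complete = frame[list(metrics)].notna().all(axis=1)
    dropped = list(frame.index[~complete])
    if dropped:
        logger.warning(
            "task %s: dropping %d participant(s) missing selected metrics: %s",
            task,
            len(dropped),
            dropped,
        )
    data = frame.loc[complete, list(metrics)]
    groups = groups.loc[complete]
    scorer = MinMaxCompositeScorer(
        _directions_for(cohort, task, metrics), weights=weights
    ).fit(data)
    scores = scorer.composite(data)
    summaries: dict[GroupLabel, tuple[float, float, int]] = {}
    for g in GroupLabel:
        s = scores[groups == g]
        if len(s):
            summaries[g] = (
                float(s.mean()),
                float(s.std(ddof=1)) if len(s) > 1 else 0.0,
                int(len(s)),
            )
    w = scorer._weight_vector()
    return CompositeScoreSet(
        scores=scores,
        groups=groups,
        included_metrics=list(metrics),
        weights={m: float(w[m]) for m in metrics},
        group_summaries=summaries,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# Sensitivity weighting
# ---------------------------------------------------------------------------

def separation(
    Z: pd.DataFrame,
    groups: pd.Series,
    weights: np.ndarray,
    lo: GroupLabel = GroupLabel.NOVICE,
    hi: GroupLabel = GroupLabel.ROBOTIC,
) -> float:
    """Standardized mean difference of the weighted composite between two groups."""
    w = np.asarray(weights, float)
    if w.sum() <= 0:
        return -np.inf
    comp = Z.to_numpy() @ (w / w.sum())
    a, b = comp[(groups == hi).to_numpy()], comp[(groups == lo).to_numpy()]
    pooled = np.sqrt(
        ((len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1))
        / (len(a) + len(b) - 2)
    )
    if pooled == 0:
        return 0.0
    return float((np.mean(a) - np.mean(b)) / pooled)


def sensitivity_weights(
    metrics: Sequence[str],
    scenario: str,
    cohort: CohortTable | None = None,
    task: str | None = None,
    lo: GroupLabel = GroupLabel.NOVICE,
    hi: GroupLabel = GroupLabel.ROBOTIC,
    n_starts: int = 8,
    seed: int = 0,
) -> dict[str, float]:
    """Weight scenarios for the composite sensitivity sub-analysis.

    ``uniform`` returns all-ones weights.  ``best_case`` / ``worst_case``
    search the weight simplex for the weights that maximize / minimize the
    standardized novice-robotic separation of the composite, via SLSQP from
    multiple starts (uniform, every vertex, and seeded Dirichlet draws); the
    uniform point is always a candidate, so best >= uniform >= worst holds by
    construction.
    """
    metrics = list(metrics)
    if not metrics:
        raise ValidationError("metric set must be nonempty")
    if scenario == "uniform":
        return {m: 1.0 for m in metrics}
    if scenario not in ("best_case", "worst_case"):
        raise ValidationError(f"unknown weighting scenario {scenario!r}")
    if cohort is None or task is None:
        raise ValidationError(f"{scenario} weighting requires a cohort and task")

    frame, groups = cohort.metric_frame(task)
    complete = frame[metrics].notna().all(axis=1)
    data, groups = frame.loc[complete, metrics], groups.loc[complete]
    scorer = MinMaxCompositeScorer(_directions_for(cohort, task, metrics)).fit(data)
    Z = scorer.transform(data)

    sign = -1.0 if scenario == "best_case" else 1.0
    k = len(metrics)

    def objective(w: np.ndarray) -> float:
        return sign * separation(Z, groups, w, lo=lo, hi=hi)

    rng = np.random.default_rng(seed)
    starts = [np.full(k, 1.0 / k)]
    starts += [np.eye(k)[i] * 0.98 + 0.02 / k for i in range(k)]
    starts += [rng.dirichlet(np.ones(k)) for _ in range(n_starts)]
    constraints = [{"type": "eq", "fun": lambda w: w.sum() - 1.0}]
    bounds = [(0.0, 1.0)] * k
    candidates = [np.full(k, 1.0 / k)] + [np.eye(k)[i] for i in range(k)]
    for w0 in starts:
        res = optimize.minimize(
            objective, w0, method="SLSQP", bounds=bounds, constraints=constraints
        )
        if res.success and res.x.sum() > 0:
            candidates.append(np.clip(res.x, 0, None))
    best = min(candidates, key=objective)
    best = best / best.sum()
    return {m: float(w) for m, w in zip(metrics, best)}
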