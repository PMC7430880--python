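"""Contrasting-groups standard setting.

The pass/fail cutoff between a less-experienced ("lo") and a more-experienced
("hi") group is the point where the two fitted normal score densities cross,
restricted to the interval strictly between the group means.  That crossing
point is exactly the cutoff minimizing the total theoretical error

    FP(c) + FN(c) = P(lo >= c) + P(hi < c),

with the pass rule "composite >= cutoff" (the boundary passes).  Theoretical
rates integrate the fitted normals; absolute rates are the empirical
fractions of the observed scores on the wrong side of the cutoff.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .cohort import GroupLabel, ValidationError
from .scoring import CompositeScoreSet

__all__ = [
    "GroupGaussian",
    "CutoffResult",
    "ContrastingGroupsStandard",
    "intersect_cutoff",
    "theoretical_rates",
    "absolute_rates",
    "contrasting_groups",
    "three_group_report",
]


@dataclass(frozen=True)
class GroupGaussian:
    """Normal model of one group's composite scores (mu, sigma on 0-100 scale)."""

    mu: float
    sigma: float
    n: int
    label: GroupLabel | str = ""

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValidationError(f"sigma must be > 0, got {self.sigma}")
        if self.n < 1:
            raise ValidationError(f"n must be >= 1, got {self.n}")


@dataclass
class CutoffResult:
    """A pass/fail standard between two groups with its error rates."""

    contrast: tuple[str, str]  # (lo label, hi label)
    cutoff: float | None
    fp_theoretical: float | None
    fn_theoretical: float | None
    fp_absolute: float | None
    fn_absolute: float | None
    method: str  # "analytic_intersection" | "numeric"
    computable: bool = True
    reason: str | None = None

    @classmethod
    def not_computable(cls, contrast: tuple[str, str], reason: str) -> "CutoffResult":
        return cls(
            contrast=contrast,
            cutoff=None,
            fp_theoretical=None,
            fn_theoretical=None,
            fp_absolute=None,
            fn_absolute=None,
            method="none",
            computable=False,
            reason=reason,
        )


def _numeric_cutoff(lo: GroupGaussian, hi: GroupGaussian) -> float:
    res = optimize.minimize_scalar(
        lambda c: sum(theoretical_rates(c, lo, hi)),
        bounds=(lo.mu, hi.mu),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def intersect_cutoff(lo: GroupGaussian, hi: GroupGaussian) -> tuple[float, str]:
    """Density-intersection cutoff strictly between the two group means.

    Equal sigmas give the midpoint.  Otherwise equating log-densities yields a
    quadratic whose between-means root is returned; if that root is
    numerically degenerate the cutoff falls back to bounded minimization of
    FP + FN over [lo.mu, hi.mu].  Returns (cutoff, method).
    """
    if not lo.mu < hi.mu:
        raise ValidationError(
            f"expected lo.mu < hi.mu, got {lo.mu} >= {hi.mu}: groups are not"
            " separated in the expected order"
        )
    if math.isclose(lo.sigma, hi.sigma, rel_tol=1e-12, abs_tol=1e-12):
        return (lo.mu + hi.mu) / 2.0, "analytic_intersection"
    a = 1.0 / lo.sigma**2 - 1.0 / hi.sigma**2
    b = -2.0 * (lo.mu / lo.sigma**2 - hi.mu / hi.sigma**2)
    c = (
        lo.mu**2 / lo.sigma**2
        - hi.mu**2 / hi.sigma**2
        + 2.0 * math.log(lo.sigma / hi.sigma)
    )
    disc = b * b - 4.0 * a * c
    if disc >= 0.0:
        sq = math.sqrt(disc)
        roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
        inside = [r for r in roots if lo.mu < r < hi.mu]
        if inside:
            return float(inside[0]), "analytic_intersection"
    return _numeric_cutoff(lo, hi), "numeric"


def theoretical_rates(
    cutoff: float, lo: GroupGaussian, hi: GroupGaussian
) -> tuple[float, float]:
    """(FP, FN) under the fitted normals: FP = P(lo >= c), FN = P(hi < c)."""
    fp = float(stats.norm.sf(cutoff, loc=lo.mu, scale=lo.sigma))
    fn = float(stats.norm.cdf(cutoff, loc=hi.mu, scale=hi.sigma))
    return fp, fn


def absolute_rates(
    cutoff: float, lo_scores: Sequence[float], hi_scores: Sequence[float]
) -> tuple[float, float]:
    """Empirical (FP, FN): fraction of lo >= cutoff, fraction of hi < cutoff."""
    lo_scores = np.asarray(lo_scores, float)
    hi_scores = np.asarray(hi_scores, float)
    if len(lo_scores) == 0 or len(hi_scores) == 0:
        raise ValidationError("score samples must be nonempty")
    return float(np.mean(lo_scores >= cutoff)), float(np.mean(hi_scores < cutoff))


class ContrastingGroupsStandard(BaseEstimator):
    """Contrasting-groups pass/fail standard as a fit/predict estimator.

    Fit on composite scores and group labels; the cutoff is the intersection
    of the two fitted group Gaussians (sample mean, SD with ddof=1).

    Fitted attributes: ``lo_``, ``hi_`` (GroupGaussian), ``cutoff_``,
    ``method_``, ``fp_theoretical_``, ``fn_theoretical_``, ``fp_absolute_``,
    ``fn_absolute_``.
    """

    def __init__(
        self,
        lo_label: GroupLabel = GroupLabel.NOVICE,
        hi_label: GroupLabel = GroupLabel.ROBOTIC,
    ) -> None:
        self.lo_label = lo_label
        self.hi_label = hi_label

    def fit(self, scores: Sequence[float], groups: Sequence) -> "ContrastingGroupsStandard":
        scores = np.asarray(scores, float)
        groups = np.asarray(list(groups), dtype=object)
        lo_scores = scores[groups == self.lo_label]
        hi_scores = scores[groups == self.hi_label]
        for label, sample in ((self.lo_label, lo_scores), (self.hi_label, hi_scores)):
            if len(sample) < 2:
                raise ValidationError(
                    f"group {label}: needs >= 2 composite scores, got {len(sample)}"
                )
            if np.std(sample, ddof=1) == 0:
                raise ValidationError(
                    f"group {label}: composite SD is zero; inspect the composite"
                    " construction before setting a standard"
                )
        self.lo_ = GroupGaussian(
            mu=float(np.mean(lo_scores)),
            sigma=float(np.std(lo_scores, ddof=1)),
            n=len(lo_scores),
            label=self.lo_label,
        )
        self.hi_ = GroupGaussian(
            mu=float(np.mean(hi_scores)),
            sigma=float(np.std(hi_scores, ddof=1)),
            n=len(hi_scores),
            label=self.hi_label,
        )
        self.cutoff_, self.method_ = intersect_cutoff(self.lo_, self.hi_)
        self.fp_theoretical_, self.fn_theoretical_ = theoretical_rates(
            self.cutoff_, self.lo_, self.hi_
        )
        self.fp_absolute_, self.fn_absolute_ = absolute_rates(
            self.cutoff_, lo_scores, hi_scores
        )
        return self

    def predict(self, scores: Sequence[float]) -> np.ndarray:
        """Pass/fail: True when composite >= cutoff (boundary passes)."""
        if not hasattr(self, "cutoff_"):
            raise ValidationError("standard is not fitted; call fit() first")
        return np.asarray(scores, float) >= self.cutoff_

    def result(self) -> CutoffResult:
        return CutoffResult(
            contrast=(_label_str(self.lo_label), _label_str(self.hi_label)),
            cutoff=self.cutoff_,
            fp_theoretical=self.fp_theoretical_,
            fn_theoretical=self.fn_theoretical_,
            fp_absolute=self.fp_absolute_,
            fn_absolute=self.fn_absolute_,
            method=self.method_,
        )


def _label_str(label) -> str:
    return label.value if isinstance(label, GroupLabel) else str(label)


def contrasting_groups(
    composites: CompositeScoreSet,
    lo_label: GroupLabel = GroupLabel.NOVICE,
    hi_label: GroupLabel = GroupLabel.ROBOTIC,
) -> CutoffResult:
    """Fit the contrasting-groups standard between two groups of a score set."""
    est = ContrastingGroupsStandard(lo_label=lo_label, hi_label=hi_label)
    est.fit(composites.scores.to_numpy(), composites.groups.to_numpy())
    return est.result()


#: Pairs reported for the three-group design: the two standards against the
#: robotic-experienced reference, plus novice-vs-laparoscopic when orderable.
_REPORT_PAIRS = (
    (GroupLabel.NOVICE, GroupLabel.ROBOTIC),
    (GroupLabel.LAPAROSCOPIC, GroupLabel.ROBOTIC),
    (GroupLabel.NOVICE, GroupLabel.LAPAROSCOPIC),
)


def three_group_report(composites: CompositeScoreSet) -> list[CutoffResult]:
    """Pairwise cutoffs over the three groups; unorderable pairs are flagged.

    A pair whose means are not separated in the expected order (or whose
    composite SD is zero) yields a flagged, not-computable entry rather than
    an abort, so partial reports remain available.
    """
    results: list[CutoffResult] = []
    for lo, hi in _REPORT_PAIRS:
        contrast = (lo.value, hi.value)
        try:
            results.append(contrasting_groups(composites, lo_label=lo, hi_label=hi))
        except ValidationError as exc:
            results.append(CutoffResult.not_computable(contrast, str(exc)))
    return results
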