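"""Composite scoring: normalization contracts, invariances, weighting."""
import logging

import numpy as np
import pandas as pd
import pytest

from simvalid.cohort import Direction, GroupLabel, ValidationError
from simvalid.scoring import (
    MinMaxCompositeScorer,
    ZeroRangeError,
    composite_scores,
    fit_normalization,
    normalize,
    sensitivity_weights,
    separation,
)
from simvalid.synthesis import GenerationSpec, generate_cohort

from conftest import toy_cohort


def _cohort_one_metric(values, direction=Direction.LOWER_BETTER):
    per_group = {
        GroupLabel.ROBOTIC: values[0::3],
        GroupLabel.LAPAROSCOPIC: values[1::3],
        GroupLabel.NOVICE: values[2::3],
    }
    return toy_cohort({"m": per_group}, directions={"m": direction})


class TestNormalization:
    def test_bounds_from_pooled_cohort(self):
        cohort = _cohort_one_metric([2.0, 4.0, 6.0])
        nmap = fit_normalization(cohort, "task1", ["m"])
        assert nmap.bounds["m"] == (2.0, 6.0)

    def test_zero_range_metric_rejected_by_name(self):
        cohort = _cohort_one_metric([3.0, 3.0, 3.0])
        with pytest.raises(ZeroRangeError, match="'m'"):
            fit_normalization(cohort, "task1", ["m"])

    def test_refit_changes_only_touched_metric(self):
        values = {
            "a": {g: [1.0, 5.0] for g in GroupLabel},
            "b": {g: [10.0, 20.0] for g in GroupLabel},
        }
        cohort = toy_cohort(values)
        before = fit_normalization(cohort, "task1", ["a", "b"])
        values["a"][GroupLabel.NOVICE] = [1.0, 9.0]  # outside the old range
        refit = fit_normalization(toy_cohort(values), "task1", ["a", "b"])
        assert refit.bounds["a"] == (1.0, 9.0)
        assert refit.bounds["b"] == before.bounds["b"]

    @pytest.mark.parametrize(
        "direction,expected",
        [
            (Direction.HIGHER_BETTER, {2.0: 0.0, 4.0: 50.0, 6.0: 100.0}),
            (Direction.LOWER_BETTER, {2.0: 100.0, 4.0: 50.0, 6.0: 0.0}),
        ],
    )
    def test_linear_scale_and_orientation(self, direction, expected):
        cohort = _cohort_one_metric([2.0, 4.0, 6.0], direction=direction)
        nmap = fit_normalization(cohort, "task1", ["m"])
        for raw, score in expected.items():
            assert normalize(raw, "m", nmap) == score

    def test_out_of_range_values_clip_to_bounds(self):
        cohort = _cohort_one_metric([2.0, 4.0, 6.0], direction=Direction.HIGHER_BETTER)
        nmap = fit_normalization(cohort, "task1", ["m"])
        assert normalize(7.0, "m", nmap) == 100.0
        assert normalize(-1.0, "m", nmap) == 0.0

    def test_unknown_metric_rejected(self):
        cohort = _cohort_one_metric([2.0, 4.0, 6.0])
        nmap = fit_normalization(cohort, "task1", ["m"])
        with pytest.raises(ValidationError):
            normalize(1.0, "other", nmap)

    def test_ambiguous_direction_cannot_be_normalized(self):
        scorer = MinMaxCompositeScorer({"m": Direction.AMBIGUOUS})
        with pytest.raises(ValidationError, match="ambiguous"):
            scorer.fit(pd.DataFrame({"m": [1.0, 2.0]}))


class TestCompositeScores:
    def test_extremes_map_to_0_and_100(self):
        cohort = toy_cohort(
            {"m": {GroupLabel.ROBOTIC: [1.0, 1.0], GroupLabel.LAPAROSCOPIC: [2.0, 2.0], GroupLabel.NOVICE: [9.0, 9.0]}},
        )
        comp = composite_scores(cohort, "task1", ["m"])
        scores = dict(zip(comp.scores.index, comp.scores))
        assert scores["robotic_0"] == 100.0  # lower_better: min is favorable
        assert scores["novice_0"] == 0.0

    def test_weighting_equals_metric_duplication(self, rng):
        base = pd.DataFrame(
            {
                "a": rng.uniform(0, 10, 12),
                "b": rng.uniform(5, 50, 12),
            }
        )
        dup = base.assign(a2=base["a"])
        weighted = MinMaxCompositeScorer(
            {"a": Direction.LOWER_BETTER, "b": Direction.HIGHER_BETTER},
            weights={"a": 2.0, "b": 1.0},
        ).fit(base).composite(base)
        duplicated = MinMaxCompositeScorer(
            {
                "a": Direction.LOWER_BETTER,
                "a2": Direction.LOWER_BETTER,
                "b": Direction.HIGHER_BETTER,
            }
        ).fit(dup).composite(dup)
        assert np.allclose(weighted, duplicated)

    def test_missing_metric_drops_participant_with_warning(self, caplog):
        cohort = toy_cohort(
            {
                "a": {g: [1.0, 2.0] for g in GroupLabel},
                "b": {
                    GroupLabel.ROBOTIC: [1.0],  # second robotic participant lacks b
                    GroupLabel.LAPAROSCOPIC: [2.0, 3.0],
                    GroupLabel.NOVICE: [4.0, 5.0],
                },
            }
        )
        with caplog.at_level(logging.WARNING):
            comp = composite_scores(cohort, "task1", ["a", "b"])
        assert comp.dropped == ["robotic_1"]
        assert "robotic_1" in caplog.text
        assert len(comp.scores) == 5

    def test_scores_bounded_and_permutation_invariant(self, registry, task1_summaries):
        spec = GenerationSpec(
            summaries=task1_summaries, group_sizes={g: 8 for g in GroupLabel}, seed=11
        )
        cohort = generate_cohort(spec, registry=registry)
        metrics = ["path_length_left", "total_time", "needle_precision"]
        comp = composite_scores(cohort, "task1", metrics)
        assert ((comp.scores >= 0) & (comp.scores <= 100)).all()
        shuffled = type(cohort)(
            records=list(reversed(cohort.records)), registry=cohort.registry
        )
        comp2 = composite_scores(shuffled, "task1", metrics)
        assert comp.scores.sort_index().equals(comp2.scores.sort_index())

    @pytest.mark.parametrize("seed", range(10))
    def test_affine_invariance_of_raw_metric_units(self, seed, registry, task1_summaries):
        """Composite is unchanged by positive affine rescaling of a raw metric."""
        spec = GenerationSpec(
            summaries=task1_summaries, group_sizes={g: 6 for g in GroupLabel}, seed=seed
        )
        cohort = generate_cohort(spec, registry=registry)
        metrics = ["path_length_left", "total_time"]
        before = composite_scores(cohort, "task1", metrics).scores
        rng = np.random.default_rng(seed)
        a, b = rng.uniform(0.1, 10), rng.uniform(0, 100)
        for rec in cohort.records:
            rec.metrics["task1"]["total_time"] = (
                a * rec.metrics["task1"]["total_time"] + b
            )
        after = composite_scores(cohort, "task1", metrics).scores
        assert np.allclose(before, after, atol=1e-9)

    def test_empty_metric_set_rejected(self):
        cohort = _cohort_one_metric([1.0, 2.0, 3.0])
        with pytest.raises(ValidationError):
            composite_scores(cohort, "task1", [])

    def test_robotic_exceeds_novice_in_every_seed(self, registry, task1_summaries):
        sizes = {
            GroupLabel.NOVICE: 29,
            GroupLabel.LAPAROSCOPIC: 26,
            GroupLabel.ROBOTIC: 15,
        }
        metrics = [
            "path_length_left",
            "path_length_right",
            "movements_left",
            "movements_right",
            "inaccurate_punctures",
            "instrument_collisions",
            "needle_precision",
            "total_time",
        ]
        for seed in range(1, 21):
            spec = GenerationSpec(summaries=task1_summaries, group_sizes=sizes, seed=seed)
            comp = composite_scores(
                generate_cohort(spec, registry=registry), "task1", metrics
            )
            assert (
                comp.group_summaries[GroupLabel.ROBOTIC][0]
                > comp.group_summaries[GroupLabel.NOVICE][0]
            )


class TestSensitivityWeights:
    def test_uniform_is_all_ones(self):
        assert sensitivity_weights(["a", "b", "c", "d"], "uniform") == {
            "a": 1.0,
            "b": 1.0,
            "c": 1.0,
            "d": 1.0,
        }

    def test_empty_metrics_rejected(self):
        with pytest.raises(ValidationError):
            sensitivity_weights([], "uniform")

    def _two_metric_cohort(self, rng):
        # metric "sep" separates novice from robotic, "noise" does not
        return toy_cohort(
            {
                "sep": {
                    GroupLabel.ROBOTIC: rng.normal(10, 1, 12),
                    GroupLabel.LAPAROSCOPIC: rng.normal(20, 1, 12),
                    GroupLabel.NOVICE: rng.normal(30, 1, 12),
                },
                "noise": {
                    GroupLabel.ROBOTIC: rng.normal(50, 5, 12),
                    GroupLabel.LAPAROSCOPIC: rng.normal(50, 5, 12),
                    GroupLabel.NOVICE: rng.normal(50, 5, 12),
                },
            }
        )

    def test_best_case_concentrates_on_separating_metric(self, rng):
        cohort = self._two_metric_cohort(rng)
        best = sensitivity_weights(
            ["sep", "noise"], "best_case", cohort=cohort, task="task1"
        )
        # grid-search oracle over the 1-simplex
        frame, groups = cohort.metric_frame("task1")
        scorer = MinMaxCompositeScorer(
            {"sep": Direction.LOWER_BETTER, "noise": Direction.LOWER_BETTER}
        ).fit(frame)
        Z = scorer.transform(frame)
        grid = np.linspace(0, 1, 2001)
        seps = [separation(Z, groups, np.array([w, 1 - w])) for w in grid]
        oracle_w = grid[int(np.argmax(seps))]
        assert best["sep"] == pytest.approx(oracle_w, abs=0.01)
        assert best["sep"] > 0.95

    def test_scenario_separation_ordering(self, rng):
        cohort = self._two_metric_cohort(rng)
        frame, groups = cohort.metric_frame("task1")
        scorer = MinMaxCompositeScorer(
            {"sep": Direction.LOWER_BETTER, "noise": Direction.LOWER_BETTER}
        ).fit(frame)
        Z = scorer.transform(frame)

        def sep_for(scenario):
            w = sensitivity_weights(
                ["sep", "noise"], scenario, cohort=cohort, task="task1"
            )
            return separation(Z, groups, np.array([w["sep"], w["noise"]]))

        best, uniform, worst = (
            sep_for("best_case"),
            separation(Z, groups, np.array([1.0, 1.0])),
            sep_for("worst_case"),
        )
        assert best >= uniform >= worst
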