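"""Two-sample screening, Likert content aggregation and parameter selection."""
import numpy as np
import pytest
from scipy import stats

from simvalid.cohort import Direction, GroupLabel, ValidationError
from simvalid.screen import (
    compare_groups,
    gated_t_test,
    levene_test,
    likert_content,
    normality_check,
    overall_content_means,
    screen_summaries,
    screen_task,
    select_construct_parameters,
    student_t_summary,
    welch_t_summary,
)
from simvalid.synthesis import GenerationSpec, generate_cohort

from conftest import toy_cohort


class TestSummaryTTests:
    @pytest.mark.parametrize("func", [student_t_summary, welch_t_summary])
    def test_identical_summaries_give_null_result(self, func):
        report = func(10.0, 2.0, 12, 10.0, 2.0, 12)
        assert report.t == 0.0
        assert report.p == 1.0

    def test_task1_total_time_printed_p_both_forms(self):
        """Laparoscopic vs novice total time: both forms print as p = 0.047."""
        student = student_t_summary(475, 219, 26, 597, 225, 29)
        welch = welch_t_summary(475, 219, 26, 597, 225, 29)
        assert round(student.p, 3) == 0.047
        assert round(welch.p, 3) == 0.047
        assert student.df == 53

    def test_task3_distance_printed_p_welch_form(self):
        """Robotic vs laparoscopic scope distance prints as p = 0.001 (Welch)."""
        assert round(welch_t_summary(94, 20, 15, 116, 10, 26).p, 3) == 0.001

    @pytest.mark.parametrize("func", [student_t_summary, welch_t_summary])
    def test_degenerate_inputs_rejected(self, func):
        with pytest.raises(ValidationError):
            func(1.0, 0.0, 10, 2.0, 0.0, 10)
        with pytest.raises(ValidationError):
            func(1.0, 1.0, 1, 2.0, 1.0, 10)

    @pytest.mark.parametrize("seed", range(5))
    def test_summary_test_matches_record_level_on_matched_moments(self, seed):
        """Summary-based t equals the record-level t on data with those moments."""
        rng = np.random.default_rng(seed)
        m1, s1, n1 = rng.uniform(0, 100), rng.uniform(1, 20), rng.integers(5, 30)
        m2, s2, n2 = rng.uniform(0, 100), rng.uniform(1, 20), rng.integers(5, 30)
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        x = (x - x.mean()) / x.std(ddof=1) * s1 + m1
        y = (y - y.mean()) / y.std(ddof=1) * s2 + m2
        for equal_var, func in ((True, student_t_summary), (False, welch_t_summary)):
            record = stats.ttest_ind(x, y, equal_var=equal_var)
            summary = func(m1, s1, int(n1), m2, s2, int(n2))
            assert summary.t == pytest.approx(record.statistic, abs=1e-10)
            assert summary.p == pytest.approx(record.pvalue, abs=1e-10)


class TestLevene:
    def test_identical_samples(self):
        res = levene_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_matches_brute_force_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([10.0, 20.0, 30.0, 40.0])
        zx, zy = np.abs(x - x.mean()), np.abs(y - y.mean())
        z = np.concatenate([zx, zy])
        num = len(x) * (zx.mean() - z.mean()) ** 2 + len(y) * (zy.mean() - z.mean()) ** 2
        den = ((zx - zx.mean()) ** 2).sum() + ((zy - zy.mean()) ** 2).sum()
        W = (len(z) - 2) / (2 - 1) * num / den
        expected_p = stats.f.sf(W, 1, len(z) - 2)
        res = levene_test(x, y)
        assert res.statistic == pytest.approx(W, rel=1e-12)
        assert res.pvalue == pytest.approx(expected_p, rel=1e-12)

    def test_constant_samples_statistic_zero(self):
        assert levene_test([2.0, 2.0, 2.0], [5.0, 5.0]).statistic == 0.0

    def test_small_sample_rejected(self):
        with pytest.raises(ValidationError):
            levene_test([1.0], [1.0, 2.0])


class TestNormalityCheck:
    def test_small_sample_rejected(self):
        with pytest.raises(ValidationError):
            normality_check([1.0, 2.0])

    def test_calibrated_under_normality(self):
        rejections = 0
        n_seeds = 400
        for seed in range(n_seeds):
            x = np.random.default_rng(seed).normal(size=500)
            rejections += normality_check(x) < 0.05
        assert 0.02 <= rejections / n_seeds <= 0.09

    def test_detects_heavy_skew(self):
        detected = sum(
            normality_check(np.exp(np.random.default_rng(seed).normal(size=200))) < 0.05
            for seed in range(200)
        )
        assert detected / 200 > 0.95


class TestGatedTest:
    def test_welch_chosen_when_variances_differ(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0, 10, 40)
        report = gated_t_test(x, y)
        assert report.method == "welch"
        assert report.levene_p < 0.05

    def test_student_chosen_when_variances_match(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 40)
        y = rng.normal(1, 1, 40)
        report = gated_t_test(x, y)
        assert report.method == "student"
        assert report.df == 78


class TestCompareGroups:
    def test_advantage_follows_direction(self):
        cohort = toy_cohort(
            {
                "time": {
                    GroupLabel.ROBOTIC: [10, 11, 12],
                    GroupLabel.LAPAROSCOPIC: [20, 21, 22],
                    GroupLabel.NOVICE: [30, 31, 32],
                }
            }
        )
        res = compare_groups(cohort, "task1", "time")
        assert res.advantage["robotic_vs_novice"] is GroupLabel.ROBOTIC
        assert res.significant_rvn

    def test_empty_group_rejected(self):
        cohort = toy_cohort(
            {
                "time": {
                    GroupLabel.ROBOTIC: [10, 11],
                    GroupLabel.LAPAROSCOPIC: [20, 21],
                    GroupLabel.NOVICE: [],
                }
            }
        )
        with pytest.raises(ValidationError, match="novice"):
            compare_groups(cohort, "task1", "time")

    def test_tied_means_give_no_advantage(self):
        cohort = toy_cohort(
            {
                "time": {
                    GroupLabel.ROBOTIC: [10, 20],
                    GroupLabel.LAPAROSCOPIC: [14, 16],
                    GroupLabel.NOVICE: [5, 25],
                }
            }
        )
        res = compare_groups(cohort, "task1", "time")
        assert res.advantage["robotic_vs_novice"] is None

    def test_table4_bold_pattern_recovered_in_majority_of_seeds(
        self, registry, task1_summaries
    ):
        """Synthetic screens reproduce >= 7 of the 8 construct-valid metrics."""
        bold = {
            "path_length_left",
            "path_length_right",
            "movements_left",
            "movements_right",
            "inaccurate_punctures",
            "instrument_collisions",
            "needle_precision",
            "total_time",
        }
        sizes = {
            GroupLabel.NOVICE: 29,
            GroupLabel.LAPAROSCOPIC: 26,
            GroupLabel.ROBOTIC: 15,
        }
        hits = 0
        for seed in range(1, 21):
            spec = GenerationSpec(
                summaries=task1_summaries, group_sizes=sizes, seed=seed
            )
            cohort = generate_cohort(spec, registry=registry)
            results = screen_task(cohort, "task1")
            significant = {r.metric for r in results if r.significant_rvn}
            hits += len(bold & significant) >= 7
        assert hits > 10


class TestLikertContent:
    def test_unanimous_agreement(self):
        likert = {
            g: {"realism": [[5, 5], [5, 5]]}
            for g in GroupLabel
        }
        cohort = toy_cohort(
            {"time": {g: [1, 2] for g in GroupLabel}}, likert=likert
        )
        (res,) = likert_content(cohort, "task1")
        assert res.total_mean == 5.0
        assert res.positive

    def test_boundary_mean_is_not_positive(self):
        likert = {
            g: {"realism": [[3, 4], [3, 4]]}
            for g in GroupLabel
        }
        cohort = toy_cohort(
            {"time": {g: [1, 2] for g in GroupLabel}}, likert=likert
        )
        (res,) = likert_content(cohort, "task1")
        assert res.total_mean == 3.5
        assert not res.positive

    def test_missing_likert_rejected(self):
        cohort = toy_cohort({"time": {g: [1, 2] for g in GroupLabel}})
        with pytest.raises(ValidationError):
            likert_content(cohort, "task1")


class TestSelection:
    def test_task1_selection_from_printed_summaries(self, registry, task1_summaries):
        results = screen_summaries(task1_summaries, registry, "task1")
        assert select_construct_parameters(results, registry) == [
            "path_length_left",
            "path_length_right",
            "movements_left",
            "movements_right",
            "inaccurate_punctures",
            "instrument_collisions",
            "needle_precision",
            "total_time",
        ]

    def test_task3_ambiguous_metrics_never_selected(self, registry):
        from simvalid.cohort import SUMMARY_FIXTURES, fixture_path, load_summary_fixture

        summaries = load_summary_fixture(fixture_path(SUMMARY_FIXTURES["task3"]))
        results = screen_summaries(summaries, registry, "task3")
        selected = select_construct_parameters(results, registry)
        assert "times_out_of_view" not in selected
        assert "distance_scope_and_tissue" not in selected
        # significant R-vs-N contrast alone is not sufficient for inclusion
        times = next(r for r in results if r.metric == "times_out_of_view")
        assert times.significant_rvn

    def test_exclude_override_removes_metric(self, registry, task1_summaries):
        results = screen_summaries(task1_summaries, registry, "task1")
        selected = select_construct_parameters(
            results, registry, exclude=["needle_precision"]
        )
        assert "needle_precision" not in selected
        assert len(selected) == 7

    def test_unknown_override_rejected(self, registry, task1_summaries):
        results = screen_summaries(task1_summaries, registry, "task1")
        with pytest.raises(ValidationError, match="warp_speed"):
            select_construct_parameters(results, registry, include=["warp_speed"])

    def test_no_significant_metrics_empty_selection(self, registry):
        cohort = toy_cohort(
            {
                "time": {
                    GroupLabel.ROBOTIC: [10, 11, 12, 13],
                    GroupLabel.LAPAROSCOPIC: [10, 12, 11, 13],
                    GroupLabel.NOVICE: [11, 12, 10, 13],
                }
            }
        )
        results = [compare_groups(cohort, "task1", "time")]
        assert select_construct_parameters(results, cohort.registry) == []


def test_overall_content_means_from_fixture(likert_summaries):
    means = overall_content_means(likert_summaries)
    assert means == {"realism": 3.7, "didactic_value": 4.0, "usability": 4.2}
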