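"""Aggregation curves, outperformance, age stratification, diversity,
bootstrap and the skill-selection sweep."""

import numpy as np
import pytest

from crowdtrace.analysis import (
    _mean_err,
    age_error_profile,
    between_subject_curve,
    bootstrap_ci,
    diversity_score,
    group_comparison,
    outperformance_from_errors,
    outperformance_percentile,
    skill_selection_sweep,
    within_subject_curve,
    woc_trajectory,
)
from crowdtrace.io import Cohort, SubjectMeta
from crowdtrace.preprocess import ProcessedCohort, ProcessedTemplate
from crowdtrace.templates import Template


def _make_processed(points, ages=None, refs=None, method="median"):
    """Build a ProcessedCohort from a raw (S, G, R, 2) offsets-from-refs array."""
    points = np.asarray(points, dtype=float)
    S, G, R, _ = points.shape
    if refs is None:
        theta = np.linspace(0, 2 * np.pi, R, endpoint=False)
        refs = np.stack([100 + 30 * np.cos(theta), 67 + 30 * np.sin(theta)], 1)
    tpl = Template(name="custom", dense_polyline=np.vstack([refs, refs[:1]]),
                   n_ref=R, reference_points=np.asarray(refs, float))
    if ages is None:
        ages = np.full(S, 12.0)
    pt = ProcessedTemplate(
        template=tpl,
        subject_ids=[f"s{i}" for i in range(S)],
        ages=np.asarray(ages, float),
        points=points + refs,
        counts=np.ones((S, G, R), dtype=int),
    )
    subjects = [SubjectMeta(f"s{i}", age=float(pt.ages[i])) for i in range(S)]
    return ProcessedCohort(templates={"custom": pt}, subjects=subjects,
                           n_segments=G, method=method)


class TestWithinSubjectCurve:
    def test_k1_equals_mean_individual_error(self, small_processed):
        curve = within_subject_curve(small_processed, "ellipse", k_values=[1],
                                     n_boot=0)
        pt = small_processed["ellipse"]
        direct = float(np.mean(np.nanmean(pt.individual_errors(), axis=1)))
        assert curve.mean_errors[0] == pytest.approx(direct, rel=1e-12)
        assert curve.n_combinations[0] == 8

    def test_k8_is_single_full_aggregate(self, small_processed):
        curve = within_subject_curve(small_processed, "ellipse", k_values=[8],
                                     n_boot=0)
        assert curve.n_combinations[0] == 1
        pt = small_processed["ellipse"]
        from crowdtrace.aggregate import aggregate_points

        per_subject = [
            float(_mean_err(aggregate_points(pt.points[i], "median"), pt))
            for i in range(pt.n_subjects)
        ]
        assert curve.mean_errors[0] == pytest.approx(np.mean(per_subject))

    def test_subset_counts_follow_binomial_coefficients(self, small_processed):
        from math import comb

        curve = within_subject_curve(small_processed, "ellipse",
                                     k_values=[2, 3, 5], n_boot=0)
        np.testing.assert_array_equal(
            curve.n_combinations, [comb(8, k) for k in (2, 3, 5)]
        )

    def test_invalid_k_rejected(self, small_processed):
        with pytest.raises(ValueError):
            within_subject_curve(small_processed, "ellipse", k_values=[9])


class TestBetweenSubjectCurve:
    def test_n1_matches_mean_individual_error(self, small_processed):
        pt = small_processed["ellipse"]
        indiv = pt.individual_errors().ravel()
        curve = between_subject_curve(small_processed, "ellipse", n_values=[1],
                                      n_reps=4000, seed=0)
        se = np.nanstd(indiv) / np.sqrt(4000)
        assert abs(curve.mean_errors[0] - np.nanmean(indiv)) < 3 * se

    def test_seeded_determinism(self, small_processed):
        a = between_subject_curve(small_processed, "ellipse",
                                  n_values=[2, 8], n_reps=300, seed=7)
        b = between_subject_curve(small_processed, "ellipse",
                                  n_values=[2, 8], n_reps=300, seed=7)
        np.testing.assert_array_equal(a.mean_errors, b.mean_errors)

    def test_monotone_decreasing_in_crowd_size(self, small_processed):
        curve = between_subject_curve(small_processed, "ellipse",
                                      n_values=[1, 2, 4, 8, 16], n_reps=1500,
                                      seed=3)
        diffs = np.diff(curve.mean_errors)
        assert np.all(diffs < 0.05 * curve.mean_errors[:-1])

    def test_crowd_size_exceeding_cohort_rejected(self, small_processed):
        with pytest.raises(ValueError, match="exceeds"):
            between_subject_curve(small_processed, "ellipse",
                                  n_values=[100], n_reps=10, seed=0)

    def test_bootstrap_ci_brackets_mean(self, small_processed):
        curve = between_subject_curve(small_processed, "ellipse",
                                      n_values=[4], n_reps=400, seed=1,
                                      n_boot=40, reps_per_boot=200)
        assert curve.ci_low[0] < curve.mean_errors[0] < curve.ci_high[0]


class TestOutperformance:
    def test_extreme_cases(self):
        errors = np.array([1.0, 2.0, 3.0])
        assert outperformance_from_errors(errors, 0.5) == 100.0
        assert outperformance_from_errors(errors, 5.0) == 0.0

    def test_counting_oracle(self, small_processed):
        res = outperformance_percentile(small_processed, "ellipse")
        count = sum(1 for e in res.individual_errors if e > res.woc_error)
        assert res.percentile == pytest.approx(
            100.0 * count / len(res.individual_errors)
        )
        assert res.hist_counts.sum() == len(res.individual_errors)

    def test_invariant_to_error_rescaling(self, rng):
        errors = rng.gamma(2.0, 1.0, size=500)
        woc = 0.7
        base = outperformance_from_errors(errors, woc)
        for scale in (0.3, 2.0, 17.5):
            assert outperformance_from_errors(scale * errors, scale * woc) == base


class TestAgeErrorProfile:
    def test_constant_error_field_maps_every_age_to_it(self):
        S, G, R = 12, 4, 10
        offsets = np.zeros((S, G, R, 2))
        offsets[..., 0] = 2.0  # every trajectory exactly 2 mm off
        ages = np.repeat([6.0, 9.0, 13.0, 17.0], 3)
        proc = _make_processed(offsets, ages=ages)
        prof = age_error_profile(proc, n_boot=10, seed=0)
        assert set(prof.index) == {6, 9, 13, 17}
        np.testing.assert_allclose(prof["error_mm"], 2.0)

    def test_single_age_cohort_degenerates_to_overall_mean(self, rng):
        offsets = rng.normal(size=(6, 4, 10, 2))
        proc = _make_processed(offsets, ages=np.full(6, 11.3))
        prof = age_error_profile(proc, n_boot=0)
        pt = proc["custom"]
        overall = float(np.mean(np.nanmean(pt.individual_errors(), axis=1)))
        assert list(prof.index) == [11]
        assert prof["error_mm"].iloc[0] == pytest.approx(overall)

    def test_decreasing_with_age_on_synthetic_cohort(self, default_processed):
        from scipy.stats import spearmanr

        for seed in (0, 1, 2):
            prof = age_error_profile(default_processed[seed], n_boot=0)
            rho, p = spearmanr(prof.index, prof["error_mm"])
            assert rho < 0 and p < 0.01


class TestGroupComparison:
    def test_exchangeable_groups_are_statistically_equal(self, rng):
        # same error structure at every age: group split is arbitrary
        offsets = rng.normal(scale=2.0, size=(40, 8, 20, 2))
        ages = np.linspace(6, 18, 40)
        proc = _make_processed(offsets, ages=ages)
        comp = group_comparison(proc, "custom", n_boot=200, seed=0)
        lo, hi = comp.ci["individual_old"]
        assert lo <= comp.individual_young * 1.05 and comp.individual_young * 0.95 <= hi

    def test_empty_group_rejected(self, rng):
        proc = _make_processed(rng.normal(size=(5, 2, 6, 2)),
                               ages=np.full(5, 8.0))
        with pytest.raises(ValueError, match="empty age group"):
            group_comparison(proc, "custom", age_threshold=3.5, n_boot=0)

    def test_young_crowd_beats_old_individual_across_thresholds(
        self, default_processed
    ):
        # qualitative robustness of the age split to the threshold choice
        proc = default_processed[0]
        for thr in (9.0, 10.5, 12.0):
            for name in proc.template_names:
                comp = group_comparison(proc, name, age_threshold=thr, n_boot=0)
                assert comp.individual_young > comp.individual_old
                assert comp.woc_young < comp.individual_old


class TestDiversity:
    def test_identical_individuals_have_zero_diversity(self, rng):
        one = rng.normal(size=(1, 1, 8, 2))
        proc = _make_processed(np.repeat(np.repeat(one, 5, axis=0), 3, axis=1))
        assert diversity_score(proc, "custom") == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_pair_diversity_equals_offset(self):
        R = 8
        offsets = np.zeros((2, 1, R, 2))
        offsets[0, ..., 1] = 1.8
        offsets[1, ..., 1] = -1.8
        proc = _make_processed(offsets, method="mean")
        assert diversity_score(proc, "custom", method="mean") == pytest.approx(1.8)

    def test_matches_bruteforce_double_loop(self, small_processed):
        got = diversity_score(small_processed, "ellipse")
        pt = small_processed["ellipse"]
        collective = woc_trajectory(pt, method="median", per_subject="first")
        dists = []
        for i in range(pt.n_subjects):
            for g in range(pt.n_segments):
                per_bin = []
                for k in range(pt.template.n_ref):
                    p = pt.points[i, g, k]
                    c = collective[k]
                    if not (np.isnan(p).any() or np.isnan(c).any()):
                        per_bin.append(np.hypot(p[0] - c[0], p[1] - c[1]))
                dists.append(np.mean(per_bin))
        assert got == pytest.approx(np.mean(dists), rel=1e-9)


class TestBootstrapCI:
    @staticmethod
    def _age_cohort(n=25, seed=0):
        rng = np.random.default_rng(seed)
        subjects = [SubjectMeta(f"s{i}", age=float(a))
                    for i, a in enumerate(rng.uniform(6, 18, n))]
        return Cohort(subjects=subjects)

    def test_constant_statistic_gives_degenerate_interval(self):
        lo, hi = bootstrap_ci(lambda c: 3.25, self._age_cohort(), n_boot=50,
                              seed=0)
        assert lo == hi == 3.25

    def test_seeded_determinism(self):
        cohort = self._age_cohort()
        stat = lambda c: np.mean([s.age for s in c.subjects])  # noqa: E731
        assert bootstrap_ci(stat, cohort, n_boot=100, seed=5) == \
            bootstrap_ci(stat, cohort, n_boot=100, seed=5)

    def test_interval_brackets_point_estimate(self):
        cohort = self._age_cohort(40, seed=3)
        stat = lambda c: np.mean([s.age for s in c.subjects])  # noqa: E731
        lo, hi = bootstrap_ci(stat, cohort, n_boot=300, seed=1)
        assert lo < stat(cohort) < hi

    def test_failing_statistic_propagates_with_context(self):
        def bad(_):
            raise KeyError("boom")

        with pytest.raises(RuntimeError, match="resample"):
            bootstrap_ci(bad, self._age_cohort(), n_boot=5, seed=0)


class TestSkillSelectionSweep:
    def test_limits_of_selector_noise(self, small_processed):
        res = skill_selection_sweep(small_processed, "ellipse", seed=0)
        skills = res.subject_errors
        assert res.selected_errors[0] == pytest.approx(np.min(skills))
        assert res.selected_errors[-1] == pytest.approx(np.mean(skills))
        # more selector noise should not improve the selection (weak check)
        assert res.selected_errors[0] <= res.selected_errors[-1]

    def test_crossover_matches_quantile_scan(self, small_processed):
        res = skill_selection_sweep(small_processed, "ellipse", seed=0)
        e = np.sort(res.subject_errors)
        count_better = int(np.searchsorted(e, res.woc_error, side="left"))
        assert res.crossover_percentile == pytest.approx(
            100.0 * count_better / len(e)
        )
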