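"""Splicing traces into equal-duration slices and subsampling to one point
per reference bin."""

import numpy as np
import pytest

from crowdtrace.io import TraceRecord
from crowdtrace.preprocess import (
    RawIndividualTrajectory,
    assign_bins,
    process_cohort,
    splice_trace,
    subsample_individual,
)
from crowdtrace.templates import Template, build_template


def _fake_template(refs):
    """Template stub with hand-chosen reference points."""
    refs = np.asarray(refs, dtype=float)
    poly = np.vstack([refs, refs[0]])
    return Template(name="custom", dense_polyline=poly, n_ref=len(refs),
                    reference_points=refs)


class TestSpliceTrace:
    def test_uniform_85hz_trace_splits_evenly(self):
        t = np.arange(2551) / 85.0  # 30 s at 85 Hz
        pts = np.stack([t, t], axis=1)
        trace = TraceRecord("s", "e", t, pts)
        segs = splice_trace(trace, 8)
        counts = [s.n_samples for s in segs]
        assert sum(counts) == 2551
        assert max(counts) - min(counts) <= 1
        # brute-force assignment by timestamp
        expected = np.minimum((8 * t / t[-1]).astype(int), 7)
        got = np.concatenate([[s.segment_index] * s.n_samples for s in segs])
        np.testing.assert_array_equal(got, expected)
        for s in segs:
            span = s.timestamps[-1] - s.timestamps[0]
            assert span == pytest.approx(3.75, abs=2 / 85.0)

    def test_single_segment_is_identity(self):
        t = np.linspace(0, 30, 100)
        trace = TraceRecord("s", "e", t, np.zeros((100, 2)))
        (seg,) = splice_trace(trace, 1)
        np.testing.assert_array_equal(seg.timestamps, trace.timestamps)
        np.testing.assert_array_equal(seg.points, trace.points)

    @pytest.mark.parametrize("n_segments", [5, 8, 12])
    def test_alternative_segment_counts(self, n_segments):
        t = np.linspace(0, 30, 600)
        trace = TraceRecord("s", "e", t, np.zeros((600, 2)))
        segs = splice_trace(trace, n_segments)
        assert len(segs) == n_segments

    def test_splicing_conserves_samples(self):
        rng = np.random.default_rng(0)
        t = np.sort(rng.uniform(0, 30, 500))
        t = np.unique(t)
        pts = rng.normal(size=(len(t), 2))
        trace = TraceRecord("s", "e", t, pts)
        segs = splice_trace(trace, 8)
        np.testing.assert_array_equal(
            np.concatenate([s.timestamps for s in segs]), t
        )
        np.testing.assert_array_equal(
            np.vstack([s.points for s in segs]), pts
        )

    def test_empty_segment_rejected(self):
        trace = TraceRecord("s", "e", [0.0, 1.0, 30.0], np.zeros((3, 2)))
        with pytest.raises(ValueError, match="empty"):
            splice_trace(trace, 8)


class TestAssignBins:
    def test_coincident_point_gets_its_bin(self):
        refs = np.array([[0, 0], [5, 0], [10, 0], [15, 0]], float)
        tpl = _fake_template(refs)
        labels = assign_bins(refs[2][None], tpl)
        assert labels[0] == 2

    def test_tie_broken_toward_lowest_index(self):
        refs = np.full((8, 2), 100.0)
        refs[3] = [0.0, 1.0]
        refs[7] = [0.0, -1.0]
        tpl = _fake_template(refs)
        assert assign_bins(np.array([[0.0, 0.0]]), tpl)[0] == 3

    def test_matches_bruteforce_nearest_neighbour(self, rng):
        tpl = build_template("four_petal", n_dense=1200)
        pts = rng.uniform([40, 10], [180, 120], size=(1000, 2))
        labels = assign_bins(pts, tpl)
        refs = tpl.reference_points
        oracle = []
        for p in pts:  # independent scalar-loop oracle
            best, best_d = -1, np.inf
            for k in range(len(refs)):
                d = float(np.hypot(p[0] - refs[k, 0], p[1] - refs[k, 1]))
                if d < best_d:
                    best, best_d = k, d
            oracle.append(best)
        np.testing.assert_array_equal(labels, oracle)


class TestSubsample:
    def test_points_on_reference_points_are_identity(self):
        tpl = build_template("ellipse", n_dense=800)
        refs = tpl.reference_points
        raw = RawIndividualTrajectory("s", "ellipse", 0,
                                      np.arange(len(refs), dtype=float), refs)
        traj = subsample_individual(raw, tpl)
        np.testing.assert_allclose(traj.aligned_points, refs)
        assert np.all(traj.bin_counts == 1)

    def test_odd_count_median_in_one_bin(self):
        refs = np.array([[0.0, 0.0], [100.0, 100.0]])
        tpl = _fake_template(refs)
        pts = np.array([[0, 0], [2, 0], [10, 0]], float)
        raw = RawIndividualTrajectory("s", "custom", 0, np.arange(3.0), pts)
        traj = subsample_individual(raw, tpl, method="median")
        np.testing.assert_allclose(traj.aligned_points[0], [2.0, 0.0])
        assert np.isnan(traj.aligned_points[1]).all()
        assert traj.coverage == 0.5

    def test_matches_bruteforce_groupby_median(self, rng):
        tpl = build_template("thin_ellipse", n_dense=900)
        pts = rng.normal(loc=[108, 67.5], scale=25, size=(400, 2))
        raw = RawIndividualTrajectory("s", "thin_ellipse", 0,
                                      np.arange(400.0), pts)
        traj = subsample_individual(raw, tpl, method="median")
        labels = assign_bins(pts, tpl)
        for k in range(tpl.n_ref):
            grp = pts[labels == k]
            if len(grp):
                np.testing.assert_array_equal(
                    traj.aligned_points[k],
                    [np.median(grp[:, 0]), np.median(grp[:, 1])],
                )
                assert traj.bin_counts[k] == len(grp)
            else:
                assert np.isnan(traj.aligned_points[k]).all()

    def test_invariant_to_within_bin_order(self, rng):
        tpl = build_template("ellipse", n_dense=800)
        pts = rng.normal(loc=[108, 67.5], scale=20, size=(300, 2))
        raw = RawIndividualTrajectory("s", "ellipse", 0, np.arange(300.0), pts)
        perm = rng.permutation(300)
        raw2 = RawIndividualTrajectory("s", "ellipse", 0, np.arange(300.0),
                                       pts[perm])
        a = subsample_individual(raw, tpl).aligned_points
        b = subsample_individual(raw2, tpl).aligned_points
        np.testing.assert_array_equal(a, b)

    def test_mean_method_preserves_weighted_centroid(self, rng):
        tpl = build_template("ellipse", n_dense=800)
        # spread points widely so every bin receives samples
        s = np.linspace(0, tpl.total_length, 600, endpoint=False)
        pts = tpl.point_at(s) + rng.normal(0, 1.0, size=(600, 2))
        raw = RawIndividualTrajectory("s", "ellipse", 0, np.arange(600.0), pts)
        traj = subsample_individual(raw, tpl, method="mean")
        assert np.all(traj.bin_counts > 0)
        weighted = np.sum(
            traj.aligned_points * traj.bin_counts[:, None], axis=0
        ) / traj.bin_counts.sum()
        np.testing.assert_allclose(weighted, pts.mean(axis=0), rtol=1e-12)


class TestProcessCohort:
    def test_equals_per_trace_pipeline(self, small_cohort):
        processed = process_cohort(small_cohort, n_segments=8, method="median")
        for name in processed.template_names:
            pt = processed[name]
            tpl = small_cohort.templates[name]
            for i, sid in enumerate(pt.subject_ids[:5]):
                trace = next(
                    t for t in small_cohort.traces
                    if t.subject_id == sid and t.template_name == name
                )
                for raw in splice_trace(trace, 8)[:3]:
                    traj = subsample_individual(raw, tpl)
                    np.testing.assert_array_equal(
                        pt.points[i, raw.segment_index], traj.aligned_points
                    )
                    np.testing.assert_array_equal(
                        pt.counts[i, raw.segment_index], traj.bin_counts
                    )

    def test_segment_count_robustness(self, small_cohort):
        """Re-splicing at 5 or 12 slices moves crowd errors only moderately."""
        from crowdtrace.analysis import _mean_err, woc_trajectory

        errs = {}
        for n_segments in (5, 8, 12):
            proc = process_cohort(small_cohort, n_segments=n_segments)
            pt = proc["ellipse"]
            errs[n_segments] = float(_mean_err(woc_trajectory(pt), pt))
        for n_segments in (5, 12):
            assert abs(errs[n_segments] - errs[8]) / errs[8] < 0.5
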