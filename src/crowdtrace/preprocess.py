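"""Splice raw traces into individual trajectories and subsample per bin.

Each 30 s trace is cut into ``n_segments`` (default 8) slices of equal
wall-clock duration; each slice is one *raw individual trajectory*.  Every
raw trajectory is then aligned to the template by assigning each touch sample
to its nearest reference point and collapsing each bin to its coordinate-wise
median (the "median centre of mass"), giving an *individual trajectory* with
exactly one (possibly missing) point per reference point.

Missing bins stay missing (NaN) throughout; nothing is interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Cohort, SubjectMeta, TraceRecord
from .templates import Template

__all__ = [
    "RawIndividualTrajectory",
    "IndividualTrajectory",
    "splice_trace",
    "assign_bins",
    "subsample_individual",
    "ProcessedTemplate",
    "ProcessedCohort",
    "process_cohort",
]


@dataclass
class RawIndividualTrajectory:
    """One equal-duration slice of a raw trace."""

    subject_id: str
    template_name: str
    segment_index: int
    timestamps: np.ndarray
    points: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)


@dataclass
class IndividualTrajectory:
    """A raw individual trajectory subsampled to one point per reference bin.

    ``aligned_points`` has shape (n_ref, 2) with NaN rows for empty bins;
    ``bin_counts`` records how many raw samples fell in each bin.
    """

    subject_id: str
    template_name: str
    segment_index: int
    aligned_points: np.ndarray
    bin_counts: np.ndarray

    @property
    def n_ref(self) -> int:
        return len(self.aligned_points)

    @property
    def coverage(self) -> float:
        return float(np.mean(self.bin_counts > 0))


def splice_trace(trace: TraceRecord, n_segments: int = 8) -> list[RawIndividualTrajectory]:
    """Cut a trace into ``n_segments`` slices of equal wall-clock duration.

    Sample *i* goes to slice ``floor(n_segments * (t_i - t_0) / duration)``,
    with the final sample assigned to the last slice.  Raises if any slice
    would be empty.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if trace.duration <= 0:
        raise ValueError("trace duration must be positive")
    t0 = trace.timestamps[0]
    idx = (n_segments * (trace.timestamps - t0) / trace.duration).astype(int)
    idx = np.minimum(idx, n_segments - 1)
    out = []
    for k in range(n_segments):
        mask = idx == k
        if not np.any(mask):
            raise ValueError(
                f"segment {k} of trace {trace.subject_id}/{trace.template_name} "
                f"would be empty (n_segments={n_segments}, {trace.n_samples} samples)"
            )
        out.append(
            RawIndividualTrajectory(
                subject_id=trace.subject_id,
                template_name=trace.template_name,
                segment_index=k,
                timestamps=trace.timestamps[mask],
                points=trace.points[mask],
            )
        )
    return out


def assign_bins(points: np.ndarray, template: Template, chunk: int = 65536) -> np.ndarray:
    """Label each point with the index of its Euclidean-nearest reference point.

    Ties are broken toward the lowest index (argmin convention).
    """
    refs = template.reference_points
    if refs is None:
        raise ValueError("template has no reference points")
    pts = np.asarray(points, dtype=float)
    labels = np.empty(len(pts), dtype=np.intp)
    for start in range(0, len(pts), chunk):
        block = pts[start : start + chunk]
        d2 = (
            np.sum(block**2, axis=1)[:, None]
            - 2.0 * block @ refs.T
            + np.sum(refs**2, axis=1)[None, :]
        )
        labels[start : start + chunk] = np.argmin(d2, axis=1)
    return labels


def _group_reduce(points: np.ndarray, labels: np.ndarray, n_ref: int, method: str):
    """Per-bin coordinate-wise median/mean; NaN rows for empty bins."""
    aligned = np.full((n_ref, 2), np.nan)
    counts = np.bincount(labels, minlength=n_ref).astype(int)
    order = np.argsort(labels, kind="stable")
    sorted_pts = points[order]
    bounds = np.cumsum(counts)
    reduce = np.median if method == "median" else np.mean
    start = 0
    for k in range(n_ref):
        stop = bounds[k]
        if stop > start:
            aligned[k] = reduce(sorted_pts[start:stop], axis=0)
        start = stop
    return aligned, counts


def subsample_individual(
    raw: RawIndividualTrajectory, template: Template, method: str = "median"
) -> IndividualTrajectory:
    """Collapse a raw trajectory to one point per reference bin.

    The aligned point of a bin is the coordinate-wise median (or mean) of the
    raw samples assigned to it; empty bins are NaN.
    """
    if method not in ("median", "mean"):
        raise ValueError("method must be 'median' or 'mean'")
    if raw.n_samples == 0:
        raise ValueError("raw trajectory is empty")
    labels = assign_bins(raw.points, template)
    aligned, counts = _group_reduce(raw.points, labels, template.n_ref, method)
    return IndividualTrajectory(
        subject_id=raw.subject_id,
        template_name=raw.template_name,
        segment_index=raw.segment_index,
        aligned_points=aligned,
        bin_counts=counts,
    )


# ---------------------------------------------------------------------------
# Whole-cohort processing
# ---------------------------------------------------------------------------

@dataclass
class ProcessedTemplate:
    """All individual trajectories of one template, stacked.

    ``points`` has shape (n_subjects, n_segments, n_ref, 2) with NaN for
    missing bins; ``counts`` the matching per-bin sample counts.  Subjects are
    those with a retained trace for this template, in cohort order.
    """

    template: Template
    subject_ids: list[str]
    ages: np.ndarray
    points: np.ndarray
    counts: np.ndarray

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_segments(self) -> int:
        return self.points.shape[1]

    def per_bin_errors(self) -> np.ndarray:
        """(S, G, n_ref) Euclidean distance of each aligned point to its
        reference point; NaN where the bin is missing."""
        refs = self.template.reference_points
        return np.linalg.norm(self.points - refs[None, None, :, :], axis=-1)

    def individual_errors(self) -> np.ndarray:
        """(S, G) mean error of every individual trajectory (over its
        non-missing bins)."""
        d = self.per_bin_errors()
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=-1)


@dataclass
class ProcessedCohort:
    """Individual trajectories for every template of a cohort."""

    templates: dict[str, ProcessedTemplate]
    subjects: list[SubjectMeta]
    n_segments: int
    method: str

    def __getitem__(self, template_name: str) -> ProcessedTemplate:
        return self.templates[template_name]

    @property
    def template_names(self) -> list[str]:
        return list(self.templates)

    def trajectories(self, template_name: str) -> list[IndividualTrajectory]:
        """Materialise the stacked arrays back into trajectory objects."""
        pt = self.templates[template_name]
        out = []
        for i, sid in enumerate(pt.subject_ids):
            for g in range(pt.n_segments):
                out.append(
                    IndividualTrajectory(
                        subject_id=sid,
                        template_name=template_name,
                        segment_index=g,
                        aligned_points=pt.points[i, g],
                        bin_counts=pt.counts[i, g],
                    )
                )
        return out


def process_cohort(
    cohort: Cohort, n_segments: int = 8, method: str = "median"
) -> ProcessedCohort:
    """Splice and subsample every trace of a cohort.

    Equivalent to looping :func:`splice_trace` + :func:`subsample_individual`
    over all traces, but grouped through pandas for speed.
    """
    if method not in ("median", "mean"):
        raise ValueError("method must be 'median' or 'mean'")
    age_of = {s.subject_id: (s.age if s.age is not None else np.nan) for s in cohort.subjects}
    processed: dict[str, ProcessedTemplate] = {}
    for name, template in cohort.templates.items():
        traces = cohort.traces_for_template(name)
        if not traces:
            continue
        n_ref = template.n_ref
        frames = []
        for si, tr in enumerate(traces):
            t0 = tr.timestamps[0]
            seg = (n_segments * (tr.timestamps - t0) / tr.duration).astype(int)
            seg = np.minimum(seg, n_segments - 1)
            if len(np.unique(seg)) < n_segments:
                raise ValueError(
                    f"trace {tr.subject_id}/{name} has an empty segment at "
                    f"n_segments={n_segments}"
                )
            bins = assign_bins(tr.points, template)
            frames.append(
                pd.DataFrame(
                    {
                        "subject": si,
                        "segment": seg,
                        "bin": bins,
                        "x": tr.points[:, 0],
                        "y": tr.points[:, 1],
                    }
                )
            )
        big = pd.concat(frames, ignore_index=True)
        grouped = big.groupby(["subject", "segment", "bin"], sort=True)[["x", "y"]]
        agg = grouped.median() if method == "median" else grouped.mean()
        sizes = grouped.size()

        S = len(traces)
        points = np.full((S, n_segments, n_ref, 2), np.nan)
        counts = np.zeros((S, n_segments, n_ref), dtype=int)
        idx = agg.index
        si_arr = idx.get_level_values(0).to_numpy()
        g_arr = idx.get_level_values(1).to_numpy()
        b_arr = idx.get_level_values(2).to_numpy()
        points[si_arr, g_arr, b_arr] = agg.to_numpy()
        counts[si_arr, g_arr, b_arr] = sizes.to_numpy()

        processed[name] = ProcessedTemplate(
            template=template,
            subject_ids=[tr.subject_id for tr in traces],
            ages=np.array([age_of[tr.subject_id] for tr in traces], dtype=float),
            points=points,
            counts=counts,
        )
    return ProcessedCohort(
        templates=processed,
        subjects=list(cohort.subjects),
        n_segments=n_segments,
        method=method,
    )
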