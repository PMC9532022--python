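"""Crowd aggregation of individual trajectories and error computation.

The crowd ("wisdom of the crowd", WOC) trajectory is the per-reference-point
median centre of mass — coordinate-wise median — of many individual
trajectories; the mean is available as an alternative.  The error of any
trajectory (individual or aggregate) is the per-bin Euclidean distance to the
template's reference points, summarised by its arithmetic mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .preprocess import IndividualTrajectory
from .templates import Template

__all__ = [
    "AggregateTrajectory",
    "ErrorProfile",
    "aggregate_points",
    "aggregate_trajectories",
    "per_bin_errors",
    "mean_error",
    "error_profile",
    "regional_error_map",
]


@dataclass
class AggregateTrajectory:
    """Per-bin aggregate of many individual trajectories."""

    template_name: str
    aligned_points: np.ndarray  # (n_ref, 2), NaN where no input had the bin
    n_contributing: np.ndarray  # (n_ref,) count of non-missing inputs per bin
    method: str

    @property
    def n_ref(self) -> int:
        return len(self.aligned_points)


@dataclass
class ErrorProfile:
    """Per-bin distances of a trajectory to the template reference points."""

    template_name: str
    per_bin_error: np.ndarray  # (n_ref,), mm, NaN for missing bins
    mean_error: float  # mm, arithmetic mean over non-missing bins
    coverage: float  # fraction of non-missing bins


def aggregate_points(stack: np.ndarray, method: str = "median") -> np.ndarray:
    """Aggregate along the first axis of a (..., n_ref, 2) stack, NaN-aware.

    A bin is NaN in the output only if it is missing in every input.
    """
    if method not in ("median", "mean"):
        raise ValueError("method must be 'median' or 'mean'")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        if method == "median":
            return np.nanmedian(stack, axis=0)
        return np.nanmean(stack, axis=0)


def aggregate_trajectories(
    trajs: list[IndividualTrajectory], method: str = "median"
) -> AggregateTrajectory:
    """Aggregate individual trajectories bin by bin.

    Inputs may come from one subject or many; all must share a template.
    """
    if not trajs:
        raise ValueError("cannot aggregate an empty list of trajectories")
    names = {t.template_name for t in trajs}
    if len(names) > 1:
        raise ValueError(f"mixed templates in aggregation: {sorted(names)}")
    stack = np.stack([t.aligned_points for t in trajs])  # (k, n_ref, 2)
    agg = aggregate_points(stack, method)
    n_contrib = np.sum(~np.isnan(stack[..., 0]), axis=0)
    return AggregateTrajectory(
        template_name=names.pop(),
        aligned_points=agg,
        n_contributing=n_contrib.astype(int),
        method=method,
    )


def per_bin_errors(aligned_points: np.ndarray, template: Template) -> np.ndarray:
    """Euclidean distance of each aligned point to its reference point.

    Works on any (..., n_ref, 2) array; NaN rows give NaN distances.
    """
    refs = template.reference_points
    if refs is None:
        raise ValueError("template has no reference points")
    pts = np.asarray(aligned_points, dtype=float)
    if pts.shape[-2] != len(refs):
        raise ValueError(
            f"trajectory length {pts.shape[-2]} does not match n_ref {len(refs)}"
        )
    return np.linalg.norm(pts - refs, axis=-1)


def mean_error(aligned_points: np.ndarray, template: Template) -> np.ndarray:
    """Arithmetic mean of the per-bin errors over non-missing bins."""
    d = per_bin_errors(aligned_points, template)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(d, axis=-1)


def error_profile(traj, template: Template) -> ErrorProfile:
    """Error profile of an individual or aggregate trajectory."""
    pts = traj.aligned_points if hasattr(traj, "aligned_points") else np.asarray(traj)
    d = per_bin_errors(pts, template)
    valid = ~np.isnan(d)
    if not np.any(valid):
        raise ValueError("trajectory has no non-missing bins; mean error undefined")
    name = getattr(traj, "template_name", template.name)
    return ErrorProfile(
        template_name=name,
        per_bin_error=d,
        mean_error=float(np.mean(d[valid])),
        coverage=float(np.mean(valid)),
    )


def regional_error_map(
    trajs: list[IndividualTrajectory],
    template: Template,
    mode: str = "improvement",
    method: str = "median",
) -> np.ndarray:
    """Per-bin error maps over a set of individual trajectories.

    mode ``individual-average``: per-bin mean of the individual errors;
    ``aggregate``: per-bin error of the aggregate trajectory;
    ``improvement``: their difference (positive where the crowd wins).
    """
    if not trajs:
        raise ValueError("empty trajectory list")
    stack = np.stack([t.aligned_points for t in trajs])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        indiv = np.nanmean(per_bin_errors(stack, template), axis=0)
    if mode == "individual-average":
        return indiv
    agg = per_bin_errors(aggregate_points(stack, method), template)
    if mode == "aggregate":
        return agg
    if mode == "improvement":
        return indiv - agg
    raise ValueError(f"unknown mode {mode!r}")
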