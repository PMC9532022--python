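"""Model/results interface to the crowd-tracing analysis.

`TracingCrowd` is built from a :class:`~crowdtrace.io.Cohort` (real or
synthetic); its :meth:`~TracingCrowd.fit` runs cleaning, trajectory
processing, crowd aggregation and the four crowd-versus-individual analyses,
returning a :class:`TracingCrowdResults` with point estimates, subject-level
bootstrap confidence intervals and a :meth:`~TracingCrowdResults.summary`
table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import analysis
from .aggregate import aggregate_points, per_bin_errors
from .analysis import (
    AggregationCurve,
    GroupComparison,
    OutperformanceResult,
    _mean_err,
    _quantile_ci,
    woc_trajectory,
)
from .io import CleaningReport, Cohort, clean_cohort
from .preprocess import ProcessedCohort, process_cohort

__all__ = ["TracingCrowd", "TracingCrowdResults"]


class TracingCrowd:
    """Crowd-aggregation model of a tracing cohort.

    Parameters
    ----------
    cohort : Cohort
        Raw traces, subjects and templates.
    n_segments : int
        Equal-duration slices per trace (the "raw individual trajectories").
    method : {"median", "mean"}
        Centre-of-mass convention for subsampling and aggregation.
    clean : bool
        Apply the three-filter cleaning step before processing.
    cleaning_params : dict, optional
        Overrides for :func:`~crowdtrace.io.clean_cohort`.
    per_subject : {"first", "random", "pool"}
        Which individual trajectory represents a subject in crowd building.
    """

    def __init__(
        self,
        cohort: Cohort,
        n_segments: int = 8,
        method: str = "median",
        clean: bool = True,
        cleaning_params: dict | None = None,
        per_subject: str = "first",
    ):
        self.cohort = cohort
        self.n_segments = n_segments
        self.method = method
        self.clean = clean
        self.cleaning_params = cleaning_params or {}
        self.per_subject = per_subject

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_directory(cls, path, **kwargs) -> "TracingCrowd":
        """Build from a cohort stored in the canonical manifest layout."""
        from .io import load_cohort

        return cls(load_cohort(path), **kwargs)

    @classmethod
    def from_synthetic(cls, config=None, **kwargs) -> "TracingCrowd":
        """Build from a freshly generated synthetic cohort."""
        from .synthetic import SyntheticConfig, generate_cohort

        if config is None:
            config = SyntheticConfig()
        return cls(generate_cohort(config), **kwargs)

    # -- fitting ----------------------------------------------------------
    def fit(
        self,
        n_boot: int = 500,
        age_threshold: float = 10.5,
        compute_curves: bool = True,
        within_k=None,
        between_n=(1, 2, 4, 8, 16, 32, 64),
        n_reps: int = 10000,
        curve_boot: int = 0,
        seed: int | None = None,
    ) -> "TracingCrowdResults":
        """Run the full analysis.

        ``n_boot`` controls the bootstrap for scalar estimates (errors, group
        comparison); ``curve_boot`` the (more expensive) bootstrap of the
        between-subject curve.  All randomness derives from ``seed``.
        """
        cleaning_report = None
        cohort = self.cohort
        if self.clean:
            cohort, cleaning_report = clean_cohort(cohort, **self.cleaning_params)
        processed = process_cohort(cohort, self.n_segments, self.method)
        rng = np.random.default_rng(seed)

        rows = []
        curves: dict[str, dict[str, AggregationCurve]] = {}
        comparisons: dict[str, GroupComparison] = {}
        outperf: dict[str, OutperformanceResult] = {}
        jensen_violations = 0

        for name in processed.template_names:
            pt = processed[name]
            subject_err = np.nanmean(pt.individual_errors(), axis=1)
            indiv_mean = float(np.mean(subject_err))
            woc = woc_trajectory(pt, method=self.method, per_subject=self.per_subject)
            woc_err = float(_mean_err(woc, pt))

            if n_boot:
                bi = np.empty(n_boot)
                bw = np.empty(n_boot)
                S = pt.n_subjects
                for b in range(n_boot):
                    idx = rng.integers(0, S, size=S)
                    bi[b] = subject_err[idx].mean()
                    w = woc_trajectory(pt, method=self.method,
                                       per_subject=self.per_subject, subject_idx=idx)
                    bw[b] = _mean_err(w, pt)
                indiv_ci = _quantile_ci(bi, 0.95)
                woc_ci = _quantile_ci(bw, 0.95)
            else:
                indiv_ci = woc_ci = (np.nan, np.nan)

            res = analysis.outperformance_percentile(
                processed, name, method=self.method, per_subject=self.per_subject
            )
            outperf[name] = res

            try:
                comp = analysis.group_comparison(
                    processed, name, age_threshold=age_threshold,
                    method=self.method, per_subject=self.per_subject,
                    n_boot=n_boot, seed=int(rng.integers(2**31)),
                )
                comparisons[name] = comp
            except ValueError:
                comp = None  # single-age cohorts have no group split

            diversity = analysis.diversity_score(
                processed, name, method=self.method, per_subject=self.per_subject
            )

            # Convexity (Jensen) diagnostic: per bin, the mean over the
            # inputs present there cannot err more than they do on average.
            one = analysis._one_per_subject(pt, self.per_subject)
            mean_agg = aggregate_points(one, "mean")
            d_ind = per_bin_errors(one, pt.template)
            d_agg = per_bin_errors(mean_agg, pt.template)
            with np.errstate(invalid="ignore"):
                bound = np.nanmean(d_ind, axis=0)
            ok = ~np.isnan(d_agg)
            jensen_violations += int(np.sum(d_agg[ok] > bound[ok] + 1e-9))

            rows.append(
                {
                    "template": name,
                    "n_subjects": pt.n_subjects,
                    "individual_error_mm": indiv_mean,
                    "individual_ci_low_mm": indiv_ci[0],
                    "individual_ci_high_mm": indiv_ci[1],
                    "woc_error_mm": woc_err,
                    "woc_ci_low_mm": woc_ci[0],
                    "woc_ci_high_mm": woc_ci[1],
                    "outperformance_pct": res.percentile,
                    "diversity_mm": diversity,
                }
            )

            if compute_curves:
                curves[name] = {
                    "within": analysis.within_subject_curve(
                        processed, name, k_values=within_k, method=self.method,
                        n_boot=n_boot, seed=int(rng.integers(2**31)),
                    ),
                    "between": analysis.between_subject_curve(
                        processed, name,
                        n_values=[n for n in between_n if n <= pt.n_subjects],
                        n_reps=n_reps, method=self.method, n_boot=curve_boot,
                        seed=int(rng.integers(2**31)),
                    ),
                }

        table = pd.DataFrame(rows).set_index("template")
        age_profile = None
        if any(np.isfinite(processed[n].ages).any() for n in processed.template_names):
            age_profile = analysis.age_error_profile(
                processed, n_boot=n_boot, seed=int(rng.integers(2**31))
            )

        return TracingCrowdResults(
            model=self,
            processed=processed,
            cleaning_report=cleaning_report,
            table=table,
            curves=curves,
            comparisons=comparisons,
            outperformance=outperf,
            age_profile=age_profile,
            jensen_violations=jensen_violations,
            age_threshold=age_threshold,
        )


@dataclass
class TracingCrowdResults:
    """Estimates, uncertainties and diagnostics from a fitted model."""

    model: TracingCrowd
    processed: ProcessedCohort
    cleaning_report: CleaningReport | None
    table: pd.DataFrame  # per-template estimates and CIs
    curves: dict[str, dict[str, AggregationCurve]]
    comparisons: dict[str, GroupComparison]
    outperformance: dict[str, OutperformanceResult]
    age_profile: pd.DataFrame | None
    jensen_violations: int
    age_threshold: float

    # -- headline scalars (unweighted means across templates) -------------
    @property
    def mean_individual_error(self) -> float:
        return float(self.table["individual_error_mm"].mean())

    @property
    def woc_error(self) -> float:
        return float(self.table["woc_error_mm"].mean())

    @property
    def min_outperformance(self) -> float:
        return float(self.table["outperformance_pct"].min())

    def comparison_table(self) -> pd.DataFrame:
        if not self.comparisons:
            raise ValueError("no age-group comparison available")
        return pd.DataFrame(
            [c.to_dict() for c in self.comparisons.values()]
        ).set_index("template")

    def to_summary_dict(self) -> dict:
        """Machine-readable summary of every headline statistic."""
        out = {
            "n_segments": self.model.n_segments,
            "method": self.model.method,
            "mean_individual_error_mm": self.mean_individual_error,
            "woc_error_mm": self.woc_error,
            "error_ratio": self.woc_error / self.mean_individual_error,
            "min_outperformance_pct": self.min_outperformance,
            "jensen_bound_violations": self.jensen_violations,
            "per_template": self.table.reset_index().to_dict(orient="records"),
        }
        if self.cleaning_report is not None:
            rep = self.cleaning_report.to_dict()
            rep.pop("reasons")
            out["cleaning"] = rep
        if self.comparisons:
            out["group_comparison"] = [
                c.to_dict() for c in self.comparisons.values()
            ]
        if self.curves:
            out["curves"] = {
                name: {src: c.to_frame().to_dict(orient="list")
                       for src, c in d.items()}
                for name, d in self.curves.items()
            }
        if self.age_profile is not None:
            out["age_profile"] = self.age_profile.reset_index().to_dict(orient="records")
        return out

    def summary(self) -> str:
        """Human-readable report."""
        lines = ["Crowd tracing analysis", "=" * 70]
        if self.cleaning_report is not None:
            r = self.cleaning_report
            lines.append(
                f"Cleaning: {r.n_input} traces in, {r.n_retained} retained "
                f"(short {r.removed_short}, low-std {r.removed_low_std}, "
                f"jump {r.removed_jump})"
            )
        lines.append(
            f"Segments per trace: {self.model.n_segments}   "
            f"aggregation: {self.model.method}"
        )
        lines.append("")
        cols = ["n_subjects", "individual_error_mm", "woc_error_mm",
                "outperformance_pct", "diversity_mm"]
        lines.append(self.table[cols].to_string(float_format=lambda v: f"{v:.3f}"))
        lines.append("")
        lines.append(
            f"Mean individual error: {self.mean_individual_error:.3f} mm   "
            f"crowd error: {self.woc_error:.3f} mm   "
            f"ratio: {self.woc_error / self.mean_individual_error:.3f}"
        )
        lines.append(
            f"Crowd outperforms at least {self.min_outperformance:.1f}% of "
            f"individual trajectories on every template"
        )
        if self.comparisons:
            lines.append("")
            lines.append(f"Age groups (threshold {self.age_threshold} y):")
            ct = self.comparison_table()[
                ["n_young", "n_old", "individual_young_mm", "individual_old_mm",
                 "woc_young_mm", "woc_old_mm"]
            ]
            lines.append(ct.to_string(float_format=lambda v: f"{v:.3f}"))
        lines.append(
            f"\nConvexity-bound violations (mean aggregation): "
            f"{self.jensen_violations}"
        )
        return "\n".join(lines)
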