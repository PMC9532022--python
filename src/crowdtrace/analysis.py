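"""Crowd-versus-individual analyses on a processed cohort.

Implements the four signatures of a strong wisdom-of-the-crowd effect:

1. crowd error far below mean individual error;
2. aggregation curves — error versus number of aggregated trajectories,
   within one subject (exhaustive subset enumeration) versus between
   subjects (Monte-Carlo draws) — with the between-subject curve falling
   well below the within-subject plateau set by each subject's systematic
   bias;
3. the crowd outperforming nearly all individual trajectories;
4. age stratification — a crowd of young (low-skill) subjects beating the
   average older (high-skill) individual.

Also: trajectory diversity, subject-level bootstrap confidence intervals,
and a simulated skill-selection sweep (how accurately must one identify top
performers before a selected individual beats the crowd).

All Monte-Carlo procedures take a ``seed`` and are reproducible.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aggregate import aggregate_points, per_bin_errors
from .io import Cohort
from .preprocess import ProcessedCohort, ProcessedTemplate

__all__ = [
    "AggregationCurve",
    "GroupComparison",
    "OutperformanceResult",
    "SkillSweepResult",
    "woc_trajectory",
    "within_subject_curve",
    "between_subject_curve",
    "outperformance_percentile",
    "outperformance_from_errors",
    "age_error_profile",
    "group_comparison",
    "diversity_score",
    "bootstrap_ci",
    "skill_selection_sweep",
]


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class AggregationCurve:
    """Error of the aggregate as a function of how many trajectories it pools."""

    template_name: str
    source: str  # "within-subject" | "between-subject"
    n_values: np.ndarray
    mean_errors: np.ndarray  # mm
    ci_low: np.ndarray | None = None  # mm, 95% subject-bootstrap
    ci_high: np.ndarray | None = None
    n_combinations: np.ndarray | None = None  # within-subject: subsets per subject

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"n": self.n_values, "mean_error_mm": self.mean_errors})
        if self.ci_low is not None:
            df["ci_low_mm"] = self.ci_low
            df["ci_high_mm"] = self.ci_high
        if self.n_combinations is not None:
            df["n_subsets"] = self.n_combinations
        df.insert(0, "source", self.source)
        df.insert(0, "template", self.template_name)
        return df


@dataclass
class GroupComparison:
    """Individual and crowd errors for young vs old subjects, one template."""

    template_name: str
    age_threshold: float
    n_young: int
    n_old: int
    individual_young: float
    individual_old: float
    woc_young: float
    woc_old: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "template": self.template_name,
            "age_threshold": self.age_threshold,
            "n_young": self.n_young,
            "n_old": self.n_old,
            "individual_young_mm": self.individual_young,
            "individual_old_mm": self.individual_old,
            "woc_young_mm": self.woc_young,
            "woc_old_mm": self.woc_old,
        }
        for k, (lo, hi) in self.ci.items():
            d[f"{k}_ci_low_mm"], d[f"{k}_ci_high_mm"] = lo, hi
        return d


@dataclass
class OutperformanceResult:
    """Fraction of individual trajectories the crowd trajectory beats."""

    template_name: str
    percentile: float  # % of individual trajectories with error > crowd error
    woc_error: float  # mm
    individual_errors: np.ndarray  # all individual-trajectory errors, mm
    hist_counts: np.ndarray
    hist_edges: np.ndarray


@dataclass
class SkillSweepResult:
    """Expected error of a noisily-selected 'best' subject vs the crowd."""

    template_name: str
    noise_levels: np.ndarray  # selector noise, in SDs of the skill spread
    selected_errors: np.ndarray  # mm, Monte-Carlo expectation per level
    crossover_percentile: float  # % of subjects that beat the crowd
    woc_error: float  # mm
    subject_errors: np.ndarray  # per-subject mean individual error, mm


# ---------------------------------------------------------------------------
# Crowd construction
# ---------------------------------------------------------------------------

def _one_per_subject(
    pt: ProcessedTemplate,
    per_subject: str = "first",
    rng: np.random.Generator | None = None,
    subject_idx: np.ndarray | None = None,
) -> np.ndarray:
    """One individual trajectory per subject: (S, n_ref, 2).

    ``per_subject``: "first" takes each subject's first time slice; "random"
    one random slice per subject (requires ``rng``); "pool" pools all slices
    of a subject into a per-bin aggregate first.
    """
    pts = pt.points if subject_idx is None else pt.points[subject_idx]
    if per_subject == "first":
        return pts[:, 0]
    if per_subject == "random":
        if rng is None:
            raise ValueError("per_subject='random' requires an rng")
        segs = rng.integers(0, pts.shape[1], size=len(pts))
        return pts[np.arange(len(pts)), segs]
    if per_subject == "pool":
        return aggregate_points(np.moveaxis(pts, 1, 0), "median")
    raise ValueError(f"unknown per_subject convention {per_subject!r}")


def woc_trajectory(
    pt: ProcessedTemplate,
    method: str = "median",
    per_subject: str = "first",
    rng: np.random.Generator | None = None,
    subject_idx: np.ndarray | None = None,
) -> np.ndarray:
    """The crowd trajectory: one trajectory per subject, aggregated per bin."""
    one = _one_per_subject(pt, per_subject, rng, subject_idx)
    return aggregate_points(one, method)


def _mean_err(points: np.ndarray, pt: ProcessedTemplate) -> np.ndarray:
    """Nanmean over the bin axis of per-bin errors; works on stacks."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(per_bin_errors(points, pt.template), axis=-1)


def _quantile_ci(values: np.ndarray, level: float) -> tuple[float, float]:
    alpha = (1.0 - level) / 2.0
    return (
        float(np.quantile(values, alpha)),
        float(np.quantile(values, 1.0 - alpha)),
    )


# ---------------------------------------------------------------------------
# Aggregation curves
# ---------------------------------------------------------------------------

def within_subject_curve(
    processed: ProcessedCohort,
    template_name: str,
    k_values=None,
    method: str | None = None,
    n_boot: int = 500,
    level: float = 0.95,
    seed: int | None = None,
    _subject_chunk: int = 32,
) -> AggregationCurve:
    """Error of aggregating k of a subject's own trajectories, exhaustively.

    For each k, every one of the C(n_segments, k) subsets of each subject's
    trajectories is aggregated and scored; errors are averaged over subsets
    within subject, then over subjects.  CIs are a subject-level bootstrap of
    the per-subject subset-averaged errors.
    """
    pt = processed[template_name]
    method = method or processed.method
    G = pt.n_segments
    if k_values is None:
        k_values = np.arange(1, G + 1)
    k_values = np.asarray(k_values, dtype=int)
    if np.any(k_values < 1) or np.any(k_values > G):
        raise ValueError(f"k values must lie in 1..{G}")

    S = pt.n_subjects
    means = np.empty(len(k_values))
    ci_lo = np.empty(len(k_values))
    ci_hi = np.empty(len(k_values))
    n_comb = np.empty(len(k_values), dtype=int)
    rng = np.random.default_rng(seed)

    for j, k in enumerate(k_values):
        combos = np.array(list(itertools.combinations(range(G), int(k))))
        n_comb[j] = len(combos)
        per_subject = np.empty(S)
        for start in range(0, S, _subject_chunk):
            block = pt.points[start : start + _subject_chunk]  # (B, G, R, 2)
            sub = block[:, combos]  # (B, C, k, R, 2)
            agg = aggregate_points(np.moveaxis(sub, 2, 0), method)  # (B, C, R, 2)
            errs = _mean_err(agg, pt)  # (B, C)
            per_subject[start : start + _subject_chunk] = errs.mean(axis=1)
        means[j] = per_subject.mean()
        if n_boot:
            draws = rng.integers(0, S, size=(n_boot, S))
            boots = per_subject[draws].mean(axis=1)
            ci_lo[j], ci_hi[j] = _quantile_ci(boots, level)
    return AggregationCurve(
        template_name=template_name,
        source="within-subject",
        n_values=k_values,
        mean_errors=means,
        ci_low=ci_lo if n_boot else None,
        ci_high=ci_hi if n_boot else None,
        n_combinations=n_comb,
    )


def _between_mc(
    points: np.ndarray,
    pt: ProcessedTemplate,
    n: int,
    n_reps: int,
    method: str,
    rng: np.random.Generator,
    max_elems: float = 4e6,
) -> float:
    """Monte-Carlo mean aggregate error for crowds of n distinct subjects."""
    S, G = points.shape[0], points.shape[1]
    if n > S:
        raise ValueError(f"crowd size {n} exceeds {S} subjects")
    total = 0.0
    done = 0
    block = max(1, int(max_elems / (n * points.shape[2])))
    while done < n_reps:
        b = min(block, n_reps - done)
        # n distinct subjects per draw, one random time slice each
        subj = np.argsort(rng.random((b, S)), axis=1)[:, :n]
        segs = rng.integers(0, G, size=(b, n))
        sel = points[subj, segs]  # (b, n, R, 2)
        agg = aggregate_points(np.moveaxis(sel, 1, 0), method)  # (b, R, 2)
        total += float(np.sum(_mean_err(agg, pt)))
        done += b
    return total / n_reps


def between_subject_curve(
    processed: ProcessedCohort,
    template_name: str,
    n_values=(1, 2, 4, 8, 16, 32, 64),
    n_reps: int = 10000,
    seed: int | None = None,
    method: str | None = None,
    n_boot: int = 0,
    reps_per_boot: int | None = None,
    level: float = 0.95,
) -> AggregationCurve:
    """Error of aggregating one trajectory each from n distinct subjects.

    Monte-Carlo: each draw picks n distinct subjects and one random time
    slice per subject.  CIs (optional, ``n_boot > 0``) are a subject-level
    bootstrap re-running a reduced-rep Monte-Carlo per resample.
    """
    pt = processed[template_name]
    method = method or processed.method
    n_values = np.asarray(n_values, dtype=int)
    rng = np.random.default_rng(seed)
    S = pt.n_subjects

    means = np.array(
        [_between_mc(pt.points, pt, int(n), n_reps, method, rng) for n in n_values]
    )
    ci_lo = ci_hi = None
    if n_boot:
        reps_b = reps_per_boot if reps_per_boot is not None else max(200, n_reps // 10)
        boots = np.empty((n_boot, len(n_values)))
        for b in range(n_boot):
            resample = rng.integers(0, S, size=S)
            pts_b = pt.points[resample]
            for j, n in enumerate(n_values):
                boots[b, j] = _between_mc(pts_b, pt, int(n), reps_b, method, rng)
        qs = np.array([_quantile_ci(boots[:, j], level) for j in range(len(n_values))])
        ci_lo, ci_hi = qs[:, 0], qs[:, 1]
    return AggregationCurve(
        template_name=template_name,
        source="between-subject",
        n_values=n_values,
        mean_errors=means,
        ci_low=ci_lo,
        ci_high=ci_hi,
    )


# ---------------------------------------------------------------------------
# Outperformance
# ---------------------------------------------------------------------------

def outperformance_from_errors(individual_errors: np.ndarray, woc_error: float) -> float:
    """Percent of individual errors strictly greater than the crowd error."""
    e = np.asarray(individual_errors, dtype=float)
    e = e[~np.isnan(e)]
    return float(100.0 * np.mean(e > woc_error))


def outperformance_percentile(
    processed: ProcessedCohort,
    template_name: str,
    method: str | None = None,
    per_subject: str = "first",
    seed: int | None = None,
    hist_bins: int = 40,
) -> OutperformanceResult:
    """Compare the crowd trajectory's error with all individual errors.

    The crowd pools one trajectory per subject; the comparison distribution
    contains every individual trajectory (all time slices of all subjects).
    """
    pt = processed[template_name]
    method = method or processed.method
    rng = np.random.default_rng(seed) if per_subject == "random" else None
    woc = woc_trajectory(pt, method=method, per_subject=per_subject, rng=rng)
    woc_err = float(_mean_err(woc, pt))
    indiv = pt.individual_errors().ravel()
    indiv = indiv[~np.isnan(indiv)]
    counts, edges = np.histogram(indiv, bins=hist_bins)
    return OutperformanceResult(
        template_name=template_name,
        percentile=outperformance_from_errors(indiv, woc_err),
        woc_error=woc_err,
        individual_errors=indiv,
        hist_counts=counts,
        hist_edges=edges,
    )


# ---------------------------------------------------------------------------
# Age stratification
# ---------------------------------------------------------------------------

def age_error_profile(
    processed: ProcessedCohort,
    n_boot: int = 500,
    level: float = 0.95,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean individual error per integer age, averaged across templates.

    Per template: each subject's error is the mean over their time slices;
    subjects of the same (floored) age are averaged; the per-template values
    are then combined by unweighted arithmetic mean.  CIs are a subject-level
    bootstrap within each age group.
    """
    rows = []
    for name, pt in processed.templates.items():
        errs = np.nanmean(pt.individual_errors(), axis=1)  # (S,) subject means
        for sid, age, e in zip(pt.subject_ids, pt.ages, errs):
            if np.isfinite(age) and np.isfinite(e):
                rows.append((name, sid, int(np.floor(age)), e))
    if not rows:
        raise ValueError("no subjects with known age")
    df = pd.DataFrame(rows, columns=["template", "subject_id", "age", "error"])
    rng = np.random.default_rng(seed)

    out = []
    for age, sub in df.groupby("age"):
        per_tpl = sub.groupby("template")["error"].mean()
        est = float(per_tpl.mean())
        lo = hi = np.nan
        if n_boot:
            sids = sub["subject_id"].unique()
            by_subject = {
                s: g.set_index("template")["error"] for s, g in sub.groupby("subject_id")
            }
            boots = np.empty(n_boot)
            for b in range(n_boot):
                pick = rng.choice(sids, size=len(sids), replace=True)
                res = pd.concat([by_subject[s] for s in pick])
                boots[b] = res.groupby(level=0).mean().mean()
            lo, hi = _quantile_ci(boots, level)
        out.append(
            {"age": age, "error_mm": est, "ci_low_mm": lo, "ci_high_mm": hi,
             "n_subjects": sub["subject_id"].nunique()}
        )
    return pd.DataFrame(out).set_index("age").sort_index()


def group_comparison(
    processed: ProcessedCohort,
    template_name: str,
    age_threshold: float = 10.5,
    method: str | None = None,
    per_subject: str = "first",
    n_boot: int = 500,
    level: float = 0.95,
    seed: int | None = None,
) -> GroupComparison:
    """Individual and crowd errors for subjects younger/older than a cutoff.

    The crowd of each group is built from that group's subjects only (one
    trajectory per subject).  CIs: subject bootstrap within group.
    """
    pt = processed[template_name]
    method = method or processed.method
    young = np.where(pt.ages < age_threshold)[0]
    old = np.where(pt.ages >= age_threshold)[0]
    if len(young) == 0 or len(old) == 0:
        raise ValueError(
            f"empty age group at threshold {age_threshold} "
            f"({len(young)} young, {len(old)} old)"
        )
    subject_err = np.nanmean(pt.individual_errors(), axis=1)  # (S,)
    rng = np.random.default_rng(seed)

    def stats(idx: np.ndarray) -> tuple[float, float]:
        indiv = float(np.mean(subject_err[idx]))
        woc = woc_trajectory(pt, method=method, per_subject=per_subject,
                             rng=rng, subject_idx=idx)
        return indiv, float(_mean_err(woc, pt))

    individual_young, woc_young = stats(young)
    individual_old, woc_old = stats(old)

    ci: dict[str, tuple[float, float]] = {}
    if n_boot:
        boots = {k: np.empty(n_boot) for k in
                 ("individual_young", "individual_old", "woc_young", "woc_old")}
        for b in range(n_boot):
            ry = young[rng.integers(0, len(young), size=len(young))]
            ro = old[rng.integers(0, len(old), size=len(old))]
            iy, wy = stats(ry)
            io, wo = stats(ro)
            boots["individual_young"][b] = iy
            boots["woc_young"][b] = wy
            boots["individual_old"][b] = io
            boots["woc_old"][b] = wo
        ci = {k: _quantile_ci(v, level) for k, v in boots.items()}

    return GroupComparison(
        template_name=template_name,
        age_threshold=age_threshold,
        n_young=len(young),
        n_old=len(old),
        individual_young=individual_young,
        individual_old=individual_old,
        woc_young=woc_young,
        woc_old=woc_old,
        ci=ci,
    )


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

def diversity_score(
    processed: ProcessedCohort,
    template_name: str,
    subject_idx: np.ndarray | None = None,
    method: str | None = None,
    per_subject: str = "first",
) -> float:
    """Mean distance of a group's individual trajectories to its crowd.

    Per individual trajectory: mean per-bin Euclidean distance to the group's
    collective (crowd) trajectory; then averaged over all trajectories.
    """
    pt = processed[template_name]
    method = method or processed.method
    collective = woc_trajectory(pt, method=method, per_subject=per_subject,
                                subject_idx=subject_idx)
    pts = pt.points if subject_idx is None else pt.points[subject_idx]
    d = np.linalg.norm(pts - collective[None, None], axis=-1)  # (S, G, R)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        per_traj = np.nanmean(d, axis=-1)  # (S, G)
        return float(np.nanmean(per_traj))


# ---------------------------------------------------------------------------
# Subject-level bootstrap
# ---------------------------------------------------------------------------

def resample_cohort(cohort: Cohort, rng: np.random.Generator) -> Cohort:
    """One bootstrap 'virtual experiment': subjects drawn with replacement
    up to the original cohort size, each carrying all their traces."""
    S = cohort.n_subjects
    picks = rng.integers(0, S, size=S)
    traces_by_subject: dict[str, list] = {}
    for tr in cohort.traces:
        traces_by_subject.setdefault(tr.subject_id, []).append(tr)
    subjects, traces = [], []
    from dataclasses import replace

    from .io import TraceRecord

    for j, i in enumerate(picks):
        s = cohort.subjects[i]
        new_id = f"{s.subject_id}__r{j}"
        subjects.append(replace(s, subject_id=new_id))
        for tr in traces_by_subject.get(s.subject_id, []):
            traces.append(
                TraceRecord(
                    subject_id=new_id,
                    template_name=tr.template_name,
                    timestamps=tr.timestamps,
                    points=tr.points,
                )
            )
    return Cohort(subjects=subjects, traces=traces, templates=dict(cohort.templates))


def bootstrap_ci(
    statistic,
    cohort: Cohort,
    n_boot: int = 500,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap CI of a cohort-level statistic.

    The resampling unit is the subject: each virtual experiment redraws
    subjects with replacement up to the original count, keeping all of each
    subject's traces together.
    """
    rng = np.random.default_rng(seed)
    values = np.empty(n_boot)
    for b in range(n_boot):
        resampled = resample_cohort(cohort, rng)
        try:
            values[b] = float(statistic(resampled))
        except Exception as exc:  # noqa: BLE001 - propagate with context
            raise RuntimeError(f"statistic failed on bootstrap resample {b}") from exc
    return _quantile_ci(values, level)


# ---------------------------------------------------------------------------
# Skill-selection sweep
# ---------------------------------------------------------------------------

def skill_selection_sweep(
    processed: ProcessedCohort,
    template_name: str,
    noise_levels=None,
    n_mc: int = 2000,
    seed: int | None = None,
    method: str | None = None,
    per_subject: str = "first",
) -> SkillSweepResult:
    """How good must a skill-selection criterion be to beat the crowd?

    A selector ranks subjects by their true skill (per-subject mean
    individual error) corrupted by Gaussian noise of the given level,
    expressed in standard deviations of the skill spread, and picks the
    apparent best.  Level 0 is a perfect selector (picks the true best);
    an infinitely noisy selector picks at random, giving the mean error.

    The crossover percentile is the fraction of subjects whose error is
    below the crowd's — the share of top performers a selector must be able
    to isolate for an individual to outperform the crowd.
    """
    pt = processed[template_name]
    method = method or processed.method
    skills = np.nanmean(pt.individual_errors(), axis=1)  # (S,)
    woc = woc_trajectory(pt, method=method, per_subject=per_subject)
    woc_err = float(_mean_err(woc, pt))
    spread = float(np.std(skills))
    if noise_levels is None:
        noise_levels = np.array([0.0, 0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, np.inf])
    noise_levels = np.asarray(noise_levels, dtype=float)
    rng = np.random.default_rng(seed)

    selected = np.empty(len(noise_levels))
    for j, lvl in enumerate(noise_levels):
        if lvl == 0.0:
            selected[j] = float(np.min(skills))
        elif np.isinf(lvl):
            selected[j] = float(np.mean(skills))
        else:
            noise = rng.standard_normal((n_mc, len(skills)))
            scores = skills[None, :] + lvl * spread * noise
            picks = np.argmin(scores, axis=1)
            selected[j] = float(np.mean(skills[picks]))

    crossover = float(100.0 * np.mean(skills < woc_err))
    return SkillSweepResult(
        template_name=template_name,
        noise_levels=noise_levels,
        selected_errors=selected,
        crossover_percentile=crossover,
        woc_error=woc_err,
        subject_errors=skills,
    )
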