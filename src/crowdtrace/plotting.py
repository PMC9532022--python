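"""Figure panels for the crowd-tracing analysis.

Overlay of individual and crowd trajectories on the template; aggregation
curves (within vs between subject); histograms of individual errors against
the crowd error; age-stratified bar comparison; error-vs-age profile.
All functions return a matplotlib Figure.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = [
    "plot_overlay",
    "plot_aggregation_curves",
    "plot_error_histogram",
    "plot_group_comparison",
    "plot_age_profile",
    "save_all",
]


def plot_overlay(results, template_name: str, max_individuals: int = 50):
    """Template (dashed), a sample of individual trajectories, and the crowd."""
    from .analysis import woc_trajectory

    pt = results.processed[template_name]
    fig, ax = plt.subplots(figsize=(5, 4))
    tpl = pt.template.dense_polyline
    ax.plot(tpl[:, 0], tpl[:, 1], "k--", lw=1.5, label="template")
    one = pt.points[:, 0]  # first slice per subject
    for traj in one[: max_individuals]:
        ok = ~np.isnan(traj[:, 0])
        ax.plot(traj[ok, 0], traj[ok, 1], color="tab:blue", alpha=0.15, lw=0.8)
    woc = woc_trajectory(pt, method=results.model.method)
    ok = ~np.isnan(woc[:, 0])
    ax.plot(woc[ok, 0], woc[ok, 1], color="tab:red", lw=2, label="crowd")
    ax.set_aspect("equal")
    ax.invert_yaxis()  # native touch convention: y grows downward
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_title(template_name)
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    return fig


def plot_aggregation_curves(results, template_name: str):
    """Error vs number of aggregated trajectories, within vs between subject."""
    curves = results.curves[template_name]
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {"within": "black", "between": "tab:red"}
    for src, curve in curves.items():
        ax.plot(curve.n_values, curve.mean_errors, "o-", color=colors[src],
                label=f"{src}-subject")
        if curve.ci_low is not None:
            ax.fill_between(curve.n_values, curve.ci_low, curve.ci_high,
                            color=colors[src], alpha=0.2, lw=0)
    ax.set_xscale("log", base=2)
    ax.set_yscale("log")
    ax.set_xlabel("trajectories aggregated")
    ax.set_ylabel("mean error (mm)")
    ax.set_title(template_name)
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_error_histogram(results, template_name: str):
    """Individual-error histogram with the crowd error marked."""
    res = results.outperformance[template_name]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.stairs(res.hist_counts, res.hist_edges, fill=True, color="tab:blue",
              alpha=0.7)
    ax.axvline(res.woc_error, color="tab:red", lw=2,
               label=f"crowd ({res.percentile:.1f}% beaten)")
    ax.set_xlabel("individual error (mm)")
    ax.set_ylabel("count")
    ax.set_title(template_name)
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_group_comparison(results):
    """Young vs old: individual and crowd errors per template, with CIs."""
    ct = results.comparison_table()
    fig, ax = plt.subplots(figsize=(1.6 * len(ct) + 2, 4))
    keys = ["individual_young_mm", "individual_old_mm", "woc_young_mm", "woc_old_mm"]
    colors = ["tab:blue", "steelblue", "tab:red", "firebrick"]
    width = 0.2
    x = np.arange(len(ct))
    for j, (key, color) in enumerate(zip(keys, colors)):
        vals = ct[key].to_numpy()
        pos = x + (j - 1.5) * width
        lo_col, hi_col = f"{key[:-3]}_ci_low_mm", f"{key[:-3]}_ci_high_mm"
        if lo_col in ct:
            yerr = np.abs(np.stack([vals - ct[lo_col], ct[hi_col] - vals]))
        else:
            yerr = None
        ax.bar(pos, vals, width=width, color=color, yerr=yerr, capsize=2,
               label=key.replace("_mm", "").replace("_", " "))
    ax.set_xticks(x, ct.index, rotation=20)
    ax.set_ylabel("mean error (mm)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_age_profile(results):
    """Mean individual error per age, averaged across templates."""
    prof = results.age_profile
    fig, ax = plt.subplots(figsize=(5, 4))
    yerr = None
    if prof["ci_low_mm"].notna().all():
        yerr = np.abs(
            np.stack([prof["error_mm"] - prof["ci_low_mm"],
                      prof["ci_high_mm"] - prof["error_mm"]])
        )
    ax.errorbar(prof.index, prof["error_mm"], yerr=yerr, fmt="o-", capsize=3)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("mean individual error (mm)")
    fig.tight_layout()
    return fig


def save_all(results, out_dir, fmt: str = "svg") -> None:
    """Render every panel for every template into ``out_dir``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in results.processed.template_names:
        plot_overlay(results, name).savefig(out / f"overlay_{name}.{fmt}")
        if name in results.curves:
            plot_aggregation_curves(results, name).savefig(
                out / f"curves_{name}.{fmt}")
        plot_error_histogram(results, name).savefig(out / f"hist_{name}.{fmt}")
    if results.comparisons:
        plot_group_comparison(results).savefig(out / f"group_comparison.{fmt}")
    if results.age_profile is not None:
        plot_age_profile(results).savefig(out / f"age_profile.{fmt}")
    plt.close("all")
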