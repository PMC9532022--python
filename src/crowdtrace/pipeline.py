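"""One-shot pipeline: simulate/load -> clean -> process -> analyse -> report.

A :class:`RunConfig` (serialisable to YAML) plus a seed fully determines a
run's numeric output.  Outputs: a JSON summary of every headline statistic,
CSV tables (curves, per-template estimates, group comparison, age profile)
and, optionally, figures.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import load_cohort
from .model import TracingCrowd
from .synthetic import SyntheticConfig, generate_cohort

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serialisable description of a full pipeline run."""

    input_dir: str | None = None  # cohort directory; None = synthetic
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides
    cleaning: dict = field(default_factory=dict)
    n_segments: int = 8
    method: str = "median"
    n_boot: int = 500
    n_reps: int = 10000
    curve_boot: int = 0
    age_threshold: float = 10.5
    between_n: tuple = (1, 2, 4, 8, 16, 32, 64)
    compute_curves: bool = True
    make_figures: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute all stages, persist tables + summary JSON, return the summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    if config.input_dir is not None:
        cohort = load_cohort(config.input_dir)
        stage = "load"
    else:
        syn = SyntheticConfig(**{"seed": config.seed, **config.synthetic})
        cohort = generate_cohort(syn)
        stage = "simulate"
    timings[stage] = time.perf_counter() - t0
    logger.info("%s: %d subjects, %d traces (%.1f s)", stage,
                cohort.n_subjects, cohort.n_traces, timings[stage])

    t0 = time.perf_counter()
    model = TracingCrowd(
        cohort,
        n_segments=config.n_segments,
        method=config.method,
        cleaning_params=config.cleaning,
    )
    results = model.fit(
        n_boot=config.n_boot,
        age_threshold=config.age_threshold,
        compute_curves=config.compute_curves,
        between_n=tuple(config.between_n),
        n_reps=config.n_reps,
        curve_boot=config.curve_boot,
        seed=config.seed,
    )
    timings["fit"] = time.perf_counter() - t0

    results.table.to_csv(out / "per_template.csv")
    if results.comparisons:
        results.comparison_table().to_csv(out / "group_comparison.csv")
    if results.age_profile is not None:
        results.age_profile.to_csv(out / "age_profile.csv")
    if results.curves:
        frames = [c.to_frame() for d in results.curves.values() for c in d.values()]
        pd.concat(frames, ignore_index=True).to_csv(out / "curves.csv", index=False)

    summary = results.to_summary_dict()
    summary["config"] = asdict(config)
    summary["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    (out / "summary.json").write_text(json.dumps(summary, indent=1, default=_json_default))

    if config.make_figures:
        from . import plotting

        plotting.save_all(results, out)
    (out / "summary.txt").write_text(results.summary())
    return summary


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
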