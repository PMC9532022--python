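"""Cohort containers, canonical on-disk format, unit conversion and cleaning.

A *cohort* bundles subject metadata, one raw 30 s touch trace per
(subject, template) pair, and the template geometry.  The canonical storage
format is plain text: a JSON manifest listing subjects, the template registry
and trace files; one CSV per trace with header ``t_s,x_mm,y_mm``.

Cleaning applies three per-trace filters: traces shorter than 25 s, traces
whose spatial spread in either axis is below half that of the template, and
traces with a jump between consecutive samples larger than a quarter of the
screen in either dimension (typically device glitches or a second touch).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .templates import SCREEN_MM, Template, load_template_csv

__all__ = [
    "SubjectMeta",
    "TraceRecord",
    "Cohort",
    "CleaningReport",
    "ScreenSpec",
    "px_to_mm",
    "load_cohort",
    "write_cohort",
    "clean_cohort",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubjectMeta:
    """Metadata for one subject."""

    subject_id: str
    age: float | None = None
    handedness: str = "unknown"  # left / right / unknown
    gender: str = "unknown"

    def __post_init__(self):
        if self.age is not None and not (3.0 <= self.age <= 99.0):
            raise ValueError(f"age {self.age} outside plausible range [3, 99]")


@dataclass
class TraceRecord:
    """One subject's raw touch stream for one template.

    ``timestamps`` are seconds (strictly increasing, starting near 0) and
    ``points`` are the matching (x, y) positions in mm.
    """

    subject_id: str
    template_name: str
    timestamps: np.ndarray
    points: np.ndarray

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.points = np.asarray(self.points, dtype=float)
        if self.timestamps.ndim != 1 or len(self.timestamps) < 2:
            raise ValueError("trace needs at least 2 samples")
        if self.points.shape != (len(self.timestamps), 2):
            raise ValueError("points must be (n_samples, 2) matching timestamps")
        if not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not (np.all(np.isfinite(self.timestamps)) and np.all(np.isfinite(self.points))):
            raise ValueError("trace contains non-finite values")

    @property
    def duration(self) -> float:
        """Trace duration in seconds (last minus first timestamp)."""
        return float(self.timestamps[-1] - self.timestamps[0])

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)


@dataclass
class Cohort:
    """Subjects + traces + template geometry, validated for consistency."""

    subjects: list[SubjectMeta] = field(default_factory=list)
    traces: list[TraceRecord] = field(default_factory=list)
    templates: dict[str, Template] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject_id in cohort")
        known = set(ids)
        seen: set[tuple[str, str]] = set()
        for tr in self.traces:
            if tr.subject_id not in known:
                raise ValueError(f"trace references unknown subject {tr.subject_id!r}")
            if tr.template_name not in self.templates:
                raise ValueError(f"trace references unknown template {tr.template_name!r}")
            key = (tr.subject_id, tr.template_name)
            if key in seen:
                raise ValueError(f"more than one trace for {key}")
            seen.add(key)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_traces(self) -> int:
        return len(self.traces)

    def subject(self, subject_id: str) -> SubjectMeta:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def traces_for_template(self, template_name: str) -> list[TraceRecord]:
        return [t for t in self.traces if t.template_name == template_name]


@dataclass
class CleaningReport:
    """Tally of the three cleaning filters.

    A trace may fail several criteria; the per-criterion counts therefore need
    not sum to the number of removed traces.
    """

    n_input: int
    removed_short: int
    removed_low_std: int
    removed_jump: int
    n_retained: int
    reasons: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return self.n_input - self.n_retained

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "removed_short": self.removed_short,
            "removed_low_std": self.removed_low_std,
            "removed_jump": self.removed_jump,
            "n_retained": self.n_retained,
            "reasons": {f"{sid}/{tpl}": r for (sid, tpl), r in self.reasons.items()},
        }


@dataclass(frozen=True)
class ScreenSpec:
    """Touchscreen geometry used to convert device pixels to millimetres."""

    width_px: float = 1920.0
    height_px: float = 1200.0
    width_mm: float = SCREEN_MM[0]
    height_mm: float = SCREEN_MM[1]

    def __post_init__(self):
        if min(self.width_px, self.height_px, self.width_mm, self.height_mm) <= 0:
            raise ValueError("screen dimensions must be positive")


#: Identity screen: data already in mm pass through unchanged.
IDENTITY_SCREEN = ScreenSpec(1.0, 1.0, 1.0, 1.0)


def px_to_mm(points_px: np.ndarray, screen: ScreenSpec = ScreenSpec()) -> np.ndarray:
    """Linear per-axis pixel-to-mm conversion."""
    pts = np.asarray(points_px, dtype=float)
    scale = np.array([screen.width_mm / screen.width_px, screen.height_mm / screen.height_px])
    return pts * scale


# ---------------------------------------------------------------------------
# Canonical on-disk format
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, path) -> Path:
    """Write a cohort to ``path`` in the canonical manifest + CSV layout.

    Coordinates are stored at full float precision so that a round trip is
    bit-identical.
    """
    root = Path(path)
    (root / "traces").mkdir(parents=True, exist_ok=True)
    manifest: dict = {"subjects": [], "templates": {}, "traces": []}
    for s in cohort.subjects:
        manifest["subjects"].append(
            {"subject_id": s.subject_id, "age": s.age,
             "handedness": s.handedness, "gender": s.gender}
        )
    for name, tpl in cohort.templates.items():
        fn = f"template_{name}.csv"
        pd.DataFrame(tpl.dense_polyline, columns=["x_mm", "y_mm"]).to_csv(
            root / fn, index=False, float_format="%.17g"
        )
        manifest["templates"][name] = {"file": fn, "n_ref": tpl.n_ref}
    for tr in cohort.traces:
        fn = f"traces/{tr.subject_id}__{tr.template_name}.csv"
        df = pd.DataFrame(
            {"t_s": tr.timestamps, "x_mm": tr.points[:, 0], "y_mm": tr.points[:, 1]}
        )
        df.to_csv(root / fn, index=False, float_format="%.17g")
        manifest["traces"].append(
            {"subject_id": tr.subject_id, "template_name": tr.template_name, "file": fn}
        )
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return root


def load_cohort(path, dialect: str = "canonical") -> Cohort:
    """Load a cohort from the canonical layout.

    Unparseable trace files (malformed rows, wrong columns) are skipped with a
    logged warning; an empty or manifest-less directory yields an empty cohort.
    """
    if dialect != "canonical":
        raise ValueError(f"unknown dialect {dialect!r}")
    root = Path(path)
    mpath = root / "manifest.json"
    if not mpath.exists():
        return Cohort()
    manifest = json.loads(mpath.read_text())

    missing = [s for s in manifest.get("subjects", []) if "subject_id" not in s]
    if missing:
        raise ValueError("manifest subjects missing subject_id")
    subjects = [
        SubjectMeta(
            subject_id=s["subject_id"],
            age=s.get("age"),
            handedness=s.get("handedness", "unknown"),
            gender=s.get("gender", "unknown"),
        )
        for s in manifest.get("subjects", [])
    ]
    templates: dict[str, Template] = {}
    for name, info in manifest.get("templates", {}).items():
        tpl = load_template_csv(root / info["file"], n_ref=info.get("n_ref") or 100)
        tpl.name = name
        templates[name] = tpl

    traces: list[TraceRecord] = []
    n_skipped = 0
    for entry in manifest.get("traces", []):
        fn = root / entry["file"]
        try:
            df = pd.read_csv(fn, float_precision="round_trip")
            if not {"t_s", "x_mm", "y_mm"}.issubset(df.columns):
                raise ValueError("missing columns")
            arr = df[["t_s", "x_mm", "y_mm"]].to_numpy(dtype=float)
            traces.append(
                TraceRecord(
                    subject_id=entry["subject_id"],
                    template_name=entry["template_name"],
                    timestamps=arr[:, 0],
                    points=arr[:, 1:],
                )
            )
        except (ValueError, OSError, KeyError) as exc:
            n_skipped += 1
            logger.warning("skipping unparseable trace %s: %s", fn, exc)
    if n_skipped:
        logger.warning("skipped %d unparseable trace(s)", n_skipped)
    return Cohort(subjects=subjects, traces=traces, templates=templates)


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------

def _trace_failures(
    trace: TraceRecord,
    template: Template,
    min_duration: float,
    std_ratio: float,
    jump_fraction: float,
    screen_mm: tuple[float, float],
) -> list[str]:
    reasons = []
    if trace.duration < min_duration:
        reasons.append("short")
    tstd = template.std()
    xstd, ystd = trace.points.std(axis=0)
    if xstd < std_ratio * tstd[0] or ystd < std_ratio * tstd[1]:
        reasons.append("low_std")
    jumps = np.abs(np.diff(trace.points, axis=0))
    if np.any(jumps[:, 0] > jump_fraction * screen_mm[0]) or np.any(
        jumps[:, 1] > jump_fraction * screen_mm[1]
    ):
        reasons.append("jump")
    return reasons


def clean_cohort(
    cohort: Cohort,
    min_duration: float = 25.0,
    std_ratio: float = 0.5,
    jump_fraction: float = 0.25,
    screen_mm: tuple[float, float] = SCREEN_MM,
) -> tuple[Cohort, CleaningReport]:
    """Remove anomalous traces; returns the retained cohort plus a report.

    The verdict for each trace depends only on that trace and its template,
    so cleaning is idempotent and order-independent.  Subjects are retained
    in the output even if all their traces are removed.
    """
    kept: list[TraceRecord] = []
    reasons: dict[tuple[str, str], list[str]] = {}
    counts = {"short": 0, "low_std": 0, "jump": 0}
    for tr in cohort.traces:
        fails = _trace_failures(
            tr, cohort.templates[tr.template_name],
            min_duration, std_ratio, jump_fraction, screen_mm,
        )
        if fails:
            reasons[(tr.subject_id, tr.template_name)] = fails
            for f in fails:
                counts[f] += 1
            logger.info(
                "removed trace %s/%s: %s", tr.subject_id, tr.template_name,
                ",".join(fails),
            )
        else:
            kept.append(tr)
    report = CleaningReport(
        n_input=len(cohort.traces),
        removed_short=counts["short"],
        removed_low_std=counts["low_std"],
        removed_jump=counts["jump"],
        n_retained=len(kept),
        reasons=reasons,
    )
    cleaned = Cohort(
        subjects=list(cohort.subjects), traces=kept, templates=dict(cohort.templates)
    )
    return cleaned, report
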