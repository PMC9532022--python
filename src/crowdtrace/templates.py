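"""Closed reference curves ("templates") and their arc-length geometry.

A template is the curve shown on the touchscreen that subjects trace with a
finger.  For analysis the curve is divided into segments of equal arc length
and each segment is summarised by one *reference point*: the coordinate-wise
("median centre of mass") median of the dense polyline points falling in the
segment.  Trajectories are later binned against, aggregated at, and scored
against these reference points.

Coordinates are millimetres in the native touch convention: origin at the
screen's top-left corner, y increasing downward.  All error statistics are
invariant to this choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Template",
    "make_template",
    "segment_by_arclength",
    "compute_reference_points",
    "SCREEN_MM",
    "TEMPLATE_NAMES",
    "DEFAULT_N_REF",
]

#: Drawing area of the tablet screen, mm (width, height).
SCREEN_MM = (216.0, 135.0)

#: Centre of the drawing area, mm.
SCREEN_CENTRE = (SCREEN_MM[0] / 2.0, SCREEN_MM[1] / 2.0)

#: The five standard template families, in presentation order.
TEMPLATE_NAMES = ("ellipse", "thin_ellipse", "three_petal", "four_petal", "lemniscate")

#: Default reference-point counts: 50 for the two ellipses, 100 otherwise.
DEFAULT_N_REF = {
    "ellipse": 50,
    "thin_ellipse": 50,
    "three_petal": 100,
    "four_petal": 100,
    "lemniscate": 100,
}

#: Default bounding boxes (width, height) in mm for the analytic families.
DEFAULT_SIZE = {
    "ellipse": (110.0, 70.0),
    "thin_ellipse": (120.0, 40.0),
    "three_petal": (110.0, 110.0),
    "four_petal": (110.0, 110.0),
    "lemniscate": (110.0, 40.0),
}

_CLOSURE_TOL = 1e-6  # mm


@dataclass
class Template:
    """A closed reference curve with equal-arc-length segmentation.

    Attributes
    ----------
    name : str
        Template identifier (one of the five standard names, or ``custom``).
    dense_polyline : (N, 2) ndarray
        Ordered points in mm tracing the closed curve once; the last point
        coincides with the first.
    is_closed : bool
        Whether the curve closes (first and last point coincide).
    n_ref : int or None
        Number of reference points (equal-arc-length segments).
    segment_boundaries : (n_ref + 1,) ndarray or None
        Arc-length positions in mm delimiting the segments.
    point_segments : (N,) ndarray or None
        Segment label of each dense point.
    reference_points : (n_ref, 2) ndarray or None
        Coordinate-wise median of the dense points of each segment.
    """

    name: str
    dense_polyline: np.ndarray
    is_closed: bool = True
    n_ref: int | None = None
    segment_boundaries: np.ndarray | None = None
    point_segments: np.ndarray | None = None
    reference_points: np.ndarray | None = None
    _arclengths: np.ndarray | None = field(default=None, repr=False)

    # -- geometry helpers -------------------------------------------------
    @property
    def arclengths(self) -> np.ndarray:
        """Cumulative arc length at each dense point (starts at 0)."""
        if self._arclengths is None:
            steps = np.linalg.norm(np.diff(self.dense_polyline, axis=0), axis=1)
            self._arclengths = np.concatenate([[0.0], np.cumsum(steps)])
        return self._arclengths

    @property
    def total_length(self) -> float:
        """Total arc length of the polyline, mm."""
        return float(self.arclengths[-1])

    def point_at(self, s) -> np.ndarray:
        """Interpolate the curve at arc position(s) ``s`` (mod total length)."""
        s = np.asarray(s, dtype=float) % self.total_length
        x = np.interp(s, self.arclengths, self.dense_polyline[:, 0])
        y = np.interp(s, self.arclengths, self.dense_polyline[:, 1])
        return np.stack([x, y], axis=-1)

    def normal_at(self, s) -> np.ndarray:
        """Unit normal (left of the tangent) at arc position(s) ``s``."""
        s = np.atleast_1d(np.asarray(s, dtype=float)) % self.total_length
        tx = np.gradient(self.dense_polyline[:, 0], self.arclengths)
        ty = np.gradient(self.dense_polyline[:, 1], self.arclengths)
        nx = np.interp(s, self.arclengths, tx)
        ny = np.interp(s, self.arclengths, ty)
        norm = np.hypot(nx, ny)
        norm[norm == 0] = 1.0
        return np.stack([-ny / norm, nx / norm], axis=-1)

    def std(self) -> np.ndarray:
        """Per-axis standard deviation of the dense polyline points, mm."""
        return self.dense_polyline.std(axis=0)


def _analytic_polyline(name: str, n_dense: int) -> np.ndarray:
    """Canonical (unscaled, origin-centred) form of the named family."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_dense)
    if name == "ellipse" or name == "thin_ellipse":
        x, y = np.cos(theta), np.sin(theta)
    elif name == "three_petal":
        r = 35.0 + 20.0 * np.cos(3.0 * theta)
        x, y = r * np.cos(theta), r * np.sin(theta)
    elif name == "four_petal":
        r = 35.0 + 20.0 * np.cos(4.0 * theta)
        x, y = r * np.cos(theta), r * np.sin(theta)
    elif name == "lemniscate":
        # Lemniscate of Bernoulli in its rational parameterisation.
        d = 1.0 + np.sin(theta) ** 2
        x = np.cos(theta) / d
        y = np.sin(theta) * np.cos(theta) / d
    else:  # pragma: no cover - guarded by make_template
        raise ValueError(f"unknown template family: {name!r}")
    pts = np.stack([x, y], axis=1)
    pts[-1] = pts[0]  # exact closure despite floating-point trig
    return pts


def make_template(
    name: str,
    size: tuple[float, float] | None = None,
    n_dense: int = 2000,
    *,
    points: np.ndarray | None = None,
    n_ref: int | None = None,
) -> Template:
    """Construct a closed template curve centred in the drawing area.

    Parameters
    ----------
    name : str
        One of ``ellipse``, ``thin_ellipse``, ``three_petal``, ``four_petal``,
        ``lemniscate``, or ``custom``.
    size : (width, height), optional
        Bounding box in mm; defaults per family.  Must fit on the screen.
    n_dense : int
        Number of dense polyline points (>= 500) for analytic families.
    points : ndarray, optional
        For ``name="custom"``: user-supplied dense polyline in mm (closure is
        implied and enforced).
    n_ref : int, optional
        Reference-point count to record on the template (segmentation itself
        is performed by :func:`segment_by_arclength` /
        :func:`compute_reference_points`, see :func:`build_template`).
    """
    if name == "custom":
        if points is None:
            raise ValueError("custom template requires a point array")
        pts = np.asarray(points, dtype=float).copy()
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise ValueError("custom template points must be an (N, 2) array, N >= 3")
        if np.linalg.norm(pts[0] - pts[-1]) > _CLOSURE_TOL:
            pts = np.vstack([pts, pts[0]])  # closure implied
        return Template(name=name, dense_polyline=pts, n_ref=n_ref)

    if name not in TEMPLATE_NAMES:
        raise ValueError(f"unknown template name: {name!r}")
    if n_dense < 500:
        raise ValueError("n_dense must be >= 500")
    if size is None:
        size = DEFAULT_SIZE[name]
    width, height = float(size[0]), float(size[1])
    if width <= 0 or height <= 0:
        raise ValueError("degenerate size: width and height must be positive")
    if width > SCREEN_MM[0] or height > SCREEN_MM[1]:
        raise ValueError(
            f"size {size} exceeds the drawing area {SCREEN_MM[0]} x {SCREEN_MM[1]} mm"
        )

    pts = _analytic_polyline(name, n_dense)
    span = pts.max(axis=0) - pts.min(axis=0)
    if name in ("three_petal", "four_petal"):
        # Isotropic scaling about the polar origin preserves the k-fold
        # rotational symmetry of the rose; the box is taken as the tight
        # square the curve must fit in.
        scale = min(width / span[0], height / span[1])
        pts = pts * scale
    else:
        mid = (pts.max(axis=0) + pts.min(axis=0)) / 2.0
        pts = (pts - mid) * np.array([width, height]) / span
    pts += np.array(SCREEN_CENTRE)
    return Template(
        name=name,
        dense_polyline=pts,
        n_ref=n_ref if n_ref is not None else DEFAULT_N_REF[name],
    )


def segment_by_arclength(
    polyline: np.ndarray, n_segments: int
) -> tuple[np.ndarray, np.ndarray]:
    """Divide a closed polyline into ``n_segments`` equal-arc-length segments.

    Returns
    -------
    boundaries : (n_segments + 1,) ndarray
        Arc-length positions ``k * L / n_segments`` for k = 0..n_segments.
    labels : (N,) ndarray
        Segment index of each point of the (possibly deduplicated) polyline;
        segments are half-open ``[start, end)`` in arc length, with the final
        point (arc position L) assigned to the last segment.

    Zero-length edges (repeated identical consecutive points) are dropped with
    a warning before computing arc lengths.
    """
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    pts = np.asarray(polyline, dtype=float)
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(steps == 0.0):
        warnings.warn(
            "polyline contains repeated consecutive points; duplicates dropped",
            stacklevel=2,
        )
        keep = np.concatenate([[True], steps > 0.0])
        pts = pts[keep]
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(steps)])
    total = s[-1]
    if total <= 0:
        raise ValueError("polyline has zero total length")
    boundaries = np.arange(n_segments + 1) * (total / n_segments)
    boundaries[-1] = total
    labels = np.minimum(
        (n_segments * s / total).astype(int), n_segments - 1
    )
    return boundaries, labels


def compute_reference_points(template: Template) -> Template:
    """Fill in a template's reference points (in place; also returned).

    The reference point of each segment is the coordinate-wise median of the
    dense polyline points in that segment — the "median centre of mass".
    Requires ``template.n_ref``; performs segmentation if not done yet.
    """
    if template.n_ref is None:
        raise ValueError("template.n_ref must be set before computing reference points")
    if template.segment_boundaries is None or template.point_segments is None:
        boundaries, labels = segment_by_arclength(template.dense_polyline, template.n_ref)
        template.segment_boundaries = boundaries
        template.point_segments = labels
    n_ref = template.n_ref
    refs = np.empty((n_ref, 2))
    for k in range(n_ref):
        seg_pts = template.dense_polyline[template.point_segments == k]
        if len(seg_pts) == 0:
            raise ValueError(
                f"segment {k} of template {template.name!r} contains no dense points; "
                "increase n_dense or decrease n_ref"
            )
        refs[k] = np.median(seg_pts, axis=0)
    template.reference_points = refs
    return template


def build_template(
    name: str,
    size: tuple[float, float] | None = None,
    n_dense: int = 2000,
    *,
    points: np.ndarray | None = None,
    n_ref: int | None = None,
) -> Template:
    """:func:`make_template` followed by :func:`compute_reference_points`."""
    t = make_template(name, size, n_dense, points=points, n_ref=n_ref)
    if t.n_ref is None:
        raise ValueError("n_ref required to build a segmented template")
    return compute_reference_points(t)


def default_templates(n_dense: int = 2000) -> dict[str, Template]:
    """The five standard templates, segmented, keyed by name."""
    return {name: build_template(name, n_dense=n_dense) for name in TEMPLATE_NAMES}


def load_template_csv(path, name: str = "custom", n_ref: int = 100) -> Template:
    """Load a custom template from a CSV with header ``x_mm,y_mm``."""
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    if not {"x_mm", "y_mm"}.issubset(df.columns):
        raise ValueError("template CSV must have columns x_mm,y_mm")
    return build_template(
        "custom", points=df[["x_mm", "y_mm"]].to_numpy(float), n_ref=n_ref
    )
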