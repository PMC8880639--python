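"""Shape recognition: model selection heuristics and constrained-DTW matching.

Each separated character must be labelled rectangle or triangle.  Typical
("model") shapes are first picked from the scan itself by cheap geometric
tests — the ratio of minimum enclosing triangle to enclosing rectangle area,
a Hough-style search for a long horizontal stroke (the rectangle's top), and
the fraction of signal samples near full amplitude (a rectangle's plateau).
Classes that yield no models fall back to three artificial templates.  Every
remaining character is then assigned the class of its nearest model under
band-constrained dynamic time warping on the normalized signal segment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .scan_io import RECTANGLE, TRIANGLE, ValidationError
from .segmentation import CharacterROI, CharacterSignal

logger = logging.getLogger(__name__)


class ShapeLabel(str, Enum):
    RECTANGLE = RECTANGLE
    TRIANGLE = TRIANGLE


@dataclass
class RecognitionConfig:
    """Thresholds of the model-selection rules (all dimensionless)."""

    tri_ratio_threshold: float = 0.55
    hough_frac: float = 0.25
    amp_hi: float = 0.66
    amp_lo: float = 0.33
    amp_level: float = 0.80
    dtw_window: float = 0.05
    hough_angle_tol: float = 5.0  # degrees


@dataclass
class ModelSet:
    """Per-scan reference signals for both shape classes."""

    rect_models: list[np.ndarray]
    tri_models: list[np.ndarray]
    rect_artificial: bool = False
    tri_artificial: bool = False
    model_length: int = 100

    def __post_init__(self) -> None:
        if not self.rect_models or not self.tri_models:
            raise ValidationError("both model lists must be non-empty")


@dataclass
class EnclosureStats:
    """Minimum-enclosure areas and derived shape cues for one character."""

    R: float  # min enclosing rectangle area, px^2
    T: float  # min enclosing triangle area, px^2
    hough_hfrac: float
    amp_frac: float

    @property
    def tri_ratio(self) -> float:
        return self.T / (self.R + self.T)


# ---------------------------------------------------------------------------
# minimum enclosing shapes (rotating calipers / flush-side enumeration)
# ---------------------------------------------------------------------------

def _hull_vertices(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or len(points) < 3:
        raise ValidationError("need at least 3 points in the plane")
    try:
        hull = ConvexHull(points)
    except QhullError as exc:
        raise ValidationError(f"degenerate (collinear) point set: {exc}") from exc
    return points[hull.vertices]  # counter-clockwise


def min_enclosing_rectangle(points: np.ndarray) -> tuple[float, np.ndarray]:
    """Minimum-area rectangle (any orientation) containing the points.

    Rotating calipers: the optimal rectangle has one side collinear with a
    convex-hull edge, so it suffices to test each hull-edge direction.
    Returns ``(area, corners)`` with corners in order around the rectangle.
    """
    hv = _hull_vertices(points)
    edges = np.roll(hv, -1, axis=0) - hv
    best_area = np.inf
    best_corners = None
    for ex, ey in edges:
        norm = np.hypot(ex, ey)
        if norm == 0:
            continue
        u = np.array([ex, ey]) / norm
        v = np.array([-u[1], u[0]])
        pu = hv @ u
        pv = hv @ v
        du, dv = pu.max() - pu.min(), pv.max() - pv.min()
        area = du * dv
        if area < best_area:
            best_area = area
            o = pu.min() * u + pv.min() * v
            best_corners = np.array([o, o + du * u, o + du * u + dv * v,
                                     o + dv * v])
    return float(best_area), best_corners


def _cross2(ax, ay, bx, by):
    return ax * by - ay * bx


def _triangle_contains(tri: np.ndarray, pts: np.ndarray, tol: float) -> bool:
    a, b, c = tri
    area2 = _cross2(b[0] - a[0], b[1] - a[1], c[0] - a[0], c[1] - a[1])
    if abs(area2) < 1e-12:
        return False
    sign = 1.0 if area2 > 0 else -1.0
    px, py = pts[:, 0], pts[:, 1]
    for p, q in ((a, b), (b, c), (c, a)):
        cr = (q[0] - p[0]) * (py - p[1]) - (q[1] - p[1]) * (px - p[0])
        if np.any(sign * cr < -tol):
            return False
    return True


def min_enclosing_triangle(points: np.ndarray) -> tuple[float, np.ndarray]:
    """Minimum-area triangle containing the points.

    A minimal enclosing triangle has every side touching the convex hull
    with the side's midpoint on the hull, and at least one side flush with a
    hull edge.  Candidates are therefore enumerated as (i) two sides flush
    with hull edges and the third tangent at a hull vertex placed at the
    side's midpoint, and (ii) all three sides flush; the smallest candidate
    containing the hull wins.  Returns ``(area, corners)``.
    """
    hv = _hull_vertices(points)
    n = len(hv)
    if n == 3:
        area = 0.5 * abs(_cross2(hv[1, 0] - hv[0, 0], hv[1, 1] - hv[0, 1],
                                 hv[2, 0] - hv[0, 0], hv[2, 1] - hv[0, 1]))
        return float(area), hv.copy()
    dirs = np.roll(hv, -1, axis=0) - hv
    scale = float(np.max(np.ptp(hv, axis=0)))
    tol = 1e-9 * max(scale, 1.0) ** 2

    best_area = np.inf
    best_tri = None

    def consider(X, Y, Z, area) -> None:
        nonlocal best_area, best_tri
        tri = np.array([X, Y, Z])
        if _triangle_contains(tri, hv, tol * 10):
            best_area = area
            best_tri = tri

    for i in range(n):
        dix, diy = dirs[i]
        for j in range(i + 1, n):
            djx, djy = dirs[j]
            denom = _cross2(dix, diy, djx, djy)
            if abs(denom) < 1e-12 * scale * scale:
                continue
            # apex: intersection of the two flush support lines
            rx = hv[j, 0] - hv[i, 0]
            ry = hv[j, 1] - hv[i, 1]
            s_apex = _cross2(rx, ry, djx, djy) / denom
            Xx = hv[i, 0] + s_apex * dix
            Xy = hv[i, 1] + s_apex * diy
            # (i) third side tangent at hull vertex V == its own midpoint:
            # solve [di dj] [s t]' = 2 (V - X)
            vx = hv[:, 0] - Xx
            vy = hv[:, 1] - Xy
            s_all = 2.0 * (vx * djy - vy * djx) / denom
            t_all = 2.0 * (diy * vx - dix * vy) / -denom
            areas = 0.5 * np.abs(s_all * t_all * denom)
            for k in range(n):
                if areas[k] >= best_area or s_all[k] == 0 or t_all[k] == 0:
                    continue
                consider((Xx, Xy),
                         (Xx + s_all[k] * dix, Xy + s_all[k] * diy),
                         (Xx + t_all[k] * djx, Xy + t_all[k] * djy),
                         areas[k])
            # (ii) third side flush with edge k
            for k in range(n):
                if k in (i, j):
                    continue
                dkx, dky = dirs[k]
                d1 = _cross2(dix, diy, dkx, dky)
                d2 = _cross2(djx, djy, dkx, dky)
                if (abs(d1) < 1e-12 * scale**2
                        or abs(d2) < 1e-12 * scale**2):
                    continue
                s1 = _cross2(hv[k, 0] - hv[i, 0], hv[k, 1] - hv[i, 1],
                             dkx, dky) / d1
                s2 = _cross2(hv[k, 0] - hv[j, 0], hv[k, 1] - hv[j, 1],
                             dkx, dky) / d2
                Yx, Yy = hv[i, 0] + s1 * dix, hv[i, 1] + s1 * diy
                Zx, Zy = hv[j, 0] + s2 * djx, hv[j, 1] + s2 * djy
                area = 0.5 * abs(_cross2(Yx - Xx, Yy - Xy, Zx - Xx, Zy - Xy))
                if area < best_area:
                    consider((Xx, Xy), (Yx, Yy), (Zx, Zy), area)

    if best_tri is None:
        raise ValidationError("no valid enclosing triangle found")
    return float(best_area), best_tri


# ---------------------------------------------------------------------------
# per-character cues
# ---------------------------------------------------------------------------

def hough_horizontal_fraction(roi: CharacterROI, angle_tol: float = 5.0,
                              gap: int = 2) -> float:
    """Length of the longest near-horizontal stroke over the character width.

    A line-parameter search restricted to ``|angle| <= angle_tol`` degrees
    from horizontal: for each candidate angle the ink pixels are sheared
    into horizontal bands one stroke-width tall and the longest run (small
    gaps bridged) is measured.  Open rectangles carry a full-width top
    stroke, triangles only short near-horizontal fragments.
    """
    sub = roi.sub_mask
    rows, cols = np.nonzero(sub)
    if len(rows) == 0:
        raise ValidationError("empty ROI")
    width = sub.shape[1]
    if width < 2:
        return 0.0
    best = 0
    for ang in np.deg2rad(np.linspace(-angle_tol, angle_tol, 11)):
        # shear pixels so a line at this angle becomes horizontal
        band = np.round(rows - np.tan(ang) * cols).astype(int)
        for b in np.unique(band):
            sel = np.sort(cols[band == b])
            if len(sel) == 0:
                continue
            run = length = 1
            for d in np.diff(sel):
                if d <= gap + 1:
                    run += d
                else:
                    run = 1
                length = max(length, run)
            best = max(best, length)
    return best / width


def amplitude_fraction(cs: CharacterSignal, level: float = 0.80) -> float:
    """Fraction of the normalized signal samples above ``level``.

    Near 1 for rectangles (flat top plateau), near 0.2 for symmetric
    triangles (only the apex region of the tent exceeds 80% amplitude).
    """
    norm = cs.normalized  # raises on zero amplitude
    return float(np.mean(norm > level))


def enclosure_stats(roi: CharacterROI, cs: CharacterSignal,
                    cfg: RecognitionConfig) -> EnclosureStats | None:
    """All recognition cues for one character; None when degenerate."""
    rows, cols = np.nonzero(roi.sub_mask)
    pts = np.column_stack([cols, rows]).astype(float)
    try:
        R, _ = min_enclosing_rectangle(pts)
        T, _ = min_enclosing_triangle(pts)
        if R <= 0 or T <= 0:
            return None
    except ValidationError:
        return None
    return EnclosureStats(R=R, T=T,
                          hough_hfrac=hough_horizontal_fraction(
                              roi, cfg.hough_angle_tol),
                          amp_frac=amplitude_fraction(cs, cfg.amp_level))


# ---------------------------------------------------------------------------
# artificial templates
# ---------------------------------------------------------------------------

def _trapezoid(length: int, top_frac: float) -> np.ndarray:
    """Unit-amplitude symmetric trapezoid; top_frac = top side / base."""
    x = np.linspace(0.0, 1.0, length)
    ramp = (1.0 - top_frac) / 2.0
    y = np.clip(np.minimum(np.minimum(x / ramp, (1.0 - x) / ramp), 1.0),
                0.0, 1.0)
    return y / y.max()  # exactly unit amplitude on the sample grid


def _tent(length: int, apex_frac: float) -> np.ndarray:
    """Unit-amplitude tent with apex at ``apex_frac`` of the width."""
    x = np.linspace(0.0, 1.0, length)
    up = x / apex_frac
    down = (1.0 - x) / (1.0 - apex_frac)
    y = np.clip(np.minimum(up, down), 0.0, 1.0)
    return y / y.max()  # exactly unit amplitude on the sample grid


def perfect_rectangle_template(length: int, edge_frac: float = 0.05
                               ) -> np.ndarray:
    """Signal form of an ideal open rectangle: near-full-width plateau."""
    return _trapezoid(length, 1.0 - 2 * edge_frac)


def perfect_triangle_template(length: int) -> np.ndarray:
    """Signal form of an ideal open triangle: symmetric tent."""
    return _tent(length, 0.5)


def artificial_rect_models(length: int) -> list[np.ndarray]:
    """Perfect rectangle plus two isosceles trapezoids (tops 0.5, 0.7)."""
    return [perfect_rectangle_template(length),
            _trapezoid(length, 0.5), _trapezoid(length, 0.7)]


def artificial_tri_models(length: int) -> list[np.ndarray]:
    """Perfect triangle plus two mirrored right triangles (apex 0.25, 0.75)."""
    return [perfect_triangle_template(length),
            _tent(length, 0.25), _tent(length, 0.75)]


# ---------------------------------------------------------------------------
# model selection
# ---------------------------------------------------------------------------

def _normalize_resample(values: np.ndarray, length: int) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    amp = v.max() - v.min()
    if amp > 0:
        v = (v - v.min()) / amp
    else:
        v = np.zeros_like(v)
    if len(v) == length:
        return v
    src = np.linspace(0.0, 1.0, len(v))
    dst = np.linspace(0.0, 1.0, length)
    return np.interp(dst, src, v)


def select_models(chars: list[tuple[CharacterROI, CharacterSignal]],
                  cfg: RecognitionConfig | None = None
                  ) -> tuple[ModelSet, dict[int, ShapeLabel]]:
    """Pick per-scan model shapes; returns the set and {index: class} of models.

    Rules, applied in order, first match wins:
      (a) enclosing-triangle share T/(R+T) below the threshold -> triangle;
      (b) the smaller of the two enclosures, when its share of R+T is below
          the same threshold -> that class;
      (c) a near-horizontal stroke longer than ``hough_frac`` of the
          character width -> rectangle;
      (d) amplitude histogram: plateau occupancy above ``amp_hi`` ->
          rectangle, below ``amp_lo`` -> triangle.
    A class left without models receives three artificial templates.
    """
    if not chars:
        raise ValidationError("no characters to select models from")
    cfg = cfg or RecognitionConfig()
    length = int(np.median([roi.width for roi, _ in chars]))
    length = max(length, 8)

    assignments: dict[int, ShapeLabel] = {}
    rect_models: list[np.ndarray] = []
    tri_models: list[np.ndarray] = []
    for i, (roi, cs) in enumerate(chars):
        try:
            stats = enclosure_stats(roi, cs, cfg)
        except ValidationError:
            stats = None
        label: ShapeLabel | None = None
        if stats is not None:
            if stats.tri_ratio < cfg.tri_ratio_threshold:
                label = ShapeLabel.TRIANGLE  # (a)
            elif (stats.R < stats.T
                  and stats.R / (stats.R + stats.T) < cfg.tri_ratio_threshold):
                label = ShapeLabel.RECTANGLE  # (b)
            elif (stats.T < stats.R
                  and stats.tri_ratio < cfg.tri_ratio_threshold):
                label = ShapeLabel.TRIANGLE  # (b)
            elif stats.hough_hfrac > cfg.hough_frac:
                label = ShapeLabel.RECTANGLE  # (c)
            elif stats.amp_frac > cfg.amp_hi:
                label = ShapeLabel.RECTANGLE  # (d)
            elif stats.amp_frac < cfg.amp_lo:
                label = ShapeLabel.TRIANGLE  # (d)
        if label is None:
            continue
        assignments[i] = label
        template = _normalize_resample(cs.values, length)
        (rect_models if label is ShapeLabel.RECTANGLE else tri_models
         ).append(template)

    rect_artificial = not rect_models
    tri_artificial = not tri_models
    if rect_artificial:
        rect_models = artificial_rect_models(length)
    if tri_artificial:
        tri_models = artificial_tri_models(length)
    return (ModelSet(rect_models, tri_models, rect_artificial,
                     tri_artificial, model_length=length), assignments)


# ---------------------------------------------------------------------------
# dynamic time warping
# ---------------------------------------------------------------------------

def dtw_distance(a: np.ndarray, b: np.ndarray,
                 window_frac: float = 0.05) -> float:
    """Band-constrained DTW distance with squared local cost.

    Classic dynamic programme with steps (i-1,j), (i,j-1), (i-1,j-1) and
    matched boundaries; a sample pair (i, j) is admissible only inside the
    slope-scaled band ``|i*(m/n) - j| <= window_frac * max(n, m)``.  If the
    band is too narrow to connect the corners the unconstrained distance is
    returned instead (logged).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("DTW inputs must be non-empty")
    if not 0 < window_frac <= 1:
        raise ValidationError("window_frac must lie in (0, 1]")
    n, m = len(a), len(b)
    w = window_frac * max(n, m)
    slope = m / n
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        centre = i * slope
        j_lo = max(int(np.ceil(centre - w)), 1)
        j_hi = min(int(np.floor(centre + w)), m)
        if j_lo > j_hi:
            continue
        for j in range(j_lo, j_hi + 1):
            cost = (a[i - 1] - b[j - 1]) ** 2
            D[i, j] = cost + min(D[i - 1, j], D[i, j - 1], D[i - 1, j - 1])
    result = D[n, m]
    if not np.isfinite(result):
        logger.warning("DTW band infeasible (n=%d, m=%d, w=%.3f); "
                       "falling back to the unconstrained path", n, m, w)
        return dtw_distance(a, b, 1.0)
    return float(result)


def classify_characters(chars: list[CharacterSignal], models: ModelSet,
                        window_frac: float = 0.05,
                        model_assignments: dict[int, ShapeLabel] | None = None,
                        ) -> list[ShapeLabel]:
    """Label every character by its nearest model under constrained DTW.

    Characters already chosen as models keep their selection class; the
    rest are amplitude-normalized, resampled to the model length and
    assigned the class of the arg-min model.  Ties break toward RECTANGLE.
    """
    model_assignments = model_assignments or {}
    labels: list[ShapeLabel] = []
    for i, cs in enumerate(chars):
        if i in model_assignments:
            labels.append(model_assignments[i])
            continue
        sig = _normalize_resample(cs.values, models.model_length)
        d_rect = min(dtw_distance(sig, m, window_frac)
                     for m in models.rect_models)
        d_tri = min(dtw_distance(sig, m, window_frac)
                    for m in models.tri_models)
        if d_rect == d_tri:
            logger.info("DTW tie for character %d; labelling RECTANGLE", i)
        labels.append(ShapeLabel.RECTANGLE if d_rect <= d_tri
                      else ShapeLabel.TRIANGLE)
    return labels
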