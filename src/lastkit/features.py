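"""Per-character feature extraction and the series-level NW coefficient.

Every character is measured both as a sub-image (bounding box before and
after straightening, ink area, convex hull, equivalent-ellipse axes and
orientation) and as a signal segment (polyline arc length, amplitude
plateau occupancy, DTW distance from the ideal template of its class).
Spatial features are additionally normalized against the template character
drawn by the examiner — the first rectangle or triangle of the series —
which makes series from different examiners comparable.  Per-series records
aggregate the medians (MED) and interquartile ranges (IQR) per shape class,
the per-class width ratios, and the NW coefficient: a normalized
Needleman–Wunsch alignment score of the recognized shape sequence against
the ideal alternation (100% = perfectly alternating series).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

from .recognition import (ModelSet, ShapeLabel, amplitude_fraction,
                          dtw_distance, perfect_rectangle_template,
                          perfect_triangle_template, _normalize_resample)
from .scan_io import RECTANGLE, TRIANGLE, ValidationError
from .segmentation import CharacterROI, CharacterSignal

def px_to_mm(px: float, dpi: int) -> float:
    """Convert a pixel measurement to millimetres at the given scan dpi."""
    return px * 25.4 / dpi


#: features divided by the examiner template during normalization (all in px)
SPATIAL_FEATURES = ("width", "height", "width_s", "height_s", "area",
                    "convex_hull_area", "long_axis", "short_axis",
                    "signal_length")

CharacterFeatures = dict  # named feature map; see character_features()


@dataclass
class NwParams:
    """Scoring of the sequence alignment: match reward, mismatch and gap."""

    m: float = 1.0
    p: float = 0.0
    g: float = 0.0


@dataclass
class SeriesRecord:
    """Aggregated per-subject outcome of one processed series."""

    subject: str
    group: str | None
    sequence: str  # examinee characters only, left-to-right
    aggregates: dict[str, float]
    width_ratio_rect: float
    width_ratio_tri: float
    nw: float
    n_characters: int
    examiner_templates: dict[str, CharacterFeatures]
    characters: list[CharacterFeatures] = field(default_factory=list)

    def as_row(self) -> dict:
        row: dict = {"subject": self.subject, "group": self.group}
        row.update(self.aggregates)
        row.update(width_ratio_rect=self.width_ratio_rect,
                   width_ratio_tri=self.width_ratio_tri, nw=self.nw,
                   n_characters=self.n_characters, sequence=self.sequence)
        return row

    def as_dict(self) -> dict:
        return {"subject": self.subject, "group": self.group,
                "sequence": self.sequence, "nw": self.nw,
                "width_ratio_rect": self.width_ratio_rect,
                "width_ratio_tri": self.width_ratio_tri,
                "aggregates": self.aggregates,
                "examiner_templates": self.examiner_templates,
                "characters": self.characters}


# ---------------------------------------------------------------------------
# straightening
# ---------------------------------------------------------------------------

def _ellipse_moments(mask: np.ndarray) -> tuple[float, float, float]:
    """Axis lengths (long, short) and orientation of the equivalent ellipse.

    Orientation is the angle of the major axis above the horizontal, in
    degrees within (-90, 90], measured in up-positive page coordinates.
    """
    rows, cols = np.nonzero(mask)
    x = cols.astype(float)
    y = -rows.astype(float)  # up-positive
    mu20 = np.var(x)
    mu02 = np.var(y)
    mu11 = np.mean((x - x.mean()) * (y - y.mean()))
    common = np.sqrt(4 * mu11**2 + (mu20 - mu02) ** 2)
    lam1 = (mu20 + mu02 + common) / 2
    lam2 = (mu20 + mu02 - common) / 2
    long_axis = 4 * np.sqrt(max(lam1, 0))
    short_axis = 4 * np.sqrt(max(lam2, 0))
    if abs(lam1 - lam2) < 1e-6:
        angle = 0.0  # isotropic: no preferred direction
    else:
        angle = np.degrees(0.5 * np.arctan2(2 * mu11, mu20 - mu02))
    if angle <= -90:
        angle += 180.0
    return float(long_axis), float(short_axis), float(angle)


def straighten(roi: CharacterROI) -> tuple[np.ndarray, float]:
    """Rotate a character upright using its equivalent-ellipse orientation.

    Returns the re-binarized rotated mask and the rotation angle (degrees).
    Isotropic characters rotate by 0 by convention.
    """
    sub = roi.sub_mask
    rows, cols = np.nonzero(sub)
    if len(rows) < 3:
        raise ValidationError("degenerate ROI: too few pixels")
    _, _, angle = _ellipse_moments(sub)
    if angle == 0.0:
        return sub.copy(), 0.0
    # page y is the negated row axis, so undoing a +angle tilt means a
    # further rotation by +angle in array coordinates
    rot = ndimage.rotate(sub.astype(float), -angle, reshape=True, order=1)
    return rot > 0.5, float(angle)


# ---------------------------------------------------------------------------
# per-character features
# ---------------------------------------------------------------------------

def character_features(roi: CharacterROI, cs: CharacterSignal,
                       label: ShapeLabel, models: ModelSet,
                       dtw_window: float = 0.05) -> CharacterFeatures:
    """Measure one character; returns the named feature map.

    ``dtw_model`` is the constrained-DTW distance between the normalized
    signal segment and the *perfect* artificial template of the character's
    class, a per-character deviation-from-ideal score.
    """
    sub = roi.sub_mask
    rows, cols = np.nonzero(sub)
    if len(rows) < 3:
        raise ValidationError("degenerate ROI")
    long_axis, short_axis, angle = _ellipse_moments(sub)
    rot, _ = straighten(roi)
    r_rows, r_cols = np.nonzero(rot)
    try:
        hull_area = float(ConvexHull(np.column_stack([cols, rows])).volume)
    except QhullError:
        hull_area = 0.0

    # arc length of the signal polyline, skipping interpolated samples
    v = cs.values
    keep = np.ones(len(v), dtype=bool)
    if cs.gap_mask is not None:
        keep = ~cs.gap_mask
    dy = np.diff(v)
    seg_ok = keep[:-1] & keep[1:]
    signal_length = float(np.sum(np.sqrt(1.0 + dy[seg_ok] ** 2)))

    length = models.model_length
    template = (perfect_rectangle_template(length)
                if label is ShapeLabel.RECTANGLE
                else perfect_triangle_template(length))
    sig = _normalize_resample(v, length)

    return {
        "width": float(roi.width),
        "height": float(roi.height),
        "width_s": float(r_cols.max() - r_cols.min() + 1) if len(r_cols) else 0.0,
        "height_s": float(r_rows.max() - r_rows.min() + 1) if len(r_rows) else 0.0,
        "area": float(sub.sum()),
        "convex_hull_area": hull_area,
        "long_axis": long_axis,
        "short_axis": short_axis,
        "angle": angle,
        "signal_length": signal_length,
        "amp_frac": amplitude_fraction(cs),
        "dtw_model": dtw_distance(sig, template, dtw_window),
    }


def normalize_to_template(f: CharacterFeatures,
                          template: CharacterFeatures) -> CharacterFeatures:
    """Divide every spatial feature by the examiner template's value.

    Adds ``*_n`` entries; dimensionless features (angle, amp_frac,
    dtw_model) are left untouched.
    """
    out = dict(f)
    for name in SPATIAL_FEATURES:
        t = template.get(name)
        if t is None or t == 0:
            raise ValidationError(f"template feature {name!r} missing or zero")
        out[name + "_n"] = f[name] / t
    return out


# ---------------------------------------------------------------------------
# the NW coefficient
# ---------------------------------------------------------------------------

def nw_coefficient(E: str, G: str, nwp: NwParams | None = None) -> float:
    """Normalized Needleman–Wunsch score of sequence E against standard G.

    The scoring matrix H is filled with reward ``m`` on a match, penalty
    ``p`` on a mismatch and gap penalty ``g``; the result is
    ``max(H_EG) / max(H_GG) * 100``.  With the defaults (m=1, p=g=0) this
    equals the longest-common-subsequence length over ``len(G)`` — 100%
    for a perfectly alternating series.
    """
    if len(G) == 0:
        raise ValidationError("standard sequence must be non-empty")
    nwp = nwp or NwParams()
    if len(E) > len(G):
        E = E[: len(G)]

    m, p, g = nwp.m, nwp.p, nwp.g

    def nw_max(a: str, b: str) -> float:
        nb = len(b)
        prev = [0.0] * (nb + 1)
        for j in range(1, nb + 1):
            prev[j] = prev[j - 1] + g
        best = max(prev)
        for ca in a:
            row = [prev[0] + g]
            for j in range(1, nb + 1):
                diag = prev[j - 1] + (m if ca == b[j - 1] else p)
                up = prev[j] + g
                left = row[j - 1] + g
                row.append(diag if diag >= up and diag >= left
                           else (up if up >= left else left))
            prev = row
            rb = max(row)
            if rb > best:
                best = rb
        return best

    denom = nw_max(G, G)
    if denom == 0:
        raise ValidationError("degenerate scoring: max(H_GG) is zero")
    return nw_max(E, G) / denom * 100.0


def ideal_alternation(first: str, length: int) -> str:
    """The perfect alternating sequence of given length starting at ``first``."""
    if first not in (RECTANGLE, TRIANGLE):
        raise ValidationError("first shape must be 'R' or 'T'")
    other = TRIANGLE if first == RECTANGLE else RECTANGLE
    return "".join(first if i % 2 == 0 else other for i in range(length))


# ---------------------------------------------------------------------------
# per-series aggregation
# ---------------------------------------------------------------------------

def _quantiles(values: list[float]) -> tuple[float, float]:
    """(median, IQR) with linear-interpolation quantiles; IQR needs n >= 2."""
    arr = np.asarray(values, dtype=float)
    med = float(np.median(arr))
    if len(arr) < 2:
        return med, np.nan
    q1, q3 = np.percentile(arr, [25, 75])
    return med, float(q3 - q1)


def series_features(chars: list[tuple[CharacterFeatures, ShapeLabel]],
                    extent: float,
                    examiner_templates: dict[str, CharacterFeatures],
                    nwp: NwParams | None = None,
                    expected_first: str | None = None,
                    subject: str = "", group: str | None = None,
                    ) -> SeriesRecord:
    """Aggregate examinee characters into one :class:`SeriesRecord`.

    ``extent`` is the full x-extent of the examinee part of the series in
    px.  ``expected_first`` is the shape the examinee should have drawn
    first (continuing the examiner's alternation); it anchors the ideal
    sequence the NW coefficient is computed against and defaults to the
    first recognized shape.
    """
    if not chars:
        raise ValidationError("no examinee characters")
    if extent <= 0:
        raise ValidationError("series extent must be positive")

    normalized: list[tuple[CharacterFeatures, ShapeLabel]] = []
    for f, label in chars:
        tpl = examiner_templates.get(label.value)
        if tpl is None:
            raise ValidationError(
                f"no examiner template for class {label.value!r}")
        normalized.append((normalize_to_template(f, tpl), label))

    aggregates: dict[str, float] = {}
    width_sums = {}
    for cls in (RECTANGLE, TRIANGLE):
        values = [f for f, lab in normalized if lab.value == cls]
        width_sums[cls] = sum(f["width"] for f in values)
        names = sorted(values[0].keys()) if values else []
        for name in names:
            med, iqr = _quantiles([f[name] for f in values])
            aggregates[f"{cls}_MED_{name}"] = med
            aggregates[f"{cls}_IQR_{name}"] = iqr

    sequence = "".join(lab.value for _, lab in chars)
    first = expected_first or sequence[0]
    nw = nw_coefficient(sequence, ideal_alternation(first, len(sequence)), nwp)

    return SeriesRecord(
        subject=subject, group=group, sequence=sequence,
        aggregates=aggregates,
        width_ratio_rect=width_sums[RECTANGLE] / extent * 100.0,
        width_ratio_tri=width_sums[TRIANGLE] / extent * 100.0,
        nw=nw, n_characters=len(chars),
        examiner_templates=examiner_templates,
        characters=[dict(f, label=lab.value) for f, lab in normalized])
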