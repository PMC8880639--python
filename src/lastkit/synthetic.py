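"""Synthetic alternating-series scans with exact ground truth.

The generator emulates a scanned paper form of the alternating-series
drawing task: a left-to-right chain of open rectangles and triangles drawn
without pen lifts (consecutive shapes joined by short baseline strokes),
with pencil stroke width, scanner noise and salt speckle, slow vertical
drift of the writing line, per-character size jitter and skew, progressive
size decay (micrographia) and perseveration errors (shape repetitions).
Because every stroke is placed analytically, the character masks, labels
and the ideal signal envelope are known exactly, which makes every pipeline
stage testable without clinical scans.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .scan_io import RECTANGLE, TRIANGLE, GrayImage, LabelOverlay, ValidationError

INK = 30          # stroke intensity, 8-bit gray
PAPER = 250       # background intensity
MARGIN = 40       # page margin, px


@dataclass
class SyntheticSpec:
    """Parametrization of one synthetic scan.

    Geometry defaults model visually plausible ~5 mm characters at 600 dpi
    (120 x 100 px).  ``micrographia_rate`` multiplies character size once
    per examinee character (1.0 = no decay); ``p_perseveration`` is the
    per-character probability of repeating the previous shape instead of
    alternating.  Drift is a slow sinusoid of the writing line; its default
    period is much longer than the series so it acts as a gentle wander.
    """

    n_chars: int = 12
    examiner_n: int = 5
    char_width_mean: float = 120.0
    char_width_sd: float = 8.0
    char_height_mean: float = 100.0
    char_height_sd: float = 8.0
    gap_mean: float = 30.0
    stroke_width: int = 3
    noise_sd: float = 4.0
    speckle_rate: float = 5e-5
    drift_amplitude: float = 20.0
    drift_period: float = 8000.0
    micrographia_rate: float = 1.0
    p_perseveration: float = 0.0
    skew_sd: float = 0.0
    rect_lean_deg: float = 4.0  # inward lean of rectangle sides (hand-drawn
    # verticals are never vertical; also anchors the first scan column at
    # the writing line rather than a character top)
    dpi: int = 600
    seed: int = 0
    page_width: int | None = None  # None = sized to fit

    def validate(self) -> None:
        if min(self.char_width_mean, self.char_height_mean, self.gap_mean,
               self.stroke_width, self.drift_period) <= 0:
            raise ValidationError("all sizes must be positive")
        if not 0 <= self.p_perseveration <= 1:
            raise ValidationError("p_perseveration must lie in [0, 1]")
        if not 0 < self.micrographia_rate <= 1:
            raise ValidationError("micrographia_rate must lie in (0, 1]")
        if self.n_chars < 1 or self.examiner_n < 0:
            raise ValidationError("need at least one examinee character")


@dataclass
class SyntheticTruth:
    """Exact ground truth of one rendered scan."""

    sequence: str                      # examiner + examinee shapes
    masks: list[np.ndarray]            # disjoint per-character ink masks
    envelope_x: np.ndarray             # columns of the ideal envelope
    envelope_y: np.ndarray             # ideal upper envelope (up-positive)
    examiner_n: int
    examiner_dims: dict[str, tuple[float, float]]  # class -> (width, height)
    spec: SyntheticSpec | None = None

    @property
    def examinee_sequence(self) -> str:
        return self.sequence[self.examiner_n:]

    def to_overlay(self) -> LabelOverlay:
        return LabelOverlay(masks=[m.copy() for m in self.masks],
                            labels=list(self.sequence),
                            examiner=[i < self.examiner_n
                                      for i in range(len(self.sequence))])


def _char_polyline(shape: str, x0: float, w: float, h: float,
                   lean_deg: float = 4.0) -> np.ndarray:
    """Vertices of one open character starting at baseline point (x0, 0)."""
    if shape == RECTANGLE:
        dx = h * np.tan(np.deg2rad(lean_deg))
        return np.array([[x0, 0.0], [x0 + dx, h],
                         [x0 + w - dx, h], [x0 + w, 0.0]])
    return np.array([[x0, 0.0], [x0 + w / 2.0, h], [x0 + w, 0.0]])


def _rotate_about(pts: np.ndarray, pivot: np.ndarray, deg: float) -> np.ndarray:
    th = np.deg2rad(deg)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    return (pts - pivot) @ R.T + pivot


def _sample_segments(polyline: np.ndarray, step: float = 0.25) -> np.ndarray:
    """Dense points along a polyline (sub-pixel step for clean rasters)."""
    out = []
    for p, q in zip(polyline[:-1], polyline[1:]):
        n = max(int(np.ceil(np.hypot(*(q - p)) / step)), 2)
        t = np.linspace(0.0, 1.0, n)[:, None]
        out.append(p + t * (q - p))
    return np.vstack(out)


def render_series(spec: SyntheticSpec
                  ) -> tuple[GrayImage, LabelOverlay, SyntheticTruth]:
    """Render one scan; deterministic given ``spec.seed``.

    Returns the grayscale scan, the ground-truth overlay and the full
    analytic truth.  The first ``examiner_n`` characters use the mean
    geometry without jitter, decay or perseveration — they are the
    examiner's template strokes; examinee characters follow with all the
    configured distortions.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_total = spec.examiner_n + spec.n_chars

    # --- plan geometry in baseline coordinates (x right, y up) -----------
    shapes: list[str] = []
    polys: list[np.ndarray] = []
    connectors: list[np.ndarray] = []
    x = 0.0
    prev_shape = TRIANGLE  # so the examiner starts with a rectangle
    dims: list[tuple[float, float]] = []
    for i in range(n_total):
        examinee = i >= spec.examiner_n
        if examinee:
            persevere = rng.random() < spec.p_perseveration
            shape = prev_shape if persevere else (
                TRIANGLE if prev_shape == RECTANGLE else RECTANGLE)
            k = i - spec.examiner_n
            decay = spec.micrographia_rate ** k
            w = (spec.char_width_mean
                 + rng.normal(0.0, spec.char_width_sd)) * decay
            h = (spec.char_height_mean
                 + rng.normal(0.0, spec.char_height_sd)) * decay
            skew = rng.normal(0.0, spec.skew_sd) if spec.skew_sd > 0 else 0.0
        else:
            shape = TRIANGLE if prev_shape == RECTANGLE else RECTANGLE
            w, h, skew = spec.char_width_mean, spec.char_height_mean, 0.0
        w = max(w, spec.char_width_mean * 0.3)
        h = max(h, spec.char_height_mean * 0.3)
        poly = _char_polyline(shape, x, w, h, spec.rect_lean_deg)
        if skew:
            poly = _rotate_about(poly, poly[0], skew)
        shapes.append(shape)
        polys.append(poly)
        dims.append((w, h))
        x_end = poly[-1, 0]
        if i < n_total - 1:
            connectors.append(np.array([[x_end, 0.0],
                                        [x_end + spec.gap_mean, 0.0]]))
            x = x_end + spec.gap_mean
        else:
            x = x_end
        prev_shape = shape

    total_len = x
    width = int(np.ceil(total_len)) + 2 * MARGIN
    if spec.page_width is not None and width > spec.page_width:
        raise ValidationError(
            f"series needs {width} px but page is {spec.page_width} px wide")
    if spec.page_width is not None:
        width = spec.page_width

    # --- drift + map to image rows ---------------------------------------
    def drift(xs: np.ndarray) -> np.ndarray:
        return spec.drift_amplitude * np.sin(2 * np.pi * xs / spec.drift_period)

    max_h = max(h for _, h in dims)
    height = int(np.ceil(max_h + 2 * abs(spec.drift_amplitude))) + 2 * MARGIN
    y_base = height - MARGIN  # image row of the undrifted baseline

    def to_rc(pts: np.ndarray) -> np.ndarray:
        xs = pts[:, 0] + MARGIN
        ys = pts[:, 1] + drift(pts[:, 0])
        rows = y_base - ys
        return np.column_stack([rows, xs])

    # --- rasterize: per-character masks first, connectors last -----------
    radius = max(spec.stroke_width // 2, 1)
    footprint = np.zeros((height, width), dtype=bool)

    def rasterize(pts_rc: np.ndarray) -> np.ndarray:
        canvas = np.zeros((height, width), dtype=bool)
        r = np.clip(np.round(pts_rc[:, 0]).astype(int), 0, height - 1)
        c = np.clip(np.round(pts_rc[:, 1]).astype(int), 0, width - 1)
        canvas[r, c] = True
        if radius > 0:
            canvas = ndimage.binary_dilation(
                canvas, structure=_disk(radius))
        return canvas

    masks: list[np.ndarray] = []
    for poly in polys:
        m = rasterize(to_rc(_sample_segments(poly)))
        m &= ~footprint  # shared junction pixels stay with the earlier char
        masks.append(m)
        footprint |= m
    conn_mask = np.zeros((height, width), dtype=bool)
    for seg in connectors:
        conn_mask |= rasterize(to_rc(_sample_segments(seg)))
    conn_mask &= ~footprint
    ink = footprint | conn_mask

    # --- intensities ------------------------------------------------------
    img = np.full((height, width), float(PAPER))
    img[ink] = INK
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)
    if spec.speckle_rate > 0:
        spots = rng.random(img.shape) < spec.speckle_rate
        img[spots] = rng.uniform(0, 100, int(spots.sum()))
    gray = GrayImage(np.clip(np.round(img), 0, 255).astype(np.uint8),
                     dpi=spec.dpi)

    # --- analytic envelope ------------------------------------------------
    all_pts = np.vstack([_sample_segments(p) for p in polys]
                        + [_sample_segments(s) for s in connectors])
    xs_img = np.round(all_pts[:, 0] + MARGIN).astype(int)
    ys = all_pts[:, 1] + drift(all_pts[:, 0])
    env_x = np.unique(xs_img)
    env_y = np.full(len(env_x), -np.inf)
    idx = np.searchsorted(env_x, xs_img)
    np.maximum.at(env_y, idx, ys)

    overlay = LabelOverlay(masks=masks, labels=shapes,
                           examiner=[i < spec.examiner_n
                                     for i in range(n_total)])
    ex_dims: dict[str, tuple[float, float]] = {}
    for i in range(spec.examiner_n):
        ex_dims.setdefault(shapes[i], dims[i])
    truth = SyntheticTruth(sequence="".join(shapes), masks=masks,
                           envelope_x=env_x, envelope_y=env_y,
                           examiner_n=spec.examiner_n,
                           examiner_dims=ex_dims, spec=spec)
    return gray, overlay, truth


def _disk(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return (yy**2 + xx**2) <= radius**2


def overlay_to_rgb(overlay: LabelOverlay, shape: tuple[int, int]) -> np.ndarray:
    """Render a LabelOverlay as the red/blue RGB image an expert would save."""
    rgb = np.full(shape + (3,), 255, dtype=np.uint8)
    for mask, label in zip(overlay.masks, overlay.labels):
        rgb[mask] = (255, 0, 0) if label == RECTANGLE else (0, 0, 255)
    return rgb


# ---------------------------------------------------------------------------
# group presets and cohorts
# ---------------------------------------------------------------------------

def control_spec(**overrides) -> SyntheticSpec:
    """Neurologically intact preset: clean alternation, minimal distortion."""
    return replace(SyntheticSpec(), p_perseveration=0.02, skew_sd=1.5,
                   **overrides)


def pd_spec(**overrides) -> SyntheticSpec:
    """Parkinson preset: smaller characters, tighter jitter, size decay."""
    return replace(SyntheticSpec(), char_width_mean=90.0,
                   char_height_mean=70.0, char_width_sd=4.0,
                   char_height_sd=4.0, micrographia_rate=0.97,
                   p_perseveration=0.08, skew_sd=2.5, **overrides)


def psp_spec(**overrides) -> SyntheticSpec:
    """PSP preset: frequent perseveration, larger skew and jitter."""
    return replace(SyntheticSpec(), char_width_sd=14.0, char_height_sd=14.0,
                   p_perseveration=0.30, skew_sd=5.0, **overrides)


PRESETS = {"CON": control_spec, "PD": pd_spec, "PSP": psp_spec}


def cohort(n_per_group: tuple[int, int, int] = (5, 5, 5), seed: int = 0,
           spec_overrides: dict | None = None,
           ) -> tuple[list[dict], "object"]:
    """Generate a three-group cohort of scans with a subject/group table.

    Returns ``(subjects, table)`` where each subject dict carries the scan,
    overlay and truth, and ``table`` is a pandas DataFrame with columns
    subject and group (PD, PSP, CON order).
    """
    import pandas as pd

    spec_overrides = spec_overrides or {}
    subjects = []
    rows = []
    counter = 0
    for group, n in zip(("PD", "PSP", "CON"), n_per_group):
        maker = PRESETS[group]
        for i in range(n):
            subj = f"{group.lower()}{i:03d}"
            sub_seed = (seed * 1_000_003 + counter) % (2**31 - 1)
            spec = maker(seed=sub_seed, **spec_overrides)
            gray, overlay, truth = render_series(spec)
            subjects.append({"subject": subj, "group": group, "scan": gray,
                             "overlay": overlay, "truth": truth})
            rows.append({"subject": subj, "group": group})
            counter += 1
    return subjects, pd.DataFrame(rows)
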