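"""Character separation: from the aligned signal to per-character ROIs.

Between two adjacent characters the pen returns to the series baseline, so
the aligned signal shows a deep local minimum there.  Those minima give the
separating columns; narrow vertical strips around them are erased from the
binary trace, the remaining 8-connected components become the characters
(tiny askew fragments are merged into the component they overlap most), and
the signal is split at the same columns.  Segmentations are scored against
expert masks by per-character Jaccard matching summarised as a DICE
percentage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label

from .baseline import AlignedSignal
from .preprocess import BinaryImage
from .scan_io import ValidationError


@dataclass
class CharacterROI:
    """One character as a binary sub-image in page coordinates."""

    mask: np.ndarray  # full-frame binary mask
    bbox: tuple[int, int, int, int]  # (x0, x1, y0, y1), half-open
    index: int
    examiner: bool = False

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise ValidationError("ROI mask is empty")
        rows, cols = np.nonzero(self.mask)
        x0, x1, y0, y1 = self.bbox
        if not (cols.min() >= x0 and cols.max() < x1
                and rows.min() >= y0 and rows.max() < y1):
            raise ValidationError("bbox does not contain all mask pixels")

    @property
    def width(self) -> int:
        return self.bbox[1] - self.bbox[0]

    @property
    def height(self) -> int:
        return self.bbox[3] - self.bbox[2]

    @property
    def sub_mask(self) -> np.ndarray:
        x0, x1, y0, y1 = self.bbox
        return self.mask[y0:y1, x0:x1]


@dataclass
class CharacterSignal:
    """The aligned-signal samples spanned by one character."""

    x_range: tuple[int, int]  # half-open, in image columns
    values: np.ndarray
    gap_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.x_range[1] - self.x_range[0] != len(self.values):
            raise ValidationError("x_range does not match sample count")

    @property
    def amplitude(self) -> float:
        return float(self.values.max() - self.values.min())

    @property
    def normalized(self) -> np.ndarray:
        amp = self.amplitude
        if amp <= 0:
            raise ValidationError("zero-amplitude character signal")
        return (self.values - self.values.min()) / amp


def find_separating_columns(a: AlignedSignal, valley_frac: float = 0.10,
                            min_sep_frac: float = 0.3) -> list[int]:
    """Columns where the aligned signal dips back to the series baseline.

    A valley is a maximal run of samples below ``valley_frac`` of the
    robust maximum (95th percentile) that contains at least one interior
    local minimum; the cut is placed at the run midpoint, so a tilted but
    uniformly low connector stretch still cuts at its centre.  Cuts closer
    than ``min_sep_frac`` of the median cut spacing merge into one (several
    shallow dips inside a single baseline plateau are one transition, not
    many).  Returned positions are image columns, ascending.
    """
    y = np.asarray(a.aligned, dtype=float)
    if len(y) == 0:
        return []
    robust_max = float(np.percentile(y, 95))
    thr = valley_frac * robust_max
    n = len(y)
    if n < 3 or robust_max <= 0:
        return []
    # local minima with plateau support
    le = np.empty(n, dtype=bool)
    le[0] = le[-1] = False
    le[1:-1] = (y[1:-1] <= y[:-2]) & (y[1:-1] <= y[2:])
    below = y < thr
    cols: list[int] = []
    i = 0
    offset = int(a.x[0]) if a.x is not None else 0
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            if le[i:j + 1].any():
                cols.append(offset + (i + j) // 2)
            i = j + 1
        else:
            i += 1
    if len(cols) > 2 and min_sep_frac > 0:
        spacing = np.diff(cols)
        min_sep = min_sep_frac * float(np.median(spacing))
        clusters: list[list[int]] = [[cols[0]]]
        for c in cols[1:]:
            if c - clusters[-1][-1] < min_sep:
                clusters[-1].append(c)
            else:
                clusters.append([c])
        cols = [int(round(np.mean(cl))) for cl in clusters]
    return cols


def split_characters(
    bin_img: BinaryImage,
    a: AlignedSignal,
    cols: list[int],
    strip_halfwidth: int = 2,
    min_area_frac: float = 0.05,
    examiner_n: int = 0,
) -> list[tuple[CharacterROI, CharacterSignal]]:
    """Split the trace at the separating columns into ordered characters.

    Vertical strips of width ``2*strip_halfwidth + 1`` centred on each
    separating column are erased from the binary trace (removing the short
    baseline stroke that connects adjacent characters); the remaining
    8-connected components are the character candidates.  Fragments smaller
    than ``min_area_frac`` of the median component area are merged into the
    component whose column interval overlaps theirs most (skew fragments of
    a neighbour) or dropped when nothing overlaps.  Characters are ordered
    left-to-right by centroid; the first ``examiner_n`` are flagged as the
    examiner's.  The aligned signal is split at the same columns.
    """
    mask = bin_img.mask.copy()
    W = mask.shape[1]
    for c in sorted(cols):
        lo = max(c - strip_halfwidth, 0)
        hi = min(c + strip_halfwidth + 1, W)
        mask[:, lo:hi] = False
    lbl, n = cc_label(mask, connectivity=2, return_num=True)
    if n == 0:
        raise ValidationError("no components remain after strip erasure")

    comps = []
    for i in range(1, n + 1):
        m = lbl == i
        rows, cc = np.nonzero(m)
        comps.append({"mask": m, "x0": cc.min(), "x1": cc.max() + 1,
                      "area": len(rows), "cx": cc.mean()})
    areas = np.array([c["area"] for c in comps])
    med = float(np.median(areas))
    keep = [c for c in comps if c["area"] >= min_area_frac * med]
    small = [c for c in comps if c["area"] < min_area_frac * med]
    if not keep:
        keep, small = comps, []
    for frag in small:
        overlaps = [min(frag["x1"], k["x1"]) - max(frag["x0"], k["x0"])
                    for k in keep]
        best = int(np.argmax(overlaps))
        if overlaps[best] > 0:
            k = keep[best]
            k["mask"] = k["mask"] | frag["mask"]
            rows, cc = np.nonzero(k["mask"])
            k.update(x0=cc.min(), x1=cc.max() + 1, area=len(rows),
                     cx=cc.mean())
        # else: isolated speck, dropped

    keep.sort(key=lambda c: c["cx"])

    # signal split points: the same separating columns
    sig_x = a.x if a.x is not None else np.arange(len(a.aligned))
    sx0, sx1 = int(sig_x[0]), int(sig_x[-1]) + 1
    bounds = [sx0] + [c for c in sorted(cols) if sx0 < c < sx1] + [sx1]

    out: list[tuple[CharacterROI, CharacterSignal]] = []
    for idx, comp in enumerate(keep):
        rows, cc = np.nonzero(comp["mask"])
        bbox = (int(cc.min()), int(cc.max()) + 1,
                int(rows.min()), int(rows.max()) + 1)
        roi = CharacterROI(mask=comp["mask"], bbox=bbox, index=idx,
                           examiner=idx < examiner_n)
        # pick the signal interval containing the component's centroid
        cx = comp["cx"]
        seg = None
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            if b0 <= cx < b1 or (b1 == bounds[-1] and cx >= b0):
                i0, i1 = b0 - sx0, b1 - sx0
                seg = CharacterSignal(
                    x_range=(b0, b1), values=a.aligned[i0:i1],
                    gap_mask=None if a.gap_mask is None else a.gap_mask[i0:i1])
                break
        assert seg is not None
        out.append((roi, seg))
    return out


def jaccard(A: np.ndarray, B: np.ndarray) -> float:
    """Intersection over union of two binary masks (1.0 when both empty)."""
    A = np.asarray(A, dtype=bool)
    B = np.asarray(B, dtype=bool)
    if A.shape != B.shape:
        raise ValidationError("mask dimensions differ")
    union = np.logical_or(A, B).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(A, B).sum() / union)


def segmentation_dice(auto: list[CharacterROI], manual: list[CharacterROI],
                      jac_threshold: float = 0.70) -> float:
    """Per-character DICE of a segmentation against expert delineations.

    Each expert ROI is greedily matched to the unmatched automatic ROI of
    highest Jaccard; a match counts as acceptable only above the Jaccard
    threshold.  Acceptable matches are true positives, unmatched expert ROIs
    false negatives and unmatched automatic ROIs false positives; the result
    is 2TP / (2TP + FP + FN) as a percentage.
    """
    if not auto and not manual:
        raise ValidationError("nothing to evaluate: both ROI lists empty")
    pairs = []
    for mi, m in enumerate(manual):
        for ai, au in enumerate(auto):
            pairs.append((jaccard(m.mask, au.mask), mi, ai))
    pairs.sort(key=lambda p: -p[0])
    used_m: set[int] = set()
    used_a: set[int] = set()
    tp = 0
    for jac, mi, ai in pairs:
        if jac <= jac_threshold:
            break
        if mi in used_m or ai in used_a:
            continue
        used_m.add(mi)
        used_a.add(ai)
        tp += 1
    fn = len(manual) - tp
    fp = len(auto) - tp
    return 2 * tp / (2 * tp + fp + fn) * 100.0
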