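"""Background removal, binarization, skeletonization and the 1-D signal form.

A scanned form is overwhelmingly white paper, so the intensity histogram has
a dominant high-intensity mode; the binarization threshold is placed at the
low-intensity foot of that mode.  After thresholding, a morphological opening
removes scanner speckle, and the trace is thinned to a one-pixel skeleton.
The skeleton is then collapsed left-to-right into the *signal form*: one
height value per image column (the upper envelope, in up-positive page
coordinates), the substrate for baseline alignment, character separation,
shape recognition and the amplitude features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_opening, uniform_filter1d
from skimage.morphology import disk, thin

from .scan_io import GrayImage, ValidationError


@dataclass
class BinaryImage:
    """Foreground (ink) mask plus the provenance of its extraction."""

    mask: np.ndarray
    threshold: float | None = None
    opening_radius: int | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValidationError("binary image must be 2-D")


@dataclass
class SignalForm:
    """One height value per column over the ink extent of the trace.

    ``y[i]`` is the height of the uppermost skeleton pixel in column
    ``x[i]`` measured up-positive from the page bottom; columns the pen did
    not visit are linearly interpolated and flagged in ``gap_mask``.
    """

    x: np.ndarray
    y: np.ndarray
    gap_mask: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=int)
        self.y = np.asarray(self.y, dtype=float)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if not (len(self.x) == len(self.y) == len(self.gap_mask)):
            raise ValidationError("x, y and gap_mask must share one length")
        if len(self.x) and np.any(np.diff(self.x) != 1):
            raise ValidationError("x must increase in steps of 1")
        if np.any(self.y < 0):
            raise ValidationError("heights must be non-negative")


def estimate_background_threshold(img: GrayImage, smooth: int = 5,
                                  margin: int = 3) -> int:
    """Place the binarization threshold below the paper-background mode.

    The histogram of a scanned form is dominated by a tall white-background
    lobe.  The threshold is the low-intensity foot of that lobe — the point
    below its mode where smoothed counts fall under 0.1% of the peak —
    minus a small safety margin, so that every ink pixel falls below it.
    """
    pixels = img.pixels
    hist = np.bincount(pixels.ravel(), minlength=256).astype(float)
    hs = uniform_filter1d(hist, size=smooth, mode="nearest")
    upper = hs[129:]
    if upper.max() <= 0:
        raise ValidationError("no paper background detected")
    mode = 129 + int(np.argmax(upper))
    peak = hs[mode]
    # walk down from the mode while counts remain non-negligible: where
    # they vanish is the low-side foot of the background lobe.  (A plain
    # monotonicity walk would stop at the dip between the true background
    # mode and the clipping spike at 255 that noisy scans produce.)
    v = mode
    while v > 0 and hs[v - 1] > 1e-3 * peak:
        v -= 1
    t = max(v - margin, 1)
    return int(min(t, 255))


def binarize_and_clean(img: GrayImage, t: float,
                       opening_radius: int | None = None) -> BinaryImage:
    """Threshold at ``t`` (ink = darker than t) and open with a disk.

    ``opening_radius`` defaults to ``round(dpi / 600)`` so the cleaning
    element scales with scan resolution; radius 0 is pure thresholding.
    The opened mask is always a subset of the raw thresholded mask.
    """
    if not 0 <= t <= 255:
        raise ValidationError("threshold must lie in [0, 255]")
    if opening_radius is None:
        opening_radius = max(round(img.dpi / 600), 0)
    fg = img.pixels < t
    if opening_radius > 0:
        fg = binary_opening(fg, structure=disk(opening_radius))
    return BinaryImage(fg, threshold=float(t), opening_radius=int(opening_radius))


def skeletonize(bin_img: BinaryImage) -> BinaryImage:
    """Thin the ink mask to a 1-px-wide, topology-preserving skeleton."""
    from skimage.measure import label as cc_label

    if not bin_img.mask.any():
        raise ValidationError("cannot skeletonize an empty foreground")
    skel = thin(bin_img.mask)
    # thinning may not fully erase isolated pixels' neighbours; sanity only
    n_in = cc_label(bin_img.mask, connectivity=2, return_num=True)[1]
    n_out = cc_label(skel, connectivity=2, return_num=True)[1]
    if n_in != n_out:  # pragma: no cover - thin() preserves topology
        raise RuntimeError("skeletonization changed component count")
    return BinaryImage(skel, bin_img.threshold, bin_img.opening_radius)


def to_signal_form(skel: BinaryImage) -> SignalForm:
    """Collapse a skeleton to its upper envelope, one height per column.

    For every column between the first and last ink column the height is
    taken from the *uppermost* skeleton pixel (up-positive: page top maps to
    large values).  Columns without skeleton pixels get linearly
    interpolated heights and a raised gap flag, so downstream features can
    skip interpolated samples.
    """
    mask = skel.mask
    if not mask.any():
        raise ValidationError("empty skeleton")
    H = mask.shape[0]
    cols_with_ink = np.nonzero(mask.any(axis=0))[0]
    x0, x1 = cols_with_ink[0], cols_with_ink[-1] + 1
    x = np.arange(x0, x1)
    y = np.full(len(x), np.nan)
    sub = mask[:, x0:x1]
    has = sub.any(axis=0)
    top_row = np.argmax(sub, axis=0)  # first True from the top
    y[has] = (H - 1) - top_row[has]
    gap = ~has
    if gap.any():
        y[gap] = np.interp(x[gap], x[has], y[has])
    return SignalForm(x=x, y=y, gap_mask=gap)


def preprocess_scan(img: GrayImage, opening_radius: int | None = None
                    ) -> tuple[BinaryImage, BinaryImage, SignalForm]:
    """Full preprocessing chain: returns (clean binary, skeleton, signal form)."""
    t = estimate_background_threshold(img)
    clean = binarize_and_clean(img, t, opening_radius)
    skel = skeletonize(clean)
    return clean, skel, to_signal_form(skel)


def dump_signal_csv(sf: SignalForm, path) -> None:
    """Debug dump of a signal form as 2-column CSV (x, y)."""
    np.savetxt(path, np.column_stack([sf.x, sf.y]), delimiter=",",
               header="x,y", comments="")
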