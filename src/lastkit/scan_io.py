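"""Reading and writing of scans, ground-truth overlays, masks and feature tables.

The alternating-series forms are digitised as 8-bit grayscale TIFF or PNG
scans (nominally 600 dpi).  Expert ground truth, when available, is an RGB
overlay of the same geometry in which every stroke has been recoloured red
(rectangle) or blue (triangle).  A small sidecar JSON per scan records the
scan dpi and how many leading characters were drawn by the examiner.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

logger = logging.getLogger(__name__)

#: ITU-R BT.601 luminance weights used when an RGB scan must be collapsed.
_LUMA = np.array([0.299, 0.587, 0.114])

RECTANGLE = "R"
TRIANGLE = "T"

GROUPS = ("PD", "PSP", "CON")


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


@dataclass
class GrayImage:
    """An 8-bit grayscale scan; 0 = black ink, 255 = white paper."""

    pixels: np.ndarray
    dpi: int

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError("scan must be a non-empty 2-D intensity grid")
        if self.dpi <= 0:
            raise ValidationError("dpi must be positive")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValidationError("intensities must lie in [0, 255]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LabelOverlay:
    """Expert per-character ground truth recovered from a red/blue recolouring.

    ``masks[i]`` is the binary stroke mask of character ``i`` (left-to-right
    by centroid), ``labels[i]`` its shape ("R" or "T") and ``examiner[i]``
    whether it belongs to the examiner-drawn prefix of the series.
    """

    masks: list[np.ndarray]
    labels: list[str]
    examiner: list[bool]

    def __post_init__(self) -> None:
        if not self.masks:
            raise ValidationError("overlay contains no labelled characters")
        if not all(m.any() for m in self.masks):
            raise ValidationError("every character mask must be non-empty")
        union = np.zeros_like(self.masks[0], dtype=int)
        for m in self.masks:
            union += m.astype(int)
        if union.max() > 1:
            raise ValidationError("character masks must be pairwise disjoint")
        if set(self.labels) - {RECTANGLE, TRIANGLE}:
            raise ValidationError("labels must be 'R' or 'T'")

    @property
    def sequence(self) -> str:
        return "".join(self.labels)


def _to_gray(arr: np.ndarray) -> np.ndarray:
    """Collapse an (H, W[, C]) array to 2-D luminance, rescaling 16-bit data."""
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        arr = arr @ _LUMA
    arr = arr.astype(float)
    if arr.max() > 255:  # 16-bit scan
        arr = arr / 257.0
    return np.clip(np.round(arr), 0, 255).astype(np.uint8)


def load_scan(path: str | Path, dpi: int = 600) -> GrayImage:
    """Load a TIFF or PNG scan as a :class:`GrayImage`.

    RGB inputs are converted by luminance; 16-bit inputs are rescaled to the
    8-bit range.  ``dpi`` is attached to the result (scanners rarely embed a
    trustworthy value).
    """
    path = Path(path)
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            arr = np.asarray(Image.open(path))
    except Exception as exc:  # unreadable / truncated file
        raise IOError(f"cannot decode scan {path}: {exc}") from exc
    if arr.size == 0:
        raise ValidationError(f"zero-area image: {path}")
    return GrayImage(_to_gray(arr), dpi=dpi)


def load_sidecar(path: str | Path) -> dict:
    """Read the per-scan sidecar JSON ``{"dpi": int, "examiner_n": int}``."""
    with open(path) as fh:
        meta = json.load(fh)
    meta.setdefault("dpi", 600)
    meta.setdefault("examiner_n", 5)
    return meta


def load_label_overlay(
    path_or_array: str | Path | np.ndarray,
    base: GrayImage,
    examiner_n: int = 5,
    color_margin: int = 40,
) -> LabelOverlay:
    """Recover per-character masks and shape labels from an RGB overlay.

    A pixel is treated as red (rectangle) when ``R - max(G, B) > color_margin``
    and symmetrically for blue (triangle); the margin tolerates anti-aliased
    editor strokes.  Same-colour touching strokes merge into one 8-connected
    component.  Components are ordered left-to-right by centroid column and
    the first ``examiner_n`` are flagged as examiner-drawn.
    """
    from skimage.measure import label as cc_label

    if isinstance(path_or_array, (str, Path)):
        arr = np.asarray(Image.open(path_or_array).convert("RGB"))
    else:
        arr = np.asarray(path_or_array)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValidationError("overlay must be an RGB image")
    if arr.shape[:2] != base.shape:
        raise ValidationError(
            f"overlay {arr.shape[:2]} does not match scan {base.shape}"
        )
    r = arr[:, :, 0].astype(int)
    g = arr[:, :, 1].astype(int)
    b = arr[:, :, 2].astype(int)
    red = (r - np.maximum(g, b)) > color_margin
    blue = (b - np.maximum(r, g)) > color_margin
    if not red.any() and not blue.any():
        raise ValidationError("overlay contains no red or blue strokes")

    entries: list[tuple[float, np.ndarray, str]] = []
    for colored, shape in ((red, RECTANGLE), (blue, TRIANGLE)):
        lbl, n = cc_label(colored, connectivity=2, return_num=True)
        for i in range(1, n + 1):
            mask = lbl == i
            cx = np.nonzero(mask)[1].mean()
            entries.append((cx, mask, shape))
    entries.sort(key=lambda e: e[0])
    masks = [e[1] for e in entries]
    labels = [e[2] for e in entries]
    examiner = [i < examiner_n for i in range(len(entries))]
    return LabelOverlay(masks, labels, examiner)


@dataclass
class FeatureTable:
    """Per-subject feature matrix keyed by (subject id, group)."""

    frame: "object"  # pandas.DataFrame with columns subject, group, features...

    def __post_init__(self) -> None:
        import pandas as pd

        if not isinstance(self.frame, pd.DataFrame):
            self.frame = pd.DataFrame(self.frame)
        if self.frame.columns.duplicated().any():
            raise ValidationError("feature columns must be unique")
        if "group" in self.frame.columns:
            present = set(self.frame["group"].dropna())
            if present - set(GROUPS):
                raise ValidationError(f"unknown groups: {present - set(GROUPS)}")

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in ("subject", "group")]


def write_outputs(record, rois, out_dir: str | Path) -> dict[str, Path]:
    """Write a series record and its character ROIs under ``out_dir``.

    Produces ``features.csv`` (one row per subject), ``record.json`` (full
    per-character detail) and one indexed-PNG mask per character.  Values
    round-trip bit-exactly for integers and to 1e-9 for reals.
    """
    import pandas as pd

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise IOError(f"output directory not writable: {out_dir}") from exc

    written: dict[str, Path] = {}
    row = record.as_row()
    if len(row) <= 2:  # subject + group only
        warnings.warn("empty record: writing header-only CSV")
    csv_path = out_dir / "features.csv"
    pd.DataFrame([row]).to_csv(csv_path, index=False, float_format="%.12g")
    written["csv"] = csv_path

    json_path = out_dir / "record.json"
    with open(json_path, "w") as fh:
        json.dump(record.as_dict(), fh, indent=1, default=float)
    written["json"] = json_path

    for roi in rois:
        mask_path = out_dir / f"roi_{roi.index:03d}.png"
        Image.fromarray(roi.mask.astype(np.uint8), mode="P").save(mask_path)
        written[f"roi_{roi.index}"] = mask_path
    return written


def read_feature_csv(path: str | Path) -> FeatureTable:
    import pandas as pd

    return FeatureTable(pd.read_csv(path))
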