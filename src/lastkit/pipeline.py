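"""End-to-end orchestration: scan in, per-subject series record out."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import features as feat
from .baseline import AlignedSignal, BeadsParams, align_signal_form
from .preprocess import BinaryImage, SignalForm, preprocess_scan
from .recognition import (ModelSet, RecognitionConfig, ShapeLabel,
                          classify_characters, select_models)
from .scan_io import RECTANGLE, TRIANGLE, GrayImage, ValidationError
from .segmentation import (CharacterROI, CharacterSignal,
                           find_separating_columns, split_characters)


@dataclass
class PipelineConfig:
    beads: BeadsParams = field(default_factory=BeadsParams)
    recognition: RecognitionConfig = field(default_factory=RecognitionConfig)
    valley_frac: float = 0.10
    min_area_frac: float = 0.05
    strip_halfwidth: int | None = None  # None = stroke-width estimate
    nw: feat.NwParams = field(default_factory=feat.NwParams)

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        """Load overrides from a TOML file with [beads], [recognition],
        [segmentation] and [nw] tables; unknown keys are rejected."""
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        cfg = cls()
        for section, target in (("beads", cfg.beads),
                                ("recognition", cfg.recognition),
                                ("nw", cfg.nw)):
            for key, value in data.get(section, {}).items():
                if not hasattr(target, key):
                    raise ValidationError(
                        f"unknown key {key!r} in [{section}]")
                setattr(target, key, value)
        for key, value in data.get("segmentation", {}).items():
            if key not in ("valley_frac", "min_area_frac", "strip_halfwidth"):
                raise ValidationError(f"unknown key {key!r} in [segmentation]")
            setattr(cfg, key, value)
        return cfg


@dataclass
class PipelineResult:
    binary: BinaryImage
    skeleton: BinaryImage
    signal: SignalForm
    aligned: AlignedSignal
    separating_columns: list[int]
    characters: list[tuple[CharacterROI, CharacterSignal]]
    models: ModelSet
    labels: list[ShapeLabel]
    record: feat.SeriesRecord

    @property
    def rois(self) -> list[CharacterROI]:
        return [roi for roi, _ in self.characters]


def estimate_stroke_halfwidth(binary: BinaryImage,
                              skeleton: BinaryImage) -> int:
    """Median skeleton-to-boundary distance, the natural strip half-width."""
    dist = ndimage.distance_transform_edt(binary.mask)
    on_skel = dist[skeleton.mask]
    if len(on_skel) == 0:
        return 1
    return max(int(round(float(np.median(on_skel)))), 1)


def _other(shape: str) -> str:
    return TRIANGLE if shape == RECTANGLE else RECTANGLE


def process_scan(img: GrayImage, examiner_n: int = 5,
                 config: PipelineConfig | None = None,
                 subject: str = "", group: str | None = None
                 ) -> PipelineResult:
    """Run the full chain on one scan.

    Preprocess to the signal form, align the baseline, split the trace into
    characters, select models and recognize shapes, then measure features
    and aggregate them — normalized against the examiner's first rectangle
    and first triangle — into a :class:`SeriesRecord`.
    """
    cfg = config or PipelineConfig()
    binary, skeleton, signal = preprocess_scan(img)
    aligned = align_signal_form(signal, params=cfg.beads)
    cols = find_separating_columns(aligned, cfg.valley_frac)
    halfwidth = (cfg.strip_halfwidth if cfg.strip_halfwidth is not None
                 else estimate_stroke_halfwidth(binary, skeleton))
    chars = split_characters(binary, aligned, cols,
                             strip_halfwidth=halfwidth,
                             min_area_frac=cfg.min_area_frac,
                             examiner_n=examiner_n)
    if len(chars) <= examiner_n:
        raise ValidationError(
            f"only {len(chars)} characters found; need more than the "
            f"{examiner_n} examiner characters")

    models, assignments = select_models(chars, cfg.recognition)
    labels = classify_characters([cs for _, cs in chars], models,
                                 cfg.recognition.dtw_window, assignments)

    all_feats = [feat.character_features(roi, cs, lab, models,
                                         cfg.recognition.dtw_window)
                 for (roi, cs), lab in zip(chars, labels)]

    # examiner templates: first examiner character of each class; fall back
    # to the first examinee of a class the examiner never drew
    templates: dict[str, dict] = {}
    for (roi, _), lab, f in zip(chars, labels, all_feats):
        if roi.examiner and lab.value not in templates:
            templates[lab.value] = f
    for lab, f in zip(labels[examiner_n:], all_feats[examiner_n:]):
        templates.setdefault(lab.value, f)

    examinee = list(zip(all_feats[examiner_n:], labels[examiner_n:]))
    rois = [roi for roi, _ in chars]
    extent = rois[-1].bbox[1] - rois[examiner_n].bbox[0]
    expected_first = _other(labels[examiner_n - 1].value) if examiner_n \
        else labels[examiner_n].value
    record = feat.series_features(examinee, extent, templates, cfg.nw,
                                  expected_first=expected_first,
                                  subject=subject, group=group)
    return PipelineResult(binary=binary, skeleton=skeleton, signal=signal,
                          aligned=aligned, separating_columns=cols,
                          characters=chars, models=models, labels=labels,
                          record=record)


def cohort_feature_table(subjects: list[dict],
                         config: PipelineConfig | None = None):
    """Process every cohort subject and stack the records into a FeatureTable.

    Subjects whose scan fails to process (e.g. hopeless segmentation) get a
    row of missing values; downstream imputation handles them the way a
    study would handle an unusable form.
    """
    import pandas as pd

    from .scan_io import FeatureTable

    rows = []
    for subj in subjects:
        try:
            res = process_scan(subj["scan"],
                               examiner_n=subj["truth"].examiner_n,
                               config=config, subject=subj["subject"],
                               group=subj["group"])
            row = res.record.as_row()
            row.pop("sequence", None)
        except Exception:  # noqa: BLE001 - one bad scan must not kill a study
            row = {"subject": subj["subject"], "group": subj["group"]}
        rows.append(row)
    return FeatureTable(pd.DataFrame(rows))
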