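"""End-to-end orchestration: strip -> beats -> features -> per-subject
model -> beat and window predictions -> metrics.

These helpers are the building blocks of the command-line ``run-study``
and of reproduction scripts; each stage remains independently usable.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import beats as beats_mod
from .config import PipelineConfig
from .evaluate import SubjectMetrics, compute_metrics
from .fiducials import features_from_beats
from .glymodel import (
    SubjectModel,
    fit_subject_model,
    predict_beats,
    vote_windows,
)
from .signal_io import GlycemicLabel, LabeledStrip, match_ecg_to_bg, split_records


@dataclass
class StripFeatures:
    """Feature matrix of one strip plus its audit counts."""

    strip_id: str
    label: GlycemicLabel
    start_time_s: float
    duration_s: float
    features: pd.DataFrame
    r_times_s: np.ndarray
    counts: dict = field(default_factory=dict)


def extract_strip_features(
    strip: LabeledStrip, cfg: PipelineConfig | None = None,
    subject_id: str = "",
) -> StripFeatures:
    """Run detection, segmentation, quality filtering and delineation on
    one labeled strip."""
    cfg = cfg or PipelineConfig()
    r_idx = beats_mod.detect_r_peaks(strip.samples, cfg)
    beat_list, n_boundary = beats_mod.segment_beats(
        strip.samples, r_idx, cfg,
        subject_id=subject_id, strip_id=strip.strip_id,
        start_time_s=strip.start_time_s,
    )
    accepted, rejected = beats_mod.quality_filter(beat_list, cfg)
    feats, dropped = features_from_beats(accepted, cfg)
    r_times = np.array([accepted[i].r_time_s for i in feats.index])
    counts = {
        "r_peaks": int(r_idx.size),
        "boundary_dropped": n_boundary,
        "beats_segmented": len(beat_list),
        "beats_accepted": len(accepted),
        "beats_rejected": len(rejected),
        "reject_reasons": _tally(r for _, r in rejected),
        "delineation_dropped": dropped,
        "feature_beats": len(feats),
    }
    return StripFeatures(
        strip_id=strip.strip_id,
        label=strip.label,
        start_time_s=strip.start_time_s,
        duration_s=strip.duration_s,
        features=feats.reset_index(drop=True),
        r_times_s=r_times,
        counts=counts,
    )


def _tally(reasons) -> dict:
    out: dict = {}
    for r in reasons:
        out[r] = out.get(r, 0) + 1
    return out


@dataclass
class SubjectResult:
    subject_id: str
    model: SubjectModel
    beat_metrics: SubjectMetrics
    window_metrics: SubjectMetrics
    strip_counts: list
    n_train_strips: int
    n_val_strips: int


def evaluate_subject(
    subject_id: str,
    strips: list[LabeledStrip],
    seed: int,
    cfg: PipelineConfig | None = None,
) -> SubjectResult:
    """The per-subject study protocol on already-labeled strips.

    Splits strips, trains the one-class SVM on the euglycemic training
    strips, scores validation beats, aggregates fixed windows by majority
    vote, and computes both levels of metrics. Dysglycemia is positive;
    window ranking uses the dysglycemic-vote fraction.
    """
    cfg = cfg or PipelineConfig()
    split = split_records([s for s in strips if s.usable], seed, cfg)

    train_feats = []
    counts = []
    for strip in split.train:
        sf = extract_strip_features(strip, cfg, subject_id)
        counts.append({"strip_id": sf.strip_id, "role": "train", **sf.counts})
        train_feats.append(sf.features)
    train_df = pd.concat(train_feats, ignore_index=True)
    model = fit_subject_model(train_df, cfg, subject_id=subject_id)

    beat_scores, beat_labels = [], []
    win_scores, win_labels, win_pred = [], [], []
    for strip in split.val:
        sf = extract_strip_features(strip, cfg, subject_id)
        counts.append({"strip_id": sf.strip_id, "role": "val", **sf.counts})
        is_dys = strip.label is GlycemicLabel.DYSGLYCEMIA
        preds = predict_beats(model, sf.features, sf.r_times_s)
        beat_scores.extend(p.score for p in preds)
        beat_labels.extend([is_dys] * len(preds))
        for w in vote_windows(preds, strip.start_time_s, cfg,
                              strip_duration_s=strip.duration_s):
            if w.n_beats == 0:
                continue
            win_scores.append(w.window_score)
            win_labels.append(is_dys)
            win_pred.append(w.label == "DYS")

    beat_metrics = compute_metrics(
        np.array(beat_scores), np.array(beat_labels),
        level="beat", subject_id=subject_id)
    window_metrics = compute_metrics(
        np.array(win_scores), np.array(win_labels),
        level="window10s", subject_id=subject_id,
        pred_labels=np.array(win_pred))
    return SubjectResult(
        subject_id=subject_id,
        model=model,
        beat_metrics=beat_metrics,
        window_metrics=window_metrics,
        strip_counts=counts,
        n_train_strips=len(split.train),
        n_val_strips=len(split.val),
    )


def subject_strips(subject, cfg: PipelineConfig | None = None) -> list[LabeledStrip]:
    """Labeled strips of a synthetic (or file-loaded) subject."""
    return match_ecg_to_bg(subject.record, subject.bg, cfg)
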