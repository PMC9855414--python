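"""Reading ECG/glucose data, glycemic labeling, strip matching and the
per-subject train/validation split.

File formats are deliberately plain text: ECG as CSV with ``time_s`` and
``voltage_mv`` columns, glucose as CSV with ``time_s,glucose_mgdl``. Times
are seconds from record start; glucose timestamps are storage times, and
each glucose value corresponds to the ECG window immediately *preceding*
its storage time.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import (
    DataError,
    SplitError,
    UnsupportedFormatError,
    UnsupportedSamplingRateError,
)

log = logging.getLogger(__name__)

BG_SANITY_LOW_MGDL = 10.0
BG_SANITY_HIGH_MGDL = 1500.0


class GlycemicLabel(enum.Enum):
    EUGLYCEMIA = "euglycemia"
    DYSGLYCEMIA = "dysglycemia"
    EXCLUDED = "excluded"


@dataclass
class ECGRecord:
    """Uniformly sampled single-lead voltage series in millivolts."""

    subject_id: str
    samples: np.ndarray
    sampling_rate_hz: float
    start_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise DataError("ECG record must be a non-empty 1-D series")
        if not np.all(np.isfinite(self.samples)):
            raise DataError("ECG record contains non-finite samples")
        if self.sampling_rate_hz <= 0:
            raise DataError("sampling rate must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz


@dataclass(frozen=True)
class BGRecord:
    """One glucose measurement: storage time (s from record start), mg/dL."""

    time_s: float
    glucose_mgdl: float

    def __post_init__(self) -> None:
        if not (BG_SANITY_LOW_MGDL < self.glucose_mgdl < BG_SANITY_HIGH_MGDL):
            raise DataError(
                f"glucose {self.glucose_mgdl} mg/dL outside sanity band "
                f"({BG_SANITY_LOW_MGDL}, {BG_SANITY_HIGH_MGDL})"
            )


@dataclass
class LabeledStrip:
    """The ECG window preceding one glucose record, with its class label.

    ``usable`` is False for strips whose label is EXCLUDED (buffer-zone
    glucose); they are kept for audit but barred from train/validation.
    """

    strip_id: str
    bg: BGRecord
    label: GlycemicLabel
    samples: np.ndarray
    start_time_s: float
    sampling_rate_hz: float

    @property
    def usable(self) -> bool:
        return self.label is not GlycemicLabel.EXCLUDED

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz


@dataclass
class TrainValSplit:
    train: list  # euglycemic LabeledStrips
    val: list    # euglycemic + dysglycemic LabeledStrips


def read_ecg(
    path: str | Path,
    format: str = "csv",
    subject_id: str | None = None,
    cfg: PipelineConfig | None = None,
) -> ECGRecord:
    """Read a single-lead ECG record and verify its sampling rate.

    Only ``format="csv"`` is supported by this build. The CSV must have a
    ``voltage_mv`` column; if a ``time_s`` column is present the sampling
    rate is inferred from it, otherwise the configured rate is assumed.
    """
    cfg = cfg or PipelineConfig()
    if format != "csv":
        raise UnsupportedFormatError(
            f"unsupported ECG format {format!r}: this build reads CSV only"
        )
    path = Path(path)
    if not path.exists():
        raise DataError(f"ECG file not found: {path}")
    df = pd.read_csv(path)
    if "voltage_mv" not in df.columns:
        raise DataError(f"{path} has no 'voltage_mv' column")
    start = 0.0
    if "time_s" in df.columns:
        t = df["time_s"].to_numpy(float)
        if t.size < 2:
            raise DataError(f"{path}: need at least two samples to infer rate")
        dt = np.median(np.diff(t))
        if dt <= 0:
            raise DataError(f"{path}: time_s must be strictly increasing")
        fs = 1.0 / dt
        start = float(t[0])
    else:
        fs = float(cfg.sampling_rate_hz)
    if abs(fs - cfg.sampling_rate_hz) > 0.01 * cfg.sampling_rate_hz:
        raise UnsupportedSamplingRateError(
            f"{path}: sampling rate {fs:.6g} Hz != required "
            f"{cfg.sampling_rate_hz} Hz (resampling is out of scope)"
        )
    return ECGRecord(
        subject_id=subject_id or path.stem,
        samples=df["voltage_mv"].to_numpy(float),
        sampling_rate_hz=float(cfg.sampling_rate_hz),
        start_time_s=start,
    )


def write_ecg_csv(record: ECGRecord, path: str | Path) -> None:
    t = record.start_time_s + np.arange(record.samples.size) / record.sampling_rate_hz
    pd.DataFrame({"time_s": t, "voltage_mv": record.samples}).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_bg_csv(path: str | Path) -> list[BGRecord]:
    df = pd.read_csv(path)
    for col in ("time_s", "glucose_mgdl"):
        if col not in df.columns:
            raise DataError(f"{path} has no '{col}' column")
    return [BGRecord(float(t), float(g))
            for t, g in zip(df["time_s"], df["glucose_mgdl"])]


def write_bg_csv(bg: list[BGRecord], path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": [b.time_s for b in bg],
         "glucose_mgdl": [b.glucose_mgdl for b in bg]}
    ).to_csv(path, index=False)


def label_bg(glucose_mgdl: float, cfg: PipelineConfig | None = None) -> GlycemicLabel:
    """Classify one glucose value.

    Strictly above the hyperglycemic or strictly below the hypoglycemic
    threshold is dysglycemia; the inclusive euglycemic band is normal;
    the two buffer bands (70-80 and 180-200 mg/dL by default, endpoints
    included) are excluded so that no run of consecutive heartbeats can
    carry two different class labels.
    """
    cfg = cfg or PipelineConfig()
    g = float(glucose_mgdl)
    if not (BG_SANITY_LOW_MGDL < g < BG_SANITY_HIGH_MGDL):
        raise DataError(f"glucose {g} mg/dL outside sanity band")
    if g > cfg.bg_hyper_mgdl or g < cfg.bg_hypo_mgdl:
        return GlycemicLabel.DYSGLYCEMIA
    if cfg.bg_eu_low_mgdl <= g <= cfg.bg_eu_high_mgdl:
        return GlycemicLabel.EUGLYCEMIA
    return GlycemicLabel.EXCLUDED


def match_ecg_to_bg(
    record: ECGRecord,
    bg: list[BGRecord],
    cfg: PipelineConfig | None = None,
) -> list[LabeledStrip]:
    """Cut one labeled strip per glucose record.

    Each strip is the half-open window ``[t - bg_corr_window_s, t)`` of
    signal preceding the glucose storage time ``t``. Glucose records whose
    window extends before the start of the record are dropped (logged);
    EXCLUDED labels are kept but flagged non-usable.
    """
    cfg = cfg or PipelineConfig()
    if record.sampling_rate_hz != cfg.sampling_rate_hz:
        raise UnsupportedSamplingRateError(
            f"record sampled at {record.sampling_rate_hz} Hz, "
            f"config requires {cfg.sampling_rate_hz} Hz"
        )
    times = [b.time_s for b in bg]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise DataError("glucose records must be sorted by time")
    fs = record.sampling_rate_hz
    window_n = round(cfg.bg_corr_window_s * fs)
    strips: list[LabeledStrip] = []
    for k, rec in enumerate(bg):
        t_start = rec.time_s - cfg.bg_corr_window_s
        if t_start < record.start_time_s - 1e-9:
            log.info(
                "subject %s: glucose record at t=%.1f s dropped "
                "(window extends before record start)",
                record.subject_id, rec.time_s,
            )
            continue
        i0 = round((t_start - record.start_time_s) * fs)
        i1 = i0 + window_n
        if i1 > record.samples.size:
            log.info(
                "subject %s: glucose record at t=%.1f s dropped "
                "(window extends past record end)",
                record.subject_id, rec.time_s,
            )
            continue
        strips.append(
            LabeledStrip(
                strip_id=f"{record.subject_id}/strip{k:03d}",
                bg=rec,
                label=label_bg(rec.glucose_mgdl, cfg),
                samples=record.samples[i0:i1],
                start_time_s=t_start,
                sampling_rate_hz=fs,
            )
        )
    return strips


def count_labels(bg: list[BGRecord], cfg: PipelineConfig | None = None) -> dict:
    cfg = cfg or PipelineConfig()
    counts = {lab: 0 for lab in GlycemicLabel}
    for rec in bg:
        counts[label_bg(rec.glucose_mgdl, cfg)] += 1
    return counts


def filter_subjects(subjects, cfg: PipelineConfig | None = None) -> list:
    """Apply the cohort inclusion rules.

    A subject is retained iff it has at least ``min_bg_records`` glucose
    records, at least ``min_dys_records`` dysglycemic ones, enough
    euglycemic ones to fill the split, and no atrial-fibrillation /
    pacemaker metadata flag. Each subject object must expose ``bg``
    (list of :class:`BGRecord`); an optional boolean attribute
    ``af_or_pacemaker`` excludes when True.
    """
    cfg = cfg or PipelineConfig()
    kept = []
    for subj in subjects:
        if getattr(subj, "af_or_pacemaker", False):
            continue
        counts = count_labels(subj.bg, cfg)
        if len(subj.bg) < cfg.min_bg_records:
            continue
        if counts[GlycemicLabel.DYSGLYCEMIA] < cfg.min_dys_records:
            continue
        if counts[GlycemicLabel.EUGLYCEMIA] < cfg.n_train_eu + cfg.n_val_eu:
            continue
        kept.append(subj)
    return kept


def split_records(
    strips: list[LabeledStrip],
    seed: int,
    cfg: PipelineConfig | None = None,
) -> TrainValSplit:
    """Draw the per-subject split: ``n_train_eu`` euglycemic strips for
    training, then ``n_val_eu`` euglycemic + ``n_val_dys`` dysglycemic
    strips for validation, sampled without replacement.
    """
    cfg = cfg or PipelineConfig()
    rng = np.random.default_rng(seed)
    eu = [s for s in strips if s.label is GlycemicLabel.EUGLYCEMIA]
    dys = [s for s in strips if s.label is GlycemicLabel.DYSGLYCEMIA]
    need_eu = cfg.n_train_eu + cfg.n_val_eu
    if len(eu) < need_eu:
        raise SplitError(
            f"need {need_eu} euglycemic strips "
            f"({cfg.n_train_eu} train + {cfg.n_val_eu} validation), have {len(eu)}"
        )
    if len(dys) < cfg.n_val_dys:
        raise SplitError(
            f"need {cfg.n_val_dys} dysglycemic strips, have {len(dys)}"
        )
    eu_idx = rng.permutation(len(eu))
    dys_idx = rng.permutation(len(dys))
    train = [eu[i] for i in eu_idx[: cfg.n_train_eu]]
    val_eu = [eu[i] for i in eu_idx[cfg.n_train_eu: need_eu]]
    val_dys = [dys[i] for i in dys_idx[: cfg.n_val_dys]]
    return TrainValSplit(train=train, val=val_eu + val_dys)
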