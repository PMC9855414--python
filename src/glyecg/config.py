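"""Pipeline configuration: every fixed constant of the method lives here.

All other modules take a :class:`PipelineConfig` argument instead of
hard-coding numbers, so the whole protocol is auditable (and testable at
reduced scale) from one flat JSON document.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path

from .errors import ConfigurationError

_STANDARDIZE_MODES = ("none", "scale", "zscore")


@dataclass(frozen=True)
class PipelineConfig:
    """Constants of the screening protocol.

    Beat geometry
    -------------
    sampling_rate_hz : ECG sampling rate; input at any other rate is an error.
    pre_r_samples, post_r_samples : beat window around the R peak. The two
        must sum to one second of samples and keep the 2:3 ratio.

    Glycemic labeling (mg/dL)
    -------------------------
    Dysglycemia is strictly ``> bg_hyper_mgdl`` or ``< bg_hypo_mgdl``;
    euglycemia is the inclusive band ``[bg_eu_low_mgdl, bg_eu_high_mgdl]``;
    the two buffer bands in between are excluded from training and
    validation so consecutive heartbeats cannot straddle two classes.

    Study structure
    ---------------
    bg_corr_window_s : ECG window preceding each glucose storage time.
    n_train_eu / n_val_eu / n_val_dys : the per-subject strip split.
    min_bg_records / min_dys_records : cohort inclusion thresholds.

    Model
    -----
    nu : one-class SVM ``nu`` — upper bound on the training-outlier
        fraction and lower bound on the support-vector fraction.
    standardize : feature pre-scaling mode, one of {none, scale, zscore}.
        Default ``none``: a linear one-class SVM separates the data from
        the origin, so centering the features (zscore) puts the origin in
        the middle of the training cloud and degenerates the fit.
    """

    sampling_rate_hz: int = 125
    pre_r_samples: int = 50
    post_r_samples: int = 75
    bg_corr_window_s: float = 600.0
    vote_window_s: float = 10.0
    nu: float = 0.75
    kernel: str = "linear"
    standardize: str = "none"
    svm_tol: float = 1e-6
    bg_hypo_mgdl: float = 70.0
    bg_eu_low_mgdl: float = 80.0
    bg_eu_high_mgdl: float = 180.0
    bg_hyper_mgdl: float = 200.0
    n_train_eu: int = 10
    n_val_eu: int = 5
    n_val_dys: int = 5
    min_bg_records: int = 20
    min_dys_records: int = 5
    min_train_beats: int = 50
    rng_seed: int = 0
    # R-peak detector (Pan-Tompkins-style chain)
    bandpass_low_hz: float = 5.0
    bandpass_high_hz: float = 15.0
    integration_window_s: float = 0.150
    refractory_s: float = 0.3
    # automated beat-quality rules (surrogate for manual noise inspection)
    quality_corr_min: float = 0.25
    quality_amp_ratio_low: float = 0.2
    quality_amp_ratio_high: float = 5.0
    quality_min_beats: int = 8
    # fiducial delineation
    wavelet: str = "db4"
    swt_levels: int = 3
    q_window_ms: float = 120.0
    s_window_ms: float = 120.0
    t_gap_ms: float = 40.0
    p_window_ms: float = 250.0
    p_gap_ms: float = 40.0
    p_prominence_mv: float = 0.01
    p_implausible_factor: float = 3.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.pre_r_samples + self.post_r_samples != self.sampling_rate_hz:
            raise ConfigurationError(
                "pre_r_samples + post_r_samples must equal sampling_rate_hz "
                f"(one 1-s beat window): {self.pre_r_samples} + "
                f"{self.post_r_samples} != {self.sampling_rate_hz}"
            )
        if self.pre_r_samples * 3 != self.post_r_samples * 2:
            raise ConfigurationError(
                "pre_r_samples:post_r_samples must reduce to 2:3, got "
                f"{self.pre_r_samples}:{self.post_r_samples}"
            )
        if not (0.0 < self.nu <= 1.0):
            raise ConfigurationError(f"nu must lie in (0, 1], got {self.nu}")
        if self.kernel != "linear":
            raise ConfigurationError(f"kernel must be 'linear', got {self.kernel!r}")
        if self.standardize not in _STANDARDIZE_MODES:
            raise ConfigurationError(
                f"standardize must be one of {_STANDARDIZE_MODES}, got "
                f"{self.standardize!r}"
            )
        if not (
            self.bg_hypo_mgdl
            < self.bg_eu_low_mgdl
            < self.bg_eu_high_mgdl
            < self.bg_hyper_mgdl
        ):
            raise ConfigurationError(
                "glucose thresholds must be ordered "
                "bg_hypo_mgdl < bg_eu_low_mgdl < bg_eu_high_mgdl < bg_hyper_mgdl"
            )
        for key in ("bg_corr_window_s", "vote_window_s", "refractory_s",
                    "integration_window_s"):
            if getattr(self, key) <= 0:
                raise ConfigurationError(f"{key} must be positive")
        if self.vote_window_s > self.bg_corr_window_s:
            raise ConfigurationError(
                "vote_window_s cannot exceed bg_corr_window_s"
            )
        for key in ("n_train_eu", "n_val_eu", "n_val_dys", "min_bg_records",
                    "min_dys_records", "min_train_beats", "quality_min_beats"):
            if getattr(self, key) < 1:
                raise ConfigurationError(f"{key} must be a positive integer")
        if not 0 < self.bandpass_low_hz < self.bandpass_high_hz:
            raise ConfigurationError("bandpass corner frequencies must satisfy "
                                     "0 < low < high")
        if self.bandpass_high_hz >= self.sampling_rate_hz / 2:
            raise ConfigurationError("bandpass_high_hz must be below Nyquist")
        if not 0 < self.quality_corr_min < 1:
            raise ConfigurationError("quality_corr_min must lie in (0, 1)")
        if not 0 < self.quality_amp_ratio_low < 1 < self.quality_amp_ratio_high:
            raise ConfigurationError(
                "amplitude ratio band must bracket 1: low in (0,1), high > 1"
            )

    # -- derived quantities ------------------------------------------------
    @property
    def beat_samples(self) -> int:
        return self.pre_r_samples + self.post_r_samples

    @property
    def q_window_samples(self) -> int:
        return max(1, round(self.q_window_ms / 1000.0 * self.sampling_rate_hz))

    @property
    def s_window_samples(self) -> int:
        return max(1, round(self.s_window_ms / 1000.0 * self.sampling_rate_hz))

    @property
    def t_gap_samples(self) -> int:
        return max(1, round(self.t_gap_ms / 1000.0 * self.sampling_rate_hz))

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from defaults, a flat JSON file and
    keyword overrides (in that order of precedence, later wins).

    Unknown keys — in the file or in ``overrides`` — are rejected so a typo
    cannot silently fall back to a default.
    """
    values: dict = {}
    if path is not None:
        try:
            raw = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ConfigurationError(f"cannot read config file {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigurationError("config file must hold a flat JSON object")
        values.update(raw)
    values.update(overrides)

    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = sorted(set(values) - known)
    if unknown:
        raise ConfigurationError(f"unknown configuration keys: {', '.join(unknown)}")
    for key, val in values.items():
        if isinstance(val, float) and not math.isfinite(val):
            raise ConfigurationError(f"configuration key {key} must be finite")
    return PipelineConfig(**values)
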