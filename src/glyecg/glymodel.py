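"""Per-subject linear nu-one-class SVM, beat scoring, 10-s majority-vote
aggregation and feature-importance ranking.

The model is trained on euglycemic beats only; dysglycemia is flagged as
an anomaly. ``nu`` upper-bounds the fraction of training beats scored as
outliers and lower-bounds the support-vector fraction. Scores are
oriented so that positive = dysglycemic (outlier); a beat exactly on the
hyperplane is labeled euglycemic.

Features enter the SVM unstandardized by default: a linear one-class SVM
separates the training cloud from the origin, and the physical offsets of
the morphology features (all intervals and pairwise amplitudes are
positive) are what give the origin its meaning. Dividing by the training
SD ("scale") or full z-scoring remain available through the
``standardize`` config key; z-scoring centers the cloud onto the origin
and degenerates the fit (see the methods note).
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.svm import OneClassSVM

from .config import PipelineConfig
from .errors import PredictionError, TrainingError
from .fiducials import FEATURE_NAMES

_ZERO_SD = 1e-12


@dataclass
class SubjectModel:
    """Fitted hyperplane ``w . x - rho`` with its training provenance."""

    subject_id: str
    feature_names: list
    weights: np.ndarray
    offset: float
    nu: float
    standardize: str
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    dropped_features: list
    train_outlier_fraction: float
    sv_fraction: float
    n_train_beats: int

    def transform(self, features: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in features.columns]
        if missing:
            raise PredictionError(f"missing features: {', '.join(missing)}")
        X = features[self.feature_names].to_numpy(float)
        if self.standardize == "zscore":
            X = (X - self.scaler_mean) / self.scaler_sd
        elif self.standardize == "scale":
            X = X / self.scaler_sd
        return X

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "feature_names": list(self.feature_names),
            "weights": self.weights.tolist(),
            "offset": self.offset,
            "nu": self.nu,
            "standardize": self.standardize,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
            "dropped_features": list(self.dropped_features),
            "train_outlier_fraction": self.train_outlier_fraction,
            "sv_fraction": self.sv_fraction,
            "n_train_beats": self.n_train_beats,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectModel":
        return cls(
            subject_id=d["subject_id"],
            feature_names=list(d["feature_names"]),
            weights=np.asarray(d["weights"], float),
            offset=float(d["offset"]),
            nu=float(d["nu"]),
            standardize=d["standardize"],
            scaler_mean=np.asarray(d["scaler_mean"], float),
            scaler_sd=np.asarray(d["scaler_sd"], float),
            dropped_features=list(d["dropped_features"]),
            train_outlier_fraction=float(d["train_outlier_fraction"]),
            sv_fraction=float(d["sv_fraction"]),
            n_train_beats=int(d["n_train_beats"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "SubjectModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class BeatPrediction:
    """Signed decision value for one beat; positive means dysglycemic."""

    r_time_s: float
    score: float

    @property
    def label(self) -> str:
        return "DYS" if self.score > 0 else "EU"


@dataclass
class WindowPrediction:
    """Majority vote over the beats of one fixed 10-s window."""

    start_s: float
    n_beats: int
    n_dys_votes: int

    @property
    def label(self) -> str | None:
        if self.n_beats == 0:
            return None
        # tie goes to dysglycemia: sensitivity outranks specificity
        return "DYS" if 2 * self.n_dys_votes >= self.n_beats else "EU"

    @property
    def window_score(self) -> float:
        if self.n_beats == 0:
            return float("nan")
        return self.n_dys_votes / self.n_beats


def fit_subject_model(
    train_features: pd.DataFrame,
    cfg: PipelineConfig | None = None,
    subject_id: str = "",
) -> SubjectModel:
    """Fit the linear nu-one-class SVM on euglycemic training beats.

    Zero-variance features are dropped (recorded on the model); the fit
    is deterministic for a fixed row order (fixed solver tolerance, no
    randomized initialization).
    """
    cfg = cfg or PipelineConfig()
    n = len(train_features)
    if n < cfg.min_train_beats:
        raise TrainingError(
            f"{n} training beats < required minimum {cfg.min_train_beats}")
    names = [c for c in FEATURE_NAMES if c in train_features.columns]
    if len(names) != len(FEATURE_NAMES):
        missing = set(FEATURE_NAMES) - set(names)
        raise TrainingError(f"missing features: {', '.join(sorted(missing))}")
    X_all = train_features[list(FEATURE_NAMES)].to_numpy(float)
    if not np.all(np.isfinite(X_all)):
        raise TrainingError("non-finite training features")
    mean = X_all.mean(axis=0)
    sd = X_all.std(axis=0)
    keep = sd > _ZERO_SD
    dropped = [f for f, k in zip(FEATURE_NAMES, keep) if not k]
    use_names = [f for f, k in zip(FEATURE_NAMES, keep) if k]
    X = X_all[:, keep]
    mean_k, sd_k = mean[keep], sd[keep]
    if cfg.standardize == "zscore":
        Xs = (X - mean_k) / sd_k
    elif cfg.standardize == "scale":
        Xs = X / sd_k
    else:
        Xs = X

    svm = OneClassSVM(kernel="linear", nu=cfg.nu, tol=cfg.svm_tol)
    svm.fit(Xs)
    decision = svm.decision_function(Xs)
    model = SubjectModel(
        subject_id=subject_id,
        feature_names=use_names,
        weights=svm.coef_.ravel().copy(),
        offset=float(np.asarray(svm.offset_).ravel()[0]),
        nu=cfg.nu,
        standardize=cfg.standardize,
        scaler_mean=mean_k,
        scaler_sd=sd_k,
        dropped_features=dropped,
        train_outlier_fraction=float(np.mean(decision < 0)),
        sv_fraction=float(svm.support_.size / n),
        n_train_beats=n,
    )
    if np.linalg.norm(model.weights) <= 0:
        raise TrainingError("degenerate fit: zero-norm hyperplane normal")
    return model


def decision_values(model: SubjectModel, features: pd.DataFrame) -> np.ndarray:
    """Signed scores, positive = dysglycemic orientation."""
    X = model.transform(features)
    return -(X @ model.weights - model.offset)


def predict_beats(
    model: SubjectModel,
    features: pd.DataFrame,
    r_times_s: np.ndarray | None = None,
) -> list[BeatPrediction]:
    scores = decision_values(model, features)
    if r_times_s is None:
        r_times_s = np.full(scores.size, np.nan)
    return [BeatPrediction(r_time_s=float(t), score=float(s))
            for t, s in zip(r_times_s, scores)]


def vote_windows(
    preds: list[BeatPrediction],
    strip_start_s: float,
    cfg: PipelineConfig | None = None,
    strip_duration_s: float | None = None,
) -> list[WindowPrediction]:
    """Partition a strip into consecutive fixed windows anchored at the
    strip start and take the majority beat vote in each.

    Windows with no beats are emitted unlabeled so the audit trail stays
    complete; callers exclude them from metrics.
    """
    cfg = cfg or PipelineConfig()
    dur = strip_duration_s if strip_duration_s is not None else cfg.bg_corr_window_s
    n_win = int(np.ceil(dur / cfg.vote_window_s))
    counts = np.zeros(n_win, dtype=int)
    dys = np.zeros(n_win, dtype=int)
    for p in preds:
        k = int((p.r_time_s - strip_start_s) // cfg.vote_window_s)
        if 0 <= k < n_win:
            counts[k] += 1
            if p.score > 0:
                dys[k] += 1
    return [
        WindowPrediction(
            start_s=strip_start_s + k * cfg.vote_window_s,
            n_beats=int(counts[k]),
            n_dys_votes=int(dys[k]),
        )
        for k in range(n_win)
    ]


def feature_importance(model: SubjectModel) -> list[tuple[str, float]]:
    """Features ranked by |hyperplane weight|, descending; ties broken by
    canonical feature order."""
    order = {f: i for i, f in enumerate(FEATURE_NAMES)}
    pairs = [(f, abs(w)) for f, w in zip(model.feature_names, model.weights)]
    return sorted(pairs, key=lambda fw: (-fw[1], order[fw[0]]))


def cohort_feature_importance(models: list[SubjectModel]) -> list[tuple[str, float]]:
    """Mean per-feature importance across subject models (features a
    model dropped contribute zero for that model)."""
    order = {f: i for i, f in enumerate(FEATURE_NAMES)}
    acc = {f: 0.0 for f in FEATURE_NAMES}
    for m in models:
        for f, w in zip(m.feature_names, m.weights):
            acc[f] += abs(w)
    n = max(1, len(models))
    return sorted(((f, v / n) for f, v in acc.items()),
                  key=lambda fw: (-fw[1], order[fw[0]]))
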