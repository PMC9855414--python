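"""Per-subject and cohort performance, and the euglycemia-vs-dysglycemia
feature comparison.

Dysglycemia is the positive class throughout. AUC is the rank statistic
(midranks for ties); threshold metrics use score > 0 at the beat level
and the majority label at the window level. Cohort values are unweighted
per-subject means with sample SD — subjects, not beats, are the unit of
analysis.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .errors import MetricsError

_METRIC_FIELDS = ("auc", "sensitivity", "specificity", "ppv", "npv", "accuracy")


@dataclass
class SubjectMetrics:
    subject_id: str
    level: str  # "beat" or "window10s"
    auc: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    n_pos: int
    n_neg: int


@dataclass
class CohortReport:
    """Mean and SD of each metric over subjects, per level."""

    levels: dict
    n_subjects: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for level, stats_ in self.levels.items():
            for metric, (mean, sd) in stats_.items():
                rows.append({"level": level, "metric": metric,
                             "mean": mean, "sd": sd})
        return pd.DataFrame(rows)

    def to_markdown(self) -> str:
        lines = ["| Level | " + " | ".join(m.upper() for m in _METRIC_FIELDS)
                 + " |",
                 "|---" * (len(_METRIC_FIELDS) + 1) + "|"]
        for level, stats_ in self.levels.items():
            cells = [f"{stats_[m][0]:.2f} ± {stats_[m][1]:.2f}"
                     for m in _METRIC_FIELDS]
            lines.append(f"| {level} | " + " | ".join(cells) + " |")
        return "\n".join(lines)


def compute_metrics(
    scores: np.ndarray,
    labels: np.ndarray,
    level: str = "beat",
    subject_id: str = "",
    threshold: float = 0.0,
    pred_labels: np.ndarray | None = None,
) -> SubjectMetrics:
    """Metrics for one subject at one level.

    ``labels`` is boolean with True = dysglycemic. ``pred_labels``
    overrides thresholding (used at the window level, where the majority
    label is the prediction and the vote fraction is the ranking score).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    if scores.size != labels.size or scores.size == 0:
        raise MetricsError("scores and labels must be equal-length, non-empty")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise MetricsError(
            f"both classes required for metrics (n_pos={n_pos}, n_neg={n_neg})")
    auc = float(roc_auc_score(labels, scores))
    pred = (scores > threshold) if pred_labels is None else np.asarray(
        pred_labels, bool)
    tp = int(np.sum(pred & labels))
    fn = int(np.sum(~pred & labels))
    tn = int(np.sum(~pred & ~labels))
    fp = int(np.sum(pred & ~labels))
    return SubjectMetrics(
        subject_id=subject_id,
        level=level,
        auc=auc,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        ppv=tp / (tp + fp) if tp + fp else float("nan"),
        npv=tn / (tn + fn) if tn + fn else float("nan"),
        accuracy=(tp + tn) / labels.size,
        n_pos=n_pos,
        n_neg=n_neg,
    )


def aggregate_cohort(metrics: list[SubjectMetrics]) -> CohortReport:
    """Unweighted per-subject mean and sample SD (ddof=1) per level."""
    levels: dict = {}
    by_level: dict = {}
    for m in metrics:
        by_level.setdefault(m.level, []).append(m)
    for level, ms in by_level.items():
        if len(ms) < 2:
            raise MetricsError(
                f"need >= 2 subjects per level to aggregate, got {len(ms)} "
                f"at level {level!r}")
        levels[level] = {
            f: (
                float(np.mean([getattr(m, f) for m in ms])),
                float(np.std([getattr(m, f) for m in ms], ddof=1)),
            )
            for f in _METRIC_FIELDS
        }
    subjects = {m.subject_id for m in metrics}
    return CohortReport(levels=levels, n_subjects=len(subjects))


def feature_comparison(
    features_eu: pd.DataFrame, features_dys: pd.DataFrame,
) -> pd.DataFrame:
    """Pooled-beat mean +/- SD per class and a two-sided Welch t p-value
    per feature.

    Zero-variance features get no p-value and a note instead.
    """
    if len(features_eu) < 2 or len(features_dys) < 2:
        raise MetricsError("need >= 2 beats per class for the comparison")
    rows = []
    for col in features_eu.columns:
        a = features_eu[col].to_numpy(float)
        b = features_dys[col].to_numpy(float)
        row = {
            "feature": col,
            "eu_mean": a.mean(), "eu_sd": a.std(ddof=1),
            "dys_mean": b.mean(), "dys_sd": b.std(ddof=1),
            "p_value": np.nan, "note": "",
        }
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            row["note"] = "zero variance in both classes; test omitted"
        else:
            row["p_value"] = stats.ttest_ind(a, b, equal_var=False).pvalue
        rows.append(row)
    return pd.DataFrame(rows).set_index("feature")


def feature_comparison_markdown(comparison: pd.DataFrame) -> str:
    lines = ["| Feature | Euglycemia | Dysglycemia | p-value |",
             "|---|---|---|---|"]
    for name, row in comparison.iterrows():
        p = ("<0.001" if row["p_value"] < 0.001 else f"{row['p_value']:.3f}") \
            if np.isfinite(row["p_value"]) else row["note"]
        lines.append(
            f"| {name} | {row['eu_mean']:.2f} ± {row['eu_sd']:.2f} "
            f"| {row['dys_mean']:.2f} ± {row['dys_sd']:.2f} | {p} |")
    return "\n".join(lines)


def anova_f_scores(
    features_eu: pd.DataFrame, features_dys: pd.DataFrame,
) -> pd.Series:
    """Secondary per-feature importance: one-way ANOVA F between classes
    on pooled beats (clearly separate from the hyperplane-weight ranking;
    the two answer different questions)."""
    from sklearn.feature_selection import f_classif

    X = pd.concat([features_eu, features_dys], ignore_index=True).to_numpy(float)
    y = np.r_[np.zeros(len(features_eu)), np.ones(len(features_dys))]
    f_vals, _ = f_classif(X, y)
    return pd.Series(f_vals, index=list(features_eu.columns),
                     name="anova_f").sort_values(ascending=False)
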