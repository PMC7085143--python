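"""Metrics and cross-task aggregation.

Binary tasks are scored by AUC, multiclass tasks by accuracy, survival tasks
by Harrell's concordance index.  Because absolute performance varies far more
between tasks than between model configurations, cross-task comparison uses a
*shifted* statistic: each configuration's metric minus the median metric of
all configurations on the same task.  Shifted scores are aggregated by a
sample-size-weighted average so that small, noisy tasks do not dominate.

Feature importance for linear models is the per-gene normalized rank of the
absolute regression coefficient, averaged over the K outer-fold models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.utils import concordance_index as _lifelines_cindex
from sklearn.metrics import roc_auc_score

__all__ = [
    "MetricRecord",
    "auc",
    "accuracy",
    "concordance_index",
    "shift_by_task_median",
    "weighted_average",
    "feature_importance",
    "metric_for_task_type",
]


@dataclass
class MetricRecord:
    """One (task, configuration) performance measurement."""

    task_id: str
    config: str
    metric: str  # "auc" | "accuracy" | "cindex"
    value: float
    n_samples: int


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (Mann-Whitney formulation, ties count 1/2)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def accuracy(predicted: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of exact class matches."""
    predicted = np.asarray(predicted)
    labels = np.asarray(labels)
    if predicted.shape != labels.shape:
        raise ValueError("predicted and labels must be aligned")
    return float(np.mean(predicted == labels))


def concordance_index(
    risk_scores: np.ndarray, times: np.ndarray, events: np.ndarray
) -> float:
    """Harrell's C: over pairs whose failure order is determined, the
    fraction in which the earlier failure has the higher risk (ties 1/2)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() == 0:
        raise ValueError("concordance requires at least one event")
    # lifelines scores *predicted survival time*; negate risk so that a higher
    # risk score means earlier expected failure.
    return float(_lifelines_cindex(times, -np.asarray(risk_scores, dtype=float), events))


def metric_for_task_type(task_type: str) -> str:
    return {"binary": "auc", "multiclass": "accuracy", "survival": "cindex"}[task_type]


def shift_by_task_median(records: list[MetricRecord]) -> pd.DataFrame:
    """Subtract, per task, the median metric of all configurations on it.

    Returns a DataFrame with columns task_id, config, metric, value,
    shifted_value, n_samples.  Positive shifted values mean the configuration
    outperformed the median model on that task.
    """
    if not records:
        return pd.DataFrame(
            columns=["task_id", "config", "metric", "value", "shifted_value", "n_samples"]
        )
    frame = pd.DataFrame([vars(r) for r in records])
    frame["shifted_value"] = frame["value"] - frame.groupby("task_id")["value"].transform(
        "median"
    )
    return frame


def weighted_average(shifted_values: np.ndarray, weights: np.ndarray) -> float:
    """Sample-size-weighted mean of shifted scores: sum(w*s)/sum(w)."""
    shifted_values = np.asarray(shifted_values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if shifted_values.size == 0:
        raise ValueError("weighted_average of empty input")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    return float(np.sum(weights * shifted_values) / np.sum(weights))


def _fold_coefficients(model) -> np.ndarray:
    """Per-gene importance magnitudes of one linear fold model.

    Multiclass logistic models contribute the maximum |coefficient| across
    classes for each gene.
    """
    coef = getattr(model, "coefficients", None)
    if coef is None:
        raise ValueError(f"model kind {getattr(model, 'kind', '?')!r} has no coefficients")
    coef = np.asarray(coef, dtype=float)
    if coef.ndim == 2:  # (n_classes, n_genes)
        return np.abs(coef).max(axis=0)
    return np.abs(coef)


def feature_importance(fold_models: list, gene_ids: np.ndarray) -> pd.DataFrame:
    """Mean normalized coefficient rank per gene across the K outer-fold models.

    Within each fold, genes are ranked by |coefficient| in descending order
    (rank 1 = largest) with ties broken by stable gene order, then ranks are
    divided by the number of genes.  Small mean normalized rank = important.
    """
    if not fold_models:
        raise ValueError("need at least one fold model")
    gene_ids = np.asarray(gene_ids)
    p = len(gene_ids)
    rank_sum = np.zeros(p)
    for model in fold_models:
        mags = _fold_coefficients(model)
        if len(mags) != p:
            raise ValueError("model coefficient length does not match gene_ids")
        order = np.lexsort((np.arange(p), -mags))  # descending |coef|, stable
        ranks = np.empty(p)
        ranks[order] = np.arange(1, p + 1)
        rank_sum += ranks / p
    return pd.DataFrame(
        {"gene_id": gene_ids, "mean_normalized_rank": rank_sum / len(fold_models)}
    )
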