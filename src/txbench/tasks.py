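"""Predictive task descriptions.

A :class:`TaskSpec` bundles one supervised problem: which samples it covers,
its label type (binary, multiclass, or right-censored survival), and which
benchmark group it belongs to (train / validate / test).  Tasks in the train
group may contribute labels to semi-supervised representation learning; the
validate and test groups are evaluation-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TASK_TYPES = ("binary", "multiclass", "survival")
GROUPS = ("train", "validate", "test")


@dataclass
class TaskSpec:
    """One predictive task over a subset of the cohort's samples."""

    task_id: str
    task_type: str
    group: str
    sample_ids: np.ndarray
    labels: np.ndarray | None = None  # class indices, classification tasks
    times: np.ndarray | None = None  # survival tasks
    events: np.ndarray | None = None
    n_classes: int | None = None

    def __post_init__(self) -> None:
        if self.task_type not in TASK_TYPES:
            raise ValueError(f"unknown task type {self.task_type!r}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        self.sample_ids = np.asarray(self.sample_ids)
        if self.task_type == "survival":
            if self.times is None or self.events is None:
                raise ValueError("survival task needs times and events")
            self.times = np.asarray(self.times, dtype=float)
            self.events = np.asarray(self.events, dtype=int)
            if np.any(self.times <= 0):
                raise ValueError("survival times must be positive")
        else:
            if self.labels is None:
                raise ValueError("classification task needs labels")
            self.labels = np.asarray(self.labels)
            observed = len(np.unique(self.labels))
            if self.task_type == "binary" and observed != 2:
                raise ValueError(f"binary task has {observed} observed classes")
            if self.n_classes is None:
                self.n_classes = observed

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def stratification_key(self) -> np.ndarray:
        """Class labels for classification tasks; event indicator for survival."""
        if self.task_type == "survival":
            return self.events
        return self.labels
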