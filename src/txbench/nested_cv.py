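"""Nested cross-validation engine and experiment bookkeeping.

Nested CV separates hyperparameter selection from performance estimation:
the outer loop splits the task into K folds; for each outer fold, an inner
K-fold loop over the outer-training data scores every hyperparameter value,
the best value is refit on all outer-training data, and the refit model is
evaluated once on the held-out outer fold.  The mean of the K outer-fold
metrics is the reported performance.  With N hyperparameter values this
trains exactly K(KN+1) models per (task, configuration, learner) cell, a
count the engine audits against its actual fit counter.

The engine also tracks sample identities so that tests can assert the
no-leak property: a held-out outer sample never participates in inner
training, hyperparameter selection, or the refit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .evaluation import accuracy, auc, concordance_index
from .supervised import Learner
from .tasks import TaskSpec

__all__ = [
    "FoldPlan",
    "CVResult",
    "ExperimentPlan",
    "make_folds",
    "nested_cv_run",
    "count_models",
    "enumerate_plan",
    "reference_plan",
]

DEFAULT_K = 5


@dataclass
class FoldPlan:
    """Outer folds and, per outer fold, inner folds over the outer-training
    samples.  All index arrays refer to positions within the task."""

    K: int
    seed: int
    outer_folds: list  # [(train_idx, test_idx), ...] length K
    inner_folds: list  # per outer fold: [(train_idx, val_idx), ...] length K

    def __post_init__(self) -> None:
        n = sum(len(test) for _, test in self.outer_folds)
        covered = np.sort(np.concatenate([test for _, test in self.outer_folds]))
        if not np.array_equal(covered, np.arange(n)):
            raise ValueError("outer folds do not partition the samples")


def make_folds(task: TaskSpec, K: int = DEFAULT_K, seed: int = 0) -> FoldPlan:
    """Stratified K-fold plan (by class, or by event indicator for survival),
    with an inner K-fold split of each outer-training set."""
    strata = task.stratification_key()
    n = len(strata)
    if n < 2 * K:
        raise ValueError(f"need at least 2K={2 * K} samples, got {n}")
    _, counts = np.unique(strata, return_counts=True)
    if counts.min() < K:
        raise ValueError(
            f"smallest stratum has {counts.min()} samples < K={K}; use a smaller K"
        )
    outer = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed)
    outer_folds = [
        (train.copy(), test.copy()) for train, test in outer.split(np.zeros(n), strata)
    ]
    inner_folds = []
    for f, (train_idx, _) in enumerate(outer_folds):
        inner = StratifiedKFold(n_splits=K, shuffle=True, random_state=seed + 1 + f)
        inner_folds.append(
            [
                (train_idx[tr], train_idx[va])
                for tr, va in inner.split(np.zeros(len(train_idx)), strata[train_idx])
            ]
        )
    return FoldPlan(K=K, seed=seed, outer_folds=outer_folds, inner_folds=inner_folds)


@dataclass
class CVResult:
    """Per-outer-fold selections and metrics for one benchmark cell."""

    task_id: str
    config: dict
    learner_kind: str
    fold_hyperparameters: list
    fold_metrics: list
    mean_metric: float
    fit_count: int
    n_samples: int
    fold_models: list = field(default_factory=list, repr=False)
    leak_free: bool = True


def _metric(task: TaskSpec, model, X_eval, eval_idx) -> float:
    if task.task_type == "survival":
        return concordance_index(
            model.decision_scores(X_eval), task.times[eval_idx], task.events[eval_idx]
        )
    if task.task_type == "binary":
        return auc(model.decision_scores(X_eval), task.labels[eval_idx])
    return accuracy(model.predict_class(X_eval), task.labels[eval_idx])


def _labels_for(task: TaskSpec, idx: np.ndarray):
    if task.task_type == "survival":
        return (task.times[idx], task.events[idx])
    return task.labels[idx]


def nested_cv_run(
    task: TaskSpec,
    features: np.ndarray,
    learner: Learner,
    plan: FoldPlan,
    config: dict | None = None,
    seed: int = 0,
) -> CVResult:
    """Run nested CV for one (task, feature representation, learner) cell.

    Hyperparameter ties in the inner loop break toward the learner's
    preferred (more regularized) value.  Returns per-fold selections and
    metrics, their mean, the audited fit count, and the K refit models.
    """
    if len(learner.grid) == 0:
        raise ValueError("empty hyperparameter grid")
    features = np.asarray(features, dtype=float)
    if len(features) != task.n_samples:
        raise ValueError("features are not aligned to the task samples")

    fit_count = 0
    fold_hps, fold_metrics, fold_models = [], [], []
    leak_free = True
    for f, (outer_train, outer_test) in enumerate(plan.outer_folds):
        held_out = set(outer_test.tolist())
        inner_means = []
        for hp in learner.grid:
            vals = []
            for g, (inner_train, inner_val) in enumerate(plan.inner_folds[f]):
                if held_out & set(inner_train.tolist()):
                    leak_free = False
                try:
                    model = learner.fit_one(
                        features[inner_train], _labels_for(task, inner_train), hp,
                        seed=seed + 1000 * f + g,
                    )
                except Exception as err:
                    raise RuntimeError(
                        f"fit failed at outer fold {f}, inner fold {g}, "
                        f"hyperparameter {hp!r}: {err}"
                    ) from err
                fit_count += 1
                vals.append(_metric(task, model, features[inner_val], inner_val))
            inner_means.append(float(np.mean(vals)))
        best_score = max(inner_means)
        tied = [hp for hp, m in zip(learner.grid, inner_means) if m == best_score]
        best_hp = max(tied, key=learner.prefer)
        if held_out & set(outer_train.tolist()):
            leak_free = False
        refit = learner.fit_one(
            features[outer_train], _labels_for(task, outer_train), best_hp,
            seed=seed + 1000 * f + 999,
        )
        fit_count += 1
        fold_hps.append(best_hp)
        fold_metrics.append(_metric(task, refit, features[outer_test], outer_test))
        fold_models.append(refit)

    expected = count_models(plan.K, len(learner.grid))
    if fit_count != expected:
        raise RuntimeError(
            f"fit counter {fit_count} does not match K(KN+1)={expected}"
        )
    return CVResult(
        task_id=task.task_id,
        config=dict(config or {}),
        learner_kind=learner.kind,
        fold_hyperparameters=fold_hps,
        fold_metrics=fold_metrics,
        mean_metric=float(np.mean(fold_metrics)),
        fit_count=fit_count,
        n_samples=task.n_samples,
        fold_models=fold_models,
        leak_free=leak_free,
    )


def count_models(K: int, n_grid: int) -> int:
    """Model fits required by nested CV: K(KN+1) for K folds, N grid values."""
    if K < 2 or n_grid < 1:
        raise ValueError("need K >= 2 and a nonempty grid")
    return K * (K * n_grid + 1)


# ---------------------------------------------------------------------------
# Experiment-plan bookkeeping
# ---------------------------------------------------------------------------

#: Embedder kinds fitted on every gene set vs. only on the reduced O/OT sets
#: (deep autoencoders are not trained on the all-genes set).
UNRESTRICTED_EMBEDDERS = ("identity", "pca")
RESTRICTED_EMBEDDERS = ("sdae", "vae")
RESTRICTED_GENE_SETS = ("O", "OT")


@dataclass
class ExperimentPlan:
    """The benchmark design: which (task, gene set, normalization, embedder,
    learner) cells exist, with the grid size of each learner."""

    n_classification_tasks: int
    n_survival_tasks: int
    gene_sets: tuple = ("all", "O", "OT")
    normalizations: tuple = ("tpm", "clr", "zscore", "zternary")
    embedders: tuple = ("identity", "pca", "sdae", "vae")
    classification_grids: dict = field(
        default_factory=lambda: {"LR": 10, "RF": 7, "kNN": 5}
    )
    survival_grids: dict = field(default_factory=lambda: {"CoxPH": 10})
    K: int = DEFAULT_K

    def admissible_representations(self):
        """(gene_set, embedder) pairs honoured by the design."""
        for gs in self.gene_sets:
            for emb in self.embedders:
                if emb in RESTRICTED_EMBEDDERS and gs not in RESTRICTED_GENE_SETS:
                    continue
                yield gs, emb


def enumerate_plan(plan: ExperimentPlan) -> tuple[int, int]:
    """Count (results, model fits) implied by a benchmark design.

    One *result* is a (task, gene set, normalization, embedder, learner)
    tuple; each result costs K(KN+1) model fits for that learner's grid."""
    reps = list(plan.admissible_representations())
    n_configs = len(reps) * len(plan.normalizations)
    cls_results = plan.n_classification_tasks * n_configs * len(plan.classification_grids)
    surv_results = plan.n_survival_tasks * n_configs * len(plan.survival_grids)

    cls_fits = (
        plan.n_classification_tasks
        * n_configs
        * sum(count_models(plan.K, n) for n in plan.classification_grids.values())
    )
    surv_fits = (
        plan.n_survival_tasks
        * n_configs
        * sum(count_models(plan.K, n) for n in plan.survival_grids.values())
    )
    return cls_results + surv_results, cls_fits + surv_fits


def reference_plan() -> ExperimentPlan:
    """The reference benchmark design: 24 classification and 26 survival
    tasks, 3 gene sets, 4 normalizations, identity/PCA everywhere plus
    SDAE/VAE on O and OT, grids of 10/7/5 for LR/RF/kNN and 10 for Cox."""
    return ExperimentPlan(n_classification_tasks=24, n_survival_tasks=26)
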