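"""Semi-supervised shared-embedding model.

A linear, single-hidden-layer autoencoder is trained jointly with one binary
logistic head per labeled task, all heads operating on the shared latent
code.  The training objective is a convex combination of the two data terms,
weighted by the predictor strength pi in [0, 1]:

    L = (1-pi)/BR * sum_m R(x_m) + pi/BC * sum_n C(x_n, l_n)
        + lambda_AE * l2(AE) + lambda_P * sum_j l2(P_j)

where R is the per-sample summed squared reconstruction error, C the binary
cross-entropy of the sample's own task head, and BR/BC the batch sizes of
the unlabeled and labeled streams.  pi = 0 is a plain autoencoder; pi = 1 a
purely supervised shared-embedding model.

Labels come only from the *first halves* of the divided tasks — binary
training-group tasks with at least 200 samples, split stratified in half —
while the second halves are held out to select the weight-penalty pair
(lambda_AE, lambda_P) from the 16-pair sweep over {0, 0.1, 0.01, 0.001}^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

from .evaluation import auc
from .nested_cv import make_folds, nested_cv_run
from .tasks import TaskSpec

__all__ = [
    "DividedTaskSplit",
    "SemiSupModel",
    "LabeledBlock",
    "LAMBDA_GRID",
    "split_divided_tasks",
    "reconstruction_loss",
    "classification_loss",
    "combined_loss",
    "train_semisup",
    "sweep_lambdas",
    "evaluate_embedding",
]

#: The swept l2 penalty values for both the autoencoder and the heads.
LAMBDA_GRID = (0.0, 0.1, 0.01, 0.001)


@dataclass
class DividedTaskSplit:
    """Which tasks were halved, and how."""

    threshold: int
    task_ids: list
    first_half: dict  # task_id -> index array into the task's samples
    second_half: dict


def split_divided_tasks(
    tasks: list, threshold: int = 200, seed: int = 0
) -> DividedTaskSplit:
    """Select binary train-group tasks with >= ``threshold`` samples and halve
    each stratified by class; halves are disjoint and exhaustive per task."""
    rng = np.random.default_rng(seed)
    selected, first, second = [], {}, {}
    for task in tasks:
        if task.task_type != "binary" or task.group != "train":
            continue
        if task.n_samples < threshold:
            continue
        selected.append(task.task_id)
        a_parts, b_parts = [], []
        for cls in np.unique(task.labels):
            idx = rng.permutation(np.flatnonzero(task.labels == cls))
            half = len(idx) // 2
            a_parts.append(idx[:half])
            b_parts.append(idx[half:])
        first[task.task_id] = np.sort(np.concatenate(a_parts))
        second[task.task_id] = np.sort(np.concatenate(b_parts))
    return DividedTaskSplit(threshold, selected, first, second)


@dataclass
class LabeledBlock:
    """First-half samples of one divided task, as presented to training."""

    task_id: str
    X: np.ndarray
    y: np.ndarray
    sample_ids: np.ndarray


@dataclass
class SemiSupModel:
    """Linear AE (p -> d -> p) plus per-task logistic heads on the latent."""

    W_enc: np.ndarray
    b_enc: np.ndarray
    W_dec: np.ndarray
    b_dec: np.ndarray
    head_w: dict  # task_id -> (d,) weights
    head_b: dict  # task_id -> bias
    pi: float
    lambda_ae: float
    lambda_p: float
    training_log: list = field(default_factory=list, repr=False)
    labeled_ids_seen: set = field(default_factory=set, repr=False)

    @property
    def latent_dim(self) -> int:
        return self.W_enc.shape[1]

    def encode(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.W_enc + self.b_enc

    def reconstruct(self, X: np.ndarray) -> np.ndarray:
        return self.encode(X) @ self.W_dec + self.b_dec

    def head_proba(self, X: np.ndarray, task_id: str) -> np.ndarray:
        if task_id not in self.head_w:
            raise KeyError(f"no head for task {task_id!r}")
        logit = self.encode(X) @ self.head_w[task_id] + self.head_b[task_id]
        return 1.0 / (1.0 + np.exp(-logit))

    def l2_ae(self) -> float:
        return float(np.sum(self.W_enc**2) + np.sum(self.W_dec**2))

    def l2_heads(self) -> float:
        return float(sum(np.sum(w**2) for w in self.head_w.values()))


def reconstruction_loss(model: SemiSupModel, x: np.ndarray) -> np.ndarray:
    """Elementwise squared reconstruction error, R(x)_i = (AE(x)_i - x_i)^2."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    return np.squeeze((model.reconstruct(x) - x) ** 2)


def classification_loss(
    model: SemiSupModel, x: np.ndarray, l_x: int, task_id: str
) -> float:
    """Binary cross-entropy of the task's head on the latent encoding of x:
    -log(P(x) l + (1 - P(x))(1 - l))."""
    if l_x not in (0, 1):
        raise ValueError("label must be 0 or 1")
    p = float(model.head_proba(np.atleast_2d(x), task_id)[0])
    return float(-np.log(p * l_x + (1.0 - p) * (1.0 - l_x) + 1e-300))


def combined_loss(
    model: SemiSupModel,
    unlabeled_batch: np.ndarray,
    labeled_batch: list,
) -> float:
    """The training objective on one pair of batches.

    ``labeled_batch`` is a list of (x, label, task_id) triples; it may be
    empty only when pi = 0, and the reconstruction batch may be empty only
    when pi = 1 (a zero-weight term contributes nothing)."""
    pi = model.pi
    total = model.lambda_ae * model.l2_ae() + model.lambda_p * model.l2_heads()
    if pi < 1.0:
        if len(unlabeled_batch) == 0:
            raise ValueError("reconstruction term has weight but no batch")
        per_sample = reconstruction_loss(model, unlabeled_batch)
        per_sample = np.atleast_2d(per_sample).sum(axis=1)
        total += (1.0 - pi) * float(per_sample.mean())
    if pi > 0.0:
        if not labeled_batch:
            raise ValueError("classification term has weight but no labeled batch")
        c = [classification_loss(model, x, l, j) for x, l, j in labeled_batch]
        total += pi * float(np.mean(c))
    return float(total)


@dataclass(frozen=True)
class SemiSupTrainSpec:
    steps: int = 400
    batch_recon: int = 256  # BR
    batch_class: int = 64  # BC
    learning_rate: float = 1e-3
    momentum: float = 0.9
    latent_dim: int = 32
    seed: int = 0


def train_semisup(
    X_pool: np.ndarray,
    labeled: list,
    pi: float,
    lambda_ae: float,
    lambda_p: float,
    spec: SemiSupTrainSpec = SemiSupTrainSpec(),
) -> SemiSupModel:
    """SGD on the combined loss.

    ``X_pool`` is the reconstruction stream (all unlabeled samples plus the
    first halves); ``labeled`` is a list of :class:`LabeledBlock`, one per
    divided task, whose union forms the classification stream.  Labeled
    batches are drawn uniformly from that union and each sample is routed to
    its own task's head.  The model records every labeled sample id it saw,
    so tests can verify the held-out halves never enter training.
    """
    if not 0.0 <= pi <= 1.0:
        raise ValueError("pi must lie in [0, 1]")
    if pi > 0.0 and not labeled:
        raise ValueError("pi > 0 requires labeled data")
    X_pool = np.asarray(X_pool, dtype=float)
    n, p = X_pool.shape
    d = spec.latent_dim
    rng = np.random.default_rng(spec.seed)

    model = SemiSupModel(
        W_enc=rng.normal(0.0, np.sqrt(1.0 / p), size=(p, d)),
        b_enc=np.zeros(d),
        W_dec=rng.normal(0.0, np.sqrt(1.0 / d), size=(d, p)),
        b_dec=np.zeros(p),
        head_w={blk.task_id: rng.normal(0.0, np.sqrt(1.0 / d), size=d) for blk in labeled},
        head_b={blk.task_id: 0.0 for blk in labeled},
        pi=pi,
        lambda_ae=lambda_ae,
        lambda_p=lambda_p,
    )

    if labeled:
        lab_X = np.vstack([blk.X for blk in labeled])
        lab_y = np.concatenate([blk.y for blk in labeled])
        lab_task = np.concatenate(
            [np.repeat(blk.task_id, len(blk.y)) for blk in labeled]
        )
        lab_ids = np.concatenate([blk.sample_ids for blk in labeled])

    v = {
        "W_enc": np.zeros_like(model.W_enc),
        "b_enc": np.zeros_like(model.b_enc),
        "W_dec": np.zeros_like(model.W_dec),
        "b_dec": np.zeros_like(model.b_dec),
    }
    v_head = {blk.task_id: (np.zeros(d), 0.0) for blk in labeled}
    lr, mom = spec.learning_rate, spec.momentum

    for step in range(spec.steps):
        gW_enc = 2.0 * lambda_ae * model.W_enc
        gb_enc = np.zeros(d)
        gW_dec = 2.0 * lambda_ae * model.W_dec
        gb_dec = np.zeros(p)
        recon_val = class_val = 0.0

        if pi < 1.0:
            idx = rng.choice(n, size=min(spec.batch_recon, n), replace=False)
            xb = X_pool[idx]
            B = len(xb)
            h = xb @ model.W_enc + model.b_enc
            xhat = h @ model.W_dec + model.b_dec
            err = xhat - xb
            recon_val = float(np.sum(err**2) / B)
            g_xhat = 2.0 * (1.0 - pi) * err / B
            gW_dec += h.T @ g_xhat
            gb_dec += g_xhat.sum(axis=0)
            g_h = g_xhat @ model.W_dec.T
            gW_enc += xb.T @ g_h
            gb_enc += g_h.sum(axis=0)

        if pi > 0.0:
            pick = rng.choice(len(lab_y), size=min(spec.batch_class, len(lab_y)),
                              replace=False)
            model.labeled_ids_seen.update(lab_ids[pick].tolist())
            xb = lab_X[pick]
            yb = lab_y[pick].astype(float)
            tb = lab_task[pick]
            B = len(xb)
            h = xb @ model.W_enc + model.b_enc
            g_h = np.zeros_like(h)
            losses = []
            for task_id in np.unique(tb):
                rows = np.flatnonzero(tb == task_id)
                w_j = model.head_w[task_id]
                logit = h[rows] @ w_j + model.head_b[task_id]
                prob = 1.0 / (1.0 + np.exp(-logit))
                y_rows = yb[rows]
                losses.extend(
                    (-np.log(np.where(y_rows == 1, prob, 1.0 - prob) + 1e-300)).tolist()
                )
                g_logit = pi * (prob - y_rows) / B
                gw = h[rows].T @ g_logit + 2.0 * lambda_p * w_j
                gb = float(g_logit.sum())
                g_h[rows] += np.outer(g_logit, w_j)
                vw, vb = v_head[task_id]
                vw = mom * vw - lr * gw
                vb = mom * vb - lr * gb
                model.head_w[task_id] = w_j + vw
                model.head_b[task_id] = model.head_b[task_id] + vb
                v_head[task_id] = (vw, vb)
            class_val = float(np.mean(losses))
            gW_enc += xb.T @ g_h
            gb_enc += g_h.sum(axis=0)

        for name, grad in (
            ("W_enc", gW_enc), ("b_enc", gb_enc), ("W_dec", gW_dec), ("b_dec", gb_dec)
        ):
            v[name] = mom * v[name] - lr * grad
            setattr(model, name, getattr(model, name) + v[name])

        total = (1.0 - pi) * recon_val + pi * class_val
        if not np.isfinite(total):
            raise FloatingPointError(
                f"semi-supervised training diverged at step {step}; "
                f"log tail {model.training_log[-5:]}"
            )
        model.training_log.append(
            {"step": step, "reconstruction": recon_val, "classification": class_val}
        )
    return model


def heldout_error(model: SemiSupModel, heldout: list) -> float:
    """1 - mean AUC of the trained heads on the held-out second halves."""
    aucs = [auc(model.head_proba(blk.X, blk.task_id), blk.y) for blk in heldout]
    return float(1.0 - np.mean(aucs))


def sweep_lambdas(
    X_pool: np.ndarray,
    labeled: list,
    heldout: list,
    pi: float,
    spec: SemiSupTrainSpec = SemiSupTrainSpec(),
    grid: tuple = LAMBDA_GRID,
) -> tuple[tuple, list]:
    """Train one model per (lambda_AE, lambda_P) pair of the 16-pair grid and
    select the pair minimizing 1 - mean held-out-half AUC.

    Returns ``(best_pair, results)`` where results is a list of dicts with
    keys lambda_ae, lambda_p, pi, heldout_error, model.  Ties keep the first
    pair in grid order (deterministic).
    """
    results = []
    for lam_ae, lam_p in product(grid, grid):
        model = train_semisup(X_pool, labeled, pi, lam_ae, lam_p, spec)
        err = heldout_error(model, heldout)
        results.append(
            {
                "lambda_ae": lam_ae,
                "lambda_p": lam_p,
                "pi": pi,
                "heldout_error": err,
                "model": model,
            }
        )
    best = min(results, key=lambda r: r["heldout_error"])
    return (best["lambda_ae"], best["lambda_p"]), results


def evaluate_embedding(
    model: SemiSupModel | None,
    tasks_with_features: list,
    learners: list,
    K: int = 5,
    seed: int = 0,
) -> list:
    """Run the standard nested CV for each (task, learner) on the latent
    encoding (or on raw features when ``model`` is None — the no-embedding
    control arm, which follows the identical computation path)."""
    results = []
    for task, X in tasks_with_features:
        feats = model.encode(X) if model is not None else np.asarray(X, dtype=float)
        plan = make_folds(task, K=K, seed=seed)
        for learner in learners:
            results.append(
                nested_cv_run(
                    task,
                    feats,
                    learner,
                    plan,
                    config={"embedding": "semisup" if model is not None else "identity"},
                    seed=seed,
                )
            )
    return results
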