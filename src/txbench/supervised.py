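"""Supervised learners and their hyperparameter grids.

Four multivariate model families are benchmarked: l2-regularized multinomial
logistic regression and an l2-regularized Cox proportional-hazards model,
both trained by first-order (gradient) descent with a fixed learning rate so
that they remain tractable when the number of genes far exceeds the number of
samples; plus random forests (100 trees) and k-nearest-neighbour classifiers
from scikit-learn.  Single-gene logistic/Cox comparators treat the choice of
gene as the hyperparameter.

The Cox model handles tied event times with the Efron correction, which
reduces exactly to the standard partial likelihood when all event times are
distinct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier

__all__ = [
    "FittedModel",
    "default_grid",
    "fit_logistic",
    "fit_rf",
    "fit_knn",
    "efron_pseudolikelihood",
    "fit_cox_efron",
    "fit_single_gene_logistic",
    "fit_single_gene_cox",
    "Learner",
    "LogisticLearner",
    "RandomForestLearner",
    "KNNLearner",
    "CoxLearner",
    "SingleGeneLearner",
]

#: Benchmark grids: l2 penalties for LR/Cox, tree depths for RF, k for kNN.
PENALTY_GRID = tuple(np.logspace(-6, 3, 10))
DEPTH_GRID = tuple(int(round(v)) for v in np.logspace(np.log2(2), np.log2(128), 7, base=2))
KNN_GRID = (1, 3, 5, 7, 9)


def default_grid(kind: str) -> tuple:
    """The benchmark hyperparameter grid for a learner kind."""
    return {
        "LR": PENALTY_GRID,
        "CoxPH": PENALTY_GRID,
        "RF": DEPTH_GRID,
        "kNN": KNN_GRID,
    }[kind]


@dataclass
class FittedModel:
    kind: str
    hyperparameter: float | int
    coefficients: np.ndarray | None = None
    intercept: np.ndarray | float | None = None
    estimator: object = None
    classes: np.ndarray | None = None
    loss_trace: list = field(default_factory=list, repr=False)
    feature_index: int | None = None  # single-gene models: which column

    # -- prediction -------------------------------------------------------
    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = self._maybe_select(X)
        if self.estimator is not None:
            return self.estimator.predict_proba(X)
        logits = X @ self.coefficients.T + self.intercept
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        return p / p.sum(axis=1, keepdims=True)

    def predict_class(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(X)
        return self.classes[np.argmax(proba, axis=1)]

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Scalar score per sample: positive-class probability (binary),
        predicted class (multiclass), or linear risk score (survival)."""
        if self.kind in ("CoxPH", "single-gene-Cox"):
            return self._maybe_select(X) @ self.coefficients
        proba = self.predict_proba(X)
        if proba.shape[1] == 2:
            return proba[:, 1]
        return self.classes[np.argmax(proba, axis=1)]

    def _maybe_select(self, X: np.ndarray) -> np.ndarray:
        if self.feature_index is not None:
            return X[:, [self.feature_index]]
        return X


# ---------------------------------------------------------------------------
# Logistic regression (multinomial softmax, first-order descent)
# ---------------------------------------------------------------------------


def _softmax(logits: np.ndarray) -> np.ndarray:
    logits = logits - logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    return p / p.sum(axis=1, keepdims=True)


def _auto_rate(X: np.ndarray, l2_penalty: float, curvature: float) -> float:
    """Fixed step 1/L from a power-iteration bound on the loss curvature.

    L = curvature * sigma_max(X)^2 / n + 2*penalty upper-bounds the Hessian
    spectral norm (curvature 1/4 for logistic losses, ~1 for the Cox
    pseudolikelihood), so gradient descent at 1/L cannot diverge."""
    n = len(X)
    v = np.ones(X.shape[1]) / np.sqrt(X.shape[1])
    for _ in range(8):
        w = X.T @ (X @ v)
        nrm = np.linalg.norm(w)
        if nrm == 0:
            break
        v = w / nrm
    sigma_sq = float(v @ (X.T @ (X @ v)))
    L = curvature * sigma_sq / n + 2.0 * l2_penalty + 1e-12
    return 1.0 / L


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    l2_penalty: float,
    *,
    learning_rate: float | None = None,
    momentum: float = 0.9,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> FittedModel:
    """Multinomial softmax regression minimizing mean cross-entropy plus
    ``l2_penalty * ||W||^2`` (intercept unpenalized) by gradient descent with
    a fixed learning rate and heavy-ball momentum.

    The default rate is the conservative 1/L bound from the data's spectral
    norm, small enough to guarantee controlled descent on any task, and
    stays fixed throughout.  Deterministic: full-batch gradients, no random
    initialization.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if l2_penalty < 0:
        raise ValueError("l2_penalty must be nonnegative")
    if learning_rate is None:
        learning_rate = _auto_rate(X, l2_penalty, curvature=0.25)
    classes, y_idx = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("fit_logistic needs at least two observed classes")
    n, p = X.shape
    k = len(classes)
    Y = np.zeros((n, k))
    Y[np.arange(n), y_idx] = 1.0

    W = np.zeros((k, p))
    b = np.zeros(k)
    vW = np.zeros_like(W)
    vb = np.zeros_like(b)
    trace = []
    for _ in range(max_iter):
        P = _softmax(X @ W.T + b)
        resid = (P - Y) / n
        gW = resid.T @ X + 2.0 * l2_penalty * W
        gb = resid.sum(axis=0)
        gnorm = max(np.abs(gW).max(), np.abs(gb).max())
        loss = -np.mean(np.log(P[np.arange(n), y_idx] + 1e-300)) + l2_penalty * np.sum(
            W * W
        )
        trace.append(loss)
        if not np.isfinite(loss):
            raise FloatingPointError(f"logistic fit diverged; trace tail {trace[-5:]}")
        if gnorm < tol:
            break
        vW = momentum * vW - learning_rate * gW
        vb = momentum * vb - learning_rate * gb
        W = W + vW
        b = b + vb
    return FittedModel(
        kind="LR",
        hyperparameter=l2_penalty,
        coefficients=W,
        intercept=b,
        classes=classes,
        loss_trace=trace,
    )


def fit_rf(X: np.ndarray, y: np.ndarray, max_depth: int, *, seed: int = 0) -> FittedModel:
    """Random forest with 100 trees at the given maximum depth."""
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    est = RandomForestClassifier(n_estimators=100, max_depth=max_depth, random_state=seed)
    est.fit(X, y)
    return FittedModel(
        kind="RF", hyperparameter=max_depth, estimator=est, classes=est.classes_
    )


def fit_knn(X: np.ndarray, y: np.ndarray, k: int, *, seed: int = 0) -> FittedModel:
    """Majority-vote k-nearest neighbours with Euclidean distance."""
    if k > len(X):
        raise ValueError(f"k={k} exceeds the number of training samples {len(X)}")
    est = KNeighborsClassifier(n_neighbors=k)
    est.fit(X, y)
    return FittedModel(
        kind="kNN", hyperparameter=k, estimator=est, classes=est.classes_
    )


# ---------------------------------------------------------------------------
# Cox proportional hazards with Efron tie handling
# ---------------------------------------------------------------------------


def efron_pseudolikelihood(
    beta: np.ndarray, X: np.ndarray, times: np.ndarray, events: np.ndarray
) -> tuple[float, np.ndarray]:
    """Negative Efron-corrected Cox partial log-likelihood and its gradient.

    For each distinct event time with d tied events, the d tied subjects'
    hazard mass is withdrawn from the risk set in equal fractions l/d,
    l = 0..d-1.  With no ties this is exactly the standard partial
    likelihood.  Returns ``(-loglik, d(-loglik)/dbeta)``.
    """
    beta = np.asarray(beta, dtype=float)
    X = np.asarray(X, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() == 0:
        raise ValueError("Efron pseudolikelihood requires at least one event")

    order = np.argsort(times, kind="stable")
    t_s, e_s, X_s = times[order], events[order], X[order]
    eta = X_s @ beta
    eta_stab = eta - eta.max()  # overflow guard; partial likelihood is shift-invariant
    w = np.exp(eta_stab)
    # suffix sums: risk set at time t = samples with time >= t
    suffix = np.cumsum(w[::-1])[::-1]

    ev_pos = np.flatnonzero(e_s == 1)  # ascending in time (stable sort)
    event_times, starts, counts = np.unique(
        t_s[ev_pos], return_index=True, return_counts=True
    )
    first = np.searchsorted(t_s, event_times, side="left")
    S_R = suffix[first]
    S_D = np.add.reduceat(w[ev_pos], starts)

    # per-group risk weight A_g = sum_l phi_l with phi_l = 1/(S_R - (l/d) S_D)
    A = np.zeros(len(event_times))
    loglik = float(eta_stab[ev_pos].sum())
    tie_weight = np.zeros(len(t_s))
    untied = counts == 1
    A[untied] = 1.0 / S_R[untied]
    loglik -= float(np.log(S_R[untied]).sum())
    for g in np.flatnonzero(~untied):  # tied event times only
        d = counts[g]
        ls = np.arange(d) / d
        denom = S_R[g] - ls * S_D[g]
        loglik -= float(np.log(denom).sum())
        phi = 1.0 / denom
        A[g] = phi.sum()
        D = ev_pos[starts[g] : starts[g] + d]
        tie_weight[D] = (ls * phi).sum()
    cumA = np.cumsum(A)

    # each sample is at risk for all event times <= its own time
    g_idx = np.searchsorted(event_times, t_s, side="right") - 1
    at_risk = g_idx >= 0
    weight = np.zeros(len(t_s))
    weight[at_risk] = cumA[g_idx[at_risk]]
    weight -= tie_weight
    dll_deta = e_s - w * weight
    grad = -(X_s.T @ dll_deta)
    return -loglik, grad


def fit_cox_efron(
    X: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    l2_penalty: float,
    *,
    learning_rate: float | None = None,
    momentum: float = 0.9,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> FittedModel:
    """l2-regularized Cox fit minimizing ``-loglik/n + l2_penalty*||beta||^2``
    by fixed-rate gradient descent with momentum (rate defaulting to the
    conservative 1/L spectral bound, fixed throughout the run).

    First-order training keeps the model usable when genes vastly outnumber
    subjects, where Newton-type solvers would need a p x p Hessian.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if l2_penalty < 0:
        raise ValueError("l2_penalty must be nonnegative")
    if learning_rate is None:
        learning_rate = _auto_rate(X - X.mean(axis=0), l2_penalty, curvature=1.0)
    beta = np.zeros(p)
    v = np.zeros(p)
    trace = []
    for _ in range(max_iter):
        negll, grad = efron_pseudolikelihood(beta, X, times, events)
        loss = negll / n + l2_penalty * beta @ beta
        trace.append(loss)
        if not np.isfinite(loss):
            raise FloatingPointError(f"Cox fit diverged; loss trace tail {trace[-5:]}")
        g = grad / n + 2.0 * l2_penalty * beta
        if np.abs(g).max() < tol:
            break
        v = momentum * v - learning_rate * g
        beta = beta + v
    return FittedModel(
        kind="CoxPH", hyperparameter=l2_penalty, coefficients=beta, loss_trace=trace
    )


# ---------------------------------------------------------------------------
# Single-gene comparators
# ---------------------------------------------------------------------------


def fit_single_gene_logistic(
    X: np.ndarray, y: np.ndarray, gene_index: int, *, seed: int = 0, **opt
) -> FittedModel:
    """Unregularized univariate logistic model on one CLR gene column."""
    opt.setdefault("max_iter", 500)
    model = fit_logistic(X[:, [gene_index]], y, 0.0, seed=seed, **opt)
    return FittedModel(
        kind="single-gene-LR",
        hyperparameter=gene_index,
        coefficients=model.coefficients,
        intercept=model.intercept,
        classes=model.classes,
        feature_index=gene_index,
    )


def fit_single_gene_cox(
    X: np.ndarray, times: np.ndarray, events: np.ndarray, gene_index: int,
    *, seed: int = 0, **opt,
) -> FittedModel:
    """Unregularized univariate Cox model on one CLR gene column."""
    opt.setdefault("max_iter", 500)
    model = fit_cox_efron(X[:, [gene_index]], times, events, 0.0, seed=seed, **opt)
    return FittedModel(
        kind="single-gene-Cox",
        hyperparameter=gene_index,
        coefficients=model.coefficients,
        feature_index=gene_index,
    )


# ---------------------------------------------------------------------------
# Uniform learner interface for the nested-CV engine
# ---------------------------------------------------------------------------


@dataclass
class Learner:
    """A learner kind with its grid and a tie-break preference.

    ``prefer`` maps a hyperparameter value to a sort key; among inner-loop
    ties the value with the *largest* key wins (more regularization)."""

    kind: str
    grid: Sequence
    fit: Callable[..., FittedModel]
    prefer: Callable[[float], float]
    task_kind: str  # "classification" | "survival"
    fit_options: dict = field(default_factory=dict)

    def fit_one(self, features, labels, hp, seed):
        if self.task_kind == "survival":
            times, events = labels
            return self.fit(features, times, events, hp, seed=seed, **self.fit_options)
        return self.fit(features, labels, hp, seed=seed, **self.fit_options)


def LogisticLearner(grid=PENALTY_GRID, **fit_options) -> Learner:
    return Learner("LR", tuple(grid), fit_logistic, lambda hp: hp, "classification",
                   fit_options)


def RandomForestLearner(grid=DEPTH_GRID, **fit_options) -> Learner:
    return Learner("RF", tuple(grid), fit_rf, lambda hp: -hp, "classification",
                   fit_options)


def KNNLearner(grid=KNN_GRID, **fit_options) -> Learner:
    return Learner("kNN", tuple(grid), fit_knn, lambda hp: hp, "classification",
                   fit_options)


def CoxLearner(grid=PENALTY_GRID, **fit_options) -> Learner:
    return Learner("CoxPH", tuple(grid), fit_cox_efron, lambda hp: hp, "survival",
                   fit_options)


def SingleGeneLearner(n_genes: int, task_kind: str, **fit_options) -> Learner:
    """Single-gene comparator: the gene index is the hyperparameter searched
    by the inner loop; ties prefer the lowest gene index (stable order)."""
    grid = tuple(range(n_genes))
    if task_kind == "survival":
        return Learner("single-gene-Cox", grid, fit_single_gene_cox,
                       lambda hp: -hp, "survival", fit_options)
    return Learner("single-gene-LR", grid, fit_single_gene_logistic,
                   lambda hp: -hp, "classification", fit_options)
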