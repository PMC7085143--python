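"""Configuration-driven orchestration of the full benchmark pipeline.

``run_experiment`` wires the stages end to end on a synthetic cohort:
simulate -> QC -> normalize (TPM/CLR/Z-score/Z-ternary) -> gene-set
restriction -> embedder fitting on the unlabeled pool -> nested CV for every
admissible (task, gene set, normalization, embedder, learner) cell ->
results table.  Every cell result is cached under a content hash of its
configuration so reruns skip completed work, and the actual fit counter is
audited against the design's predicted K(KN+1) bookkeeping.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import embeddings as emb
from .nested_cv import (
    ExperimentPlan,
    RESTRICTED_EMBEDDERS,
    RESTRICTED_GENE_SETS,
    count_models,
    enumerate_plan,
    make_folds,
    nested_cv_run,
)
from .preprocess import (
    build_tissue_reference,
    qc_filter,
    select_gene_set,
    to_clr,
    to_tpm,
    to_zscore,
    to_zternary,
)
from .simulate import SimulationConfig, generate_dataset
from .supervised import (
    CoxLearner,
    KNNLearner,
    LogisticLearner,
    RandomForestLearner,
)

__all__ = ["RunConfig", "run_experiment", "dry_run"]


@dataclass
class RunConfig:
    """One benchmark run: cohort recipe, design axes, and optimizer scale."""

    simulation: SimulationConfig
    gene_sets: tuple = ("all", "O", "OT")
    normalizations: tuple = ("tpm", "clr", "zscore", "zternary")
    embedders: tuple = ("identity", "pca")
    classification_learners: tuple = ("LR", "RF", "kNN")
    K: int = 5
    latent_dim: int = 32
    seed: int = 0
    out_dir: str | None = None
    fit_options: dict = field(default_factory=dict)  # passed to LR/Cox fits
    embed_spec: emb.TrainSpec = field(default_factory=emb.TrainSpec)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim = SimulationConfig(**raw.pop("simulation", {}))
        spec = emb.TrainSpec(**raw.pop("embed_spec", {}))
        for key in ("gene_sets", "normalizations", "embedders", "classification_learners"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(simulation=sim, embed_spec=spec, **raw)

    def plan(self) -> ExperimentPlan:
        n_cls = sum(
            1 for t in self.simulation.tasks if t.task_type in ("binary", "multiclass")
        )
        n_surv = sum(1 for t in self.simulation.tasks if t.task_type == "survival")
        from .supervised import default_grid

        return ExperimentPlan(
            n_classification_tasks=n_cls,
            n_survival_tasks=n_surv,
            gene_sets=self.gene_sets,
            normalizations=self.normalizations,
            embedders=self.embedders,
            classification_grids={
                k: len(default_grid(k)) for k in self.classification_learners
            },
            K=self.K,
        )


def _stage_seed(master: int, *labels) -> int:
    """Independent, reproducible stream per (stage, cell) label tuple."""
    digest = hashlib.sha256(repr((master,) + labels).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _learner_for(kind: str, fit_options: dict):
    opts = dict(fit_options)
    if kind == "LR":
        return LogisticLearner(**opts)
    if kind == "RF":
        return RandomForestLearner()
    if kind == "kNN":
        return KNNLearner()
    if kind == "CoxPH":
        return CoxLearner(**opts)
    raise ValueError(f"unknown learner kind {kind!r}")


def dry_run(config: RunConfig) -> dict:
    """Enumerate the plan without training: cells, result and fit counts."""
    plan = config.plan()
    n_results, n_fits = enumerate_plan(plan)
    cells = []
    for gs, embedder in plan.admissible_representations():
        for norm in plan.normalizations:
            cells.append({"gene_set": gs, "normalization": norm, "embedder": embedder})
    return {
        "n_results": n_results,
        "n_model_fits": n_fits,
        "n_representation_cells": len(cells),
        "cells": cells,
    }


def run_experiment(config: RunConfig) -> pd.DataFrame:
    """Execute the full pipeline; returns the per-cell results table.

    Columns: task_id, gene_set, normalization, embedder, learner, fold,
    chosen_hyperparameter, metric, mean_metric, n_samples.  If ``out_dir``
    is set, the table is written to ``results.csv`` there and completed
    cells are cached (content-addressed) for cheap reruns.
    """
    sim = config.simulation
    dataset = generate_dataset(sim)
    counts, meta, annot = dataset.counts, dataset.metadata, dataset.annotation

    qc = qc_filter(counts, meta, annot, set(meta.table["tissue"].dropna()))
    counts = counts.subset_samples(qc.keep_mask)
    meta = meta.subset(qc.keep_mask)
    kept_ids = set(counts.sample_ids.tolist())
    tasks = [_restrict_task(t, kept_ids) for t in dataset.tasks]

    tpm = to_tpm(counts)
    clr = to_clr(tpm)
    labeled_ids = set()
    for task in tasks:
        labeled_ids.update(task.sample_ids.tolist())
    unlabeled_mask = ~np.isin(counts.sample_ids, sorted(labeled_ids))
    ref = build_tissue_reference(clr, meta, unlabeled_mask)
    zscore = to_zscore(clr, meta, ref)
    zternary = to_zternary(zscore)
    norm_matrices = {"tpm": tpm, "clr": clr, "zscore": zscore, "zternary": zternary}

    sample_pos = {sid: i for i, sid in enumerate(counts.sample_ids)}

    cache_dir = None
    if config.out_dir is not None:
        cache_dir = Path(config.out_dir) / "cache"
        cache_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    total_fits = 0
    plan = config.plan()
    for gene_set, embedder_kind in plan.admissible_representations():
        for norm in config.normalizations:
            matrix = select_gene_set(norm_matrices[norm], annot, gene_set)
            cell_seed = _stage_seed(config.seed, "embed", gene_set, norm, embedder_kind)
            embedder = _fit_embedder(
                embedder_kind,
                matrix.values[unlabeled_mask],
                config.latent_dim,
                config.embed_spec,
                cell_seed,
            )
            for task in tasks:
                kinds = (
                    ("CoxPH",)
                    if task.task_type == "survival"
                    else config.classification_learners
                )
                task_rows_idx = np.array([sample_pos[s] for s in task.sample_ids])
                features = embedder.encode(matrix.values[task_rows_idx])
                for kind in kinds:
                    cell = {
                        "task_id": task.task_id,
                        "gene_set": gene_set,
                        "normalization": norm,
                        "embedder": embedder_kind,
                        "learner": kind,
                    }
                    key = hashlib.sha256(
                        repr((sorted(cell.items()), config.seed)).encode()
                    ).hexdigest()
                    cached = _cache_load(cache_dir, key)
                    if cached is not None:
                        cell_rows, fits = cached
                    else:
                        try:
                            learner = _learner_for(kind, config.fit_options)
                            fold_plan = make_folds(
                                task, K=config.K,
                                seed=_stage_seed(config.seed, "folds", task.task_id),
                            )
                            result = nested_cv_run(
                                task, features, learner, fold_plan, config=cell,
                                seed=_stage_seed(config.seed, "fit", *cell.values()),
                            )
                        except Exception as err:
                            raise RuntimeError(f"stage failed at cell {cell}: {err}") from err
                        cell_rows = [
                            {
                                **cell,
                                "fold": f,
                                "chosen_hyperparameter": result.fold_hyperparameters[f],
                                "metric": result.fold_metrics[f],
                                "mean_metric": result.mean_metric,
                                "n_samples": task.n_samples,
                            }
                            for f in range(config.K)
                        ]
                        fits = result.fit_count
                        _cache_store(cache_dir, key, (cell_rows, fits))
                    rows.extend(cell_rows)
                    total_fits += fits

    expected_results, expected_fits = enumerate_plan(plan)
    n_results = len(rows) // config.K
    if n_results != expected_results or total_fits != expected_fits:
        raise RuntimeError(
            f"bookkeeping mismatch: ran {n_results} results / {total_fits} fits, "
            f"design predicts {expected_results} / {expected_fits}"
        )
    frame = pd.DataFrame(rows)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "results.csv", index=False)
    return frame


def _restrict_task(task, kept_ids):
    """Drop task samples that failed cohort QC; error if the task degrades."""
    from .tasks import TaskSpec

    keep = np.array([sid in kept_ids for sid in task.sample_ids])
    if keep.all():
        return task
    if task.task_type == "survival":
        return TaskSpec(
            task.task_id, "survival", task.group, task.sample_ids[keep],
            times=task.times[keep], events=task.events[keep],
        )
    return TaskSpec(
        task.task_id, task.task_type, task.group, task.sample_ids[keep],
        labels=task.labels[keep], n_classes=task.n_classes,
    )


def _fit_embedder(kind, X_unlabeled, d, spec, seed):
    spec = emb.TrainSpec(**{**asdict(spec), "seed": seed})
    if kind == "identity":
        return emb.identity_embedder(X_unlabeled.shape[1])
    if kind == "pca":
        return emb.fit_pca_stochastic(X_unlabeled, d, spec)
    if kind == "sdae":
        return emb.fit_sdae(X_unlabeled, d, spec)
    if kind == "vae":
        return emb.fit_vae(X_unlabeled, d, spec)
    raise ValueError(f"unknown embedder kind {kind!r}")


def _cache_load(cache_dir, key):
    if cache_dir is None:
        return None
    path = cache_dir / f"{key}.json"
    if not path.exists():
        return None
    payload = json.loads(path.read_text())
    return payload["rows"], payload["fits"]


def _cache_store(cache_dir, key, value) -> None:
    if cache_dir is None:
        return
    rows, fits = value
    (cache_dir / f"{key}.json").write_text(json.dumps({"rows": rows, "fits": fits}))
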