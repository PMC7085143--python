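"""Synthetic bulk RNA-seq cohorts with planted, recoverable signal.

The public compendium behind the benchmark (healthy-tissue atlas, cancer
atlas, and archive studies) cannot be bundled, so every downstream stage is
exercised on synthetic data with known ground truth.  Counts are generated by
a compositional hierarchy:

1. each gene has a baseline log-expression, each tissue a per-gene offset;
2. a sample adds i.i.d. Gaussian log-expression noise, and labeled samples
   additionally add ``label x effect-vector`` (classification) in
   log-expression space — which makes the planted signal *linear in CLR
   coordinates*, so an l2 logistic model on CLR data is well specified;
3. the log-expression vector is softmaxed to a composition and counts are
   drawn from a multinomial at the sample's library size (log-normal, heavy
   tailed), preserving the relative-abundance structure the CLR transform
   assumes.

Survival tasks draw exponential proportional-hazards times whose log-hazard
is the planted effect vector dotted with the sample's noise-free CLR vector;
censoring is an independent uniform horizon tuned numerically to the
requested censoring fraction.

Quality-control violations (cell lines, single-cell studies, unknown
tissues, duplicated accessions, sparse samples) are injected on top of a
clean cohort so the five-rule filter has exact, known targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import CountMatrix, GeneAnnotation, SampleMetadata
from .tasks import TaskSpec

__all__ = [
    "TaskBlueprint",
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "generate_dataset",
    "inject_qc_violations",
    "write_dataset",
]


@dataclass(frozen=True)
class TaskBlueprint:
    """Recipe for one labeled task in the synthetic cohort.

    ``module_correlation`` makes the planted genes behave as a co-regulated
    module: the fraction of each signal gene's per-sample log-expression
    variance carried by a shared latent factor (aligned with the effect
    signs).  Real disease signatures are coordinated pathways, not isolated
    genes, and a rank-based survival signal spread over independent genes
    would be statistically invisible at cohort scale regardless of effect
    size."""

    task_id: str
    task_type: str  # binary | multiclass | survival
    n_samples: int
    n_signal_genes: int
    effect_size: float
    group: str = "train"
    n_classes: int = 2
    signal_gene_set: str = "O"  # where the planted genes live
    module_correlation: float = 0.9


@dataclass(frozen=True)
class SimulationConfig:
    """Desk-scale stand-in for the benchmark's cohort structure.

    Defaults mirror the reduced problem sizes used throughout the test
    suite: 5 tissues, 2000 genes of which 600 carry GO annotation (O) and
    100 are annotated transcription factors (OT), 2000 unlabeled samples,
    and labeled tasks of a few hundred samples.
    """

    n_tissues: int = 5
    n_genes: int = 2000
    genes_in_O: int = 600
    genes_in_OT: int = 100
    n_unlabeled: int = 2000
    tasks: tuple = ()
    library_size_mean: float = 1e5
    library_size_sigma: float = 0.5
    censoring_fraction: float = 0.3
    tissue_sd: float = 0.8
    sample_sd: float = 0.5
    gene_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.genes_in_OT <= self.genes_in_O <= self.n_genes):
            raise ValueError("need 0 < genes_in_OT <= genes_in_O <= n_genes")
        if not (0 <= self.censoring_fraction < 1):
            raise ValueError("censoring_fraction must be in [0, 1)")
        for v in (self.n_tissues, self.n_genes, self.n_unlabeled):
            if v <= 0:
                raise ValueError("all counts must be positive")


@dataclass
class GroundTruth:
    """What was planted: per-task effect vectors (CLR-space coefficients for
    classification, log-hazard coefficients for survival) plus the tissue
    profiles the cohort was drawn from."""

    effects: dict  # task_id -> (n_genes,) vector with exactly s nonzeros
    signal_genes: dict  # task_id -> sorted array of planted gene indices
    tissue_mean_log: np.ndarray  # (n_tissues, n_genes)
    sample_sd: float


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    metadata: SampleMetadata
    annotation: GeneAnnotation
    tasks: list
    truth: GroundTruth


def _gene_set_indices(config: SimulationConfig, which: str) -> np.ndarray:
    if which == "OT":
        return np.arange(config.genes_in_OT)
    if which == "O":
        return np.arange(config.genes_in_O)
    return np.arange(config.n_genes)


def _library_sizes(rng, config: SimulationConfig, n: int) -> np.ndarray:
    mu = np.log(config.library_size_mean) - config.library_size_sigma**2 / 2
    sizes = rng.lognormal(mu, config.library_size_sigma, size=n)
    return np.maximum(sizes.round().astype(np.int64), 1000)


def _draw_counts(rng, eta: np.ndarray, library: int) -> np.ndarray:
    comp = np.exp(eta - eta.max())
    comp /= comp.sum()
    return rng.multinomial(library, comp)


def _tune_censoring_horizon(raw_times: np.ndarray, fraction: float) -> float:
    """Bisection for the uniform-horizon upper bound giving the requested
    expected censoring fraction on the drawn event times."""
    if fraction == 0:
        return float(np.inf)

    def censored_frac(c_max: float) -> float:
        # P(C < T) with C ~ U(0, c_max): mean over samples of min(T, c_max)/c_max
        return float(np.mean(np.minimum(raw_times, c_max) / c_max))

    lo, hi = 1e-6, float(raw_times.max()) * 100
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        if censored_frac(mid) > fraction:
            lo = mid  # too much censoring -> raise horizon
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def generate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Draw a full synthetic cohort: unlabeled pool plus one labeled block
    per task blueprint, with metadata, nested gene-set flags, and the planted
    ground truth.  Identical (config, seed) gives byte-identical output."""
    rng = np.random.default_rng(config.seed)
    G, T = config.n_genes, config.n_tissues

    gene_ids = np.array([f"G{i:05d}" for i in range(G)])
    gene_lengths = np.maximum(rng.lognormal(np.log(1500), 0.6, size=G), 100.0)
    base_log = rng.normal(0.0, config.gene_sd, size=G)
    tissue_dev = rng.normal(0.0, config.tissue_sd, size=(T, G))
    tissue_mean_log = base_log[None, :] + tissue_dev
    tissue_names = np.array([f"tissue_{t}" for t in range(T)])

    effects: dict[str, np.ndarray] = {}
    signal_genes: dict[str, np.ndarray] = {}
    for bp in config.tasks:
        pool = _gene_set_indices(config, bp.signal_gene_set)
        # plant effects only in the expressed half of the set: genes whose
        # baseline expression sits below the set median yield so few reads
        # that their CLR coordinate is dominated by counting noise, making a
        # planted effect unobservable for any method
        expressed = pool[base_log[pool] > np.median(base_log[pool])]
        if bp.n_signal_genes > len(expressed):
            raise ValueError(
                f"task {bp.task_id!r}: {bp.n_signal_genes} signal genes exceed "
                f"the {len(expressed)} expressed genes of set {bp.signal_gene_set!r}"
            )
        chosen = np.sort(rng.choice(expressed, size=bp.n_signal_genes, replace=False))
        vec = np.zeros(G)
        if bp.n_signal_genes:
            signs = rng.choice([-1.0, 1.0], size=bp.n_signal_genes)
            vec[chosen] = bp.effect_size * signs
        effects[bp.task_id] = vec
        signal_genes[bp.task_id] = chosen

    rows_counts, rows_meta = [], []
    tasks: list[TaskSpec] = []
    sample_counter = 0

    def add_sample(
        tissue_idx: int,
        study: str,
        shift: np.ndarray | None,
        module: tuple | None = None,
    ):
        nonlocal sample_counter
        dev = rng.normal(0.0, config.sample_sd, size=G)
        if module is not None:
            idx, signs, r = module
            factor = rng.normal()
            dev[idx] = config.sample_sd * (
                np.sqrt(1.0 - r) * dev[idx] / config.sample_sd
                + np.sqrt(r) * factor * signs
            )
        eta = tissue_mean_log[tissue_idx] + dev
        if shift is not None:
            eta = eta + shift
        library = _library_sizes(rng, config, 1)[0]
        rows_counts.append(_draw_counts(rng, eta, library))
        sid = f"S{sample_counter:06d}"
        rows_meta.append(
            {
                "sample_id": sid,
                "tissue": tissue_names[tissue_idx],
                "study": study,
                "accession": f"GSM{sample_counter:06d}",
                "is_cell_line": False,
                "is_single_cell": False,
            }
        )
        sample_counter += 1
        return sid, eta

    for i in range(config.n_unlabeled):
        add_sample(int(rng.integers(T)), f"SRP{i % 20:03d}", None)

    for k, bp in enumerate(config.tasks):
        tissue_idx = k % T
        study = f"TASK{k:02d}"
        vec = effects[bp.task_id]
        chosen = signal_genes[bp.task_id]
        module = None
        if len(chosen) and bp.module_correlation > 0:
            module = (chosen, np.sign(vec[chosen]), bp.module_correlation)
        sids, etas = [], []
        if bp.task_type in ("binary", "multiclass"):
            n_classes = 2 if bp.task_type == "binary" else bp.n_classes
            labels = rng.integers(n_classes, size=bp.n_samples)
            # guard: every class observed
            labels[: n_classes] = np.arange(n_classes)
            for lab in labels:
                scale = lab / max(n_classes - 1, 1)
                sid, _ = add_sample(tissue_idx, study, scale * vec, module)
                sids.append(sid)
            tasks.append(
                TaskSpec(
                    task_id=bp.task_id,
                    task_type=bp.task_type,
                    group=bp.group,
                    sample_ids=np.array(sids),
                    labels=labels,
                    n_classes=n_classes,
                )
            )
        elif bp.task_type == "survival":
            for _ in range(bp.n_samples):
                sid, eta = add_sample(tissue_idx, study, None, module)
                sids.append(sid)
                etas.append(eta)
            clr = np.asarray(etas)
            clr = clr - clr.mean(axis=1, keepdims=True)
            lp = clr @ vec
            lp = lp - lp.mean()
            raw = rng.exponential(1.0, size=bp.n_samples) / np.exp(lp)
            horizon = _tune_censoring_horizon(raw, config.censoring_fraction)
            if np.isfinite(horizon):
                cens = rng.uniform(0.0, horizon, size=bp.n_samples)
            else:
                cens = np.full(bp.n_samples, np.inf)
            times = np.minimum(raw, cens)
            events = (raw <= cens).astype(int)
            if events.sum() == 0:
                raise RuntimeError(f"task {bp.task_id!r}: censoring removed all events")
            times = np.maximum(times, 1e-9)
            tasks.append(
                TaskSpec(
                    task_id=bp.task_id,
                    task_type="survival",
                    group=bp.group,
                    sample_ids=np.array(sids),
                    times=times,
                    events=events,
                )
            )
        else:
            raise ValueError(f"unknown task type {bp.task_type!r}")

    counts = CountMatrix(
        counts=np.asarray(rows_counts, dtype=np.int64),
        gene_ids=gene_ids,
        gene_lengths=gene_lengths,
        sample_ids=np.array([r["sample_id"] for r in rows_meta]),
    )
    metadata = SampleMetadata(pd.DataFrame(rows_meta))
    annotation = GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": gene_ids,
                "in_O": np.arange(G) < config.genes_in_O,
                "in_OT": np.arange(G) < config.genes_in_OT,
            }
        )
    )
    truth = GroundTruth(
        effects=effects,
        signal_genes=signal_genes,
        tissue_mean_log=tissue_mean_log,
        sample_sd=config.sample_sd,
    )
    return SimulatedDataset(counts, metadata, annotation, tasks, truth)


def inject_qc_violations(
    data: CountMatrix,
    meta: SampleMetadata,
    annot: GeneAnnotation,
    counts_per_criterion: dict[str, int],
    seed: int = 0,
) -> tuple[CountMatrix, SampleMetadata]:
    """Mutate copies of (counts, metadata) so that *exactly* the requested
    number of samples match each of the five exclusion rules.

    Keys of ``counts_per_criterion``: ``cell_line``, ``single_cell_study``,
    ``tissue_not_in_reference``, ``duplicate_accession``, ``zero_fraction_O``.
    Samples already matching a rule count toward its total; the injector
    tops up with previously clean samples (overlap across rules is allowed
    and rules stay non-exclusive).
    """
    from .preprocess import qc_filter  # deferred: avoids cycle at import time

    rng = np.random.default_rng(seed)
    new_counts = data.counts.copy()
    table = meta.table.copy()
    reference_tissues = set(table["tissue"].dropna())

    def current_masks():
        cm = CountMatrix(new_counts, data.gene_ids, data.gene_lengths, data.sample_ids)
        return qc_filter(cm, SampleMetadata(table), annot, reference_tissues).match_masks

    o_mask = annot.mask("O")
    n_o = int(o_mask.sum())
    n_zero_target = int(np.floor(0.30 * n_o)) + 1  # strictly more than 30%

    for criterion, requested in counts_per_criterion.items():
        masks = current_masks()
        if criterion not in masks:
            raise KeyError(f"unknown QC criterion {criterion!r}")
        have = int(masks[criterion].sum())
        if have > requested:
            raise ValueError(
                f"{criterion}: {have} samples already match, cannot reduce to {requested}"
            )
        need = requested - have
        if need == 0:
            continue
        clean = np.flatnonzero(~masks[criterion])
        if need > len(clean):
            raise ValueError(f"{criterion}: not enough samples to flag {need} more")
        chosen = rng.choice(clean, size=need, replace=False)
        if criterion == "cell_line":
            table.loc[chosen, "is_cell_line"] = True
        elif criterion == "single_cell_study":
            table.loc[chosen, "study"] = "SC_INJECTED"
            table.loc[chosen, "is_single_cell"] = True
        elif criterion == "tissue_not_in_reference":
            table.loc[chosen, "tissue"] = "tissue_unknown"
        elif criterion == "duplicate_accession":
            if need == 1:
                if have >= 2:
                    # join an existing duplicate group: only the newcomer is a
                    # new match
                    existing = table.loc[np.flatnonzero(masks[criterion])[0], "accession"]
                    table.loc[chosen, "accession"] = existing
                else:
                    raise ValueError(
                        "duplicate matches come in groups of >= 2 samples; "
                        "cannot create exactly 1 match from a clean cohort"
                    )
            else:
                groups = np.array_split(chosen, max(need // 2, 1))
                for grp in groups:
                    table.loc[grp, "accession"] = f"GSMDUP{grp[0]:06d}"
        elif criterion == "zero_fraction_O":
            o_idx = np.flatnonzero(o_mask)[:n_zero_target]
            for s in chosen:
                new_counts[s, o_idx] = 0
        masks = current_masks()
        if int(masks[criterion].sum()) != requested:
            raise RuntimeError(f"{criterion}: injection did not hit the target count")

    cm = CountMatrix(new_counts, data.gene_ids, data.gene_lengths, data.sample_ids)
    return cm, SampleMetadata(table)


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> None:
    """Write counts (gzipped TSV, genes x samples with id/length columns),
    metadata, task labels, and ground-truth effects as delimited text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = dataset.counts
    frame = pd.DataFrame(
        counts.counts.T, index=counts.gene_ids, columns=counts.sample_ids
    )
    frame.insert(0, "length", counts.gene_lengths)
    frame.index.name = "gene_id"
    frame.to_csv(out / "counts.tsv.gz", sep="\t", compression="gzip")
    dataset.metadata.table.to_csv(out / "metadata.tsv", sep="\t", index=False)
    dataset.annotation.table.to_csv(out / "gene_annotation.tsv", sep="\t", index=False)

    label_rows = []
    for task in dataset.tasks:
        for i, sid in enumerate(task.sample_ids):
            row = {"task_id": task.task_id, "sample_id": sid, "group": task.group}
            if task.task_type == "survival":
                row.update(time=task.times[i], event=task.events[i])
            else:
                row.update(label=task.labels[i])
            label_rows.append(row)
    pd.DataFrame(label_rows).to_csv(out / "labels.tsv", sep="\t", index=False)

    truth_rows = []
    for task_id, vec in dataset.truth.effects.items():
        for g in np.flatnonzero(vec):
            truth_rows.append(
                {"task_id": task_id, "gene_id": counts.gene_ids[g], "effect": vec[g]}
            )
    pd.DataFrame(truth_rows).to_csv(out / "ground_truth.tsv", sep="\t", index=False)
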