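"""Sample quality control, gene-set restriction, and expression normalization.

The pipeline operates on gene-level read counts and applies a fixed chain of
transforms: counts -> TPM -> CLR -> tissue Z-score -> Z-ternary.  Each stage
consumes only its declared predecessor; gene-set restriction happens *after*
normalization, by plain column subsetting, so that e.g. CLR rows restricted to
a subset no longer sum to zero (the transform is defined on all genes).

Containers are thin wrappers over pandas/numpy: a :class:`CountMatrix` holds
raw integer counts with gene lengths, :class:`SampleMetadata` and
:class:`GeneAnnotation` are aligned DataFrames, and an
:class:`ExpressionMatrix` tags a real-valued matrix with the transform and
gene set that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleMetadata",
    "GeneAnnotation",
    "ExpressionMatrix",
    "TissueReference",
    "QCResult",
    "qc_filter",
    "select_gene_set",
    "to_tpm",
    "to_clr",
    "build_tissue_reference",
    "to_zscore",
    "to_zternary",
]

NORMALIZATIONS = ("counts", "tpm", "clr", "zscore", "zternary")
GENE_SETS = ("all", "O", "OT")

#: Zero-variance guard for reference standard deviations.
STD_FLOOR = 1e-6

#: |Z| threshold separating "normal" from up/down-regulated expression.
ZTERNARY_THRESHOLD = 2.0


@dataclass
class CountMatrix:
    """Raw gene-level read counts for a cohort.

    Attributes
    ----------
    counts : (n_samples, n_genes) int array of nonnegative read counts.
    gene_ids : length n_genes sequence of gene identifiers.
    gene_lengths : length n_genes array of strictly positive lengths (bases).
    sample_ids : length n_samples sequence of sample identifiers.
    """

    counts: np.ndarray
    gene_ids: np.ndarray
    gene_lengths: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = np.asarray(self.gene_ids)
        self.gene_lengths = np.asarray(self.gene_lengths, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids)
        n_samples, n_genes = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.gene_lengths) != n_genes:
            raise ValueError("gene annotation length does not match counts")
        if len(self.sample_ids) != n_samples:
            raise ValueError("sample_ids length does not match counts")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(self.gene_lengths <= 0):
            raise ValueError("gene lengths must be strictly positive")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, mask: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts[mask],
            gene_ids=self.gene_ids,
            gene_lengths=self.gene_lengths,
            sample_ids=self.sample_ids[mask],
        )


class SampleMetadata:
    """Per-sample metadata aligned to a :class:`CountMatrix`.

    Wraps a DataFrame with columns ``sample_id``, ``tissue``, ``study``,
    ``accession``, ``is_cell_line``, ``is_single_cell``.  A missing tissue is
    encoded as NaN/empty and is treated downstream as "not a reference
    tissue".
    """

    COLUMNS = ("sample_id", "tissue", "study", "accession", "is_cell_line", "is_single_cell")

    def __init__(self, table: pd.DataFrame):
        missing = set(self.COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        self.table = table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def aligned_to(self, data: CountMatrix) -> "SampleMetadata":
        if len(self) != data.n_samples or not np.array_equal(
            self.table["sample_id"].to_numpy(), data.sample_ids
        ):
            raise ValueError("metadata is not aligned to the count matrix")
        return self

    def subset(self, mask: np.ndarray) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[np.asarray(mask)].reset_index(drop=True))


class GeneAnnotation:
    """Gene-set membership flags: ``in_O`` (GO-annotated) and ``in_OT``
    (GO-annotated transcription factors), with OT nested inside O."""

    def __init__(self, table: pd.DataFrame):
        missing = {"gene_id", "in_O", "in_OT"} - set(table.columns)
        if missing:
            raise ValueError(f"gene annotation missing columns: {sorted(missing)}")
        table = table.reset_index(drop=True)
        if np.any(table["in_OT"] & ~table["in_O"]):
            raise ValueError("OT genes must be a subset of O genes")
        self.table = table

    def __len__(self) -> int:
        return len(self.table)

    def mask(self, which: str) -> np.ndarray:
        if which == "all":
            return np.ones(len(self.table), dtype=bool)
        if which == "O":
            return self.table["in_O"].to_numpy(dtype=bool)
        if which == "OT":
            return self.table["in_OT"].to_numpy(dtype=bool)
        raise ValueError(f"unknown gene set {which!r}; expected one of {GENE_SETS}")


@dataclass
class ExpressionMatrix:
    """Normalized expression values tagged by transform and gene set."""

    values: np.ndarray
    normalization: str
    gene_set: str
    gene_ids: np.ndarray
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.gene_set not in GENE_SETS:
            raise ValueError(f"unknown gene set {self.gene_set!r}")
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]


@dataclass
class TissueReference:
    """Per-(tissue, gene) mean and standard deviation of CLR expression in a
    healthy reference cohort; used to standardize samples by tissue."""

    tissues: np.ndarray
    gene_ids: np.ndarray
    mean_clr: np.ndarray  # (n_tissues, n_genes)
    std_clr: np.ndarray  # (n_tissues, n_genes), floored at STD_FLOOR

    def index_of(self, tissue: str) -> int:
        hits = np.flatnonzero(self.tissues == tissue)
        if len(hits) == 0:
            raise KeyError(f"tissue {tissue!r} not present in the reference")
        return int(hits[0])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t_idx, tissue in enumerate(self.tissues):
            rows.append(
                pd.DataFrame(
                    {
                        "tissue": tissue,
                        "gene_id": self.gene_ids,
                        "mean_clr": self.mean_clr[t_idx],
                        "std_clr": self.std_clr[t_idx],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


@dataclass
class QCResult:
    """Outcome of the five-rule sample filter.

    ``criterion_matches`` are non-exclusive: a sample excluded by several
    rules is counted once per rule it matches but removed only once.
    """

    keep_mask: np.ndarray
    criterion_matches: dict[str, int]
    match_masks: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    @property
    def n_removed(self) -> int:
        return int((~self.keep_mask).sum())


QC_CRITERIA = (
    "cell_line",
    "single_cell_study",
    "tissue_not_in_reference",
    "duplicate_accession",
    "zero_fraction_O",
)


def qc_filter(
    data: CountMatrix,
    meta: SampleMetadata,
    annot: GeneAnnotation,
    reference_tissues: Iterable[str],
    zero_fraction_threshold: float = 0.30,
) -> QCResult:
    """Apply the five sample-exclusion rules and report non-exclusive counts.

    A sample is removed iff it matches at least one of:

    1. its reported cell type is a cell line;
    2. its study is a single-cell sequencing study;
    3. its reported tissue is absent from the reference tissue set (a missing
       tissue label counts as a match);
    4. its accession occurs more than once in the cohort;
    5. strictly more than ``zero_fraction_threshold`` of the GO-annotated (O)
       genes have a zero count.
    """
    meta = meta.aligned_to(data)
    t = meta.table
    reference_tissues = set(reference_tissues)

    cell_line = t["is_cell_line"].to_numpy(dtype=bool)

    single_cell_studies = set(t.loc[t["is_single_cell"].astype(bool), "study"])
    single_cell = t["study"].isin(single_cell_studies).to_numpy()

    tissue = t["tissue"]
    bad_tissue = (~tissue.isin(reference_tissues) | tissue.isna()).to_numpy()

    dup = t["accession"].duplicated(keep=False).to_numpy()

    o_mask = annot.mask("O")
    if not o_mask.any():
        raise ValueError("gene annotation defines an empty O set")
    zero_frac = (data.counts[:, o_mask] == 0).mean(axis=1)
    too_sparse = zero_frac > zero_fraction_threshold

    masks = dict(
        zip(QC_CRITERIA, (cell_line, single_cell, bad_tissue, dup, too_sparse))
    )
    remove = np.zeros(data.n_samples, dtype=bool)
    for m in masks.values():
        remove |= m
    return QCResult(
        keep_mask=~remove,
        criterion_matches={k: int(m.sum()) for k, m in masks.items()},
        match_masks=masks,
    )


def select_gene_set(
    data: ExpressionMatrix, annot: GeneAnnotation, which: str
) -> ExpressionMatrix:
    """Restrict an already-normalized matrix to a gene set by column subset.

    Normalization is *not* recomputed: the transform chain is defined on all
    genes, and subset values are taken verbatim from the all-gene matrix.
    """
    if len(annot) != data.n_genes:
        raise ValueError("annotation does not match the matrix gene dimension")
    mask = annot.mask(which)
    if not mask.any():
        raise ValueError(f"gene set {which!r} is empty")
    if which == "all":
        return ExpressionMatrix(
            data.values, data.normalization, "all", data.gene_ids, data.sample_ids
        )
    return ExpressionMatrix(
        values=data.values[:, mask],
        normalization=data.normalization,
        gene_set=which,
        gene_ids=data.gene_ids[mask],
        sample_ids=data.sample_ids,
    )


def to_tpm(data: CountMatrix, pseudocount: float | None = 0.5) -> ExpressionMatrix:
    """Transcripts-per-million: length-normalized counts scaled to sum 1e6.

    tpm_i = 1e6 * (counts_i / length_i) / sum_j (counts_j / length_j).

    When any count is zero, ``pseudocount`` is added to *all* raw counts
    before length normalization so that the downstream log transform stays
    finite; pass ``None`` to disable (zeros then propagate as zero TPM).
    """
    counts = data.counts.astype(float)
    zero_rows = ~counts.any(axis=1)
    if zero_rows.any():
        bad = data.sample_ids[zero_rows]
        raise ValueError(f"samples with all-zero counts: {list(bad[:5])}")
    if pseudocount is not None and (counts == 0).any():
        counts = counts + pseudocount
    rate = counts / data.gene_lengths[None, :]
    tpm = 1e6 * rate / rate.sum(axis=1, keepdims=True)
    return ExpressionMatrix(tpm, "tpm", "all", data.gene_ids, data.sample_ids)


def to_clr(data: ExpressionMatrix) -> ExpressionMatrix:
    """Centered log-ratio: clr_i = log(tpm_i) - mean_j log(tpm_j).

    Maps the compositional TPM vector to an unconstrained space where
    fold-changes are additive; rows sum to zero; invariant to per-sample
    rescaling of the input.
    """
    if data.normalization != "tpm":
        raise ValueError("CLR is defined on TPM input")
    if np.any(data.values < 0):
        raise ValueError("TPM values must be nonnegative")
    if np.any(data.values == 0):
        raise ValueError(
            "zero TPM values cannot be log-transformed; "
            "use to_tpm(..., pseudocount=...) upstream"
        )
    log = np.log(data.values)
    clr = log - log.mean(axis=1, keepdims=True)
    return ExpressionMatrix(clr, "clr", data.gene_set, data.gene_ids, data.sample_ids)


def build_tissue_reference(
    clr_data: ExpressionMatrix,
    meta: SampleMetadata,
    reference_mask: np.ndarray,
    std_floor: float = STD_FLOOR,
) -> TissueReference:
    """Per-tissue, per-gene mean/std of CLR over healthy reference samples.

    Uses the population standard deviation, floored at ``std_floor`` so that
    genes constant in the reference cannot produce infinite Z-scores.  Every
    tissue present among the reference samples needs at least two samples.
    """
    if clr_data.normalization != "clr":
        raise ValueError("tissue reference is built from CLR data")
    reference_mask = np.asarray(reference_mask, dtype=bool)
    tissues_all = meta.table["tissue"].to_numpy()
    ref_tissues = pd.unique(tissues_all[reference_mask])
    if len(ref_tissues) == 0:
        raise ValueError("reference mask selects no samples")
    means, stds = [], []
    for tissue in ref_tissues:
        sel = reference_mask & (tissues_all == tissue)
        if sel.sum() < 2:
            raise ValueError(
                f"tissue {tissue!r} has {int(sel.sum())} reference sample(s); need >= 2"
            )
        block = clr_data.values[sel]
        means.append(block.mean(axis=0))
        stds.append(np.maximum(block.std(axis=0), std_floor))
    return TissueReference(
        tissues=np.asarray(ref_tissues),
        gene_ids=clr_data.gene_ids,
        mean_clr=np.vstack(means),
        std_clr=np.vstack(stds),
    )


def to_zscore(
    clr_data: ExpressionMatrix, meta: SampleMetadata, ref: TissueReference
) -> ExpressionMatrix:
    """Tissue-referenced Z-score: (clr - tissue mean) / tissue std.

    Measures each gene's deviation from its normal expression in healthy
    tissue of the same type, putting samples from different tissues on a
    common "deviation from normal" scale.
    """
    if clr_data.normalization != "clr":
        raise ValueError("Z-score is defined on CLR input")
    if len(meta) != clr_data.n_samples:
        raise ValueError("metadata is not aligned to the expression matrix")
    tissue_idx = np.empty(clr_data.n_samples, dtype=int)
    for i, (sid, tissue) in enumerate(
        zip(clr_data.sample_ids, meta.table["tissue"].to_numpy())
    ):
        try:
            tissue_idx[i] = ref.index_of(tissue)
        except KeyError:
            raise KeyError(
                f"sample {sid!r} has tissue {tissue!r} absent from the reference"
            ) from None
    z = (clr_data.values - ref.mean_clr[tissue_idx]) / ref.std_clr[tissue_idx]
    return ExpressionMatrix(
        z, "zscore", clr_data.gene_set, clr_data.gene_ids, clr_data.sample_ids
    )


def to_zternary(
    z_data: ExpressionMatrix, threshold: float = ZTERNARY_THRESHOLD
) -> ExpressionMatrix:
    """Discretize Z-scores: below -threshold -> -1, above +threshold -> +1,
    inclusive band in between -> 0 (values exactly at the threshold map to 0)."""
    if z_data.normalization != "zscore":
        raise ValueError("Z-ternary is defined on Z-score input")
    tern = np.zeros_like(z_data.values)
    tern[z_data.values < -threshold] = -1.0
    tern[z_data.values > threshold] = 1.0
    return ExpressionMatrix(
        tern, "zternary", z_data.gene_set, z_data.gene_ids, z_data.sample_ids
    )
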