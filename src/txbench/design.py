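"""The reference benchmark task catalogue.

Fifty predictive tasks drive the benchmark bookkeeping: 18 TCGA binary tasks
(10 tumor-stage, 8 tumor-grade contrasts), 6 SRA clinical tasks (binary and
three-class), and 26 TCGA survival tasks (13 overall-survival, 13
progression-free-interval).  Each task carries its cohort size and its
allocation to the train / validate / test group.  These tables are
inputs to the plan enumeration and to the divided-task selection rule used by
semi-supervised training; the expression data behind them is not shipped.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["task_table", "count_tasks", "divided_task_ids", "DIVIDED_TASK_THRESHOLD"]

#: Minimum cohort size for a binary training task to be split in half for
#: within-task semi-supervised validation.
DIVIDED_TASK_THRESHOLD = 200

# (task_id, category, task_type, group, n_samples)
_TASKS = [
    # TCGA tumor stage (binary)
    ("COAD stage", "stage", "binary", "train", 505),
    ("KIRC stage", "stage", "binary", "train", 544),
    ("LIHC stage", "stage", "binary", "train", 374),
    ("LUAD stage", "stage", "binary", "train", 542),
    ("SKCM stage", "stage", "binary", "train", 249),
    ("STAD stage", "stage", "binary", "train", 416),
    ("THCA stage", "stage", "binary", "train", 513),
    ("UCEC stage", "stage", "binary", "train", 554),
    ("LUSC stage", "stage", "binary", "validate", 504),
    ("BRCA stage", "stage", "binary", "test", 1134),
    # TCGA tumor grade (binary)
    ("CESC grade", "grade", "binary", "train", 306),
    ("KIRC grade", "grade", "binary", "train", 544),
    ("LGG grade", "grade", "binary", "train", 532),
    ("LIHC grade", "grade", "binary", "train", 374),
    ("PAAD grade", "grade", "binary", "train", 179),
    ("STAD grade", "grade", "binary", "train", 416),
    ("UCEC grade", "grade", "binary", "train", 554),
    ("HNSC grade", "grade", "binary", "test", 504),
    # SRA clinical tasks
    ("GSE65832 atopic dermatitis", "sra", "binary", "train", 40),
    ("GSE66207 Crohn's disease", "sra", "multiclass", "train", 20),
    ("GSE72819 ulcerative colitis", "sra", "binary", "validate", 69),
    ("GSE47944 psoriasis", "sra", "multiclass", "validate", 63),
    ("GSE50244 diabetes", "sra", "multiclass", "validate", 76),
    ("GSE67785 psoriasis", "sra", "binary", "test", 28),
    # TCGA overall survival
    ("CESC OS", "os", "survival", "train", 304),
    ("COAD OS", "os", "survival", "train", 455),
    ("ESCA OS", "os", "survival", "train", 184),
    ("KIRP OS", "os", "survival", "train", 289),
    ("LUAD OS", "os", "survival", "train", 507),
    ("OV OS", "os", "survival", "train", 420),
    ("PAAD OS", "os", "survival", "train", 178),
    ("SARC OS", "os", "survival", "train", 259),
    ("STAD OS", "os", "survival", "train", 409),
    ("UCEC OS", "os", "survival", "train", 540),
    ("HNSC OS", "os", "survival", "validate", 501),
    ("BLCA OS", "os", "survival", "test", 407),
    ("LUSC OS", "os", "survival", "test", 495),
    # TCGA progression-free interval
    ("CESC PFI", "pfi", "survival", "train", 304),
    ("COAD PFI", "pfi", "survival", "train", 455),
    ("ESCA PFI", "pfi", "survival", "train", 184),
    ("KIRP PFI", "pfi", "survival", "train", 288),
    ("LUAD PFI", "pfi", "survival", "train", 507),
    ("OV PFI", "pfi", "survival", "train", 420),
    ("PAAD PFI", "pfi", "survival", "train", 178),
    ("SARC PFI", "pfi", "survival", "train", 259),
    ("STAD PFI", "pfi", "survival", "train", 411),
    ("UCEC PFI", "pfi", "survival", "train", 540),
    ("HNSC PFI", "pfi", "survival", "validate", 501),
    ("BLCA PFI", "pfi", "survival", "test", 408),
    ("LUSC PFI", "pfi", "survival", "test", 496),
]


def task_table() -> pd.DataFrame:
    """The 50-task catalogue as a DataFrame with columns
    task_id, category, task_type, group, n_samples."""
    return pd.DataFrame(
        _TASKS, columns=["task_id", "category", "task_type", "group", "n_samples"]
    )


def count_tasks(table: pd.DataFrame | None = None) -> dict[str, int]:
    """Benchmark bookkeeping: classification vs. survival task counts."""
    t = task_table() if table is None else table
    n_cls = int((t["task_type"].isin(["binary", "multiclass"])).sum())
    n_surv = int((t["task_type"] == "survival").sum())
    return {
        "classification": n_cls,
        "survival": n_surv,
        "total": n_cls + n_surv,
    }


def divided_task_ids(
    table: pd.DataFrame | None = None, threshold: int = DIVIDED_TASK_THRESHOLD
) -> list[str]:
    """Binary training-group tasks with at least ``threshold`` samples —
    the tasks whose cohorts are halved for semi-supervised training and
    within-task validation."""
    t = task_table() if table is None else table
    sel = (
        (t["task_type"] == "binary")
        & (t["group"] == "train")
        & (t["n_samples"] >= threshold)
    )
    return t.loc[sel, "task_id"].tolist()
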