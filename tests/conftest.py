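import numpy as np
import pytest

import txbench as tb


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale cohort with one planted binary, one multiclass, and one
    survival task; shared across tests that only read it."""
    cfg = tb.SimulationConfig(
        n_tissues=3,
        n_genes=300,
        genes_in_O=120,
        genes_in_OT=30,
        n_unlabeled=200,
        tasks=(
            tb.TaskBlueprint("bin", "binary", 200, 10, 2.0),
            tb.TaskBlueprint("multi", "multiclass", 150, 10, 2.0, n_classes=3),
            tb.TaskBlueprint("surv", "survival", 200, 10, 1.5),
        ),
        seed=42,
    )
    return tb.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_clr(small_dataset):
    return tb.to_clr(tb.to_tpm(small_dataset.counts))


@pytest.fixture(scope="session")
def task_features(small_dataset, small_clr):
    """CLR feature matrix aligned to each task's samples."""
    pos = {s: i for i, s in enumerate(small_dataset.counts.sample_ids)}

    def _get(task_id):
        task = next(t for t in small_dataset.tasks if t.task_id == task_id)
        rows = [pos[s] for s in task.sample_ids]
        return task, small_clr.values[rows]

    return _get
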