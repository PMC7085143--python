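"""Enumerate the full benchmark design and dry-run a desk-scale config.

A "result" is one (task, gene set, normalization, embedder, learner) cell;
each cell costs K(KN+1) nested-CV fits for a grid of N values.  The deep
autoencoders are only fitted on the reduced O/OT gene sets.
"""

import txbench as tb

plan = tb.reference_plan()
n_results, n_fits = tb.enumerate_plan(plan)
counts = tb.count_tasks()
print(f"tasks: {counts['classification']} classification + "
      f"{counts['survival']} survival = {counts['total']}")
print(f"full design: {n_results} results, {n_fits} individual model fits")
print(f"divided tasks (binary, train group, >= 200 samples): "
      f"{len(tb.divided_task_ids())}")

cfg = tb.RunConfig(
    simulation=tb.SimulationConfig(
        n_tissues=2, n_genes=200, genes_in_O=80, genes_in_OT=20, n_unlabeled=100,
        tasks=(
            tb.TaskBlueprint("bin", "binary", 80, 5, 2.0, signal_gene_set="OT"),
            tb.TaskBlueprint("surv", "survival", 80, 5, 1.5, signal_gene_set="OT"),
        ),
        seed=4,
    ),
    gene_sets=("OT",),
    normalizations=("clr", "zscore"),
    embedders=("identity", "pca"),
    latent_dim=8,
    seed=0,
)
summary = tb.dry_run(cfg)
print(f"\ndesk-scale dry run: {summary['n_results']} results, "
      f"{summary['n_model_fits']} fits over "
      f"{summary['n_representation_cells']} representation cells")
# dry_run enumerates without training; run_experiment executes the same plan
# and audits its actual fit counter against these numbers.
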