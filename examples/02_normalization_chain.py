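"""The fixed normalization chain: counts -> TPM -> CLR -> Z-score -> Z-ternary.

TPM estimates relative transcript concentration (rows sum to one million);
CLR maps the composition to an unconstrained space where fold-changes are
linear (rows sum to zero); the tissue Z-score standardizes each gene by its
healthy-reference distribution in the same tissue; Z-ternary discretizes
into down/normal/up-regulated at |Z| = 2.  Gene-set restriction happens
afterwards by plain column subsetting.
"""

import numpy as np

import txbench as tb

cfg = tb.SimulationConfig(
    n_tissues=3, n_genes=400, genes_in_O=150, genes_in_OT=40, n_unlabeled=300,
    seed=3,
)
dataset = tb.generate_dataset(cfg)

tpm = tb.to_tpm(dataset.counts)
print("TPM row sums (all 1e6):", np.unique(np.round(tpm.values.sum(axis=1), 3))[:3])

clr = tb.to_clr(tpm)
print("max |CLR row sum| (zero up to float error):", np.abs(clr.values.sum(axis=1)).max())

reference_mask = np.ones(dataset.counts.n_samples, dtype=bool)
ref = tb.build_tissue_reference(clr, dataset.metadata, reference_mask)
z = tb.to_zscore(clr, dataset.metadata, ref)
print("Z-score moments on the reference itself: mean %.2e, std %.4f"
      % (z.values.mean(), z.values.std()))

zt = tb.to_zternary(z)
frac = {int(v): float((zt.values == v).mean()) for v in (-1, 0, 1)}
print("Z-ternary composition:", frac)
# ~95% of healthy-reference values fall in the |Z| <= 2 "normal" band, as
# expected for approximately normal Z-scores.

o_only = tb.select_gene_set(clr, dataset.annotation, "O")
print("CLR restricted to O genes: %d columns; rows no longer sum to 0 "
      "(max |sum| = %.3f) because the transform is defined on all genes"
      % (o_only.n_genes, np.abs(o_only.values.sum(axis=1)).max()))
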