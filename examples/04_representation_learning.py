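"""Fit the three unsupervised embedders on an unlabeled expression pool.

Streaming PCA (Oja stochastic approximation) avoids the O(p^3) exact
eigendecomposition; the stacked denoising autoencoder (SDAE) learns a
nonlinear hourglass code with layerwise pretraining; the variational
autoencoder (VAE) learns a Gaussian latent with KL annealing.  All three
expose the same `encode` contract used by the supervised stages.
"""

import numpy as np

import txbench as tb

cfg = tb.SimulationConfig(
    n_tissues=4, n_genes=200, genes_in_O=80, genes_in_OT=20, n_unlabeled=400,
    seed=9,
)
dataset = tb.generate_dataset(cfg)
clr = tb.to_clr(tb.to_tpm(dataset.counts))
X = tb.select_gene_set(clr, dataset.annotation, "O").values  # deep nets: O/OT only
d = 16

spec = tb.TrainSpec(epochs=60, batch_size=32, learning_rate=0.05, seed=0)
pca = tb.fit_pca_stochastic(X, d, spec)
total_var = ((X - X.mean(0)) ** 2).sum(axis=0).sum() / len(X)
print(f"PCA: {d} components capture "
      f"{pca.explained_variance.sum() / total_var:.1%} of variance")

nn_spec = tb.TrainSpec(epochs=40, batch_size=32, learning_rate=0.01,
                       noise_variance=0.05, kl_anneal_epochs=20, seed=0)
sdae = tb.fit_sdae(X, d, nn_spec)
finetune = [e[2] for e in sdae.training_log if e[0] == "finetune"]
print(f"SDAE: reconstruction MSE {finetune[0]:.4f} -> {finetune[-1]:.4f} "
      f"(input variance {X.var():.4f})")

vae = tb.fit_vae(X, d, nn_spec)
log = vae.training_log
print(f"VAE: recon {log[0]['reconstruction']:.1f} -> {log[-1]['reconstruction']:.1f}, "
      f"KL {log[-1]['kl']:.2f} (weight ramped 0 -> 1 over {nn_spec.kl_anneal_epochs} epochs)")

for emb in (tb.identity_embedder(X.shape[1]), pca, sdae, vae):
    z = tb.encode(emb, X[:5])
    print(f"  {emb.kind:8s} encodes to dimension {z.shape[1]}")
# The identity control keeps the raw normalized features; the learned
# embedders compress to d dimensions for the downstream predictors.
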