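"""Train the semi-supervised shared embedding across divided tasks.

A linear autoencoder and per-task logistic heads share a latent space; the
predictor strength pi interpolates between pure reconstruction (pi=0) and
pure supervision (pi=1).  Binary training tasks with >= 200 samples are
halved: first halves train the model, second halves select the weight
penalties (lambda_AE, lambda_P) from the 16-pair sweep.
"""

import numpy as np

import txbench as tb
from txbench.semisupervised import SemiSupTrainSpec, heldout_error

rng = np.random.default_rng(0)
p = 30

# an unlabeled pool plus two separable "divided" tasks
X_pool = rng.normal(size=(400, p))
labeled, heldout = [], []
for j in range(2):
    y = rng.integers(2, size=260)
    y[:2] = [0, 1]
    X = rng.normal(size=(260, p))
    X[:, 3 * j : 3 * j + 3] += 2.0 * y[:, None]
    ids = np.array([f"T{j}_{i}" for i in range(260)])
    labeled.append(tb.LabeledBlock(f"task{j}", X[:130], y[:130], ids[:130]))
    heldout.append(tb.LabeledBlock(f"task{j}", X[130:], y[130:], ids[130:]))

spec = SemiSupTrainSpec(steps=400, latent_dim=8, learning_rate=5e-3, seed=0)
for pi in (0.0, 0.1, 1.0):
    model = tb.train_semisup(X_pool, labeled, pi, 0.001, 0.001, spec)
    last = model.training_log[-1]
    msg = f"pi={pi:3.1f}: recon {last['reconstruction']:8.2f}"
    if pi > 0:
        msg += (f"  class {last['classification']:.3f}"
                f"  held-out AUC {1 - heldout_error(model, heldout):.3f}")
    print(msg)

best, results = tb.sweep_lambdas(
    X_pool, labeled, heldout, 0.1, SemiSupTrainSpec(steps=60, latent_dim=8, seed=1)
)
print(f"lambda sweep over {len(results)} pairs; best (lambda_AE, lambda_P) = {best} "
      f"with held-out error {min(r['heldout_error'] for r in results):.3f}")
# pi=0 ignores the heads entirely (a plain autoencoder); pi=1 ignores
# reconstruction; the mixture shares the latent space between both goals.
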