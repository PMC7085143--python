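"""Unsupervised representation learners: streaming PCA, stacked denoising
autoencoder, variational autoencoder, and the no-embedding control.

All three learned embedders map a normalized expression vector to a
d-dimensional latent vector and are fitted on the unlabeled training pool,
then frozen before any supervised benchmarking.  PCA is fitted by Oja-style
stochastic approximation (periodically re-orthonormalized), which scales to
gene dimensions where the exact eigendecomposition is impractical.  The
autoencoders are "hourglass" networks with seven layers narrowing to the
latent dimension; the SDAE is trained layerwise and then fine-tuned
end-to-end to reconstruct clean input from Gaussian-corrupted input, and the
VAE uses self-normalizing (selu) hidden units with linear KL annealing over
the first epochs.  In the benchmark design the deep autoencoders are fitted
only on the reduced O/OT gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Activation, Dense, Sequential, minibatches
from .preprocess import ExpressionMatrix

__all__ = [
    "TrainSpec",
    "Embedder",
    "fit_pca_stochastic",
    "fit_sdae",
    "fit_vae",
    "identity_embedder",
    "encode",
]


@dataclass(frozen=True)
class TrainSpec:
    """Optimizer settings shared by the neural embedders.

    ``noise_variance`` is the variance of the additive Gaussian corruption
    used by the SDAE; ``kl_anneal_epochs`` is the horizon over which the
    VAE's KL weight ramps linearly from 0 to 1."""

    epochs: int = 40
    batch_size: int = 32
    learning_rate: float = 0.01
    momentum: float = 0.9
    noise_variance: float = 0.1
    weight_penalty: float = 0.0
    kl_anneal_epochs: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size) <= 0 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size, learning_rate must be positive")
        if self.kl_anneal_epochs > self.epochs:
            raise ValueError("kl_anneal_epochs must not exceed epochs")


@dataclass
class Embedder:
    """A fitted map from input_dim-dimensional expression to a latent vector."""

    kind: str  # identity | pca | sdae | vae
    input_dim: int
    latent_dim: int
    mean: np.ndarray | None = None
    components: np.ndarray | None = None  # pca: (d, p) orthonormal frame
    explained_variance: np.ndarray | None = None
    encoder: Sequential | None = field(default=None, repr=False)
    mu_head: Dense | None = field(default=None, repr=False)
    training_log: list = field(default_factory=list, repr=False)

    def encode(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.input_dim:
            raise ValueError(
                f"expected (*, {self.input_dim}) input, got {X.shape}"
            )
        if self.kind == "identity":
            return X
        if self.kind == "pca":
            return (X - self.mean) @ self.components.T
        h = self.encoder.forward(X)
        if self.kind == "vae":
            return self.mu_head.forward(h)
        return h


def identity_embedder(input_dim: int) -> Embedder:
    """The no-embedding control: features pass through unchanged."""
    return Embedder(kind="identity", input_dim=input_dim, latent_dim=input_dim)


def _values(data) -> np.ndarray:
    if isinstance(data, ExpressionMatrix):
        return data.values
    return np.asarray(data, dtype=float)


# ---------------------------------------------------------------------------
# Streaming PCA
# ---------------------------------------------------------------------------


def fit_pca_stochastic(
    data, d: int, spec: TrainSpec = TrainSpec(), reorth_every: int = 10
) -> Embedder:
    """Top-d principal subspace by Oja-style stochastic approximation.

    Minibatch updates ``Q += lr_t * X_b^T (X_b Q) / |b|`` on mean-centered
    data, with the Robbins-Monro step schedule ``lr_t = lr / (1 + epoch)``
    so the iterate averages out minibatch noise, and QR re-orthonormalization
    every ``reorth_every`` steps for numerical stability.  After the final
    pass the frame is rotated so components are ordered by explained
    variance (non-increasing) and ``encode(x) = frame @ (x - mean)``.
    """
    X = _values(data)
    n, p = X.shape
    if d > min(n, p):
        raise ValueError(f"d={d} exceeds min(n_samples, n_genes)={min(n, p)}")
    rng = np.random.default_rng(spec.seed)
    mean = X.mean(axis=0)
    Xc = X - mean

    Q, _ = np.linalg.qr(rng.normal(size=(p, d)))
    step = 0
    for epoch in range(spec.epochs):
        lr_t = spec.learning_rate / (1.0 + epoch)
        for idx in minibatches(n, spec.batch_size, rng):
            B = Xc[idx]
            Q += lr_t * (B.T @ (B @ Q)) / len(idx)
            step += 1
            if step % reorth_every == 0:
                Q, _ = np.linalg.qr(Q)
    Q, _ = np.linalg.qr(Q)

    # rotate within the learned subspace to variance-ordered components
    Z = Xc @ Q
    C = (Z.T @ Z) / n
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    Q = Q @ evecs[:, order]
    return Embedder(
        kind="pca",
        input_dim=p,
        latent_dim=d,
        mean=mean,
        components=Q.T,
        explained_variance=evals[order],
    )


# ---------------------------------------------------------------------------
# Stacked denoising autoencoder
# ---------------------------------------------------------------------------


def _hourglass_widths(p: int, d: int) -> list[int]:
    """Geometric taper p -> ceil(sqrt(p*d)) -> 2d -> d for the encoder."""
    h1 = max(int(np.ceil(np.sqrt(p * d))), 2 * d)
    return [p, h1, 2 * d, d]


def _mse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean((a - b) ** 2))


def _train_dae_pair(
    X: np.ndarray, enc: list, dec: list, spec: TrainSpec, rng, log: list, tag: str
) -> None:
    """SGD on mean squared reconstruction of clean X from corrupted X."""
    net = Sequential(enc + dec)
    sd = np.sqrt(spec.noise_variance)
    for epoch in range(spec.epochs):
        for idx in minibatches(len(X), spec.batch_size, rng):
            clean = X[idx]
            noisy = clean + rng.normal(0.0, sd, size=clean.shape) if sd > 0 else clean
            out = net.forward(noisy)
            g = 2.0 * (out - clean) / clean.size
            net.backward(g)
            net.step(spec.learning_rate, spec.momentum, spec.weight_penalty)
        loss = _mse(net.forward(X), X)
        if not np.isfinite(loss):
            raise FloatingPointError(f"{tag} diverged at epoch {epoch}; log={log[-5:]}")
        log.append((tag, epoch, loss))


def fit_sdae(data, d: int, spec: TrainSpec = TrainSpec()) -> Embedder:
    """Seven-layer hourglass denoising autoencoder with layerwise pretraining.

    Each encoder/decoder pair is first trained greedily as a shallow
    denoising autoencoder on the previous layer's codes; the stacked network
    is then fine-tuned end-to-end.  Fine-tuning is monitored on the training
    data and the best (lowest reconstruction error) parameters are kept, so
    the final loss never exceeds the pretraining-only loss.  ``encode`` is
    the deterministic forward pass to the d-dimensional middle layer.
    """
    X = _values(data)
    n, p = X.shape
    if n < spec.batch_size:
        raise ValueError("need at least one full batch of samples")
    rng = np.random.default_rng(spec.seed)
    widths = _hourglass_widths(p, d)
    log: list = []

    enc_layers, dec_layers = [], []
    codes = X
    for level in range(len(widths) - 1):
        enc = [Dense(widths[level], widths[level + 1], rng), Activation("tanh")]
        dec = [Dense(widths[level + 1], widths[level], rng), Activation("linear")]
        _train_dae_pair(codes, enc, dec, spec, rng, log, f"pretrain-{level}")
        enc_layers.extend(enc)
        dec_layers[:0] = dec  # decoder mirrors in reverse order
        codes = Sequential(enc).forward(codes)

    net = Sequential(enc_layers + dec_layers)
    best_loss = _mse(net.forward(X), X)
    log.append(("pretrained", -1, best_loss))
    best_state = net.state()
    sd = np.sqrt(spec.noise_variance)
    for epoch in range(spec.epochs):
        for idx in minibatches(n, spec.batch_size, rng):
            clean = X[idx]
            noisy = clean + rng.normal(0.0, sd, size=clean.shape) if sd > 0 else clean
            out = net.forward(noisy)
            net.backward(2.0 * (out - clean) / clean.size)
            net.step(spec.learning_rate, spec.momentum, spec.weight_penalty)
        loss = _mse(net.forward(X), X)
        if not np.isfinite(loss):
            raise FloatingPointError(f"fine-tuning diverged at epoch {epoch}; log={log[-5:]}")
        log.append(("finetune", epoch, loss))
        if loss < best_loss:
            best_loss, best_state = loss, net.state()
    net.load(best_state)
    encoder = Sequential(net.layers[: len(enc_layers)])
    return Embedder(
        kind="sdae", input_dim=p, latent_dim=d, encoder=encoder, training_log=log
    )


# ---------------------------------------------------------------------------
# Variational autoencoder
# ---------------------------------------------------------------------------


def kl_anneal_weight(epoch: int, horizon: int) -> float:
    """Linear KL ramp: 0 at epoch 0, 1 from ``horizon`` onwards."""
    if horizon <= 0:
        return 1.0
    return min(epoch / horizon, 1.0)


def fit_vae(data, d: int, spec: TrainSpec = TrainSpec()) -> Embedder:
    """Gaussian-latent VAE with selu hidden units and KL annealing.

    The latent parameterization is 2d-dimensional (d means + d log
    variances); ``encode`` returns the d means only.  The loss is the
    per-sample summed squared reconstruction error plus the annealed KL
    divergence of the latent posterior from the standard normal prior,
    jointly rescaled by the input dimension so gradient magnitudes (and
    hence usable learning rates) are width-independent.
    """
    X = _values(data)
    n, p = X.shape
    if n < spec.batch_size:
        raise ValueError("need at least one full batch of samples")
    rng = np.random.default_rng(spec.seed)
    widths = _hourglass_widths(p, d)

    trunk = Sequential(
        [
            Dense(widths[0], widths[1], rng),
            Activation("selu"),
            Dense(widths[1], widths[2], rng),
            Activation("selu"),
        ]
    )
    mu_head = Dense(widths[2], d, rng)
    lv_head = Dense(widths[2], d, rng)
    decoder = Sequential(
        [
            Dense(d, widths[2], rng),
            Activation("selu"),
            Dense(widths[2], widths[1], rng),
            Activation("selu"),
            Dense(widths[1], widths[0], rng),
            Activation("linear"),
        ]
    )

    log: list = []
    for epoch in range(spec.epochs):
        w = kl_anneal_weight(epoch, spec.kl_anneal_epochs)
        recon_sum = kl_sum = 0.0
        n_batches = 0
        for idx in minibatches(n, spec.batch_size, rng):
            x = X[idx]
            B = len(x)
            h = trunk.forward(x)
            mu = mu_head.forward(h)
            lv = np.clip(lv_head.forward(h), -10.0, 10.0)
            eps = rng.normal(size=mu.shape)
            z = mu + eps * np.exp(0.5 * lv)
            xhat = decoder.forward(z)

            recon = float(np.sum((xhat - x) ** 2) / B)
            kl = float(0.5 * np.sum(mu**2 + np.exp(lv) - 1.0 - lv) / B)
            if not np.isfinite(recon + kl):
                raise FloatingPointError(
                    f"VAE diverged at epoch {epoch}; log tail {log[-5:]}"
                )
            recon_sum += recon
            kl_sum += kl
            n_batches += 1

            scale = B * p  # width-independent gradient magnitudes
            dz = decoder.backward(2.0 * (xhat - x) / scale)
            dmu = dz + w * mu / scale
            dlv = dz * eps * 0.5 * np.exp(0.5 * lv) + w * 0.5 * (np.exp(lv) - 1.0) / scale
            g_h = mu_head.backward(dmu) + lv_head.backward(dlv)
            trunk.backward(g_h)
            for part in (trunk, decoder):
                part.step(spec.learning_rate, spec.momentum, spec.weight_penalty)
            for head in (mu_head, lv_head):
                head.step(spec.learning_rate, spec.momentum, spec.weight_penalty)
        log.append(
            {
                "epoch": epoch,
                "kl_weight": w,
                "reconstruction": recon_sum / n_batches,
                "kl": kl_sum / n_batches,
            }
        )
    return Embedder(
        kind="vae",
        input_dim=p,
        latent_dim=d,
        encoder=trunk,
        mu_head=mu_head,
        training_log=log,
    )


def encode(model: Embedder, data) -> np.ndarray:
    """Deterministic latent encoding of a matrix (identity kind: unchanged)."""
    return model.encode(_values(data))
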