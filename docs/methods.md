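# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limitations of `txbench`. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The benchmarking problem

Given gene-level read counts for a cohort, per-gene lengths, and per-sample
metadata, the package estimates how well a phenotype (binary or multiclass
label, or right-censored survival time) can be predicted out of sample, as a
function of four design axes: normalization, gene set, learned
representation, and supervised learner. One *result* is the nested-CV
performance of one (task, gene set, normalization, embedder, learner) cell.
The reference design — 24 classification and 26 survival tasks, gene sets
all/O/OT, normalizations TPM/CLR/Z-score/Z-ternary, identity and PCA
embedders on every gene set with SDAE/VAE restricted to O and OT, learners
LR/RF/kNN for classification and Cox for survival — comprises 3920 results
and 807,600 model fits (K(KN+1) per cell at K=5 with grids of 10/7/5/10).

## Normalization

All transforms are computed on the all-genes matrix; restricting to a gene
set afterwards copies columns verbatim (so CLR rows restricted to O genes
do not sum to zero — intentionally, since the log-ratio reference is the
full composition).

- **TPM** divides counts by gene length and scales each sample to 10^6,
  estimating relative molar transcript concentration.
- **CLR** is `log(tpm) − mean(log tpm)` per sample (natural log). Zeros are
  handled upstream: when any count is zero, a pseudocount (default 0.5,
  configurable, disabled with `pseudocount=None`) is added to all raw counts
  before TPM. This is a convention; the choice of pseudocount is not
  prescribed by the underlying formulas.
- **Z-score** standardizes each CLR value by the per-(tissue, gene) mean and
  *population* standard deviation over healthy reference samples. The
  reference std is floored at 1e-6 so genes constant in the reference cannot
  produce infinite scores. Population vs. sample std is another convention;
  at realistic reference sizes the difference is far below test tolerances.
- **Z-ternary** maps Z < −2 → −1, Z > 2 → +1, and the closed band
  [−2, 2] → 0. Values exactly at ±2 map to 0 (configurable threshold).

QC applies five rules to metadata flags and the count matrix directly
(cell line, single-cell study, tissue absent from the reference set —
including missing tissue labels —, duplicated accession, >30% zero counts
among O genes, strictly greater). Matches are reported non-exclusively;
removal is the union.

## Supervised models

**Logistic regression** is multinomial softmax trained by full-batch
gradient descent with heavy-ball momentum on mean cross-entropy plus
`λ‖W‖²` (intercept unpenalized). **Cox proportional hazards** minimizes the
negative Efron-corrected partial log-likelihood (exact gradient, reduced to
the standard partial likelihood when event times are unique) scaled by 1/n,
plus `λ‖β‖²`. Both use a *fixed* learning rate throughout a fit; the default
rate is the conservative bound 1/L, with L estimated by power iteration as
`curvature · σ²max(X)/n + 2λ` (curvature 1/4 for logistic, 1 for Cox), which
guarantees controlled descent on any task without per-task tuning. First-
order training is the point: with tens of thousands of genes a Newton-type
solver would need a p×p Hessian. Convergence is checked in the test suite by
agreement with second-order reference solvers (statsmodels Logit, lifelines
CoxPHFitter) to 1e-2 in the ∞-norm on small dense problems; iteration caps
(default 300, raised to 5·10^4 with tolerance 1e-10 in the oracle tests) and
the gradient-norm tolerance are configurable per fit.

Random forests (100 trees, depth grid 2…128) and kNN (k ∈ {1,3,5,7,9},
Euclidean) wrap scikit-learn. Single-gene comparators fit unregularized
univariate logistic/Cox models, with the gene index treated as the
hyperparameter searched by the inner CV loop; they are restricted to CLR
features.

Grids: penalties log-spaced over [1e-6, 1e3] in ten steps for LR and Cox.

## Nested cross-validation

Outer and inner loops both use K=5 stratified folds (by class, or by event
indicator for survival); stratification is an addition over plain random
folds, preventing degenerate single-class folds on small tasks, and can be
disabled by constructing folds manually. Inner means select the
hyperparameter per outer fold; ties break toward stronger regularization
(larger penalty, smaller depth, larger k) for a deterministic, conservative
choice. The engine counts its fits and raises if the count deviates from
K(KN+1); it also tracks sample indices so tests can assert that held-out
outer samples never appear in inner training, selection, or the refit.
Embedders are fitted once on the unlabeled pool and frozen before any
supervised stage, so the leak audit concerns the supervised stages only.

## Representation learners

- **Streaming PCA** uses Oja-style stochastic approximation: minibatch
  updates `Q += lr_t · Xᵀ(XQ)/|b|` on centered data with QR
  re-orthonormalization every 10 steps, and a Robbins–Monro step decay
  `lr_t = lr/(1+epoch)` so the iterate averages out minibatch noise (a
  constant step leaves a noise floor proportional to the rate). The frame is
  finally rotated to variance-ordered components. Tests compare captured
  variance against the exact eigensolver (within 2% relative) and recover
  exact low-dimensional subspaces to principal angles below 1e-2.
- **SDAE**: seven-layer hourglass `p → ⌈√(p·d)⌉ → 2d → d → …` (geometric
  taper, configurable; the reference architecture tables are not part of this
  implementation), tanh hidden units, additive Gaussian input corruption
  with variance from the training spec, layerwise greedy pretraining of each
  encoder/decoder pair followed by end-to-end fine-tuning. Fine-tuning keeps
  the best-so-far parameters on the training reconstruction error, so the
  final model is never worse than the pretrained stack.
- **VAE**: same trunk widths with selu (self-normalizing) activations,
  Gaussian latent with d means and d log-variances, linear KL annealing from
  0 to 1 over the first `kl_anneal_epochs` epochs. The objective is the
  per-sample summed squared reconstruction error plus annealed KL, jointly
  rescaled by the input dimension so usable learning rates do not depend on
  the gene-set width. `encode` returns the means only.
- The **identity** embedder passes features through unchanged and is the
  control against which learned representations are compared.

Defaults in tests use latent d = 8–32; the latent dimension is a parameter
(512 in the full-scale design) and every tested property is d-independent.
All networks are plain numpy with hand-written backprop and SGD+momentum; a
divergent loss (NaN/inf) raises with the training log attached.

## Semi-supervised model

A linear single-hidden-layer autoencoder (p → d → p) shares its latent code
with one binary logistic head per divided task. The loss is

    L = (1−π)/BR Σ R(x_m) + π/BC Σ C(x_n, l_n) + λ_AE ℓ2(AE) + λ_P Σ_j ℓ2(P_j)

with R the per-sample summed squared reconstruction error and C binary
cross-entropy. π=0 is a plain autoencoder (the heads receive no data
gradient and label batches are never drawn); π=1 drops reconstruction.
Labeled batches (size BC, default 64) are drawn uniformly from the union of
the first halves of all divided tasks and routed per-sample to the matching
head — the pooled-batch choice matches the single-BC form of the loss;
reconstruction batches (size BR, default 256) come from the whole training
pool. Divided tasks are the binary training-group tasks with at least 200
samples (14 in the reference catalogue), split in half stratified by class;
second halves are evaluation-only. The (λ_AE, λ_P) pair is chosen from the
16-pair grid {0, 0.1, 0.01, 0.001}² by minimizing 1 − mean held-out-half AUC
("average error" defined as AUC error; a misclassification-rate variant
would slot into the same hook). Head l2 decay is applied within the batches
that update a head.

## Evaluation

AUC (scikit-learn, midrank ties), accuracy, and Harrell's C (lifelines,
tied risks ½) — each cross-checked in tests against brute-force pair
enumeration. Cross-task aggregation subtracts the per-task median over all
configurations (the shifted statistic) and averages weighted by task sample
counts. Feature importance ranks genes per outer-fold model by
|coefficient| descending — magnitude, not signed value, on the view that
importance is strength of influence; a signed variant is a one-line change —
with ties broken by stable gene order, normalizes ranks by the gene count,
and averages over the K fold models. Multiclass models contribute the
maximum |coefficient| across classes per gene.

## Synthetic compendium

The generator is a stand-in: no generative description of the real
compendium exists, so all distributional choices here are package
conventions, documented and fixed.

Hierarchy: gene baseline log-expression ~ N(0, 1.5²); per-tissue offsets ~
N(0, 0.8²); per-sample deviations ~ N(0, 0.5²); softmax to a composition;
counts ~ Multinomial at a log-normal library size (mean 10^5, σ=0.5, floored
at 1000). The multinomial (rather than independent Poisson) preserves the
compositional structure that CLR assumes. Gene lengths are log-normal around
1.5 kb. O and OT flags mark nested prefixes of the gene list.

Planted classification signal: class c shifts the log-expression of the s
signal genes by `(c/(k−1)) · β · sign_g` *before* the softmax, which makes
the planted effect linear in CLR coordinates — the recommended model
(ℓ2-LR on CLR) is therefore well specified and recovery tests are
meaningful. Survival tasks draw exponential times with log-hazard `effect ·
clr(η)` from the latent (pre-count) CLR vector, and censor by an independent
uniform horizon whose upper bound is tuned by geometric bisection to the
requested censoring fraction (default 0.3).

Two design rules keep ground-truth recovery well-posed:

1. **Signal genes are drawn from the expressed half of their gene set.**
   Genes below the set's median baseline expression receive so few reads
   that their CLR coordinate is counting noise; an effect planted there is
   unobservable for *any* method.
2. **Signal genes form a co-regulated module** (`module_correlation`,
   default 0.9): a shared per-sample latent factor, aligned with the effect
   signs, carries most of their log-expression variance. Real disease
   signatures are coordinated pathways rather than isolated genes, and the
   choice is also what makes survival recovery statistically possible: with
   s independent signal genes, each gene's marginal association with a
   rank-based survival outcome is ~1/√s regardless of effect size, and at
   400 subjects × 2000 genes a ridge Cox fit (first- or second-order — both
   were checked) plateaus near chance. With the module structure the fitted
   C-index tracks the oracle closely.

QC violations are injected on top of a clean cohort so that *exactly* the
requested number of samples match each criterion (topping up over any
baseline matches; a request for a single duplicate-accession match on a
clean cohort is rejected, since duplicates come in groups of ≥ 2).

What the generator does not emulate: batch effects between studies, isoform
structure, single-cell dropout, gene–gene correlation outside the planted
module, and realistic metadata noise. Passing recovery tests therefore
demonstrates the correctness and statistical sanity of the pipeline, not
expected performance on real cohorts.

## Problem sizes and defaults

Tests and the acceptance script run at desk scale, chosen as the smallest
sizes at which the statistical properties under test are stable: recovery
tasks at 400 samples × 2000 genes with s=20, other suites at a few hundred
samples and genes, latent dimensions 8–32, and the first-order fitters at
their default 300-iteration cap inside nested CV (50k with tolerance 1e-10
in oracle-equivalence tests). The reference design's full scale (~37k
unlabeled samples, up to ~56k genes, d=512) is reachable through the same
configuration surfaces.

## Known limitations

- The deep embedders are CPU numpy implementations; full-scale (d=512,
  all-genes) training is out of reach for routine runs and untested.
- The SGD Cox model assumes proportional hazards and handles ties only via
  Efron (no Breslow option).
- `run_experiment` caches per-cell results keyed by a hash of the cell
  configuration and master seed; it does not hash the underlying data, so a
  cache directory must not be reused across changed simulation configs with
  an unchanged seed.
- Single-gene comparators search genes exhaustively; for gene sets much
  larger than the desk-scale defaults an inner-fold univariate screen would
  be needed to cap cost (not implemented).
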