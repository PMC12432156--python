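# Methods

## Data model and harmonization

Input is one delimited table per modality per split (`train/omics_*.csv`,
`test/omics_*.csv`; rows = features, header row = sample ids) plus a
sample metadata table `clin.csv` per split. Each split is restricted to
the intersection of sample ids present in every modality file and the
metadata; modalities not present in both splits are dropped with a
warning (or rejected, configurable).

Training-side processing, in order: per-feature **median imputation**,
dropping all-missing samples; a **variance filter** removing features
below a configurable quantile (default 0.01) of the per-feature variance
distribution (zero-variance features always removed) — a quantile rather
than an absolute cutoff so the rule is scale-free across modalities;
optional `log1p`; per-feature centering/scaling to mean 0, sd 1 using the
population sd (ddof 0). The order impute → filter is fixed. Test data is
only ever transformed with the train-fitted centers and scales and
restricted to the train-selected features; a selected feature missing from
the test file is a hard error rather than a zero-fill, because silent
zero-fill would corrupt downstream attribution rankings. Categorical
covariates are one-hot encoded with train-fitted level sets and enter the
model as an extra modality named `covariates` (exempt from feature
selection, since the user curated it). Classification labels are coded on
train only; test labels unseen in training are masked with a warning.
Survival labels are a `(time, event)` pair with a joint missingness mask.

## Feature selection

Laplacian score in the He-et-al. normalization: a kNN sample graph
(default k = 10, capped at n−1) with heat-kernel weights
`w_ij = exp(−‖x_i−x_j‖²/σ)`, bandwidth σ defaulting to the median squared
pairwise distance; for feature r with degree matrix D, Laplacian L and
weighted-mean-removed f̃, the score is `(f̃ᵀLf̃)/(f̃ᵀDf̃)`, lower =
better; constant features score +∞ and are never chosen. Selection keeps
the best `⌈top_fraction·p⌉` features (never fewer than `min_features`),
then greedily drops features whose absolute Pearson correlation with an
already-kept, better-scoring feature exceeds 0.8 (ties broken
lexicographically on feature id). Selection runs per modality on the
cleaned, scaled training matrix only. For graph-convolutional runs,
features are additionally restricted to the node set of the user-supplied
interaction edge list.

## Architectures and losses

All encoders are `input → ⌈hidden_dim_factor·input⌉ → latent_dim` MLPs
(ReLU default; tanh available via `mlp_activation` — the smooth variant
also serves numerical checks of the attribution path integral). Early
fusion concatenates modality matrices before one encoder; intermediate
fusion concatenates per-modality latents (embedding width = latent_dim ×
n_modalities). Supervisor heads are `embedding → supervisor_hidden_dim →
output` MLPs; the survival head emits an unbounded risk score (no output
nonlinearity), consistent with the partial-likelihood objective.

* **Cox loss**: negative Breslow partial log-likelihood, averaged over
  events, risk set `{j : t_j ≥ t_i}`. Breslow handles ties in the
  simplest consistent way; averaging (vs summing) only rescales the
  effective learning rate.
* **MMD**: biased V-statistic MMD² against fresh standard-normal prior
  draws, Gaussian kernel with bandwidth 2·latent_dim (scales with
  dimension), prior sample size = batch size; all configurable.
* **Triplet**: mean hinge `max(0, ‖a−p‖ − ‖a−n‖ + margin)`, margin 1.0;
  positives/negatives drawn within the batch keyed on the first
  classification target; single-class batches skip the term with a
  warning. A small epsilon inside the square root keeps the distance
  gradient finite for coincident embeddings.
* **Uncertainty weighting**: `Σ_t exp(−s_t)·L_t + s_t` with one trainable
  log-variance per task (auxiliary reconstruction/MMD/triplet terms count
  as tasks); disabled = plain sum. This parameterization is finite for
  any real `s_t`. Tasks with zero observed labels in a batch are excluded
  entirely, so no gradient flows to their heads or weights.

The VAE family uses one Gaussian encoder per modality (intermediate) or
one over the fused input (early); training draws a single
reparameterized sample, evaluation uses the mean. `supervised_vae`
decoders reconstruct their own input from their own latent;
`CrossModalPred` decoders read the *fused* latent and reconstruct the
declared output modalities, so with input = output = all modalities it
reduces to a supervised VAE whose decoders see the joint code. Heads read
the sampled latent during training.

The GNN builds, per sample, a graph whose nodes are the (early-fused)
features; the node's scalar value is embedded by a shared 1→d linear map
(d = node_embedding_dim), followed by 1–4 rounds of GraphConv
(`W₁x_i + W₂Σ_{j∈N(i)}x_j`), GCNConv (symmetric-normalized adjacency with
self-loops) or SAGEConv (mean aggregation), ReLU between rounds, then
mean pooling over nodes and a linear map to the latent. Mean (not sum)
pooling was fixed so the readout is invariant to feature count. Because
the value-embedding map is shared across nodes, feature identity enters
only through graph structure — a deliberate economy that keeps the
parameter count independent of p; per-node embeddings are the natural
extension if identity matters more than structure.

## Training, search and fine-tuning

Adam (default betas), minibatches of a power-of-two size from
{32, 64, 128}. The training split is 80/20 train/validation by default
(stratified on the first fully observed classification target when every
class permits), or k-fold. Early stopping monitors the uncertainty-
weighted total validation loss with patience 10 (default) and restores
the best-validation parameters. Non-finite losses abort with the
offending term named.

Hyperparameter search: 5 random points, then a Gaussian-process surrogate
(Matérn 5/2, fixed length scales 0.3 in the unit-cube encoding)
maximizing expected improvement over 256 random candidates per iteration.
lr is searched on log₁₀ scale; batch size and convolution type are
categorical. One fixed, seeded train/validation split serves the whole
search so trials are comparable. The trials log records every
(configuration, validation loss).

Fine-tuning for shifted test domains: a held-in fraction of test samples
is split 5-fold; a grid over learning rates {1e-4, 1e-3, 1e-2} × freezing
strategies {freeze_encoders, freeze_heads, freeze_none} is scored by
cross-validated loss with patience 3; the winner is retrained on the full
held-in slice and evaluated strictly on the untouched held-out remainder.

## Evaluation

Regression: MSE, R² (= 1 − SS_res/SS_tot), Pearson r. Classification:
balanced accuracy (mean per-class recall), prevalence-weighted F1, one-
vs-rest prevalence-weighted AUROC and AUPR, Cohen's kappa. Survival:
Harrell's C over comparable pairs (event i, any j with t_j > t_i), risk
ties scored 0.5, higher risk ⇒ earlier event. Baselines (random forest,
SVM, XGBoost; random survival forest for survival) are tuned by small
default grids under 5-fold CV on training data and scored on test with
the same metrics. Paired bootstrap comparison: 100 resamples of test
instances, identical indices for both models per replicate, percentile
95% CIs, paired t-test on per-replicate scores; replicates where a metric
is undefined (e.g. a single class drawn) are redrawn so the replicate
count stays exact.

## Attribution

Integrated Gradients with the composite trapezoid rule over `steps`
intervals (default 64): exact for linear models and accurate to
O(1/steps²) on smooth networks, which is what makes a 1e-3 completeness
check at 256 steps meaningful; one-sided Riemann sums are first-order and
cannot reach that tolerance at realistic output scales. The default
baseline is all-zeros in scaled feature space — i.e. the training mean of
every feature. Classification targets are attributed against the class
*logit* (not the softmax probability) to avoid saturation. GradientSHAP
averages `(x − b)·∇F` at uniformly interpolated, noise-perturbed points
with baselines drawn from a reference sample (defaults: 32 draws, noise
sd 0.1). Marker tables aggregate by the mean absolute attribution across
test samples, normalized so the best marker scores exactly 1.

## Batch alignment and clustering

rPCA-MNN: PCA fit per batch; each batch is centred by its own mean and
projected onto the other batch's components (own-mean centring is what
cancels constant batch offsets and makes anchors reliable); anchors are
pairs that are mutual k-nearest neighbours (k = 5) in *both* reciprocal
projections; every moving sample is corrected by a Gaussian-kernel
weighted average of anchor displacement vectors, weights measured to the
pair midpoint (so mirrored mismatched pairs cancel and identical batches
receive exactly zero correction), bandwidth = median sample-to-anchor
distance. The reference batch is never moved. Optimal transport uses
squared-Euclidean cost with the exact solver (assignment for uniform
equal-size batches, otherwise a linear program) up to 500 samples and
entropic Sinkhorn (reg 0.05 on the normalized cost) above; moving samples
map by barycentric projection of the plan.

Clustering evaluates a candidate grid (k = 2..10 for k-means; resolutions
{0.25, 0.5, 1, 2} for Louvain on a Jaccard-weighted 15-NN graph) and
keeps the silhouette maximizer; degenerate candidates are skipped.
Adjusted mutual information quantifies partition concordance.

## Synthetic data generator

All modalities read out a shared latent `Z ∈ R^{n×d}` of i.i.d. standard
normals: `X = ZWᵀ + ε` with i.i.d. N(0,1) loadings fixed by a seed shared
across splits and i.i.d. Gaussian noise — the simplest structure that
preserves the shared-latent assumption the fusion architectures exploit.
Outcomes are driven by the same latent: numeric `y = Zβ + ε` with
`‖β‖ = effect_size`; categorical labels are Gumbel-max draws from
`softmax((2·effect_size)²·ZB)`, calibrated against the Bayes classifier so
effect 0 gives uniform labels, effect 1 a moderate signal (Bayes accuracy
≈ 0.9 at d = 4, K = 3) and effect 2 a near-noiseless one (≈ 0.98);
survival times are exponential with rate `exp(Zγ)`, `‖γ‖ = effect_size`,
censored by an independent exponential whose rate is found by bisection
so the realized censoring fraction matches the request within a few
percent. Coefficients derive from one seed and noise from another, so
train and test share the latent-to-outcome map. Batch shift adds a
per-feature offset drawn around the requested magnitude (sd 10% of it)
and an optional scale, applied to the test split to emulate a shifted
target domain. Label missingness sets exactly `⌊fraction·n⌋` entries of a
column to NaN, matching the masked-loss contract. For clustering studies,
`generate_clustered_latent` places unit-variance Gaussian blobs at
`separation` times random *orthonormal* directions, so all centre pairs
are equidistant and difficulty is a single knob.

What the generator does not emulate: realistic omics marginals (counts,
beta values, zero inflation), copy-number segmentation, mutation
sparsity, or feature-feature correlation beyond the low-rank structure.
Passing tests therefore demonstrate that the machinery recovers planted
low-rank signal under Gaussian noise and distribution shift — not
performance on any real cohort.

## Problem sizes and numerical choices

The bundled experiments run at n = 300–400 training samples, 100–200
features per modality, latent dimension 16–32 and ≤ 150 epochs — sizes
chosen so every experiment completes in seconds on one CPU while leaving
the planted-signal recovery regimes clearly above their thresholds.
Fixed conventions: float64 throughout; Kaiming-uniform init seeded per
model; a fresh computation graph per step (no state across backward
passes); validation losses compared with a 1e-12 improvement margin;
k-means with 10 restarts; all randomness flows from explicit integer
seeds, and identical seeds reproduce splits, search trajectories and
metrics bit-for-bit.

## Known limitations

No GPU path and no minibatch parallelism — the engine is deliberately
small. Cox loss builds an events × samples risk-set matrix (fine at desk
scale, quadratic in batch size). The GNN's shared node embedding limits
its expressiveness on graphs with weak structure. Fine-tuning refits
uncertainty weights from zero rather than carrying them over. The exact
OT solver is O(n³ log n)-ish in practice and is switched to Sinkhorn
above 500 samples.
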