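# Methods

## The generative model

Each cell's raw UMI count vector **x** over the informative gene set G*
is modelled as negative binomial,

    x | l, b  ~  NB(mu, theta),
    mu    = s · softmax(Dec_mu(l, b)),      sum_j mu_j = s,
    theta = softplus(Dec_theta(l, b)) + 1e-4,

where `s = sum_{j in G*} x_j` is the cell's size factor and **b** its
one-hot batch membership (one block per batch level, e.g. donor and
dataset). Feeding `s` and `b` to the decoder keeps sequencing depth and
batch identity out of the embedding **l**, which is left to carry
biological variation. The NB dispersion is gene- and cell-dependent by
default (`theta_per_cell=True`); a gene-only dispersion vector is
available as a config switch. Zero inflation is deliberately not
modelled: for UMI counts the plain NB is sufficient and better
identified.

The latent variable decomposes as `l = z + H c` with `z ~ N(0, I_D)`
capturing continuous variation and a categorical head `c` (uniform prior
over K components) capturing discrete structure; the learnable matrix
`H` (D x K) holds mixture component means, so the effective prior on `l`
is a K-component Gaussian mixture with identity covariances. With
`n_components = 0` the categorical part is dropped and `l = z`. The
categorical head outputs a softmax simplex vector rather than a hard
sample; the soft relaxation keeps gradients exact under plain SGD.

## Posterior uncertainty

Encoding proceeds as: normalize counts to a fixed total of 1e4 over
*all* detected genes (so restriction to G* stays comparable across
datasets of different depth), optionally perturb with Poisson noise,
log1p, then a one-hidden-layer MLP with separate z and c heads. The
Poisson perturbation is the model's device for representing embedding
uncertainty: M independently perturbed encodings of the same cell are M
samples of its approximate posterior (default M = 50). Point estimates
skip the perturbation. Only the G*-restricted slice of the normalized
vector enters the encoder.

## Training

Three adversarial pairs regularize the encoder:

- `D_z` discriminates encoder z from prior draws N(0, I) and `D_c`
  discriminates encoder c from uniform one-hot draws (weight
  `lambda_prior`, default 0.001 for both, separately overridable);
- one multiclass batch discriminator per batch level predicts batch
  membership from `l` (weight `lambda_batch` per level).

Each SGD iteration has two steps: all discriminators update first, then
the encoder, decoder and H, both sides evaluated on the same Poisson
samples. The optimizer is RMSProp without momentum (lr 1e-3, minibatch
128, 500 epochs by default); per-epoch loss means are logged.

For the encoder-side batch term the package defaults to a
*confusion* objective — minimize the cross-entropy of the discriminator
output against the uniform distribution — instead of maximizing the
discriminator's own cross-entropy (the minimax form, available as
`batch_adversary="minimax"`). Both share the fixed point where the
per-batch embedding distributions coincide (the generalized
Jensen-Shannon divergence among them is minimized; see
`scquery.align` for the closed forms used as test oracles), but the
minimax form saturates once the discriminator is confident — at the
small epoch counts used here the encoder then receives vanishing
gradients and alignment never engages, which is why the non-saturating
form is the default. `lambda_batch` defaults to 0.5, calibrated for the
confusion form on the bundled simulation.

Networks are MLPs with leaky-ReLU hidden layers (alpha 0.1, hidden
width 128, depth 1 by default); the non-saturating activation keeps
gradients alive both for adversarial training and for gradient-based
gene attribution. The whole model is implemented on a small in-package
reverse-mode autodiff engine over numpy arrays (`scquery.nn`), which
also supplies the log-gamma arithmetic for the NB likelihood. Training
warns below 1000 cells and refuses below 50. All randomness flows from
`ModelConfig.seed`; a saved and reloaded model reproduces point-estimate
embeddings bit for bit.

## Gene selection

Informative genes are chosen by dispersion binning: log1p of the
normalized expression, per-gene dispersion = variance/mean, genes
grouped into `n_bins` (default 20) by mean expression —
equal-frequency bins by default, equal-width optional — and z-scored
within bins; genes above `dispersion_z_cutoff` (default 0.5) are kept.
Bins with fewer than two genes merge into the adjacent lower-mean bin so
z-scores stay defined. With multiple batches, selection runs per batch
and a gene is retained if selected in at least `min_batch_fraction`
(default 0.5, inclusive) of batches. When datasets are merged, the
selected set is the union of per-dataset selections intersected with the
genes detected in every dataset, and dataset origin becomes a new batch
level; an optional two-column gene map collapses names (e.g. orthologs)
into shared groups before merging.

## Querying

Cell-to-cell similarity is the normalized projection distance (NPD):
both cells' posterior samples are projected onto the line through their
point estimates; the projections are z-normalized twice, once by each
cell's own projected mean/sd; NPD is the average of the two 1-D
Wasserstein-1 distances between the normalized sample sets (for equal
sample counts, W1 is the mean absolute difference of order statistics).
Coincident point estimates define NPD = 0. The local z-normalization
makes the distance honest about each cell's embedding uncertainty:
distances shrink where posteriors are wide.

Querying first takes each model's k = 50 Euclidean nearest reference
cells (exhaustive search, ties broken by index), unions the candidates
across the ensemble, and computes per-model NPDs only for those.
Significance is empirical: per model, the NPD null is built from 10,000
random distinct reference-cell pairs, and a hit's p-value is
`(1 + #{null <= npd}) / (1 + n_pairs)` (never exactly 0). A hit counts
only if its p-value passes the cutoff (default 0.05) in *every* model
of the ensemble; the reported p-value is the maximum. Ensembles of four
independently seeded models are the default workflow; embeddings of
types absent from the reference are close to arbitrary, so requiring
consistency across models is what converts that arbitrariness into
rejections.

Predictions from significant hits: discrete labels by majority vote
(at least `min_hits = 2` significant hits, winning fraction strictly
above 0.5, otherwise ambiguous/rejected); continuous annotations (e.g.
lineage-probability vectors) as the unweighted mean, which preserves the
probability simplex.

## Online tuning

When the query set carries its own batch shift, a pretrained model is
fine-tuned on reference + query jointly: the decoder's first layer gains
a two-column reference/query indicator initialized to zero (so the
forward pass is unchanged at step 0) and a dedicated two-class
discriminator aligns the two sets in latent space. Two safeguards limit
over-alignment: the adversarial term applies only to cells currently in
a mutual-nearest-neighbour pair across the sets, recomputed within each
minibatch on current embeddings (`k_mnn = 10`), and all pre-existing
weights are anchored to their originals by a quadratic penalty applied
as an exact proximal step after each update, `w <- a + (w - a) /
(1 + lr·pen)`. The proximal form is used instead of a loss term because
RMSProp's gradient normalization would otherwise cancel the penalty's
scale; as `pen -> inf` the model is frozen exactly. Defaults
(`lambda_query_batch = 5`, `deviation_penalty = 1`, 100 epochs) were
calibrated on the bundled shift simulation.

## Gene attribution

For a target cell type, its cells are held out as queries against the
remaining cells; for each query cell and reference hit the unit latent
deviation is backpropagated through the encoder (including the log1p
input transform) to per-gene values, and these are averaged over hits,
cells and models. Scores are signed so that positive means "higher
expression pulls the embedding towards the target type". Significant
consensus hits are used when any exist; on data where the held-out type
is rejected outright (the specificity machinery working as intended) the
raw nearest neighbours are used instead, with a warning. Attribution
concentrates on a marker only when the marker actually carries the
type's discriminative signal; when hundreds of genes separate the types
redundantly, the encoder spreads its weights and no single gene
dominates — the bundled near-twin-subtype fixture reflects the regime
where single-marker recovery is well-posed.

## Ontology-aware inference

Given hits annotated with ontology terms, each term's confidence is the
sum of its hits' similarities (1 - p), normalized over all hits;
confidences propagate to ancestors along is_a edges (summing over
annotated *terms*, so diamond paths count once). Terms above the
confidence threshold (default 0.5) form the confident subgraph; its
induced leaves with longest-root-path depth >= `min_depth` (default 3)
are candidates; a unique maximal-confidence candidate is predicted, ties
are ambiguous, no candidate is rejected. Ties are compared with
tolerance 1e-12.

The ontology-aware accuracy scores a prediction 1 if it equals the true
term or a descendant of it; if an ancestor is predicted, partial credit
is the mean over reference-inferable intermediate terms c_k (true <=
c_k <= predicted, some reference term below c_k) of
|descendants(c_k)| / |descendants(predicted)| with inclusive descendant
sets; anything else scores 0, and for negative (out-of-reference) truth
only rejection scores 1. The term-balanced mean averages per-term
accuracies so abundant types do not dominate. OBO files are read with
obonet (Term stanzas, is_a edges, obsolete terms dropped); only is_a
relations are used.

## Evaluation metrics

- **MAP**: mean over cells of average precision of the cell's label in
  its Euclidean k-NN (self excluded, K = 1% of cells by default);
  with K = 1 it is nearest-neighbour accuracy. Chance level is slightly
  above the class fraction (average precision conditions on hit ranks).
- **Alignment score**: batches subsampled without replacement to the
  smallest batch size; with x̄ the mean same-batch count among k nearest
  neighbours, the score is `1 - (x̄ - k/N)/(k - k/N)` clipped to [0, 1].
- **MBA**: per-type accuracy against a binary expected-prediction matrix
  (rows actual types incl. negatives, columns predictions incl.
  "rejected"), averaged per type; positive- and negative-type MBAs are
  averaged with equal weight so the larger negative set cannot dominate.
- **JSD** between probability vectors, natural log, 0·log 0 = 0; bounded
  by log 2.
- **Enrichment ratio**, implemented exactly as the source formula prints
  it: (class fraction overall) / (class fraction among rejected). Note
  this is the *reciprocal* of the conventional enrichment-in-rejections
  direction — values below 1 mean the class is over-represented among
  rejections; `rejection_enrichment=True` returns the reciprocal.

## The simulation

`simulate_dataset` draws NB counts with mean
`library · softmax(baseline + cluster effect + batch effect + factor
term + noise)`: per-gene baseline N(0,1); per-cluster effects
N(0, sigma_cluster = 0.6) with `n_markers = 10` planted marker genes per
cluster up-regulated `marker_fold_change = 8`-fold (optionally
restricted to a baseline-expression quantile band, and optionally making
one cluster a near-twin of another via `twin_of`); per-batch per-gene
effects N(0, sigma_batch = 0.5); `n_factors = 2` shared continuous
factors with N(0, 0.3) loadings; per-cell per-gene noise N(0, 0.2);
log-normal library sizes (median 5000); fixed NB dispersion theta = 10.
Defaults: 2000 cells, 500 genes, 3 equal clusters, 2 batches.

The factor term matters: with purely independent per-gene noise,
independently seeded models embed within-cluster geometry as unrelated
random projections and ensemble consensus collapses even for types
present in the reference. Real tissues have shared low-dimensional
cell-state variation; the factors emulate it. What the simulation does
*not* emulate: gene-gene regulatory correlation beyond the factors,
trajectory/pseudotime geometry, doublets or ambient RNA, and real
protocol-specific noise — so passing tests demonstrate internal
correctness and recovery of planted structure, not performance on any
real tissue.

`simulate_fate_vectors` draws Dirichlet lineage probabilities with a
committed (low-entropy) and an undifferentiated (high-entropy)
subpopulation; `toy_ontology` is a fixed 15-term DAG with a diamond and
four depth levels for exercising the ontology code.

## Problem sizes and numerical choices

The bundled tests and examples run the full method at desk scale:
hundreds to 2000 cells, 150-500 genes, hidden width 32-64, 50-100
training epochs (400 for the marker-attribution study, which needs a
converged encoder), ensembles of up to four models, 2000-10,000 null
pairs. Degenerate inputs are explicit errors: all-zero cells cannot be
normalized, zero size factors cannot be decoded, zero projected
posterior variance has no defined NPD, zero latent deviation has no
gradient direction. k-NN ties break by reference index; all stochastic
steps take explicit seeds and the ensemble derives per-model streams
from each model's own seed, so duplicated models give identical
query-side samples.
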