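# Methods

`gatewaykit` detects *gateway cells* — rare cells positioned at the interface
between two annotated cell states — and the *bell/valley genes* whose
expression peaks or dips specifically at that interface.  This note documents
the model, its parameters, the synthetic study conditions, the numerical
choices, and the known limitations.

## Why plain embeddings miss boundary cells

Reconstruction-trained embeddings optimize an average over all cells, so the
gradient contribution of a population scales with its size.  Populations that
make up 0.05–1% of an atlas are structurally underweighted, and their local
neighborhoods are the first casualty: interface cells get absorbed into the
large stable states on either side.  Endpoint differential expression then
never sees them as a group.

## Binary mutual information (BMI) graph

Similarity is defined on gene *detection* rather than expression magnitude.
Counts are binarized at a threshold `tau` and, for a pair of cells *i*, *j*,

    BMI(i, j) = sum_{a,b in {0,1}} p_ij(a,b) log2 [ p_ij(a,b) / (p_i(a) p_j(b)) ]

where `p_ij(a,b)` is the empirical 2×2 joint detection frequency across
retained genes and `p_i`, `p_j` the marginals.  Plug-in frequencies, log base
2 (bits), no pseudocounts; `0·log 0 = 0`.  A cell that is all-ON or all-OFF
over the retained genes has a degenerate marginal: its BMI with any partner
is exactly zero, and such cells are listed in the graph diagnostics rather
than raised as errors.

Defaults (all configurable):

| parameter | default | meaning |
|---|---|---|
| `tau` | 1 | detection threshold (counts ≥ tau) |
| `min_freq`, `max_freq` | 0.01, 0.75 | inclusive detection-frequency band for retained genes |
| `n_perm` | 50 | column permutations for the null |
| `percentile` | 25 | pooled-null percentile used as the edge threshold |
| `k` | 32 | BMI neighbors kept per cell |
| `T` | 0.25 | softmax temperature of the attention weights |
| `alpha_mix` | 1.0 | blend of softmax (1.0) vs uniform (0.0) neighbor weights |

The null permutes every gene column independently across cells (preserving
per-gene detection frequencies, destroying cell–cell structure) and pools BMI
values across permutations into one empirical distribution; the threshold is
a single global scalar.  With fewer than 2,000 cells every pair enters the
null; above that, 200,000 sampled pairs per permutation keep the percentile
estimate stable at O(n) cost.  Top-k selection breaks ties at the k-th rank
toward the smaller cell index; symmetrization is by *union* (an edge survives
if either endpoint selected it), which preserves the connectivity of rare
cells — the purpose of the graph.  `alpha_mix` blends the softmax weights
with uniform neighbor weights; at the default 1.0 the weights are the pure
masked softmax, and non-neighbors carry exactly zero weight.

## scAttnVI: the regularized count VAE

The latent model is an NB (optionally ZINB) variational autoencoder in the
scVI family, trained directly on raw integer counts: the encoder maps
`log1p` counts to a diagonal-Gaussian posterior over a `n_latent = 10`
latent; the decoder maps `z` to softmax gene proportions scaled by each
cell's observed library size; dispersion is one free parameter per gene.
The training objective adds the BMI-weighted neighborhood penalty

    L = L_elbo + lambda_bmi * [ sum_{(i,j)} w_ij ||z_i - z_j||^2 / sum_{(i,j)} w_ij ]

over graph edges whose endpoints co-occur in the current minibatch (and
share the same experimental batch when one is annotated); the normalizing
denominator is the within-minibatch weight sum, so the penalty is a weighted
mean squared latent distance.  The weights `w_ij` are the static BMI-derived
attention coefficients — nothing is learned about them.

Implementation is pure NumPy with hand-written gradients (verified in the
test suite against central finite differences to 1e-5 relative error) and
Adam (lr 1e-3).  Design choices worth knowing:

- **Penalty target.** By default the penalty acts on the posterior means
  (lower gradient variance); `penalty_on="sample"` applies it to the
  reparameterized draw instead.  The penalty consumes no randomness, so a
  `lambda_bmi = 0` run is *step-for-step identical* to the unregularized
  baseline under the same seed — an invariant the tests assert exactly.
- **KL warmup** is linear over the first `kl_warmup_epochs` (default 20) to
  avoid early posterior collapse.
- **Early stopping** monitors the deterministic validation ELBO (posterior
  mean, 90/10 split) with the configured patience; the best-validation
  parameters are restored.
- **Batch covariate**, when provided, enters as a one-hot condition on the
  decoder, and the penalty is restricted to same-batch edges.
- Presets: `atlas-large` (hidden 256, 4 layers, batch 4,096, patience 30),
  `pbmc-small` (128/2/512, patience 45), `test-tiny` (32/1/256) for CI-scale
  work.

**Choosing `lambda_bmi`.**  The penalty is scale-sensitive: past a critical
weight it contracts the latent space globally (reconstruction rises, KL and
penalty collapse toward zero), which destroys the geometry instead of
preserving it.  The operating point is therefore selected by the
reconstruction-vs-penalty sweep on the rare-population thinning benchmark:
over `lambda ∈ {0.5, 1, 2, 8}` at 5% retention across three seeds,
`lambda = 0.5` preserved kNN retention and maximized cluster purity, while
`lambda ≥ 2` collapsed the embedding.  `LAMBDA_OPERATING_POINT = 0.5` is the
package default; the value is tied to this loss normalization (per-cell mean
reconstruction, weighted-mean penalty) and does not transfer to other
normalizations.

## Gateway scoring

With latent coordinates `z` and the atlas's own cell-state annotations:

1. **Fate pulls** (k = 30 by default): for each cell, the fraction of its k
   exact Euclidean nearest neighbors (self excluded; distance ties broken by
   cell index) carrying each annotation.  Rows sum to 1 in multiples of 1/k.
2. **Gateway score**: `min(pull_source, pull_target)` for a chosen boundary
   (pairwise mode, bounded by 0.5), or `min(pull_target, best other pull)`
   (target-vs-best-other mode) when any route into the target matters.
3. **PPR diffusion**: three iterations of
   `s ← (1 − alpha) s0 + alpha P s` with `alpha = 0.5`, where `P`
   row-normalizes a *separate* inverse-distance-weighted kNN graph (k = 30,
   zero distances capped).  The update is convex, so diffusion can never
   leave the range of the raw scores.
4. **Selection**: hard set at a diffused-score percentile (ties at the
   cutoff included).  Published-scale atlases use 99–99.95; on synthetic
   atlases the percentile is matched to the planted prevalence.  The *soft
   core* alternative keeps the top 5% of strictly-positive-score cells with
   score-proportional weights; a full-positive-zone variant keeps them all.
5. **Fate bias**: `pull_A − pull_B ∈ [−1, 1]` for lineage-gradient analyses.

## Bell/valley gene programs

Genes expressed in < 5% of the pooled gateway+flank cells or with
log1p-normalized variance < 0.01 are dropped.  All cells are scaled to the
pooled median library size and log1p-transformed (the model trains on raw
counts; this normalization exists only for effect-size reporting and is
configurable).  Per gene, two two-sided Mann–Whitney U tests (gateway vs
each flank; exact enumeration for tie-free samples of ≤ 50, normal
approximation with tie correction otherwise) are BH-corrected *within each
comparison*.  A gene is classified only if significant against both flanks
(q < 0.05) and its amplitude `A = (|LFC_S| + |LFC_T|)/2` reaches
`amp_tau = 0.25`; the sign pattern then assigns bell / valley / ascending /
descending.  An optional stricter gate additionally requires each individual
|LFC| ≥ `amp_tau` (off by default — the threshold is defined on A).
Cross-boundary sharing is summarized by Fisher's exact odds ratio over the
common tested universe, with a Haldane–Anscombe 0.5 correction (flagged)
when the raw odds ratio divides by zero.

## Control battery

- **Synthetic 50:50 mixtures**: mixture profiles average the log1p profiles
  of one random cell from each flank, matched in count to the gateway set;
  per-gene difference of means with a 95% bootstrap CI over resampling both
  groups (2,000 resamples by default).  Percentile intervals undercover at
  gateway-set sizes of a few dozen cells, so the implementation uses
  Hesterberg's expanded-percentile interval (t-adjusted tail quantiles).
  Note one subtlety the tests quantify: cells *drawn* from an interpolated
  mean program are not the same object as an *average of two cells'
  profiles* (log1p is concave), so even an effect-0 boundary carries a small
  genuine mixture-control signal on genes where the flanks differ; under the
  null study condition the flagged fraction sits near 8–9% rather than
  exactly 5%.
- **Matched controls**: per gateway cell, `ratio` controls (default 1:5)
  sampled without replacement within matching strata, with a recorded
  fallback to coarser strata on shortfall; balance reported as standardized
  mean differences (pooled-SD convention) before/after.  Outcomes are tested
  with a one-sided Wilcoxon signed-rank on gateway-minus-mean-of-controls
  differences plus a bootstrap CI of the median difference.
- **Hilltop overlap**: two exit-specific score vectors thresholded within a
  corridor; observed overlap against the exact hypergeometric matched-size
  null (mean |A||B|/N, upper-tail p) and a Monte-Carlo replication that
  literally redraws matched-size subsets (default 100,000 draws).
- **Gateway classifier**: regularized logistic regression on the log1p
  expression of the top 10 bell + top 10 valley genes, majority class
  undersampled, 5-fold stratified CV AUROC/AUPRC; transfer mode scores a
  second dataset without retraining.
- **Confound report**: two-sided Mann–Whitney per continuous QC metric,
  chi-squared for categorical phase composition, and curated-signature
  module scores (mean z-scored log1p over the genes present; packaged
  signature table shipped under `gatewaykit/data/signatures.tsv`).
- **Embedding metrics**: `knn_retention` (mean fraction of a target cell's k
  latent neighbors that are target; k capped at n_target − 1 and flagged
  when the target is smaller) and `purity`, defined here as the precision of
  the cluster containing the most target cells under a fixed clustering
  configuration (Leiden, RBConfiguration, resolution 1.0, k = 15 union kNN
  graph, fixed seed).  Purity has no single standard definition; this one is
  a deliberate, documented choice.

## Synthetic study conditions

The generator draws NB counts (`var = mu + mu^2/theta`, one theta per gene)
with per-cell log-normal library factors.  Population programs combine a
shared log-normal baseline, a transcriptome-wide per-population log-normal
perturbation (sigma 0.5 — real cell types differ broadly, and without this
no detection-pattern graph can wire rare cells together), and disjoint
marker blocks.  Boundary cells interpolate the two flank programs at weight
0.5 (or a per-cell gradient), then planted bell genes are multiplied by
`exp(+effect)` and valley genes by `exp(−effect)`; by default boundary cells
carry flank labels, the way annotation transfer would absorb them.  Planted
genes are chosen from expression bands where the effect is detectable
(bell: both flank means in [0.4, 3]; valley: both ≥ 1.5 so a dip has room).

Frozen conditions:

- **standard atlas**: 10,000 cells, 500 genes, 4 populations, 150 boundary
  cells (1.5%), 10 bell + 10 valley genes at log-effect 1.0;
- **null atlas**: 640 cells, 200 genes, effect-0 interpolation boundary;
- **thinning atlas**: 3,600 cells, 300 genes, 5 populations with a 600-cell
  rare target subsampled to 5% for the abundance-stress benchmark.

The benchmark model is a compact configuration (hidden 64, 1 layer, batch
512, 40 epochs) adequate for these problem sizes; it is the package's choice
of reference scale, and larger presets exist for real atlases.  What the
generator does **not** emulate: ambient RNA, doublets, batch effects beyond
a mean shift, within-population trajectories, or the zero-inflation excess
of some protocols — so passing tests certify the machinery and its
calibration, not performance on any particular real atlas.

## Numerical and degenerate-input conventions

- BMI computed in float32 matmuls, assembled in float64; tiny negative
  round-off clipped at 0; blocked fast path equals the literal per-pair
  formula to 1e-12.
- Empty gateway selections, empty soft cores, all-below-threshold graphs,
  isolated graph rows: warnings plus empty results, never exceptions.
- All-zero signed-rank differences: p = 1, flagged.
- Non-integer count matrices are rejected with guidance (models require raw
  counts); float-typed but integral MTX input is cast.
- One master seed per run; sub-streams are derived deterministically per
  stage, so any artifact is bit-reproducible from its manifest on the same
  platform.

## Limitations

- Flanking states come from existing annotations; the method refines the
  interval between credible states and cannot discover boundaries without
  labels.
- The score is agnostic to transit direction.
- Valley calls are less powered than bell calls near the expression floor.
- The NumPy trainer is single-threaded-BLAS friendly up to ~10^5 cells ×
  ~10^3 genes; it does not aim at GPU-scale atlases.
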