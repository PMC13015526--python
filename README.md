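# gatewaykit

Rare transition-state ("gateway") cell detection and transient gene-program
calling for single-cell RNA-seq atlases.

Single-cell atlases catalog stable cell states well, but the brief states a
cell passes through while *changing* fate are rare (typically 0.05–1% of an
atlas), and reconstruction-trained embeddings absorb them into the abundant
populations on either side.  `gatewaykit` is for computational biologists who
want to recover those interface cells between two annotated states and the
genes that peak (*bell*) or dip (*valley*) specifically there — signals that
endpoint differential expression misses by construction.

The pipeline:

1. **BMI graph.** Cell–cell similarity from *binary mutual information* of
   gene-detection patterns,
   `BMI(i,j) = Σ_{a,b} p_ij(a,b) log2[p_ij(a,b)/(p_i(a)p_j(b))]` (bits),
   filtered against a column-permutation null and sparsified to each cell's
   top k = 32 partners.  Detection-pattern similarity ignores expression
   magnitude, so rare cells stay tied to their true neighbors regardless of
   abundance or depth.
2. **scAttnVI.** A negative-binomial variational autoencoder (scVI-family
   ELBO, raw counts, library-size–scaled softmax decoder) whose loss adds
   `λ_BMI · Σ ŵ_ij‖z_i−z_j‖² / Σ ŵ_ij` over graph neighbors, with static
   masked-softmax attention weights `ŵ` derived from BMI.  At `λ_BMI = 0` it
   is exactly the plain baseline.  Implemented natively in NumPy with
   hand-written, finite-difference-verified gradients.
3. **Gateway score.** Per-cell *fate pulls* = kNN label fractions in latent
   space; gateway score = `min(pull_source, pull_target)`; denoised by
   personalized PageRank `s ← (1−α)s₀ + αPs` (α = 0.5, 3 iterations) and
   thresholded at a percentile (hard set) or kept as a score-weighted soft
   core.
4. **Gene programs.** Dual-flank Mann–Whitney tests with BH correction and an
   amplitude gate `A = (|LFC_S|+|LFC_T|)/2 ≥ 0.25` classify genes as
   ascending / descending / bell / valley.
5. **Controls.** Synthetic 50:50 mixture controls, stratified matched
   controls with SMD balance, hilltop-overlap hypergeometric nulls,
   expression-only classifiers, confound reports, and rare-population
   benchmark metrics.

A synthetic-atlas generator with planted ground truth (populations, rare
boundary cells, bell/valley genes, thinning harness) makes every stage
testable without downloads.

## Worked example

`examples/` holds one short script per capability.  Generating the standard
planted atlas (10,000 cells, 500 genes, a 150-cell boundary population
carrying 10 bell + 10 valley genes at log-effect 1.0) and running the full
pipeline (`examples/04_gateway_scoring.py`, `examples/05_gene_programs.py`)
prints:

```
boundary: progenitor -> committed
hard gateway set: 150 cells (planted boundary: 150)
precision 1.000, recall 1.000 against planted boundary cells
diffused score: median 0.000, 99.9th pct 0.473 (skewed: most cells ~0, thin high tail)
```

so the min-pull + diffusion score isolated exactly the planted interface
cells among 10,000, and:

```
class
none          395
ascending      45
descending     39
bell           10
valley         10

top bell genes (amplitude = mean |LFC| vs the two flanks):
 * gene_337   A=0.70 lfc_src=+0.91 lfc_tgt=+0.48 q=(2.6e-41, 3.8e-14)
 * gene_217   A=0.67 lfc_src=+0.85 lfc_tgt=+0.50 q=(1.5e-51, 2.7e-17)
 ...
planted bell recovered: 100%, valley recovered: 100%
```

where `*` marks planted genes: every called bell/valley gene is a planted
one, and the ascending/descending classes capture the monotone flank-to-flank
differences, as they should for interpolated boundary cells.  The thinning
benchmark (`examples/03_train_embedding.py`) shows what the BMI penalty buys
when the rare population is cut to 5% (30 cells among 3,030):

```
scAttnVI (lambda=0.5)  recon   446.2  kl  7.48  penalty  1.596  kNN retention 0.725  purity 1.000
baseline NB-VAE        recon   445.9  kl  7.80  penalty  0.000  kNN retention 0.679  purity 1.000
```

A thin CLI wraps the same library for shell use:

```bash
gatewaykit simulate --preset standard --seed 1 --out atlas/
gatewaykit run --data atlas/ --source progenitor --target committed \
    --preset test-tiny --percentile 98.5 --out results/
```

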