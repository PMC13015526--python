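"""Score gateway cells at a fate boundary and check them against the truth.

Fate pulls are kNN label fractions in the latent space (k=30); the gateway
score is min(pull_source, pull_target); scores are denoised by personalized
PageRank (alpha=0.5, 3 iterations) and thresholded at the percentile matched
to the planted boundary prevalence.
"""

import numpy as np

from gatewaykit.benchmarks import run_standard_pipeline

res = run_standard_pipeline(seed=1)
truth = res["truth"]
hard = res["hard_set"]

print(f"boundary: {truth.source} -> {truth.target}")
print(f"hard gateway set: {hard.size} cells "
      f"(planted boundary: {truth.boundary_cells.size})")
print(f"precision {res['precision']:.3f}, recall {res['recall']:.3f} "
      "against planted boundary cells")

d = res["diffused"]
print(f"diffused score: median {np.median(d):.3f}, "
      f"99.9th pct {np.percentile(d, 99.9):.3f} "
      "(skewed: most cells ~0, thin high tail)")
# A precision and recall near 1 mean the min-pull + diffusion score found
# exactly the planted interface cells among 10,000.
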