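"""Generate a synthetic atlas with a planted rare boundary population.

The standard atlas holds 10,000 cells in four stable populations plus 150
boundary cells (1.5%) whose mean program interpolates the two flanking
populations, with 10 bell genes multiplied by e and 10 valley genes divided
by e.  Every downstream stage can be scored against this ground truth.
"""

import numpy as np

from gatewaykit.synthetic import generate_atlas, standard_atlas_spec, truth_table

spec = standard_atlas_spec(seed=1)
ds = generate_atlas(spec)
truth = truth_table(ds)

labels, counts = np.unique(np.asarray(ds.cell_labels), return_counts=True)
print(f"atlas: {ds.n_cells} cells x {ds.n_genes} genes")
for l, c in zip(labels, counts):
    print(f"  {l:<12} {c:>6} cells")
print(f"planted boundary: {truth.boundary_cells.size} cells between "
      f"{truth.source} and {truth.target}")
print(f"planted bell genes:   {truth.bell_genes.tolist()} (log-effect "
      f"{truth.bell_effect})")
print(f"planted valley genes: {truth.valley_genes.tolist()}")
print(f"median library size: {np.median(ds.library_size):.0f} UMIs")
# The boundary cells carry flank labels (the way annotation transfer would
# absorb them), so only their expression betrays them -- that is what the
# gateway score has to find.
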