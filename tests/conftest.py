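import numpy as np
import pytest

from gatewaykit.synthetic import (
    AtlasSpec,
    Boundary,
    Population,
    generate_atlas,
    random_programs,
)


def small_spec(seed=0, n_genes=120, sizes=(250, 250), boundary_cells=40,
               bell=None, valley=None, effect=1.0, label_mode="flank"):
    rng = np.random.default_rng(seed + 999)
    progs = random_programs(len(sizes), n_genes, rng, n_markers=12)
    labels = [f"pop{i}" for i in range(len(sizes))]
    b = None
    if boundary_cells:
        b = Boundary(
            source="pop0",
            target="pop1",
            n_cells=boundary_cells,
            bell_genes=np.asarray(bell if bell is not None else [], dtype=int),
            valley_genes=np.asarray(valley if valley is not None else [], dtype=int),
            bell_effect=effect,
            valley_effect=effect,
            label_mode=label_mode,
        )
    return AtlasSpec(
        n_genes=n_genes,
        populations=tuple(Population(l, n, p) for l, n, p in zip(labels, sizes, progs)),
        boundary=b,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_atlas():
    """250+250 cells with a 40-cell interpolation boundary (no planted effect)."""
    return generate_atlas(small_spec(seed=3, boundary_cells=40, effect=0.0))


@pytest.fixture(scope="session")
def planted_atlas():
    """Small atlas with strongly planted bell/valley genes for recovery tests."""
    rng = np.random.default_rng(5 + 999)
    progs = random_programs(2, 150, rng, n_markers=12)
    lo = np.minimum(progs[0], progs[1])
    hi = np.maximum(progs[0], progs[1])
    bell = np.flatnonzero((lo >= 0.4) & (hi <= 3.0))[:3]
    valley = np.setdiff1d(np.flatnonzero(lo >= 1.5), bell)[:3]
    spec = small_spec(seed=5, n_genes=150, sizes=(400, 400), boundary_cells=60,
                      bell=bell, valley=valley, effect=1.2)
    return generate_atlas(spec)
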