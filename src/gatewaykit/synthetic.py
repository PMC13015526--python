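"""Synthetic single-cell atlases with known ground truth.

Generates negative-binomial UMI count matrices containing a handful of stable
populations of skewed abundances plus, optionally, a rare "boundary"
population sitting between two flanking populations.  Boundary cells draw
their mean expression program as a convex interpolation of the two flank
programs; a chosen set of *bell* genes is then multiplied by ``exp(+effect)``
and a set of *valley* genes by ``exp(-effect)``, so that every downstream
stage (graph, embedding, gateway scoring, gene-program calling, controls) can
be tested against a planted truth.

The negative binomial is parameterized by mean and inverse dispersion
(``var = mu + mu**2 / theta``), one ``theta`` per gene, matching the
likelihood of the variational model in :mod:`gatewaykit.vae`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Population",
    "Boundary",
    "AtlasSpec",
    "AtlasTruth",
    "CountDataset",
    "generate_atlas",
    "thin_population",
    "truth_table",
    "random_programs",
    "standard_atlas_spec",
    "null_atlas_spec",
    "thinning_atlas_spec",
]


@dataclass(frozen=True)
class Population:
    """A stable cell population: label, size and per-gene mean program.

    ``program`` holds expected counts per gene for a cell of unit size
    factor; actual cell means are ``size_factor * program``.
    """

    label: str
    n_cells: int
    program: np.ndarray


@dataclass(frozen=True)
class Boundary:
    """A rare interface population between ``source`` and ``target``.

    Mean program is ``(1 - w) * source + w * target`` with
    ``w = interpolation_weight``; planted bell genes are multiplied by
    ``exp(+bell_effect)`` and valley genes by ``exp(-valley_effect)``.

    ``label_mode`` controls annotation of boundary cells: ``"flank"``
    (default) assigns each boundary cell the source or target label, the way
    an annotation transfer would absorb interface cells into the nearest
    stable state; ``"own"`` gives them a dedicated label.  With
    ``gradient=True`` each boundary cell gets its own interpolation weight
    drawn uniformly on [0, 1] (for fate-bias tests) instead of the shared
    ``interpolation_weight``.
    """

    source: str
    target: str
    n_cells: int
    bell_genes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    valley_genes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    bell_effect: float = 1.0
    valley_effect: float = 1.0
    interpolation_weight: float = 0.5
    label_mode: str = "flank"
    gradient: bool = False


@dataclass(frozen=True)
class AtlasSpec:
    """Full recipe for one synthetic atlas; reproducible from ``seed``."""

    n_genes: int
    populations: tuple[Population, ...]
    boundary: Boundary | None = None
    dispersion: np.ndarray | float = 2.0
    library_mu: float = 0.0
    library_sigma: float = 0.35
    library_shift: dict[str, float] | None = None  # per-population log-depth shift
    n_batches: int = 0
    batch_shift_sigma: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not self.populations:
            raise ValueError("at least one population required")
        labels = [p.label for p in self.populations]
        if len(set(labels)) != len(labels):
            raise ValueError("population labels must be unique")
        for p in self.populations:
            if p.n_cells < 1:
                raise ValueError(f"population {p.label!r} has zero cells")
            if len(p.program) != self.n_genes:
                raise ValueError(f"program length mismatch for {p.label!r}")
            if np.any(p.program < 0) or not np.all(np.isfinite(p.program)):
                raise ValueError(f"program for {p.label!r} must be finite and >= 0")
        b = self.boundary
        if b is not None:
            if b.source not in labels or b.target not in labels:
                raise ValueError("boundary flanks must name existing populations")
            if b.n_cells < 1:
                raise ValueError("boundary population has zero cells")
            if not 0.0 <= b.interpolation_weight <= 1.0:
                raise ValueError("interpolation_weight must lie in [0, 1]")
            if np.intersect1d(b.bell_genes, b.valley_genes).size:
                raise ValueError("planted bell and valley gene sets overlap")
            if not (np.isfinite(b.bell_effect) and np.isfinite(b.valley_effect)):
                raise ValueError("planted effects must be finite")
            for g in (b.bell_genes, b.valley_genes):
                if len(g) and (g.min() < 0 or g.max() >= self.n_genes):
                    raise ValueError("planted gene indices out of range")
        if b is not None and b.label_mode not in ("flank", "own"):
            raise ValueError("label_mode must be 'flank' or 'own'")


@dataclass
class AtlasTruth:
    """Planted ground truth carried alongside a generated dataset."""

    boundary_cells: np.ndarray
    bell_genes: np.ndarray
    valley_genes: np.ndarray
    bell_effect: float
    valley_effect: float
    source: str | None
    target: str | None
    interpolation: np.ndarray  # per-boundary-cell interpolation weight
    spec: AtlasSpec | None = None


@dataclass
class CountDataset:
    """Cells x genes integer UMI counts plus per-cell annotations."""

    counts: np.ndarray
    cell_labels: pd.Categorical
    gene_names: list[str]
    batch: pd.Categorical | None = None
    day: np.ndarray | None = None
    truth: AtlasTruth | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.issubdtype(self.counts.dtype, np.floating):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be non-negative integers")
            self.counts = np.round(self.counts).astype(np.int64)
        if self.counts.min(initial=0) < 0:
            raise ValueError("counts must be non-negative")
        if len(self.cell_labels) != self.n_cells:
            raise ValueError("cell_labels length must equal n_cells")
        if len(self.gene_names) != self.n_genes:
            raise ValueError("gene_names length must equal n_genes")
        if len(set(self.gene_names)) != self.n_genes:
            raise ValueError("gene_names must be unique")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def library_size(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def to_anndata(self):
        import anndata

        obs = pd.DataFrame({"cell_type": pd.Series(self.cell_labels)})
        obs.index = [f"cell_{i}" for i in range(self.n_cells)]
        if self.batch is not None:
            obs["batch"] = pd.Series(self.batch).values
        if self.day is not None:
            obs["day"] = self.day
        import scipy.sparse as sp

        adata = anndata.AnnData(
            X=sp.csr_matrix(self.counts), obs=obs, var=pd.DataFrame(index=self.gene_names)
        )
        return adata


def random_programs(
    n_populations: int,
    n_genes: int,
    rng: np.random.Generator,
    base_log_mean: float = np.log(0.8),
    base_log_sigma: float = 1.0,
    n_markers: int = 40,
    marker_log_effect: float = 1.5,
    pop_log_sigma: float = 0.5,
) -> list[np.ndarray]:
    """Draw per-population mean programs sharing a common baseline.

    Real cell types differ transcriptome-wide, not only at a handful of
    markers, so each population combines (i) a genome-wide log-normal
    perturbation of the shared baseline (``pop_log_sigma``) with (ii) a
    disjoint block of ``n_markers`` marker genes upregulated by
    ``exp(marker_log_effect)``.
    """
    base = np.exp(rng.normal(base_log_mean, base_log_sigma, size=n_genes))
    base = np.clip(base, 0.02, 25.0)
    order = rng.permutation(n_genes)
    programs = []
    for k in range(n_populations):
        prog = base * np.exp(rng.normal(0.0, pop_log_sigma, size=n_genes))
        block = order[k * n_markers : (k + 1) * n_markers]
        prog[block] *= np.exp(marker_log_effect)
        programs.append(np.clip(prog, 0.01, 40.0))
    return programs


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Gamma-Poisson draw of NB(mean, theta); var = mu + mu^2/theta."""
    mean = np.maximum(mean, 1e-12)
    lam = rng.gamma(shape=theta, scale=mean / theta)
    return rng.poisson(lam)


def generate_atlas(spec: AtlasSpec) -> CountDataset:
    """Sample a :class:`CountDataset` from ``spec``; byte-reproducible from the seed."""
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_lib, rng_counts, rng_labels, rng_batch = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    theta = np.broadcast_to(np.asarray(spec.dispersion, dtype=float), (spec.n_genes,)).copy()
    if np.any(theta <= 0):
        raise ValueError("dispersion must be positive")

    prog_by_label = {p.label: p.program for p in spec.populations}
    rows_mean: list[np.ndarray] = []
    labels: list[str] = []

    for p in spec.populations:
        shift = 0.0 if not spec.library_shift else spec.library_shift.get(p.label, 0.0)
        sf = np.exp(rng_lib.normal(spec.library_mu + shift, spec.library_sigma, p.n_cells))
        rows_mean.append(sf[:, None] * p.program[None, :])
        labels.extend([p.label] * p.n_cells)

    truth = None
    b = spec.boundary
    if b is not None:
        if b.gradient:
            w = rng_labels.uniform(0.0, 1.0, b.n_cells)
        else:
            w = np.full(b.n_cells, b.interpolation_weight)
        prog = (1.0 - w)[:, None] * prog_by_label[b.source][None, :] + w[:, None] * (
            prog_by_label[b.target][None, :]
        )
        if len(b.bell_genes):
            prog[:, b.bell_genes] *= np.exp(b.bell_effect)
        if len(b.valley_genes):
            prog[:, b.valley_genes] *= np.exp(-b.valley_effect)
        sf = np.exp(rng_lib.normal(spec.library_mu, spec.library_sigma, b.n_cells))
        start = len(labels)
        rows_mean.append(sf[:, None] * prog)
        if b.label_mode == "own":
            blab = [f"{b.source}->{b.target}"] * b.n_cells
        else:
            pick_target = np.where(
                w == 0.5, rng_labels.random(b.n_cells) < 0.5, w > 0.5
            )
            blab = [b.target if t else b.source for t in pick_target]
        labels.extend(blab)
        truth = AtlasTruth(
            boundary_cells=np.arange(start, start + b.n_cells),
            bell_genes=np.asarray(b.bell_genes, dtype=int),
            valley_genes=np.asarray(b.valley_genes, dtype=int),
            bell_effect=b.bell_effect,
            valley_effect=b.valley_effect,
            source=b.source,
            target=b.target,
            interpolation=w,
            spec=spec,
        )

    mean = np.vstack(rows_mean)
    batch = None
    if spec.n_batches > 1:
        assign = rng_batch.integers(0, spec.n_batches, mean.shape[0])
        shifts = rng_batch.normal(0.0, spec.batch_shift_sigma, (spec.n_batches, spec.n_genes))
        mean = mean * np.exp(shifts[assign])
        batch = pd.Categorical([f"batch{j}" for j in assign])

    counts = _nb_sample(rng_counts, mean, theta[None, :])
    gene_names = [f"gene_{g}" for g in range(spec.n_genes)]
    return CountDataset(
        counts=counts,
        cell_labels=pd.Categorical(labels),
        gene_names=gene_names,
        batch=batch,
        truth=truth,
    )


def thin_population(
    ds: CountDataset, label: str, retention: float, seed: int
) -> CountDataset:
    """Uniformly subsample cells of ``label`` to ``round(retention * n_label)``.

    All other cells are untouched and keep their original relative order.
    Planted truth (boundary cell ids) is remapped to surviving cells.
    """
    if not 0.0 < retention <= 1.0:
        raise ValueError("retention must lie in (0, 1]")
    lab = np.asarray(ds.cell_labels)
    if label not in set(lab):
        raise ValueError(f"label {label!r} not present")
    idx = np.flatnonzero(lab == label)
    n_keep = int(round(retention * idx.size))
    if n_keep == 0:
        raise ValueError("retention leaves zero cells of the thinned population")
    rng = np.random.default_rng(seed)
    keep_members = np.sort(rng.choice(idx, size=n_keep, replace=False))
    keep = np.sort(np.concatenate([np.flatnonzero(lab != label), keep_members]))

    truth = None
    if ds.truth is not None:
        old_to_new = -np.ones(ds.n_cells, dtype=int)
        old_to_new[keep] = np.arange(keep.size)
        surv = old_to_new[ds.truth.boundary_cells]
        mask = surv >= 0
        truth = dataclasses.replace(
            ds.truth,
            boundary_cells=surv[mask],
            interpolation=ds.truth.interpolation[mask],
        )
    return CountDataset(
        counts=ds.counts[keep],
        cell_labels=pd.Categorical(lab[keep]),
        gene_names=list(ds.gene_names),
        batch=None if ds.batch is None else pd.Categorical(np.asarray(ds.batch)[keep]),
        day=None if ds.day is None else np.asarray(ds.day)[keep],
        truth=truth,
    )


def truth_table(ds: CountDataset) -> AtlasTruth:
    """Return planted ground truth; raises for externally loaded datasets."""
    if ds.truth is None:
        raise ValueError("no ground truth: dataset was not generated by this module")
    return ds.truth


# ---------------------------------------------------------------------------
# Named study conditions.  These constructors freeze the synthetic conditions
# used throughout the test suite and the reproduction script: the planted
# boundary is 1.5% of a 10,000-cell atlas with 10 bell and 10 valley genes at
# log-effect 1.0 (standard atlas); the null atlas plants effect 0; the
# thinning atlas holds one rare population for the abundance-stress benchmark.
# ---------------------------------------------------------------------------


def _pick_planted(programs: dict[str, np.ndarray], source: str, target: str,
                  rng: np.random.Generator, n_bell: int, n_valley: int):
    """Choose planted genes with detectable baselines in both flanks.

    Bell genes need moderate baseline expression (so the fold-up is visible
    but not saturated); valley genes need a high enough floor that a dip is
    statistically detectable despite zero inflation.
    """
    s, t = programs[source], programs[target]
    lo = np.minimum(s, t)
    hi = np.maximum(s, t)
    bell_pool = np.flatnonzero((lo >= 0.4) & (hi <= 3.0))
    valley_pool = np.flatnonzero(lo >= 1.5)
    valley_pool = np.setdiff1d(valley_pool, bell_pool)
    bell = rng.choice(bell_pool, size=n_bell, replace=False)
    valley = rng.choice(valley_pool, size=n_valley, replace=False)
    return np.sort(bell), np.sort(valley)


def standard_atlas_spec(seed: int = 0) -> AtlasSpec:
    """10,000 cells, 500 genes, 4 stable populations + 150 boundary cells.

    Boundary prevalence 1.5%; 10 bell + 10 valley genes planted at
    log-effect 1.0, the reference condition for planted-program recovery.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    n_genes = 500
    progs = random_programs(4, n_genes, rng, n_markers=40)
    labels = ["progenitor", "committed", "bystander_a", "bystander_b"]
    sizes = [4200, 3650, 1400, 600]
    prog_map = dict(zip(labels, progs))
    bell, valley = _pick_planted(prog_map, "progenitor", "committed", rng, 10, 10)
    theta = np.clip(np.exp(rng.normal(np.log(2.0), 0.4, n_genes)), 0.5, 10.0)
    return AtlasSpec(
        n_genes=n_genes,
        populations=tuple(
            Population(l, n, p) for l, n, p in zip(labels, sizes, progs)
        ),
        boundary=Boundary(
            source="progenitor",
            target="committed",
            n_cells=150,
            bell_genes=bell,
            valley_genes=valley,
            bell_effect=1.0,
            valley_effect=1.0,
        ),
        dispersion=theta,
        seed=seed,
    )


def null_atlas_spec(seed: int = 0) -> AtlasSpec:
    """Light null atlas: pure interpolation boundary (planted effect 0)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    n_genes = 200
    progs = random_programs(2, n_genes, rng, n_markers=20)
    labels = ["source_pop", "target_pop"]
    sizes = [300, 300]
    theta = np.clip(np.exp(rng.normal(np.log(2.0), 0.4, n_genes)), 0.5, 10.0)
    return AtlasSpec(
        n_genes=n_genes,
        populations=tuple(Population(l, n, p) for l, n, p in zip(labels, sizes, progs)),
        boundary=Boundary(
            source="source_pop",
            target="target_pop",
            n_cells=40,
            bell_effect=0.0,
            valley_effect=0.0,
        ),
        dispersion=theta,
        seed=seed,
    )


def thinning_atlas_spec(seed: int = 0) -> AtlasSpec:
    """3,600 cells, 300 genes, 5 populations incl. one rare target for thinning."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    n_genes = 300
    progs = random_programs(5, n_genes, rng, n_markers=30)
    labels = ["pop_a", "pop_b", "pop_c", "rare_target", "pop_d"]
    sizes = [1200, 800, 600, 600, 400]
    theta = np.clip(np.exp(rng.normal(np.log(2.0), 0.4, n_genes)), 0.5, 10.0)
    return AtlasSpec(
        n_genes=n_genes,
        populations=tuple(Population(l, n, p) for l, n, p in zip(labels, sizes, progs)),
        dispersion=theta,
        seed=seed,
    )
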