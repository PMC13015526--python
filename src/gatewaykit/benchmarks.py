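"""Reference benchmark harnesses on the synthetic study conditions.

These functions wire the full pipeline together under the frozen synthetic
conditions (see :mod:`gatewaykit.synthetic`): planted-program recovery on the
standard 10,000-cell atlas, the abundance-stress thinning benchmark, and
null calibration of the boundary tests on pure-interpolation atlases.  They
are used both by the test suite and by the reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import bmi, gateway, programs, synthetic, validation
from .vae import ModelConfig, train_embedding

__all__ = [
    "gateway_model_config",
    "run_standard_pipeline",
    "run_thinning_benchmark",
    "run_null_calibration",
    "LAMBDA_OPERATING_POINT",
]

# Operating point of the BMI penalty weight, selected once by the prescribed
# reconstruction-vs-penalty sweep on the thinning benchmark (see docs/methods.md).
LAMBDA_OPERATING_POINT = 0.5


def gateway_model_config(lambda_bmi: float = LAMBDA_OPERATING_POINT,
                         seed: int = 42) -> ModelConfig:
    """Benchmark model: compact NB-VAE adequate for the synthetic atlases."""
    return ModelConfig(
        n_hidden=64, n_layers=1, batch_size=512, max_epochs=40, seed=seed,
        lambda_bmi=lambda_bmi, early_stopping_patience=40, kl_warmup_epochs=10,
    )


def _graph_weights(ds, seed: int, k: int = 32):
    b = bmi.binarize_and_filter(ds)
    thr = bmi.null_threshold(b, n_perm=50, percentile=25.0, seed=seed)
    g = bmi.build_bmi_graph(b, thr, k=k)
    return bmi.attention_weights(g, T=0.25, alpha_mix=1.0)


def run_standard_pipeline(seed: int, lambda_bmi: float = LAMBDA_OPERATING_POINT) -> dict:
    """Full gateway analysis on the standard planted atlas.

    Returns detection precision/recall of the hard gateway set against the
    planted boundary cells (percentile matched to the planted prevalence),
    bell/valley recovery of the planted genes at BH q < 0.05, and the
    ingredients needed for the expression-only classifier check.
    """
    spec = synthetic.standard_atlas_spec(seed)
    ds = synthetic.generate_atlas(spec)
    truth = synthetic.truth_table(ds)
    weights = _graph_weights(ds, seed=seed)
    emb = train_embedding(ds, weights, gateway_model_config(lambda_bmi))

    pulls = gateway.fate_pulls(emb.z, ds.cell_labels, k=30)
    raw = gateway.gateway_score(pulls, truth.source, truth.target, mode="pairwise")
    diffused = gateway.ppr_diffuse(raw, emb.z, k=30, alpha=0.5, iterations=3)
    prevalence = truth.boundary_cells.size / ds.n_cells
    percentile = 100.0 * (1.0 - prevalence)
    hard = gateway.select_gateway_cells(diffused, percentile)

    planted = set(truth.boundary_cells.tolist())
    detected = set(hard.tolist())
    precision = len(planted & detected) / max(len(detected), 1)
    recall = len(planted & detected) / len(planted)

    lab = np.asarray(ds.cell_labels)
    in_hard = np.zeros(ds.n_cells, bool)
    in_hard[hard] = True
    src = np.flatnonzero((lab == truth.source) & ~in_hard)
    tgt = np.flatnonzero((lab == truth.target) & ~in_hard)
    mask = programs.prefilter_genes(ds.counts[hard], ds.counts[src], ds.counts[tgt])
    gidx = np.flatnonzero(mask)
    table = programs.boundary_de(
        ds.counts[np.ix_(hard, gidx)],
        ds.counts[np.ix_(src, gidx)],
        ds.counts[np.ix_(tgt, gidx)],
        gene_names=[ds.gene_names[i] for i in gidx],
    )
    table = programs.classify_genes(table, amp_tau=0.25, alpha=0.05)

    bell_called = set(table.loc[table["class"] == "bell", "gene"])
    valley_called = set(table.loc[table["class"] == "valley", "gene"])
    planted_bell = {f"gene_{i}" for i in truth.bell_genes}
    planted_valley = {f"gene_{i}" for i in truth.valley_genes}
    return {
        "dataset": ds,
        "truth": truth,
        "embedding": emb,
        "diffused": diffused,
        "hard_set": hard,
        "table": table,
        "precision": precision,
        "recall": recall,
        "bell_recovery": len(bell_called & planted_bell) / len(planted_bell),
        "valley_recovery": len(valley_called & planted_valley) / len(planted_valley),
        "flank_cells": (src, tgt),
    }


def run_thinning_benchmark(seed: int, retention: float = 0.05,
                           lambda_bmi: float = LAMBDA_OPERATING_POINT) -> dict:
    """Rare-population abundance stress: penalty vs baseline on one thinned atlas."""
    spec = synthetic.thinning_atlas_spec(seed)
    ds = synthetic.thin_population(
        synthetic.generate_atlas(spec), "rare_target", retention, seed=seed + 100
    )
    lab = np.asarray(ds.cell_labels)
    weights = _graph_weights(ds, seed=seed)
    out = {}
    for name, lam in (("penalty", lambda_bmi), ("baseline", 0.0)):
        emb = train_embedding(ds, weights if lam > 0 else None,
                              gateway_model_config(lam))
        out[name] = validation.embedding_metrics(
            emb.z, lab, "rare_target", k=30, seed=0
        )
    return out


def run_null_calibration(n_replicates: int, seed: int, n_boot: int = 500) -> dict:
    """Pure-interpolation boundary: per-gene mixture-control flags and
    BH-gated bell/valley discoveries over light replicate atlases."""
    rng = np.random.default_rng(seed)
    mixture_fracs = []
    class_fracs = []
    for r in range(n_replicates):
        rep_seed = int(rng.integers(0, 2 ** 31 - 1))
        ds = synthetic.generate_atlas(synthetic.null_atlas_spec(rep_seed))
        truth = synthetic.truth_table(ds)
        lab = np.asarray(ds.cell_labels)
        gw = truth.boundary_cells
        mask = np.zeros(ds.n_cells, bool)
        mask[gw] = True
        src = np.flatnonzero((lab == truth.source) & ~mask)
        tgt = np.flatnonzero((lab == truth.target) & ~mask)
        mc = validation.synthetic_mixture_test(
            ds.counts[gw], ds.counts[src], ds.counts[tgt],
            n_boot=n_boot, seed=rep_seed,
        )
        mixture_fracs.append(float(mc.table["significant"].mean()))
        gmask = programs.prefilter_genes(ds.counts[gw], ds.counts[src],
                                         ds.counts[tgt])
        gidx = np.flatnonzero(gmask)
        tab = programs.classify_genes(programs.boundary_de(
            ds.counts[np.ix_(gw, gidx)],
            ds.counts[np.ix_(src, gidx)],
            ds.counts[np.ix_(tgt, gidx)],
        ))
        n_bv = int((tab["class"].isin(["bell", "valley"])).sum())
        class_fracs.append(n_bv / len(tab))
    return {
        "mixture_significant_fraction": float(np.mean(mixture_fracs)),
        "mixture_fractions": mixture_fracs,
        "bell_valley_fraction": float(np.mean(class_fracs)),
        "bell_valley_fractions": class_fracs,
        "n_replicates": n_replicates,
    }
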