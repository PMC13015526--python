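"""Readers, writers, run configuration and pipeline orchestration.

On-disk formats are deliberately plain: MatrixMarket counts (genes x cells on
disk, the community convention, transposed on load) with TSV sidecars for
cell and gene annotations, or the AnnData ``.h5ad`` container.  Run
configuration round-trips through YAML; every stage of
:func:`run_pipeline` leaves a JSON manifest with parameters and seeds so a
run can be reproduced bit-for-bit on the same platform.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from . import bmi, gateway, programs, vae
from .synthetic import CountDataset

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "write_dataset_mtx",
    "read_dataset",
    "write_dataset_h5ad",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """All pipeline parameters; defaults follow the published operating points."""

    # graph
    tau: int = 1
    min_freq: float = 0.01
    max_freq: float = 0.75
    n_perm: int = 50
    null_percentile: float = 25.0
    k_graph: int = 32
    temperature: float = 0.25
    alpha_mix: float = 1.0
    # model
    preset: str = "test-tiny"
    lambda_bmi: float = 0.5
    n_latent: int = 10
    learning_rate: float = 1e-3
    max_epochs: int = 400
    model_seed: int = 42
    batch_covariate: str | None = None
    # gateway
    source: str = ""
    target: str = ""
    score_mode: str = "pairwise"
    fate_k: int = 30
    ppr_k: int = 30
    ppr_alpha: float = 0.5
    ppr_iterations: int = 3
    gateway_percentile: float = 99.95
    # gene programs
    amp_tau: float = 0.25
    de_alpha: float = 0.05
    min_frac: float = 0.05
    min_var: float = 0.01
    # global
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def model_config(self) -> vae.ModelConfig:
        kw = dict(vae.PRESETS.get(self.preset, {}))
        kw.update(
            n_latent=self.n_latent,
            lambda_bmi=self.lambda_bmi,
            learning_rate=self.learning_rate,
            seed=self.model_seed,
            batch_covariate=self.batch_covariate,
        )
        if "max_epochs" not in vae.PRESETS.get(self.preset, {}):
            kw["max_epochs"] = self.max_epochs
        return vae.ModelConfig(**kw)


def write_dataset_mtx(ds: CountDataset, outdir: str | Path) -> None:
    """Write counts as MTX (genes x cells on disk) plus TSV sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), sp.csr_matrix(ds.counts.T))
    pd.DataFrame({"gene_id": ds.gene_names}).to_csv(
        outdir / "genes.tsv", sep="\t", index=False
    )
    cells = pd.DataFrame(
        {
            "cell_id": [f"cell_{i}" for i in range(ds.n_cells)],
            "cell_type": np.asarray(ds.cell_labels),
        }
    )
    if ds.batch is not None:
        cells["batch"] = np.asarray(ds.batch)
    if ds.day is not None:
        cells["day"] = np.asarray(ds.day)
    cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)


def write_dataset_h5ad(ds: CountDataset, path: str | Path) -> None:
    ds.to_anndata().write_h5ad(Path(path))


def _counts_from_float(x: np.ndarray) -> np.ndarray:
    if not np.allclose(x, np.round(x)):
        raise ValueError(
            "non-integer values in the count matrix: raw integer counts are required"
        )
    return np.round(x).astype(np.int64)


def read_dataset(path: str | Path, fmt: str = "mtx") -> CountDataset:
    """Load a :class:`CountDataset` from ``mtx`` directory or ``h5ad`` file."""
    path = Path(path)
    if fmt == "mtx":
        m = scipy.io.mmread(str(path / "matrix.mtx"))
        counts = _counts_from_float(np.asarray(m.todense()).T)
        genes = pd.read_csv(path / "genes.tsv", sep="\t")
        cells = pd.read_csv(path / "cells.tsv", sep="\t")
        if len(cells) != counts.shape[0]:
            n = counts.shape[0]
            raise ValueError(
                f"cell annotation mismatch: matrix has {n} cells but cells.tsv lists "
                f"{len(cells)}; offending ids: "
                f"{list(cells['cell_id'][min(n, len(cells)):].head(5))}"
            )
        gene_names = list(genes["gene_id"].astype(str))
        # de-duplicate colliding gene names with suffixes
        seen: dict[str, int] = {}
        for i, g in enumerate(gene_names):
            if g in seen:
                seen[g] += 1
                gene_names[i] = f"{g}.{seen[g]}"
                logger.warning("gene name collision: %s renamed to %s", g, gene_names[i])
            else:
                seen[g] = 0
        return CountDataset(
            counts=counts,
            cell_labels=pd.Categorical(cells["cell_type"]),
            gene_names=gene_names,
            batch=pd.Categorical(cells["batch"]) if "batch" in cells else None,
            day=cells["day"].to_numpy() if "day" in cells else None,
        )
    if fmt in ("h5ad", "h5-container"):
        import anndata

        ad = anndata.read_h5ad(path)
        X = ad.X.toarray() if sp.issparse(ad.X) else np.asarray(ad.X)
        return CountDataset(
            counts=_counts_from_float(X),
            cell_labels=pd.Categorical(ad.obs["cell_type"]),
            gene_names=list(ad.var_names),
            batch=pd.Categorical(ad.obs["batch"]) if "batch" in ad.obs else None,
            day=ad.obs["day"].to_numpy() if "day" in ad.obs else None,
        )
    raise ValueError(f"unknown format {fmt!r}")


def run_pipeline(
    ds: CountDataset, cfg: RunConfig, outdir: str | Path | None = None
) -> dict:
    """Graph -> train -> score -> genes, with per-stage artifacts and a manifest."""
    if not cfg.source or not cfg.target:
        raise ValueError("config must name the source and target flanking states")
    out: dict = {"config": cfg}

    logger.info("stage graph: binarize + null threshold + top-k BMI graph")
    b = bmi.binarize_and_filter(ds, tau=cfg.tau, min_freq=cfg.min_freq,
                                max_freq=cfg.max_freq)
    thr = bmi.null_threshold(b, n_perm=cfg.n_perm, percentile=cfg.null_percentile,
                             seed=cfg.seed)
    graph = bmi.build_bmi_graph(
        b, thr, k=cfg.k_graph,
        provenance={"n_permutations": cfg.n_perm, "percentile": cfg.null_percentile,
                    "seed": cfg.seed},
    )
    weights = bmi.attention_weights(graph, T=cfg.temperature, alpha_mix=cfg.alpha_mix)
    out.update(binarized=b, graph=graph, weights=weights)

    logger.info("stage train: lambda_bmi=%g preset=%s%s", cfg.lambda_bmi, cfg.preset,
                " (baseline mode)" if cfg.lambda_bmi == 0 else "")
    emb = vae.train_embedding(ds, weights if cfg.lambda_bmi > 0 else None,
                              cfg.model_config())
    out["embedding"] = emb

    logger.info("stage score: fate pulls + gateway score + PPR diffusion")
    pulls = gateway.fate_pulls(emb.z, ds.cell_labels, k=cfg.fate_k)
    raw = gateway.gateway_score(pulls, cfg.source, cfg.target, mode=cfg.score_mode)
    diffused = gateway.ppr_diffuse(raw, emb.z, k=cfg.ppr_k, alpha=cfg.ppr_alpha,
                                   iterations=cfg.ppr_iterations)
    hard = gateway.select_gateway_cells(diffused, cfg.gateway_percentile)
    result = gateway.GatewayResult(
        boundary=(cfg.source, cfg.target),
        mode=cfg.score_mode,
        raw_scores=raw,
        diffused_scores=diffused,
        ppr_params={"k": cfg.ppr_k, "alpha": cfg.ppr_alpha,
                    "iterations": cfg.ppr_iterations},
        hard_set=hard,
        percentile=cfg.gateway_percentile,
    )
    out.update(pulls=pulls, gateway=result)

    logger.info("stage genes: dual-flank DE + classification (%d gateway cells)",
                hard.size)
    lab = np.asarray(ds.cell_labels)
    in_hard = np.zeros(ds.n_cells, dtype=bool)
    in_hard[hard] = True
    src_cells = np.flatnonzero((lab == cfg.source) & ~in_hard)
    tgt_cells = np.flatnonzero((lab == cfg.target) & ~in_hard)
    mask = programs.prefilter_genes(
        ds.counts[hard], ds.counts[src_cells], ds.counts[tgt_cells],
        min_frac=cfg.min_frac, min_var=cfg.min_var,
    )
    gidx = np.flatnonzero(mask)
    table = programs.boundary_de(
        ds.counts[np.ix_(hard, gidx)],
        ds.counts[np.ix_(src_cells, gidx)],
        ds.counts[np.ix_(tgt_cells, gidx)],
        gene_names=[ds.gene_names[i] for i in gidx],
    )
    table = programs.classify_genes(table, amp_tau=cfg.amp_tau, alpha=cfg.de_alpha)
    table["gene_index"] = gidx
    out["gene_programs"] = table

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(outdir / "bmi_graph.mtx"), graph.edges)
        scipy.io.mmwrite(str(outdir / "attention.mtx"), weights.w_hat)
        pd.DataFrame(emb.z).to_csv(outdir / "latent.tsv", sep="\t", index=False,
                                   header=False)
        emb.loss_history.to_csv(outdir / "loss_history.tsv", sep="\t", index=False)
        gw_tab = pd.DataFrame({
            "cell_id": np.arange(ds.n_cells),
            "raw_score": raw,
            "diffused_score": diffused,
            "hard": in_hard,
        })
        gw_tab.to_csv(outdir / "gateway.tsv", sep="\t", index=False)
        table.to_csv(outdir / "gene_programs.tsv", sep="\t", index=False)
        manifest = {
            "config": dataclasses.asdict(cfg),
            "null_threshold": graph.null_threshold,
            "n_cells": ds.n_cells,
            "n_genes": ds.n_genes,
            "n_retained_genes": int(b.retained_genes.sum()),
            "n_gateway": int(hard.size),
            "baseline_mode": cfg.lambda_bmi == 0,
            "class_counts": table["class"].value_counts().to_dict(),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
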