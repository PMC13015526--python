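"""Bell/valley gene-program calling at a fate boundary.

Each gene is tested between the gateway set and *both* flanking populations
(two-sided Mann-Whitney U, Benjamini-Hochberg correction within each
comparison) and classified from the signs of the two log-fold changes on the
log1p scale:

    ascending:  source < gateway < target   (lfc_source > 0 > lfc_target)
    descending: source > gateway > target
    bell:       gateway above both flanks
    valley:     gateway below both flanks

A class is assigned only when both comparisons are significant
(q < alpha) and the amplitude ``A = (|LFC_S| + |LFC_T|) / 2`` reaches the
threshold ``amp_tau``; everything else is "none".  Weighted (soft-core)
gateway means are supported for the soft-threshold variant.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "lognorm",
    "prefilter_genes",
    "boundary_de",
    "classify_genes",
    "shared_programs",
]

CLASSES = ("ascending", "descending", "bell", "valley", "none")


def lognorm(counts: np.ndarray, target_sum: float | None = None) -> np.ndarray:
    """Scale each cell to the median library size (or ``target_sum``), then log1p."""
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=1)
    if target_sum is None:
        target_sum = float(np.median(lib))
    scale = target_sum / np.maximum(lib, 1e-300)
    return np.log1p(counts * scale[:, None])


def prefilter_genes(
    gateway_counts: np.ndarray,
    source_counts: np.ndarray,
    target_counts: np.ndarray,
    min_frac: float = 0.05,
    min_var: float = 0.01,
) -> np.ndarray:
    """Mask of genes expressed in >= ``min_frac`` of the pooled cells with
    log1p-normalized variance >= ``min_var``."""
    for a in (gateway_counts, source_counts, target_counts):
        if len(a) == 0:
            raise ValueError("cell sets must be non-empty")
    pooled = np.vstack([gateway_counts, source_counts, target_counts])
    frac = (pooled > 0).mean(axis=0)
    var = lognorm(pooled).var(axis=0)
    mask = (frac >= min_frac) & (var >= min_var)
    if not mask.any():
        warnings.warn("prefilter removed every gene")
    return mask


def _mwu(x: np.ndarray, y: np.ndarray, exact_max_n: int = 50) -> np.ndarray:
    """Two-sided Mann-Whitney p-values per gene (columns).

    Exact enumeration for small tie-free samples, normal approximation with
    tie correction otherwise.
    """
    n1, n2 = x.shape[0], y.shape[0]
    pvals = np.empty(x.shape[1])
    small = max(n1, n2) <= exact_max_n
    for g in range(x.shape[1]):
        xs, ys = x[:, g], y[:, g]
        if xs.min() == xs.max() == ys.min() == ys.max():
            pvals[g] = 1.0
            continue
        has_ties = np.unique(np.concatenate([xs, ys])).size < n1 + n2
        method = "exact" if small and not has_ties else "asymptotic"
        pvals[g] = stats.mannwhitneyu(
            xs, ys, alternative="two-sided", method=method
        ).pvalue
    return pvals


def boundary_de(
    gateway: np.ndarray,
    source: np.ndarray,
    target: np.ndarray,
    weights: np.ndarray | None = None,
    gene_names: list[str] | None = None,
) -> pd.DataFrame:
    """Dual-flank differential expression of the gateway set.

    Inputs are raw count matrices (cells x genes) for the gateway cells and
    the two flanking populations.  All cells are depth-normalized to the
    pooled median library size and log1p-transformed; LFCs are differences of
    mean log1p expression (gateway minus flank).  With ``weights`` the
    gateway-side means are score-weighted (soft mode) while the rank tests
    still run on the unweighted soft-core membership.
    """
    for name, a in (("gateway", gateway), ("source", source), ("target", target)):
        if len(a) < 3:
            raise ValueError(f"{name} set has fewer than 3 cells")
    pooled = np.vstack([gateway, source, target])
    target_sum = float(np.median(pooled.sum(axis=1)))
    g_log = lognorm(gateway, target_sum)
    s_log = lognorm(source, target_sum)
    t_log = lognorm(target, target_sum)

    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape[0] != g_log.shape[0]:
            raise ValueError("weights length must match gateway cells")
        w = w / w.sum()
        g_mean = w @ g_log
    else:
        g_mean = g_log.mean(axis=0)

    lfc_source = g_mean - s_log.mean(axis=0)
    lfc_target = g_mean - t_log.mean(axis=0)
    p_source = _mwu(g_log, s_log)
    p_target = _mwu(g_log, t_log)
    q_source = multipletests(p_source, method="fdr_bh")[1]
    q_target = multipletests(p_target, method="fdr_bh")[1]

    names = gene_names if gene_names is not None else [
        f"gene_{i}" for i in range(gateway.shape[1])
    ]
    return pd.DataFrame(
        {
            "gene": names,
            "lfc_source": lfc_source,
            "lfc_target": lfc_target,
            "p_source": p_source,
            "p_target": p_target,
            "q_source": q_source,
            "q_target": q_target,
            "amplitude": 0.5 * (np.abs(lfc_source) + np.abs(lfc_target)),
        }
    )


def classify_genes(
    table: pd.DataFrame,
    amp_tau: float = 0.25,
    alpha: float = 0.05,
    require_each_lfc: bool = False,
) -> pd.DataFrame:
    """Assign one class per gene from signs, significance and amplitude.

    Requires q < alpha against *both* flanks and amplitude >= ``amp_tau``;
    ``require_each_lfc`` additionally demands |LFC| >= amp_tau individually
    on both sides (off by default: the threshold is defined on A).
    """
    t = table.copy()
    ls, lt = t["lfc_source"].to_numpy(), t["lfc_target"].to_numpy()
    sig = (t["q_source"].to_numpy() < alpha) & (t["q_target"].to_numpy() < alpha)
    amp_ok = t["amplitude"].to_numpy() >= amp_tau
    if require_each_lfc:
        amp_ok &= (np.abs(ls) >= amp_tau) & (np.abs(lt) >= amp_tau)
    gate = sig & amp_ok
    cls = np.full(len(t), "none", dtype=object)
    cls[gate & (ls > 0) & (lt > 0)] = "bell"
    cls[gate & (ls < 0) & (lt < 0)] = "valley"
    cls[gate & (ls > 0) & (lt < 0)] = "ascending"
    cls[gate & (ls < 0) & (lt > 0)] = "descending"
    t["class"] = pd.Categorical(cls, categories=list(CLASSES))
    return t


def shared_programs(
    table_a: pd.DataFrame, table_b: pd.DataFrame, gene_class: str = "bell"
) -> dict:
    """Cross-boundary overlap of a gene class over the common tested universe.

    Returns counts, Jaccard, and the Fisher exact odds ratio / p-value of the
    2x2 membership table; zero cells trigger a Haldane-Anscombe 0.5
    correction for the reported odds ratio (flagged).
    """
    universe = np.intersect1d(table_a["gene"].to_numpy(), table_b["gene"].to_numpy())
    if universe.size == 0:
        raise ValueError("empty common gene universe")
    in_a = set(table_a.loc[table_a["class"] == gene_class, "gene"]) & set(universe)
    in_b = set(table_b.loc[table_b["class"] == gene_class, "gene"]) & set(universe)
    n = universe.size
    a = len(in_a & in_b)
    b = len(in_a) - a
    c = len(in_b) - a
    d = n - a - b - c
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    haldane = False
    if not np.isfinite(odds):  # divide-by-zero OR: Haldane-Anscombe 0.5 correction
        haldane = True
        odds = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
    union = a + b + c
    return {
        "n_universe": int(n),
        "n_a": len(in_a),
        "n_b": len(in_b),
        "overlap": a,
        "jaccard": a / union if union else np.nan,
        "odds_ratio": float(odds),
        "p_value": float(p),
        "haldane_corrected": haldane,
        "shared_genes": sorted(in_a & in_b),
    }
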