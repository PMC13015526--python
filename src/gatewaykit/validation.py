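"""Control battery for gateway analysis.

Implements the validation tests that separate a genuine boundary state from
artifacts of the scoring procedure: synthetic 50:50 mixture controls
(gateway cells must overshoot/undershoot an arithmetic blend of the flanks),
stratified matched-control designs with standardized-mean-difference balance
reporting, hilltop-overlap nulls (exact hypergeometric plus matched-size
Monte-Carlo draws), expression-only gateway classifiers, technical-confound
reports with curated signature module scores, and the rare-population
embedding benchmark metrics (kNN retention and cluster purity).
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .gateway import knn_indices
from .programs import lognorm

__all__ = [
    "MixtureControl",
    "MatchedDesign",
    "HilltopResult",
    "synthetic_mixture_test",
    "match_controls",
    "matched_outcome_test",
    "hilltop_overlap_test",
    "gateway_classifier",
    "confound_report",
    "load_signatures",
    "module_scores",
    "embedding_metrics",
]


@dataclass
class MixtureControl:
    table: pd.DataFrame  # per gene: diff, ci_lo, ci_hi, significant
    n_boot: int
    degenerate_ci: bool = False


@dataclass
class MatchedDesign:
    pairs: dict[int, np.ndarray]  # gateway cell -> control cell ids
    ratio: int
    strata_keys: list[str]
    balance: pd.DataFrame  # per covariate: smd_before, smd_after
    shortfall: dict[int, int] = field(default_factory=dict)
    dropped: list[int] = field(default_factory=list)


@dataclass
class HilltopResult:
    table: pd.DataFrame
    n_draws: int


def synthetic_mixture_test(
    gateway_counts: np.ndarray,
    flank_a_counts: np.ndarray,
    flank_b_counts: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
    gene_names: list[str] | None = None,
) -> MixtureControl:
    """Compare gateway cells with synthetic 50:50 flank mixtures.

    Mixture profiles average the log1p-normalized profiles of one random
    cell from each flank; the synthetic set is matched in size to the
    gateway set.  The per-gene statistic is the difference of means
    (gateway - mixture) with a 95% bootstrap CI over resampling both groups;
    genes whose CI excludes zero are flagged.  This is a per-gene
    nominal-level test: under a pure interpolation null ~5% of genes flag.
    """
    if len(flank_a_counts) == 0 or len(flank_b_counts) == 0:
        raise ValueError("flanks must be non-empty")
    n_gw = len(gateway_counts)
    if n_gw < 5:
        warnings.warn("fewer than 5 gateway cells; expect wide CIs")
    rng = np.random.default_rng(seed)
    pooled = np.vstack([gateway_counts, flank_a_counts, flank_b_counts])
    target = float(np.median(pooled.sum(axis=1)))
    g_log = lognorm(gateway_counts, target)
    a_log = lognorm(flank_a_counts, target)
    b_log = lognorm(flank_b_counts, target)
    ia = rng.integers(0, len(a_log), n_gw)
    ib = rng.integers(0, len(b_log), n_gw)
    mix = 0.5 * (a_log[ia] + b_log[ib])

    diff = g_log.mean(axis=0) - mix.mean(axis=0)
    # vectorized bootstrap of both group means via multinomial resampling
    w_g = rng.multinomial(n_gw, np.full(n_gw, 1.0 / n_gw), size=n_boot) / n_gw
    w_m = rng.multinomial(n_gw, np.full(n_gw, 1.0 / n_gw), size=n_boot) / n_gw
    boots = w_g @ g_log - w_m @ mix
    # expanded percentile interval (Hesterberg): plain percentile CIs
    # undercover at small n, so widen the tail quantiles to the t-adjusted level
    z_adj = stats.t.ppf(0.975, max(n_gw - 1, 1)) * np.sqrt(n_gw / max(n_gw - 1, 1))
    tail = 100.0 * stats.norm.cdf(-z_adj)
    lo, hi = np.percentile(boots, [tail, 100.0 - tail], axis=0)
    degenerate = n_boot < 20
    if degenerate:
        warnings.warn("too few bootstrap resamples for a stable CI")
    sig = (lo > 0) | (hi < 0)
    names = gene_names if gene_names is not None else [
        f"gene_{i}" for i in range(g_log.shape[1])
    ]
    return MixtureControl(
        table=pd.DataFrame(
            {"gene": names, "diff": diff, "ci_lo": lo, "ci_hi": hi, "significant": sig}
        ),
        n_boot=n_boot,
        degenerate_ci=degenerate,
    )


def _smd(x_t: np.ndarray, x_c: np.ndarray) -> float:
    """Standardized mean difference with pooled standard deviation."""
    sd = np.sqrt(0.5 * (x_t.var(ddof=1) + x_c.var(ddof=1)))
    if sd == 0:
        return 0.0
    return float((x_t.mean() - x_c.mean()) / sd)


def match_controls(
    gateway_ids: np.ndarray,
    pool_ids: np.ndarray,
    cell_meta: pd.DataFrame,
    strata_keys: list[str],
    ratio: int = 5,
    fallback_strata: list[str] | None = None,
    covariates: list[str] | None = None,
    seed: int = 0,
) -> MatchedDesign:
    """Sample ``ratio`` controls per gateway cell within matching strata.

    Controls are drawn without replacement from ``pool_ids`` within each
    gateway cell's stratum; on shortfall the ``fallback_strata`` (e.g. same
    day regardless of lineage) are used and the shortfall recorded.  The
    balance table reports per-covariate standardized mean differences before
    (gateway vs whole pool) and after matching.
    """
    gateway_ids = np.asarray(gateway_ids)
    pool_ids = np.asarray(pool_ids)
    if np.intersect1d(gateway_ids, pool_ids).size:
        raise ValueError("control pool must be disjoint from the gateway set")
    rng = np.random.default_rng(seed)

    def key(ids, keys):
        return pd.MultiIndex.from_frame(cell_meta.loc[ids, keys].reset_index(drop=True))

    avail: dict = {}
    for pid, k in zip(pool_ids, key(pool_ids, strata_keys)):
        avail.setdefault(k, []).append(pid)
    for v in avail.values():
        rng.shuffle(v)
    fb_avail: dict = {}
    if fallback_strata:
        for pid, k in zip(pool_ids, key(pool_ids, fallback_strata)):
            fb_avail.setdefault(k, []).append(pid)
        for v in fb_avail.values():
            rng.shuffle(v)
    used: set = set()

    pairs: dict[int, np.ndarray] = {}
    shortfall: dict[int, int] = {}
    dropped: list[int] = []
    gw_keys = key(gateway_ids, strata_keys)
    gw_fb_keys = key(gateway_ids, fallback_strata) if fallback_strata else gw_keys
    for gid, k, kf in zip(gateway_ids, gw_keys, gw_fb_keys):
        chosen: list[int] = []
        bucket = avail.get(k, [])
        while bucket and len(chosen) < ratio:
            cand = bucket.pop()
            if cand not in used:
                chosen.append(cand)
        if len(chosen) < ratio and fallback_strata:
            bucket = fb_avail.get(kf, [])
            while bucket and len(chosen) < ratio:
                cand = bucket.pop()
                if cand not in used and cand not in chosen:
                    chosen.append(cand)
        if not chosen:
            dropped.append(int(gid))
            continue
        if len(chosen) < ratio:
            shortfall[int(gid)] = ratio - len(chosen)
        used.update(chosen)
        pairs[int(gid)] = np.array(chosen)

    rows = []
    cov = covariates or [
        c for c in cell_meta.columns
        if c not in strata_keys and np.issubdtype(cell_meta[c].dtype, np.number)
    ]
    matched_controls = (
        np.concatenate(list(pairs.values())) if pairs else np.array([], dtype=int)
    )
    for c in cov:
        x_g = cell_meta.loc[gateway_ids, c].to_numpy(dtype=float)
        x_pool = cell_meta.loc[pool_ids, c].to_numpy(dtype=float)
        before = _smd(x_g, x_pool)
        after = (
            _smd(x_g, cell_meta.loc[matched_controls, c].to_numpy(dtype=float))
            if matched_controls.size
            else np.nan
        )
        rows.append({"covariate": c, "smd_before": before, "smd_after": after})
    return MatchedDesign(
        pairs=pairs,
        ratio=ratio,
        strata_keys=list(strata_keys),
        balance=pd.DataFrame(rows),
        shortfall=shortfall,
        dropped=dropped,
    )


def matched_outcome_test(
    design: MatchedDesign,
    outcome: np.ndarray | pd.Series,
    alternative: str = "greater",
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """One-sided Wilcoxon signed-rank test on gateway-minus-controls differences.

    The per-pair statistic is the gateway cell's outcome minus the mean of
    its matched controls.  All-zero differences return p = 1 (flagged).
    """
    outcome = pd.Series(outcome)
    diffs = np.array(
        [outcome[g] - outcome[c].mean() for g, c in design.pairs.items()]
    )
    all_zero = bool(np.all(diffs == 0))
    if all_zero:
        p = 1.0
        w = 0.0
    else:
        res = stats.wilcoxon(diffs, alternative=alternative, zero_method="wilcox")
        w, p = float(res.statistic), float(res.pvalue)
    rng = np.random.default_rng(seed)
    boots = np.median(
        diffs[rng.integers(0, diffs.size, (n_boot, diffs.size))], axis=1
    )
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {
        "n_pairs": diffs.size,
        "statistic": w,
        "p_value": p,
        "median_diff": float(np.median(diffs)),
        "ci_lo": float(lo),
        "ci_hi": float(hi),
        "all_zero": all_zero,
    }


def hilltop_overlap_test(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    corridor_ids: np.ndarray,
    percentiles,
    n_draws: int = 100_000,
    seed: int = 0,
) -> HilltopResult:
    """Overlap of two exit-specific gateway sets against a matched-size null.

    Within the corridor, the top sets A and B are taken at each percentile of
    the two scores; the null is two uniformly random corridor subsets of the
    same sizes.  Reports the observed overlap, Jaccard, the exact
    hypergeometric mean ``|A||B|/N`` and upper-tail p, and a Monte-Carlo
    replication that literally redraws matched-size subsets.
    """
    corridor_ids = np.asarray(corridor_ids)
    N = corridor_ids.size
    sa = np.asarray(scores_a)[corridor_ids]
    sb = np.asarray(scores_b)[corridor_ids]
    rng = np.random.default_rng(seed)
    rows = []
    for pct in np.atleast_1d(percentiles):
        A = np.flatnonzero(sa >= np.percentile(sa, pct))
        B = np.flatnonzero(sb >= np.percentile(sb, pct))
        if A.size == 0 or B.size == 0:
            rows.append({"percentile": pct, "defined": False})
            continue
        obs = np.intersect1d(A, B).size
        mean_h = A.size * B.size / N
        p_h = float(stats.hypergeom.sf(obs - 1, N, A.size, B.size))
        # Monte-Carlo: redraw B-sized subsets against a fixed random A-sized set
        in_a = np.zeros(N, dtype=bool)
        overlaps = np.empty(n_draws, dtype=np.int64)
        chunk = max(1, min(n_draws, int(2e7 // max(N, 1))))
        done = 0
        while done < n_draws:
            c = min(chunk, n_draws - done)
            keys = rng.random((c, N))
            subs_a = np.argpartition(keys, A.size - 1, axis=1)[:, : A.size]
            keys2 = rng.random((c, N))
            subs_b = np.argpartition(keys2, B.size - 1, axis=1)[:, : B.size]
            for r in range(c):
                in_a[:] = False
                in_a[subs_a[r]] = True
                overlaps[done + r] = in_a[subs_b[r]].sum()
            done += c
        p_mc = float((np.sum(overlaps >= obs) + 1) / (n_draws + 1))
        union = A.size + B.size - obs
        rows.append(
            {
                "percentile": float(pct),
                "defined": True,
                "n_corridor": int(N),
                "size_a": int(A.size),
                "size_b": int(B.size),
                "observed_overlap": int(obs),
                "jaccard": obs / union if union else np.nan,
                "hypergeom_mean": float(mean_h),
                "hypergeom_p": p_h,
                "mc_mean": float(overlaps.mean()),
                "mc_p": p_mc,
                "mc_se_mean": float(overlaps.std(ddof=1) / np.sqrt(n_draws)),
                "fold_enrichment": float(obs / mean_h) if mean_h > 0 else np.nan,
            }
        )
    return HilltopResult(table=pd.DataFrame(rows), n_draws=n_draws)


def gateway_classifier(
    expr_counts: np.ndarray,
    is_gateway: np.ndarray,
    gene_idx: np.ndarray,
    folds: int = 5,
    transfer: tuple[np.ndarray, np.ndarray] | None = None,
    undersample_ratio: int = 5,
    seed: int = 0,
) -> dict:
    """Regularized logistic regression on a bell/valley gene panel.

    Trains on log1p-normalized expression of ``gene_idx`` (typically the top
    10 bell + top 10 valley genes) with majority-class undersampling, and
    reports stratified cross-validated AUROC / AUPRC.  ``transfer`` supplies
    ``(expr_counts, is_gateway)`` of a second dataset scored without
    retraining.
    """
    gene_idx = np.asarray(gene_idx)
    if gene_idx.size < 2:
        raise ValueError("need at least 2 panel genes")
    y = np.asarray(is_gateway).astype(int)
    if y.sum() == 0:
        raise ValueError("gateway class is empty")
    X = lognorm(expr_counts)[:, gene_idx]
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    n_neg = min(neg.size, undersample_ratio * pos.size)
    keep = np.concatenate([pos, rng.choice(neg, n_neg, replace=False)])
    keep.sort()
    Xb, yb = X[keep], y[keep]

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aurocs, auprcs = [], []
    for tr, te in skf.split(Xb, yb):
        clf = LogisticRegression(max_iter=2000, C=1.0)
        clf.fit(Xb[tr], yb[tr])
        s = clf.predict_proba(Xb[te])[:, 1]
        aurocs.append(roc_auc_score(yb[te], s))
        auprcs.append(average_precision_score(yb[te], s))
    out = {
        "auroc_mean": float(np.mean(aurocs)),
        "auroc_folds": [float(a) for a in aurocs],
        "auprc_mean": float(np.mean(auprcs)),
        "n_pos": int(pos.size),
        "n_neg_used": int(n_neg),
    }
    if transfer is not None:
        Xt = lognorm(np.asarray(transfer[0]))[:, gene_idx]
        yt = np.asarray(transfer[1]).astype(int)
        clf = LogisticRegression(max_iter=2000, C=1.0)
        clf.fit(Xb, yb)
        out["transfer_auroc"] = float(roc_auc_score(yt, clf.predict_proba(Xt)[:, 1]))
    return out


def load_signatures() -> pd.DataFrame:
    """Curated stress / apoptosis-senescence / MET-gate signatures (packaged)."""
    with importlib.resources.files("gatewaykit.data").joinpath(
        "signatures.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def module_scores(
    counts: np.ndarray, gene_names: list[str], signature_genes: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Mean z-scored log1p expression over the signature genes present.

    Returns per-cell scores and the subset of genes actually present; with
    no present genes the scores are NaN (flagged by the caller).
    """
    present = [g for g in signature_genes if g in gene_names]
    if not present:
        return np.full(len(counts), np.nan), []
    idx = [gene_names.index(g) for g in present]
    X = lognorm(counts)[:, idx]
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=0)) / sd
    return Z.mean(axis=1), present


def confound_report(
    qc: pd.DataFrame,
    gateway_mask: np.ndarray,
    phase_labels=None,
) -> pd.DataFrame:
    """Technical-confound comparison of gateway vs non-gateway cells.

    Continuous QC metrics (library size, detected genes, mito/ribo fraction,
    module scores) get two-sided Mann-Whitney p-values and an effect
    direction; categorical phase labels get a chi-squared test.
    """
    gw = np.asarray(gateway_mask, dtype=bool)
    rows = []
    for col in qc.columns:
        x = qc[col].to_numpy(dtype=float)
        if np.all(np.isnan(x)):
            rows.append({"metric": col, "test": "skipped", "p_value": np.nan,
                         "direction": "undefined"})
            continue
        a, b = x[gw], x[~gw]
        p = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        d = np.median(a) - np.median(b)
        if d == 0:
            d = a.mean() - b.mean()
        rows.append({
            "metric": col, "test": "mannwhitneyu", "p_value": float(p),
            "direction": "higher" if d > 0 else ("lower" if d < 0 else "equal"),
        })
    if phase_labels is not None:
        tab = pd.crosstab(gw, pd.Categorical(phase_labels))
        chi2, p, _, _ = stats.chi2_contingency(tab)
        rows.append({"metric": "phase", "test": "chi2", "p_value": float(p),
                     "direction": "n/a"})
    return pd.DataFrame(rows)


def _leiden_clusters(z: np.ndarray, k: int = 15, resolution: float = 1.0,
                     seed: int = 0) -> np.ndarray:
    """Fixed clustering configuration: Leiden (RBConfiguration) on an
    undirected union kNN graph of the latent space."""
    import igraph
    import leidenalg

    nn, _ = knn_indices(z, min(k, len(z) - 1))
    n = len(z)
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in nn[i]}
    g = igraph.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(part.membership)


def embedding_metrics(
    z: np.ndarray,
    labels,
    target_label: str,
    k: int = 30,
    cluster_k: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> dict:
    """Rare-population benchmark metrics on a latent embedding.

    ``knn_retention``: mean over target cells of the fraction of their k
    nearest latent neighbors that are also target cells (k capped at
    n_target - 1 when the target is smaller, flagged).  ``purity``:
    precision of the cluster containing the most target cells under the
    fixed Leiden configuration.
    """
    labels = np.asarray(labels)
    t_mask = labels == target_label
    n_t = int(t_mask.sum())
    if n_t == 0:
        raise ValueError("target population is empty")
    capped = k >= n_t
    k_eff = min(k, max(n_t - 1, 1))
    nn, _ = knn_indices(z, k_eff)
    is_t = t_mask[nn]  # n x k
    retention = float(is_t[t_mask].mean())
    clusters = _leiden_clusters(z, k=cluster_k, resolution=resolution, seed=seed)
    best, purity = None, 0.0
    for c in np.unique(clusters):
        hits = int((t_mask & (clusters == c)).sum())
        if best is None or hits > best[1]:
            best = (c, hits)
    c_star = clusters == best[0]
    purity = float((t_mask & c_star).sum() / c_star.sum())
    return {
        "knn_retention": retention,
        "purity": purity,
        "k_effective": k_eff,
        "k_capped": capped,
        "n_target": n_t,
        "n_clusters": int(np.unique(clusters).size),
    }
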