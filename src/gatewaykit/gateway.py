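"""Gateway-cell scoring: fate pulls, min-pull scores, PageRank diffusion.

A cell's *fate pull* toward an annotated state is the fraction of its k
nearest latent-space neighbors carrying that annotation.  A cell deep inside
one state pulls ~1 toward it and ~0 toward everything else; a cell at the
interface between two states is pulled toward both.  The *gateway score* is
the minimum of the pulls toward the two flanking states (or, in
target-vs-best-other mode, toward the target and the strongest competing
state), so only cells connected to both fates score high.  Raw scores are
optionally denoised by personalized-PageRank diffusion on a separate
inverse-distance-weighted kNN graph, and gateway sets are selected at a
percentile cutoff (hard set) or as a score-weighted soft core.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "FatePullProfile",
    "GatewayResult",
    "knn_indices",
    "fate_pulls",
    "gateway_score",
    "ppr_diffuse",
    "select_gateway_cells",
    "soft_core_weights",
    "fate_bias",
]


@dataclass
class FatePullProfile:
    pulls: np.ndarray  # cells x states, rows sum to 1, entries multiples of 1/k
    states: list[str]
    k: int

    def pull(self, state: str) -> np.ndarray:
        return self.pulls[:, self.states.index(state)]


@dataclass
class GatewayResult:
    boundary: tuple[str, str]
    mode: str
    raw_scores: np.ndarray
    diffused_scores: np.ndarray
    ppr_params: dict
    hard_set: np.ndarray
    percentile: float
    soft_core: tuple[np.ndarray, np.ndarray] | None = None
    provenance: dict = field(default_factory=dict)


def knn_indices(z: np.ndarray, k: int, block: int = 2048):
    """Exact Euclidean k-nearest neighbors, self excluded.

    Ties at the k-th distance are broken deterministically toward the
    smaller cell index.  Returns ``(indices, distances)`` of shape
    ``(n, k)``.
    """
    z = np.asarray(z, dtype=np.float64)
    n = z.shape[0]
    if not 0 < k < n:
        raise ValueError("require 0 < k < n_cells")
    sq = (z ** 2).sum(axis=1)
    idx_out = np.empty((n, k), dtype=np.int64)
    dist_out = np.empty((n, k))
    for start in range(0, n, block):
        stop = min(start + block, n)
        d2 = sq[start:stop, None] + sq[None, :] - 2.0 * (z[start:stop] @ z.T)
        np.maximum(d2, 0.0, out=d2)
        d2[np.arange(stop - start), np.arange(start, stop)] = np.inf  # self
        # shrink with argpartition, then order by (distance, index)
        m = min(4 * k + 8, n - 1)
        part = np.argpartition(d2, m - 1, axis=1)[:, :m]
        for r in range(stop - start):
            cand = part[r]
            order = cand[np.lexsort((cand, d2[r, cand]))][:k]
            idx_out[start + r] = order
            dist_out[start + r] = np.sqrt(d2[r, order])
        del d2
    return idx_out, dist_out


def fate_pulls(z: np.ndarray, labels, k: int) -> FatePullProfile:
    """Per-cell fraction of the k nearest latent neighbors in each state."""
    labels = pd.Categorical(labels)
    if len(labels) != len(z):
        raise ValueError("labels must cover all cells")
    counts = pd.Series(labels).value_counts()
    empty = [s for s in labels.categories if counts.get(s, 0) == 0]
    if empty:
        warnings.warn(f"states with zero cells dropped: {empty}")
        labels = labels.remove_categories(empty)
    states = list(labels.categories)
    codes = np.asarray(labels.codes)
    nn, _ = knn_indices(z, k)
    n = len(z)
    pulls = np.zeros((n, len(states)))
    neigh_codes = codes[nn]  # n x k
    for s in range(len(states)):
        pulls[:, s] = (neigh_codes == s).mean(axis=1)
    return FatePullProfile(pulls=pulls, states=states, k=k)


def gateway_score(
    p: FatePullProfile, source: str, target: str, mode: str = "pairwise"
) -> np.ndarray:
    """min(pull_source, pull_target), or min(pull_target, best non-target pull).

    In pairwise mode the score is bounded by 0.5 (the two pulls share a row
    summing to at most 1); a cell deep in either flank scores ~0.
    """
    if source == target:
        raise ValueError("source and target must differ")
    for s in (source, target):
        if s not in p.states:
            raise ValueError(f"unknown state {s!r}")
    if mode == "pairwise":
        return np.minimum(p.pull(source), p.pull(target))
    if mode == "target-vs-best-other":
        t = p.states.index(target)
        others = np.delete(p.pulls, t, axis=1)
        return np.minimum(p.pulls[:, t], others.max(axis=1))
    raise ValueError("mode must be 'pairwise' or 'target-vs-best-other'")


def ppr_diffuse(
    scores: np.ndarray,
    z: np.ndarray,
    k: int = 30,
    alpha: float = 0.5,
    iterations: int = 3,
    max_weight: float = 1e6,
) -> np.ndarray:
    """Personalized-PageRank denoising of a per-cell score.

    Applies exactly ``iterations`` steps of ``s <- (1 - alpha) * s0 +
    alpha * P s`` where ``P`` row-normalizes an inverse-distance-weighted
    kNN graph built on ``z`` (a separate graph from the fate-pull
    neighborhoods).  Zero-distance pairs get weight capped at
    ``max_weight``.  ``alpha = 0`` returns the raw scores.
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must lie in [0, 1)")
    s0 = np.asarray(scores, dtype=float)
    if alpha == 0.0 or iterations == 0:
        return s0.copy()
    nn, dist = knn_indices(z, k)
    w = np.minimum(1.0 / np.maximum(dist, 1.0 / max_weight), max_weight)
    n = len(s0)
    rows = np.repeat(np.arange(n), k)
    P = sp.csr_matrix((w.ravel(), (rows, nn.ravel())), shape=(n, n))
    rs = np.asarray(P.sum(axis=1)).ravel()
    P = sp.diags(1.0 / np.maximum(rs, 1e-300)) @ P
    s = s0.copy()
    for _ in range(iterations):
        s = (1.0 - alpha) * s0 + alpha * (P @ s)
    return s


def select_gateway_cells(diffused: np.ndarray, percentile: float) -> np.ndarray:
    """Cells at or above the given percentile of the diffused score.

    Ties at the cutoff are all included, so the set can exceed the nominal
    count; an empty selection returns an empty array with a warning.
    """
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must lie in (0, 100)")
    thr = np.percentile(diffused, percentile)
    sel = np.flatnonzero(diffused >= thr)
    if sel.size == 0:
        warnings.warn("empty gateway selection")
    return sel


def soft_core_weights(
    diffused: np.ndarray, top_frac: float = 0.05, full_zone: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Score-weighted soft gateway core.

    Restricts to cells with strictly positive diffused score; keeps the top
    ``top_frac`` fraction (ties at the boundary broken toward the smaller
    cell index) or, with ``full_zone=True``, every positive-score cell.
    Weights are the diffused scores normalized to sum 1.
    """
    s = np.asarray(diffused, dtype=float)
    pos = np.flatnonzero(s > 0)
    if pos.size == 0:
        warnings.warn("no positive diffused scores; empty soft core")
        return np.array([], dtype=int), np.array([])
    if full_zone or top_frac >= 1.0:
        keep = pos
    else:
        n_keep = max(1, int(np.ceil(top_frac * pos.size)))
        order = pos[np.argsort(-s[pos], kind="stable")]
        keep = np.sort(order[:n_keep])
    w = s[keep]
    return keep, w / w.sum()


def fate_bias(p: FatePullProfile, state_a: str, state_b: str) -> np.ndarray:
    """Continuous per-cell bias ``pull_A - pull_B`` in [-1, 1]."""
    if state_a == state_b:
        raise ValueError("states must differ")
    return p.pull(state_a) - p.pull(state_b)
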