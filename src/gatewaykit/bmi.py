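"""Binary-mutual-information cell-cell graphs.

Cells are compared through their gene *detection* patterns: counts are
binarized at a threshold ``tau`` and, for each pair of cells, the mutual
information of the two indicator vectors is computed (in bits) from the
empirical 2x2 joint detection table across retained genes,

    BMI(i, j) = sum_{a,b in {0,1}} p_ij(a,b) * log2( p_ij(a,b) / (p_i(a) p_j(b)) ).

Because BMI scores shared ON/OFF program structure rather than expression
magnitude, a rare cell stays close to its true neighbors even when flanked by
much larger populations and regardless of abundance-correlated sequencing
depth.  Edges are filtered against a column-permutation null, each cell keeps
its top-k partners, and the surviving graph is converted into static
masked-softmax attention weights used by the regularized embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .synthetic import CountDataset

__all__ = [
    "BinarizedMatrix",
    "BMIGraph",
    "AttentionWeights",
    "binarize_and_filter",
    "pairwise_bmi",
    "bmi_for_pairs",
    "null_threshold",
    "sparsify_topk",
    "build_bmi_graph",
    "attention_weights",
]


@dataclass
class BinarizedMatrix:
    """Boolean detection matrix restricted to genes in the frequency band."""

    bits: np.ndarray  # cells x retained genes, bool
    retained_genes: np.ndarray  # boolean mask over original genes
    tau: int

    @property
    def n_cells(self) -> int:
        return self.bits.shape[0]

    @property
    def n_genes(self) -> int:
        return self.bits.shape[1]


@dataclass
class BMIGraph:
    """Sparse symmetric null-filtered top-k BMI graph (weights in bits)."""

    edges: sp.csr_matrix
    null_threshold: float
    k: int
    provenance: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)


@dataclass
class AttentionWeights:
    """Row-normalized masked-softmax weights over graph neighbors."""

    w_hat: sp.csr_matrix
    temperature: float
    alpha_mix: float


def binarize_and_filter(
    ds: CountDataset | np.ndarray,
    tau: int = 1,
    min_freq: float = 0.01,
    max_freq: float = 0.75,
) -> BinarizedMatrix:
    """Binarize detection at ``tau`` and keep genes with detection frequency
    in ``[min_freq, max_freq]`` (inclusive band), computed over all cells."""
    counts = ds.counts if isinstance(ds, CountDataset) else np.asarray(ds)
    if counts.min(initial=0) < 0:
        raise ValueError("counts must be non-negative")
    bits_all = counts >= tau
    freq = bits_all.mean(axis=0)
    retained = (freq >= min_freq) & (freq <= max_freq)
    if not retained.any():
        raise ValueError(
            "no genes fall in the detection-frequency band; widen [min_freq, max_freq]"
        )
    return BinarizedMatrix(
        bits=np.ascontiguousarray(bits_all[:, retained]),
        retained_genes=retained,
        tau=tau,
    )


def _bmi_from_counts(n11, n1i, n1j, G):
    """Vectorized BMI (bits) from joint detection counts; 0*log0 -> 0."""
    n11 = np.asarray(n11, dtype=np.float64)
    n1i = np.asarray(n1i, dtype=np.float64)
    n1j = np.asarray(n1j, dtype=np.float64)
    n10 = n1i - n11
    n01 = n1j - n11
    n00 = G - n1i - n1j + n11
    out = np.zeros(np.broadcast_shapes(n11.shape, n1i.shape, n1j.shape))
    for nab, pa, pb in (
        (n11, n1i, n1j),
        (n10, n1i, G - n1j),
        (n01, G - n1i, n1j),
        (n00, G - n1i, G - n1j),
    ):
        with np.errstate(divide="ignore", invalid="ignore"):
            term = (nab / G) * np.log2(nab * G / (pa * pb))
        out += np.where(nab > 0, term, 0.0)
    # guard tiny negative round-off
    return np.maximum(out, 0.0)


def pairwise_bmi(
    b: BinarizedMatrix, pairs: tuple[np.ndarray, np.ndarray] | None = None
) -> np.ndarray:
    """Pairwise BMI in bits.

    With ``pairs=None`` returns the dense symmetric cells x cells matrix
    (zero diagonal by convention is *not* imposed; the diagonal holds each
    cell's detection entropy).  With ``pairs=(i_idx, j_idx)`` returns the
    vector of BMI values for those candidate pairs.

    A cell that is all-ON or all-OFF over retained genes has a degenerate
    marginal; its BMI with any partner is exactly 0 and the cell is reported
    in the diagnostics of :func:`build_bmi_graph` rather than raising.
    """
    if b.n_genes < 2:
        raise ValueError("need at least 2 retained genes")
    B = b.bits.astype(np.float32)
    G = b.n_genes
    ones = B.sum(axis=1)
    if pairs is None:
        n11 = B @ B.T
        return _bmi_from_counts(n11, ones[:, None], ones[None, :], G)
    i_idx, j_idx = (np.asarray(p) for p in pairs)
    n11 = np.count_nonzero(b.bits[i_idx] & b.bits[j_idx], axis=1)
    return _bmi_from_counts(n11, ones[i_idx], ones[j_idx], G)


def bmi_for_pairs(b: BinarizedMatrix, i_idx, j_idx) -> np.ndarray:
    """Convenience wrapper for candidate-pair evaluation."""
    return pairwise_bmi(b, pairs=(np.asarray(i_idx), np.asarray(j_idx)))


def null_threshold(
    b: BinarizedMatrix,
    n_perm: int = 50,
    percentile: float = 25.0,
    seed: int = 0,
    pair_budget: int = 200_000,
    exact_below: int = 2000,
) -> float:
    """Permutation-null edge threshold.

    Each permutation independently shuffles every gene column across cells,
    destroying cell-cell program structure while preserving per-gene detection
    frequencies.  BMI is computed on all pairs (when ``n_cells <
    exact_below``) or on ``pair_budget`` sampled pairs per permutation; the
    threshold is the requested percentile of the pooled null values.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n = b.n_cells
    pooled: list[np.ndarray] = []
    enumerate_all = n < exact_below
    if enumerate_all:
        iu = np.triu_indices(n, k=1)
    for _ in range(n_perm):
        # independent uniform permutation of every gene column at once
        order = np.argsort(rng.random((n, b.n_genes)), axis=0)
        perm_bits = np.take_along_axis(b.bits, order, axis=0)
        pb = BinarizedMatrix(perm_bits, b.retained_genes, b.tau)
        if enumerate_all:
            vals = pairwise_bmi(pb)[iu]
        else:
            i_idx = rng.integers(0, n, pair_budget)
            j_idx = rng.integers(0, n - 1, pair_budget)
            j_idx[j_idx >= i_idx] += 1  # avoid self pairs
            vals = pairwise_bmi(pb, pairs=(i_idx, j_idx))
        pooled.append(vals)
    return float(np.percentile(np.concatenate(pooled), percentile))


def _topk_rows(vals: np.ndarray, row_offset: int, threshold: float, k: int):
    """Per row: zero sub-threshold/self entries, keep k largest with ties at
    the k-th rank broken toward the smaller cell index."""
    n_rows, n = vals.shape
    rows, cols, w = [], [], []
    for r in range(n_rows):
        v = vals[r].copy()
        v[row_offset + r] = -np.inf  # self
        v[v < threshold] = -np.inf
        alive = np.flatnonzero(np.isfinite(v) & (v > -np.inf))
        if alive.size == 0:
            continue
        # stable sort on -value keeps smaller index first among ties
        order = alive[np.argsort(-v[alive], kind="stable")][:k]
        rows.append(np.full(order.size, row_offset + r))
        cols.append(order)
        w.append(v[order])
    if not rows:
        return (np.array([], int), np.array([], int), np.array([], float))
    return np.concatenate(rows), np.concatenate(cols), np.concatenate(w)


def sparsify_topk(
    bmi: np.ndarray, threshold: float, k: int = 32, provenance: dict | None = None
) -> BMIGraph:
    """Null-filter a dense BMI matrix and keep each cell's top-k partners.

    Symmetrization is by union: an edge survives if either endpoint selected
    it (preserving connectivity of rare cells); the weight is the BMI value.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = bmi.shape[0]
    rows, cols, w = _topk_rows(np.asarray(bmi, dtype=float), 0, threshold, k)
    A = sp.csr_matrix((w, (rows, cols)), shape=(n, n))
    A = A.maximum(A.T)  # union; weights are symmetric BMI values
    A.eliminate_zeros()
    deg = np.diff(A.indptr)
    n_isolated = int((deg == 0).sum())
    if A.nnz == 0:
        warnings.warn("all edges fell below the null threshold; graph is empty")
    return BMIGraph(
        edges=A,
        null_threshold=float(threshold),
        k=k,
        provenance=provenance or {},
        diagnostics={"n_isolated": n_isolated},
    )


def build_bmi_graph(
    b: BinarizedMatrix,
    threshold: float,
    k: int = 32,
    block: int = 1024,
    provenance: dict | None = None,
) -> BMIGraph:
    """Blocked fast path: identical result to ``sparsify_topk(pairwise_bmi(b))``
    without materializing the full cells x cells matrix."""
    if k < 1:
        raise ValueError("k must be >= 1")
    B = b.bits.astype(np.float32)
    G = b.n_genes
    ones = B.sum(axis=1)
    n = b.n_cells
    rows_l, cols_l, w_l = [], [], []
    for start in range(0, n, block):
        stop = min(start + block, n)
        n11 = B[start:stop] @ B.T
        vals = _bmi_from_counts(n11, ones[start:stop, None], ones[None, :], G)
        # degenerate marginals give exact 0 already
        r, c, w = _topk_rows(vals, start, threshold, k)
        rows_l.append(r)
        cols_l.append(c)
        w_l.append(w)
    rows = np.concatenate(rows_l)
    cols = np.concatenate(cols_l)
    w = np.concatenate(w_l)
    A = sp.csr_matrix((w, (rows, cols)), shape=(n, n))
    A = A.maximum(A.T)
    A.eliminate_zeros()
    deg = np.diff(A.indptr)
    degen = np.flatnonzero((ones == 0) | (ones == G))
    diag = {"n_isolated": int((deg == 0).sum()), "degenerate_cells": degen}
    if A.nnz == 0:
        warnings.warn("all edges fell below the null threshold; graph is empty")
    return BMIGraph(
        edges=A, null_threshold=float(threshold), k=k,
        provenance=provenance or {}, diagnostics=diag,
    )


def attention_weights(
    g: BMIGraph, T: float = 0.25, alpha_mix: float = 1.0
) -> AttentionWeights:
    """Static masked-softmax attention from BMI edge weights.

    Per row, ``w = alpha_mix * softmax(BMI / T over neighbors) +
    (1 - alpha_mix) * uniform``.  Non-neighbors get exactly zero; rows with
    neighbors sum to one; isolated rows stay all-zero and contribute nothing
    to the embedding penalty.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    if not 0.0 <= alpha_mix <= 1.0:
        raise ValueError("alpha_mix must lie in [0, 1]")
    A = g.edges.tocsr().copy().astype(np.float64)
    data = A.data
    out = np.empty_like(data)
    for r in range(A.shape[0]):
        lo, hi = A.indptr[r], A.indptr[r + 1]
        if hi == lo:
            continue
        x = data[lo:hi] / T
        x = np.exp(x - x.max())
        soft = x / x.sum()
        out[lo:hi] = alpha_mix * soft + (1.0 - alpha_mix) / (hi - lo)
    W = sp.csr_matrix((out, A.indices, A.indptr), shape=A.shape)
    return AttentionWeights(w_hat=W, temperature=T, alpha_mix=alpha_mix)
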