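import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from gatewaykit.bmi import (
    BinarizedMatrix,
    attention_weights,
    binarize_and_filter,
    build_bmi_graph,
    null_threshold,
    pairwise_bmi,
    sparsify_topk,
)
from gatewaykit.synthetic import generate_atlas

from conftest import small_spec


def naive_bmi(bits_i, bits_j):
    """Literal 2x2 plug-in mutual information in bits (test oracle)."""
    G = len(bits_i)
    total = 0.0
    for a in (0, 1):
        for b in (0, 1):
            pab = np.mean((bits_i == a) & (bits_j == b))
            pa = np.mean(bits_i == a)
            pb = np.mean(bits_j == b)
            if pab > 0:
                total += pab * np.log2(pab / (pa * pb))
    return total


def bm(bits):
    bits = np.asarray(bits, dtype=bool)
    return BinarizedMatrix(bits, np.ones(bits.shape[1], bool), 1)


class TestBinarize:
    def test_threshold_definition(self):
        counts = np.array([[0, 1, 2], [3, 0, 1], [1, 1, 0], [2, 2, 2]])
        b = binarize_and_filter(counts, tau=1, min_freq=0.0, max_freq=1.0)
        assert np.array_equal(b.bits, counts >= 1)
        b2 = binarize_and_filter(counts, tau=2, min_freq=0.0, max_freq=1.0)
        assert np.array_equal(b2.bits, counts >= 2)

    def test_band_is_inclusive(self):
        # gene 0: 80% detection (excluded), gene 1: exactly 75% (kept),
        # gene 2: exactly 1% (kept), gene 3: 0% (excluded)
        n = 100
        counts = np.zeros((n, 4), int)
        counts[:80, 0] = 1
        counts[:75, 1] = 1
        counts[:1, 2] = 1
        b = binarize_and_filter(counts)
        assert b.retained_genes.tolist() == [False, True, True, False]

    def test_matches_bruteforce_frequency_scan(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(0.8, (100, 50))
        b = binarize_and_filter(counts, min_freq=0.1, max_freq=0.6)
        expected = []
        for g in range(50):
            f = np.mean(counts[:, g] >= 1)
            expected.append(0.1 <= f <= 0.6)
        assert b.retained_genes.tolist() == expected

    def test_empty_band_errors(self):
        with pytest.raises(ValueError, match="widen"):
            binarize_and_filter(np.ones((10, 3), int), min_freq=0.01, max_freq=0.5)


class TestPairwiseBMI:
    def test_analytic_cases(self):
        i = [1, 1, 0, 0]
        j = [1, 0, 1, 0]
        k = [1, 1, 1, 0]
        M = pairwise_bmi(bm(np.array([i, j, i, k, k])))
        assert M[0, 1] == pytest.approx(0.0, abs=1e-12)  # independent patterns
        assert M[0, 2] == pytest.approx(1.0, abs=1e-12)  # identical half-on
        assert M[3, 4] == pytest.approx(0.8112781244591328, abs=1e-12)  # 3/4 on

    def test_degenerate_marginal_gives_zero(self):
        allon = [1, 1, 1, 1]
        other = [1, 0, 1, 0]
        M = pairwise_bmi(bm(np.array([allon, other])))
        assert M[0, 1] == 0.0

    def test_equals_naive_loop(self):
        rng = np.random.default_rng(1)
        bits = rng.random((40, 60)) < 0.4
        M = pairwise_bmi(bm(bits))
        for i in range(0, 40, 7):
            for j in range(40):
                assert M[i, j] == pytest.approx(naive_bmi(bits[i], bits[j]), abs=1e-12)

    def test_pair_list_matches_dense(self):
        rng = np.random.default_rng(2)
        bits = rng.random((30, 25)) < 0.5
        b = bm(bits)
        M = pairwise_bmi(b)
        ii = rng.integers(0, 30, 50)
        jj = rng.integers(0, 30, 50)
        v = pairwise_bmi(b, pairs=(ii, jj))
        assert np.allclose(v, M[ii, jj], atol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 32 - 1))
    def test_symmetry_nonneg_entropy_bound(self, seed):
        rng = np.random.default_rng(seed)
        bits = rng.random((12, 20)) < rng.uniform(0.2, 0.8)
        M = pairwise_bmi(bm(bits))
        assert np.allclose(M, M.T, atol=1e-12)
        assert (M >= 0).all()
        # MI(i,j) <= min(H(i), H(j)); diagonal of M is the entropy
        H = np.diag(M)
        bound = np.minimum(H[:, None], H[None, :])
        assert (M <= bound + 1e-9).all()


class TestNullThreshold:
    def test_constant_bits_gives_zero(self):
        # every cell all-ON: degenerate marginals make all BMI values exactly 0
        bits = np.ones((30, 10), bool)
        assert null_threshold(bm(bits), n_perm=3, seed=0) == 0.0

    def test_monotone_in_percentile(self):
        rng = np.random.default_rng(3)
        bits = rng.random((50, 30)) < 0.5
        b = bm(bits)
        t25 = null_threshold(b, n_perm=5, percentile=25, seed=4)
        t50 = null_threshold(b, n_perm=5, percentile=50, seed=4)
        t100 = null_threshold(b, n_perm=5, percentile=100, seed=4)
        assert t25 <= t50 <= t100

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        bits = rng.random((40, 20)) < 0.4
        b = bm(bits)
        assert null_threshold(b, n_perm=4, seed=9) == null_threshold(b, n_perm=4, seed=9)

    def test_percentile_100_removes_almost_everything(self):
        rng = np.random.default_rng(6)
        bits = rng.random((60, 40)) < 0.5
        b = bm(bits)
        thr = null_threshold(b, n_perm=5, percentile=100, seed=1)
        M = pairwise_bmi(b)
        g = sparsify_topk(M, thr, k=59)
        frac = g.edges.nnz / (60 * 59)
        assert frac < 0.2


class TestSparsify:
    def test_hand_enumeration_5_cells(self):
        M = np.array([
            [9.0, 0.5, 0.3, 0.1, 0.05],
            [0.5, 9.0, 0.4, 0.2, 0.01],
            [0.3, 0.4, 9.0, 0.6, 0.02],
            [0.1, 0.2, 0.6, 9.0, 0.03],
            [0.05, 0.01, 0.02, 0.03, 9.0],
        ])
        g = sparsify_topk(M, threshold=0.1, k=2)
        # per-row top-2 at/above 0.1: {0:(1,2), 1:(0,2), 2:(3,1), 3:(2,1)},
        # then union symmetrization
        expected = {(0, 1), (0, 2), (1, 2), (2, 3), (1, 3)}
        got = {(min(i, j), max(i, j)) for i, j in zip(*g.edges.nonzero())}
        assert got == expected
        assert g.edges[0, 1] == 0.5
        assert g.diagnostics["n_isolated"] == 1  # cell 4 below threshold everywhere

    def test_complete_graph_when_k_large_threshold_zero(self):
        rng = np.random.default_rng(7)
        M = rng.uniform(0.1, 1.0, (6, 6))
        M = (M + M.T) / 2
        g = sparsify_topk(M, threshold=0.0, k=5)
        assert g.edges.nnz == 6 * 5

    def test_all_below_threshold_warns_empty(self):
        M = np.full((4, 4), 0.1)
        with pytest.warns(UserWarning, match="empty"):
            g = sparsify_topk(M, threshold=0.5, k=2)
        assert g.edges.nnz == 0

    def test_tie_break_prefers_smaller_index(self):
        from gatewaykit.bmi import _topk_rows

        vals = np.array([[0.0, 0.5, 0.5, 0.5]])  # exact ties at rank k
        rows, cols, w = _topk_rows(vals, row_offset=0, threshold=0.1, k=2)
        assert cols.tolist() == [1, 2]  # smaller indices win the tie
        assert w.tolist() == [0.5, 0.5]

    def test_blocked_fast_path_equals_naive(self):
        ds = generate_atlas(small_spec(seed=13, sizes=(90, 90), boundary_cells=20))
        b = binarize_and_filter(ds)
        M = pairwise_bmi(b)
        for i in range(0, b.n_cells, 37):
            for j in range(0, b.n_cells, 11):
                assert M[i, j] == pytest.approx(
                    naive_bmi(b.bits[i], b.bits[j]), abs=1e-12
                )
        thr = 0.01
        dense = sparsify_topk(M, thr, k=8)
        fast = build_bmi_graph(b, thr, k=8, block=64)
        assert (dense.edges != fast.edges).nnz == 0

    def test_raising_threshold_never_adds_edges(self):
        rng = np.random.default_rng(8)
        bits = rng.random((50, 30)) < 0.5
        M = pairwise_bmi(bm(bits))
        lo = sparsify_topk(M, 0.01, k=10).edges
        hi = sparsify_topk(M, 0.05, k=10).edges
        hi_set = set(zip(*hi.nonzero()))
        lo_set = set(zip(*lo.nonzero()))
        assert hi_set <= lo_set


class TestAttention:
    def _graph(self, weights):
        n = len(weights) + 1
        M = np.zeros((n, n))
        M[0, 1:] = weights
        M = M + M.T
        return sparsify_topk(M, threshold=0.0, k=n - 1)

    def test_equal_bmi_gives_half_half(self):
        w = attention_weights(self._graph([0.4, 0.4]), T=0.25)
        assert w.w_hat[0, 1] == pytest.approx(0.5)
        assert w.w_hat[0, 2] == pytest.approx(0.5)

    def test_closed_form_softmax(self):
        w = attention_weights(self._graph([0.5, 0.25]), T=0.25)
        e2, e1 = np.exp(2.0), np.exp(1.0)
        assert w.w_hat[0, 1] == pytest.approx(e2 / (e2 + e1), abs=1e-9)
        assert w.w_hat[0, 2] == pytest.approx(e1 / (e2 + e1), abs=1e-9)

    def test_alpha_mix_zero_is_uniform(self):
        w = attention_weights(self._graph([0.9, 0.1, 0.2]), T=0.25, alpha_mix=0.0)
        for j in (1, 2, 3):
            assert w.w_hat[0, j] == pytest.approx(1 / 3)

    def test_rows_sum_to_one_and_mask(self, small_atlas):
        b = binarize_and_filter(small_atlas)
        g = build_bmi_graph(b, 0.02, k=8)
        w = attention_weights(g)
        sums = np.asarray(w.w_hat.sum(axis=1)).ravel()
        deg = np.diff(g.edges.indptr)
        assert np.allclose(sums[deg > 0], 1.0, atol=1e-9)
        assert np.allclose(sums[deg == 0], 0.0)
        # non-neighbors are exactly zero (same sparsity pattern)
        assert (w.w_hat != 0).nnz == (g.edges != 0).nnz

    def test_isolated_row_stays_zero(self):
        A = sp.csr_matrix((3, 3))
        from gatewaykit.bmi import BMIGraph

        g = BMIGraph(edges=A, null_threshold=0.0, k=1)
        w = attention_weights(g)
        assert w.w_hat.nnz == 0


def test_depth_robustness_bmi_vs_euclidean():
    """BMI neighbor structure survives a 3x depth shift better than
    euclidean distance on log1p counts: two same-program populations at
    different depths should still find each other under BMI."""
    import dataclasses

    from gatewaykit.synthetic import AtlasSpec, Population, random_programs

    rng = np.random.default_rng(21)
    progs = random_programs(2, 200, rng, n_markers=20)
    spec = AtlasSpec(
        n_genes=200,
        populations=(
            Population("a_shallow", 100, progs[0]),
            Population("a_deep", 100, progs[0]),  # same program, deeper
            Population("b", 100, progs[1]),
        ),
        library_shift={"a_deep": np.log(3.0)},
        seed=21,
    )
    ds = generate_atlas(spec)
    lab = np.asarray(ds.cell_labels)
    b = binarize_and_filter(ds)
    M = pairwise_bmi(b)
    X = np.log1p(ds.counts)
    D = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    shallow = np.flatnonzero(lab == "a_shallow")
    deep = set(np.flatnonzero(lab == "a_deep").tolist())

    def top_frac(sim, asc):
        frac = []
        for i in shallow:
            order = np.argsort(sim[i] if asc else -sim[i])
            order = order[order != i][:100]
            frac.append(np.mean([j in deep for j in order]))
        return np.mean(frac)

    bmi_frac = top_frac(M, asc=False)
    eu_frac = top_frac(D, asc=True)
    assert bmi_frac > eu_frac
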