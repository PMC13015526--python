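import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gatewaykit.synthetic import generate_atlas, truth_table
from gatewaykit.validation import (
    confound_report,
    embedding_metrics,
    gateway_classifier,
    hilltop_overlap_test,
    load_signatures,
    match_controls,
    matched_outcome_test,
    module_scores,
    synthetic_mixture_test,
)

from conftest import small_spec


class TestMixtureControl:
    def test_null_calibration_single_replicate(self, small_atlas):
        """Effect-0 interpolation boundary: the per-gene CI test flags ~5%."""
        ds = small_atlas
        truth = truth_table(ds)
        lab = np.asarray(ds.cell_labels)
        gw = truth.boundary_cells
        mask = np.zeros(ds.n_cells, bool)
        mask[gw] = True
        res = synthetic_mixture_test(
            ds.counts[gw],
            ds.counts[(lab == "pop0") & ~mask],
            ds.counts[(lab == "pop1") & ~mask],
            n_boot=500,
            seed=1,
        )
        assert res.table["significant"].mean() < 0.20

    def test_planted_shift_flagged(self, planted_atlas):
        ds = planted_atlas
        truth = truth_table(ds)
        lab = np.asarray(ds.cell_labels)
        gw = truth.boundary_cells
        mask = np.zeros(ds.n_cells, bool)
        mask[gw] = True
        res = synthetic_mixture_test(
            ds.counts[gw],
            ds.counts[(lab == "pop0") & ~mask],
            ds.counts[(lab == "pop1") & ~mask],
            n_boot=500,
            seed=2,
        )
        t = res.table.set_index("gene")
        for g in truth.bell_genes:
            row = t.loc[f"gene_{g}"]
            assert row["significant"] and row["diff"] > 0
        for g in truth.valley_genes:
            row = t.loc[f"gene_{g}"]
            assert row["significant"] and row["diff"] < 0

    def test_single_bootstrap_degenerate_flagged(self, small_atlas):
        ds = small_atlas
        with pytest.warns(UserWarning):
            res = synthetic_mixture_test(
                ds.counts[:10], ds.counts[10:60], ds.counts[60:110], n_boot=1, seed=0
            )
        assert res.degenerate_ci


class TestMatching:
    def _meta(self, n, rng):
        return pd.DataFrame(
            {
                "day": rng.integers(0, 3, n),
                "lineage": rng.choice(["x", "y"], n),
                "depth": rng.normal(1000, 100, n),
            }
        )

    def test_identical_pool_gives_zero_smd(self):
        rng = np.random.default_rng(0)
        meta_g = self._meta(20, rng)
        meta = pd.concat([meta_g] + [meta_g] * 5, ignore_index=True)
        gw = np.arange(20)
        pool = np.arange(20, 120)
        design = match_controls(gw, pool, meta, ["day"], ratio=5,
                                covariates=["depth"], seed=0)
        smd = design.balance.set_index("covariate").loc["depth"]
        assert smd["smd_before"] == pytest.approx(0.0, abs=1e-9)
        assert smd["smd_after"] == pytest.approx(0.0, abs=1e-9)

    def test_single_stratum_reduces_to_srs(self):
        rng = np.random.default_rng(1)
        meta = pd.DataFrame({"day": np.zeros(60, int), "depth": rng.normal(0, 1, 60)})
        design = match_controls(np.arange(10), np.arange(10, 60), meta, ["day"],
                                ratio=3, seed=0)
        all_controls = np.concatenate(list(design.pairs.values()))
        assert len(all_controls) == 30
        assert len(set(all_controls)) == 30  # without replacement
        assert set(all_controls) <= set(range(10, 60))

    def test_deterministic_given_seed_and_fallback(self):
        rng = np.random.default_rng(2)
        meta = pd.DataFrame({
            "day": rng.integers(0, 2, 50),
            "lineage": rng.choice(["x", "y"], 50),
        })
        gw = np.arange(5)
        pool = np.arange(5, 50)
        a = match_controls(gw, pool, meta, ["day", "lineage"], ratio=8,
                           fallback_strata=["day"], seed=3)
        b = match_controls(gw, pool, meta, ["day", "lineage"], ratio=8,
                           fallback_strata=["day"], seed=3)
        for g in a.pairs:
            assert np.array_equal(a.pairs[g], b.pairs[g])
        assert a.shortfall == b.shortfall

    def test_overlapping_pool_rejected(self):
        meta = pd.DataFrame({"day": np.zeros(10, int)})
        with pytest.raises(ValueError):
            match_controls(np.arange(5), np.arange(3, 10), meta, ["day"])


class TestMatchedOutcome:
    def _design(self, n_pairs, ratio=2):
        from gatewaykit.validation import MatchedDesign

        pairs = {
            g: np.arange(100 + g * ratio, 100 + (g + 1) * ratio)
            for g in range(n_pairs)
        }
        return MatchedDesign(pairs=pairs, ratio=ratio, strata_keys=[],
                             balance=pd.DataFrame())

    def test_identical_outcomes_p_one(self):
        design = self._design(10)
        outcome = pd.Series(np.ones(200))
        res = matched_outcome_test(design, outcome)
        assert res["p_value"] == 1.0
        assert res["all_zero"]

    def test_uniform_shift_detected(self):
        rng = np.random.default_rng(4)
        design = self._design(25)
        outcome = pd.Series(rng.normal(0, 1, 200))
        outcome[np.arange(25)] = outcome[np.arange(25)] + 1.0
        # gateway outcomes are entries 0..24 shifted by +1
        out = pd.Series(np.zeros(200))
        out[:] = rng.normal(0, 0.3, 200)
        out[np.arange(25)] += 1.0
        res = matched_outcome_test(design, out)
        assert res["p_value"] < 0.01
        assert res["median_diff"] > 0.5

    def test_signed_rank_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        design = self._design(10, ratio=1)
        out = pd.Series(np.zeros(200))
        out[np.arange(10)] = rng.normal(0.4, 1, 10)
        out[100:110] = 0.0
        res = matched_outcome_test(design, out)
        diffs = out[np.arange(10)].to_numpy()
        ranks = pd.Series(np.abs(diffs)).rank().to_numpy()
        w_obs = ranks[diffs > 0].sum()
        ws = [
            ranks[list(signs)].sum()
            for r in range(11)
            for signs in itertools.combinations(range(10), r)
        ]
        p_exact = np.mean([w >= w_obs for w in ws])
        assert res["p_value"] == pytest.approx(p_exact, rel=1e-9)


class TestHilltop:
    def _scores(self, n, seed):
        rng = np.random.default_rng(seed)
        return rng.random(n), rng.random(n), np.arange(n)

    def test_null_mean_formula(self):
        sa, sb, ids = self._scores(100, 6)
        res = hilltop_overlap_test(sa, sb, ids, [90.0], n_draws=2000, seed=0)
        row = res.table.iloc[0]
        assert row["size_a"] == 10 and row["size_b"] == 10
        assert row["hypergeom_mean"] == pytest.approx(1.0)

    def test_mc_agrees_with_hypergeometric(self):
        sa, sb, ids = self._scores(200, 7)
        res = hilltop_overlap_test(sa, sb, ids, [80.0, 90.0], n_draws=20000, seed=1)
        for _, row in res.table.iterrows():
            se = row["mc_se_mean"]
            assert abs(row["mc_mean"] - row["hypergeom_mean"]) <= 3 * se

    def test_identical_scores_give_full_overlap_minimal_p(self):
        sa, _, ids = self._scores(150, 8)
        res = hilltop_overlap_test(sa, sa, ids, [90.0], n_draws=2000, seed=2)
        row = res.table.iloc[0]
        assert row["observed_overlap"] == row["size_a"]
        assert row["hypergeom_p"] == pytest.approx(
            stats.hypergeom.pmf(row["size_a"], 150, row["size_a"], row["size_b"]),
            rel=1e-6,
        )
        assert row["jaccard"] == 1.0


class TestClassifier:
    def test_random_labels_near_chance_and_separable_fixture(self):
        rng = np.random.default_rng(9)
        n = 400
        counts = rng.poisson(2.0, (n, 10))
        y = np.zeros(n, bool)
        y[rng.choice(n, 40, replace=False)] = True
        res = gateway_classifier(counts, y, np.arange(4), folds=4, seed=0)
        assert 0.3 < res["auroc_mean"] < 0.7
        # perfectly separable: one gene carries the label
        counts2 = counts.copy()
        counts2[y, 0] += 200
        res2 = gateway_classifier(counts2, y, np.array([0, 1]), folds=4, seed=0)
        assert res2["auroc_mean"] == pytest.approx(1.0)

    def test_transfer_mode_scores_second_dataset(self):
        rng = np.random.default_rng(10)
        def make(seed):
            r = np.random.default_rng(seed)
            c = r.poisson(2.0, (300, 6))
            y = np.zeros(300, bool)
            y[r.choice(300, 30, replace=False)] = True
            c[y, 0] += 50
            return c, y
        c1, y1 = make(1)
        c2, y2 = make(2)
        res = gateway_classifier(c1, y1, np.array([0, 1]), folds=3,
                                 transfer=(c2, y2), seed=0)
        assert res["transfer_auroc"] > 0.9
        del rng

    def test_requires_genes_and_positives(self):
        counts = np.ones((10, 3), int)
        with pytest.raises(ValueError):
            gateway_classifier(counts, np.zeros(10, bool), np.array([0, 1]))
        with pytest.raises(ValueError):
            gateway_classifier(counts, np.ones(10, bool), np.array([0]))


class TestConfounds:
    def test_identical_groups_not_significant(self):
        base = np.tile(np.arange(50, dtype=float), 2)
        qc = pd.DataFrame({"library_size": base, "mito_frac": base / 100})
        mask = np.zeros(100, bool)
        mask[:50] = True  # identical value multisets in both groups
        rep = confound_report(qc, mask)
        assert (rep["p_value"] > 0.9).all()

    def test_shifted_metric_detected_with_direction(self):
        rng = np.random.default_rng(11)
        mito = rng.normal(0.05, 0.01, 300)
        mask = np.zeros(300, bool)
        mask[:60] = True
        mito[mask] += 0.05
        qc = pd.DataFrame({"mito_frac": mito})
        rep = confound_report(qc, mask, phase_labels=rng.choice(["G1", "S"], 300))
        row = rep.set_index("metric").loc["mito_frac"]
        assert row["p_value"] < 1e-6
        assert row["direction"] == "higher"
        assert "phase" in set(rep["metric"])

    def test_missing_metric_skipped(self):
        qc = pd.DataFrame({"broken": np.full(20, np.nan)})
        rep = confound_report(qc, np.arange(20) < 5)
        assert rep.iloc[0]["test"] == "skipped"


class TestSignatures:
    def test_packaged_signatures_load(self):
        sig = load_signatures()
        assert {"context", "signature", "genes"} <= set(sig.columns)
        stress = sig.loc[
            (sig["context"] == "Kidney") & (sig["signature"] == "Stress/proteostasis"),
            "genes",
        ].iloc[0]
        assert "Hspa8" in stress.split(";")

    def test_module_scores_on_present_subset(self):
        rng = np.random.default_rng(12)
        counts = rng.poisson(2.0, (50, 3))
        scores, present = module_scores(counts, ["Hspa8", "Jun", "Other"],
                                        ["Hspa8", "Jun", "Missing"])
        assert present == ["Hspa8", "Jun"]
        assert np.isfinite(scores).all()
        empty, present2 = module_scores(counts, ["A", "B", "C"], ["Zzz"])
        assert present2 == []
        assert np.isnan(empty).all()


class TestEmbeddingMetrics:
    def test_perfect_separation(self):
        rng = np.random.default_rng(13)
        z = np.vstack([rng.normal(0, 0.1, (60, 2)), rng.normal(20, 0.1, (40, 2))])
        labels = np.array(["bg"] * 60 + ["t"] * 40)
        m = embedding_metrics(z, labels, "t", k=10, seed=0)
        assert m["knn_retention"] == 1.0
        assert m["purity"] == 1.0

    def test_scattered_target_retention_near_prevalence(self):
        rng = np.random.default_rng(14)
        z = rng.normal(size=(500, 3))
        labels = np.where(rng.random(500) < 0.2, "t", "bg")
        m = embedding_metrics(z, labels, "t", k=30, seed=0)
        rho = (labels == "t").mean()
        assert abs(m["knn_retention"] - rho) < 0.08

    def test_small_target_caps_k_with_flag(self):
        rng = np.random.default_rng(15)
        z = rng.normal(size=(100, 2))
        labels = np.array(["t"] * 5 + ["bg"] * 95)
        m = embedding_metrics(z, labels, "t", k=30, seed=0)
        assert m["k_capped"] and m["k_effective"] == 4

    def test_empty_target_errors(self):
        with pytest.raises(ValueError):
            embedding_metrics(np.zeros((10, 2)), np.array(["a"] * 10), "t")
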