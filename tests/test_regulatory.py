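"""DEGs, pseudobulk, hypo-DMRs, motif recovery AUC/NES, shuffle FDR, GRN."""

import numpy as np
import pandas as pd
import pytest

from epiretro.motifs import MotifPwm
from epiretro.regulatory import (
    MotifEnrichmentResult,
    assign_hypo_dmrs,
    build_grn,
    dmr_gene_association,
    expressed_tf_filter,
    motif_enrichment,
    pairwise_degs,
    pseudobulk_by_cluster,
    quantile_normalize_within_cluster,
    recovery_auc,
    shuffle_fdr_edges,
)
from epiretro.simulate import simulate_grn_profiles, simulate_motif_regions


class TestPairwiseDegs:
    def _expr(self, rng, fold=4.0, n=60, g=80, n_de=10):
        base = rng.gamma(2.0, 2.0, size=g)
        lam = np.tile(base, (2 * n, 1))
        lam[:n, :n_de] *= fold
        counts = rng.poisson(lam)
        totals = counts.sum(axis=1, keepdims=True)
        vals = np.log1p(counts / totals * totals.mean())
        return pd.DataFrame(vals, columns=[f"g{i}" for i in range(g)])

    def test_planted_fold_recovered(self, rng):
        expr = self._expr(rng)
        clusters = np.array(["a"] * 60 + ["b"] * 60)
        union, per_pair = pairwise_degs(expr, clusters)
        planted = {f"g{i}" for i in range(10)}
        recall = len(union & planted) / len(planted)
        fdr = len(union - planted) / max(len(union), 1)
        assert recall >= 0.9
        assert fdr <= 0.05

    def test_identical_clusters_give_none(self, rng):
        expr = self._expr(rng, fold=1.0, n_de=0)
        clusters = np.array(["a"] * 60 + ["b"] * 60)
        union, _ = pairwise_degs(expr, clusters)
        assert len(union) <= 1

    def test_truncation_to_top_n(self, rng):
        # >100 strongly differential genes -> exactly 100 kept, best FDRs first;
        # folds are planted in both directions so library-size normalization
        # does not cancel them
        base = rng.gamma(2.0, 2.0, size=150)
        lam = np.tile(base, (80, 1))
        lam[:40, :60] *= 8.0    # up in cluster a
        lam[40:, 60:120] *= 8.0  # up in cluster b
        counts = rng.poisson(lam)
        totals = counts.sum(axis=1, keepdims=True)
        expr = pd.DataFrame(
            np.log1p(counts / totals * totals.mean()),
            columns=[f"g{i}" for i in range(150)],
        )
        clusters = np.array(["a"] * 40 + ["b"] * 40)
        union, per_pair = pairwise_degs(expr, clusters, top_n=100)
        tab = per_pair[("a", "b")]
        assert len(tab) == 100
        assert len(union) == 100
        assert (tab["fdr"].to_numpy()[:-1] <= tab["fdr"].to_numpy()[1:] + 1e-12).all()

    def test_small_cluster_skipped(self, rng):
        expr = self._expr(rng)
        clusters = np.array(["a"] * 5 + ["b"] * 115)
        union, per_pair = pairwise_degs(expr, clusters)
        assert per_pair == {} and union == set()


class TestPseudobulk:
    def test_pooled_ratio(self):
        mc = np.array([[1], [3]])
        cov = np.array([[4], [4]])
        out = pseudobulk_by_cluster(mc, cov, np.array(["c", "c"]), np.array(["f"]),
                                    min_cells=2)
        assert out.loc["c", "f"] == pytest.approx(0.5)

    def test_min_cells_exclusion(self):
        mc = np.zeros((29, 1), dtype=int)
        cov = np.ones((29, 1), dtype=int)
        out = pseudobulk_by_cluster(mc, cov, np.array(["c"] * 29), np.array(["f"]))
        assert out.empty

    def test_zero_coverage_feature_missing(self):
        mc = np.zeros((2, 2), dtype=int)
        cov = np.array([[0, 4], [0, 4]])
        out = pseudobulk_by_cluster(mc, cov, np.array(["c", "c"]), np.array(["f0", "f1"]),
                                    min_cells=2)
        assert np.isnan(out.loc["c", "f0"]) and out.loc["c", "f1"] == 0.0


class TestHypoDmrs:
    def test_worked_quantile_example(self):
        m = pd.DataFrame(
            [[0.1, 0.9, 0.9], [0.8, 0.85, 0.9], [0.9, 0.9, 0.2]],
            index=["d1", "d2", "d3"], columns=["c1", "c2", "c3"],
        )
        flags = assign_hypo_dmrs(m, q=0.10)
        assert flags.loc["d1", "c1"]
        assert flags.to_numpy().sum() == 1  # hypo in cluster 1 only

    def test_constant_matrix_has_no_flags(self):
        m = pd.DataFrame(np.full((4, 3), 0.5))
        assert not assign_hypo_dmrs(m).to_numpy().any()

    def test_flag_count_nondecreasing_in_q(self, rng):
        m = pd.DataFrame(rng.beta(5, 2, size=(30, 6)))
        counts = [assign_hypo_dmrs(m, q).to_numpy().sum() for q in (0.05, 0.1, 0.3, 0.7)]
        assert (np.diff(counts) >= 0).all()

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            assign_hypo_dmrs(pd.DataFrame({"c": [0.1, 0.2]}))


class TestRecoveryCurve:
    def test_worked_example(self):
        # foreground of 3 ranked 1..3 of 100, T=5 -> (1/3, 2/3, 1, 1, 1)
        ranked = np.array([f"d{i}" for i in range(100)])
        fg = {"d0", "d1", "d2"}
        assert recovery_auc(ranked, fg, top=5) == pytest.approx(0.8)

    def test_oracle_on_random_instances(self, rng):
        for _ in range(100):
            n = int(rng.integers(10, 60))
            ids = np.array([f"x{i}" for i in range(n)])
            order = rng.permutation(ids)
            fg = set(rng.choice(ids, size=int(rng.integers(1, n // 2 + 1)), replace=False))
            top = int(rng.integers(1, n + 1))
            # direct enumeration oracle
            rec = []
            seen = 0
            for r in range(top):
                seen += order[r] in fg
                rec.append(seen / len(fg))
            assert recovery_auc(order, fg, top) == pytest.approx(np.mean(rec), abs=1e-12)

    def test_invariant_to_monotone_score_transform(self, rng):
        # AUC depends on scores only through the ranking
        motif = MotifPwm("m", np.full((4, 4), 0.25))
        scores = rng.normal(size=50)
        ids = np.array([f"d{i}" for i in range(50)])
        fg = set(ids[:5])
        r1 = ids[np.lexsort((ids, -scores))]
        r2 = ids[np.lexsort((ids, -np.exp(scores)))]
        assert recovery_auc(r1, fg, 10) == recovery_auc(r2, fg, 10)


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(0)
    mat = np.full((8, 4), 0.02)
    mat[np.arange(8), rng.integers(0, 4, 8)] = 0.94
    target = MotifPwm("target", mat)
    records, seqs = simulate_motif_regions(300, target, 0.25, seed=4)
    fg = set(records.loc[records["planted"], "dmr_id"])
    background = []
    for i in range(29):
        m = np.full((8, 4), 0.02)
        m[np.arange(8), rng.integers(0, 4, 8)] = 0.94
        background.append(MotifPwm(f"bg{i}", m))
    return records, seqs, fg, [target] + background


class TestMotifEnrichment:
    def test_planted_motif_enriched(self, planted):
        records, seqs, fg, motifs = planted
        res = motif_enrichment({"c0": fg}, records["dmr_id"].to_numpy(), seqs, motifs)
        assert res.nes.loc["target", "c0"] > 3
        assert res.enriched.loc["target", "c0"]

    def test_background_motifs_not_enriched(self, planted):
        records, seqs, fg, motifs = planted
        res = motif_enrichment({"c0": fg}, records["dmr_id"].to_numpy(), seqs, motifs)
        bg_nes = res.nes.drop(index="target")["c0"]
        assert (bg_nes < 3).mean() >= 0.95

    def test_empty_hypo_set_skipped(self, planted):
        records, seqs, fg, motifs = planted
        res = motif_enrichment(
            {"c0": fg, "empty": set()}, records["dmr_id"].to_numpy(), seqs, motifs
        )
        assert "empty" not in res.auc.columns


class TestExpressedTfFilter:
    def _enrichment(self):
        idx = ["m_tfA", "m_tfB"]
        enr = pd.DataFrame([[True], [True]], index=idx, columns=["c0"])
        return MotifEnrichmentResult(
            auc=enr.astype(float), nes=enr.astype(float) * 5, enriched=enr
        )

    def test_silent_tf_removed_active_kept(self):
        motifs = [
            MotifPwm("m_tfA", np.full((4, 4), 0.25), tf_genes=("tfA",)),
            MotifPwm("m_tfB", np.full((4, 4), 0.25), tf_genes=("tfB",)),
        ]
        expr = pd.DataFrame({"c0": [0.0, 2.1]}, index=["tfA", "tfB"])
        mch = pd.DataFrame({"c0": [0.5, 0.8]}, index=["tfA", "tfB"])
        out = expressed_tf_filter(self._enrichment(), motifs, expr, mch)
        assert out["c0"] == {"tfB"}

    def test_multi_tf_motif_keeps_only_passing(self):
        motifs = [MotifPwm("m_tfA", np.full((4, 4), 0.25), tf_genes=("tfA", "tfB"))]
        enr = pd.DataFrame([[True]], index=["m_tfA"], columns=["c0"])
        res = MotifEnrichmentResult(enr.astype(float), enr.astype(float), enr)
        expr = pd.DataFrame({"c0": [1.0, 1.0]}, index=["tfA", "tfB"])
        mch = pd.DataFrame({"c0": [0.5, 1.5]}, index=["tfA", "tfB"])  # tfB too methylated
        out = expressed_tf_filter(res, motifs, expr, mch)
        assert out["c0"] == {"tfA"}


class TestQuantileNormalize:
    def test_identical_rank_orders_become_identical(self, rng):
        base = np.sort(rng.normal(size=10))
        df = pd.DataFrame({"c1": base * 2 + 1, "c2": base * 0.5 - 3, "c3": base})
        out = quantile_normalize_within_cluster(df)
        assert np.allclose(out["c1"], out["c2"])
        assert np.allclose(out["c1"], out["c3"])

    def test_distribution_shared_across_clusters(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 4)))
        out = quantile_normalize_within_cluster(df)
        sorted_cols = np.sort(out.to_numpy(), axis=0)
        assert np.allclose(sorted_cols, sorted_cols[:, [0]] @ np.ones((1, 4)))


class TestShuffleFdr:
    def test_perfect_correlation_retained_nulls_rejected(self, rng):
        n_clusters = 20
        shared = rng.normal(size=n_clusters)
        a = pd.DataFrame(
            np.vstack([shared, rng.normal(size=(9, n_clusters))]),
            index=[f"a{i}" for i in range(10)],
        )
        b = pd.DataFrame(
            np.vstack([shared, rng.normal(size=(9, n_clusters))]),
            index=[f"b{i}" for i in range(10)],
        )
        pairs = [(i, j) for i in range(10) for j in range(10)]
        pcc, sig, thr = shuffle_fdr_edges(a, b, pairs, n_shuffles=50, seed=0)
        assert pcc[0] == pytest.approx(1.0)
        assert sig[0]
        assert sig.sum() <= 3  # the planted edge plus at most stray nulls

    def test_shuffled_data_yields_no_edges(self, rng):
        a = pd.DataFrame(rng.normal(size=(15, 12)))
        b = pd.DataFrame(rng.normal(size=(15, 12)))
        pairs = [(i, j) for i in range(15) for j in range(15)]
        _, sig, _ = shuffle_fdr_edges(a, b, pairs, n_shuffles=50, seed=1)
        assert sig.mean() < 0.02

    def test_too_few_clusters_rejected(self, rng):
        a = pd.DataFrame(rng.normal(size=(3, 2)))
        with pytest.raises(ValueError):
            shuffle_fdr_edges(a, a, [(0, 0)])


class TestDmrGeneAssociation:
    def test_planted_pairs_recovered(self):
        sim = simulate_grn_profiles(n_clusters=30, n_triplets=8, seed=2)
        mid = dict(zip(sim["dmr_records"]["dmr_id"],
                       (sim["dmr_records"]["start"] + sim["dmr_records"]["end"]) // 2))
        # gene-body mCH stand-in anticorrelated with expression
        gene_mch = 1.0 - sim["gene_expr"] / (sim["gene_expr"].max(axis=None) + 0.1)
        out = dmr_gene_association(
            sim["dmr_mcg"], gene_mch, mid, sim["tss"], n_shuffles=50, seed=0
        )
        planted = {(t[1], t[2]) for t in sim["triplets"]}
        got = set(map(tuple, out.loc[out["significant"], ["dmr", "gene"]].to_numpy()))
        assert len(got & planted) / len(planted) >= 0.8

    def test_no_candidates_within_window(self):
        dmr = pd.DataFrame(np.random.default_rng(0).random((2, 5)), index=["d0", "d1"])
        gene = pd.DataFrame(np.random.default_rng(1).random((2, 5)), index=["g0", "g1"])
        out = dmr_gene_association(
            dmr, gene, {"d0": 0, "d1": 100}, {"g0": 5_000_000, "g1": 9_000_000},
        )
        assert out.empty


@pytest.fixture(scope="module")
def grn_sim():
    return simulate_grn_profiles(n_clusters=30, n_triplets=8, seed=3)


class TestGrn:
    def test_planted_triplets_recovered(self, grn_sim):
        sim = grn_sim
        mid = dict(zip(sim["dmr_records"]["dmr_id"],
                       (sim["dmr_records"]["start"] + sim["dmr_records"]["end"]) // 2))
        triplets = build_grn(
            sim["tf_expr"], sim["gene_expr"], sim["dmr_mcg"],
            sim["sequences"], sim["motifs"], mid, sim["tss"],
            enriched_tfs=set(sim["tf_expr"].index),
            deg_union=set(sim["gene_expr"].index),
            n_shuffles=50, seed=0,
        )
        got = {(t.tf, t.dmr, t.target) for t in triplets}
        planted = set(sim["triplets"])
        recall = len(got & planted) / len(planted)
        precision = len(got & planted) / max(len(got), 1)
        assert recall >= 0.8
        assert precision >= 0.8

    def test_tf_without_motif_hit_never_linked_to_dmr(self, grn_sim):
        sim = grn_sim
        mid = dict(zip(sim["dmr_records"]["dmr_id"],
                       (sim["dmr_records"]["start"] + sim["dmr_records"]["end"]) // 2))
        # strip every motif annotation except tf0's, then tf1..tfN can have
        # no TF-DMR edge regardless of correlation
        motifs = [m for m in sim["motifs"] if m.tf_genes == ("tf0",)]
        triplets = build_grn(
            sim["tf_expr"], sim["gene_expr"], sim["dmr_mcg"],
            sim["sequences"], motifs, mid, sim["tss"],
            enriched_tfs=set(sim["tf_expr"].index),
            deg_union=set(sim["gene_expr"].index),
            n_shuffles=30, seed=0,
        )
        assert {t.tf for t in triplets} <= {"tf0"}

    def test_empty_gating_sets_give_empty_grn(self, grn_sim):
        sim = grn_sim
        mid = dict(zip(sim["dmr_records"]["dmr_id"],
                       (sim["dmr_records"]["start"] + sim["dmr_records"]["end"]) // 2))
        out = build_grn(
            sim["tf_expr"], sim["gene_expr"], sim["dmr_mcg"],
            sim["sequences"], sim["motifs"], mid, sim["tss"],
            enriched_tfs=set(), deg_union=set(sim["gene_expr"].index),
        )
        assert out == []
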