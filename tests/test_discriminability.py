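"""Logistic AUROC discriminability: recovery, nulls, symmetry, DMGs."""

import numpy as np
import pandas as pd
import pytest

from epiretro.discriminability import (
    cross_source_auroc,
    gene_category_auroc,
    identify_dmgs,
    pairwise_projection_auroc,
)
from epiretro.methylome import posterior_methylation
from epiretro.simulate import SimulationConfig, simulate_multiomic_cohort


@pytest.fixture(scope="module")
def labelled_levels():
    cfg = SimulationConfig(
        n_clusters=4,
        cells_per_cluster_mc=60,
        n_genes=200,
        marker_fraction=0.3,
        marker_effect=0.3,
        coverage_mean=50.0,
        n_projections=2,
        seed=5,
    )
    mcm, _, meta, truth = simulate_multiomic_cohort(cfg)
    levels = posterior_methylation(mcm)
    proj = np.array([truth.cell_projection_observed[c] for c in levels.cells])
    return levels.levels, proj


class TestPairwiseAuroc:
    def test_planted_signal_recovered(self, labelled_levels):
        x, proj = labelled_levels
        res = pairwise_projection_auroc(
            x, proj, ("target0", "target1"), n_seeds=10, seed=0
        )
        assert res.mean_auroc >= 0.9
        assert len(res.auroc_values) == 10

    def test_permuted_labels_give_chance(self, labelled_levels):
        x, proj = labelled_levels
        perm = np.random.default_rng(1).permutation(proj)
        res = pairwise_projection_auroc(
            x, perm, ("target0", "target1"), n_seeds=20, seed=0
        )
        assert abs(res.mean_auroc - 0.5) < 0.05

    def test_identical_feature_rows_give_chance(self):
        x = np.tile(np.linspace(0, 1, 30), (60, 1))
        labels = np.array(["a"] * 30 + ["b"] * 30)
        res = pairwise_projection_auroc(x, labels, ("a", "b"), n_seeds=10, seed=0)
        assert abs(res.mean_auroc - 0.5) < 0.1

    def test_pair_order_invariance(self, labelled_levels):
        # flipping the pair flips both the class encoding and the decision
        # orientation, so the reported separability is unchanged; with the
        # deterministic sex-based split this holds to solver precision
        x, proj = labelled_levels
        sex = np.where(np.arange(len(proj)) % 2 == 0, "M", "F")
        r1 = pairwise_projection_auroc(
            x, proj, ("target0", "target1"), split="biological", sex=sex
        )
        r2 = pairwise_projection_auroc(
            x, proj, ("target1", "target0"), split="biological", sex=sex
        )
        assert np.allclose(r1.auroc_values, r2.auroc_values, atol=1e-6)

    def test_minimum_class_size_enforced(self, labelled_levels):
        x, proj = labelled_levels
        small = proj.copy()
        small[np.flatnonzero(small == "target0")[5:]] = "target1"
        with pytest.raises(ValueError):
            pairwise_projection_auroc(x, small, ("target0", "target1"))

    def test_biological_split_unavailable_with_one_sex(self, labelled_levels):
        x, proj = labelled_levels
        sex = np.full(len(proj), "M")
        res = pairwise_projection_auroc(
            x, proj, ("target0", "target1"), split="biological", sex=sex
        )
        assert not res.available and np.isnan(res.mean_auroc)

    def test_biological_split_both_directions(self, labelled_levels):
        x, proj = labelled_levels
        sex = np.where(np.arange(len(proj)) % 2 == 0, "M", "F")
        res = pairwise_projection_auroc(
            x, proj, ("target0", "target1"), split="biological", sex=sex
        )
        assert res.available and len(res.auroc_values) == 2
        assert res.mean_auroc >= 0.85


class TestCrossSource:
    def _make(self, flip=False, seed=0):
        rng = np.random.default_rng(seed)
        n, g = 80, 40
        x = rng.normal(0, 1, size=(n, g))
        y = np.array(["ET"] * (n // 2) + ["IT"] * (n // 2))
        delta = np.zeros(g)
        delta[:10] = 1.5
        x[y == "ET"] += delta if not flip else -delta
        return x, y

    def test_diagonal_matches_within_source(self):
        x, y = self._make()
        src = np.full(len(y), "A")
        diag = cross_source_auroc(x, y, src, "A", "A", n_seeds=10, seed=0)
        within = pairwise_projection_auroc(
            x, y, ("ET", "IT"), n_seeds=10, seed=0
        ).mean_auroc
        assert diag == pytest.approx(within)

    def test_shared_signal_transfers(self):
        xa, ya = self._make(seed=0)
        xb, yb = self._make(seed=1)
        x = np.vstack([xa, xb])
        y = np.concatenate([ya, yb])
        src = np.array(["A"] * len(ya) + ["B"] * len(yb))
        assert cross_source_auroc(x, y, src, "A", "B") >= 0.85

    def test_reversed_signal_fails_to_transfer(self):
        xa, ya = self._make(seed=0)
        xb, yb = self._make(flip=True, seed=1)
        x = np.vstack([xa, xb])
        y = np.concatenate([ya, yb])
        src = np.array(["A"] * len(ya) + ["B"] * len(yb))
        assert cross_source_auroc(x, y, src, "A", "B") <= 0.5

    def test_missing_class_gives_null(self):
        x, y = self._make()
        src = np.where(y == "ET", "A", "B")  # source B has no ET
        assert cross_source_auroc(x, y, src, "A", "B") is None


@pytest.fixture(scope="module")
def category_setup():
    rng = np.random.default_rng(7)
    n, g = 120, 60
    genes = [f"g{i}" for i in range(g)]
    x = rng.normal(0, 1, size=(n, g))
    y = np.array(["t0"] * (n // 2) + ["t1"] * (n // 2))
    x[y == "t0", :15] += 1.2          # only the first 15 genes carry signal
    feats = pd.DataFrame(x, columns=genes)
    categories = {
        "signal": genes[:15],
        "random": genes[30:45],
    }
    return feats, y, categories


class TestGeneCategories:
    def test_signal_category_beats_random(self, category_setup):
        feats, y, categories = category_setup
        long, tests = gene_category_auroc(
            feats, y, categories, comparisons=[("t0", "t1")], n_seeds=5, seed=0
        )
        wide = long.pivot(index="comparison", columns="category", values="auroc")
        assert wide.loc["t0|t1", "signal"] > wide.loc["t0|t1", "random"] + 0.2

    def test_downsampling_is_seed_deterministic(self, category_setup):
        feats, y, categories = category_setup
        categories = dict(categories)
        categories["big"] = list(feats.columns[15:55])  # will be downsampled
        out1, _ = gene_category_auroc(
            feats, y, categories, comparisons=[("t0", "t1")], n_seeds=3, seed=9
        )
        out2, _ = gene_category_auroc(
            feats, y, categories, comparisons=[("t0", "t1")], n_seeds=3, seed=9
        )
        pd.testing.assert_frame_equal(out1, out2)

    def test_absent_genes_intersected_out(self, category_setup):
        feats, y, categories = category_setup
        categories = dict(categories)
        categories["signal"] = categories["signal"] + ["not_a_gene"]
        long, _ = gene_category_auroc(
            feats, y, categories, comparisons=[("t0", "t1")], n_seeds=2, seed=0
        )
        assert (long["tier_size"] == 15).all()


class TestDmgs:
    def test_planted_dmgs_recovered(self):
        cfg = SimulationConfig(
            n_clusters=2,
            cells_per_cluster_mc=100,
            n_genes=200,
            marker_fraction=0.2,
            marker_effect=0.25,
            coverage_mean=100.0,
            n_projections=2,
            seed=13,
        )
        mcm, _, meta, truth = simulate_multiomic_cohort(cfg)
        levels = posterior_methylation(mcm)
        frame = levels.frame()
        classes = np.array([truth.cell_projection_observed[c] for c in levels.cells])
        sources = np.full(len(classes), "src0")
        dmgs, fc = identify_dmgs(
            frame, classes, sources, classes=("target0", "target1")
        )
        planted = truth.markers_per_cluster[0] | truth.markers_per_cluster[1]
        recall = len(dmgs & planted) / len(planted)
        fdr = len(dmgs - planted) / max(len(dmgs), 1)
        assert recall >= 0.9
        assert fdr <= 0.05
        assert fc.shape[0] == 1 and set(fc.columns) == dmgs

    def test_null_simulation_yields_no_dmgs(self, rng):
        x = pd.DataFrame(
            rng.beta(2, 20, size=(120, 100)),
            columns=[f"g{i}" for i in range(100)],
        )
        classes = np.array(["a", "b"] * 60)
        sources = np.full(120, "s")
        dmgs, _ = identify_dmgs(x, classes, sources, classes=("a", "b"))
        assert len(dmgs) <= 1

    def test_single_source_signal_keeps_union_membership(self, rng):
        # a gene differential only in source A stays in the union with a
        # near-zero fold change in source B
        n = 80
        g = 30
        x = rng.beta(2, 20, size=(2 * n, g))
        x[:n // 2, 0] += 0.5  # class a in source A only
        frame = pd.DataFrame(x, columns=[f"g{i}" for i in range(g)])
        classes = np.array((["a"] * (n // 2) + ["b"] * (n // 2)) * 2)
        sources = np.array(["A"] * n + ["B"] * n)
        dmgs, fc = identify_dmgs(frame, classes, sources, classes=("a", "b"))
        assert "g0" in dmgs
        assert abs(fc.loc["B", "g0"]) < abs(fc.loc["A", "g0"])
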