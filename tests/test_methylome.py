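"""Feature construction, posterior shrinkage, normalization, reduction."""

import numpy as np
import pandas as pd
import pytest

from epiretro.methylome import (
    FeatureSet,
    MethylCountMatrix,
    extend_gene_bodies,
    filter_autosomal,
    filter_features_by_coverage,
    make_genomic_bins,
    normalize_rna,
    posterior_methylation,
    reduce_dimensions,
    select_integration_features,
)


def _genes(rows):
    return FeatureSet(
        pd.DataFrame(rows, columns=["feature_id", "chrom", "start", "end"])
    )


class TestGenomicBins:
    @pytest.mark.parametrize(
        "length,expected",
        [
            (250_000, [(0, 100_000), (100_000, 200_000), (200_000, 250_000)]),
            (100_000, [(0, 100_000)]),
            (0, []),
        ],
    )
    def test_tiling(self, length, expected):
        fs = make_genomic_bins({"chr1": length})
        got = list(zip(fs.table["start"], fs.table["end"]))
        assert got == expected

    def test_tiling_covers_each_base_once(self):
        fs = make_genomic_bins({"chr1": 314_159}, bin_size=50_000)
        t = fs.table
        assert t["start"].iloc[0] == 0 and t["end"].iloc[-1] == 314_159
        assert (t["start"].iloc[1:].to_numpy() == t["end"].iloc[:-1].to_numpy()).all()

    def test_bad_bin_size(self):
        with pytest.raises(ValueError):
            make_genomic_bins({"chr1": 1000}, bin_size=0)


class TestExtendGenes:
    def test_two_kb_both_directions(self):
        fs = _genes([("g1", "chr1", 10_000, 20_000)])
        out = extend_gene_bodies(fs, flank=2000)
        assert (out.table.loc[0, "start"], out.table.loc[0, "end"]) == (8_000, 22_000)
        assert out.table.loc[0, "feature_id"] == "g1"

    def test_clip_at_origin_and_chrom_end(self):
        fs = _genes([("g1", "chr1", 1_000, 3_000)])
        out = extend_gene_bodies(fs, flank=2000, chrom_sizes={"chr1": 4_000})
        assert (out.table.loc[0, "start"], out.table.loc[0, "end"]) == (0, 4_000)

    def test_zero_flank_is_identity(self):
        fs = _genes([("g1", "chr1", 500, 900)])
        out = extend_gene_bodies(fs, flank=0)
        assert (out.table.loc[0, "start"], out.table.loc[0, "end"]) == (500, 900)


class TestAutosomalFilter:
    def test_sex_chroms_removed_order_preserved(self):
        fs = _genes(
            [("a", "chr1", 0, 10), ("b", "chrX", 0, 10), ("c", "chr2", 0, 10)]
        )
        out = filter_autosomal(fs, {"chrX", "chrY"})
        assert list(out.table["feature_id"]) == ["a", "c"]

    def test_empty_sex_set_is_identity(self):
        fs = _genes([("a", "chr1", 0, 10), ("b", "chrX", 0, 10)])
        out = filter_autosomal(fs, set())
        assert len(out) == 2

    def test_all_sex_features_warns(self):
        fs = _genes([("a", "chrX", 0, 10)])
        with pytest.warns(UserWarning):
            out = filter_autosomal(fs, {"chrX"})
        assert len(out) == 0


def _matrix(mc, cov, context="CH"):
    mc = np.asarray(mc)
    fs = _genes([(f"g{j}", "chr1", j * 10, j * 10 + 5) for j in range(mc.shape[1])])
    return MethylCountMatrix(
        cells=np.array([f"c{i}" for i in range(mc.shape[0])]),
        features=fs,
        mc=mc,
        cov=np.asarray(cov),
        context=context,
    )


class TestPosterior:
    def test_posterior_matches_beta_binomial_identity(self):
        """levels == (mc + mu*nu) / (cov + nu) with the fitted per-cell prior."""
        rng = np.random.default_rng(1)
        cov = rng.poisson(30, size=(5, 40))
        mc = rng.binomial(cov, 0.1)
        m = _matrix(mc, cov)
        post = posterior_methylation(m)
        mu = post.prior_mean[:, None]
        nu = post.prior_strength[:, None]
        expected = (mc + mu * nu) / (cov + nu)
        assert np.allclose(post.levels, expected, atol=1e-12)

    def test_zero_coverage_entry_gets_prior_mean(self):
        cov = np.array([[10, 0, 10]])
        mc = np.array([[5, 0, 5]])
        post = posterior_methylation(_matrix(mc, cov))
        assert post.levels[0, 1] == pytest.approx(post.prior_mean[0])

    def test_large_coverage_dominates_prior(self):
        cov = np.array([[1_000_000, 100, 50]])
        mc = np.array([[800_000, 10, 5]])
        post = posterior_methylation(_matrix(mc, cov))
        assert post.levels[0, 0] == pytest.approx(0.8, abs=1e-3)

    def test_shrinkage_decreases_with_coverage(self):
        """For fixed mc/cov the posterior moves toward the raw fraction as
        coverage grows."""
        gaps = []
        for scale in (4, 40, 400):
            cov = np.array([[scale, scale, scale, scale]])
            mc = np.array([[scale, 0, 0, 0]])  # raw fraction 1 on first feature
            post = posterior_methylation(_matrix(mc, cov))
            gaps.append(abs(post.levels[0, 0] - 1.0))
        assert gaps[0] > gaps[1] > gaps[2]

    def test_zero_total_coverage_cell_excluded(self):
        cov = np.array([[0, 0], [4, 4]])
        mc = np.array([[0, 0], [1, 2]])
        post = posterior_methylation(_matrix(mc, cov))
        assert list(post.cells) == ["c1"]


class TestNormalizeRna:
    def test_hand_computed_value(self):
        # one gene with count 10 in a cell of total 100; mean total 200
        counts = np.array([[10, 90], [200, 100]])
        out = normalize_rna(counts)
        assert out.values[0, 0] == pytest.approx(np.log(21), abs=1e-4)

    def test_zero_count_maps_to_zero(self):
        out = normalize_rna(np.array([[0, 5]]))
        assert out.values[0, 0] == 0.0

    def test_single_cell_identity_scaling(self):
        out = normalize_rna(np.array([[3, 7]]))
        assert np.allclose(out.values, np.log1p([3, 7]))

    def test_preserves_within_cell_rank_order(self, rng):
        counts = rng.poisson(5, size=(10, 30))
        counts[:, 0] += 100
        out = normalize_rna(counts)
        for i in range(counts.shape[0]):
            raw_rank = np.argsort(np.argsort(counts[i]))
            norm_rank = np.argsort(np.argsort(out.values[i]))
            assert np.array_equal(raw_rank, norm_rank)

    def test_zero_total_cell_excluded(self):
        out = normalize_rna(np.array([[0, 0], [1, 1]]))
        assert len(out.cells) == 1


class TestCoverageFilter:
    def test_threshold_boundary_inclusive(self):
        cov = np.array([[499, 500], [500, 500], [501, 500]])  # means: 500, 500
        m = _matrix(np.zeros_like(cov), cov)
        assert len(filter_features_by_coverage(m, 500)) == 2
        cov2 = np.array([[499], [500], [500]])  # mean 499.67
        m2 = _matrix(np.zeros_like(cov2), cov2)
        assert len(filter_features_by_coverage(m2, 500)) == 0

    def test_mean_across_cells(self):
        cov = np.array([[300], [600], [900]])
        m = _matrix(np.zeros_like(cov), cov)
        assert len(filter_features_by_coverage(m, 500)) == 1

    def test_zero_threshold_keeps_all(self):
        cov = np.zeros((2, 3), dtype=int)
        m = _matrix(np.zeros_like(cov), cov)
        assert len(filter_features_by_coverage(m, 0)) == 3


class TestIntegrationFeatures:
    def _frames(self):
        rng = np.random.default_rng(0)
        mch = pd.DataFrame(
            {
                "hi_hi": rng.normal(0, 0.4, 50),     # var ~0.16
                "hi_lo": rng.normal(0, 0.4, 50),
                "lo_hi": np.full(50, 0.3),           # var 0
            }
        )
        expr = pd.DataFrame(
            {
                "hi_hi": rng.normal(0, 0.3, 50),
                "hi_lo": np.full(50, 1.0),           # var 0
                "lo_hi": rng.normal(0, 0.3, 50),
            }
        )
        return mch, expr

    def test_both_thresholds_required(self):
        mch, expr = self._frames()
        keep = select_integration_features(mch, expr, ["hi_hi", "hi_lo", "lo_hi"])
        assert list(keep) == ["hi_hi"]

    def test_empty_result_rejected(self):
        mch, expr = self._frames()
        with pytest.raises(ValueError):
            select_integration_features(mch, expr, ["hi_lo", "lo_hi"])

    def test_unshared_gene_rejected(self):
        mch, expr = self._frames()
        with pytest.raises(ValueError):
            select_integration_features(mch, expr, ["missing"])


class TestReduceDimensions:
    def test_transform_of_fit_matrix_reproduces_coordinates(self, rng):
        X = rng.normal(size=(30, 12))
        model = reduce_dimensions(X, 5, mode="fit")
        again = reduce_dimensions(X, 5, mode="transform", model=model)
        assert np.allclose(again, model.coords, atol=1e-10)

    def test_components_have_unit_scale_after_sv_normalization(self, rng):
        X = rng.normal(size=(40, 15))
        model = reduce_dimensions(X, 6, mode="fit")
        norms = np.linalg.norm(model.coords, axis=0)
        assert np.allclose(norms, 1.0, atol=1e-10)

    def test_rank_deficient_input_truncated_with_warning(self, rng):
        base = rng.normal(size=(20, 1))
        X = base @ rng.normal(size=(1, 8))  # rank 1
        with pytest.warns(UserWarning):
            model = reduce_dimensions(X, 3, mode="fit")
        assert model.n_components == 1

    def test_singular_values_non_increasing(self, rng):
        X = rng.normal(size=(25, 10))
        model = reduce_dimensions(X, 8, mode="fit")
        assert (np.diff(model.singular_values) <= 1e-12).all()
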