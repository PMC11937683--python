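"""Coverage filter, windowing, aggregation, summaries, PCA, clustering."""

import itertools

import numpy as np
import pandas as pd
import pytest

from myometh.io_formats import Chromosome, GeneAnnotation
from myometh.methylome_core import (
    Region,
    aggregate_regions,
    filter_by_coverage,
    hcluster,
    make_feature_regions,
    make_windows,
    pca_samples,
    summarize_global,
    zscore_rows,
)

from conftest import make_table


class TestCoverageFilter:
    @pytest.mark.parametrize("total,min_reads,kept", [
        (9, 10, False),   # below the inclusive >=10 bound
        (10, 10, True),   # boundary retained
        (5, 5, True),
        (1, 1, True),
        (0, 1, False),
    ])
    def test_inclusive_boundary(self, total, min_reads, kept):
        table = make_table("chr1", [100], [total], [0])
        out = filter_by_coverage(table, min_reads)
        assert (len(out) == 1) is kept

    def test_order_preserved(self, rng):
        pos = np.sort(rng.choice(10_000, 50, replace=False))
        table = make_table("chr1", pos, rng.integers(0, 20, 50), rng.integers(0, 20, 50))
        out = filter_by_coverage(table, 10)
        assert (np.diff(out["pos"]) > 0).all()


class TestWindows:
    def test_disjoint_tiling_includes_trailing_partial(self):
        layout = [Chromosome("chr1", 250_000)]
        windows = make_windows(layout, 100_000)
        spans = [(w.start, w.end) for w in windows]
        assert spans == [(0, 100_000), (100_000, 200_000), (200_000, 250_000)]

    def test_half_step_sliding(self):
        layout = [Chromosome("chr1", 250_000)]
        windows = make_windows(layout, 100_000, step=50_000)
        spans = [(w.start, w.end) for w in windows]
        assert spans == [(0, 100_000), (50_000, 150_000), (100_000, 200_000),
                         (150_000, 250_000), (200_000, 250_000)]

    def test_sex_chromosomes_excluded(self):
        layout = [Chromosome("chr1", 100_000), Chromosome("chrX", 100_000, True)]
        windows = make_windows(layout, 50_000, exclude_sex=True)
        assert {w.chrom for w in windows} == {"chr1"}
        with_sex = make_windows(layout, 50_000, exclude_sex=False)
        assert {w.chrom for w in with_sex} == {"chr1", "chrX"}

    def test_step_larger_than_size_rejected(self):
        with pytest.raises(ValueError):
            make_windows([Chromosome("chr1", 100_000)], 1000, step=2000)


class TestFeatureRegions:
    layout = [Chromosome("chr1", 1_000_000)]

    def test_promoter_is_upstream_of_tss_plus_strand(self):
        genes = [GeneAnnotation("A", "chr1", 2000, 3000, "+")]
        feats = make_feature_regions(genes, [], self.layout, promoter_bp=2000)
        prom = feats["promoters"][0]
        assert (prom.start, prom.end) == (0, 2000)

    def test_promoter_mirrored_on_minus_strand(self):
        genes = [GeneAnnotation("B", "chr1", 2000, 3000, "-")]
        feats = make_feature_regions(genes, [], self.layout, promoter_bp=2000)
        prom = feats["promoters"][0]
        assert (prom.start, prom.end) == (3000, 5000)

    def test_tss_proximal_clipped_to_chromosome(self):
        genes = [GeneAnnotation("C", "chr1", 500, 4000, "+")]
        feats = make_feature_regions(genes, [], self.layout, tss_flank_bp=2000)
        tssp = feats["TSS_proximal"][0]
        assert (tssp.start, tssp.end) == (0, 2500)

    def test_gene_bodies_kept_as_is(self):
        genes = [GeneAnnotation("D", "chr1", 2000, 3000, "+")]
        feats = make_feature_regions(genes, [], self.layout)
        assert (feats["gene_bodies"][0].start, feats["gene_bodies"][0].end) == (2000, 3000)


class TestAggregate:
    def test_unweighted_mean_of_levels(self):
        # levels 0.2 (1/5) and 0.4 (8/20): unweighted mean 0.3, coverage ignored
        table = make_table("chr1", [10, 20], [1, 8], [4, 12])
        m = aggregate_regions({"s": table}, [Region("chr1", 0, 100)])
        assert m.iloc[0, 0] == pytest.approx(0.3)

    def test_min_sites_yields_missing(self):
        table = make_table("chr1", [10], [1], [4])
        m = aggregate_regions({"s": table}, [Region("chr1", 500, 600)], min_sites=1)
        assert np.isnan(m.iloc[0, 0])

    def test_empty_region_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate_regions({"s": make_table("chr1", [1], [1], [1])}, [])

    def test_matches_brute_force_on_random_regions(self, rng):
        pos = np.sort(rng.choice(50_000, 400, replace=False))
        meth = rng.integers(0, 20, 400)
        unmeth = rng.integers(0, 20, 400)
        tables = {"s1": make_table("chr1", pos, meth, unmeth),
                  "s2": make_table("chr1", pos, unmeth, meth)}
        regions = []
        for i in range(50):
            start = int(rng.integers(0, 49_000))
            regions.append(Region("chr1", start, start + int(rng.integers(100, 3000)),
                                  f"r{i}"))
        m = aggregate_regions(tables, regions, min_sites=1)
        for r in regions:
            for s, t in tables.items():
                inside = t[(t["pos"] >= r.start) & (t["pos"] < r.end)]["level"].dropna()
                expected = inside.mean() if len(inside) else np.nan
                got = m.at[r.name, s]
                if np.isnan(expected):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected, abs=1e-12)


class TestSummaries:
    def test_median_of_three(self):
        m = pd.DataFrame({"s": [0.1, 0.2, 0.3]})
        assert summarize_global(m).loc["s", "median"] == pytest.approx(0.2)

    def test_constant_matrix_identical_summaries(self):
        m = pd.DataFrame(0.4, index=range(5), columns=["a", "b", "c"])
        s = summarize_global(m)
        assert (s.nunique() == 1).all()

    def test_median_matches_sorting_oracle(self, rng):
        vals = rng.random(1001)
        m = pd.DataFrame({"s": vals})
        assert summarize_global(m).loc["s", "median"] == np.sort(vals)[500]

    def test_all_missing_sample_named_in_error(self):
        m = pd.DataFrame({"good": [0.1, 0.2], "empty": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="empty"):
            summarize_global(m)


class TestPca:
    def test_duplicated_sample_gets_identical_coordinates(self, rng):
        base = rng.random(30)
        m = pd.DataFrame({"a": base, "b": base, "c": rng.random(30)})
        coords, frac = pca_samples(m)
        assert np.allclose(coords.loc["a"], coords.loc["b"], atol=1e-10)
        assert frac[0] >= frac[-1]
        assert frac.sum() <= 1 + 1e-9

    def test_two_sample_pc1_separation_equals_euclidean_distance(self, rng):
        x, y = rng.random(20), rng.random(20)
        m = pd.DataFrame({"a": x, "b": y})
        coords, _ = pca_samples(m)
        sep = abs(coords.loc["a", "PC1"] - coords.loc["b", "PC1"])
        assert sep == pytest.approx(np.linalg.norm(x - y), abs=1e-9)

    def test_incomplete_regions_dropped(self, rng):
        m = pd.DataFrame(rng.random((10, 3)), columns=["a", "b", "c"])
        m.iloc[0, 0] = np.nan
        complete = pca_samples(m)[0]
        same = pca_samples(m.iloc[1:])[0]
        pd.testing.assert_frame_equal(complete, same)

    def test_too_few_complete_regions_rejected(self):
        m = pd.DataFrame({"a": [np.nan, 0.1], "b": [0.2, 0.3]})
        with pytest.raises(ValueError):
            pca_samples(m)


def brute_force_complete_linkage(X):
    """O(n^3) reference: merge the pair of clusters with smallest max-distance."""
    clusters = {i: [i] for i in range(len(X))}
    d = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    heights = []
    next_id = len(X)
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            h = max(d[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or h < best[0]:
                best = (h, a, b)
        h, a, b = best
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        heights.append(h)
        next_id += 1
    return sorted(heights)


class TestHcluster:
    def test_identical_samples_merge_first(self, rng):
        base = rng.random(10)
        m = pd.DataFrame({"A": base, "B": base, "C": base + 3.0})
        Z, order = hcluster(m, distance="euclidean")
        assert set(Z[0, :2].astype(int)) == {0, 1}  # A and B
        assert Z[0, 2] == pytest.approx(0.0)

    def test_correlation_distance_scale_invariant(self, rng):
        m = pd.DataFrame(rng.random((12, 4)), columns=list("abcd"))
        Z1, _ = hcluster(m, distance="correlation")
        Z2, _ = hcluster(m * 2.0, distance="correlation")
        assert np.allclose(Z1, Z2, atol=1e-10)

    def test_complete_linkage_heights_match_brute_force(self, rng):
        m = pd.DataFrame(rng.random((15, 6)), columns=list("abcdef"))
        Z, _ = hcluster(m, distance="euclidean")
        expected = brute_force_complete_linkage(m.to_numpy().T)
        assert np.allclose(sorted(Z[:, 2]), expected, atol=1e-10)

    def test_zero_variance_row_named_under_correlation(self):
        m = pd.DataFrame({"flat": [1.0, 1.0, 1.0], "var": [0.1, 0.5, 0.9]})
        with pytest.raises(ValueError, match="flat"):
            hcluster(m, distance="correlation")


class TestZscore:
    def test_three_point_row(self):
        m = pd.DataFrame([[1.0, 2.0, 3.0]], columns=["a", "b", "c"])
        z = zscore_rows(m)
        assert np.allclose(z.iloc[0], [-1.0, 0.0, 1.0])

    def test_constant_row_errors_or_drops(self):
        m = pd.DataFrame([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]], columns=["a", "b", "c"])
        with pytest.raises(ValueError):
            zscore_rows(m, on_zero_spread="error")
        z = zscore_rows(m, on_zero_spread="drop")
        assert len(z) == 1

    def test_output_rows_standardized(self, rng):
        m = pd.DataFrame(rng.random((40, 6)))
        m.iloc[3, 2] = np.nan
        z = zscore_rows(m)
        assert np.allclose(z.mean(axis=1, skipna=True), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=1, ddof=1), 1.0, atol=1e-12)
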