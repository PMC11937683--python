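"""Segmentation, region testing and DMR filtering against hand and
brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from myometh.io_formats import GeneAnnotation
from myometh.dmr_caller import (
    DMR,
    DmrParams,
    annotate_nearest_gene,
    build_site_matrix,
    call_dmrs,
    reciprocal_overlap_stats,
    segment_candidates,
)
from myometh.dmr_caller import test_region as region_test

from conftest import make_table


def site_matrix_from_diffs(diffs, positions=None, chrom="chr1"):
    """Minimal site matrix carrying only the per-site difference track."""
    n = len(diffs)
    if positions is None:
        positions = np.arange(n) * 100
    idx = pd.MultiIndex.from_arrays([[chrom] * n, positions], names=["chrom", "pos"])
    return pd.DataFrame({"diff": np.asarray(diffs, dtype=float)}, index=idx)


def exhaustive_best_block(diffs, min_len):
    """All-contiguous-blocks scan-statistic search, independent of the caller."""
    best = None
    n = len(diffs)
    for i in range(n):
        for j in range(i + min_len, n + 1):
            score = abs(np.sum(diffs[i:j])) / np.sqrt(j - i)
            if best is None or score > best[0] + 1e-12:
                best = (score, i, j)
    return best


class TestSiteMatrix:
    def _tables(self):
        # site at pos 300 missing (zero coverage) in sample a2
        a1 = make_table("chr1", [100, 200, 300], [2, 4, 6], [8, 6, 4], "a1")
        a2 = make_table("chr1", [100, 200, 300], [5, 5, 0], [5, 5, 0], "a2")
        b1 = make_table("chr1", [100, 200, 300], [8, 9, 10], [2, 1, 0], "b1")
        b2 = make_table("chr1", [100, 200, 300], [6, 7, 8], [4, 3, 2], "b2")
        return {"a1": a1, "a2": a2, "b1": b1, "b2": b2}

    def test_fully_covered_sites_enter_partially_covered_drop(self):
        m = build_site_matrix(self._tables(), ["a1", "a2"], ["b1", "b2"])
        assert list(m.index.get_level_values("pos")) == [100, 200]

    def test_min_present_relaxation_recovers_site(self):
        m = build_site_matrix(self._tables(), ["a1", "a2"], ["b1", "b2"], min_present=1)
        assert list(m.index.get_level_values("pos")) == [100, 200, 300]

    def test_mean_difference_matches_hand_computation(self):
        m = build_site_matrix(self._tables(), ["a1", "a2"], ["b1", "b2"])
        # pos 100: A mean = (0.2 + 0.5)/2 = 0.35; B mean = (0.8 + 0.6)/2 = 0.7
        assert m["diff"].iloc[0] == pytest.approx(0.35)
        # pos 200: A mean = (0.4 + 0.5)/2 = 0.45; B mean = (0.9 + 0.7)/2 = 0.8
        assert m["diff"].iloc[1] == pytest.approx(0.35)

    def test_single_sample_group_rejected(self):
        with pytest.raises(ValueError):
            build_site_matrix(self._tables(), ["a1"], ["b1", "b2"])


class TestSegmentation:
    def test_embedded_block_recovered_exactly(self):
        diffs = np.zeros(12)
        diffs[4:10] = 0.4
        params = DmrParams(min_cpgs=6)
        cands = segment_candidates(site_matrix_from_diffs(diffs), params)
        _, i, j = exhaustive_best_block(diffs, 6)
        assert (i, j) == (4, 10)
        assert len(cands) == 1
        assert (cands[0]["ilo"], cands[0]["ihi"]) == (i, j)

    def test_matches_exhaustive_search_on_random_tracks(self, rng):
        params = DmrParams(min_cpgs=5)
        for _ in range(20):
            diffs = rng.normal(0, 0.1, size=rng.integers(8, 30))
            cands = segment_candidates(site_matrix_from_diffs(diffs), params)
            score, i, j = exhaustive_best_block(diffs, 5)
            stat = lambda c: abs(np.sum(diffs[c["ilo"]:c["ihi"]])) / np.sqrt(c["ihi"] - c["ilo"])
            assert stat(max(cands, key=stat)) == pytest.approx(score, abs=1e-12)

    def test_gap_rule_never_merges_distant_clusters(self):
        diffs = np.full(12, 0.4)
        positions = np.concatenate([np.arange(6) * 100, 1500 + np.arange(6) * 100])
        params = DmrParams(min_cpgs=6, max_cpg_gap_bp=300)
        cands = segment_candidates(site_matrix_from_diffs(diffs, positions), params)
        assert len(cands) == 2
        assert all(c["ihi"] - c["ilo"] == 6 for c in cands)

    def test_flat_track_yields_single_whole_block(self):
        diffs = np.zeros(15)
        cands = segment_candidates(site_matrix_from_diffs(diffs), DmrParams(min_cpgs=10))
        assert len(cands) == 1
        assert (cands[0]["ilo"], cands[0]["ihi"]) == (0, 15)

    def test_short_presegment_emits_nothing(self):
        cands = segment_candidates(site_matrix_from_diffs(np.ones(5)), DmrParams(min_cpgs=10))
        assert cands == []


def enum_ks_mwu(values_a, values_b):
    """Independent exhaustive-permutation oracle: own statistics, own counting."""
    def ks_stat(a, b):
        grid = np.sort(np.concatenate([a, b]))
        fa = np.searchsorted(np.sort(a), grid, side="right") / len(a)
        fb = np.searchsorted(np.sort(b), grid, side="right") / len(b)
        return np.max(np.abs(fa - fb))

    def u_stat(a, b):
        return sum((x > y) + 0.5 * (x == y) for x in a for y in b)

    pooled = np.concatenate([values_a, values_b])
    n = len(values_a)
    d_obs = ks_stat(values_a, values_b)
    mu = n * (len(pooled) - n) / 2.0
    u_obs = u_stat(values_a, values_b)
    ks_count = u_count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(comb)] = True
        a, b = pooled[mask], pooled[~mask]
        ks_count += ks_stat(a, b) >= d_obs - 1e-12
        u_count += abs(u_stat(a, b) - mu) >= abs(u_obs - mu) - 1e-12
        total += 1
    return ks_count / total, u_count / total


class TestRegionTest:
    def test_identical_groups_give_p_one(self):
        vals = np.array([0.1, 0.2, 0.3, 0.4])
        p_ks, p_mwu, diff = region_test(vals, vals, vals, vals)
        assert p_ks == 1.0
        assert p_mwu == pytest.approx(1.0)
        assert diff == 0.0

    def test_full_separation_gives_d_one(self):
        a, b = np.zeros(3), np.ones(3)
        from scipy import stats
        assert stats.ks_2samp(a, b).statistic == 1.0
        p_ks, _, diff = region_test(a, b, a, b)
        assert diff == 1.0
        assert p_ks < 0.2  # the smallest achievable two-sided p at n=3 vs 3

    def test_exact_small_sample_p_matches_enumeration(self, rng):
        for _ in range(5):
            a, b = rng.random(4), rng.random(4) + rng.normal(0, 0.3)
            p_ks, p_mwu, _ = region_test(a, b, a, b)
            e_ks, e_mwu = enum_ks_mwu(a, b)
            assert p_ks == pytest.approx(e_ks, abs=1e-12)
            assert p_mwu == pytest.approx(e_mwu, abs=1e-12)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError):
            region_test(np.array([0.1]), np.array([0.2, 0.3]),
                        np.array([0.1]), np.array([0.25]))


class TestCallDmrs:
    def _planted_tables(self, diff, seed=0, n_sites=40, block=(10, 25)):
        rng = np.random.default_rng(seed)
        pos = np.arange(n_sites) * 100
        tables = {}
        for group, shift in (("a", 0.0), ("b", diff)):
            for k in range(1, 4):
                p = np.full(n_sites, 0.4)
                p[block[0]:block[1]] += shift if group == "b" else 0.0
                total = rng.poisson(20, n_sites) + 1
                meth = rng.binomial(total, np.clip(p, 0, 1))
                tables[f"{group}{k}"] = make_table("chr1", pos, meth, total - meth, f"{group}{k}")
        return tables

    def test_sub_threshold_difference_rejected_regardless_of_p(self):
        tables = self._planted_tables(0.15, seed=1)
        params = DmrParams(p_threshold=0.9999, diff_threshold=0.20, min_cpgs=10)
        dmrs = call_dmrs(tables, ["a1", "a2", "a3"], ["b1", "b2", "b3"], params)
        assert all(abs(d.mean_diff) > 0.20 for d in dmrs)

    def test_planted_block_called_and_disjoint(self):
        tables = self._planted_tables(0.35, seed=2)
        params = DmrParams(p_threshold=0.01, diff_threshold=0.20, min_cpgs=10)
        dmrs = call_dmrs(tables, ["a1", "a2", "a3"], ["b1", "b2", "b3"], params)
        assert len(dmrs) >= 1
        assert all(d.n_cpgs >= 10 for d in dmrs)
        for d1, d2 in zip(dmrs, dmrs[1:]):
            assert d1.end <= d2.start or d1.chrom != d2.chrom
        truth = pd.DataFrame({"chrom": ["chr1"], "start": [1000], "end": [2401]})
        stats = reciprocal_overlap_stats(dmrs, truth)
        assert stats["recall"] == 1.0

    def test_raising_diff_threshold_never_increases_calls(self):
        tables = self._planted_tables(0.30, seed=3)
        counts = []
        for thr in (0.05, 0.15, 0.25, 0.40):
            params = DmrParams(p_threshold=0.05, diff_threshold=thr, min_cpgs=10)
            counts.append(len(call_dmrs(tables, ["a1", "a2", "a3"], ["b1", "b2", "b3"], params)))
        assert counts == sorted(counts, reverse=True)

    def test_direction_follows_sign(self):
        tables = self._planted_tables(0.35, seed=4)
        params = DmrParams(p_threshold=0.05, diff_threshold=0.20, min_cpgs=10)
        up = call_dmrs(tables, ["a1", "a2", "a3"], ["b1", "b2", "b3"], params)
        down = call_dmrs(tables, ["b1", "b2", "b3"], ["a1", "a2", "a3"], params)
        assert {d.direction for d in up} == {"hyper"}
        assert {d.direction for d in down} == {"hypo"}


class TestNearestGene:
    genes = [
        GeneAnnotation("near", "chr1", 2000, 3000, "+"),
        GeneAnnotation("far", "chr1", 5000, 6000, "+"),
    ]

    def _dmr(self, start, end, chrom="chr1"):
        return DMR(chrom, start, end, 10, 0.3, 0.001, 0.001, "hyper")

    def test_gap_distance(self):
        out = annotate_nearest_gene([self._dmr(1000, 1100)], self.genes)
        assert out.loc[0, "gene_id"] == "near"
        assert out.loc[0, "distance"] == 900

    def test_overlap_distance_zero(self):
        out = annotate_nearest_gene([self._dmr(2500, 2600)], self.genes)
        assert out.loc[0, "gene_id"] == "near"
        assert out.loc[0, "distance"] == 0

    def test_equidistant_tie_broken_by_start_then_id(self):
        genes = [GeneAnnotation("zz", "chr1", 0, 1000, "+"),
                 GeneAnnotation("aa", "chr1", 2000, 3000, "+")]
        out = annotate_nearest_gene([self._dmr(1500, 1500 + 1)], genes)
        # gaps: zz ends at 1000 -> 500; aa starts at 2000 -> 499 ... make symmetric
        out = annotate_nearest_gene([self._dmr(1400, 1600)], genes)
        assert out.loc[0, "distance"] == 400
        assert out.loc[0, "gene_id"] == "zz"  # equidistant; smaller start wins

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError):
            annotate_nearest_gene([self._dmr(0, 10)], [])
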