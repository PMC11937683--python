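"""Descriptive methylome layer: coverage filtering, window/feature
aggregation, global summaries, PCA, hierarchical clustering, z-scoring.

Methylation matrices are regions × samples DataFrames of mean CpG levels
in [0, 1], with NaN where a sample has fewer than ``min_sites`` eligible
CpGs in a region.  Region labels have the form ``chrom:start-end``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .io_formats import Chromosome, GeneAnnotation


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"region {self.label or self.chrom}: start must be < end")

    @property
    def name(self) -> str:
        return self.label or f"{self.chrom}:{self.start}-{self.end}"


def filter_by_coverage(table: pd.DataFrame, min_reads: int) -> pd.DataFrame:
    """Keep CpGs covered by at least ``min_reads`` reads (inclusive bound).

    This is the per-tissue coverage rule applied before any aggregation
    (≥10 reads for tibialis anterior, ≥5 for gastrocnemius data).
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    total = table["meth_count"] + table["unmeth_count"]
    out = table[total >= min_reads].reset_index(drop=True)
    out.attrs = dict(table.attrs)
    return out


def make_windows(layout: Sequence[Chromosome], size: int, step: int | None = None,
                 exclude_sex: bool = True) -> list[Region]:
    """Tile every retained chromosome with windows of ``size`` bp.

    Default step = size (disjoint tiling); a smaller step gives true
    sliding windows.  The trailing partial window is always included.
    Sex chromosomes contribute no windows when ``exclude_sex``.
    """
    if step is None:
        step = size
    if not (size >= step >= 1):
        raise ValueError(f"require size >= step >= 1, got size={size} step={step}")
    windows: list[Region] = []
    for chrom in layout:
        if exclude_sex and chrom.is_sex_chromosome:
            continue
        start = 0
        while start < chrom.length:
            windows.append(Region(chrom.chrom, start, min(start + size, chrom.length)))
            start += step
    return windows


def make_feature_regions(genes: Iterable[GeneAnnotation], cgis: Sequence[Region],
                         layout: Sequence[Chromosome], promoter_bp: int = 2000,
                         tss_flank_bp: int = 2000) -> dict[str, list[Region]]:
    """Gene-anchored feature sets: promoters, gene bodies, CGIs, TSS-proximal.

    Promoter = the ``promoter_bp`` bases immediately upstream of the TSS
    (strand-aware); TSS-proximal = ± ``tss_flank_bp`` around the TSS.
    All regions are clipped to chromosome bounds.
    """
    if promoter_bp <= 0 or tss_flank_bp <= 0:
        raise ValueError("promoter_bp and tss_flank_bp must be positive")
    lengths = {c.chrom: c.length for c in layout}

    def clip(chrom: str, start: int, end: int, label: str) -> Region | None:
        start = max(start, 0)
        end = min(end, lengths.get(chrom, end))
        if start >= end:
            return None
        return Region(chrom, start, end, label)

    features: dict[str, list[Region]] = {"promoters": [], "gene_bodies": [],
                                         "CGIs": list(cgis), "TSS_proximal": []}
    for g in genes:
        if g.strand == "+":
            prom = clip(g.chrom, g.tss - promoter_bp, g.tss, f"prom_{g.gene_id}")
        else:
            prom = clip(g.chrom, g.tss + 1, g.tss + 1 + promoter_bp, f"prom_{g.gene_id}")
        if prom:
            features["promoters"].append(prom)
        body = clip(g.chrom, g.start, g.end, f"body_{g.gene_id}")
        if body:
            features["gene_bodies"].append(body)
        tssp = clip(g.chrom, g.tss - tss_flank_bp, g.tss + tss_flank_bp, f"tss_{g.gene_id}")
        if tssp:
            features["TSS_proximal"].append(tssp)
    return features


def aggregate_regions(tables: Mapping[str, pd.DataFrame], regions: Sequence[Region],
                      min_sites: int = 1) -> pd.DataFrame:
    """Regions × samples matrix of unweighted mean CpG levels.

    The value for (region, sample) is the plain mean of the sample's
    per-site levels inside the region — CpGs are not weighted by
    coverage.  NaN where the sample has fewer than ``min_sites`` CpGs
    with a defined level in the region.
    """
    if len(regions) == 0:
        raise ValueError("empty region list")
    index = [r.name for r in regions]
    out = pd.DataFrame(np.nan, index=index, columns=list(tables.keys()), dtype=float)
    for sample_id, table in tables.items():
        by_chrom = {
            chrom: (sub["pos"].to_numpy(), sub["level"].to_numpy())
            for chrom, sub in table.groupby("chrom", sort=False)
        }
        for r in regions:
            if r.chrom not in by_chrom:
                continue
            pos, level = by_chrom[r.chrom]
            lo, hi = np.searchsorted(pos, [r.start, r.end])
            vals = level[lo:hi]
            vals = vals[~np.isnan(vals)]
            if len(vals) >= min_sites:
                out.at[r.name, sample_id] = vals.mean()
    out.attrs["min_sites"] = min_sites
    return out


def summarize_global(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-sample mean/median/quartiles over non-missing region values."""
    if matrix.size == 0:
        raise ValueError("empty matrix")
    rows = {}
    for sample in matrix.columns:
        vals = matrix[sample].dropna()
        if vals.empty:
            raise ValueError(f"sample {sample!r} has no non-missing region values")
        rows[sample] = {
            "mean": vals.mean(),
            "q25": vals.quantile(0.25),
            "median": vals.median(),
            "q75": vals.quantile(0.75),
            "n_regions": len(vals),
        }
    return pd.DataFrame(rows).T


def pca_samples(matrix: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on complete-case regions (rows with any NaN dropped).

    Returns (coordinates DataFrame indexed by sample, variance-explained
    fractions, non-increasing, summing to ≤ 1).  Centered, not scaled.
    """
    if matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    complete = matrix.dropna(axis=0)
    if complete.shape[0] < 2:
        raise ValueError("fewer than 2 complete regions after dropping missing values")
    X = complete.to_numpy().T  # samples × regions
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, _vt = np.linalg.svd(Xc, full_matrices=False)
    coords = u * s
    var = s**2 / (X.shape[0] - 1)
    frac = var / Xc.var(axis=0, ddof=1).sum() if Xc.any() else np.zeros_like(var)
    k = min(len(s), X.shape[0] - 1)
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(coords[:, :k], index=matrix.columns, columns=cols), frac[:k]


def _pairwise_distance(X: np.ndarray, distance: str, names: Sequence[str]) -> np.ndarray:
    if distance == "euclidean":
        return ssd.pdist(X, metric="euclidean")
    if distance == "correlation":
        spread = X.std(axis=1)
        zero = np.flatnonzero(spread == 0)
        if len(zero):
            raise ValueError(f"zero-variance row under correlation distance: {names[zero[0]]!r}")
        return ssd.pdist(X, metric="correlation")
    raise ValueError(f"unknown distance {distance!r}")


def hcluster(matrix: pd.DataFrame, distance: str = "euclidean",
             linkage: str = "complete", axis: str = "samples"):
    """Complete-linkage hierarchical clustering of samples (or regions).

    Rows with missing values are dropped first.  Returns
    ``(linkage_matrix, leaf_order)`` in scipy's linkage format; ties are
    resolved by scipy's deterministic ordering of the input, so reruns on
    the same matrix give the same tree.
    """
    if linkage != "complete":
        raise ValueError("only complete linkage is supported")
    complete = matrix.dropna(axis=0)
    X = complete.to_numpy().T if axis == "samples" else complete.to_numpy()
    names = list(matrix.columns) if axis == "samples" else list(complete.index)
    if X.shape[0] < 2:
        raise ValueError("clustering needs at least 2 observations")
    d = _pairwise_distance(X, distance, names)
    Z = sch.linkage(d, method="complete")
    order = [names[i] for i in sch.leaves_list(Z)]
    return Z, order


def zscore_rows(matrix: pd.DataFrame, on_zero_spread: str = "error") -> pd.DataFrame:
    """Per-row z-scores over non-missing entries (sample sd, ddof=1).

    ``on_zero_spread``: "error" raises on a constant row, "drop" removes
    it (the policy used for heat-map displays).
    """
    means = matrix.mean(axis=1, skipna=True)
    sds = matrix.std(axis=1, ddof=1, skipna=True)
    counts = matrix.notna().sum(axis=1)
    bad = (counts < 2) | (sds == 0) | sds.isna()
    if bad.any():
        if on_zero_spread == "error":
            raise ValueError(f"zero-spread or underpopulated row: {matrix.index[bad][0]!r}")
        matrix = matrix[~bad]
        means, sds = means[~bad], sds[~bad]
    return matrix.sub(means, axis=0).div(sds, axis=0)
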