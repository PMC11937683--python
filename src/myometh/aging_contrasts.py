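"""Age-DMR classification, four-group region matrices, the
Dnmt3a-sensitivity contrast, and gene-set overlaps.

The central quantity is the per-region genotype shift at young age,
delta = mean(young Tg) − mean(young WT), computed separately over
age-hyper and age-hypo DMR sets.  The sensitivity claim under test is
that delta is larger in age-hyper regions than in age-hypo regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dmr_caller import DMR
from .methylome_core import Region, aggregate_regions, zscore_rows


@dataclass
class AgeDmrSets:
    """Partition of an old-vs-young WT DMR list by direction."""

    hyper: list[DMR]
    hypo: list[DMR]


@dataclass
class SensitivityResult:
    """Outcome of the genotype-sensitivity contrast at young age."""

    delta_hyper: float
    delta_hypo: float
    per_region_hyper: np.ndarray
    per_region_hypo: np.ndarray
    p_value: float
    conclusion: str


def classify_age_dmrs(dmrs: Sequence[DMR]) -> AgeDmrSets:
    """Split age-contrast DMRs into hyper (old > young) and hypo sets."""
    hyper = [d for d in dmrs if d.mean_diff > 0]
    hypo = [d for d in dmrs if d.mean_diff < 0]
    return AgeDmrSets(hyper=hyper, hypo=hypo)


def dmrs_to_regions(dmrs: Sequence[DMR], prefix: str = "dmr") -> list[Region]:
    return [Region(d.chrom, d.start, d.end, f"{prefix}_{i + 1}") for i, d in enumerate(dmrs)]


def region_group_matrix(regions: Sequence[Region], tables: Mapping[str, pd.DataFrame],
                        groups: Mapping[str, Sequence[str]], min_sites: int = 1):
    """Regions × samples methylation matrix with per-group mean columns.

    Returns ``(matrix, group_means, zscored)``; the z-scored copy (rows
    standardised over samples) is the heat-map representation, with
    constant rows dropped.
    """
    matrix = aggregate_regions(tables, regions, min_sites=min_sites)
    group_means = pd.DataFrame({
        g: matrix[list(ids)].mean(axis=1) for g, ids in groups.items()
    })
    zscored = zscore_rows(matrix, on_zero_spread="drop")
    return matrix, group_means, zscored


def dnmt3a_sensitivity(age_sets: AgeDmrSets, tables: Mapping[str, pd.DataFrame],
                       young_wt: Sequence[str], young_tg: Sequence[str],
                       min_sites: int = 1) -> SensitivityResult:
    """Genotype shift of age-DMR methylation at young age.

    Per region: delta = (mean level over young Tg samples) − (mean over
    young WT samples); regions where either group mean is undefined are
    dropped.  The hyper-set and hypo-set delta distributions are compared
    with a two-sided Mann–Whitney U test (rank test — deltas are bounded
    and need not be normal).
    """
    deltas = {}
    for name, dmrs in (("hyper", age_sets.hyper), ("hypo", age_sets.hypo)):
        if not dmrs:
            raise ValueError(f"age-{name}DMR set is empty")
        regions = dmrs_to_regions(dmrs, prefix=name)
        sub = {s: tables[s] for s in list(young_wt) + list(young_tg)}
        matrix = aggregate_regions(sub, regions, min_sites=min_sites)
        wt = matrix[list(young_wt)].mean(axis=1)
        tg = matrix[list(young_tg)].mean(axis=1)
        delta = (tg - wt).dropna().to_numpy()
        if len(delta) == 0:
            raise ValueError(f"age-{name}DMR set has no measurable region")
        deltas[name] = delta

    p = float(stats.mannwhitneyu(deltas["hyper"], deltas["hypo"],
                                 alternative="two-sided").pvalue)
    d_hyper, d_hypo = float(deltas["hyper"].mean()), float(deltas["hypo"].mean())
    order = ">" if d_hyper > d_hypo else ("<" if d_hyper < d_hypo else "=")
    return SensitivityResult(
        delta_hyper=d_hyper, delta_hypo=d_hypo,
        per_region_hyper=deltas["hyper"], per_region_hypo=deltas["hypo"],
        p_value=p,
        conclusion=f"delta_hyper {order} delta_hypo (MWU p={p:.3g})",
    )


def overlap_sets(a: set[str], b: set[str]) -> dict:
    """Venn partition of two gene-id sets."""
    shared = a & b
    return {
        "a_only": len(a - b), "shared": len(shared), "b_only": len(b - a),
        "a_only_genes": sorted(a - b), "shared_genes": sorted(shared),
        "b_only_genes": sorted(b - a),
    }


def overlap_with_degs(dmrg: pd.DataFrame, degs: pd.DataFrame) -> dict:
    """Join DMR-associated genes against a differential-expression table.

    ``dmrg`` needs gene_id + direction columns (from
    :func:`myometh.dmr_caller.annotate_nearest_gene`); ``degs`` needs
    gene_id + log2fc.  Duplicated gene_ids on either side are collapsed
    (first occurrence wins) with a recorded warning.
    """
    warnings: list[str] = []
    for name, df in (("dmrg", dmrg), ("degs", degs)):
        if df["gene_id"].duplicated().any():
            warnings.append(f"{name}: duplicate gene_ids collapsed")
    dmrg = dmrg.drop_duplicates("gene_id")
    degs = degs.drop_duplicates("gene_id")
    merged = dmrg.merge(degs, on="gene_id", how="inner", suffixes=("_dmr", "_deg"))
    split: dict[str, int] = {}
    if len(merged):
        deg_dir = np.where(merged["log2fc"] > 0, "up", "down")
        for dmr_dir in ("hyper", "hypo"):
            for d_dir in ("up", "down"):
                split[f"{dmr_dir}_{d_dir}"] = int(
                    ((merged["direction"] == dmr_dir) & (deg_dir == d_dir)).sum()
                )
    else:
        split = {f"{a}_{b}": 0 for a in ("hyper", "hypo") for b in ("up", "down")}
    return {
        "n_dmrg": int(dmrg["gene_id"].nunique()),
        "n_deg": int(degs["gene_id"].nunique()),
        "n_overlap": int(len(merged)),
        "split": split,
        "overlap_genes": sorted(merged["gene_id"]),
        "warnings": warnings,
    }
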