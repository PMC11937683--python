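"""Descriptive view of the simulated methylomes: 100-kb window means,
per-sample global summaries, PCA and hierarchical clustering.

Reads the coverage files written by 01_simulate_methylomes.py, applies
the >=5-read coverage filter, and reports whether the four groups
separate and whether old-WT samples sit above young-WT in median window
methylation (the global aging direction).
"""

from pathlib import Path

import pandas as pd

from myometh import io_formats
from myometh.methylome_core import (
    aggregate_regions, filter_by_coverage, hcluster, make_windows, pca_samples,
    summarize_global,
)
from myometh.io_formats import Chromosome

RESULTS = Path(__file__).resolve().parent.parent / "results"
SIM = RESULTS / "simulation"
OUT = RESULTS / "methylome"
MIN_READS = 5
CHROM_LENGTH = 2_000_000


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tables = {}
    for path in sorted(SIM.glob("*.cov.tsv")):
        sample = path.name.split(".")[0]
        tables[sample] = filter_by_coverage(io_formats.read_cpg_table(path, sample), MIN_READS)
    layout = [Chromosome("chr1", CHROM_LENGTH)]

    windows = make_windows(layout, 100_000)
    matrix = aggregate_regions(tables, windows)
    io_formats.write_matrix_tsv(matrix, OUT / "window_matrix_100kb.tsv")

    summary = summarize_global(matrix)
    summary.to_csv(OUT / "global_summary.tsv", sep="\t", float_format="%.10g")
    group = pd.Series({s: s.rsplit("_", 1)[0] for s in summary.index})
    group_medians = summary["median"].groupby(group).median()
    print("median 100-kb window methylation by group:")
    print(group_medians.to_string(float_format="%.4f"))
    gain = group_medians["oldWT"] - group_medians["youngWT"]
    print(f"global aging direction: old WT - young WT = {gain:+.4f} "
          f"({'gain' if gain > 0 else 'loss'} with age)")

    coords, var_frac = pca_samples(matrix)
    coords.to_csv(OUT / "pca_coordinates.tsv", sep="\t", float_format="%.10g")
    print(f"PCA: PC1 {var_frac[0]:.1%}, PC2 {var_frac[1]:.1%} of variance")

    _, order = hcluster(matrix, distance="euclidean")
    (OUT / "hcluster_leaf_order.txt").write_text("\n".join(order) + "\n")
    print("clustering: group blocks along the leaf order: "
          + ", ".join(dict.fromkeys(o.rsplit("_", 1)[0] for o in order)))


if __name__ == "__main__":
    main()
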