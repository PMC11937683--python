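"""MIAMI two-enzyme methylation-difference classification.

MIAMI (microarray-based integrated analysis of methylation by
isoschizomers) digests two genomic DNA samples with methylation-sensitive
HpaII and methylation-insensitive MspI and cohybridises them; the
HpaII/MspI between-sample signal ratio of each probe reflects the
methylation difference.  Probes are classified on the linear ratio
scale: < 0.714 hypomethylated, > 1.3 hypermethylated, in between
unchanged.  Normalising HpaII by the MspI ratio cancels probe-level
copy/amplification variation shared by the two digests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CLASSES = ("hypomethylated", "hypermethylated", "unchanged")


@dataclass
class MiamiThresholds:
    """Ratio cut-offs on the linear scale (published asymmetric defaults)."""

    low: float = 0.714
    high: float = 1.3
    mspi_band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.low < 1 < self.high:
            raise ValueError("require 0 < low < 1 < high")


def classify_probes(table: pd.DataFrame, thr: MiamiThresholds | None = None) -> pd.DataFrame:
    """Fill ``meth_class`` from the HpaII/MspI signal ratio.

    The classified value is hpaii_ratio / mspi_ratio when an MspI column
    is present (the two-enzyme difference), else the raw HpaII ratio.
    When ``thr.mspi_band`` is set, probes whose MspI ratio falls outside
    the band are forced to "unchanged" (copy-number guard).
    """
    thr = thr or MiamiThresholds()
    out = table.copy()
    hpaii = out["hpaii_ratio"].to_numpy(dtype=float)
    if (hpaii <= 0).any():
        bad = out.loc[hpaii <= 0, "probe_id"].iloc[0]
        raise ValueError(f"non-positive hpaii_ratio at probe {bad!r}")
    if "mspi_ratio" in out.columns:
        mspi = out["mspi_ratio"].to_numpy(dtype=float)
        if (mspi <= 0).any():
            bad = out.loc[mspi <= 0, "probe_id"].iloc[0]
            raise ValueError(f"non-positive mspi_ratio at probe {bad!r}")
        value = hpaii / mspi
    else:
        mspi = None
        value = hpaii
    meth_class = np.where(value < thr.low, "hypomethylated",
                          np.where(value > thr.high, "hypermethylated", "unchanged"))
    if thr.mspi_band is not None and mspi is not None:
        lo, hi = thr.mspi_band
        meth_class = np.where((mspi < lo) | (mspi > hi), "unchanged", meth_class)
    out["meth_class"] = meth_class
    return out


def miami_summary(table: pd.DataFrame) -> dict:
    """Class counts and the deduplicated hyper/hypomethylated gene lists."""
    if "meth_class" not in table.columns:
        raise ValueError("table is not classified; run classify_probes first")
    counts = {c: int((table["meth_class"] == c).sum()) for c in CLASSES}

    def gene_list(cls: str) -> list[str]:
        if "gene_id" not in table.columns:
            return []
        genes = table.loc[table["meth_class"] == cls, "gene_id"].dropna()
        return sorted(set(genes))

    return {
        "n_probes": int(len(table)),
        "counts": counts,
        "hypermethylated_genes": gene_list("hypermethylated"),
        "hypomethylated_genes": gene_list("hypomethylated"),
    }
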