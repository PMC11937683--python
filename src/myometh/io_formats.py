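"""Readers and writers for the on-disk formats the pipeline touches.

All in-memory coordinates are 0-based half-open.  Conversion to and from
1-based conventions (Bismark coverage files) happens only here, at the
file boundary, so no other module needs to reason about offsets.

Tables are plain :class:`pandas.DataFrame` objects with documented
columns; small record types (genes, chromosomes) are dataclasses.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

#: Columns of a per-CpG count table (one table per sample).
CPG_COLUMNS = ["chrom", "pos", "meth_count", "unmeth_count"]

#: Columns written for a called DMR (BED + statistics).
DMR_BED_COLUMNS = [
    "chrom", "start", "end", "name",
    "n_cpgs", "mean_diff", "p_ks", "p_mwu", "direction",
]


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval with its transcriptional start site (TSS).

    Coordinates are 0-based half-open; ``tss`` is ``start`` on the +
    strand and ``end - 1`` on the − strand (the first transcribed base).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end ({self.start} >= {self.end})")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class Chromosome:
    """One chromosome of the genome layout."""

    chrom: str
    length: int
    is_sex_chromosome: bool = False

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.chrom}: length must be positive")


def add_level(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with a ``level`` column = meth/(meth+unmeth), NaN at zero coverage.

    The level is always recomputed from counts; any percentage column in
    the source file is deliberately ignored.
    """
    out = table.copy()
    total = out["meth_count"] + out["unmeth_count"]
    out["level"] = out["meth_count"].where(total > 0) / total.where(total > 0)
    return out


def read_cpg_table(path: str | os.PathLike, sample_id: str, *,
                   collapse_strands: bool = False) -> pd.DataFrame:
    """Read a Bismark-coverage-style TSV into a per-CpG count table.

    Expected columns: chrom, start (1-based inclusive), end, methylation %,
    count methylated, count unmethylated.  Positions are converted to
    0-based; the percentage column is ignored and ``level`` is recomputed
    from the counts.  Rows with zero coverage are retained with NaN level.

    With ``collapse_strands=True``, adjacent rows at positions p and p+1 on
    the same chromosome (the two strands of one CpG) are merged by summing
    counts at the forward-strand position p.
    """
    try:
        raw = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start1", "end1", "pct", "meth_count", "unmeth_count"],
            dtype={"chrom": str},
        )
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValueError(f"{path}: malformed coverage file: {exc}") from exc
    for col in ("start1", "meth_count", "unmeth_count"):
        numeric = pd.to_numeric(raw[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ValueError(f"{path}: malformed value in column {col!r} at line {line}")
        raw[col] = numeric.astype(int)
    if (raw["meth_count"] < 0).any() or (raw["unmeth_count"] < 0).any():
        line = int(((raw["meth_count"] < 0) | (raw["unmeth_count"] < 0)).idxmax()) + 1
        raise ValueError(f"{path}: negative read count at line {line}")

    table = pd.DataFrame({
        "chrom": raw["chrom"],
        "pos": raw["start1"] - 1,
        "meth_count": raw["meth_count"],
        "unmeth_count": raw["unmeth_count"],
    })
    table = table.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    if collapse_strands:
        table = _collapse_strands(table)
    table = add_level(table)
    table.attrs["sample_id"] = sample_id
    return table


def _collapse_strands(table: pd.DataFrame) -> pd.DataFrame:
    """Sum counts of ±1-adjacent rows onto the forward-strand (lower) position."""
    same_chrom = table["chrom"].eq(table["chrom"].shift())
    adjacent = table["pos"].diff().eq(1) & same_chrom
    # rows flagged `adjacent` are reverse-strand mates of the previous row
    group = (~adjacent).cumsum()
    collapsed = (
        table.assign(_g=group)
        .groupby("_g", sort=False)
        .agg(chrom=("chrom", "first"), pos=("pos", "first"),
             meth_count=("meth_count", "sum"), unmeth_count=("unmeth_count", "sum"))
        .reset_index(drop=True)
    )
    return collapsed


def write_cpg_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a per-CpG count table as a Bismark-coverage-style TSV (1-based)."""
    total = table["meth_count"] + table["unmeth_count"]
    pct = (100.0 * table["meth_count"] / total.where(total > 0)).fillna(0.0)
    out = pd.DataFrame({
        "chrom": table["chrom"],
        "start1": table["pos"] + 1,
        "end1": table["pos"] + 1,
        "pct": pct.map("{:.6g}".format),
        "meth_count": table["meth_count"],
        "unmeth_count": table["unmeth_count"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_gene_bed(path: str | os.PathLike) -> list[GeneAnnotation]:
    """Read gene annotations from a BED6 file (0-based half-open, strand required)."""
    genes: list[GeneAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}:{lineno}: BED6 requires 6 columns (strand missing?)")
            chrom, start, end, name, _score, strand = fields[:6]
            genes.append(GeneAnnotation(name, chrom, int(start), int(end), strand))
    return genes


def write_gene_bed(genes: Iterable[GeneAnnotation], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")


def write_dmr_bed(dmrs: Sequence, path: str | os.PathLike) -> None:
    """Write called DMRs as BED with statistics columns (header line included).

    Accepts any sequence of objects with chrom/start/end/n_cpgs/mean_diff/
    p_ks/p_mwu/direction attributes (see :class:`myometh.dmr_caller.DMR`).
    """
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(DMR_BED_COLUMNS) + "\n")
        for i, d in enumerate(dmrs):
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\tdmr_{i + 1}\t{d.n_cpgs}\t"
                f"{d.mean_diff:.6g}\t{d.p_ks:.6g}\t{d.p_mwu:.6g}\t{d.direction}\n"
            )


def read_dmr_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read a DMR BED written by :func:`write_dmr_bed` back into a DataFrame."""
    table = pd.read_csv(path, sep="\t", header=0)
    table = table.rename(columns={table.columns[0]: "chrom"})
    table["chrom"] = table["chrom"].astype(str)
    return table


def write_matrix_tsv(matrix: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a regions × samples matrix as TSV (region labels in the index)."""
    matrix.to_csv(path, sep="\t", index=True, float_format="%.10g")


def read_matrix_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_feeding_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a fed/fasted/refed phenotype table.

    Columns: mouse_id, genotype, state, tissue_or_gene, value.  Values must
    be positive; each mouse carries exactly one feeding state.
    """
    table = pd.read_csv(path, sep="\t", dtype={"mouse_id": str})
    required = {"mouse_id", "genotype", "state", "tissue_or_gene", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad_state = ~table["state"].isin(["fed", "fasted", "refed"])
    if bad_state.any():
        raise ValueError(f"{path}: unknown feeding state {table.loc[bad_state, 'state'].iloc[0]!r}")
    table["value"] = table["value"].astype(float)
    if (table["value"] <= 0).any():
        raise ValueError(f"{path}: values must be positive")
    states = table.groupby("mouse_id")["state"].nunique()
    if (states > 1).any():
        mouse = states[states > 1].index[0]
        raise ValueError(f"{path}: mouse {mouse!r} appears in more than one feeding state")
    return table


def write_feeding_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_miami_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a two-enzyme (HpaII/MspI) probe signal-ratio table.

    Columns: probe_id, optional gene_id, hpaii_ratio, mspi_ratio (linear
    scale, positive).
    """
    table = pd.read_csv(path, sep="\t")
    for col in ("probe_id", "hpaii_ratio"):
        if col not in table.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return table


def write_miami_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
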