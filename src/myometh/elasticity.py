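"""Tissue Elasticity Score (ElaS) and fed/fasted/refed responsiveness.

ElaS quantifies how fully a tissue rebounds from fasting on refeeding.
Weights are first normalised within genotype to the fasted-group mean:

    X_i = fed_i   / mean(fasted) * 100 - 100      (per fed mouse)
    Y_j = refed_j / mean(fasted) * 100 - 100      (per refed mouse)

and the score follows the published spreadsheet formula verbatim, with
y = Y - 100 and A = mean over fed mice of (X - 100):

    Value1 = (y + A) * min(y, A) / max(y, A)
    Value2 = Value1 if y > 0 else -Value1
    ElaS   = -Value2 if (|y| > A and y < 0) else Value2

The two extra "-100" subtractions (X and Y are already percent-change
values) are part of the published formula and are reproduced exactly;
see docs/methods.md for the consequences.  When max(y, A) = 0 the score
is undefined; it is reported as 0 with a degenerate flag so batch runs
complete.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ElasResult:
    """Per genotype × tissue ElaS summary."""

    genotype: str
    tissue: str
    x_per_fed_mouse: np.ndarray
    y_per_refed_mouse: np.ndarray
    elas_per_refed_mouse: np.ndarray
    degenerate_flags: np.ndarray
    group_mean: float
    group_se: float


def normalize_to_fasted(table: pd.DataFrame, genotype: str, tissue: str):
    """(X values, Y values, fasted mean) for one genotype × tissue cell.

    Normalisation is within genotype: each genotype's fed and refed
    values are expressed relative to its own fasted-group mean.
    """
    cell = table[(table["genotype"] == genotype) & (table["tissue_or_gene"] == tissue)]
    fasted = cell.loc[cell["state"] == "fasted", "value"].to_numpy(dtype=float)
    if len(fasted) == 0 or fasted.mean() == 0:
        raise ValueError(f"{genotype}/{tissue}: fasted group absent or zero mean")
    fasted_mean = float(fasted.mean())
    fed = cell.loc[cell["state"] == "fed", "value"].to_numpy(dtype=float)
    refed = cell.loc[cell["state"] == "refed", "value"].to_numpy(dtype=float)
    x = fed / fasted_mean * 100.0 - 100.0
    y = refed / fasted_mean * 100.0 - 100.0
    return x, y, fasted_mean


def elas_score(Y: float, A: float) -> tuple[float, bool]:
    """ElaS for one refed mouse given its Y and the fed-group constant A.

    A is the mean over fed mice of (X − 100), fixed per genotype ×
    tissue.  Returns (score, degenerate); degenerate means
    max(Y−100, A) = 0, where the formula's division is undefined and 0
    is reported.
    """
    y = Y - 100.0
    hi = max(y, A)
    if hi == 0:
        return 0.0, True
    value1 = (y + A) * min(y, A) / hi
    value2 = value1 if y > 0 else -value1
    if abs(y) > A and y < 0:
        return -value2, False
    return value2, False


def elas_table(table: pd.DataFrame, tissues: list[str] | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ElaS per genotype × tissue, plus between-genotype t-test comparisons.

    Returns ``(scores, comparisons)``: one row per refed mouse in
    ``scores`` (with group mean ± SE repeated per group), and one row per
    tissue in ``comparisons`` with the WT-vs-Tg two-sided unpaired
    Student's t-test on per-mouse scores.  Degenerate scores are excluded
    from group summaries and tests; a single-mouse group reports SE as
    NaN.
    """
    genotypes = sorted(table["genotype"].unique())
    if tissues is None:
        tissues = sorted(table["tissue_or_gene"].unique())
    rows = []
    per_group: dict[tuple[str, str], np.ndarray] = {}
    for genotype in genotypes:
        for tissue in tissues:
            x, y_vals, _ = normalize_to_fasted(table, genotype, tissue)
            if len(x) == 0:
                raise ValueError(f"{genotype}/{tissue}: no fed mice")
            A = float(np.mean(x - 100.0))
            scores, flags = zip(*(elas_score(Y, A) for Y in y_vals)) if len(y_vals) else ((), ())
            scores = np.asarray(scores, dtype=float)
            flags = np.asarray(flags, dtype=bool)
            valid = scores[~flags]
            per_group[(genotype, tissue)] = valid
            mean = float(valid.mean()) if len(valid) else np.nan
            se = float(valid.std(ddof=1) / np.sqrt(len(valid))) if len(valid) > 1 else np.nan
            for j, (s, f) in enumerate(zip(scores, flags)):
                rows.append({
                    "genotype": genotype, "tissue": tissue, "refed_index": j + 1,
                    "Y": y_vals[j], "A": A, "elas": s, "degenerate": bool(f),
                    "group_mean": mean, "group_se": se,
                })
    scores_df = pd.DataFrame(rows)

    comparisons = []
    if len(genotypes) >= 2:
        g1, g2 = genotypes[0], genotypes[1]
        for tissue in tissues:
            a, b = per_group.get((g1, tissue)), per_group.get((g2, tissue))
            if a is None or b is None or len(a) < 2 or len(b) < 2:
                t, p = np.nan, np.nan
            else:
                t, p = stats.ttest_ind(a, b, equal_var=True)
            comparisons.append({
                "tissue": tissue, "group_1": g1, "group_2": g2,
                "mean_1": float(np.mean(a)) if a is not None and len(a) else np.nan,
                "mean_2": float(np.mean(b)) if b is not None and len(b) else np.nan,
                "t_stat": float(t), "p_value": float(p),
            })
    return scores_df, pd.DataFrame(comparisons)


def gene_responsiveness(table: pd.DataFrame) -> pd.DataFrame:
    """Fasting induction and refeeding restoration per gene × genotype.

    induction   = mean(fasted) / mean(fed)
    restoration = 1 − |mean(refed) − mean(fed)| / |mean(fasted) − mean(fed)|

    restoration is 1 when refeeding returns expression to the fed level
    and 0 when it stays at the fasted level; it is undefined (NaN,
    flagged) when fasting did not move the gene at all.
    """
    rows = []
    for (genotype, gene), cell in table.groupby(["genotype", "tissue_or_gene"]):
        means = cell.groupby("state")["value"].mean()
        for state in ("fed", "fasted", "refed"):
            if state not in means:
                raise ValueError(f"{genotype}/{gene}: missing state {state!r}")
        if means["fed"] == 0:
            raise ValueError(f"{genotype}/{gene}: zero fed mean")
        induction = means["fasted"] / means["fed"]
        denom = abs(means["fasted"] - means["fed"])
        if denom == 0:
            restoration, flagged = np.nan, True
        else:
            restoration = 1.0 - abs(means["refed"] - means["fed"]) / denom
            flagged = False
        rows.append({
            "genotype": genotype, "gene": gene,
            "induction": float(induction), "restoration": float(restoration),
            "restoration_undefined": flagged,
        })
    return pd.DataFrame(rows)
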