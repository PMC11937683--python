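"""Standard simulation scenarios and their evaluation.

These functions pin down the study conditions used throughout the test
suite and the reproduction script: the planted-DMR recovery scenario,
the null (no-effect) scenario, the genotype-sensitivity replicates, the
global aging direction, the elasticity rho sweep, and the MIAMI probe
recovery.  Every function takes an explicit seed and is deterministic
given it.  Problem sizes (one 2-Mb chromosome, ~20k CpGs, n = 4 per
group, coverage 20) are chosen so a full sweep runs in minutes on one
CPU while keeping Monte-Carlo error well below the effects under test.
"""

from __future__ import annotations

import numpy as np

from .aging_contrasts import classify_age_dmrs, dnmt3a_sensitivity
from .dmr_caller import DmrParams, call_dmrs, reciprocal_overlap_stats
from .elasticity import elas_table
from .methylome_core import aggregate_regions, filter_by_coverage, make_windows, summarize_global
from .miami_array import classify_probes, miami_summary
from .synthetic_data import (
    FeedingSimParams,
    SimDesign,
    SimEffects,
    simulate_feeding,
    simulate_genome,
    simulate_methylomes,
    simulate_miami,
)

#: Published strict DMR filter (tibialis-anterior mode): p(KS) < 0.01, |diff| > 0.20.
STRICT_PARAMS = DmrParams(p_threshold=0.01, diff_threshold=0.20)


def standard_design(seed: int, n_per_group: int = 4,
                    chrom_length: int = 2_000_000) -> SimDesign:
    """The 2×2 (WT/Tg × young/old) design: coverage 20, ~20k CpGs."""
    return SimDesign(n_per_group=n_per_group, chrom_lengths={"chr1": chrom_length},
                     cpg_spacing_mean=100, coverage_mean=20.0, seed=seed)


def standard_effects() -> SimEffects:
    """Planted effects of the standard aging scenario.

    50 regions of 15 CpGs (25 hyper + 25 hypo), age shift 0.30, genotype
    shift 0.15 in hyper vs 0.03 in hypo regions, global aging gain 0.02.
    """
    return SimEffects()


def null_effects() -> SimEffects:
    """No planted effects anywhere (type-I-error scenario)."""
    return SimEffects(n_age_hyper=0, n_age_hypo=0, age_effect_background=0.0,
                      tg_effect_in_hyper=0.0, tg_effect_in_hypo=0.0)


def _simulate_filtered(seed: int, effects: SimEffects, min_reads: int = 5,
                       chrom_length: int = 2_000_000):
    design = standard_design(seed, chrom_length=chrom_length)
    genome = simulate_genome(design, effects)
    tables = {s: filter_by_coverage(t, min_reads)
              for s, t in simulate_methylomes(genome, design, effects).items()}
    return design, genome, tables


def dmr_recovery(seed: int) -> dict:
    """Recall/precision of the caller on the standard planted scenario."""
    design, genome, tables = _simulate_filtered(seed, standard_effects())
    ids = design.sample_ids()
    dmrs = call_dmrs(tables, ids["youngWT"], ids["oldWT"], STRICT_PARAMS)
    return reciprocal_overlap_stats(dmrs, genome[3])


def dmr_null_fraction(seeds: range | list[int]) -> dict:
    """Fraction of candidate regions called as DMRs on null simulations."""
    from .dmr_caller import build_site_matrix, segment_candidates

    n_candidates = n_called = 0
    for seed in seeds:
        design, _genome, tables = _simulate_filtered(seed, null_effects(),
                                                     chrom_length=1_000_000)
        ids = design.sample_ids()
        site_matrix = build_site_matrix(tables, ids["youngWT"], ids["oldWT"])
        n_candidates += len(segment_candidates(site_matrix, STRICT_PARAMS))
        n_called += len(call_dmrs(tables, ids["youngWT"], ids["oldWT"], STRICT_PARAMS))
    return {"n_candidates": n_candidates, "n_called": n_called,
            "fraction": n_called / n_candidates if n_candidates else 0.0}


def sensitivity_replicate(seed: int) -> dict:
    """One full replicate of the genotype-sensitivity analysis.

    Calls age DMRs (old WT vs young WT), classifies them, and measures
    the young Tg-vs-WT shift per region set.
    """
    design, _genome, tables = _simulate_filtered(seed, standard_effects())
    ids = design.sample_ids()
    dmrs = call_dmrs(tables, ids["youngWT"], ids["oldWT"], STRICT_PARAMS)
    sets = classify_age_dmrs(dmrs)
    result = dnmt3a_sensitivity(sets, tables, ids["youngWT"], ids["youngTg"])
    return {"delta_hyper": result.delta_hyper, "delta_hypo": result.delta_hypo,
            "p_value": result.p_value,
            "ordering_ok": result.delta_hyper > result.delta_hypo}


def aging_direction(seed: int, window_size: int = 100_000) -> dict:
    """Old-WT vs young-WT median window methylation on the standard scenario."""
    design, genome, tables = _simulate_filtered(seed, standard_effects())
    ids = design.sample_ids()
    windows = make_windows(genome[0], window_size)
    matrix = aggregate_regions(tables, windows)
    summary = summarize_global(matrix)
    med = {g: float(np.median([summary.loc[s, "median"] for s in samples]))
           for g, samples in ids.items()}
    return {"median_old_wt": med["oldWT"], "median_young_wt": med["youngWT"],
            "old_minus_young": med["oldWT"] - med["youngWT"]}


def feeding_mean_elas(rho: float, seed: int, tissue: str = "gastrocnemius",
                      cv: float = 0.05, n_per_state: int = 8) -> float:
    """Group-mean ElaS of one simulated feeding cohort with planted rho."""
    table = simulate_feeding(FeedingSimParams(elasticity_rho=rho, cv=cv,
                                              n_per_state=n_per_state, seed=seed))
    scores, _ = elas_table(table)
    return float(scores.loc[scores["tissue"] == tissue, "elas"].mean())


def elas_rho_sweep(seed: int, n_replicates: int = 4,
                   rhos: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)) -> dict:
    """Replicate-mean ElaS per planted rho (monotone-recovery check)."""
    means = {}
    for rho in rhos:
        reps = [feeding_mean_elas(rho, seed * 1000 + r) for r in range(n_replicates)]
        means[rho] = float(np.mean(reps))
    values = [means[r] for r in rhos]
    return {"means": means, "monotone": all(b >= a for a, b in zip(values, values[1:]))}


def elas_separation(seed: int, n_replicates: int = 20,
                    rho_high: float = 1.0, rho_low: float = 0.2) -> dict:
    """How often full restoration scores above partial restoration."""
    wins = sum(
        feeding_mean_elas(rho_high, seed * 1000 + r) > feeding_mean_elas(rho_low, seed * 1000 + r)
        for r in range(n_replicates)
    )
    return {"n_replicates": n_replicates, "wins": wins, "rate": wins / n_replicates}


def miami_recovery(seed: int, n_probes: int = 10_000, frac: float = 0.1,
                   noise_sd: float = 0.1) -> dict:
    """Planted-fraction recovery of the probe classification."""
    table = simulate_miami(n_probes, frac, frac, float(np.log(2)), noise_sd, seed=seed)
    classified = classify_probes(table)
    counts = miami_summary(classified)["counts"]
    return {
        "frac_hyper": counts["hypermethylated"] / n_probes,
        "frac_hypo": counts["hypomethylated"] / n_probes,
        "planted": frac,
        "binomial_se": float(np.sqrt(frac * (1 - frac) / n_probes)),
        "n_conserved": sum(counts.values()) == n_probes,
    }
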