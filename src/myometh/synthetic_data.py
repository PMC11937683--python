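"""Synthetic inputs with the statistical structure the analysis assumes.

Four generators cover the pipeline end to end:

* :func:`simulate_genome` — chromosome layout, CpG positions with
  exponential spacing, a regular gene grid, and disjoint planted regions
  (future age-hyper/hypo DMRs) each spanning a fixed number of
  consecutive CpGs.
* :func:`simulate_methylomes` — per-sample per-CpG beta-binomial read
  counts for the 2×2 genotype (WT/Tg) × age (young/old) design, with a
  small global aging gain, planted age effects inside the planted
  regions, and genotype shifts that are stronger inside age-hyper
  regions than age-hypo regions.
* :func:`simulate_feeding` — fed/fasted/refed tissue weights (or
  expression) with lognormal noise and a planted restoration fraction
  ``rho`` (refed mean = fasted + rho × (fed − fasted)).
* :func:`simulate_miami` — two-enzyme array probe log-ratios with
  planted hyper/hypo fractions.

All randomness flows through one global seed; each sample/stage derives
an independent sub-stream keyed on stable identifiers, so adding samples
does not perturb existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import Chromosome, GeneAnnotation, add_level

GROUPS = ("youngWT", "oldWT", "youngTg", "oldTg")


def substream(seed: int, *keys) -> np.random.Generator:
    """Derive an independent RNG stream from a global seed and stable keys.

    String keys are hashed with CRC-32 so the stream depends only on the
    key's value, not on Python's per-process hash randomization.
    """
    ints = [int(seed) & 0xFFFFFFFF]
    for key in keys:
        if isinstance(key, (int, np.integer)):
            ints.append(int(key) & 0xFFFFFFFF)
        else:
            ints.append(zlib.crc32(str(key).encode()))
    return np.random.default_rng(ints)


@dataclass
class SimDesign:
    """Sample layout and genome geometry of a methylome simulation."""

    n_per_group: int = 4
    groups: tuple[str, ...] = GROUPS
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 2_000_000})
    cpg_spacing_mean: int = 100
    coverage_mean: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        unknown = set(self.groups) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown groups: {sorted(unknown)}")

    def sample_ids(self) -> dict[str, list[str]]:
        """Per-group sample identifiers, e.g. ``youngWT_1 .. youngWT_n``."""
        return {g: [f"{g}_{i + 1}" for i in range(self.n_per_group)] for g in self.groups}


@dataclass
class SimEffects:
    """Planted effect sizes, on the methylation-proportion scale.

    ``age_effect`` is the within-region shift of old samples (+ in
    age-hyper regions, − in age-hypo regions); ``age_effect_background``
    is a small genome-wide gain in old samples, giving the global upward
    drift of the aging methylome.  ``tg_effect_in_hyper`` >
    ``tg_effect_in_hypo`` encodes genotype sensitivity concentrated in
    age-hyper regions.  ``overdispersion`` is the intra-class correlation
    of the beta-binomial read counts; 0 reduces to plain binomial.
    """

    baseline_beta: tuple[float, float] = (6.0, 6.0)
    n_age_hyper: int = 25
    n_age_hypo: int = 25
    region_n_cpgs: int = 15
    age_effect: float = 0.30
    age_effect_background: float = 0.02
    tg_effect_in_hyper: float = 0.15
    tg_effect_in_hypo: float = 0.03
    tg_effect_background: float = 0.0
    overdispersion: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.age_effect < 1:
            raise ValueError("age_effect must be in (0, 1)")
        if self.overdispersion < 0 or self.overdispersion >= 1:
            raise ValueError("overdispersion must be in [0, 1)")
        if min(self.baseline_beta) <= 0:
            raise ValueError("baseline_beta shape parameters must be positive")


@dataclass
class FeedingSimParams:
    """Fed/fasted/refed phenotype simulation for one genotype.

    Means are in the units of the measured quantity (mg for tissue
    weights).  ``elasticity_rho`` sets the refed mean to
    fasted + rho × (fed − fasted): rho=1 is full restoration, rho=0 none.
    ``cv`` is the standard deviation of the lognormal noise on the log
    scale.
    """

    tissues: tuple[str, ...] = ("liver", "gastrocnemius")
    fed_mean: dict[str, float] = field(default_factory=lambda: {"liver": 1300.0, "gastrocnemius": 150.0})
    fasted_mean: dict[str, float] = field(default_factory=lambda: {"liver": 900.0, "gastrocnemius": 130.0})
    elasticity_rho: float = 1.0
    cv: float = 0.05
    n_per_state: int = 8
    seed: int = 0
    genotype: str = "WT"

    def __post_init__(self) -> None:
        if not 0 <= self.elasticity_rho <= 1:
            raise ValueError("elasticity_rho must be in [0, 1]")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        for t in self.tissues:
            if self.fed_mean[t] <= 0 or self.fasted_mean[t] <= 0:
                raise ValueError(f"tissue {t}: means must be positive")


def simulate_genome(
    design: SimDesign,
    effects: SimEffects,
    *,
    gene_spacing: int = 10_000,
    region_max_gap_bp: int = 300,
    sex_chromosomes: tuple[str, ...] = ("chrX", "chrY"),
):
    """Simulate the genomic scaffold: layout, CpG positions, genes, planted regions.

    Returns ``(layout, cpg_positions, genes, planted)`` where
    ``cpg_positions`` maps chrom → sorted int array and ``planted`` is a
    DataFrame (chrom, start, end, first_idx, last_idx, kind) with kind in
    {age_hyper, age_hypo}.  Planted regions are disjoint, each spanning
    ``effects.region_n_cpgs`` consecutive CpGs, and are placed only on
    CpG-dense runs (internal gaps ≤ ``region_max_gap_bp``), where DMRs of
    real methylomes live.
    """
    layout = [
        Chromosome(c, length, is_sex_chromosome=c in sex_chromosomes)
        for c, length in design.chrom_lengths.items()
    ]
    rng = substream(design.seed, "genome")
    positions: dict[str, np.ndarray] = {}
    for chrom in layout:
        n_expected = int(chrom.length / design.cpg_spacing_mean * 1.3) + 10
        gaps = rng.exponential(design.cpg_spacing_mean, size=n_expected)
        pos = np.cumsum(gaps).astype(np.int64)
        pos = np.unique(pos[pos < chrom.length])
        positions[chrom.chrom] = pos

    genes: list[GeneAnnotation] = []
    for chrom in layout:
        k = 0
        for start in range(1_000, chrom.length - gene_spacing // 2, gene_spacing):
            k += 1
            strand = "+" if k % 2 == 1 else "-"
            genes.append(GeneAnnotation(f"{chrom.chrom}_g{k}", chrom.chrom,
                                        start, start + gene_spacing // 2, strand))

    planted = _place_regions(positions, layout, effects, region_max_gap_bp,
                             substream(design.seed, "regions"))
    return layout, positions, genes, planted


def _place_regions(positions, layout, effects: SimEffects, max_gap: int,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Pick disjoint runs of ``region_n_cpgs`` consecutive dense CpGs."""
    n_regions = effects.n_age_hyper + effects.n_age_hypo
    rows = []
    if n_regions == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "first_idx", "last_idx", "kind"])

    # candidate start indices: windows whose internal gaps are all <= max_gap
    candidates: list[tuple[str, int]] = []
    for chrom in layout:
        if chrom.is_sex_chromosome:
            continue
        pos = positions[chrom.chrom]
        if len(pos) < effects.region_n_cpgs:
            continue
        gaps_ok = np.diff(pos) <= max_gap
        w = effects.region_n_cpgs - 1
        dense = np.convolve(gaps_ok.astype(int), np.ones(w, dtype=int), mode="valid") == w
        candidates.extend((chrom.chrom, int(i)) for i in np.flatnonzero(dense))

    rng.shuffle(candidates)
    taken: dict[str, list[tuple[int, int]]] = {}
    chosen: list[tuple[str, int]] = []
    for chrom_name, i in candidates:
        lo, hi = i, i + effects.region_n_cpgs  # CpG index range, half-open
        spans = taken.setdefault(chrom_name, [])
        # keep a one-CpG buffer so planted regions never touch
        if all(hi + 1 <= a or b + 1 <= lo for a, b in spans):
            spans.append((lo, hi))
            chosen.append((chrom_name, i))
            if len(chosen) == n_regions:
                break
    if len(chosen) < n_regions:
        raise ValueError(
            f"genome too short / too sparse to host {n_regions} planted regions "
            f"of {effects.region_n_cpgs} dense CpGs (placed {len(chosen)})"
        )

    kinds = ["age_hyper"] * effects.n_age_hyper + ["age_hypo"] * effects.n_age_hypo
    for (chrom_name, i), kind in zip(chosen, kinds):
        pos = positions[chrom_name]
        rows.append({
            "chrom": chrom_name,
            "start": int(pos[i]),
            "end": int(pos[i + effects.region_n_cpgs - 1]) + 1,
            "first_idx": i,
            "last_idx": i + effects.region_n_cpgs - 1,
            "kind": kind,
        })
    planted = pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
    return planted


def group_mean_levels(pi: np.ndarray, region_kind: np.ndarray, group: str,
                      effects: SimEffects) -> np.ndarray:
    """Expected methylation level per CpG for one group, clipped to [0, 1].

    ``region_kind`` codes each CpG as 0 (background), +1 (age-hyper
    region) or −1 (age-hypo region).
    """
    mu = pi.astype(float).copy()
    old = group.startswith("old")
    tg = group.endswith("Tg")
    if old:
        mu += effects.age_effect_background
        mu += effects.age_effect * (region_kind == 1)
        mu -= effects.age_effect * (region_kind == -1)
    if tg:
        mu += effects.tg_effect_background
        mu += effects.tg_effect_in_hyper * (region_kind == 1)
        mu += effects.tg_effect_in_hypo * (region_kind == -1)
    return np.clip(mu, 0.0, 1.0)


def simulate_methylomes(genome, design: SimDesign, effects: SimEffects) -> dict[str, pd.DataFrame]:
    """Beta-binomial per-CpG count tables for every sample of the design.

    Per CpG i a baseline level pi ~ Beta(a, b) is shared by all samples;
    each group's expected level adds the planted shifts (see
    :func:`group_mean_levels`).  Per sample: total ~ Poisson(coverage),
    meth ~ BetaBinomial(total, mu, overdispersion), where overdispersion
    is the intra-class correlation (0 → binomial).
    """
    layout, positions, _genes, planted = genome
    a, b = effects.baseline_beta
    tables: dict[str, pd.DataFrame] = {}

    chrom_arrays = []
    for chrom in layout:
        pos = positions[chrom.chrom]
        kind = np.zeros(len(pos), dtype=np.int8)
        if len(planted):
            for row in planted[planted["chrom"] == chrom.chrom].itertuples():
                kind[row.first_idx:row.last_idx + 1] = 1 if row.kind == "age_hyper" else -1
        chrom_arrays.append((chrom.chrom, pos, kind))

    pi_by_chrom = {
        name: substream(design.seed, "baseline", name).beta(a, b, size=len(pos))
        for name, pos, _ in chrom_arrays
    }

    rho = effects.overdispersion
    for group, ids in design.sample_ids().items():
        for sample_id in ids:
            frames = []
            for name, pos, kind in chrom_arrays:
                mu = group_mean_levels(pi_by_chrom[name], kind, group, effects)
                rng = substream(design.seed, "counts", sample_id, name)
                total = rng.poisson(design.coverage_mean, size=len(pos))
                if rho > 0:
                    theta = (1.0 - rho) / rho
                    alpha = np.clip(mu * theta, 1e-9, None)
                    beta_p = np.clip((1.0 - mu) * theta, 1e-9, None)
                    q = rng.beta(alpha, beta_p)
                else:
                    q = mu
                meth = rng.binomial(total, q)
                frames.append(pd.DataFrame({
                    "chrom": name, "pos": pos,
                    "meth_count": meth, "unmeth_count": total - meth,
                }))
            table = add_level(pd.concat(frames, ignore_index=True))
            table.attrs["sample_id"] = sample_id
            table.attrs["group"] = group
            tables[sample_id] = table
    return tables


def simulate_feeding(params: FeedingSimParams) -> pd.DataFrame:
    """One FeedingTable (mouse × tissue × state rows) for one genotype.

    Each mouse is measured in exactly one state; weights are
    state-mean × LogNormal(0, cv), so cv→0 collapses every weight onto
    its state mean.
    """
    rows = []
    for state in ("fed", "fasted", "refed"):
        for i in range(params.n_per_state):
            mouse = f"{params.genotype}_{state}_{i + 1}"
            for tissue in params.tissues:
                fed, fasted = params.fed_mean[tissue], params.fasted_mean[tissue]
                if state == "fed":
                    mean = fed
                elif state == "fasted":
                    mean = fasted
                else:
                    mean = fasted + params.elasticity_rho * (fed - fasted)
                rng = substream(params.seed, "feeding", params.genotype, state, i, tissue)
                noise = np.exp(rng.normal(0.0, params.cv)) if params.cv > 0 else 1.0
                rows.append({
                    "mouse_id": mouse, "genotype": params.genotype, "state": state,
                    "tissue_or_gene": tissue, "value": mean * noise,
                })
    return pd.DataFrame(rows)


def simulate_miami(n_probes: int, frac_hyper: float, frac_hypo: float,
                   effect_logfc: float, noise_sd: float, seed: int = 0) -> pd.DataFrame:
    """Two-enzyme array probe table with planted methylation classes.

    The MspI log-ratio carries probe-level variation shared by both
    enzymes (copy/amplification effects); the HpaII log-ratio adds the
    class shift (±effect_logfc, natural log) plus independent noise.
    True classes are recorded in ``true_class``.
    """
    if frac_hyper + frac_hypo > 1:
        raise ValueError("frac_hyper + frac_hypo must be <= 1")
    rng = substream(seed, "miami")
    u = rng.random(n_probes)
    true_class = np.where(u < frac_hyper, "hypermethylated",
                          np.where(u < frac_hyper + frac_hypo, "hypomethylated", "unchanged"))
    shift = np.where(true_class == "hypermethylated", effect_logfc,
                     np.where(true_class == "hypomethylated", -effect_logfc, 0.0))
    log_mspi = rng.normal(0.0, noise_sd, size=n_probes) if noise_sd > 0 else np.zeros(n_probes)
    log_hpaii = log_mspi + shift + (rng.normal(0.0, noise_sd, size=n_probes)
                                    if noise_sd > 0 else 0.0)
    return pd.DataFrame({
        "probe_id": [f"probe_{i + 1}" for i in range(n_probes)],
        "gene_id": [f"gene_{i // 2 + 1}" for i in range(n_probes)],
        "hpaii_ratio": np.exp(log_hpaii),
        "mspi_ratio": np.exp(log_mspi),
        "true_class": true_class,
    })
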