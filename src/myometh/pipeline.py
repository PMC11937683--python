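"""Config-driven orchestration of end-to-end runs.

A YAML scenario file fully specifies a run: simulation parameters (or
paths to real inputs), the stages to execute, the coverage filter and
the DMR/MIAMI thresholds.  ``run_pipeline`` executes the stages in
order, writes every output with a sha256 checksum into a JSON manifest,
and stops at the first failing stage.  Deterministic stages are
byte-identical across reruns with the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats, methylome_core, synthetic_data
from .aging_contrasts import classify_age_dmrs, dnmt3a_sensitivity, dmrs_to_regions, region_group_matrix
from .dmr_caller import DmrParams, annotate_nearest_gene, call_dmrs
from .elasticity import elas_table
from .miami_array import MiamiThresholds, classify_probes, miami_summary

STAGES = ("simulate", "methylome", "dmr", "aging", "miami", "elas")

#: Published filter presets: strict (tibialis anterior) and relaxed
#: (gastrocnemius) p/diff thresholds.
TISSUE_MODES = {
    "TA": {"p_threshold": 0.01, "diff_threshold": 0.20},
    "gastrocnemius": {"p_threshold": 0.05, "diff_threshold": 0.10},
}

_KNOWN_KEYS = {
    "stages", "output_dir", "seed", "coverage_min", "tissue_mode",
    "simulation", "dmr_params", "miami", "feeding", "window_size", "window_step",
}
_SIM_KEYS = {
    "n_per_group", "groups", "chrom_lengths", "cpg_spacing_mean", "coverage_mean",
    "baseline_beta", "n_age_hyper", "n_age_hypo", "region_n_cpgs", "age_effect",
    "age_effect_background", "tg_effect_in_hyper", "tg_effect_in_hypo",
    "tg_effect_background", "overdispersion",
}


@dataclass
class RunConfig:
    stages: list[str]
    output_dir: str
    seed: int = 0
    coverage_min: int = 5
    tissue_mode: str = "gastrocnemius"
    window_size: int = 100_000
    window_step: int | None = None
    simulation: dict = field(default_factory=dict)
    dmr_params: DmrParams = field(default_factory=DmrParams)
    thresholds: MiamiThresholds = field(default_factory=MiamiThresholds)
    miami: dict = field(default_factory=dict)
    feeding: dict = field(default_factory=dict)


def validate_config(path: str | Path) -> RunConfig:
    """Parse and schema-check a YAML scenario file, filling defaults.

    The tissue mode sets the published DMR filter preset ("TA" → p<0.01,
    diff>0.20; "gastrocnemius" → p<0.05, diff>0.10) unless the config
    overrides individual values.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    sim = raw.get("simulation") or {}
    unknown_sim = set(sim) - _SIM_KEYS
    if unknown_sim:
        raise ValueError(f"unknown simulation key(s): {sorted(unknown_sim)}")

    stages = raw.get("stages", list(STAGES))
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stage(s): {bad}")
    order = {s: i for i, s in enumerate(STAGES)}
    if sorted(stages, key=order.get) != stages:
        raise ValueError(f"stages out of dependency order: {stages}")
    if any(s in stages for s in ("methylome", "dmr", "aging")) and "simulate" not in stages:
        raise ValueError("methylome/dmr/aging stages require the simulate stage")

    tissue_mode = raw.get("tissue_mode", "gastrocnemius")
    if tissue_mode not in TISSUE_MODES:
        raise ValueError(f"unknown tissue_mode {tissue_mode!r}; choose from {sorted(TISSUE_MODES)}")
    dmr_kwargs = dict(TISSUE_MODES[tissue_mode])
    dmr_kwargs.update(raw.get("dmr_params") or {})
    dmr_params = DmrParams(**dmr_kwargs)

    thr_kwargs = {k: v for k, v in (raw.get("miami") or {}).items()
                  if k in ("low", "high", "mspi_band")}
    thresholds = MiamiThresholds(**thr_kwargs)

    coverage_min = int(raw.get("coverage_min", 10 if tissue_mode == "TA" else 5))
    if coverage_min < 1:
        raise ValueError("coverage_min must be >= 1")
    seed = int(raw.get("seed", 0))

    return RunConfig(
        stages=list(stages),
        output_dir=str(raw.get("output_dir", "pipeline_out")),
        seed=seed,
        coverage_min=coverage_min,
        tissue_mode=tissue_mode,
        window_size=int(raw.get("window_size", 100_000)),
        window_step=raw.get("window_step"),
        simulation=sim,
        dmr_params=dmr_params,
        thresholds=thresholds,
        miami=raw.get("miami") or {},
        feeding=raw.get("feeding") or {},
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return the run manifest.

    The manifest records the seed, per-stage status, wall-clock time and
    sha256 checksums of every file written.  A stage failure is recorded
    and aborts the run (no partial silent success).
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "tissue_mode": config.tissue_mode, "stages": {}}
    state: dict = {}

    runners = {
        "simulate": _stage_simulate, "methylome": _stage_methylome, "dmr": _stage_dmr,
        "aging": _stage_aging, "miami": _stage_miami, "elas": _stage_elas,
    }
    for stage in config.stages:
        t0 = time.perf_counter()
        entry: dict = {"status": "ok", "outputs": {}}
        try:
            outputs = runners[stage](config, out_dir, state)
            entry["outputs"] = {str(p.name): _sha256(p) for p in outputs}
        except Exception as exc:  # recorded, then re-raised after manifest write
            entry["status"] = "failed"
            entry["error"] = f"{type(exc).__name__}: {exc}"
            entry["seconds"] = round(time.perf_counter() - t0, 3)
            manifest["stages"][stage] = entry
            _write_manifest(manifest, out_dir)
            raise
        entry["seconds"] = round(time.perf_counter() - t0, 3)
        manifest["stages"][stage] = entry
    _write_manifest(manifest, out_dir)
    return manifest


def _write_manifest(manifest: dict, out_dir: Path) -> None:
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def _sim_objects(config: RunConfig):
    sim = dict(config.simulation)
    design_keys = {"n_per_group", "groups", "chrom_lengths", "cpg_spacing_mean", "coverage_mean"}
    design_kwargs = {k: v for k, v in sim.items() if k in design_keys}
    if "groups" in design_kwargs:
        design_kwargs["groups"] = tuple(design_kwargs["groups"])
    effect_kwargs = {k: v for k, v in sim.items() if k not in design_keys}
    if "baseline_beta" in effect_kwargs:
        effect_kwargs["baseline_beta"] = tuple(effect_kwargs["baseline_beta"])
    design = synthetic_data.SimDesign(seed=config.seed, **design_kwargs)
    effects = synthetic_data.SimEffects(**effect_kwargs)
    return design, effects


def _stage_simulate(config: RunConfig, out_dir: Path, state: dict) -> list[Path]:
    design, effects = _sim_objects(config)
    genome = synthetic_data.simulate_genome(design, effects)
    tables = synthetic_data.simulate_methylomes(genome, design, effects)
    state.update(design=design, effects=effects, genome=genome, tables=tables)
    written = []
    layout, _positions, genes, planted = genome
    p = out_dir / "genes.bed"
    io_formats.write_gene_bed(genes, p)
    written.append(p)
    p = out_dir / "planted_regions.tsv"
    planted.to_csv(p, sep="\t", index=False)
    written.append(p)
    for sample_id, table in tables.items():
        p = out_dir / f"{sample_id}.cov.tsv"
        io_formats.write_cpg_table(table, p)
        written.append(p)
    return written


def _filtered_tables(config: RunConfig, state: dict) -> dict[str, pd.DataFrame]:
    if "filtered" not in state:
        state["filtered"] = {
            s: methylome_core.filter_by_coverage(t, config.coverage_min)
            for s, t in state["tables"].items()
        }
    return state["filtered"]


def _stage_methylome(config: RunConfig, out_dir: Path, state: dict) -> list[Path]:
    layout = state["genome"][0]
    tables = _filtered_tables(config, state)
    windows = methylome_core.make_windows(layout, config.window_size,
                                          config.window_step, exclude_sex=True)
    matrix = methylome_core.aggregate_regions(tables, windows)
    summary = methylome_core.summarize_global(matrix)
    coords, var_frac = methylome_core.pca_samples(matrix)
    state["window_matrix"] = matrix
    written = []
    p = out_dir / "window_matrix.tsv"
    io_formats.write_matrix_tsv(matrix, p)
    written.append(p)
    p = out_dir / "global_summary.tsv"
    summary.to_csv(p, sep="\t", float_format="%.10g")
    written.append(p)
    p = out_dir / "pca.tsv"
    coords.assign().to_csv(p, sep="\t", float_format="%.10g")
    written.append(p)
    p = out_dir / "pca_variance.tsv"
    pd.Series(var_frac, index=coords.columns, name="variance_fraction").to_csv(p, sep="\t")
    written.append(p)
    return written


def _group_ids(state: dict) -> dict[str, list[str]]:
    return state["design"].sample_ids()


def _stage_dmr(config: RunConfig, out_dir: Path, state: dict) -> list[Path]:
    tables = _filtered_tables(config, state)
    ids = _group_ids(state)
    dmrs = call_dmrs(tables, ids["youngWT"], ids["oldWT"], config.dmr_params)
    state["age_dmrs"] = dmrs
    genes = state["genome"][2]
    dmrg = annotate_nearest_gene(dmrs, genes)
    written = []
    p = out_dir / "age_dmrs.bed"
    io_formats.write_dmr_bed(dmrs, p)
    written.append(p)
    p = out_dir / "age_dmrg.tsv"
    dmrg.to_csv(p, sep="\t", index=False, float_format="%.10g")
    written.append(p)
    return written


def _stage_aging(config: RunConfig, out_dir: Path, state: dict) -> list[Path]:
    tables = _filtered_tables(config, state)
    ids = _group_ids(state)
    sets = classify_age_dmrs(state["age_dmrs"])
    written = []
    for name, dmrs in (("hyper", sets.hyper), ("hypo", sets.hypo)):
        if not dmrs:
            continue
        regions = dmrs_to_regions(dmrs, prefix=f"age_{name}")
        matrix, group_means, zscored = region_group_matrix(regions, tables, ids)
        p = out_dir / f"age_{name}_matrix.tsv"
        io_formats.write_matrix_tsv(matrix, p)
        written.append(p)
        p = out_dir / f"age_{name}_zscore.tsv"
        io_formats.write_matrix_tsv(zscored, p)
        written.append(p)
    if sets.hyper and sets.hypo:
        result = dnmt3a_sensitivity(sets, tables, ids["youngWT"], ids["youngTg"])
        p = out_dir / "sensitivity.json"
        p.write_text(json.dumps({
            "delta_hyper": result.delta_hyper, "delta_hypo": result.delta_hypo,
            "p_value": result.p_value, "conclusion": result.conclusion,
        }, indent=2) + "\n")
        written.append(p)
    return written


def _stage_miami(config: RunConfig, out_dir: Path, state: dict) -> list[Path]:
    m = config.miami
    table = synthetic_data.simulate_miami(
        n_probes=int(m.get("n_probes", 10_000)),
        frac_hyper=float(m.get("frac_hyper", 0.1)),
        frac_hypo=float(m.get("frac_hypo", 0.1)),
        effect_logfc=float(m.get("effect_logfc", np.log(2))),
        noise_sd=float(m.get("noise_sd", 0.1)),
        seed=config.seed,
    )
    classified = classify_probes(table, config.thresholds)
    summary = miami_summary(classified)
    written = []
    p = out_dir / "miami_classified.tsv"
    io_formats.write_miami_table(classified, p)
    written.append(p)
    p = out_dir / "miami_summary.json"
    p.write_text(json.dumps(summary, indent=2) + "\n")
    written.append(p)
    return written


def _stage_elas(config: RunConfig, out_dir: Path, state: dict) -> list[Path]:
    f = config.feeding
    frames = []
    for genotype, rho in (("WT", float(f.get("rho_wt", 1.0))),
                          ("Tg", float(f.get("rho_tg", 0.4)))):
        params = synthetic_data.FeedingSimParams(
            elasticity_rho=rho, cv=float(f.get("cv", 0.05)),
            n_per_state=int(f.get("n_per_state", 8)),
            seed=config.seed, genotype=genotype,
        )
        frames.append(synthetic_data.simulate_feeding(params))
    feeding = pd.concat(frames, ignore_index=True)
    scores, comparisons = elas_table(feeding)
    written = []
    p = out_dir / "feeding_table.tsv"
    io_formats.write_feeding_table(feeding, p)
    written.append(p)
    p = out_dir / "elas_scores.tsv"
    scores.to_csv(p, sep="\t", index=False, float_format="%.10g")
    written.append(p)
    p = out_dir / "elas_comparisons.tsv"
    comparisons.to_csv(p, sep="\t", index=False, float_format="%.10g")
    written.append(p)
    return written
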