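"""End-to-end orchestration: ingest/simulate -> QC -> association ->
weights -> score -> evaluate, from one YAML config.

The run reproduces a two-by-two layout: weighting design (``local``
in-sample betas, ``replicate`` betas from an independent simulated
replicate, or ``gwas_corrected`` external betas) crossed with case stratum
(``all_cases``, ``moderate_severe``).  In-sample weighting deliberately
reuses the same individuals for weight estimation and evaluation — the run
manifest carries an explicit optimistic-bias notice — while the
``replicate`` design provides the unbiased counterpart.

All outputs are plain TSV plus a JSON manifest; identical config and seed
give byte-identical bundles (the output directory itself is excluded from
the manifest so bundles are comparable across locations).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io_formats import (VariantPanel, default_panel, read_panel,
                         read_genotypes, read_summary_stats, write_results)
from .synthetic_data import SimConfig, simulate_case_control, \
    true_parameter_manifest
from .assoc_qc import (associate_all, qc_report, prune_by_ld,
                       DEFAULT_HWE_ALPHA, DEFAULT_LD_THRESHOLD)
from .weights import build_weight_set, DEFAULT_PROXY_R2
from .pgs_score import compute_pgs, score_association, stratum_mask, STRATA
from .roc_eval import roc_summary

IN_SAMPLE_NOTICE = ("weights estimated in-sample; AUC/OR optimistically "
                    "biased — use the 'replicate' design for an unbiased "
                    "estimate")

WEIGHT_MODES = ("local", "replicate", "gwas_corrected")


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class PipelineConfig:
    """One analysis run: input source, weighting designs, strata, thresholds."""

    seed: int = 26
    out_dir: str = "results"
    source: str = "simulate"                     # simulate | files
    sim: SimConfig | None = None
    genotypes: str | None = None
    dialect: str = "vcf"
    phenotype: str | None = None
    panel_path: str | None = None
    weight_modes: tuple[str, ...] = ("local", "replicate")
    strata: tuple[str, ...] = ("all_cases", "moderate_severe")
    hwe_alpha: float = DEFAULT_HWE_ALPHA
    ld_prune: float = DEFAULT_LD_THRESHOLD
    proxy_r2: float = DEFAULT_PROXY_R2
    missing_policy: str = "mean_impute"
    ci_method: str = "delong"
    summary_stats: str | None = None
    removed_cohort: str | None = None
    proxy_map: str | None = None
    orient_by: str = "local"

    def __post_init__(self) -> None:
        if not self.weight_modes:
            raise ConfigError("need at least one weight mode")
        if not self.strata:
            raise ConfigError("need at least one stratum")
        bad = set(self.weight_modes) - set(WEIGHT_MODES)
        if bad:
            raise ConfigError(f"unknown weight modes: {sorted(bad)}")
        bad = set(self.strata) - set(STRATA)
        if bad:
            raise ConfigError(f"unknown strata: {sorted(bad)}")
        for name, val, lo, hi in (("hwe_alpha", self.hwe_alpha, 0, 1),
                                  ("ld_prune", self.ld_prune, 0, 1),
                                  ("proxy_r2", self.proxy_r2, 0, 1)):
            if not lo <= val <= hi:
                raise ConfigError(f"{name}={val} outside [{lo}, {hi}]")
        if self.source == "simulate" and self.sim is None:
            self.sim = SimConfig(seed=self.seed)
        if self.source == "files" and self.genotypes is None:
            raise ConfigError("source=files requires a genotypes path")
        if "gwas_corrected" in self.weight_modes and self.summary_stats is None:
            raise ConfigError("gwas_corrected mode requires summary_stats")


def load_config(path) -> PipelineConfig:
    """Parse a YAML pipeline config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    seed = int(raw.get("seed", 26))
    inp = raw.get("input", {})
    source = inp.get("source", "simulate")
    sim = None
    if source == "simulate":
        sim_raw = dict(inp.get("sim", {}))
        panel = (read_panel(sim_raw.pop("panel")) if "panel" in sim_raw
                 else default_panel())
        sim_raw.setdefault("seed", seed)
        if "ld_pairs" in sim_raw:
            sim_raw["ld_pairs"] = [tuple(p) for p in sim_raw["ld_pairs"]]
        sim = SimConfig(panel=panel, **sim_raw)
    files = inp.get("files", {})
    qc = raw.get("qc", {})
    gwas = raw.get("gwas", {})
    return PipelineConfig(
        seed=seed,
        out_dir=raw.get("out_dir", "results"),
        source=source,
        sim=sim,
        genotypes=files.get("genotypes"),
        dialect=files.get("dialect", "vcf"),
        phenotype=files.get("phenotype"),
        panel_path=files.get("panel"),
        weight_modes=tuple(raw.get("weight_modes", ["local", "replicate"])),
        strata=tuple(raw.get("strata", ["all_cases", "moderate_severe"])),
        hwe_alpha=float(qc.get("hwe_alpha", DEFAULT_HWE_ALPHA)),
        ld_prune=float(qc.get("ld_prune", DEFAULT_LD_THRESHOLD)),
        proxy_r2=float(qc.get("proxy_r2", DEFAULT_PROXY_R2)),
        missing_policy=raw.get("missing_policy", "mean_impute"),
        ci_method=raw.get("ci_method", "delong"),
        summary_stats=gwas.get("summary_stats"),
        removed_cohort=gwas.get("removed_cohort"),
        proxy_map=gwas.get("proxy_map"),
        orient_by=raw.get("orient_by", "local"),
    )


def _subpanel(panel: VariantPanel, keep: list[str]) -> VariantPanel:
    t = panel.table[panel.table["snp_id"].isin(set(keep))]
    return VariantPanel(t.reset_index(drop=True))


def _replicate_seed(seed: int) -> int:
    return (seed + 1000003) % (2**31)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured (weight mode, stratum) cell and persist the
    result bundle under ``config.out_dir``.

    Returns the bundle as a dict of DataFrames/objects; the same content is
    written as TSVs plus ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- input -------------------------------------------------------------
    if config.source == "simulate":
        panel = config.sim.panel
        dataset = simulate_case_control(config.sim)
    else:
        panel = (read_panel(config.panel_path) if config.panel_path
                 else default_panel())
        dataset = read_genotypes(config.genotypes, panel, config.dialect,
                                 phenotype_path=config.phenotype)
        if dataset.absent_snps:
            panel = _subpanel(panel, dataset.snp_ids)
    dataset.require_phenotype()

    # --- QC + association --------------------------------------------------
    qc = qc_report(dataset)
    assoc = associate_all(dataset)
    pvals = dict(zip(assoc["snp_id"], assoc["p"].fillna(1.0)))
    hwe_fail = qc.loc[qc["hwe_p"] <= config.hwe_alpha, "snp_id"].tolist()
    kept_hwe = [s for s in dataset.snp_ids if s not in set(hwe_fail)]
    ds_hwe = _subset_dataset(dataset, kept_hwe)
    retained, pruning = prune_by_ld(ds_hwe, pvals, threshold=config.ld_prune)
    analysis_panel = _subpanel(panel, retained)
    analysis_assoc = assoc[assoc["snp_id"].isin(set(retained))]

    # --- weights -----------------------------------------------------------
    summary_stats = (read_summary_stats(config.summary_stats)
                     if config.summary_stats else None)
    removed = (read_summary_stats(config.removed_cohort)
               if config.removed_cohort else None)
    proxy_map = None
    if config.proxy_map:
        pm = pd.read_csv(config.proxy_map, sep="\t")
        proxy_map = list(pm[["missing_snp", "proxy_snp", "r2"]]
                         .itertuples(index=False, name=None))

    weight_sets: dict[str, pd.DataFrame] = {}
    dropped: dict[str, list[str]] = {}
    for mode in config.weight_modes:
        if mode == "local":
            ws, dr = build_weight_set(analysis_panel, analysis_assoc,
                                      mode="local")
        elif mode == "replicate":
            if config.source != "simulate":
                raise ConfigError("replicate weighting requires a simulated "
                                  "input source")
            rep_cfg = SimConfig(
                panel=config.sim.panel, effects=config.sim.effects,
                intercept=config.sim.intercept, n_cases=config.sim.n_cases,
                n_controls=config.sim.n_controls,
                severity_fraction=config.sim.severity_fraction,
                missing_rate=config.sim.missing_rate,
                ld_pairs=config.sim.ld_pairs,
                seed=_replicate_seed(config.sim.seed))
            rep_ds = simulate_case_control(rep_cfg)
            rep_assoc = associate_all(_subset_dataset(rep_ds, retained))
            ws, dr = build_weight_set(analysis_panel, rep_assoc, mode="local")
            ws = ws.assign(source="replicate")
        else:  # gwas_corrected
            ws, dr = build_weight_set(
                analysis_panel, analysis_assoc, summary_stats=summary_stats,
                removed_cohort=removed, proxy_map=proxy_map,
                mode="gwas_corrected", proxy_threshold=config.proxy_r2,
                orient_by=config.orient_by)
        weight_sets[mode] = ws
        dropped[mode] = dr

    # --- score + evaluate --------------------------------------------------
    ds_analysis = _subset_dataset(dataset, retained)
    score_tables = {}
    assoc_rows, roc_rows, curves = [], [], {}
    for mode in config.weight_modes:
        pgs = compute_pgs(ds_analysis, weight_sets[mode],
                          missing_policy=config.missing_policy)
        score_tables[mode] = pgs
        for stratum in config.strata:
            mask = stratum_mask(ds_analysis, stratum)
            sa = score_association(pgs["raw_score"].to_numpy(),
                                   ds_analysis.phenotype, stratum=stratum,
                                   mask=mask)
            assoc_rows.append({"weight_mode": mode, **sa.as_dict()})
            z = pgs["raw_score"].to_numpy()[mask]
            rs = roc_summary(z, ds_analysis.phenotype[mask],
                             ci_method=config.ci_method, seed=config.seed)
            roc_rows.append({"weight_mode": mode, "stratum": stratum,
                             **rs.as_dict()})
            curves[f"roc_curve_{mode}_{stratum}"] = rs.curve

    score_assoc_table = pd.DataFrame(assoc_rows)
    roc_table = pd.DataFrame(roc_rows)

    # --- persist -----------------------------------------------------------
    tables = {
        "association": assoc,
        "qc_report": qc,
        "ld_pruning": pruning,
        "score_association": score_assoc_table,
        "roc_summary": roc_table,
        **{f"weights_{m}": weight_sets[m] for m in config.weight_modes},
        **{f"scores_{m}": score_tables[m] for m in config.weight_modes},
        **curves,
    }
    write_results(tables, out)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "source": config.source,
        "weight_modes": list(config.weight_modes),
        "strata": list(config.strata),
        "thresholds": {"hwe_alpha": config.hwe_alpha,
                       "ld_prune": config.ld_prune,
                       "proxy_r2": config.proxy_r2},
        "missing_policy": config.missing_policy,
        "ci_method": config.ci_method,
        "or_scale": "per SD of the PGS (assumed convention; flagged)",
        "hwe_excluded": hwe_fail,
        "ld_pruned": pruning["snp_id"].tolist(),
        "dropped_by_mode": dropped,
        "notices": ([IN_SAMPLE_NOTICE] if "local" in config.weight_modes
                    else []),
    }
    if config.source == "simulate":
        manifest["simulation_truth"] = true_parameter_manifest(config.sim)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "dataset": dataset,
        "panel": analysis_panel,
        "association": assoc,
        "qc_report": qc,
        "ld_pruning": pruning,
        "weight_sets": weight_sets,
        "scores": score_tables,
        "score_association": score_assoc_table,
        "roc_summary": roc_table,
        "manifest": manifest,
    }


def _subset_dataset(dataset, keep: list[str]):
    """Dataset restricted to the given SNP columns (panel order)."""
    from .io_formats import GenotypeDataset

    keep_set = set(keep)
    idx = [j for j, s in enumerate(dataset.snp_ids) if s in keep_set]
    return GenotypeDataset(
        sample_ids=dataset.sample_ids,
        snp_ids=[dataset.snp_ids[j] for j in idx],
        dosages=dataset.dosages[:, idx],
        counted_alleles=[dataset.counted_alleles[j] for j in idx],
        other_alleles=[dataset.other_alleles[j] for j in idx],
        phenotype=dataset.phenotype,
        severity=dataset.severity,
        absent_snps=dataset.absent_snps,
    )
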