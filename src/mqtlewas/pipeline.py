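"""End-to-end orchestration: simulate -> QC -> scan -> database -> EWAS -> report.

Every stage reads only the artifacts of earlier stages and writes its own
files into the run directory; nothing mutates an upstream artifact.  All
randomness flows from the single seed in the config (per-CpG permutation
streams are derived by stable hashing), so re-running a config reproduces
every numeric output exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import celltypes, enrichment, ewas, meta_db, mqtl_scan
from .io_formats import apply_genotype_qc
from .synthetic_cohort import (SimConfig, simulate_cohort, simulate_mixture,
                               simulate_reference, write_cohort)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "sim": {},  # SimConfig defaults
    "scan": {"window_bp": 2_000_000, "n_perm": 1000, "seed": 0},
    "thresholds": {"adjusted_p": 0.05, "r2": 0.5, "change": 0.20,
                   "bonferroni_alpha": 0.05},
    "platform": "BOTH",
    "deconvolve": True,
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # halt with the stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(cfg: dict, outdir: str | Path, force: bool = False) -> dict:
    """Run every stage on a synthetic cohort; returns the artifact summary.

    The run directory receives the cohort fixtures, per-stratum QC reports
    and scan tables, the mQTL database, cross-stratum concordance, both
    EWAS tables with their meta-analysis and comparison, island-relation
    enrichment, deconvoluted proportions, and a manifest stamped with the
    config hash and seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim_cfg = SimConfig.from_dict(cfg.get("sim", {}))
    scan_cfg = {**DEFAULT_CONFIG["scan"], **cfg.get("scan", {})}
    thr = {**DEFAULT_CONFIG["thresholds"], **cfg.get("thresholds", {})}
    seed = int(scan_cfg["seed"])
    artifacts: dict = {"outdir": str(outdir)}

    cohort = _stage("simulate")(simulate_cohort)(sim_cfg)
    write_cohort(outdir / "cohort", cohort, force=True)

    strata = list(cohort["strata"])
    qc_reports = {}
    for s in strata:
        data = cohort["strata"][s]
        g, report = _stage("qc")(apply_genotype_qc)(data["genotypes"])
        data["genotypes"] = g
        qc_reports[s] = report.as_dict()
    (outdir / "qc_report.json").write_text(json.dumps(qc_reports, indent=2))

    if cfg.get("deconvolve", True):
        _deconvolve_stage(cohort, sim_cfg, outdir)

    scan_results = {}
    for s in strata:
        data = cohort["strata"][s]
        res = _stage("scan")(mqtl_scan.scan_dataset)(
            data["methylation"], data["genotypes"], data["samples"],
            window_bp=int(scan_cfg["window_bp"]),
            n_perm=int(scan_cfg["n_perm"]), seed=seed,
            alpha=thr["adjusted_p"])
        res.to_tsv(outdir / f"scan.{s}.tsv")
        scan_results[s] = res

    db = _stage("build-db")(meta_db.build_database)(
        [scan_results[s].table for s in strata], platform=cfg["platform"],
        alpha=thr["adjusted_p"])
    db.to_tsv(outdir / "mqtl_database.tsv")
    artifacts["n_db_pairs"] = db.n_pairs
    artifacts["n_db_cpgs"] = db.n_cpgs

    if len(strata) >= 2:
        per_stratum_dbs = {
            s: meta_db.build_database([scan_results[s].table],
                                      platform=cfg["platform"],
                                      alpha=thr["adjusted_p"])
            for s in strata}
        conc = _stage("concordance")(meta_db.concordance)(
            per_stratum_dbs[strata[0]], per_stratum_dbs[strata[1]],
            cohort["strata"][strata[0]]["genotypes"], r2_min=thr["r2"])
        conc["detail"].to_csv(outdir / "concordance.tsv", sep="\t",
                              index=False, na_rep="NA")
        artifacts["concordance"] = {k: v for k, v in conc.items()
                                    if k != "detail"}
        (outdir / "concordance.json").write_text(
            json.dumps(artifacts["concordance"], indent=2))

    mqtl_tables, plain_tables = [], []
    for s in strata:
        data = cohort["strata"][s]
        res_m, res_p = _stage("ewas")(ewas.fit_paired_dataset)(
            data["methylation"], data["samples"], data["genotypes"], db)
        res_m.to_tsv(outdir / f"ewas.mqtl.{s}.tsv")
        res_p.to_tsv(outdir / f"ewas.plain.{s}.tsv")
        mqtl_tables.append(res_m.table)
        plain_tables.append(res_p.table)

    meta_m = _stage("meta")(ewas.meta_ewas)(
        mqtl_tables, platform=cfg["platform"], alpha=thr["bonferroni_alpha"])
    meta_p = ewas.meta_ewas(plain_tables, platform=cfg["platform"],
                            alpha=thr["bonferroni_alpha"])
    meta_m.to_csv(outdir / "ewas.meta.mqtl.tsv", sep="\t", index=False,
                  na_rep="NA")
    meta_p.to_csv(outdir / "ewas.meta.plain.tsv", sep="\t", index=False,
                  na_rep="NA")
    artifacts["n_significant_mqtl_model"] = int(meta_m["significant"].sum())
    artifacts["n_significant_plain_model"] = int(meta_p["significant"].sum())

    comp, summary = _stage("compare")(ewas.compare_models)(
        mqtl_tables[0], plain_tables[0], change_threshold=thr["change"],
        alpha=thr["bonferroni_alpha"])
    comp.to_csv(outdir / "comparison.tsv", sep="\t", index=False, na_rep="NA")
    artifacts["comparison_summary"] = summary
    (outdir / "comparison_summary.json").write_text(
        json.dumps(summary, indent=2, default=float))

    cpgs = cohort["strata"][strata[0]]["methylation"].cpgs
    assigned = set(db.assigned()["cpg_id"])
    flags = cpgs["id"].isin(assigned).to_numpy()
    if flags.any():
        isl = _stage("enrich")(enrichment.island_relation_test)(cpgs, flags)
        isl.to_csv(outdir / "island_enrichment.tsv", sep="\t", index=False,
                   na_rep="NA")
        artifacts["frac_cpgs_with_mqtl"] = float(flags.mean())

    manifest = {"config_hash": config_hash(cfg), "seed": seed,
                "config": cfg, "artifacts": {k: v for k, v in artifacts.items()
                                             if k != "outdir"}}
    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
    return artifacts


@_stage("deconvolve")
def _deconvolve_stage(cohort: dict, sim_cfg: SimConfig, outdir: Path) -> None:
    """Estimate cell proportions from reference mixtures and install them
    as the EWAS cell covariates (replacing the simulated truth columns)."""
    reference = simulate_reference(200, seed=sim_cfg.seed)
    for s, data in cohort["strata"].items():
        props_true = cohort["truth"].cell_props[s]
        est = {}
        for i, sample in enumerate(props_true.index):
            y = simulate_mixture(reference, props_true.loc[sample].to_numpy(),
                                 noise_sd=0.02, seed=sim_cfg.seed + i)
            est[sample] = celltypes.estimate_proportions(y, reference)
        est = pd.DataFrame(est).T
        est.to_csv(outdir / f"cell_proportions.{s}.tsv", sep="\t",
                   index_label="sample_id", na_rep="NA")
        cov = celltypes.make_covariates(est)
        samples = data["samples"].set_index("sample_id")
        samples.loc[cov.index, cov.columns] = cov
        data["samples"] = samples.reset_index()
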