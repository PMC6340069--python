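"""Stage sequencing for the full analysis, restartable from files.

The pipeline runs QC -> association -> (co-clustering ERS + genetic risk
scores) -> interaction models, writing each stage's outputs as plain CSV/JSON
under the output directory so any stage can be re-run from the previous
stage's files:

    cohort.csv, genotypes.csv          simulated or copied inputs
    qc_report.csv, table1.csv          QC decisions + cohort characterisation
    table2_env.csv, table3_snp.csv     association tables
    ers.csv, blockmodel_report.json    environmental risk score
    grs.csv                            genetic risk scores
    table4_ers_snp.csv, table5_grs_env.csv, grs_ers.csv
    manifest.json                      seed, config hash, per-stage counts
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import encode_additive, env_association, snp_association
from .blockmodel import assign_ers, cem_cocluster, label_variables, mode_impute
from .dataio import (
    COVARIATES,
    CohortTable,
    GenotypeMatrix,
    read_cohort,
    read_genotypes,
    write_cohort,
    write_genotypes,
    write_table,
)
from .interaction import ers_snp_interactions, grs_env_interactions, grs_ers_interaction
from .qc import cohort_summary, filter_snps, filter_variables
from .risk_scores import compute_grs
from .synthetic import SimulationConfig, paperlike_config, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Serializable run configuration; config + seed reproduce all outputs."""

    out_dir: str = "results/run"
    seed: int = 0
    simulation: str | dict | None = "paperlike"  # None -> read input files
    genotypes_path: str | None = None
    cohort_path: str | None = None
    hwe_p_threshold: float = 1e-4
    snp_missing_threshold: float = 0.1
    variable_missing_threshold: float = 0.05
    covariates: list[str] = field(default_factory=lambda: list(COVARIATES))
    grs_variant: str = "weighted"  # which dichotomized GRS drives the GRS x E table
    cem_restarts: int = 20

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _load_inputs(cfg: PipelineConfig) -> tuple[GenotypeMatrix, CohortTable]:
    if cfg.simulation is not None:
        if cfg.simulation == "paperlike":
            sim = paperlike_config(seed=cfg.seed)
        elif isinstance(cfg.simulation, dict):
            sim = SimulationConfig(**{**cfg.simulation, "seed": cfg.seed})
        else:
            raise ValueError(f"unknown simulation spec {cfg.simulation!r}")
        cohort = simulate_cohort(sim)
        return cohort.genotypes, cohort.table
    if not cfg.genotypes_path or not cfg.cohort_path:
        raise FileNotFoundError("simulation disabled and input paths not given")
    for p in (cfg.genotypes_path, cfg.cohort_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input file {p} not found")
    return read_genotypes(cfg.genotypes_path), read_cohort(cfg.cohort_path)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and return the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    gm, table = _load_inputs(cfg)
    write_genotypes(gm, out / "genotypes.csv")
    write_cohort(table, out / "cohort.csv")
    logger.info("cohort: %d cases / %d controls, %d SNPs, %d exposures",
                table.n_cases, table.n_controls, len(gm.snp_ids), len(table.exposures))

    # --- QC ---------------------------------------------------------------
    snp_qc = filter_snps(gm, table.outcome, cfg.hwe_p_threshold, cfg.snp_missing_threshold)
    var_qc = filter_variables(table, cfg.variable_missing_threshold)
    for name, reason in {**snp_qc.dropped, **var_qc.dropped}.items():
        logger.info("QC drop: %s (%s)", name, reason)
    qc_all = pd.concat(
        [snp_qc.items.assign(kind="snp"), var_qc.items.assign(kind="variable")],
        ignore_index=True,
    )
    write_table(qc_all, out / "qc_report.csv")
    kept_snps = snp_qc.kept
    kept_vars = [v for v in var_qc.kept if v in table.exposures]
    table_kept = CohortTable(
        table.data[["outcome"] + kept_vars + list(cfg.covariates)].copy(),
        exposures=kept_vars, covariates=list(cfg.covariates),
    )
    gm_kept = gm.subset_snps(kept_snps)
    write_table(cohort_summary(table_kept), out / "table1.csv")

    # --- association -------------------------------------------------------
    env_table = env_association(table_kept, covariates=cfg.covariates)
    write_table(env_table, out / "table2_env.csv")
    doses = encode_additive(gm_kept, table.outcome)
    snp_table = snp_association(doses, table_kept, covariates=cfg.covariates)
    write_table(snp_table, out / "table3_snp.csv")

    # --- environmental risk score ------------------------------------------
    labels = label_variables(env_table)
    matrix = mode_impute(table_kept.data[kept_vars].to_numpy(dtype=float))
    fit = cem_cocluster(matrix, labels, restarts=cfg.cem_restarts, seed=cfg.seed)
    ers = assign_ers(fit, labels)
    ers_df = table_kept.data[["outcome"]].copy()
    ers_df["ers"] = ers
    ers_df.index.name = "sample_id"
    ers_df[["ers"]].to_csv(out / "ers.csv")
    (out / "blockmodel_report.json").write_text(json.dumps({
        "col_labels": dict(zip(labels.names, labels.labels.tolist())),
        "block_params": fit.block_params.tolist(),
        "row_props": fit.row_props.tolist(),
        "loglik": fit.loglik,
        "n_restarts": fit.n_restarts,
        "n_reseeds": fit.n_reseeds,
        "best_restart": fit.best_restart,
        "converged": fit.converged,
    }, indent=2))

    # --- genetic risk scores -----------------------------------------------
    scores = compute_grs(doses, table.outcome)
    scores.frame().to_csv(out / "grs.csv")

    # --- interactions --------------------------------------------------------
    t4 = ers_snp_interactions(ers, doses, table_kept, covariates=cfg.covariates)
    write_table(t4, out / "table4_ers_snp.csv")
    variants = {"weighted": scores.w_grs_binary, "unweighted": scores.u_grs_binary}
    grs_binary = variants[cfg.grs_variant]
    t5 = grs_env_interactions(grs_binary, table_kept, covariates=cfg.covariates)
    write_table(t5, out / "table5_grs_env.csv")
    other = next(k for k in variants if k != cfg.grs_variant)
    write_table(
        grs_env_interactions(variants[other], table_kept, covariates=cfg.covariates),
        out / f"table5_grs_env_{other}.csv",
    )
    t6 = grs_ers_interaction(grs_binary, ers, table_kept, covariates=cfg.covariates)
    write_table(t6, out / "grs_ers.csv")

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.content_hash(),
        "n_cases": table.n_cases,
        "n_controls": table.n_controls,
        "n_snps_input": len(gm.snp_ids),
        "n_snps_kept": len(kept_snps),
        "n_snps_dropped_hwe": sum(r == "hwe" for r in snp_qc.dropped.values()),
        "n_snps_dropped_missing": sum(r == "missing_rate" for r in snp_qc.dropped.values()),
        "n_exposures_input": len(table.exposures),
        "n_exposures_kept": len(kept_vars),
        "n_variables_kept": len(kept_vars) + len(cfg.covariates),
        "ers_cases_rate": float(np.mean(ers[table.outcome == 1])),
        "n_interaction_rows": int(len(t4) + len(t5) + len(t6)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
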