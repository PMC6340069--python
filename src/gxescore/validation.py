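"""Headline validation experiments for the pipeline.

Two kinds of check live here.  Desk-scale reproductions recompute, from the
published group-level counts, the quantities those counts determine exactly:
the crude environmental odds ratios, the benzene separation row and the
sparse-marker trend test.  Property-based experiments characterise the parts
whose individual-level inputs are not public: interaction-coefficient
recovery on synthetic cohorts at the study's sample size, the empirical size
of the interaction test under the null, and planted-partition recovery of
the CEM co-clustering.

Everything is seeded; each function is a pure function of its arguments.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import study_counts as sc
from .association import env_association, encode_additive, snp_association
from .blockmodel import cem_cocluster
from .interaction import grs_env_interactions
from .pipeline import PipelineConfig, run_pipeline
from .stats_core import cochran_armitage
from .synthetic import (
    CovariateSpec,
    ExposureSpec,
    InteractionSpec,
    ScoreSpec,
    SimulationConfig,
    simulate_cohort,
)

#: the study's published headline interaction: smoking x weighted GRS ROR.
HEADLINE_ROR = 0.23


def printed_crude_or_table() -> pd.DataFrame:
    """Univariate exposure odds ratios recomputed from the printed 2x2
    counts (the per-variable margins determine these exactly)."""
    return env_association(sc.reconstruct_cohort()).set_index("variable")


def printed_snp_table() -> pd.DataFrame:
    """Trend tests and genotype-count strings from the printed per-SNP
    genotype counts."""
    table = sc.reconstruct_cohort()
    doses = encode_additive(sc.reconstruct_genotypes(), table.outcome)
    return snp_association(doses, table, covariates=[]).set_index("snp")


def sparse_marker_trend_p(snp: str = "rs13306698") -> float:
    """Cochran-Armitage p for one marker's printed genotype counts."""
    _, _, ctl, cas = sc.SNP_GENOTYPE_COUNTS[snp]
    _, p = cochran_armitage(cas[::-1], ctl[::-1])  # counts printed rare-first
    return p


# ---------------------------------------------------------------------------
# property-based experiments


def _interaction_sim_config(beta_int: float, seed: int) -> SimulationConfig:
    """Study-sized score x exposure cohort: smoking at its control
    prevalence with its crude effect, a balanced binary risk score, the five
    covariates at their control distributions (null effects)."""
    return SimulationConfig(
        n_cases=sc.N_CASES,
        n_controls=sc.N_CONTROLS,
        exposure_specs=(ExposureSpec("smoking", 0.36, math.log(1.39)),),
        score_specs=(ScoreSpec("grs", 0.5, math.log(1.5)),),
        interaction_specs=(InteractionSpec("grs", "smoking", beta_int),),
        covariate_specs=(
            CovariateSpec("age", "normal", sc.CONTROL_COVARIATES["age"]),
            CovariateSpec("gender", "bernoulli", (sc.CONTROL_COVARIATES["gender"],)),
            CovariateSpec("education", "bernoulli", (sc.CONTROL_COVARIATES["education"],)),
            CovariateSpec("family_history", "bernoulli",
                          (sc.CONTROL_COVARIATES["family_history"],)),
            CovariateSpec("bmi", "normal", sc.CONTROL_COVARIATES["bmi"]),
        ),
        intercept=-1.5,
        seed=seed,
    )


def interaction_recovery(
    beta_int: float = math.log(HEADLINE_ROR),
    n_replicates: int = 500,
    seed: int = 0,
) -> dict:
    """Recover a planted score x exposure interaction at the study size.

    Each replicate simulates 169 cases / 421 controls and refits the product
    model through the interaction module, recording the fitted interaction
    log-OR of the unadjusted variant (the variant behind the published
    headline ROR; the covariates carry null effects here, so the adjusted
    estimand is identical).  Returns the replicate mean, its Monte-Carlo
    standard error, the z-score of the deviation from the planted value, and
    the fraction of replicates whose own 3-SE interval covers it.
    """
    rng = np.random.default_rng(seed)
    betas, ses = [], []
    covered = 0
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        cohort = simulate_cohort(_interaction_sim_config(beta_int, rep_seed))
        out = grs_env_interactions(cohort.scores["grs"], cohort.table)
        row = out.iloc[0]
        if row["separation"] or not np.isfinite(row["ror"]):
            continue
        b = math.log(row["ror"])
        se = (math.log(row["ci_high"]) - math.log(row["ci_low"])) / (2 * 1.959964)
        betas.append(b)
        ses.append(se)
        if abs(b - beta_int) <= 3 * se:
            covered += 1
    betas = np.asarray(betas)
    mc_se = betas.std(ddof=1) / math.sqrt(betas.size)
    return {
        "planted": beta_int,
        "mean": float(betas.mean()),
        "mc_se": float(mc_se),
        "z": float((betas.mean() - beta_int) / mc_se),
        "coverage_3se": covered / betas.size,
        "n_used": int(betas.size),
    }


def interaction_type1_error(
    n_replicates: int = 500, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Empirical size of the unadjusted interaction test under the null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    used = 0
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        cohort = simulate_cohort(_interaction_sim_config(0.0, rep_seed))
        out = grs_env_interactions(cohort.scores["grs"], cohort.table)
        p = out["p"].iloc[0]
        if np.isfinite(p):
            used += 1
            rejections += int(p < alpha)
    return {"rate": rejections / used, "n_used": used, "alpha": alpha}


def adjusted_rand_index(a, b) -> float:
    """Adjusted Rand index between two partitions (pair-counting form)."""
    a = np.asarray(a)
    b = np.asarray(b)
    ua, ub = np.unique(a), np.unique(b)
    table = np.array([[(a == i)[b == j].sum() for j in ub] for i in ua], dtype=float)
    comb2 = lambda x: x * (x - 1) / 2.0  # noqa: E731
    sum_ij = comb2(table).sum()
    sum_a = comb2(table.sum(axis=1)).sum()
    sum_b = comb2(table.sum(axis=0)).sum()
    n = comb2(a.size)
    expected = sum_a * sum_b / n
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def cem_recovery(
    n_replicates: int = 100,
    n: int = 200,
    d: int = 20,
    noise: float = 0.2,
    seed: int = 0,
) -> dict:
    """Planted-partition recovery of the semi-supervised co-clustering.

    The planted 2x2 block matrix is block-diagonal: each row cluster has
    Bernoulli rate 1-noise on its own column group and noise elsewhere, so
    every column is informative about the row partition.  Reports the
    fraction of replicates with adjusted Rand index >= 0.9 and the
    noise-free ARI (which should be exactly 1).
    """
    rng = np.random.default_rng(seed)
    col_labels = np.array([1] * (d // 2) + [0] * (d - d // 2))
    z_true = np.array([0] * (n // 2) + [1] * (n - n // 2))

    def one(noise_level, rep_seed):
        probs = np.where(np.equal.outer(z_true, col_labels), 1 - noise_level, noise_level)
        x = (rng.random((n, d)) < probs).astype(float)
        fit = cem_cocluster(x, col_labels, seed=rep_seed)
        mono = bool((np.diff(fit.loglik_trace) >= -1e-9).all())
        return adjusted_rand_index(z_true, fit.row_labels), mono

    noise_free_ari, _ = one(0.0, seed)
    aris, monos = zip(*(one(noise, seed + 1 + r) for r in range(n_replicates)))
    return {
        "noise_free_ari": noise_free_ari,
        "fraction_ari_ge_090": float(np.mean([a >= 0.9 for a in aris])),
        "median_ari": float(np.median(aris)),
        "all_traces_monotone": bool(all(monos)),
        "n_replicates": n_replicates,
    }


def pipeline_bookkeeping(seed: int = 0, out_dir: str = "scratch/acceptance_run") -> dict:
    """Full paperlike pipeline run; returns the QC bookkeeping manifest."""
    return run_pipeline(PipelineConfig(out_dir=out_dir, seed=seed))
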