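"""Gene-environment interaction models on the multiplicative (odds) scale.

Three analyses share one engine: environmental risk score x SNP dose,
dichotomized genetic risk score x individual exposure, and GRS x ERS.  Each
fits logit(outcome) ~ a + b + a*b, unadjusted and adjusted for the five
covariates, and reports the ratio of odds ratios ROR = exp(beta_int) with a
Wald 95% interval.  The ROR is the factor by which the odds ratio of one
factor changes between strata of the other; for binary factors the
unadjusted ROR equals the stratified 2x2 cross-product ratio identity.
BH adjustment runs within each analysis table's family of tests.

Sparse cross-cells (for example an exposure with no exposed controls in one
score stratum) separate the interaction term; such rows report a missing
ROR with a (0, inf) interval and a flag, never a spuriously finite number.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import DoseMatrix
from .dataio import CohortTable
from .stats_core import bh_adjust, fit_logistic, odds_ratio_ci

__all__ = ["interaction_fit", "ers_snp_interactions", "grs_env_interactions",
           "grs_ers_interaction"]


def interaction_fit(
    a, b, y, covars: np.ndarray | None, names: tuple[str, str], covar_names=()
) -> dict:
    """Fit logit(y) ~ a + b + a:b (+ covariates) and extract the interaction row."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    int_name = f"{names[0]}:{names[1]}"
    cols = [np.ones_like(a), a, b, a * b]
    terms = ["intercept", names[0], names[1], int_name]
    if covars is not None:
        cols.extend(np.asarray(covars, dtype=float).T)
        terms.extend(covar_names or [f"c{j}" for j in range(covars.shape[1])])
    try:
        fit = fit_logistic(np.column_stack(cols), np.asarray(y, dtype=float), terms)
    except ValueError as exc:
        raise ValueError(f"interaction model {int_name} not fittable: {exc}") from exc
    ror, lo, hi = odds_ratio_ci(fit, int_name)
    j = fit[int_name]
    return {
        "ror": ror, "ci_low": lo, "ci_high": hi,
        "p": float(fit.p[j]), "coef": float(fit.coef[j]),
        "separation": int_name in fit.separated_terms,
        "n_used": fit.n_used,
    }


_DEGENERATE = {"ror": np.nan, "ci_low": 0.0, "ci_high": np.inf, "p": np.nan,
               "coef": np.nan, "separation": True, "n_used": 0}


def _paired_row(a, b, y, covar_mat, names, covar_names) -> dict:
    """Unadjusted + adjusted interaction fits for one term pair.

    A degenerate cross-tabulation (e.g. the product column collinear with a
    main effect because one stratum has no exposed samples) is reported as a
    flagged row with a missing ROR and an uninformative interval, mirroring
    how separation is reported, rather than aborting the whole family.
    """
    try:
        un = interaction_fit(a, b, y, None, names)
    except ValueError:
        un = dict(_DEGENERATE)
    try:
        ad = interaction_fit(a, b, y, covar_mat, names, covar_names)
    except ValueError:
        ad = dict(_DEGENERATE)
    return {
        "ror": un["ror"], "ci_low": un["ci_low"], "ci_high": un["ci_high"],
        "p": un["p"], "separation": un["separation"],
        "ror_adj": ad["ror"], "ci_adj_low": ad["ci_low"], "ci_adj_high": ad["ci_high"],
        "p_adj": ad["p"], "separation_adj": ad["separation"],
    }


def _add_bh(out: pd.DataFrame) -> pd.DataFrame:
    for col, bh_col in (("p", "p_bh"), ("p_adj", "p_adj_bh")):
        p = out[col].to_numpy(dtype=float)
        ok = np.isfinite(p)
        adj = np.full(p.shape, np.nan)
        if ok.any():
            adj[ok] = bh_adjust(p[ok])
        out[bh_col] = adj
    return out


def _covar_matrix(table: CohortTable, covariates):
    covariates = list(covariates if covariates is not None else table.covariates)
    mat = table.data[covariates].to_numpy(dtype=float) if covariates else None
    return mat, covariates


def ers_snp_interactions(
    ers, doses: DoseMatrix, table: CohortTable, covariates: list[str] | None = None
) -> pd.DataFrame:
    """One interaction model per SNP: outcome ~ ERS + dose + ERS:dose.

    Returns one row per SNP with unadjusted and covariate-adjusted ROR/CI/p
    and BH-adjusted p-values across the SNP family.
    """
    ers = np.asarray(ers, dtype=float)
    if np.nanstd(ers) == 0:
        raise ValueError("ERS is constant; interaction with ERS is not identifiable")
    covar_mat, covariates = _covar_matrix(table, covariates)
    y = table.outcome
    rows = []
    for snp in doses.snp_ids:
        row = {"snp": snp}
        row.update(_paired_row(ers, doses.column(snp), y, covar_mat,
                               ("ERS", snp), covariates))
        rows.append(row)
    return _add_bh(pd.DataFrame(rows))


def grs_env_interactions(
    grs_binary, table: CohortTable, covariates: list[str] | None = None,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """One interaction model per exposure: outcome ~ GRS + E + GRS:E.

    ``grs_binary`` is a dichotomized (weighted or unweighted) genetic risk
    score.  BH adjustment runs across the exposure family.
    """
    g = np.asarray(grs_binary, dtype=float)
    if np.nanstd(g) == 0:
        raise ValueError("dichotomized GRS is constant; interaction not identifiable")
    covar_mat, covariates = _covar_matrix(table, covariates)
    variables = list(variables if variables is not None else table.exposures)
    y = table.outcome
    rows = []
    for name in variables:
        row = {"variable": name}
        row.update(_paired_row(g, table.data[name].to_numpy(dtype=float), y,
                               covar_mat, ("GRS", name), covariates))
        rows.append(row)
    return _add_bh(pd.DataFrame(rows))


def grs_ers_interaction(
    grs_binary, ers, table: CohortTable, covariates: list[str] | None = None
) -> pd.DataFrame:
    """Single-row interaction between the two scores (family of one: the
    BH-adjusted p equals the raw p)."""
    g = np.asarray(grs_binary, dtype=float)
    e = np.asarray(ers, dtype=float)
    for vec, label in ((g, "GRS"), (e, "ERS")):
        if np.nanstd(vec) == 0:
            raise ValueError(f"{label} is constant; interaction not identifiable")
    covar_mat, covariates = _covar_matrix(table, covariates)
    row = {"term": "GRS:ERS"}
    row.update(_paired_row(g, e, table.outcome, covar_mat, ("GRS", "ERS"), covariates))
    return _add_bh(pd.DataFrame([row]))
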