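"""Association analyses: additive coding, exposure and SNP models.

``encode_additive`` orients each marker by its control-group minor allele
and codes genotypes as minor-allele counts (0/1/2).  ``env_association``
fits one logistic model per exposure, univariate and covariate-adjusted,
reporting odds ratios with Wald intervals; ``snp_association`` reports the
published table layout for markers: genotype-count strings per group, a
Cochran-Armitage trend test, and the adjusted additive-model odds ratio.
Benjamini-Hochberg adjustment is applied within each result table's family
of tests, separately per p-value column.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import CohortTable, GenotypeMatrix
from .stats_core import bh_adjust, cochran_armitage, fit_logistic, odds_ratio_ci

__all__ = ["DoseMatrix", "encode_additive", "env_association", "snp_association"]


@dataclass
class DoseMatrix:
    """Samples x SNPs minor-allele counts (0/1/2, NaN = missing) with the
    minor/major allele identities and control minor-allele frequencies."""

    sample_ids: list[str]
    snp_ids: list[str]
    doses: np.ndarray
    minor_allele: dict[str, str] = field(default_factory=dict)
    major_allele: dict[str, str] = field(default_factory=dict)
    control_maf: dict[str, float] = field(default_factory=dict)

    def column(self, snp: str) -> np.ndarray:
        return self.doses[:, self.snp_ids.index(snp)]

    def genotype_count_string(self, snp: str, mask) -> str:
        """'rare/het/common' genotype counts over the masked rows."""
        d = self.column(snp)[np.asarray(mask, bool)]
        return f"{int((d == 2).sum())}/{int((d == 1).sum())}/{int((d == 0).sum())}"


def encode_additive(gm: GenotypeMatrix, outcome) -> DoseMatrix:
    """Code genotype calls as counts of the control-group minor allele.

    The minor allele is the less frequent allele among control calls; an
    exact 0.5 tie is broken alphabetically.  A SNP monomorphic in controls
    but polymorphic in cases is oriented by the pooled frequency (with a
    warning).
    """
    y = np.asarray(outcome, dtype=float)
    controls = y == 0
    n, m = gm.calls.shape
    doses = np.full((n, m), np.nan)
    minor_d, major_d, maf_d = {}, {}, {}
    for j, snp in enumerate(gm.snp_ids):
        col = gm.calls[:, j]

        def allele_freqs(mask) -> dict[str, int]:
            counts: dict[str, int] = {}
            for c in col[mask]:
                if c is not None:
                    for a in c:
                        counts[a] = counts.get(a, 0) + 1
            return counts

        counts = allele_freqs(controls)
        if len(counts) < 2:
            pooled = allele_freqs(np.ones(n, bool))
            if len(pooled) == 2:
                warnings.warn(
                    f"SNP {snp} monomorphic in controls; minor allele from pooled frequency",
                    stacklevel=2,
                )
                counts = pooled
            else:
                counts = pooled  # monomorphic everywhere (or all missing)
        if not counts:
            minor, major, maf = "?", "?", math.nan
        elif len(counts) == 1:
            major = next(iter(counts))
            declared = gm.alleles.get(snp)
            minor = declared[0] if declared and declared[0] != major else "?"
            maf = 0.0
        else:
            (a1, c1), (a2, c2) = sorted(counts.items())  # alphabetical for ties
            minor, major = (a1, a2) if c1 <= c2 else (a2, a1)
            ctl = allele_freqs(controls)
            tot = sum(ctl.values())
            maf = ctl.get(minor, 0) / tot if tot else math.nan
        minor_d[snp], major_d[snp], maf_d[snp] = minor, major, maf
        for i, c in enumerate(col):
            if c is not None:
                doses[i, j] = sum(a == minor for a in c)
    return DoseMatrix(list(gm.sample_ids), list(gm.snp_ids), doses, minor_d, major_d, maf_d)


def _one_variable_fit(x, y, covars: np.ndarray | None, name: str, covar_names=()):
    """Fit logit(y) ~ x (+ covariates); return (fit, or, lo, hi, p, coef, sep)."""
    cols = [np.ones_like(np.asarray(x, dtype=float)), np.asarray(x, dtype=float)]
    terms = ["intercept", name]
    if covars is not None:
        cols.extend(covars.T)
        terms.extend(covar_names or [f"c{j}" for j in range(covars.shape[1])])
    fit = fit_logistic(np.column_stack(cols), y, terms)
    or_, lo, hi = odds_ratio_ci(fit, name)
    j = fit[name]
    return fit, or_, lo, hi, float(fit.p[j]), float(fit.coef[j]), name in fit.separated_terms


def env_association(
    table: CohortTable,
    variables: list[str] | None = None,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Per-exposure logistic association with the outcome.

    Each exposure gets a univariate model (crude OR, Wald 95% CI, p) and a
    model adjusted for the covariates (adjusted OR/CI, p).  Both p-value
    columns are BH-adjusted across the tested exposures.  Separation (for
    example an exposure with zero exposed controls) yields a missing OR with
    a (0, inf) interval rather than a finite estimate.
    """
    variables = list(variables if variables is not None else table.exposures)
    covariates = list(covariates if covariates is not None else table.covariates)
    y = table.outcome
    covar_mat = table.data[covariates].to_numpy(dtype=float) if covariates else None
    rows = []
    for name in variables:
        x = table.data[name].to_numpy(dtype=float)
        _, or_u, lo_u, hi_u, p_u, coef_u, sep_u = _one_variable_fit(x, y, None, name)
        _, or_a, lo_a, hi_a, p_a, coef_a, sep_a = _one_variable_fit(
            x, y, covar_mat, name, covariates
        )
        rows.append({
            "variable": name,
            "or_univariate": or_u, "ci_low": lo_u, "ci_high": hi_u,
            "coef_univariate": coef_u, "separation": sep_u,
            "or_adjusted": or_a, "ci_adj_low": lo_a, "ci_adj_high": hi_a,
            "separation_adjusted": sep_a,
            "p_univariate": p_u, "p_multivariable": p_a,
        })
    out = pd.DataFrame(rows)
    out["p_univariate_bh"] = bh_adjust(out["p_univariate"].to_numpy())
    out["p_multivariable_bh"] = bh_adjust(out["p_multivariable"].to_numpy())
    return out


def snp_association(
    doses: DoseMatrix,
    table: CohortTable,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Per-SNP association: trend test plus additive logistic models.

    Emits the genotype-count strings (rare hom/het/common hom) per group,
    the Cochran-Armitage trend p (unadjusted counts), the crude and
    covariate-adjusted additive odds ratios, and BH-adjusted p columns
    (trend family and multivariable family, each across the SNPs).  A SNP
    with zero dose variance after complete-case reduction is emitted with
    missing statistics.
    """
    covariates = list(covariates if covariates is not None else table.covariates)
    y = table.outcome
    cases, controls = y == 1, y == 0
    covar_mat = table.data[covariates].to_numpy(dtype=float) if covariates else None
    rows = []
    for snp in doses.snp_ids:
        d = doses.column(snp)
        counts_cases = tuple(int((d[cases] == k).sum()) for k in (0, 1, 2))
        counts_controls = tuple(int((d[controls] == k).sum()) for k in (0, 1, 2))
        row = {
            "snp": snp,
            "minor_allele": doses.minor_allele.get(snp, "?"),
            "major_allele": doses.major_allele.get(snp, "?"),
            "counts_cases": doses.genotype_count_string(snp, cases),
            "counts_controls": doses.genotype_count_string(snp, controls),
        }
        obs = d[np.isfinite(d)]
        if obs.size == 0 or np.nanstd(d) == 0:
            row.update({k: np.nan for k in (
                "trend_stat", "p_trend", "or_univariate", "ci_low", "ci_high",
                "coef_univariate", "or_adjusted", "ci_adj_low", "ci_adj_high",
                "p_multivariable")})
            row["separation"] = False
            rows.append(row)
            continue
        stat, p_trend = cochran_armitage(counts_cases, counts_controls)
        _, or_u, lo_u, hi_u, _, coef_u, sep_u = _one_variable_fit(d, y, None, snp)
        _, or_a, lo_a, hi_a, p_a, _, sep_a = _one_variable_fit(d, y, covar_mat, snp, covariates)
        row.update({
            "trend_stat": stat, "p_trend": p_trend,
            "or_univariate": or_u, "ci_low": lo_u, "ci_high": hi_u,
            "coef_univariate": coef_u,
            "or_adjusted": or_a, "ci_adj_low": lo_a, "ci_adj_high": hi_a,
            "p_multivariable": p_a, "separation": sep_u or sep_a,
        })
        rows.append(row)
    out = pd.DataFrame(rows)
    for col, bh_col in (("p_trend", "p_trend_bh"), ("p_multivariable", "p_multivariable_bh")):
        p = out[col].to_numpy(dtype=float)
        ok = np.isfinite(p)
        adj = np.full(p.shape, np.nan)
        if ok.any():
            adj[ok] = bh_adjust(p[ok])
        out[bh_col] = adj
    return out
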