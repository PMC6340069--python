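"""Quality-control filters and the cohort characterisation table.

SNP QC operates on the genotype matrix: markers are dropped when the exact
Hardy-Weinberg test in the CONTROL group gives p < 1e-4 (genotyping-error
signal), then when the missing rate over all study samples exceeds 0.1.
Variable QC drops exposures whose missing rate exceeds 0.05; the five
covariates (age, gender, education, family history, BMI) are reported but
never auto-dropped, since they serve as adjusters downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import CohortTable, GenotypeMatrix
from .stats_core import descriptive_tests, hwe_exact

__all__ = ["QCReport", "filter_snps", "filter_variables", "cohort_summary"]

HWE_P_THRESHOLD = 1e-4
SNP_MISSING_THRESHOLD = 0.1
VARIABLE_MISSING_THRESHOLD = 0.05


@dataclass
class QCReport:
    """Per-item QC decisions; ``items`` has one row per SNP or variable with
    columns (name, missing_rate, hwe_p [SNPs only], kept, reason)."""

    items: pd.DataFrame
    thresholds: dict

    @property
    def kept(self) -> list[str]:
        return self.items.loc[self.items["kept"], "name"].tolist()

    @property
    def dropped(self) -> dict[str, str]:
        d = self.items.loc[~self.items["kept"]]
        return dict(zip(d["name"], d["reason"]))


def _control_genotype_triple(gm: GenotypeMatrix, snp: str, controls) -> tuple[int, int, int]:
    """(hom_a, het, hom_b) genotype counts among controls; orientation is
    irrelevant for the exact HWE test (label-symmetric)."""
    counts = gm.genotype_counts(snp, mask=controls)
    het = sum(v for g, v in counts.items() if g[0] != g[1])
    homs = sorted(v for g, v in counts.items() if g[0] == g[1])
    homs = [0] * (2 - len(homs)) + homs
    return (homs[0], het, homs[1])


def filter_snps(
    gm: GenotypeMatrix,
    outcome,
    hwe_p_threshold: float = HWE_P_THRESHOLD,
    missing_threshold: float = SNP_MISSING_THRESHOLD,
) -> QCReport:
    """Apply HWE (controls only) then missing-rate filtering to every SNP.

    A SNP failing both filters is reported once, with reason ``hwe`` (the
    filters are applied in that order).  Thresholds are strict: drop when
    hwe_p < threshold or missing_rate > threshold.
    """
    y = np.asarray(outcome, dtype=float)
    controls = y == 0
    if not controls.any():
        raise ValueError("no controls present; HWE QC is defined on the control group")
    rows = []
    for snp in gm.snp_ids:
        triple = _control_genotype_triple(gm, snp, controls)
        hwe_p = hwe_exact(*triple) if sum(triple) > 0 else 1.0
        miss = gm.missing_rate(snp)
        if hwe_p < hwe_p_threshold:
            kept, reason = False, "hwe"
        elif miss > missing_threshold:
            kept, reason = False, "missing_rate"
        else:
            kept, reason = True, ""
        rows.append({"name": snp, "missing_rate": miss, "hwe_p": hwe_p,
                     "kept": kept, "reason": reason})
    return QCReport(
        pd.DataFrame(rows),
        {"hwe_p": hwe_p_threshold, "snp_missing": missing_threshold},
    )


def filter_variables(
    table: CohortTable, missing_threshold: float = VARIABLE_MISSING_THRESHOLD
) -> QCReport:
    """Drop exposures with missing rate strictly above the threshold.

    The missing-rate denominator is the full sample size.  Covariates are
    exempt from dropping; their missing rates are still reported.
    """
    n = len(table.data)
    rows = []
    for name in list(table.exposures) + list(table.covariates):
        miss = float(table.data[name].isna().sum() / n)
        exempt = name in table.covariates
        dropped = (miss > missing_threshold) and not exempt
        rows.append({
            "name": name,
            "missing_rate": miss,
            "kept": not dropped,
            "reason": "missing_rate" if dropped else "",
            "covariate": exempt,
        })
    return QCReport(pd.DataFrame(rows), {"variable_missing": missing_threshold})


def cohort_summary(table: CohortTable, continuous: tuple[str, ...] = ("age", "bmi")) -> pd.DataFrame:
    """Descriptive characterisation of the cohort by case/control group.

    Continuous variables get mean, SD, median, min, max and missing count
    per group; categorical ones get the count and percent of non-missing
    observations per level.  Percentages exclude missing values.  The
    ``significant`` column marks variables with a two-group descriptive test
    p < 0.05 (chi-square for categorical, t-test for continuous).
    """
    df = table.data
    groups = {"full": np.ones(len(df), bool),
              "controls": (df["outcome"] == 0).to_numpy(),
              "cases": (df["outcome"] == 1).to_numpy()}
    rows = []
    for name in list(table.covariates) + list(table.exposures):
        v = df[name].to_numpy(dtype=float)
        kind = "continuous" if name in continuous else "categorical"
        res = descriptive_tests(v, table.outcome, name, kind=kind)
        for gname, mask in groups.items():
            x = v[mask]
            obs = x[np.isfinite(x)]
            row = {"variable": name, "kind": kind, "group": gname,
                   "n_missing": int(np.sum(~np.isfinite(x))),
                   "p": res.p, "significant": res.significant}
            if kind == "continuous":
                if obs.size:
                    row.update(mean=obs.mean(), sd=obs.std(ddof=1) if obs.size > 1 else 0.0,
                               median=float(np.median(obs)), min=obs.min(), max=obs.max())
                else:
                    row.update(mean=np.nan, sd=np.nan, median=np.nan, min=np.nan, max=np.nan)
            else:
                n_yes = int((obs == 1).sum())
                row.update(
                    count_yes=n_yes,
                    count_no=int((obs == 0).sum()),
                    pct_yes=100.0 * n_yes / obs.size if obs.size else np.nan,
                )
            rows.append(row)
    return pd.DataFrame(rows)
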