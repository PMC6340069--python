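"""Genetic risk scores from additive SNP doses.

For each QC-passing marker a univariate additive logistic model is fitted;
the risk allele is the minor allele when its per-allele log-OR is positive,
otherwise the major allele (the dose is flipped to 2 - dose).  The
unweighted score U_GRS sums risk-allele doses; the weighted score W_GRS
weights each dose by the magnitude of the per-allele log-OR, so per-allele
contributions are non-negative after risk orientation.  Missing doses are
imputed with the per-SNP mean risk-allele dose.  Both scores are
dichotomized at the pooled cohort median with a strict greater-than rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import DoseMatrix
from .stats_core import fit_logistic

__all__ = ["RiskScores", "compute_grs", "dichotomize"]


@dataclass
class RiskScores:
    """Per-sample genetic risk scores and their dichotomized forms.

    ``snp_info`` has one row per input SNP: risk allele, |log-OR| weight and
    whether the SNP was excluded (separated univariate fit).
    """

    sample_ids: list[str]
    u_grs: np.ndarray
    w_grs: np.ndarray
    u_grs_binary: np.ndarray
    w_grs_binary: np.ndarray
    snp_info: pd.DataFrame

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "u_grs": self.u_grs,
                "w_grs": self.w_grs,
                "u_grs_binary": self.u_grs_binary,
                "w_grs_binary": self.w_grs_binary,
            },
            index=pd.Index(self.sample_ids, name="sample_id"),
        )


def dichotomize(scores) -> np.ndarray:
    """1 where the score strictly exceeds the pooled median, else 0.

    For an even number of samples the median is the midpoint of the two
    central order statistics.  If all scores are identical everything is 0
    (with a warning).
    """
    s = np.asarray(scores, dtype=float)
    if not np.isfinite(s).any():
        raise ValueError("need at least one non-missing score")
    med = float(np.median(s[np.isfinite(s)]))
    if np.nanmin(s) == np.nanmax(s):
        warnings.warn("all scores identical; dichotomized score is all zeros", stacklevel=2)
    return (s > med).astype(int)


def compute_grs(doses: DoseMatrix, outcome, weights: dict[str, float] | None = None) -> RiskScores:
    """Compute unweighted and weighted genetic risk scores.

    Parameters
    ----------
    doses
        QC-passed minor-allele dose matrix.
    outcome
        Binary case/control status used to fit the per-SNP univariate
        weights.
    weights
        Optional externally forced per-SNP weights (used mainly to check the
        all-weights-1 identity W_GRS == U_GRS); when given, risk orientation
        still comes from the fitted sign.
    """
    y = np.asarray(outcome, dtype=float)
    n = len(doses.sample_ids)
    u = np.zeros(n)
    w = np.zeros(n)
    info_rows = []
    for snp in doses.snp_ids:
        d = doses.column(snp).astype(float)
        obs = np.isfinite(d)
        excluded, coef = False, np.nan
        if obs.sum() == 0 or np.nanstd(d) == 0:
            excluded = True
            warnings.warn(f"SNP {snp}: constant/empty dose column, excluded from GRS",
                          stacklevel=2)
        else:
            fit = fit_logistic(
                np.column_stack([np.ones(n), d]), y, ["intercept", snp]
            )
            coef = float(fit.coef[fit[snp]])
            if snp in fit.separated_terms:
                excluded = True
                warnings.warn(f"SNP {snp}: separated univariate fit, excluded from GRS",
                              stacklevel=2)
        if excluded:
            info_rows.append({"snp": snp, "risk_allele": "", "weight": np.nan,
                              "flipped": False, "excluded": True})
            continue
        flipped = coef <= 0
        risk_dose = (2.0 - d) if flipped else d.copy()
        weight = abs(coef) if weights is None else float(weights[snp])
        mean_dose = np.nanmean(risk_dose) if obs.any() else 0.0
        risk_dose[~obs] = mean_dose
        u += risk_dose
        w += weight * risk_dose
        risk_allele = (
            doses.major_allele.get(snp, "?") if flipped else doses.minor_allele.get(snp, "?")
        )
        info_rows.append({"snp": snp, "risk_allele": risk_allele, "weight": weight,
                          "flipped": flipped, "excluded": False})
    return RiskScores(
        sample_ids=list(doses.sample_ids),
        u_grs=u,
        w_grs=w,
        u_grs_binary=dichotomize(u),
        w_grs_binary=dichotomize(w),
        snp_info=pd.DataFrame(info_rows),
    )
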