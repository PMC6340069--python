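"""Shared statistical kernel for the case-control analyses.

Everything downstream (QC, association, risk scores, interaction models)
goes through the primitives here: a logistic-regression fitter (IRLS with
explicit separation handling), the exact conditional Hardy-Weinberg test,
the Cochran-Armitage trend test, Benjamini-Hochberg adjustment, and the
descriptive two-group tests used for cohort characterisation.

The logistic fitter is deliberately small and transparent: it keeps the
per-iteration log-likelihood trace (monotone under IRLS step-halving), and
flags quasi-complete separation instead of reporting a divergent finite
odds ratio -- a pattern that occurs in these data whenever an exposure has
zero exposed controls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "FitResult",
    "fit_logistic",
    "odds_ratio_ci",
    "hwe_exact",
    "cochran_armitage",
    "bh_adjust",
    "descriptive_tests",
    "DescriptiveResult",
]

#: |log-odds| beyond which a coefficient is treated as diverging (separation).
SEPARATION_THRESHOLD = 15.0
#: relative log-likelihood change declaring convergence.
CONVERGENCE_TOL = 1e-10
MAX_ITER = 100


@dataclass
class FitResult:
    """Maximum-likelihood logistic fit for one model.

    Coefficients are on the log-odds scale; standard errors come from the
    inverse observed information.  ``separated_terms`` lists terms whose
    estimates diverged (quasi-complete separation); their odds ratios are
    reported as missing with a one-sided infinite confidence bound rather
    than as a large finite number.
    """

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    converged: bool
    separation: bool
    separated_terms: list[str]
    n_used: int
    loglik: float
    loglik_trace: list[float] = field(default_factory=list, repr=False)

    def __getitem__(self, term: str) -> int:
        try:
            return self.terms.index(term)
        except ValueError:
            raise KeyError(f"term {term!r} not in fit ({self.terms})") from None


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # stable: log sigma(eta) = -log1p(exp(-eta)),  log(1-sigma) = -log1p(exp(eta))
    return float(-(np.logaddexp(0.0, -eta) * y + np.logaddexp(0.0, eta) * (1 - y)).sum())


def fit_logistic(
    design: np.ndarray,
    outcome: np.ndarray,
    terms: list[str] | None = None,
) -> FitResult:
    """Fit logit(P(y=1)) = X beta by iteratively reweighted least squares.

    Parameters
    ----------
    design
        n x p matrix including the intercept column.  Rows containing any
        non-finite value are dropped (complete-case analysis).
    outcome
        Binary 0/1 vector aligned with ``design`` rows.
    terms
        Column names; defaults to ``x0..x{p-1}`` (``x0`` the intercept).

    Raises
    ------
    ValueError
        If the outcome is constant after complete-case reduction, or the
        design is rank-deficient (collinear columns are named).
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if X.ndim != 2 or y.shape[0] != X.shape[0]:
        raise ValueError("design must be 2-D and aligned with outcome")
    if terms is None:
        terms = [f"x{j}" for j in range(X.shape[1])]

    keep = np.isfinite(X).all(axis=1) & np.isfinite(y)
    X, y = X[keep], y[keep]
    n, p = X.shape
    if n < p:
        raise ValueError(f"only {n} complete-case rows for {p} parameters")
    uniq = np.unique(y)
    if not np.isin(uniq, (0.0, 1.0)).all():
        raise ValueError("outcome must be binary 0/1")
    if uniq.size < 2:
        raise ValueError("outcome is constant after complete-case reduction")

    # rank check on the standardized design so collinearity is named, not
    # silently absorbed into a singular information matrix
    scale = np.abs(X).max(axis=0)
    scale[scale == 0] = 1.0
    rank = np.linalg.matrix_rank(X / scale)
    if rank < p:
        _, R = np.linalg.qr(X / scale)
        bad = [terms[j] for j in range(p) if abs(R[j, j]) < 1e-8]
        raise ValueError(f"design is rank-deficient; collinear columns: {bad or terms}")

    beta = np.zeros(p)
    trace = [_log_likelihood(X @ beta, y)]
    converged = False
    singular_info = False
    for _ in range(MAX_ITER):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
        w = mu * (1.0 - mu)
        info = (X * w[:, None]).T @ X
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            singular_info = True
            break
        # step-halving keeps the likelihood monotone on hard problems
        ll_old = trace[-1]
        factor = 1.0
        for _half in range(30):
            cand = beta + factor * step
            ll_new = _log_likelihood(X @ cand, y)
            if ll_new >= ll_old - 1e-12:
                break
            factor /= 2.0
        beta = cand
        trace.append(ll_new)
        if abs(ll_new - ll_old) <= CONVERGENCE_TOL * (abs(ll_old) + 1e-12):
            converged = True
            break

    separated = [terms[j] for j in range(p) if abs(beta[j]) > SEPARATION_THRESHOLD]
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -500, 500)))
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        singular_info = True
        se = np.full(p, np.nan)
    if singular_info and not separated:
        separated = list(terms)

    separation = bool(separated) or singular_info
    with np.errstate(divide="ignore", invalid="ignore"):
        zval = beta / se
    pval = 2.0 * sps.norm.sf(np.abs(zval))
    return FitResult(
        terms=list(terms),
        coef=beta,
        se=se,
        z=zval,
        p=pval,
        converged=converged and not separation,
        separation=separation,
        separated_terms=separated,
        n_used=n,
        loglik=trace[-1],
        loglik_trace=trace,
    )


def odds_ratio_ci(
    fit: FitResult, term: str, level: float = 0.95
) -> tuple[float, float, float]:
    """Odds ratio exp(beta) with a Wald confidence interval for one term.

    A separation-flagged term yields ``(nan, 0, inf)``: the point estimate
    is not identified and only the uninformative interval is reported.
    """
    j = fit[term]
    if term in fit.separated_terms:
        return (math.nan, 0.0, math.inf)
    zq = sps.norm.ppf(0.5 + level / 2.0)
    b, s = fit.coef[j], fit.se[j]
    return (math.exp(b), math.exp(b - zq * s), math.exp(b + zq * s))


def hwe_exact(n_hom_rare: int, n_het: int, n_hom_common: int) -> float:
    """Exact conditional Hardy-Weinberg equilibrium test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count (same parity) whose conditional probability
    does not exceed that of the observed genotype table.  A monomorphic
    marker returns p = 1.
    """
    counts = (n_hom_rare, n_het, n_hom_common)
    if any(c < 0 or c != int(c) for c in counts):
        raise ValueError(f"genotype counts must be non-negative integers, got {counts}")
    if sum(counts) == 0:
        raise ValueError("all genotype counts are zero")
    n_hom_rare, n_het, n_hom_common = (int(c) for c in counts)
    n = n_hom_rare + n_het + n_hom_common
    rare = 2 * min(n_hom_rare, n_hom_common) + n_het
    if rare == 0:
        return 1.0

    # log-probability of each het count given allele totals (hypergeometric-like)
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    lg = math.lgamma
    logp = np.array(
        [
            lg(n + 1) - lg(h + 1) - lg(hr + 1) - lg(hc + 1)
            + h * math.log(2.0)
            - (lg(2 * n + 1) - lg(rare + 1) - lg(2 * n - rare + 1))
            for h, hr, hc in zip(hets, homr, homc)
        ]
    )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[np.searchsorted(hets, n_het)]
    return float(min(1.0, prob[prob <= obs * (1 + 1e-12)].sum()))


def cochran_armitage(
    cases: tuple[int, int, int], controls: tuple[int, int, int]
) -> tuple[float, float]:
    """Cochran-Armitage trend test with additive scores (0, 1, 2).

    Uses the hypergeometric (permutation) variance, so the statistic is the
    squared standardized trend and the two-sided p-value comes from its
    chi-squared(1) reference distribution.

    Returns ``(statistic, p)``; a table with identical case/control genotype
    distributions gives statistic 0 and p = 1.
    """
    r = np.asarray(cases, dtype=float)
    s = np.asarray(controls, dtype=float)
    if (r < 0).any() or (s < 0).any():
        raise ValueError("genotype counts must be non-negative")
    R, S = r.sum(), s.sum()
    if R == 0 or S == 0:
        raise ValueError("both case and control groups must be non-empty")
    n = r + s
    N = R + S
    w = np.array([0.0, 1.0, 2.0])
    t = w @ r - R * (w @ n) / N
    var = R * S / (N * N * (N - 1)) * (N * (w * w) @ n - (w @ n) ** 2)
    if var <= 0:
        return (0.0, 1.0)
    stat = t * t / var
    return (float(stat), float(sps.chi2.sf(stat, df=1)))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR), capped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


@dataclass
class DescriptiveResult:
    """Two-group descriptive test for one cohort variable."""

    variable: str
    kind: str  # "categorical" or "continuous"
    p: float  # chi-square p (categorical) or t-test p (continuous)
    p_wilcoxon: float | None = None  # rank-sum p, continuous only

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def descriptive_tests(values, outcome, variable: str = "", kind: str = "auto") -> DescriptiveResult:
    """Case-vs-control descriptive test for one variable.

    Categorical variables get a Pearson chi-square test (no continuity
    correction); continuous ones get both Welch's t-test and the Wilcoxon
    rank-sum test.  Missing values are excluded pairwise.  A constant
    variable returns p = 1 with a warning.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(outcome, dtype=float)
    ok = np.isfinite(v) & np.isfinite(y)
    v, y = v[ok], y[ok]
    if kind == "auto":
        kind = "categorical" if np.unique(v).size <= 5 else "continuous"
    if np.unique(v).size < 2:
        warnings.warn(f"variable {variable!r} is constant; p set to 1", stacklevel=2)
        return DescriptiveResult(variable, kind, 1.0, 1.0 if kind == "continuous" else None)
    if np.unique(y).size < 2:
        warnings.warn(
            f"variable {variable!r} observed in only one outcome group; p set to 1",
            stacklevel=2,
        )
        return DescriptiveResult(variable, kind, 1.0, 1.0 if kind == "continuous" else None)
    if kind == "categorical":
        levels = np.unique(v)
        table = np.array(
            [[(v[y == g] == lev).sum() for lev in levels] for g in (0.0, 1.0)]
        )
        stat, p, _, _ = sps.chi2_contingency(table, correction=False)
        return DescriptiveResult(variable, kind, float(p))
    a, b = v[y == 1], v[y == 0]
    p_t = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
    p_w = float(sps.ranksums(a, b).pvalue)
    return DescriptiveResult(variable, kind, p_t, p_w)
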