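"""Semi-supervised binary co-clustering for the environmental risk score.

The sample x exposure binary matrix is modelled as a Bernoulli latent block
model: rows (samples) belong to one of two latent clusters, columns
(exposures) to one of two groups, and each (row-cluster, column-group)
block has its own Bernoulli success probability.  The column groups are
SUPERVISED: each exposure is labelled 1 when its univariate odds ratio with
the outcome exceeds 1 (risk direction) and 0 otherwise, and these labels
stay fixed throughout.  Only the row partition is estimated, by
classification EM (CEM): hard row assignments maximizing each row's
classification log-likelihood alternate with block-parameter updates.

Block parameters use add-one (Beta(2,2) MAP) smoothing and the row mixing
proportions a matching Dirichlet(2) MAP, so the traced objective -- the
smoothed complete-data log-likelihood -- is exactly coordinate-ascended and
therefore non-decreasing within every restart; this is asserted at run time.
The best of ``restarts`` random initialisations (by final objective, ties to
the lowest restart index) is kept.

The per-sample environmental risk score (ERS) is then the row cluster with
the higher exposure prevalence on the risk-labelled columns: that cluster
maps to ERS = 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VariableLabels",
    "BlockModelFit",
    "label_variables",
    "mode_impute",
    "cem_cocluster",
    "assign_ers",
]

logger = logging.getLogger(__name__)


@dataclass
class VariableLabels:
    """Supervised column labels: 1 = risk direction (univariate OR > 1)."""

    names: list[str]
    labels: np.ndarray  # int {0,1} per variable
    odds_ratios: np.ndarray  # the univariate ORs that produced the labels

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0/1")


def label_variables(assoc: pd.DataFrame) -> VariableLabels:
    """Label each exposure by the direction of its univariate association.

    Label 1 iff the univariate OR is strictly greater than 1 (equivalently
    the log-odds coefficient is positive); an OR of exactly 1 gives label 0.
    Separation-flagged rows are labelled by the sign of the diverging
    coefficient, extending "OR > 1" naturally to +infinity.
    """
    names = assoc["variable"].tolist()
    coefs = assoc["coef_univariate"].to_numpy(dtype=float)
    ors = assoc["or_univariate"].to_numpy(dtype=float)
    labels = (coefs > 0).astype(int)
    return VariableLabels(names, labels, ors)


@dataclass
class BlockModelFit:
    """Fitted semi-supervised Bernoulli latent block model."""

    row_labels: np.ndarray  # per-sample cluster in {0,1}
    col_labels: np.ndarray  # per-variable group in {0,1}, fixed
    block_params: np.ndarray  # 2x2 Bernoulli success probabilities [row, col]
    row_props: np.ndarray  # row mixing proportions
    loglik: float  # final smoothed complete-data log-likelihood
    loglik_trace: list[float] = field(repr=False, default_factory=list)
    n_restarts: int = 0
    n_reseeds: int = 0
    best_restart: int = -1
    seed: int | None = None
    converged: bool = False


def mode_impute(matrix) -> np.ndarray:
    """Replace missing cells with the column mode (ties favour 0)."""
    x = np.asarray(matrix, dtype=float).copy()
    for j in range(x.shape[1]):
        col = x[:, j]
        miss = ~np.isfinite(col)
        if miss.any():
            obs = col[~miss]
            mode = 1.0 if obs.size and (obs == 1).sum() > (obs == 0).sum() else 0.0
            col[miss] = mode
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("matrix must be binary after imputation")
    return x


def _objective(x, z, col_labels, alpha, pi) -> float:
    """Smoothed complete-data objective: classification log-likelihood plus
    the Beta(2,2)/Dirichlet(2) smoothing terms the M-step maximizes.  Both
    CEM steps coordinate-ascend exactly this quantity, which is what makes
    the monotonicity assertion sound."""
    ll = float(np.log(pi[z]).sum())
    ll += float(np.log(alpha).sum() + np.log1p(-alpha).sum() + np.log(pi).sum())
    for k in (0, 1):
        rows = z == k
        if not rows.any():
            continue
        for l in (0, 1):
            cols = col_labels == l
            if not cols.any():
                continue
            block = x[np.ix_(rows, cols)]
            s = block.sum()
            t = block.size
            ll += s * math.log(alpha[k, l]) + (t - s) * math.log(1 - alpha[k, l])
    return ll


def _m_step(x, z, col_labels):
    """MAP block parameters (add-one smoothing) and row proportions."""
    n = x.shape[0]
    alpha = np.empty((2, 2))
    for k in (0, 1):
        rows = z == k
        for l in (0, 1):
            cols = col_labels == l
            if rows.any() and cols.any():
                block = x[np.ix_(rows, cols)]
                alpha[k, l] = (block.sum() + 1.0) / (block.size + 2.0)
            else:
                alpha[k, l] = 0.5
    pi = np.array([( (z == 0).sum() + 1.0) / (n + 2.0), ((z == 1).sum() + 1.0) / (n + 2.0)])
    return alpha, pi


def _row_scores(x, col_labels, alpha, pi) -> np.ndarray:
    """n x 2 classification log-likelihood of each row under each cluster."""
    scores = np.tile(np.log(pi), (x.shape[0], 1))
    for l in (0, 1):
        cols = col_labels == l
        if not cols.any():
            continue
        s = x[:, cols].sum(axis=1)
        t = cols.sum()
        for k in (0, 1):
            scores[:, k] += s * math.log(alpha[k, l]) + (t - s) * math.log(1 - alpha[k, l])
    return scores


def cem_cocluster(
    matrix,
    col_labels: VariableLabels | np.ndarray,
    restarts: int = 20,
    max_iter: int = 100,
    tol: float = 1e-8,
    seed: int = 0,
) -> BlockModelFit:
    """Fit the semi-supervised Bernoulli block model by classification EM.

    Parameters
    ----------
    matrix
        n x d binary matrix (impute missing cells first; see ``mode_impute``).
    col_labels
        Fixed column groups (``VariableLabels`` or a 0/1 vector).
    restarts
        Number of stratified-random row initialisations; the best final
        objective wins, ties broken by the lowest restart index.

    A restart whose row partition empties is re-seeded (counted in
    ``n_reseeds``); if every restart degenerates a ``RuntimeError`` is
    raised.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("matrix must be binary (mode-impute missing cells first)")
    c = col_labels.labels if isinstance(col_labels, VariableLabels) else np.asarray(col_labels, int)
    if c.shape[0] != x.shape[1]:
        raise ValueError("one column label per matrix column required")

    rng = np.random.default_rng(seed)
    n = x.shape[0]
    best: BlockModelFit | None = None
    n_reseeds = 0
    for r in range(restarts):
        for _attempt in range(50):
            # stratified-random init: a shuffled half/half split
            perm = rng.permutation(n)
            z = np.zeros(n, dtype=int)
            z[perm[n // 2:]] = 1
            alpha, pi = _m_step(x, z, c)
            trace = [_objective(x, z, c, alpha, pi)]
            converged = False
            degenerate = False
            for _ in range(max_iter):
                scores = _row_scores(x, c, alpha, pi)
                z_new = np.argmax(scores, axis=1)  # argmax ties -> lower index
                if (z_new == 0).all() or (z_new == 1).all():
                    degenerate = True
                    break
                alpha, pi = _m_step(x, z_new, c)
                obj = _objective(x, z_new, c, alpha, pi)
                if obj < trace[-1] - 1e-9:
                    raise AssertionError(
                        f"CEM objective decreased ({trace[-1]:.6f} -> {obj:.6f})"
                    )
                stable = bool((z_new == z).all())
                z = z_new
                trace.append(obj)
                if stable or abs(trace[-1] - trace[-2]) < tol:
                    converged = True
                    break
            if not degenerate:
                break
            n_reseeds += 1
            logger.info("restart %d degenerated (empty row cluster); re-seeding", r)
        else:
            continue  # all attempts for this restart degenerate
        if best is None or trace[-1] > best.loglik + 1e-12:
            best = BlockModelFit(
                row_labels=z.copy(), col_labels=c.copy(), block_params=alpha.copy(),
                row_props=pi.copy(), loglik=trace[-1], loglik_trace=list(trace),
                n_restarts=restarts, n_reseeds=n_reseeds, best_restart=r,
                seed=seed, converged=converged,
            )
    if best is None:
        raise RuntimeError("all CEM restarts degenerated to a single row cluster")
    best.n_reseeds = n_reseeds
    return best


def assign_ers(fit: BlockModelFit, labels: VariableLabels | np.ndarray) -> np.ndarray:
    """Map row clusters to the binary environmental risk score.

    The row cluster with the higher (smoothed) exposure prevalence on the
    risk-labelled (label 1) columns becomes ERS = 1.  On an exact tie the
    smaller cluster takes ERS = 1 (logged).  Raises if no risk column
    exists, since the ERS is then undefined.
    """
    c = labels.labels if isinstance(labels, VariableLabels) else np.asarray(labels, int)
    if not (c == 1).any():
        raise ValueError("no risk-labelled (label 1) columns: ERS undefined")
    prev = fit.block_params[:, 1]  # block prevalence on risk columns per row cluster
    if prev[0] == prev[1]:
        sizes = [(fit.row_labels == k).sum() for k in (0, 1)]
        risk_cluster = int(np.argmin(sizes))
        logger.info("risk-column prevalence tie; smaller cluster %d -> ERS=1", risk_cluster)
    else:
        risk_cluster = int(np.argmax(prev))
    return (fit.row_labels == risk_cluster).astype(int)
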