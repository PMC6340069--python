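"""Case-control cohort simulator.

Generates cohorts with the structure the downstream analyses assume:
biallelic genotypes with optional Hardy-Weinberg violation (inbreeding
coefficient F), independent binary exposures, the five standard covariates,
an optional latent binary risk-score variable, and a binary outcome drawn
from a logistic model with configurable main effects and product-term
(gene x environment) interactions.

Case-control sampling is emulated by rejection: individuals are drawn from
the population model and retained until the requested numbers of cases and
controls accrue, so the intercept acts as a baseline-risk calibration knob
and all non-intercept log-odds ratios remain consistently estimable.
Missingness is injected completely at random, after status assignment, to
exercise the QC filters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import study_counts as sc
from .dataio import COVARIATES, CohortTable, GenotypeMatrix

__all__ = [
    "SnpSpec",
    "ExposureSpec",
    "CovariateSpec",
    "ScoreSpec",
    "InteractionSpec",
    "SimulationConfig",
    "Cohort",
    "simulate_cohort",
    "paperlike_config",
]


@dataclass(frozen=True)
class SnpSpec:
    """One biallelic marker: minor-allele frequency, additive per-allele
    log-OR, inbreeding coefficient F (>0 inflates homozygosity, violating
    HWE), and a completely-at-random missing rate."""

    name: str
    maf: float
    log_or: float = 0.0
    f: float = 0.0
    missing_rate: float = 0.0
    alleles: tuple[str, str] = ("G", "A")  # (minor, major)

    def genotype_probs(self) -> tuple[float, float, float]:
        """(hom minor, het, hom major) probabilities: q^2+Fpq, 2pq(1-F), p^2+Fpq."""
        q, p, f = self.maf, 1.0 - self.maf, self.f
        return (q * q + f * p * q, 2 * p * q * (1 - f), p * p + f * p * q)


@dataclass(frozen=True)
class ExposureSpec:
    name: str
    prevalence: float
    log_or: float = 0.0
    missing_rate: float = 0.0


@dataclass(frozen=True)
class CovariateSpec:
    """Covariate generator: ``kind`` is "normal" (params = mean, sd) or
    "bernoulli" (params = prevalence); log_or is per unit / per level."""

    name: str
    kind: str
    params: tuple[float, ...]
    log_or: float = 0.0
    missing_rate: float = 0.0


@dataclass(frozen=True)
class ScoreSpec:
    """Latent binary risk-score variable (e.g., a dichotomized genetic risk
    score) entering the outcome model directly; exposed via ``Cohort.scores``
    rather than the cohort table."""

    name: str
    prevalence: float
    log_or: float = 0.0


@dataclass(frozen=True)
class InteractionSpec:
    """Product term between two named variables (SNP dose, exposure, score,
    or covariate) with the given interaction log-OR."""

    term_a: str
    term_b: str
    log_or: float


@dataclass(frozen=True)
class SimulationConfig:
    n_cases: int
    n_controls: int
    snp_specs: tuple[SnpSpec, ...] = ()
    exposure_specs: tuple[ExposureSpec, ...] = ()
    covariate_specs: tuple[CovariateSpec, ...] = ()
    score_specs: tuple[ScoreSpec, ...] = ()
    interaction_specs: tuple[InteractionSpec, ...] = ()
    intercept: float = 0.0
    seed: int = 0
    draw_budget_factor: int = 200  # max draws = factor * (n_cases + n_controls)

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        for s in self.snp_specs:
            if not (0 <= s.maf <= 1 and 0 <= s.f <= 1 and 0 <= s.missing_rate <= 1):
                raise ValueError(f"SNP {s.name}: maf/F/missing rate must lie in [0,1]")
        for e in self.exposure_specs:
            if not (0 <= e.prevalence <= 1 and 0 <= e.missing_rate <= 1):
                raise ValueError(f"exposure {e.name}: prevalence/missing rate in [0,1]")
        for s in self.score_specs:
            if not 0 <= s.prevalence <= 1:
                raise ValueError(f"score {s.name}: prevalence in [0,1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Cohort:
    """Simulated cohort: genotype matrix + cohort table + generative truth."""

    genotypes: GenotypeMatrix
    table: CohortTable
    truth: SimulationConfig
    scores: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.genotypes.sample_ids != self.table.sample_ids:
            raise ValueError("genotype matrix and cohort table sample ids disagree")


def _draw_batch(cfg: SimulationConfig, rng: np.random.Generator, size: int):
    """Draw one population batch: (doses, exposures, covariates, scores, status)."""
    cols: dict[str, np.ndarray] = {}
    eta = np.full(size, cfg.intercept)
    doses = {}
    for s in cfg.snp_specs:
        pr = s.genotype_probs()
        d = rng.choice([2.0, 1.0, 0.0], size=size, p=np.asarray(pr) / sum(pr))
        doses[s.name] = d
        eta += s.log_or * d
    for e in cfg.exposure_specs:
        x = (rng.random(size) < e.prevalence).astype(float)
        cols[e.name] = x
        eta += e.log_or * x
    for c in cfg.covariate_specs:
        if c.kind == "normal":
            v = rng.normal(c.params[0], c.params[1], size=size)
        elif c.kind == "bernoulli":
            v = (rng.random(size) < c.params[0]).astype(float)
        else:
            raise ValueError(f"unknown covariate kind {c.kind!r}")
        cols[c.name] = v
        eta += c.log_or * v
    scores = {}
    for s in cfg.score_specs:
        v = (rng.random(size) < s.prevalence).astype(float)
        scores[s.name] = v
        eta += s.log_or * v
    lookup = {**doses, **cols, **scores}
    for it in cfg.interaction_specs:
        try:
            eta += it.log_or * lookup[it.term_a] * lookup[it.term_b]
        except KeyError as exc:
            raise ValueError(f"interaction references unknown term {exc}") from None
    prob = 1.0 / (1.0 + np.exp(-eta))
    status = (rng.random(size) < prob).astype(int)
    return doses, cols, scores, status


def simulate_cohort(cfg: SimulationConfig) -> Cohort:
    """Simulate a case-control cohort by rejection sampling.

    Raises
    ------
    RuntimeError
        If either group fails to accrue within the draw budget (an intercept
        so extreme that cases or controls are essentially never produced).
    """
    rng = np.random.default_rng(cfg.seed)
    need = {1: cfg.n_cases, 0: cfg.n_controls}
    kept: dict[int, list[dict]] = {0: [], 1: []}
    total = cfg.n_cases + cfg.n_controls
    budget = cfg.draw_budget_factor * total
    drawn = 0
    batch = max(256, 2 * total)
    while (len(kept[1]) < need[1] or len(kept[0]) < need[0]) and drawn < budget:
        size = min(batch, budget - drawn)
        doses, cols, scores, status = _draw_batch(cfg, rng, size)
        drawn += size
        for i in range(size):
            g = int(status[i])
            if len(kept[g]) < need[g]:
                kept[g].append(
                    {
                        "dose": {k: v[i] for k, v in doses.items()},
                        "col": {k: v[i] for k, v in cols.items()},
                        "score": {k: v[i] for k, v in scores.items()},
                    }
                )
    for g, label in ((1, "case"), (0, "control")):
        if len(kept[g]) < need[g]:
            rate = len(kept[g]) / drawn if drawn else 0.0
            raise RuntimeError(
                f"draw budget exhausted: {label} accrual rate {rate:.2e} too low "
                f"({len(kept[g])}/{need[g]} after {drawn} draws); adjust the intercept"
            )

    # cases first, then controls; ids are stable given the seed
    records = kept[1] + kept[0]
    outcome = np.array([1] * need[1] + [0] * need[0], dtype=float)
    n = len(records)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    snp_ids = [s.name for s in cfg.snp_specs]
    calls = np.empty((n, len(snp_ids)), dtype=object)
    for j, s in enumerate(cfg.snp_specs):
        minor, major = s.alleles
        geno = {2.0: "".join(sorted(minor + minor)), 1.0: "".join(sorted(minor + major)),
                0.0: "".join(sorted(major + major))}
        for i, rec in enumerate(records):
            calls[i, j] = geno[rec["dose"][s.name]]
        if s.missing_rate > 0:
            miss = rng.random(n) < s.missing_rate
            calls[miss, j] = None
    alleles = {s.name: s.alleles for s in cfg.snp_specs}
    gm = GenotypeMatrix(sample_ids, snp_ids, calls, alleles)

    data = {"outcome": outcome}
    for e in cfg.exposure_specs:
        v = np.array([rec["col"][e.name] for rec in records], dtype=float)
        if e.missing_rate > 0:
            v[rng.random(n) < e.missing_rate] = np.nan
        data[e.name] = v
    for c in cfg.covariate_specs:
        v = np.array([rec["col"][c.name] for rec in records], dtype=float)
        if c.missing_rate > 0:
            v[rng.random(n) < c.missing_rate] = np.nan
        data[c.name] = v
    df = pd.DataFrame(data, index=pd.Index(sample_ids, name="sample_id"))
    table = CohortTable(
        df,
        exposures=[e.name for e in cfg.exposure_specs],
        covariates=[c.name for c in cfg.covariate_specs if c.name in COVARIATES],
    )
    scores = {
        s.name: np.array([rec["score"][s.name] for rec in records], dtype=float)
        for s in cfg.score_specs
    }
    return Cohort(gm, table, cfg, scores)


def paperlike_config(seed: int = 0) -> SimulationConfig:
    """Configuration emulating the published Shanghai NHL study design.

    169 cases / 421 controls; 29 candidate SNPs: the 22 retained markers at
    their published control minor-allele frequencies (planted per-allele
    effects = log of the published odds ratios), 3 markers with strong
    Hardy-Weinberg violation (F = 0.6) and 4 with a 20% missing rate so the
    QC stage removes exactly the published seven; 11 exposures at their
    control prevalences (planted effects = log crude odds ratios), plus the
    study's five high-missingness questionnaire variables (12% missing) that
    the environment QC drops.  Retained-marker missing rates follow the
    published genotype totals, capped at 0.06 so QC outcomes are stable.
    """
    snps = []
    for name, (minor, major, (rr, het, cc), (ar, ah, ac)) in sc.SNP_GENOTYPE_COUNTS.items():
        observed = rr + het + cc + ar + ah + ac
        miss = min(max(0.0, 1.0 - observed / (sc.N_CASES + sc.N_CONTROLS)), 0.06)
        snps.append(
            SnpSpec(
                name=name,
                maf=sc.control_maf(name),
                log_or=math.log(sc.SNP_PUBLISHED_OR[name]),
                missing_rate=round(miss, 4),
                alleles=(minor, major),
            )
        )
    for name in sc.SNPS_FAILING_HWE:
        snps.append(SnpSpec(name=name, maf=0.3, f=0.6))
    for name in sc.SNPS_FAILING_MISSING:
        snps.append(SnpSpec(name=name, maf=0.2, missing_rate=0.2))

    exposures = []
    for name in sc.EXPOSURE_COUNTS:
        prev = sc.exposure_control_prevalence(name)
        or_ = sc.crude_or(name)
        if name == "benzene":
            # zero exposed controls in print; emulate a rare, strongly
            # case-enriched exposure
            prev, or_ = 0.01, 30.0
        exposures.append(ExposureSpec(name, prev, math.log(or_), missing_rate=0.003))
    for name in sc.VARIABLES_FAILING_MISSING:
        exposures.append(ExposureSpec(name, 0.3, 0.0, missing_rate=0.12))

    covariates = (
        CovariateSpec("age", "normal", sc.CONTROL_COVARIATES["age"], log_or=-0.015),
        CovariateSpec("gender", "bernoulli", (sc.CONTROL_COVARIATES["gender"],), log_or=0.0),
        CovariateSpec("education", "bernoulli", (sc.CONTROL_COVARIATES["education"],),
                      log_or=math.log(27.5)),
        CovariateSpec("family_history", "bernoulli", (sc.CONTROL_COVARIATES["family_history"],),
                      log_or=math.log(7.6)),
        CovariateSpec("bmi", "normal", sc.CONTROL_COVARIATES["bmi"], log_or=-0.04),
    )
    return SimulationConfig(
        n_cases=sc.N_CASES,
        n_controls=sc.N_CONTROLS,
        snp_specs=tuple(snps),
        exposure_specs=tuple(exposures),
        covariate_specs=covariates,
        intercept=-2.0,
        seed=seed,
    )
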