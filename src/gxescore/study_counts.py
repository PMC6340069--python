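"""Published summary counts from the Shanghai NHL case-control study.

The individual-level data of the motivating study (169 non-Hodgkin lymphoma
cases, 421 hospital controls, 29 candidate SNPs, 21 questionnaire variables)
are not public; what the publication prints are group-level contingency
counts.  Those counts are sufficient inputs for two purposes here:

* exact re-computation of every crude (2x2) environmental odds ratio and of
  the genotype trend tests, and
* calibrating the synthetic cohort generator (control-group minor-allele
  frequencies, exposure prevalences, covariate distributions).

All counts below are transcriptions of the published descriptive and
association tables; they are data, not results of this package.
"""

from __future__ import annotations

N_CASES = 169
N_CONTROLS = 421

#: exposure -> (cases_exposed, cases_unexposed, controls_exposed, controls_unexposed)
EXPOSURE_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "smoking": (75, 94, 153, 267),
    "alcohol": (41, 128, 91, 328),
    "hairdye": (63, 105, 142, 279),
    "farm": (88, 80, 120, 301),
    "ets": (44, 125, 210, 211),  # environmental tobacco smoking
    "benzene": (11, 158, 0, 421),  # zero exposed controls: separation
    "solvent": (21, 148, 60, 361),
    "metal": (8, 161, 14, 407),
    "agrichem": (46, 123, 26, 395),
    "others": (5, 164, 36, 385),  # other occupational exposures
    "pesticide": (43, 126, 25, 396),
}

#: SNP -> (minor allele, major allele,
#:         control (rare hom, het, common hom), case (rare hom, het, common hom))
SNP_GENOTYPE_COUNTS: dict[str, tuple[str, str, tuple[int, int, int], tuple[int, int, int]]] = {
    "rs1518111": ("G", "A", (52, 193, 150), (15, 89, 58)),
    "rs3021094": ("G", "T", (72, 208, 103), (24, 90, 41)),
    "rs1800893": ("T", "C", (5, 125, 260), (3, 90, 68)),
    "rs1056836": ("G", "C", (8, 109, 267), (1, 41, 113)),
    "rs4251961": ("C", "T", (4, 73, 311), (7, 46, 109)),
    "rs1052133": ("G", "C", (89, 186, 123), (31, 99, 32)),
    "rs293795": ("G", "A", (1, 30, 386), (2, 22, 145)),
    "rs2243267": ("C", "G", (14, 180, 188), (6, 75, 74)),
    "rs1041981": ("T", "G", (72, 207, 105), (32, 93, 30)),
    "rs1800630": ("T", "G", (16, 101, 270), (2, 77, 83)),
    "rs1800629": ("A", "G", (2, 61, 319), (1, 20, 134)),
    "rs3917567": ("C", "T", (4, 74, 317), (4, 29, 129)),
    "rs662": ("A", "G", (51, 191, 142), (20, 74, 61)),
    "rs13306698": ("C", "T", (0, 18, 379), (0, 46, 116)),
    "rs854560": ("T", "A", (2, 26, 356), (0, 15, 140)),
    "rs1799931": ("A", "G", (6, 90, 288), (1, 22, 139)),
    "rs743534": ("C", "A", (12, 109, 262), (2, 37, 116)),
    "rs2480258": ("C", "T", (104, 166, 129), (44, 57, 64)),
    "rs3740955": ("A", "G", (16, 141, 255), (8, 67, 92)),
    "rs17655": ("C", "G", (89, 191, 104), (40, 74, 41)),
    "rs1800566": ("T", "C", (80, 197, 107), (39, 72, 44)),
    "rs1799966": ("G", "A", (45, 194, 156), (14, 95, 53)),
}

#: published per-SNP odds ratios (presumed covariate-adjusted); used only as
#: generative effect sizes for the synthetic cohort, never as test oracles.
SNP_PUBLISHED_OR: dict[str, float] = {
    "rs1518111": 1.18, "rs3021094": 0.77, "rs1800893": 2.84, "rs1056836": 0.74,
    "rs4251961": 2.54, "rs1052133": 1.11, "rs293795": 1.73, "rs2243267": 1.01,
    "rs1041981": 1.34, "rs1800630": 2.35, "rs1800629": 0.37, "rs3917567": 1.06,
    "rs662": 0.68, "rs13306698": 10.82, "rs854560": 0.84, "rs1799931": 0.27,
    "rs743534": 0.82, "rs2480258": 0.97, "rs3740955": 1.55, "rs17655": 1.22,
    "rs1800566": 1.21, "rs1799966": 0.95,
}

#: markers the study dropped at QC, by failure mode.
SNPS_FAILING_HWE = ["rs1051740", "rs1346044", "rs2227973"]
SNPS_FAILING_MISSING = ["rs2229094", "rs1799930", "rs915906", "rs13181"]

#: questionnaire variables dropped for missing rate > 0.05.
VARIABLES_FAILING_MISSING = ["smok100", "noeh3", "smok_num", "voltage", "radiation"]

#: control-group covariate distributions (age/BMI: mean, sd; others: prevalence).
CONTROL_COVARIATES = {
    "age": (57.9, 13.7),
    "bmi": (24.3, 6.8),
    "gender": 163 / 421,  # male
    "education": 73 / 421,  # none/primary school
    "family_history": 98 / 420,
}


def control_maf(snp: str) -> float:
    """Control-group minor-allele frequency from the printed genotype counts."""
    _, _, (rr, het, cc), _ = SNP_GENOTYPE_COUNTS[snp]
    n = rr + het + cc
    return (2 * rr + het) / (2 * n)


def exposure_control_prevalence(name: str) -> float:
    ce, cu = EXPOSURE_COUNTS[name][2], EXPOSURE_COUNTS[name][3]
    return ce / (ce + cu)


def reconstruct_cohort() -> "CohortTable":
    """Rebuild a cohort table whose per-variable 2x2 margins equal the
    printed exposure counts.

    The joint distribution of the real data is unrecoverable from printed
    margins, but every UNIVARIATE analysis (crude odds ratios, per-variable
    tests) depends on its variable's 2x2 table only, which this
    reconstruction reproduces exactly.  Group sizes not accounted for by a
    variable's printed counts (its missing values) become NaN.
    """
    from .dataio import CohortTable  # local import avoids a cycle
    import numpy as np
    import pandas as pd

    n = N_CASES + N_CONTROLS
    data = {"outcome": np.r_[np.ones(N_CASES), np.zeros(N_CONTROLS)]}
    for name, (a, b, c, d) in EXPOSURE_COUNTS.items():
        col = np.full(n, np.nan)
        col[:a] = 1.0
        col[a:a + b] = 0.0
        col[N_CASES:N_CASES + c] = 1.0
        col[N_CASES + c:N_CASES + c + d] = 0.0
        data[name] = col
    ids = [f"P{i + 1:04d}" for i in range(n)]
    df = pd.DataFrame(data, index=pd.Index(ids, name="sample_id"))
    return CohortTable(df, exposures=list(EXPOSURE_COUNTS), covariates=[])


def reconstruct_genotypes() -> "GenotypeMatrix":
    """Rebuild a genotype matrix matching the printed per-SNP genotype
    counts per group (same caveat as ``reconstruct_cohort``: only per-SNP
    margins are faithful, not the joint distribution)."""
    from .dataio import GenotypeMatrix
    import numpy as np

    n = N_CASES + N_CONTROLS
    ids = [f"P{i + 1:04d}" for i in range(n)]
    snps = list(SNP_GENOTYPE_COUNTS)
    calls = np.full((n, len(snps)), None, dtype=object)
    for j, snp in enumerate(snps):
        minor, major, ctl, cas = SNP_GENOTYPE_COUNTS[snp]
        geno = ["".join(sorted(minor + minor)), "".join(sorted(minor + major)),
                "".join(sorted(major + major))]
        i = 0
        for g, count in zip(geno, cas):
            calls[i:i + count, j] = g
            i += count
        i = N_CASES
        for g, count in zip(geno, ctl):
            calls[i:i + count, j] = g
            i += count
    alleles = {s: SNP_GENOTYPE_COUNTS[s][:2] for s in snps}
    return GenotypeMatrix(ids, snps, calls, alleles)


def crude_or(name: str) -> float:
    """Cross-product odds ratio from the printed 2x2 exposure counts (inf/0 on
    empty cells)."""
    a, b, c, d = EXPOSURE_COUNTS[name]
    if c == 0 or b == 0:
        return float("inf") if a * d > 0 else float("nan")
    return (a * d) / (b * c)
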