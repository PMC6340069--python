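"""Tabular containers and file formats for the case-control pipeline.

Two in-memory containers carry all data between stages:

``GenotypeMatrix``
    samples x SNPs genotype calls for biallelic markers, each call an
    unordered allele pair (``"AG" == "GA"``) or missing.  Dose coding is
    deliberately NOT done here: minor-allele orientation depends on the
    observed control allele frequencies, so it lives in the association
    module.

``CohortTable``
    per-sample outcome (1 = case, 0 = control), named binary exposures and
    the five standard covariates (age, gender, education, family history,
    BMI).  Missing values are allowed everywhere except the outcome.

On disk, genotypes travel as a CSV calls table or as whitespace-delimited
PED/MAP (6 leading pedigree columns, two allele fields per marker; the PED
phenotype column is ignored in favour of the cohort table's outcome).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "COVARIATES",
    "GenotypeMatrix",
    "CohortTable",
    "read_genotypes",
    "write_genotypes",
    "read_cohort",
    "write_cohort",
    "write_table",
]

#: canonical covariate columns; never auto-dropped by QC, always adjusters.
COVARIATES = ["age", "gender", "education", "family_history", "bmi"]

_MISSING_CALLS = {"", "NA", "00", "0", "--", "NN"}


def _normalize_call(call) -> str | None:
    """Canonicalize one genotype call: sorted 2-letter string or None."""
    if call is None or (isinstance(call, float) and np.isnan(call)):
        return None
    s = str(call).strip().upper().replace(" ", "").replace("/", "")
    if s in _MISSING_CALLS:
        return None
    if len(s) != 2:
        raise ValueError(f"malformed genotype call {call!r}")
    if "0" in s or "N" in s:
        return None
    if not set(s) <= set("ACGT"):
        raise ValueError(f"non-nucleotide allele in call {call!r}")
    return "".join(sorted(s))


@dataclass
class GenotypeMatrix:
    """Samples x SNPs biallelic genotype calls.

    ``calls`` is an object array of canonical calls (``"AG"``) or ``None``.
    ``alleles`` optionally declares (minor, major) per SNP; when absent the
    association stage infers orientation from control allele counts.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    calls: np.ndarray
    alleles: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.snp_ids = [str(s) for s in self.snp_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicated sample id in genotype matrix")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicated SNP id in genotype matrix")
        self.calls = np.asarray(self.calls, dtype=object)
        if self.calls.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        for j, snp in enumerate(self.snp_ids):
            col = [_normalize_call(c) for c in self.calls[:, j]]
            seen = set("".join(c for c in col if c is not None))
            if len(seen) > 2:
                raise ValueError(f"SNP {snp} has >2 alleles ({sorted(seen)}): not biallelic")
            self.calls[:, j] = col

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def missing_rate(self, snp: str) -> float:
        j = self.snp_ids.index(snp)
        col = self.calls[:, j]
        return float(sum(c is None for c in col) / len(col))

    def genotype_counts(self, snp: str, mask=None) -> dict[str, int]:
        """Counts of each observed genotype string, optionally row-masked."""
        j = self.snp_ids.index(snp)
        col = self.calls[:, j] if mask is None else self.calls[np.asarray(mask, bool), j]
        out: dict[str, int] = {}
        for c in col:
            if c is not None:
                out[c] = out.get(c, 0) + 1
        return out

    def subset_snps(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.snp_ids.index(s) for s in keep]
        return GenotypeMatrix(
            self.sample_ids,
            list(keep),
            self.calls[:, idx].copy(),
            {s: self.alleles[s] for s in keep if s in self.alleles},
        )


@dataclass
class CohortTable:
    """Per-sample outcome, binary exposures and covariates.

    ``data`` is indexed by sample id with an ``outcome`` column plus the
    named exposure and covariate columns; binary columns hold {0, 1, NaN}.
    """

    data: pd.DataFrame
    exposures: list[str]
    covariates: list[str] = field(default_factory=lambda: list(COVARIATES))

    def __post_init__(self) -> None:
        df = self.data
        if "outcome" not in df.columns:
            raise ValueError("cohort table must have an 'outcome' column")
        if df["outcome"].isna().any():
            bad = df.index[df["outcome"].isna()].tolist()
            raise ValueError(f"outcome missing for samples {bad[:5]}")
        if not df["outcome"].isin([0, 1]).all():
            raise ValueError("outcome must be 0 (control) or 1 (case)")
        binary_cols = list(self.exposures) + [
            c for c in ("gender", "education", "family_history") if c in df.columns
        ]
        for col in binary_cols:
            vals = df[col].dropna()
            if not vals.isin([0, 1]).all():
                raise ValueError(f"binary column {col!r} contains non-binary values")
        self.data = df

    @property
    def outcome(self) -> np.ndarray:
        return self.data["outcome"].to_numpy(dtype=float)

    @property
    def sample_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def n_cases(self) -> int:
        return int((self.data["outcome"] == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.data["outcome"] == 0).sum())


# ---------------------------------------------------------------------------
# genotype file formats


def read_genotypes(path, format: str = "csv-calls", map_path=None) -> GenotypeMatrix:
    """Read a genotype table (``csv-calls`` or ``ped-map``).

    For ``ped-map`` the companion ``.map`` file supplies SNP ids (column 2);
    ``map_path`` defaults to the PED path with a ``.map`` suffix.
    """
    path = Path(path)
    if format == "csv-calls":
        df = pd.read_csv(path, dtype=str, index_col=0, keep_default_na=False)
        return GenotypeMatrix(list(df.index), list(df.columns), df.to_numpy(dtype=object))
    if format == "ped-map":
        map_path = Path(map_path) if map_path else path.with_suffix(".map")
        if not map_path.exists():
            raise FileNotFoundError(f"companion map file {map_path} not found")
        snp_ids = [line.split()[1] for line in map_path.read_text().splitlines() if line.strip()]
        sample_ids, rows = [], []
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * len(snp_ids):
                raise ValueError(
                    f"PED line for sample {fields[1] if len(fields) > 1 else '?'} has "
                    f"{len(fields)} fields, expected {6 + 2 * len(snp_ids)}"
                )
            sample_ids.append(fields[1])
            alleles = fields[6:]
            rows.append(
                [
                    None if "0" in (a1, a2) or "N" in (a1, a2) else a1 + a2
                    for a1, a2 in zip(alleles[0::2], alleles[1::2])
                ]
            )
        return GenotypeMatrix(sample_ids, snp_ids, np.array(rows, dtype=object))
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(gm: GenotypeMatrix, path, format: str = "csv-calls", map_path=None) -> None:
    path = Path(path)
    if format == "csv-calls":
        df = pd.DataFrame(
            [[c if c is not None else "" for c in row] for row in gm.calls],
            index=pd.Index(gm.sample_ids, name="sample_id"),
            columns=gm.snp_ids,
        )
        df.to_csv(path)
        return
    if format == "ped-map":
        map_path = Path(map_path) if map_path else path.with_suffix(".map")
        map_path.write_text(
            "".join(f"0\t{snp}\t0\t{j + 1}\n" for j, snp in enumerate(gm.snp_ids))
        )
        with open(path, "w") as fh:
            for sid, row in zip(gm.sample_ids, gm.calls):
                geno = " ".join("0 0" if c is None else f"{c[0]} {c[1]}" for c in row)
                fh.write(f"FAM {sid} 0 0 0 -9 {geno}\n")
        return
    raise ValueError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# cohort table and result tables


def read_cohort(path, exposures: list[str] | None = None) -> CohortTable:
    """Read a cohort CSV (sample_id, outcome, covariates, exposures).

    Missing cells may be empty or ``NA``.  Columns that are neither the
    outcome nor covariates are treated as exposures unless listed.
    """
    df = pd.read_csv(path, index_col=0, na_values=["NA", ""])
    df.index = df.index.map(str)
    if exposures is None:
        exposures = [c for c in df.columns if c != "outcome" and c not in COVARIATES]
    return CohortTable(df, list(exposures), [c for c in COVARIATES if c in df.columns])


def write_cohort(table: CohortTable, path) -> None:
    out = table.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, na_rep="NA")


def write_table(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    """Write a results table (association/interaction rows) as CSV."""
    df.to_csv(path, index=False, na_rep="NA", float_format=float_format)
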