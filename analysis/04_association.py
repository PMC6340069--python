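#!/usr/bin/env python
"""Exposure and SNP association tables on the QC-passed simulated cohort.

Fits the univariate and covariate-adjusted logistic models per exposure and
the trend test + additive logistic model per SNP, with BH adjustment within
each table, and prints the rows significant after FDR control.
"""

from pathlib import Path

import pandas as pd

from gxescore.association import encode_additive, env_association, snp_association
from gxescore.dataio import read_cohort, read_genotypes, write_table

OUT = Path("results/analysis")


def kept(kind: str) -> list[str]:
    qc = pd.read_csv(OUT / "qc_report.csv")
    return qc.loc[(qc["kind"] == kind) & qc["kept"], "name"].tolist()


def main() -> None:
    gm = read_genotypes(OUT / "genotypes.csv")
    table = read_cohort(OUT / "cohort.csv")
    kept_env = [v for v in kept("variable") if v in table.exposures]

    env = env_association(table, kept_env)
    write_table(env, OUT / "table2_env_association.csv")
    sig = env[env["p_univariate_bh"] < 0.05]
    print(f"exposures significant after BH (univariate): {sig['variable'].tolist()}")

    doses = encode_additive(gm.subset_snps(kept("snp")), table.outcome)
    snp = snp_association(doses, table)
    write_table(snp, OUT / "table3_snp_association.csv")
    sig = snp[snp["p_trend_bh"] < 0.05]
    print(f"SNPs significant after BH (trend): {sig['snp'].tolist()}")


if __name__ == "__main__":
    main()
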