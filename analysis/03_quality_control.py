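#!/usr/bin/env python
"""Genotype and variable QC on the simulated cohort.

Applies the control-group exact Hardy-Weinberg filter (p < 1e-4), the SNP
missing-rate filter (> 0.1) and the variable missing-rate filter (> 0.05),
then writes the QC report and the descriptive characterisation table.
Expected finding: 29 -> 22 SNPs (3 dropped for HWE, 4 for missingness) and
16 retained variables of which 11 are environmental, matching the study's
narrative by construction.
"""

from pathlib import Path

import pandas as pd

from gxescore.dataio import read_cohort, read_genotypes, write_table
from gxescore.qc import cohort_summary, filter_snps, filter_variables

OUT = Path("results/analysis")


def main() -> None:
    gm = read_genotypes(OUT / "genotypes.csv")
    table = read_cohort(OUT / "cohort.csv")
    snp_qc = filter_snps(gm, table.outcome)
    var_qc = filter_variables(table)
    report = pd.concat(
        [snp_qc.items.assign(kind="snp"), var_qc.items.assign(kind="variable")],
        ignore_index=True,
    )
    write_table(report, OUT / "qc_report.csv")
    write_table(cohort_summary(table), OUT / "table1_characteristics.csv")
    kept_env = [v for v in var_qc.kept if v in table.exposures]
    print(f"SNPs: {len(gm.snp_ids)} -> {len(snp_qc.kept)} kept "
          f"({list(snp_qc.dropped.values()).count('hwe')} HWE, "
          f"{list(snp_qc.dropped.values()).count('missing_rate')} missing-rate)")
    print(f"variables: kept {len(kept_env)} environmental + {len(table.covariates)} covariates; "
          f"dropped {sorted(var_qc.dropped)}")


if __name__ == "__main__":
    main()
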