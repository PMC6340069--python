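#!/usr/bin/env python
"""Gene-environment interaction analyses on the simulated cohort.

Fits the three interaction families -- ERS x SNP (per marker), dichotomized
weighted GRS x exposure (per exposure), and GRS x ERS -- each with and
without covariate adjustment, reporting ratios of odds ratios with BH
adjustment within each family.
"""

from pathlib import Path

import pandas as pd

from gxescore.association import encode_additive
from gxescore.dataio import read_cohort, read_genotypes, write_table
from gxescore.interaction import (
    ers_snp_interactions,
    grs_env_interactions,
    grs_ers_interaction,
)

OUT = Path("results/analysis")


def main() -> None:
    gm = read_genotypes(OUT / "genotypes.csv")
    table = read_cohort(OUT / "cohort.csv")
    qc = pd.read_csv(OUT / "qc_report.csv")
    kept_snps = qc.loc[(qc["kind"] == "snp") & qc["kept"], "name"].tolist()
    kept_env = pd.read_csv(OUT / "table2_env_association.csv")["variable"].tolist()
    scores = pd.read_csv(OUT / "risk_scores.csv", index_col=0)
    table = type(table)(table.data, kept_env, table.covariates)

    ers = scores["ers"].to_numpy(dtype=float)
    grs = scores["w_grs_binary"].to_numpy(dtype=float)
    doses = encode_additive(gm.subset_snps(kept_snps), table.outcome)

    t4 = ers_snp_interactions(ers, doses, table)
    write_table(t4, OUT / "table4_ers_snp_interaction.csv")
    best = t4.loc[t4["p"].idxmin()]
    print(f"ERS x SNP: smallest raw p {best['p']:.3g} ({best['snp']}, "
          f"ROR {best['ror']:.2f}); {int((t4['p_bh'] < 0.05).sum())} significant after BH")

    t5 = grs_env_interactions(grs, table)
    write_table(t5, OUT / "table5_grs_env_interaction.csv")
    finite = t5[t5["p"].notna()]
    best = finite.loc[finite["p"].idxmin()]
    print(f"W_GRS x exposure: smallest raw p {best['p']:.3g} ({best['variable']}, "
          f"ROR {best['ror']:.2f}); {int((t5['p_bh'] < 0.05).sum())} significant after BH")

    t6 = grs_ers_interaction(grs, ers, table)
    write_table(t6, OUT / "grs_ers_interaction.csv")
    print(f"GRS x ERS: ROR {t6['ror'].iloc[0]:.2f}, p {t6['p'].iloc[0]:.2f}")


if __name__ == "__main__":
    main()
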