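#!/usr/bin/env python
"""Environmental and genetic risk scores on the simulated cohort.

The environmental risk score (ERS) comes from semi-supervised Bernoulli
co-clustering of the sample x exposure matrix (columns labelled by the
direction of their crude odds ratio, rows clustered by classification EM);
the genetic risk scores sum risk-allele doses, unweighted and weighted by
per-SNP |log-OR|, each dichotomized at the cohort median.
"""

import argparse
from pathlib import Path

import pandas as pd

from gxescore.association import encode_additive
from gxescore.blockmodel import assign_ers, cem_cocluster, label_variables, mode_impute
from gxescore.dataio import read_cohort, read_genotypes
from gxescore.risk_scores import compute_grs

OUT = Path("results/analysis")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    gm = read_genotypes(OUT / "genotypes.csv")
    table = read_cohort(OUT / "cohort.csv")
    qc = pd.read_csv(OUT / "qc_report.csv")
    kept_snps = qc.loc[(qc["kind"] == "snp") & qc["kept"], "name"].tolist()
    env = pd.read_csv(OUT / "table2_env_association.csv")
    kept_env = env["variable"].tolist()

    labels = label_variables(env)
    fit = cem_cocluster(
        mode_impute(table.data[kept_env].to_numpy(dtype=float)), labels, seed=args.seed
    )
    ers = assign_ers(fit, labels)
    y = table.outcome
    print(f"ERS=1 rate: cases {ers[y == 1].mean():.2f}, controls {ers[y == 0].mean():.2f} "
          f"(risk-labelled variables: {[n for n, l in zip(labels.names, labels.labels) if l]})")

    doses = encode_additive(gm.subset_snps(kept_snps), y)
    scores = compute_grs(doses, y)
    frame = scores.frame()
    frame["ers"] = ers
    frame.to_csv(OUT / "risk_scores.csv")
    for col in ("u_grs", "w_grs"):
        med_case = frame.loc[y == 1, col].median()
        med_ctl = frame.loc[y == 0, col].median()
        print(f"{col}: median cases {med_case:.2f} vs controls {med_ctl:.2f}")


if __name__ == "__main__":
    main()
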