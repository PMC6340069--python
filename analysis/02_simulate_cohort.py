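#!/usr/bin/env python
"""Simulate the study-sized synthetic cohort used by the rest of the analysis.

Draws 169 cases / 421 controls with 29 candidate markers (22 at the
published control minor-allele frequencies, 3 with planted Hardy-Weinberg
violation, 4 with a planted high missing rate), 11 exposures at their
control prevalences plus 5 high-missingness questionnaire variables, and
the five covariates.  Writes genotypes.csv and cohort.csv for the
downstream numbered scripts.
"""

import argparse
from pathlib import Path

from gxescore.dataio import write_cohort, write_genotypes
from gxescore.synthetic import paperlike_config, simulate_cohort

OUT = Path("results/analysis")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(paperlike_config(seed=args.seed))
    write_genotypes(cohort.genotypes, OUT / "genotypes.csv")
    write_cohort(cohort.table, OUT / "cohort.csv")
    t = cohort.table
    print(f"simulated {t.n_cases} cases / {t.n_controls} controls, "
          f"{len(cohort.genotypes.snp_ids)} SNPs, {len(t.exposures)} candidate variables")


if __name__ == "__main__":
    main()
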