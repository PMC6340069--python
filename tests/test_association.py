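"""Additive coding and the exposure/SNP association tables."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gxescore import study_counts as sc
from gxescore.association import encode_additive, env_association, snp_association
from gxescore.dataio import CohortTable, GenotypeMatrix, write_table
from gxescore.stats_core import fit_logistic


@pytest.fixture(scope="module")
def printed_cohort():
    return sc.reconstruct_cohort()


@pytest.fixture(scope="module")
def printed_doses(printed_cohort):
    return encode_additive(sc.reconstruct_genotypes(), printed_cohort.outcome)


class TestEncodeAdditive:
    def test_het_call_counts_one_minor_allele(self):
        gm = GenotypeMatrix(
            ["a", "b", "c"], ["rs1"],
            np.array([["AG"], ["GG"], ["AA"]], dtype=object),
        )
        doses = encode_additive(gm, np.array([1, 0, 0]))
        # among controls (b, c): alleles G,G,A,A -> tie broken alphabetically: A minor
        assert doses.minor_allele["rs1"] == "A"
        assert doses.column("rs1").tolist() == [1.0, 0.0, 2.0]

    def test_control_maf_matches_printed_counts(self, printed_doses):
        """Control counts 52/193/150 give maf (2*52+193)/790 ~ 0.376 with the
        published minor allele."""
        assert printed_doses.control_maf["rs1518111"] == pytest.approx(
            (2 * 52 + 193) / (2 * 395)
        )
        assert printed_doses.minor_allele["rs1518111"] == "G"

    def test_all_printed_mafs_below_half(self, printed_doses):
        for snp, maf in printed_doses.control_maf.items():
            assert maf <= 0.5, snp

    def test_allele_flip_negates_fitted_log_or(self):
        rng = np.random.default_rng(5)
        n = 400
        dose = rng.integers(0, 3, n).astype(float)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-0.5 + 0.6 * dose)))).astype(float)
        f1 = fit_logistic(np.column_stack([np.ones(n), dose]), y)
        f2 = fit_logistic(np.column_stack([np.ones(n), 2 - dose]), y)
        assert f1.coef[1] == pytest.approx(-f2.coef[1], rel=1e-6)

    def test_monomorphic_in_controls_uses_pooled_with_warning(self):
        calls = np.array([["AG"], ["AA"], ["AA"], ["AA"]], dtype=object)
        gm = GenotypeMatrix(list("abcd"), ["rs1"], calls)
        with pytest.warns(UserWarning, match="monomorphic in controls"):
            doses = encode_additive(gm, np.array([1, 1, 0, 0]))
        assert doses.minor_allele["rs1"] == "G"


class TestEnvAssociation:
    def test_reproduces_all_printed_crude_ors(self, printed_cohort):
        """Every printed univariate OR equals the cross-product ratio of its
        2x2 counts (10 regular exposures to 2 dp; benzene separates)."""
        out = env_association(printed_cohort).set_index("variable")
        for name, (a, b, c, d) in sc.EXPOSURE_COUNTS.items():
            row = out.loc[name]
            if name == "benzene":
                assert row["separation"]
                assert math.isnan(row["or_univariate"])
                assert row["ci_low"] == 0.0 and math.isinf(row["ci_high"])
            else:
                assert row["or_univariate"] == pytest.approx((a * d) / (b * c), rel=1e-6)

    def test_ets_and_farm_match_published_table(self, printed_cohort):
        out = env_association(printed_cohort).set_index("variable")
        assert round(out.loc["ets", "or_univariate"], 2) == 0.35
        assert round(out.loc["farm", "or_univariate"], 2) == 2.76

    def test_bh_family_is_the_table(self, printed_cohort):
        full = env_association(printed_cohort).set_index("variable")
        fewer = env_association(printed_cohort, variables=["smoking", "agrichem"]).set_index(
            "variable"
        )
        for v in ("smoking", "agrichem"):
            assert fewer.loc[v, "p_univariate"] == pytest.approx(
                full.loc[v, "p_univariate"]
            )
        assert not np.allclose(
            fewer["p_univariate_bh"], full.loc[["smoking", "agrichem"], "p_univariate_bh"]
        )

    def test_null_exposure_p_uniform(self):
        """p-values of an unrelated exposure are uniform under the null
        (Kolmogorov-Smirnov over 400 small replicates)."""
        rng = np.random.default_rng(11)
        n = 120
        pvals = []
        for _ in range(400):
            df = pd.DataFrame({
                "outcome": rng.permutation(np.r_[np.ones(n // 2), np.zeros(n // 2)]),
                "expo": (rng.random(n) < 0.4).astype(float),
            }, index=[f"s{i}" for i in range(n)])
            t = CohortTable(df, ["expo"], [])
            pvals.append(env_association(t)["p_univariate"].iloc[0])
        assert sps.kstest(pvals, "uniform").pvalue > 1e-3


class TestSnpAssociation:
    def test_printed_sparse_snp_trend_p(self, printed_doses, printed_cohort):
        out = snp_association(printed_doses, printed_cohort).set_index("snp")
        assert out.loc["rs13306698", "p_trend"] < 1e-10

    def test_genotype_count_strings_match_printed_table(self, printed_doses, printed_cohort):
        out = snp_association(printed_doses, printed_cohort).set_index("snp")
        for snp, (_, _, ctl, cas) in sc.SNP_GENOTYPE_COUNTS.items():
            assert out.loc[snp, "counts_controls"] == "/".join(map(str, ctl))
            assert out.loc[snp, "counts_cases"] == "/".join(map(str, cas))

    def test_identical_distributions_null(self):
        calls = (["GG"] * 10 + ["AG"] * 20 + ["AA"] * 30) * 2
        gm = GenotypeMatrix([f"s{i}" for i in range(120)], ["rs1"],
                            np.array(calls, dtype=object).reshape(-1, 1))
        y = np.r_[np.ones(60), np.zeros(60)]
        df = pd.DataFrame({"outcome": y}, index=gm.sample_ids)
        t = CohortTable(df, [], [])
        doses = encode_additive(gm, y)
        out = snp_association(doses, t, covariates=[])
        assert out["or_univariate"].iloc[0] == pytest.approx(1.0, abs=1e-8)
        assert out["p_trend"].iloc[0] == pytest.approx(1.0)

    def test_zero_variance_snp_emits_missing_row(self):
        calls = ["AA"] * 40
        gm = GenotypeMatrix([f"s{i}" for i in range(40)], ["rs_flat"],
                            np.array(calls, dtype=object).reshape(-1, 1))
        y = np.r_[np.ones(20), np.zeros(20)]
        t = CohortTable(pd.DataFrame({"outcome": y}, index=gm.sample_ids), [], [])
        out = snp_association(encode_additive(gm, y), t, covariates=[])
        assert len(out) == 1
        assert math.isnan(out["p_trend"].iloc[0]) and math.isnan(out["or_adjusted"].iloc[0])

    def test_count_string_round_trips_csv(self, tmp_path, printed_doses, printed_cohort):
        out = snp_association(printed_doses, printed_cohort)
        write_table(out, tmp_path / "t3.csv")
        back = pd.read_csv(tmp_path / "t3.csv")
        assert (back["counts_controls"] == out["counts_controls"]).all()
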