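"""Generator correctness: determinism, genotype law, effect recovery."""

import math

import numpy as np
import pandas as pd
import pytest

from gxescore.stats_core import fit_logistic, hwe_exact
from gxescore.synthetic import (
    ExposureSpec,
    InteractionSpec,
    ScoreSpec,
    SimulationConfig,
    SnpSpec,
    paperlike_config,
    simulate_cohort,
)


class TestSimulateCohort:
    def test_identical_seed_gives_identical_cohort(self):
        cfg = paperlike_config(seed=123)
        c1, c2 = simulate_cohort(cfg), simulate_cohort(cfg)
        assert (c1.genotypes.calls == c2.genotypes.calls).all()
        pd.testing.assert_frame_equal(c1.table.data, c2.table.data)

    def test_different_seed_differs(self):
        c1 = simulate_cohort(paperlike_config(seed=1))
        c2 = simulate_cohort(paperlike_config(seed=2))
        assert not c1.table.data["age"].equals(c2.table.data["age"])

    def test_genotypes_follow_hwe_when_f_zero(self):
        n = 5000
        maf = 0.3
        cfg = SimulationConfig(
            n_cases=n, n_controls=n,
            snp_specs=(SnpSpec("rs1", maf=maf),), seed=3,
        )
        cohort = simulate_cohort(cfg)
        counts = cohort.genotypes.genotype_counts("rs1")
        total = sum(counts.values())
        expected = {"GG": maf**2, "AG": 2 * maf * (1 - maf), "AA": (1 - maf) ** 2}
        from scipy import stats as sps

        gof = sps.chisquare(
            [counts.get(g, 0) for g in expected],
            [p * total for p in expected.values()],
        )
        assert gof.pvalue > 1e-3  # genotype law consistent with HWE proportions

    def test_inbreeding_inflates_homozygosity(self):
        cfg = SimulationConfig(
            n_cases=2000, n_controls=2000,
            snp_specs=(SnpSpec("rs1", maf=0.3, f=0.5),), seed=4,
        )
        counts = simulate_cohort(cfg).genotypes.genotype_counts("rs1")
        total = sum(counts.values())
        het = counts.get("AG", 0) / total
        assert het < 2 * 0.3 * 0.7 * 0.7  # 2pq(1-F) plus margin

    def test_null_effects_balance_exposure_prevalence(self):
        cfg = SimulationConfig(
            n_cases=4000, n_controls=4000,
            exposure_specs=(ExposureSpec("e", 0.4, 0.0),), seed=5,
        )
        t = simulate_cohort(cfg).table
        prev_cases = t.data.loc[t.data["outcome"] == 1, "e"].mean()
        prev_controls = t.data.loc[t.data["outcome"] == 0, "e"].mean()
        se = math.sqrt(2 * 0.4 * 0.6 / 4000)
        assert abs(prev_cases - prev_controls) < 4 * se

    def test_planted_snp_effect_recovered(self):
        cfg = SimulationConfig(
            n_cases=5000, n_controls=5000,
            snp_specs=(SnpSpec("rs1", maf=0.3, log_or=math.log(2.0)),),
            intercept=-1.0, seed=6,
        )
        cohort = simulate_cohort(cfg)
        geno = cohort.genotypes.calls[:, 0]
        dose = np.array([0.0 if g == "AA" else 1.0 if g == "AG" else 2.0 for g in geno])
        fit = fit_logistic(
            np.column_stack([np.ones(dose.size), dose]), cohort.table.outcome
        )
        assert 1.8 <= math.exp(fit.coef[1]) <= 2.2

    def test_mcar_missingness_near_configured_rate(self):
        cfg = SimulationConfig(
            n_cases=2000, n_controls=2000,
            snp_specs=(SnpSpec("rs1", maf=0.3, missing_rate=0.1),),
            exposure_specs=(ExposureSpec("e", 0.4, missing_rate=0.05),), seed=7,
        )
        cohort = simulate_cohort(cfg)
        assert cohort.genotypes.missing_rate("rs1") == pytest.approx(0.1, abs=0.02)
        assert cohort.table.data["e"].isna().mean() == pytest.approx(0.05, abs=0.015)

    def test_extreme_intercept_exhausts_budget_with_named_group(self):
        cfg = SimulationConfig(
            n_cases=100, n_controls=100, intercept=-30.0, seed=8,
            draw_budget_factor=20,
        )
        with pytest.raises(RuntimeError, match="case accrual rate"):
            simulate_cohort(cfg)

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError, match="maf"):
            SimulationConfig(n_cases=10, n_controls=10,
                             snp_specs=(SnpSpec("rs1", maf=1.5),))
        with pytest.raises(ValueError, match="positive"):
            SimulationConfig(n_cases=0, n_controls=10)


class TestPaperlikeConfig:
    def test_pure_function(self):
        assert paperlike_config(seed=3) == paperlike_config(seed=3)

    def test_study_dimensions(self):
        cfg = paperlike_config()
        assert cfg.n_cases == 169 and cfg.n_controls == 421
        assert len(cfg.snp_specs) == 29
        assert len(cfg.exposure_specs) == 16
        planted_hwe = [s for s in cfg.snp_specs if s.f > 0]
        planted_missing = [s for s in cfg.snp_specs if s.missing_rate > 0.1]
        assert len(planted_hwe) == 3 and len(planted_missing) == 4
        high_missing_vars = [e for e in cfg.exposure_specs if e.missing_rate > 0.05]
        assert len(high_missing_vars) == 5


class TestHweFilterSize:
    def test_null_rejection_rate_is_tiny(self, rng):
        """Under HWE (F=0) the exact test at p<1e-4 rejects in well under
        0.1% of replicates (the filter has almost no false-positive cost)."""
        probs = np.array([0.09, 0.42, 0.49])  # maf 0.3
        rejections = 0
        n_rep = 2000
        for counts in rng.multinomial(400, probs, size=n_rep):
            if hwe_exact(*counts) < 1e-4:
                rejections += 1
        assert rejections / n_rep <= 0.002


class TestPlantedInteractionRecovery:
    def test_score_exposure_interaction_recovered(self):
        """Refitting the score x exposure product model on large simulated
        cohorts recovers the planted interaction within 3 SE in >=95% of
        replicates."""
        beta_int = math.log(0.23)
        hits = 0
        n_rep = 60
        for rep in range(n_rep):
            cfg = SimulationConfig(
                n_cases=1000, n_controls=1000,
                exposure_specs=(ExposureSpec("smoking", 0.36, math.log(1.39)),),
                score_specs=(ScoreSpec("grs", 0.5, math.log(1.5)),),
                interaction_specs=(InteractionSpec("grs", "smoking", beta_int),),
                intercept=-1.0, seed=1000 + rep,
            )
            cohort = simulate_cohort(cfg)
            g = cohort.scores["grs"]
            e = cohort.table.data["smoking"].to_numpy(dtype=float)
            y = cohort.table.outcome
            X = np.column_stack([np.ones_like(g), g, e, g * e])
            fit = fit_logistic(X, y, ["b0", "grs", "smoking", "grs:smoking"])
            j = fit["grs:smoking"]
            if abs(fit.coef[j] - beta_int) <= 3 * fit.se[j]:
                hits += 1
        assert hits / n_rep >= 0.95
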