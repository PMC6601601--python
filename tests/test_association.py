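"""Association layer: chi-square, ORs, genetic models, normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from amplisnp import (
    CohortConfig,
    anova_by_genotype,
    assoc_genetic_models,
    bonferroni_threshold,
    encode_genetic_model,
    haplotype_assoc,
    logistic_fit,
    odds_ratio_2x2,
    orq_normalize,
    pearson_chi2_2x2,
    simulate_cohort,
    simulate_genotypes,
    welch_t,
)
from amplisnp.association import GENETIC_MODELS, SeparationError
from amplisnp.popgen import em_haplotype_freqs, haplotype_dosages
from amplisnp.simulate import HaplotypeFreqs

from conftest import STUDY_FREQS


class TestChi2:
    def test_heterozygote_vs_rest_published_counts(self):
        # PvuII TC row: cases 57/45, controls 47/65
        res = pearson_chi2_2x2(57, 45, 47, 65)
        assert res.chi2 == pytest.approx(4.14, abs=0.01)
        assert res.p == pytest.approx(0.042, abs=0.001)

    def test_equal_proportions_give_zero(self):
        res = pearson_chi2_2x2(25, 25, 25, 25)
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_xbai_heterozygote_row(self):
        res = pearson_chi2_2x2(57, 45, 44, 68)
        assert res.chi2 == pytest.approx(5.90, abs=0.02)
        assert res.p == pytest.approx(0.015, abs=0.001)

    def test_zero_margin_flagged(self):
        with pytest.warns(UserWarning, match="zero margin"):
            res = pearson_chi2_2x2(0, 0, 10, 10)
        assert not res.defined


class TestOddsRatio:
    def test_balanced_table_is_null(self):
        res = odds_ratio_2x2(25, 25, 25, 25)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.ci_low < 1 < res.ci_high
        assert res.ci_low * res.ci_high == pytest.approx(1.0)

    def test_unadjusted_overdominant_cross_product(self):
        res = odds_ratio_2x2(57, 45, 47, 65)
        assert res.odds_ratio == pytest.approx(1.752, abs=0.001)
        assert res.ci_low == pytest.approx(1.02, abs=0.01)
        assert res.ci_high == pytest.approx(3.01, abs=0.01)

    def test_tiny_table_is_wide(self):
        res = odds_ratio_2x2(1, 1, 1, 1)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.ci_high / res.ci_low > 50

    def test_zero_cell_haldane_flagged(self):
        res = odds_ratio_2x2(10, 0, 5, 5)
        assert res.haldane_corrected and np.isfinite(res.odds_ratio)


class TestLogisticFit:
    def test_intercept_only_balanced_outcome(self):
        y = np.r_[np.ones(40), np.zeros(40)]
        fit = logistic_fit(y, pd.DataFrame(index=range(80)))
        assert fit.params["const"] == pytest.approx(0.0, abs=1e-8)

    def test_matches_cross_product_or_within_1e6(self):
        y = np.r_[np.ones(57), np.zeros(45), np.ones(47), np.zeros(65)]
        x = np.r_[np.ones(102), np.zeros(112)]
        fit = logistic_fit(y, pd.DataFrame({"x": x}))
        assert np.exp(fit.params["x"]) == pytest.approx(
            odds_ratio_2x2(57, 45, 47, 65).odds_ratio, abs=1e-6
        )

    def test_perfect_separation_raises(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        x = np.r_[np.ones(20), np.zeros(20)]
        with pytest.raises(SeparationError):
            logistic_fit(y, pd.DataFrame({"x": x}))

    def test_collinear_design_rejected(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        x = np.arange(20.0)
        with pytest.raises(ValueError, match="rank"):
            logistic_fit(y, pd.DataFrame({"a": x, "b": 2 * x}))


class TestEncoding:
    @pytest.mark.parametrize(
        "model,expected",
        [
            ("codominant", {"het": [0, 1, 0], "hom_alt": [0, 0, 1]}),
            ("dominant", {"carrier": [0, 1, 1]}),
            ("recessive", {"hom_alt": [0, 0, 1]}),
            ("overdominant", {"het": [0, 1, 0]}),
            ("log-additive", {"alt_count": [0, 1, 2]}),
        ],
    )
    def test_all_five_models(self, model, expected):
        enc = encode_genetic_model([0, 1, 2], model)
        assert {k: v.tolist() for k, v in enc.items()} == expected

    def test_hom_ref_is_all_zero_reference(self):
        for model in GENETIC_MODELS:
            assert not encode_genetic_model([0], model).to_numpy().any()

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError, match="unknown genetic model"):
            encode_genetic_model([0, 1], "heterotic")


class TestGeneticModels:
    def test_null_large_n_ors_near_one(self):
        cohort = simulate_cohort(
            CohortConfig(n_case=1500, n_control=1500, beta_geno=0.0), seed=41
        )
        from amplisnp.popgen import geno_codes
        from amplisnp import DEFAULT_DESIGN

        codes = geno_codes(cohort["genotype_rs2234693"], DEFAULT_DESIGN.snps[0])
        y = (cohort["status"] == "case").astype(float)
        res = assoc_genetic_models(codes, y, cohort[["age", "bmi"]])
        for r in res.values():
            for _, or_, lo, hi in r.levels:
                assert 0.75 < or_ < 1.35
            assert 0 <= r.lrt_p <= 1

    def test_degrees_of_freedom_by_model(self):
        g = simulate_genotypes(STUDY_FREQS, 300, seed=42)[:, 0]
        y = (np.arange(300) % 2).astype(float)
        res = assoc_genetic_models(g, y)
        assert res["codominant"].df == 2
        for m in ("dominant", "recessive", "overdominant", "log-additive"):
            assert res[m].df == 1

    def test_missing_genotypes_dropped(self, rng):
        g = np.array([0, 1, 2, -1] * 50)
        y = (rng.random(200) < 0.5).astype(float)
        res = assoc_genetic_models(g, y)
        assert all(r.n == 150 for r in res.values())


class TestHaplotypeAssoc:
    @staticmethod
    def _dosages(n, freqs, seed):
        g = simulate_genotypes(freqs, n, seed=seed)
        est = em_haplotype_freqs(g[:, 0], g[:, 1])
        return pd.DataFrame(
            haplotype_dosages(g[:, 0], g[:, 1], est.freqs),
            columns=["TA", "TG", "CA", "CG"],
        )

    def test_reference_is_most_frequent(self, rng):
        dos = self._dosages(400, STUDY_FREQS, 43)
        y = rng.random(400) < 0.5
        res = haplotype_assoc(dos, y.astype(float))
        assert res.reference == "TA"
        assert all(lab != "TA" for lab, *_ in res.levels)

    def test_single_haplotype_population_not_estimable(self):
        dos = pd.DataFrame({"TA": [2.0] * 30, "TG": [0.0] * 30,
                            "CA": [0.0] * 30, "CG": [0.0] * 30})
        y = (np.arange(30) % 2).astype(float)
        with pytest.raises(ValueError):
            haplotype_assoc(dos, y)

    def test_rare_haplotypes_pooled(self, rng):
        dos = self._dosages(500, HaplotypeFreqs(0.60, 0.005, 0.005, 0.39), 44)
        y = (rng.random(500) < 0.5).astype(float)
        res = haplotype_assoc(dos, y, freq_floor=0.05)
        assert set(res.pooled_rare) <= {"TG", "CA"}
        assert any(lab == "rare" for lab, *_ in res.levels) or not res.pooled_rare

    def test_effect_recovery_cg_haplotype(self):
        # per-CG-dosage log-OR = log(2); recovered mean over replicates
        rng = np.random.default_rng(45)
        ors = []
        for rep in range(20):
            g = simulate_genotypes(STUDY_FREQS, 1200, seed=300 + rep)
            est = em_haplotype_freqs(g[:, 0], g[:, 1])
            dos = pd.DataFrame(
                haplotype_dosages(g[:, 0], g[:, 1], est.freqs),
                columns=["TA", "TG", "CA", "CG"],
            )
            logit = -0.5 + np.log(2.0) * dos["CG"].to_numpy()
            y = (rng.random(1200) < 1 / (1 + np.exp(-logit))).astype(float)
            res = haplotype_assoc(dos, y)
            ors.append(dict((lab, or_) for lab, or_, *_ in res.levels)["CG"])
        assert 1.7 < np.mean(ors) < 2.3


class TestUtilities:
    def test_bonferroni_thresholds(self):
        assert bonferroni_threshold(0.05, 2) == pytest.approx(0.025)
        assert bonferroni_threshold(0.05, 1) == pytest.approx(0.05)
        assert bonferroni_threshold(0.05, 5) == pytest.approx(0.01)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)

    def test_orq_output_standardised(self, rng):
        x = rng.exponential(size=500)
        z = orq_normalize(x)
        assert abs(z.mean()) < 0.02
        assert abs(z.std() - 1) < 0.05

    def test_orq_preserves_normal_data(self, rng):
        x = rng.standard_normal(1000)
        z = orq_normalize(x)
        assert np.corrcoef(x, z)[0, 1] > 0.99

    def test_orq_ties_map_identically(self):
        z = orq_normalize([1.0, 2.0, 2.0, 3.0])
        assert z[1] == z[2]

    def test_orq_constant_vector_warns_zeros(self):
        with pytest.warns(UserWarning, match="constant"):
            z = orq_normalize([5.0, 5.0, 5.0, 5.0])
        assert np.all(z == 0)

    @settings(max_examples=25, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=40, unique=True))
    def test_orq_strictly_monotone_in_ranks(self, values):
        z = orq_normalize(values)
        order = np.argsort(values)
        assert np.all(np.diff(z[order]) > 0)

    def test_anova_identical_groups(self):
        f, p = anova_by_genotype([1.0, 1.0, 1.0, 1.0], [0, 0, 1, 1])
        assert f == 0.0 and p == 1.0

    def test_anova_null_pvalues_uniform(self, rng):
        ps = []
        for _ in range(200):
            trait = rng.standard_normal(60)
            g = rng.integers(0, 3, 60)
            _, p = anova_by_genotype(trait, g)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_welch_identical_groups(self):
        t, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_welch_separated_group_means(self, rng):
        a = rng.normal(90.1, 10.3, 500)
        b = rng.normal(161.8, 49.5, 500)
        _, p = welch_t(a, b)
        assert p < 1e-10
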