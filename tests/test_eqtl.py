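"""cis-eQTL mapping: Frisch-Waugh equivalence, window boundaries, the
permutation machinery, enrichment tests and subgroup heterogeneity."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from cavspipe import eqtl, simulate as sim
from cavspipe.expression import inverse_normal_matrix, log_cpm, tmm_normalize


def _study_frames(study):
    samples = list(study.counts.columns)
    dosages = pd.DataFrame(
        study.genotypes.dosages, index=samples, columns=study.genotypes.variant_ids
    )
    cpm = log_cpm(study.counts, tmm_normalize(study.counts))
    normalized = inverse_normal_matrix(cpm)
    covariates = study.covariates.set_axis(samples, axis=0)
    return dosages, normalized, covariates


class TestNominalPass:
    def test_slope_matches_full_multiple_regression(self, eqtl_study):
        """Residual-on-residual slope equals the dosage coefficient of the
        joint OLS fit (Frisch-Waugh), including its SE and p."""
        dosages, normalized, covariates = _study_frames(eqtl_study)
        nominal = eqtl.map_cis_nominal(
            dosages, normalized, covariates, eqtl_study.genotypes.variants, eqtl_study.annotations
        )
        row = nominal[(nominal.gene_id == "GENE1") & (nominal.variant_id == "rs3")].iloc[0]
        X = sm.add_constant(
            np.column_stack([covariates.to_numpy(dtype=float), dosages["rs3"].to_numpy()])
        )
        fit = sm.OLS(normalized.loc["GENE1"].to_numpy(), X).fit()
        assert row["slope"] == pytest.approx(fit.params[-1], rel=1e-8)
        assert row["slope_se"] == pytest.approx(fit.bse[-1], rel=1e-8)
        assert row["p_nominal"] == pytest.approx(fit.pvalues[-1], rel=1e-6)

    def test_simulated_slope_recovered(self, eqtl_study):
        """PVE 0.3 at n=400: the measured-scale slope is recovered within
        +/-0.15 of its generative value sqrt(pve * kappa) / sd(dosage)."""
        dosages, normalized, covariates = _study_frames(eqtl_study)
        nominal = eqtl.map_cis_nominal(
            dosages, normalized, covariates, eqtl_study.genotypes.variants, eqtl_study.annotations
        )
        row = nominal[(nominal.gene_id == "GENE1") & (nominal.variant_id == "rs3")].iloc[0]
        kappa = eqtl_study.truth.measured_fraction
        expected = np.sqrt(0.3 * kappa) / dosages["rs3"].std()
        assert row["slope"] == pytest.approx(expected, abs=0.15)

    def test_permuted_labels_are_null(self, eqtl_study):
        dosages, normalized, covariates = _study_frames(eqtl_study)
        rng = np.random.default_rng(0)
        shuffled = normalized.sample(frac=1.0, axis=1, random_state=3)
        shuffled.columns = normalized.columns
        nominal = eqtl.map_cis_nominal(
            dosages, shuffled, covariates, eqtl_study.genotypes.variants, eqtl_study.annotations
        )
        assert stats.kstest(nominal["p_nominal"], "uniform").pvalue > 0.01

    def test_window_boundary_inclusive_at_one_megabase(self):
        variants = pd.DataFrame(
            {
                "variant_id": ["in", "out"],
                "chrom": "1",
                "pos": [2_000_000 + 1_000_000, 2_000_000 + 1_000_001],
                "maf": 0.3,
                "info": 1.0,
            }
        )
        cis = eqtl.cis_window_variants(variants, tss=2_000_000, chrom="1")
        assert list(cis["variant_id"]) == ["in"]

    def test_distance_sign_respects_strand(self):
        variants = pd.DataFrame(
            {"variant_id": ["v"], "chrom": "1", "pos": [2_100_000], "maf": 0.3, "info": 1.0}
        )
        plus = eqtl.cis_window_variants(variants, 2_000_000, "1", "+")
        minus = eqtl.cis_window_variants(variants, 2_000_000, "1", "-")
        assert plus["tss_distance"].iloc[0] == 100_000
        assert minus["tss_distance"].iloc[0] == -100_000


class TestPermutationPass:
    def test_rank_formula_extremes(self, eqtl_study):
        dosages, normalized, covariates = _study_frames(eqtl_study)
        perm, nominal = eqtl.permutation_pass(
            dosages,
            normalized,
            covariates,
            eqtl_study.genotypes.variants,
            eqtl_study.annotations,
            n_permutations=100,
            seed=1,
        )
        causal = perm[perm.gene_id == "GENE1"].iloc[0]
        # the causal gene's best p beats every permutation minimum
        assert causal["p_empirical_direct"] == pytest.approx(1 / 101)
        assert causal["p_empirical"] < 0.02

    def test_median_observed_p_gives_half(self):
        """An observed best p equal to the median permutation minimum maps
        to an empirical p near 0.5 (direct and beta-smoothed)."""
        rng = np.random.default_rng(2)
        minima = rng.beta(1, 8, size=200)
        observed = float(np.median(minima))
        r = int(np.sum(minima <= observed))
        direct = (r + 1) / (len(minima) + 1)
        assert direct == pytest.approx(0.5, abs=0.01)
        a, b, _, _ = stats.beta.fit(minima, floc=0, fscale=1)
        assert stats.beta.cdf(observed, a, b) == pytest.approx(0.5, abs=0.06)

    def test_too_few_permutations_rejected(self, eqtl_study):
        dosages, normalized, covariates = _study_frames(eqtl_study)
        with pytest.raises(ValueError):
            eqtl.permutation_pass(
                dosages, normalized, covariates,
                eqtl_study.genotypes.variants, eqtl_study.annotations, n_permutations=50,
            )

    def test_egene_fdr_produces_usable_thresholds(self, eqtl_study):
        dosages, normalized, covariates = _study_frames(eqtl_study)
        perm, nominal = eqtl.permutation_pass(
            dosages, normalized, covariates,
            eqtl_study.genotypes.variants, eqtl_study.annotations,
            n_permutations=200, seed=3,
        )
        egenes = eqtl.egene_fdr(perm)
        assert bool(egenes.set_index("gene_id").loc["GENE1", "significant"])
        pairs = eqtl.call_significant_pairs(nominal, egenes)
        causal_pairs = pairs[pairs["gene_id"] == "GENE1"]
        assert "rs3" in set(causal_pairs["variant_id"])
        # per-gene thresholds are below the global nominal level
        assert (egenes["nominal_threshold"] < 0.05).all()


class TestEnrichment:
    def test_reproduces_published_chi_squared(self):
        """48/915 lead-SNP pairs vs 4,671,347/182,925,823 genome-wide pairs:
        continuity-corrected chi-squared p = 4.25e-7."""
        res = eqtl.lead_snp_enrichment(48, 915, 4_671_347, 182_925_823)
        assert res["p_chi2"] == pytest.approx(4.25e-7, rel=0.005)

    def test_identical_proportions_are_null(self):
        res = eqtl.lead_snp_enrichment(50, 1000, 500, 10_000)
        assert res["p_chi2"] > 0.9

    def test_toy_table_matches_hand_computation(self):
        """8/10 vs 2/10 with Yates correction, evaluated by hand."""
        table = np.array([[8, 2], [2, 8]], dtype=float)
        n = table.sum()
        row = table.sum(axis=1)
        col = table.sum(axis=0)
        expected = np.outer(row, col) / n
        chi2_hand = float(np.sum((np.abs(table - expected) - 0.5) ** 2 / expected))
        res = eqtl.lead_snp_enrichment(8, 10, 2, 10)
        assert res["chi2"] == pytest.approx(chi2_hand, rel=1e-10)
        assert res["p_chi2"] == pytest.approx(stats.chi2.sf(chi2_hand, 1), rel=1e-10)

    def test_wilcoxon_detects_smaller_lead_pvalues(self):
        rng = np.random.default_rng(5)
        lead = rng.uniform(0, 0.2, 200)
        background = rng.uniform(0, 1, 2000)
        res = eqtl.lead_snp_enrichment(10, 200, 100, 2000, lead, background)
        assert res["p_wilcoxon"] < 1e-6

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            eqtl.lead_snp_enrichment(0, 10, 0, 0)


class TestTissueSpecific:
    def test_classification_rules(self):
        table = pd.DataFrame(
            {
                "valve": [True, True, False],
                "lung": [False, True, False],
                "liver": [False, False, False],
            },
            index=["pair1", "pair2", "pair3"],
        )
        out = eqtl.classify_tissue_specific(table).set_index("index")
        assert out.loc["pair1", "tissue"] == "valve"
        assert "pair2" not in out.index  # two tissues
        assert "pair3" not in out.index  # none

    def test_needs_two_tissues(self):
        with pytest.raises(ValueError):
            eqtl.classify_tissue_specific(pd.DataFrame({"valve": [True]}))


class TestSubgroupHeterogeneity:
    def test_identical_slopes_are_null(self):
        z, p = eqtl.subgroup_heterogeneity(0.4, 0.1, 0.4, 0.2)
        assert z == 0.0
        assert p == 1.0

    def test_hand_computed_z(self):
        z, p = eqtl.subgroup_heterogeneity(0.5, 0.1, -0.5, 0.1)
        assert abs(z) == pytest.approx(5 * np.sqrt(2), rel=1e-9)  # ~7.07
        assert p < 1e-10

    def test_null_calibration(self):
        rng = np.random.default_rng(6)
        ps = []
        for _ in range(500):
            s1 = rng.normal(0.3, 0.1)
            s2 = rng.normal(0.3, 0.15)
            ps.append(eqtl.subgroup_heterogeneity(s1, 0.1, s2, 0.15)[1])
        frac = np.mean(np.array(ps) < 0.05)
        assert 0.02 < frac < 0.08
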