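"""GWAS association, QC, IVW meta-analysis, inflation, clumping and
single-causal-variant fine-mapping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cavspipe import gwas, simulate as sim


def _assoc_row(**kw):
    base = {
        "variant_id": "rs1",
        "chrom": "1",
        "pos": 1000,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": 0.3,
        "beta": 0.1,
        "se": 0.05,
        "p": 0.05,
        "info": 1.0,
        "n_cases": 1000,
        "n_controls": 1000,
        "flag": "",
    }
    base.update(kw)
    return base


class TestCohortGwas:
    def test_balanced_phenotype_within_genotype_gives_zero_beta(self):
        """Phenotype exactly balanced within each dosage class: beta = 0."""
        dosages = np.repeat([0.0, 1.0, 2.0], 40)[:, None]
        pheno = np.tile([0, 1], 60)
        panel = sim.SimulatedGenotypes(
            dosages=dosages,
            variants=pd.DataFrame(
                [{"variant_id": "rs1", "chrom": "1", "pos": 1, "effect_allele": "A",
                  "other_allele": "G", "maf": 0.5, "info": 1.0}]
            ),
            ld=np.eye(1),
        )
        cov = pd.DataFrame({"age": np.zeros(120)})
        cohort = sim.SimulatedCohort(panel, pheno, cov, sim.SimTruth())
        res = gwas.run_cohort_gwas(cohort, covariate_names=[])
        assert res["beta"].iloc[0] == pytest.approx(0.0, abs=1e-8)

    def test_null_association_is_calibrated(self, independent_panel):
        truth = sim.SimTruth(prevalence=0.5)
        coh = sim.simulate_case_control(independent_panel, truth, 1, 2000, seed=7)[0]
        res = gwas.run_cohort_gwas(coh)
        assert res["beta"].abs().max() < 0.3
        ks = stats.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_simulated_log_or_recovered(self):
        spec = sim.LdSpec(n_variants=2, rho=0.0, block_size=1, maf_low=0.3, maf_high=0.3)
        panel = sim.simulate_genotypes(spec, 20000, seed=13)
        truth = sim.SimTruth(causal_variants={"rs1": 0.4}, prevalence=0.5)
        coh = sim.simulate_case_control(panel, truth, 1, 20000, seed=14)[0]
        res = gwas.run_cohort_gwas(coh).set_index("variant_id")
        assert res.loc["rs1", "beta"] == pytest.approx(0.4, abs=0.1)

    def test_monomorphic_variant_flagged_not_fatal(self):
        dosages = np.column_stack([np.zeros(100), np.random.default_rng(0).integers(0, 3, 100)])
        panel = sim.SimulatedGenotypes(
            dosages=dosages.astype(float),
            variants=pd.DataFrame(
                [
                    {"variant_id": f"rs{i}", "chrom": "1", "pos": i, "effect_allele": "A",
                     "other_allele": "G", "maf": 0.3, "info": 1.0}
                    for i in (1, 2)
                ]
            ),
            ld=np.eye(2),
        )
        pheno = np.random.default_rng(1).integers(0, 2, 100)
        cohort = sim.SimulatedCohort(panel, pheno, pd.DataFrame({"age": np.zeros(100)}), sim.SimTruth())
        res = gwas.run_cohort_gwas(cohort, covariate_names=[])
        assert res["flag"].iloc[0] == "monomorphic"
        assert np.isnan(res["beta"].iloc[0])
        assert res["flag"].iloc[1] == ""


class TestQcFilter:
    def test_info_just_below_threshold_excluded(self):
        df = pd.DataFrame([_assoc_row(info=0.29), _assoc_row(variant_id="rs2", info=0.30)])
        kept, excluded = gwas.qc_filter(df)
        assert list(kept["variant_id"]) == ["rs2"]
        assert excluded["exclusion_rule"].iloc[0] == "low_info"

    def test_maf_exactly_at_bound_retained(self):
        # large case count so the corrected-MAC rule is not the binding one
        df = pd.DataFrame(
            [
                _assoc_row(eaf=0.001, n_cases=10_000),
                _assoc_row(variant_id="rs2", eaf=0.0009, n_cases=10_000),
            ]
        )
        kept, _ = gwas.qc_filter(df)
        assert list(kept["variant_id"]) == ["rs1"]

    def test_counting_three_single_rule_violations(self):
        rows = [_assoc_row(variant_id=f"rs{i}") for i in range(1, 11)]
        rows[1]["info"] = 0.1
        rows[4]["eaf"] = 0.0001
        rows[7]["n_cases"] = 2  # corrected MAC = .3*2*2*1 < 5
        kept, excluded = gwas.qc_filter(pd.DataFrame(rows))
        assert len(kept) == 7
        assert len(excluded) == 3
        assert set(excluded["exclusion_rule"]) == {"low_info", "low_maf", "low_mac_cases"}


class TestMetaAnalysis:
    def test_single_cohort_identity(self, toy_summary_stats):
        meta = gwas.meta_analyze([toy_summary_stats(0.2, 0.05)])
        row = meta.iloc[0]
        assert row["beta"] == pytest.approx(0.2)
        assert row["se"] == pytest.approx(0.05)
        assert row["q_stat"] == pytest.approx(0.0)
        assert row["p_het"] == 1.0

    def test_hand_computed_ivw(self, toy_summary_stats):
        """beta (0.1, 0.3) with equal SE 0.1: meta = 0.2, se = 0.1/sqrt(2)."""
        meta = gwas.meta_analyze([toy_summary_stats(0.1, 0.1), toy_summary_stats(0.3, 0.1)])
        row = meta.iloc[0]
        assert row["beta"] == pytest.approx(0.2)
        assert row["se"] == pytest.approx(0.1 / np.sqrt(2))

    def test_identical_betas_have_no_heterogeneity(self, toy_summary_stats):
        meta = gwas.meta_analyze([toy_summary_stats(0.2, 0.1)] * 3)
        row = meta.iloc[0]
        assert row["q_stat"] == pytest.approx(0.0)
        assert row["i2"] == 0.0
        assert row["p_het"] == pytest.approx(1.0)
        assert row["direction"] == "+++"

    def test_cohort_order_invariance(self, toy_summary_stats):
        a = [toy_summary_stats(0.1, 0.1), toy_summary_stats(0.3, 0.2)]
        m1 = gwas.meta_analyze(a)
        m2 = gwas.meta_analyze(a[::-1])
        assert m1.iloc[0]["beta"] == pytest.approx(m2.iloc[0]["beta"])
        assert m1.iloc[0]["se"] == pytest.approx(m2.iloc[0]["se"])

    def test_swapped_alleles_flip_sign(self, toy_summary_stats):
        flipped = toy_summary_stats(-0.1, 0.1, eaf=0.7, ea="G", oa="A")
        m = gwas.meta_analyze([toy_summary_stats(0.1, 0.1), flipped])
        assert m.iloc[0]["beta"] == pytest.approx(0.1)
        assert m.iloc[0]["q_stat"] == pytest.approx(0.0)

    def test_irreconcilable_alleles_dropped(self, toy_summary_stats):
        other = toy_summary_stats(0.1, 0.1, ea="C", oa="T")
        m = gwas.meta_analyze([toy_summary_stats(0.1, 0.1), other])
        assert m.iloc[0]["n_cohorts"] == 1

    def test_palindromic_high_maf_dropped(self, toy_summary_stats):
        amb = toy_summary_stats(0.1, 0.1, eaf=0.45, ea="A", oa="T")
        assert gwas.meta_analyze([amb]).empty

    def test_adding_a_cohort_never_increases_se(self, toy_summary_stats):
        one = gwas.meta_analyze([toy_summary_stats(0.1, 0.1)]).iloc[0]["se"]
        two = gwas.meta_analyze(
            [toy_summary_stats(0.1, 0.1), toy_summary_stats(0.2, 0.3)]
        ).iloc[0]["se"]
        assert two <= one


class TestGenomicInflation:
    def test_uniform_grid_gives_unity(self):
        p = (np.arange(1, 10001) - 0.5) / 10000
        assert gwas.genomic_inflation(p) == pytest.approx(1.0, abs=0.01)

    def test_scale_equivariance(self):
        """Doubling every association chi-squared doubles lambda."""
        p = (np.arange(1, 10001) - 0.5) / 10000
        chi2 = stats.chi2.isf(p, 1)
        p_inflated = stats.chi2.sf(2.0 * chi2, 1)
        lam = gwas.genomic_inflation(p_inflated)
        assert lam == pytest.approx(2.0, rel=0.02)

    def test_too_few_pvalues_rejected(self):
        with pytest.raises(ValueError):
            gwas.genomic_inflation(np.linspace(0.01, 0.99, 50))


def _meta_row(vid, pos, p, chrom="1"):
    return {
        "variant_id": vid, "chrom": chrom, "pos": pos, "effect_allele": "A",
        "other_allele": "G", "eaf": 0.3, "beta": 0.1, "se": 0.01, "p": p,
    }


class TestClumping:
    def test_no_ld_every_variant_is_a_lead(self):
        meta = pd.DataFrame([_meta_row(f"rs{i}", 1_000_000 * (i + 1), 1e-9) for i in range(3)])
        ld = pd.DataFrame(np.eye(3), index=meta["variant_id"], columns=meta["variant_id"])
        loci = gwas.clump_and_define_loci(meta, ld)
        assert len(loci) == 3

    def test_perfect_proxy_collapses_to_one_locus(self):
        meta = pd.DataFrame([_meta_row("rs1", 100_000, 1e-10), _meta_row("rs2", 110_000, 1e-9)])
        ld = pd.DataFrame(np.ones((2, 2)), index=meta["variant_id"], columns=meta["variant_id"])
        loci = gwas.clump_and_define_loci(meta, ld)
        assert len(loci) == 1
        assert loci[0].lead_variant == "rs1"

    def test_500kb_merge_rule(self):
        """Leads at 1.0, 1.4 and 2.1 Mb: first two merge, third stays."""
        meta = pd.DataFrame(
            [
                _meta_row("rs1", 1_000_000, 1e-12),
                _meta_row("rs2", 1_400_000, 1e-10),
                _meta_row("rs3", 2_100_000, 1e-9),
            ]
        )
        ld = pd.DataFrame(np.eye(3), index=meta["variant_id"], columns=meta["variant_id"])
        loci = gwas.clump_and_define_loci(meta, ld)
        assert len(loci) == 2
        assert loci[0].lead_variant == "rs1"
        assert set(loci[0].members) == {"rs1", "rs2"}

    def test_merge_window_is_configurable(self):
        meta = pd.DataFrame(
            [
                _meta_row("rs1", 1_000_000, 1e-12),
                _meta_row("rs2", 1_400_000, 1e-10),
                _meta_row("rs3", 2_100_000, 1e-9),
            ]
        )
        ld = pd.DataFrame(np.eye(3), index=meta["variant_id"], columns=meta["variant_id"])
        assert len(gwas.clump_and_define_loci(meta, ld, merge_kb=100)) == 3

    def test_deterministic_tiebreak(self):
        meta = pd.DataFrame(
            [_meta_row("rsB", 200_000, 1e-9), _meta_row("rsA", 100_000, 1e-9)]
        )
        ld = pd.DataFrame(np.ones((2, 2)), index=meta["variant_id"], columns=meta["variant_id"])
        loci = gwas.clump_and_define_loci(meta, ld)
        assert loci[0].lead_variant == "rsA"  # p tie -> smaller position wins

    def test_nothing_significant_gives_no_loci(self):
        meta = pd.DataFrame([_meta_row("rs1", 100, 1e-3)])
        ld = pd.DataFrame(np.eye(1), index=["rs1"], columns=["rs1"])
        assert gwas.clump_and_define_loci(meta, ld) == []


class TestFineMapping:
    def test_wakefield_closed_form(self):
        labf = gwas.wakefield_log_abf(np.array([0.5]), np.array([0.1]), 0.2)
        assert labf[0] == pytest.approx(0.5 * (np.log(0.2) + 25 * 0.8), rel=1e-6)

    def test_dominant_variant_forms_singleton_set(self):
        rec = pd.DataFrame(
            [_meta_row("rs1", 1000, 1e-30)] + [_meta_row(f"rs{i}", 1000 + i, 0.5) for i in range(2, 8)]
        )
        rec.loc[0, "beta"], rec.loc[0, "se"] = 1.0, 0.1  # z = 10
        rec.loc[1:, "beta"] = 0.0
        cs = gwas.fine_map_credible_set(rec)
        assert cs["in_credible_set"].sum() == 1
        assert cs.iloc[0]["variant_id"] == "rs1"
        assert cs.iloc[0]["posterior"] > 0.99

    def test_identical_evidence_gives_symmetric_set(self):
        k = 20
        rec = pd.DataFrame([_meta_row(f"rs{i}", 1000 + i, 0.5) for i in range(k)])
        rec["beta"], rec["se"] = 0.05, 0.05
        cs = gwas.fine_map_credible_set(rec)
        np.testing.assert_allclose(cs["posterior"], 1.0 / k)
        assert cs["in_credible_set"].sum() == int(np.ceil(0.95 * k))
        assert bool(cs["uninformative"].iloc[0])

    def test_posteriors_sum_to_one_and_coverage_monotone(self):
        rng = np.random.default_rng(3)
        rec = pd.DataFrame([_meta_row(f"rs{i}", 1000 + i, 0.5) for i in range(30)])
        rec["beta"] = rng.normal(0, 0.2, 30)
        rec["se"] = 0.05
        cs = gwas.fine_map_credible_set(rec)
        assert cs["posterior"].sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(cs["cumulative"]) >= -1e-12).all()

    def test_credible_set_covers_causal_variant(self):
        """Simulated locus with one causal variant: the 95% set contains it
        in >= 90% of replicates."""
        from cavspipe.gwas import run_cohort_gwas

        spec = sim.LdSpec(n_variants=10, rho=0.9, block_size=10, maf_low=0.2, maf_high=0.4)
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            panel = sim.simulate_genotypes(spec, 3000, seed=500 + rep)
            truth = sim.SimTruth(causal_variants={"rs5": 0.35}, prevalence=0.5)
            coh = sim.simulate_case_control(panel, truth, 1, 3000, seed=600 + rep)[0]
            assoc = run_cohort_gwas(coh)
            cs = gwas.fine_map_credible_set(assoc)
            members = set(cs[cs["in_credible_set"]]["variant_id"])
            hits += "rs5" in members
        assert hits >= 9
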