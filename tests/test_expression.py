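"""Expression processing: TPM, expressed-gene filters, TMM, inverse-normal
transform, hidden-factor recovery and tissue-specificity scoring."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cavspipe import expression as ex


class TestTpm:
    def test_length_normalization_ratio(self):
        counts = pd.DataFrame({"S1": [100, 100]}, index=["G1", "G2"])
        lengths = pd.Series([1000.0, 2000.0], index=["G1", "G2"])
        tpm = ex.compute_tpm(counts, lengths)
        assert tpm.loc["G1", "S1"] / tpm.loc["G2", "S1"] == pytest.approx(2.0)

    def test_single_gene_gets_the_full_million(self):
        tpm = ex.compute_tpm(
            pd.DataFrame({"S1": [7]}, index=["G1"]), pd.Series([500.0], index=["G1"])
        )
        assert tpm.loc["G1", "S1"] == pytest.approx(1e6)

    def test_columns_sum_to_one_million(self, expression_counts):
        counts, lengths = expression_counts
        tpm = ex.compute_tpm(counts, lengths)
        np.testing.assert_allclose(tpm.sum(axis=0), 1e6, rtol=1e-3)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            ex.compute_tpm(
                pd.DataFrame({"S1": [1]}, index=["G1"]), pd.Series([0.0], index=["G1"])
            )


class TestExpressedFilter:
    def test_tpm_exactly_at_threshold_removed(self):
        tpm = pd.DataFrame(0.1, index=["G1"], columns=[f"S{i}" for i in range(10)])
        counts = pd.DataFrame(100, index=["G1"], columns=tpm.columns)
        assert ex.filter_expressed(counts, tpm) == []

    def test_19_percent_read_support_removed(self):
        n = 100
        counts = pd.DataFrame(
            [[6] * 19 + [0] * 81], index=["G1"], columns=[f"S{i}" for i in range(n)]
        )
        tpm = pd.DataFrame(5.0, index=["G1"], columns=counts.columns)
        assert ex.filter_expressed(counts, tpm) == []
        counts20 = pd.DataFrame(
            [[6] * 20 + [0] * 80], index=["G1"], columns=counts.columns
        )
        assert ex.filter_expressed(counts20, tpm) == ["G1"]

    def test_hand_enumerated_clauses(self):
        samples = [f"S{i}" for i in range(10)]
        counts = pd.DataFrame(
            {
                "pass_both": [10] * 10,
                "fail_tpm": [10] * 10,
                "fail_reads": [5] * 10,
                "fail_both": [0] * 10,
                "edge_pass": [6, 6] + [0] * 8,  # 20% of samples at 6 reads
            },
            index=samples,
        ).T
        tpm = pd.DataFrame(
            {
                "pass_both": [1.0] * 10,
                "fail_tpm": [0.05] * 10,
                "fail_reads": [1.0] * 10,
                "fail_both": [0.0] * 10,
                "edge_pass": [0.2, 0.2] + [0.0] * 8,
            },
            index=samples,
        ).T
        assert ex.filter_expressed(counts, tpm) == ["pass_both", "edge_pass"]


class TestTmm:
    def test_identical_columns_have_unit_factors(self):
        counts = pd.DataFrame({"S1": [10, 20, 30, 40], "S2": [10, 20, 30, 40]})
        f = ex.tmm_normalize(counts)
        np.testing.assert_allclose(f, 1.0)

    def test_pure_depth_difference_has_unit_factors(self):
        """Column 2 = 2 x column 1: all M-values are zero after library
        offset, so the TMM factors stay at 1."""
        rng = np.random.default_rng(0)
        c1 = rng.integers(10, 1000, 50)
        counts = pd.DataFrame({"S1": c1, "S2": 2 * c1})
        f = ex.tmm_normalize(counts)
        np.testing.assert_allclose(f, 1.0, atol=1e-8)

    def test_composition_spike_downweights_spiked_sample(self):
        rng = np.random.default_rng(1)
        base = rng.integers(100, 1000, 100)
        spiked = base.copy()
        spiked[:5] = spiked[:5] * 10  # 5% of genes 10x in sample 2
        counts = pd.DataFrame({"S1": base, "S2": spiked})
        f = ex.tmm_normalize(counts, reference_sample="S1")
        # non-spiked genes in S2 look under-expressed per library size;
        # the trimmed mean pushes S2's factor below S1's
        assert f["S2"] < f["S1"]

    def test_factors_invariant_to_global_count_scaling(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(1, 500, size=(80, 4)))
        f1 = ex.tmm_normalize(counts)
        f2 = ex.tmm_normalize(counts * 3)
        np.testing.assert_allclose(f1, f2, rtol=1e-10)

    def test_matches_edger_reference_implementation(self):
        """Cross-check factors against edgeR's calcNormFactors on a small
        deterministic matrix."""
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(
            rng.negative_binomial(5, 0.01, size=(200, 3)), columns=["S1", "S2", "S3"]
        )
        counts.iloc[:10, 2] *= 8
        ours = ex.tmm_normalize(counts)
        csv = counts.to_csv(index=False)
        script = textwrap.dedent(
            """
            suppressMessages(library(edgeR))
            x <- as.matrix(read.csv("stdin"))
            f <- calcNormFactors(x, method="TMM")
            cat(f, sep="\\n")
            """
        )
        res = subprocess.run(
            ["Rscript", "-e", script], input=csv, capture_output=True, text=True, check=True
        )
        theirs = np.array([float(v) for v in res.stdout.strip().splitlines()])
        np.testing.assert_allclose(ours.to_numpy(), theirs, rtol=0.02)

    def test_all_zero_sample_flagged(self):
        counts = pd.DataFrame({"S1": [10, 20], "S2": [0, 0]})
        f = ex.tmm_normalize(counts, reference_sample="S1")
        assert np.isnan(f["S2"])


class TestInverseNormal:
    def test_three_value_closed_form(self):
        out = ex.inverse_normal(np.array([10.0, -5.0, 3.0]))
        expected = stats.norm.ppf([5 / 6, 1 / 6, 3 / 6])
        np.testing.assert_allclose(out, expected)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        x = rng.gamma(2.0, size=50)
        np.testing.assert_allclose(ex.inverse_normal(x), ex.inverse_normal(np.log(x)))

    def test_output_is_centered_and_symmetric(self):
        out = ex.inverse_normal(np.arange(101, dtype=float))
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(np.sort(out), -np.sort(-out)[::-1], atol=1e-12)

    def test_constant_gene_rejected(self):
        with pytest.raises(ValueError):
            ex.inverse_normal(np.ones(10))


class TestExpressionCovariates:
    def test_rank_one_matrix_captured_by_first_component(self):
        u = np.random.default_rng(5).standard_normal(30)
        mat = pd.DataFrame(np.outer(np.arange(1, 11), u))
        comps = ex.expression_covariates(mat, 2)
        r = abs(np.corrcoef(comps["EC1"], u)[0, 1])
        assert r > 0.999

    def test_components_orthonormal(self):
        rng = np.random.default_rng(6)
        mat = pd.DataFrame(rng.standard_normal((40, 25)))
        comps = ex.expression_covariates(mat, 5).to_numpy()
        np.testing.assert_allclose(comps.T @ comps, np.eye(5), atol=1e-8)

    def test_recovers_simulated_batch_factor(self):
        """A shared batch factor across genes appears among the top
        components with |r| > 0.9."""
        rng = np.random.default_rng(7)
        n_genes, n_samples = 60, 80
        factor = rng.standard_normal(n_samples)
        loadings = rng.normal(0.0, 0.8, size=n_genes)
        mat = pd.DataFrame(
            rng.standard_normal((n_genes, n_samples)) + np.outer(loadings, factor)
        )
        comps = ex.expression_covariates(mat, 3)
        best = max(abs(np.corrcoef(comps[c], factor)[0, 1]) for c in comps)
        assert best > 0.9

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            ex.expression_covariates(pd.DataFrame(np.ones((5, 5))), 5)


class TestSpecificity:
    def test_valve_share_above_threshold_flagged(self):
        medians = pd.DataFrame(
            {"G1": [12.0] + [88.0 / 43] * 43},
            index=["aortic_valve"] + [f"t{i}" for i in range(43)],
        )
        scores = ex.specificity_scores(medians)
        assert scores.loc["G1", "valve_ess"] == pytest.approx(0.12)
        assert bool(scores.loc["G1", "valve_specific"])

    def test_share_exactly_at_threshold_not_flagged(self):
        # 10.75 / (10.75 + 43 * 2.25) is exactly the float nearest 0.1
        medians = pd.DataFrame(
            {"G1": [10.75] + [2.25] * 43},
            index=["aortic_valve"] + [f"t{i}" for i in range(43)],
        )
        scores = ex.specificity_scores(medians)
        assert scores.loc["G1", "valve_ess"] == pytest.approx(0.1)
        assert not bool(scores.loc["G1", "valve_specific"])

    def test_negative_medians_clamped_before_division(self):
        medians = pd.DataFrame(
            {"G1": [2.0, -1.0, 2.0]}, index=["aortic_valve", "t1", "t2"]
        )
        ess = ex.ess_table(medians)
        assert ess.loc["aortic_valve", "G1"] == pytest.approx(0.5)
        assert ess["G1"].sum() == pytest.approx(1.0)

    def test_all_zero_gene_flagged_undefined(self):
        medians = pd.DataFrame({"G1": [0.0, 0.0]}, index=["aortic_valve", "t1"])
        scores = ex.specificity_scores(medians)
        assert bool(scores.loc["G1", "undefined"])
        assert not bool(scores.loc["G1", "valve_specific"])


class TestHighExpression:
    def test_exactly_ten_percent_flagged(self):
        medians = pd.Series(np.arange(100, dtype=float), index=[f"G{i}" for i in range(100)])
        flags = ex.flag_high_expression(medians)
        assert flags.sum() == 10

    def test_all_equal_flags_none(self):
        medians = pd.Series(np.ones(50), index=[f"G{i}" for i in range(50)])
        assert ex.flag_high_expression(medians).sum() == 0

    def test_shifting_a_gene_to_the_top_flags_it(self):
        medians = pd.Series(np.arange(50, dtype=float), index=[f"G{i}" for i in range(50)])
        medians["G3"] = 1000.0
        assert bool(ex.flag_high_expression(medians)["G3"])
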