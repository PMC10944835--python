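import numpy as np
import pandas as pd
import pytest

from cavspipe import simulate as sim


@pytest.fixture(scope="session")
def independent_panel():
    """2000 samples x 20 unlinked variants."""
    spec = sim.LdSpec(n_variants=20, rho=0.0, block_size=1, maf_low=0.1, maf_high=0.5)
    return sim.simulate_genotypes(spec, 2000, seed=11)


@pytest.fixture(scope="session")
def eqtl_study():
    """400-sample expression study with one strong cis-eQTL (PVE 0.3).

    Thirty genes keep the count compositionality (fixed library size)
    negligible per gene.
    """
    spec = sim.LdSpec(n_variants=12, rho=0.0, block_size=1, maf_low=0.2, maf_high=0.4)
    panel = sim.simulate_genotypes(spec, 400, seed=21)
    ann = sim.make_gene_annotations(30, spacing=20_000, length=10_000)
    truth = sim.SimTruth(
        eqtl_effects=[sim.EqtlEffect("GENE1", "rs3", 0.3)],
        mediation_effects={},
    )
    study = sim.simulate_expression(panel, truth, n_genes=30, seed=22, annotations=ann)
    return study


@pytest.fixture()
def toy_summary_stats():
    """Hand-written per-cohort association tables for meta-analysis tests."""

    def make(beta, se, eaf=0.3, variant="rs1", ea="A", oa="G"):
        return pd.DataFrame(
            [
                {
                    "variant_id": variant,
                    "chrom": "1",
                    "pos": 1000,
                    "effect_allele": ea,
                    "other_allele": oa,
                    "eaf": eaf,
                    "beta": beta,
                    "se": se,
                    "p": 0.5,
                    "info": 1.0,
                    "n_cases": 100,
                    "n_controls": 100,
                    "flag": "",
                }
            ]
        )

    return make


@pytest.fixture()
def expression_counts():
    """Small deterministic count matrix with lengths."""
    counts = pd.DataFrame(
        {
            "S1": [100, 100, 0, 500, 7],
            "S2": [120, 80, 0, 480, 6],
            "S3": [90, 110, 1, 530, 8],
        },
        index=["G1", "G2", "G3", "G4", "G5"],
    )
    lengths = pd.Series([1000.0, 2000.0, 1500.0, 1000.0, 800.0], index=counts.index)
    return counts, lengths


def assert_allclose(a, b, **kw):
    np.testing.assert_allclose(a, b, **kw)
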