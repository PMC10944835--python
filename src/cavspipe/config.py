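"""Pipeline configuration with every analysis threshold at its published
default, plus the synthetic-scenario parameters.

The scenario defaults describe the package's reference mediation study: a
60-variant panel in six LD blocks, ten genes, one causal gene whose
measured expression mediates disease risk (total cis-PVE 0.3 over four
variants in distinct blocks, mediation effect 0.3 per expression SD), one
additional variant with a direct effect, two balanced case-control GWAS
cohorts of 10,000 samples each and a 400-sample expression study.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # reproducibility
    seed: int = 1

    # genotype panel
    n_variants: int = 60
    block_size: int = 10
    rho: float = 0.95
    maf_low: float = 0.1
    maf_high: float = 0.5
    variant_spacing: int = 5_000

    # genes
    n_genes: int = 10
    gene_spacing: int = 100_000
    gene_length: int = 20_000

    # causal architecture (variant ids refer to the panel layout above)
    causal_gene: str = "GENE2"
    primary_eqtl_variant: str = "rs23"
    primary_eqtl_pve: float = 0.12
    secondary_eqtl_variants: tuple = ("rs9", "rs35", "rs45")
    secondary_eqtl_pve: float = 0.06
    mediation_effect: float = 0.3
    direct_variant: str = "rs55"
    direct_log_or: float = 0.25
    direct_region_start: int = 2_600_000  # last LD block sits here, its own locus
    prevalence: float = 0.5  # balanced case-control design
    expression_log_sd: float = 0.5
    nb_dispersion: float = 0.1

    # cohort sizes
    n_cohorts: int = 2
    n_gwas_per_cohort: int = 10_000
    n_eqtl_samples: int = 400

    # GWAS / meta thresholds
    p_threshold: float = 5e-8
    r2_independent: float = 0.6
    r2_lead: float = 0.1
    merge_kb: float = 500.0
    info_min: float = 0.3
    maf_min_gwas: float = 0.001
    mac_cases_min: float = 5.0
    finemap_prior_sd: float = 0.2
    credible_coverage: float = 0.95

    # expression thresholds
    min_tpm: float = 0.1
    min_reads: int = 6
    min_frac: float = 0.2
    # hidden expression factors regressed out before eQTL mapping; 0 at the
    # synthetic scale, where components of a ten-gene matrix are dominated
    # by the causal gene's own variation rather than shared structure
    n_expression_covariates: int = 0
    n_tissues: int = 44
    valve_share: float = 0.2  # designated ESS of the causal gene in the valve
    ess_threshold: float = 0.1
    high_expression_percentile: float = 90.0

    # eQTL
    cis_window: int = 1_000_000
    eqtl_maf_min: float = 0.01
    eqtl_info_min: float = 0.3
    n_permutations: int = 1000
    eqtl_fdr: float = 0.05

    # TWAS
    twas_min_r: float = 0.1
    twas_max_p: float = 0.05
    twas_fdr: float = 0.05

    # colocalization
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    pp4_threshold: float = 0.75

    # MR
    mr_p_exposure: float = 1e-4
    mr_clump_r2: float = 0.1
    mr_min_instruments: int = 3
    mr_f_min: float = 15.0
    mr_q_alpha: float = 0.01
    mr_fdr: float = 0.05

    # prioritization
    gene_window: int = 10_000
    missense_r2: float = 0.8
    missense_variants: dict = field(default_factory=dict)  # variant id -> gene id
    min_features: int = 4
    gene_test_fdr: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "secondary_eqtl_variants" in payload:
            payload["secondary_eqtl_variants"] = tuple(payload["secondary_eqtl_variants"])
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["secondary_eqtl_variants"] = list(self.secondary_eqtl_variants)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
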