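"""Synthetic genotype, phenotype and expression generators with known truth.

Every downstream stage of the pipeline (GWAS meta-analysis, eQTL mapping,
TWAS, colocalization, MR, prioritization) is exercised on data produced
here, so the generators encode the causal structure those methods assume:

* **Genotypes** — haplotypes from a blockwise AR(1) latent-Gaussian
  threshold model.  Within an LD block the latent Gaussians of adjacent
  variants correlate at ``rho``; thresholding at the normal quantile of the
  allele frequency yields 0/1 haplotypes and dosages in {0, 1, 2}.  This
  gives smooth control over pairwise r² without a phased reference panel.
* **Case-control phenotypes** — a liability-threshold model: liability is
  the sum of direct variant effects (log-OR per dose), expression-mediated
  effects, small covariate effects and standard-normal noise; case status is
  assigned by thresholding at the quantile matching the target prevalence.
* **RNA-seq counts** — latent gene expression with additive cis-eQTL dosage
  effects parameterized by the proportion of variance explained (PVE), then
  negative-binomial counts with per-gene dispersion and sample library sizes.
* **Tissue panels** — median log2(TPM) tables across tissues with designated
  tissue-specific genes, for expression-specificity scoring.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LdSpec",
    "EqtlEffect",
    "SimTruth",
    "SimulatedGenotypes",
    "SimulatedCohort",
    "SimulatedExpression",
    "simulate_genotypes",
    "simulate_case_control",
    "simulate_expression",
    "simulate_tissue_panel",
    "make_gene_annotations",
]


@dataclass
class LdSpec:
    """Layout of a simulated variant panel.

    Parameters
    ----------
    n_variants : int
        Number of variants.
    maf_low, maf_high : float
        Bounds of the uniform distribution from which per-variant minor
        allele frequencies are drawn; both in [0, 1] with low <= high.
    rho : float
        Latent-Gaussian correlation between adjacent variants within an LD
        block, in [0, 1).
    block_size : int
        Number of variants per LD block; blocks are mutually independent.
    positions : array-like of int, optional
        1-based base-pair coordinates, strictly increasing.  Defaults to an
        even grid with 5 kb spacing starting at 1,000,000.
    chrom : str
        Chromosome label used in variant metadata.
    """

    n_variants: int
    maf_low: float = 0.05
    maf_high: float = 0.5
    rho: float = 0.8
    block_size: int = 10
    positions: np.ndarray | None = None
    chrom: str = "1"

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if not (0.0 <= self.maf_low <= self.maf_high <= 1.0):
            raise ValueError("require 0 <= maf_low <= maf_high <= 1")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if self.positions is None:
            self.positions = 1_000_000 + 5_000 * np.arange(self.n_variants)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if len(self.positions) != self.n_variants:
            raise ValueError("positions length must equal n_variants")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")


@dataclass(frozen=True)
class EqtlEffect:
    """A cis-eQTL effect: ``variant`` explains ``pve`` of the variance of
    ``gene``'s latent expression, with the given effect sign."""

    gene: str
    variant: str
    pve: float
    sign: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.pve < 1.0):
            raise ValueError("cis PVE must be in [0, 1)")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be -1 or +1")


@dataclass
class SimTruth:
    """Generating parameters against which recovery is scored.

    Attributes
    ----------
    causal_variants : dict
        variant id -> direct liability effect (log-OR per effect-allele dose).
    eqtl_effects : list of EqtlEffect
        cis genotype -> expression effects, parameterized by PVE; a gene may
        carry several (their PVEs must sum below 1).
    mediation_effects : dict
        gene id -> effect of measured expression (per SD) on disease
        liability (log-odds scale).
    prevalence : float
        Population disease probability, in (0, 1).
    expression_log_sd : float
        Biological log-scale expression amplitude: one latent SD of a
        gene's expression corresponds to this many natural-log units of
        its transcription rate.
    count_dispersion : float
        Negative-binomial dispersion of the count noise around the latent
        rate.  Together with ``expression_log_sd`` it fixes the fraction
        kappa = log_sd^2 / (log_sd^2 + dispersion) of measured-expression
        variance that is biological, which both the expression generator
        and the mediated-liability generator share so that exposure and
        outcome effects live on the same (measured expression) scale.
    """

    causal_variants: dict[str, float] = field(default_factory=dict)
    eqtl_effects: list[EqtlEffect] = field(default_factory=list)
    mediation_effects: dict[str, float] = field(default_factory=dict)
    prevalence: float = 0.1
    expression_log_sd: float = 0.5
    count_dispersion: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")
        if self.expression_log_sd <= 0:
            raise ValueError("expression_log_sd must be positive")
        if self.count_dispersion < 0:
            raise ValueError("count_dispersion must be >= 0")
        for gene, total in self.pve_by_gene().items():
            if total >= 1.0:
                raise ValueError(f"cis PVEs of gene {gene!r} sum to {total} >= 1")

    def pve_by_gene(self) -> dict[str, float]:
        totals: dict[str, float] = {}
        for e in self.eqtl_effects:
            totals[e.gene] = totals.get(e.gene, 0.0) + e.pve
        return totals

    @property
    def measured_fraction(self) -> float:
        """kappa: share of measured-expression variance that is biological."""
        s2 = self.expression_log_sd**2
        return s2 / (s2 + self.count_dispersion)

    def validate_against(self, variant_ids: list[str]) -> None:
        known = set(variant_ids)
        missing = (set(self.causal_variants) | {e.variant for e in self.eqtl_effects}) - known
        if missing:
            raise ValueError(f"truth references unknown variants: {sorted(missing)}")


@dataclass
class SimulatedGenotypes:
    """Dosage panel with variant metadata and realized LD."""

    dosages: np.ndarray  # samples x variants, values in {0, 1, 2}
    variants: pd.DataFrame  # variant_id, chrom, pos, effect_allele, other_allele, maf, info
    ld: np.ndarray  # realized pairwise r^2

    @property
    def variant_ids(self) -> list[str]:
        return list(self.variants["variant_id"])

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]


@dataclass
class SimulatedCohort:
    """One case-control cohort drawn on a genotype panel."""

    genotypes: SimulatedGenotypes
    phenotype: np.ndarray  # 0/1 per sample
    covariates: pd.DataFrame  # age, sex, PC1..PCk
    truth: SimTruth
    name: str = "cohort"

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return int((1 - self.phenotype).sum())


@dataclass
class SimulatedExpression:
    """RNA-seq counts for one tissue with matched genotypes and truth."""

    counts: pd.DataFrame  # genes x samples, non-negative integers
    gene_lengths: pd.Series  # bp per gene
    library_sizes: np.ndarray
    dispersions: pd.Series
    genotypes: SimulatedGenotypes
    annotations: pd.DataFrame  # gene_id, chrom, start, end, strand, tss
    covariates: pd.DataFrame
    truth: SimTruth
    latent: pd.DataFrame | None = None  # latent SD-scale expression (genes x samples)


def _ar1_block_normals(rng: np.random.Generator, n: int, sizes: list[int], rho: float) -> np.ndarray:
    """n draws of a blockwise AR(1) standard-normal vector."""
    cols = []
    for size in sizes:
        z = np.empty((n, size))
        z[:, 0] = rng.standard_normal(n)
        if size > 1:
            eps = rng.standard_normal((n, size - 1))
            scale = np.sqrt(1.0 - rho**2)
            for j in range(1, size):
                z[:, j] = rho * z[:, j - 1] + scale * eps[:, j - 1]
        cols.append(z)
    return np.concatenate(cols, axis=1)


def realized_r2(dosages: np.ndarray) -> np.ndarray:
    """Pairwise squared Pearson correlation of dosage columns.

    Monomorphic columns get r^2 = 0 off-diagonal (no LD information).
    """
    x = np.asarray(dosages, dtype=float)
    sd = x.std(axis=0)
    ok = sd > 0
    r2 = np.zeros((x.shape[1], x.shape[1]))
    if ok.sum() >= 2:
        c = np.corrcoef(x[:, ok], rowvar=False)
        r2[np.ix_(ok, ok)] = c**2
    np.fill_diagonal(r2, 1.0)
    return r2


def simulate_genotypes(spec: LdSpec, n_samples: int, seed: int = 0) -> SimulatedGenotypes:
    """Draw diploid dosages from the blockwise AR(1) latent-Gaussian model.

    Each of the two haplotypes per sample is an independent AR(1) latent
    Gaussian vector thresholded at the normal quantile of the allele
    frequency, so marginal allele frequencies are exact in expectation and
    adjacent-variant LD is controlled by ``spec.rho``.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    rng = np.random.default_rng(seed)
    m = spec.n_variants
    sizes = [min(spec.block_size, m - i) for i in range(0, m, spec.block_size)]
    # variants within a block share their allele frequency, as tightly
    # linked variants do; frequencies vary across blocks
    block_maf = rng.uniform(spec.maf_low, spec.maf_high, size=len(sizes))
    maf = np.repeat(block_maf, sizes)
    thresh = stats.norm.ppf(maf)
    hap1 = _ar1_block_normals(rng, n_samples, sizes, spec.rho) < thresh
    hap2 = _ar1_block_normals(rng, n_samples, sizes, spec.rho) < thresh
    dosages = (hap1.astype(np.int8) + hap2.astype(np.int8)).astype(float)
    variants = pd.DataFrame(
        {
            "variant_id": [f"rs{i + 1}" for i in range(m)],
            "chrom": spec.chrom,
            "pos": spec.positions,
            "effect_allele": "A",
            "other_allele": "G",
            "maf": maf,
            "info": 1.0,
        }
    )
    return SimulatedGenotypes(dosages=dosages, variants=variants, ld=realized_r2(dosages))


def _covariates(rng: np.random.Generator, dosages: np.ndarray, n_pcs: int = 5) -> pd.DataFrame:
    """Age, sex and ancestry principal components.

    The generator has no population structure, so genome-wide ancestry PCs
    are independent of any simulated locus; they are drawn as independent
    standard normals rather than from the SVD of the (locus-sized) panel,
    whose components would be linear combinations of the tested variants
    and would distort single-variant association.
    """
    n = dosages.shape[0]
    cov = pd.DataFrame(
        {
            "age": rng.normal(65.0, 10.0, size=n),
            "sex": rng.integers(0, 2, size=n).astype(float),
        }
    )
    for j in range(n_pcs):
        cov[f"PC{j + 1}"] = rng.standard_normal(n)
    return cov


def _genetic_component(
    genotypes: SimulatedGenotypes, truth: SimTruth
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Per-gene genetic contribution to latent expression (sum over the
    gene's cis effects on standardized dosages) and the residual variance
    1 - sum(PVE)."""
    n = genotypes.n_samples
    idx = {v: i for i, v in enumerate(genotypes.variant_ids)}
    genetic: dict[str, np.ndarray] = {}
    for eff in truth.eqtl_effects:
        g = genotypes.dosages[:, idx[eff.variant]]
        sd = g.std()
        gz = (g - g.mean()) / sd if sd > 0 else np.zeros(n)
        term = eff.sign * np.sqrt(eff.pve) * gz
        genetic[eff.gene] = genetic.get(eff.gene, 0.0) + term
    resid_var = {gene: 1.0 - pve for gene, pve in truth.pve_by_gene().items()}
    return genetic, resid_var


def _liability(
    rng: np.random.Generator,
    genotypes: SimulatedGenotypes,
    truth: SimTruth,
    covariates: pd.DataFrame,
) -> np.ndarray:
    """Disease liability per sample on the log-odds scale.

    The noise is standard logistic, so thresholding reproduces an exact
    logistic model: direct variant effects and mediated effects are log
    odds ratios that per-variant logistic regression recovers without a
    scale conversion.  Mediation acts through the *measured* expression
    score — the biological latent mixed with count-level noise in the
    proportion kappa fixed by the truth — because measured expression is
    the exposure the eQTL, TWAS and MR stages actually analyze.
    """
    n = genotypes.n_samples
    idx = {v: i for i, v in enumerate(genotypes.variant_ids)}
    liab = rng.logistic(0.0, 1.0, size=n)
    for vid, beta in truth.causal_variants.items():
        liab += beta * genotypes.dosages[:, idx[vid]]
    if truth.mediation_effects:
        genetic, resid_var = _genetic_component(genotypes, truth)
        kappa = truth.measured_fraction
        for gene, theta in truth.mediation_effects.items():
            if theta == 0.0:
                continue
            latent = genetic.get(gene, np.zeros(n)) + np.sqrt(
                resid_var.get(gene, 1.0)
            ) * rng.standard_normal(n)
            measured = np.sqrt(kappa) * latent + np.sqrt(1.0 - kappa) * rng.standard_normal(n)
            liab += theta * measured
    liab += 0.05 * (covariates["age"].to_numpy() - 65.0) / 10.0
    liab += 0.10 * covariates["sex"].to_numpy()
    return liab


def simulate_case_control(
    genotypes: SimulatedGenotypes,
    truth: SimTruth,
    n_cohorts: int = 1,
    n_samples_per_cohort: int | list[int] = 2000,
    seed: int = 0,
) -> list[SimulatedCohort]:
    """Draw case-control cohorts under the liability-threshold model.

    Cohorts share the variant panel (same allele frequencies and LD) but are
    otherwise independent: each cohort's samples are drawn with replacement
    from the panel rows and receive fresh covariates, liability noise and —
    under mediation — fresh latent-expression noise.  Case status is
    assigned by thresholding the liability at the quantile matching the
    target prevalence.
    """
    truth.validate_against(genotypes.variant_ids)
    if isinstance(n_samples_per_cohort, int):
        n_samples_per_cohort = [n_samples_per_cohort] * n_cohorts
    if len(n_samples_per_cohort) != n_cohorts:
        raise ValueError("need one sample size per cohort")
    rng = np.random.default_rng(seed)
    cohorts = []
    for c in range(n_cohorts):
        n = n_samples_per_cohort[c]
        rows = rng.integers(0, genotypes.n_samples, size=n)
        panel = SimulatedGenotypes(
            dosages=genotypes.dosages[rows],
            variants=genotypes.variants.copy(),
            ld=genotypes.ld,
        )
        cov = _covariates(rng, panel.dosages)
        liab = _liability(rng, panel, truth, cov)
        cut = np.quantile(liab, 1.0 - truth.prevalence)
        pheno = (liab > cut).astype(int)
        cohorts.append(
            SimulatedCohort(
                genotypes=panel,
                phenotype=pheno,
                covariates=cov,
                truth=truth,
                name=f"cohort{c + 1}",
            )
        )
    return cohorts


def make_gene_annotations(
    n_genes: int,
    chrom: str = "1",
    start: int = 1_000_000,
    spacing: int = 100_000,
    length: int = 20_000,
) -> pd.DataFrame:
    """Evenly spaced gene models on one chromosome, alternating strand.

    Coordinates are 1-based inclusive; the TSS is ``start`` for + strand
    genes and ``end`` for − strand genes.
    """
    starts = start + spacing * np.arange(n_genes)
    ends = starts + length - 1
    strands = np.where(np.arange(n_genes) % 2 == 0, "+", "-")
    return pd.DataFrame(
        {
            "gene_id": [f"GENE{i + 1}" for i in range(n_genes)],
            "chrom": chrom,
            "start": starts,
            "end": ends,
            "strand": strands,
            "tss": np.where(strands == "+", starts, ends),
        }
    )


def simulate_expression(
    genotypes: SimulatedGenotypes,
    truth: SimTruth,
    n_genes: int = 50,
    nb_dispersion: float | None = None,
    library_size_range: tuple[float, float] = (8e6, 12e6),
    seed: int = 0,
    annotations: pd.DataFrame | None = None,
    n_batch_factors: int = 0,
    batch_sd: float = 0.0,
) -> SimulatedExpression:
    """Negative-binomial RNA-seq counts with cis-eQTL dosage effects.

    Latent SD-scale expression of gene *g* in sample *s* is
    ``x = sum_j sign_j * sqrt(pve_j) * z(dose_j) + sqrt(1 - sum pve) * eps``
    over the gene's cis effects (``z`` standardizes the dosage), and pure
    noise for genes without one; optional shared batch factors add
    covariate structure.  The latent value scales the gene's transcription
    rate by ``exp(expression_log_sd * x)``; counts are drawn negative-
    binomial (gamma-Poisson) with the truth's dispersion around library-
    size-scaled means, so the measured (rank-normalized) expression mixes
    biology and count noise in the proportion kappa that the liability
    generator also uses.
    """
    if nb_dispersion is None:
        nb_dispersion = truth.count_dispersion
    if nb_dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    truth.validate_against(genotypes.variant_ids)
    rng = np.random.default_rng(seed)
    n = genotypes.n_samples
    if annotations is None:
        annotations = make_gene_annotations(n_genes)
    if len(annotations) != n_genes:
        raise ValueError("annotations must have one row per gene")
    genes = list(annotations["gene_id"])
    pos = dict(zip(genotypes.variant_ids, genotypes.variants["pos"]))
    tss = dict(zip(annotations["gene_id"], annotations["tss"]))
    for eff in truth.eqtl_effects:
        if eff.gene in tss and abs(pos[eff.variant] - tss[eff.gene]) > 1_000_000:
            raise ValueError(f"eQTL variant {eff.variant} outside the cis window of {eff.gene}")

    genetic, resid_var = _genetic_component(genotypes, truth)
    latent = np.empty((n_genes, n))
    for gi, gene in enumerate(genes):
        eps = rng.standard_normal(n)
        latent[gi] = genetic.get(gene, 0.0) + np.sqrt(resid_var.get(gene, 1.0)) * eps
    if n_batch_factors > 0 and batch_sd > 0:
        loadings = rng.normal(0.0, batch_sd, size=(n_genes, n_batch_factors))
        factors = rng.standard_normal((n_batch_factors, n))
        latent = latent + loadings @ factors

    lengths = pd.Series(rng.integers(500, 10_000, size=n_genes).astype(float), index=genes)
    lib = rng.uniform(*library_size_range, size=n)
    base = rng.normal(2.0, 1.0, size=n_genes)  # log-scale baseline abundance
    rate = np.exp(base[:, None] + truth.expression_log_sd * latent)
    weight = rate * lengths.to_numpy()[:, None]
    mean = lib[None, :] * weight / weight.sum(axis=0, keepdims=True)
    if nb_dispersion > 1e-8:
        shape = 1.0 / nb_dispersion
        lam = rng.gamma(shape, mean * nb_dispersion)
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mean)
    cov = _covariates(rng, genotypes.dosages)
    cov["smoking"] = rng.integers(0, 2, size=n).astype(float)
    return SimulatedExpression(
        counts=pd.DataFrame(counts, index=genes, columns=[f"S{i + 1}" for i in range(n)]),
        gene_lengths=lengths,
        library_sizes=lib,
        dispersions=pd.Series(nb_dispersion, index=genes),
        genotypes=genotypes,
        annotations=annotations,
        covariates=cov,
        truth=truth,
        latent=pd.DataFrame(latent, index=genes, columns=[f"S{i + 1}" for i in range(n)]),
    )


def simulate_tissue_panel(
    n_tissues: int,
    genes: list[str],
    specificity_pattern: dict[str, tuple[str, float]] | None = None,
    baseline: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Tissue x gene table of median log2 TPM.

    ``specificity_pattern`` maps a gene id to ``(tissue, share)``: that
    tissue's median is constructed so the gene's expression-specificity
    score there equals ``share`` exactly (share = 1 means expressed in that
    tissue only).  All other genes are uniform across tissues.
    """
    if n_tissues < 2:
        raise ValueError("n_tissues must be >= 2")
    tissues = ["aortic_valve"] + [f"tissue{i}" for i in range(1, n_tissues)]
    rng = np.random.default_rng(seed)
    table = pd.DataFrame(baseline, index=tissues, columns=list(genes), dtype=float)
    for gene, (tissue, share) in (specificity_pattern or {}).items():
        if tissue not in tissues:
            raise ValueError(f"unknown tissue {tissue!r}")
        if not (0.0 < share <= 1.0):
            raise ValueError("share must be in (0, 1]")
        if share == 1.0:
            table[gene] = 0.0
            table.loc[tissue, gene] = baseline
        else:
            table.loc[tissue, gene] = share / (1.0 - share) * baseline * (n_tissues - 1)
    if noise_sd > 0:
        table += np.abs(rng.normal(0.0, noise_sd, size=table.shape))
    return table
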