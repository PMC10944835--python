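"""cis-eQTL mapping: nominal pass, permutation pass with beta-approximated
empirical p-values and per-gene FDR-matched nominal thresholds, lead-SNP
enrichment tests, tissue-specific classification and subgroup heterogeneity.

The nominal pass residualizes both expression and dosage on the covariates
and regresses residual on residual; by the Frisch-Waugh theorem the slope
equals the dosage coefficient of the full multiple regression, and the
t-test uses the full-model residual degrees of freedom.  The permutation
pass follows the FastQTL construction: the best nominal p-value per
permutation of the expression vector is recorded, a Beta(a, b) distribution
is fitted to the permutation minima by maximum likelihood, and the smoothed
empirical p-value is the fitted CDF at the observed best p.  Benjamini-
Hochberg across genes on those empirical p-values at FDR 5% yields the set
of eGenes; inverting each gene's beta CDF at the empirical-p cutoff gives
the per-gene nominal significance threshold used to call significant pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "residualizer",
    "cis_window_variants",
    "map_cis_nominal",
    "permutation_pass",
    "GenePermutationResult",
    "egene_fdr",
    "call_significant_pairs",
    "lead_snp_enrichment",
    "classify_tissue_specific",
    "subgroup_heterogeneity",
]


def residualizer(covariates: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Projection matrix onto the orthogonal complement of [1, covariates]."""
    c = np.asarray(covariates, dtype=float)
    X = np.column_stack([np.ones(c.shape[0]), c])
    q, r = np.linalg.qr(X)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10))
    if rank < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    return np.eye(c.shape[0]) - q @ q.T


def cis_window_variants(
    variants: pd.DataFrame,
    tss: int,
    chrom: str,
    strand: str = "+",
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Variants within ``window`` bp of the TSS (inclusive), with signed
    distance to the TSS oriented by strand (positive = downstream)."""
    sub = variants[variants["chrom"].astype(str) == str(chrom)].copy()
    dist = sub["pos"].astype(int) - int(tss)
    if strand == "-":
        dist = -dist
    sub["tss_distance"] = dist
    return sub[dist.abs() <= window]


def _regress_residuals(
    g_resid: np.ndarray, y_resid: np.ndarray, dof: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slopes, SEs and two-sided p for each residualized dosage column."""
    gg = np.einsum("ij,ij->j", g_resid, g_resid)
    gy = y_resid @ g_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = gy / gg
        rss = (y_resid @ y_resid) - slope * gy
        sigma2 = np.maximum(rss, 0.0) / dof
        se = np.sqrt(sigma2 / gg)
        tstat = slope / se
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    return slope, se, p


def map_cis_nominal(
    dosages: pd.DataFrame,
    expression: pd.DataFrame,
    covariates: pd.DataFrame,
    variants: pd.DataFrame,
    annotations: pd.DataFrame,
    window: int = 1_000_000,
    maf_min: float = 0.01,
    info_min: float = 0.3,
) -> pd.DataFrame:
    """Nominal cis-eQTL pass for every gene in ``expression``.

    ``dosages``: samples x variant_id; ``expression``: genes x samples,
    already inverse-normal transformed; ``variants``: variant metadata with
    chrom/pos/maf/info; ``annotations``: gene metadata with chrom/tss/strand.
    Variants with MAF below ``maf_min`` or INFO below ``info_min`` are not
    tested (both bounds inclusive, matching "≥0.01" and "≥0.3").
    """
    samples = list(expression.columns)
    if list(dosages.index) != samples:
        dosages = dosages.loc[samples]
    resid = residualizer(covariates.loc[samples])
    dof = len(samples) - covariates.shape[1] - 2  # intercept + dosage

    eligible = variants[(variants["maf"] >= maf_min) & (variants["info"] >= info_min)]
    ann = annotations.set_index("gene_id")
    out = []
    for gene in expression.index:
        if gene not in ann.index:
            continue
        meta = ann.loc[gene]
        cis = cis_window_variants(eligible, int(meta["tss"]), meta["chrom"], meta["strand"], window)
        if cis.empty:
            continue
        vids = list(cis["variant_id"])
        g_resid = resid @ dosages[vids].to_numpy(dtype=float)
        y_resid = resid @ expression.loc[gene].to_numpy(dtype=float)
        slope, se, p = _regress_residuals(g_resid, y_resid, dof)
        out.append(
            pd.DataFrame(
                {
                    "gene_id": gene,
                    "variant_id": vids,
                    "tss_distance": cis["tss_distance"].to_numpy(),
                    "slope": slope,
                    "slope_se": se,
                    "p_nominal": p,
                }
            )
        )
    if not out:
        return pd.DataFrame(
            columns=["gene_id", "variant_id", "tss_distance", "slope", "slope_se", "p_nominal"]
        )
    return pd.concat(out, ignore_index=True)


@dataclass
class GenePermutationResult:
    """Permutation summary for one gene."""

    gene_id: str
    best_variant: str
    best_p_nominal: float
    n_permutations: int
    p_empirical_direct: float
    beta_a: float
    beta_b: float
    p_empirical: float  # beta-smoothed; falls back to direct on degenerate fits
    degenerate_fit: bool


def _best_p_per_permutation(
    g_resid: np.ndarray, y_perm_resid: np.ndarray, dof: int
) -> np.ndarray:
    """Minimum nominal p across variants for each permuted phenotype row."""
    gg = np.einsum("ij,ij->j", g_resid, g_resid)
    yy = np.einsum("ij,ij->i", y_perm_resid, y_perm_resid)
    gy = y_perm_resid @ g_resid  # B x m
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = gy**2 / (gg[None, :] * yy[:, None])
        r2 = np.clip(r2, 0.0, 1.0 - 1e-12)
        t2 = dof * r2 / (1.0 - r2)
    best_t2 = np.nanmax(t2, axis=1)
    return 2.0 * stats.t.sf(np.sqrt(best_t2), dof)


def permutation_pass(
    dosages: pd.DataFrame,
    expression: pd.DataFrame,
    covariates: pd.DataFrame,
    variants: pd.DataFrame,
    annotations: pd.DataFrame,
    n_permutations: int = 1000,
    seed: int = 0,
    window: int = 1_000_000,
    maf_min: float = 0.01,
    info_min: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Permutation pass for all genes.

    Returns (per-gene permutation table, nominal pair table).  For each
    gene, the expression vector is permuted across samples B times with the
    covariates fixed; the direct empirical p is (r + 1)/(B + 1) where r is
    the number of permutation minima at or below the observed best nominal
    p, and the smoothed empirical p is the CDF of a maximum-likelihood
    Beta(a, b) fit to the permutation minima.
    """
    if n_permutations < 100:
        raise ValueError("need at least 100 permutations")
    nominal = map_cis_nominal(
        dosages, expression, covariates, variants, annotations, window, maf_min, info_min
    )
    samples = list(expression.columns)
    if list(dosages.index) != samples:
        dosages = dosages.loc[samples]
    resid = residualizer(covariates.loc[samples])
    dof = len(samples) - covariates.shape[1] - 2
    rng = np.random.default_rng(seed)

    results = []
    for gene, pairs in nominal.groupby("gene_id", sort=False):
        vids = list(pairs["variant_id"])
        g_resid = resid @ dosages[vids].to_numpy(dtype=float)
        y = expression.loc[gene].to_numpy(dtype=float)
        perms = np.stack([rng.permutation(y) for _ in range(n_permutations)])
        perm_resid = perms @ resid.T
        perm_best = _best_p_per_permutation(g_resid, perm_resid, dof)
        i_best = int(np.argmin(pairs["p_nominal"].to_numpy()))
        best_p = float(pairs["p_nominal"].iloc[i_best])
        r = int(np.sum(perm_best <= best_p))
        p_direct = (r + 1) / (n_permutations + 1)
        degenerate = False
        try:
            a, b, _, _ = stats.beta.fit(
                np.clip(perm_best, 1e-300, 1.0 - 1e-12), floc=0.0, fscale=1.0
            )
            if not (a > 0 and b > 0 and np.isfinite(a) and np.isfinite(b)):
                raise ValueError
            p_smooth = float(stats.beta.cdf(best_p, a, b))
            if not np.isfinite(p_smooth):
                raise ValueError
        except Exception:
            degenerate = True
            a = b = np.nan
            p_smooth = p_direct
        results.append(
            GenePermutationResult(
                gene_id=gene,
                best_variant=str(pairs["variant_id"].iloc[i_best]),
                best_p_nominal=best_p,
                n_permutations=n_permutations,
                p_empirical_direct=p_direct,
                beta_a=float(a),
                beta_b=float(b),
                p_empirical=max(p_smooth, 1e-300),
                degenerate_fit=degenerate,
            )
        )
    perm_df = pd.DataFrame([r.__dict__ for r in results])
    return perm_df, nominal


def egene_fdr(perm_df: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg across genes on empirical p-values, and per-gene
    nominal significance thresholds.

    Significant genes (eGenes) are those whose BH-adjusted empirical p is
    at or below ``fdr``.  The empirical-p cutoff is the midpoint between
    the largest passing and smallest failing raw empirical p (FastQTL
    convention); each gene's nominal threshold is the inverse of its fitted
    beta CDF at that cutoff.
    """
    out = perm_df.copy()
    if out.empty:
        out["q_value"] = out["significant"] = out["nominal_threshold"] = None
        return out
    rej, qvals, _, _ = multipletests(out["p_empirical"], alpha=fdr, method="fdr_bh")
    out["q_value"] = qvals
    out["significant"] = rej
    if rej.any():
        passing = out.loc[rej, "p_empirical"].max()
        failing = out.loc[~rej, "p_empirical"]
        cutoff = (passing + failing.min()) / 2.0 if len(failing) else passing
    else:
        cutoff = 0.0
    thresholds = []
    for _, row in out.iterrows():
        if row["degenerate_fit"] or not np.isfinite(row["beta_a"]):
            thresholds.append(cutoff)
        else:
            thresholds.append(float(stats.beta.ppf(cutoff, row["beta_a"], row["beta_b"])))
    out["nominal_threshold"] = thresholds
    return out


def call_significant_pairs(nominal: pd.DataFrame, egenes: pd.DataFrame) -> pd.DataFrame:
    """Significant SNP-gene pairs: nominal p at or below the gene's nominal
    threshold, restricted to significant eGenes."""
    sig = egenes[egenes["significant"]].set_index("gene_id")["nominal_threshold"]
    pairs = nominal.merge(sig.rename("nominal_threshold"), left_on="gene_id", right_index=True)
    out = pairs[pairs["p_nominal"] <= pairs["nominal_threshold"]].copy()
    out["significant"] = True
    return out.reset_index(drop=True)


def lead_snp_enrichment(
    n_sig_lead: int,
    n_lead: int,
    n_sig_all: int,
    n_all: int,
    lead_p_values: np.ndarray | None = None,
    all_p_values: np.ndarray | None = None,
) -> dict[str, float]:
    """Enrichment of significant SNP-gene pairs among lead-SNP pairs.

    A 2x2 continuity-corrected Pearson chi-squared test compares the
    proportion of significant pairs among lead-SNP pairs with the
    proportion among all tested pairs; optionally a Wilcoxon rank-sum test
    (normal approximation with tie correction) compares the two p-value
    samples directly.
    """
    if min(n_sig_lead, n_sig_all) < 0 or n_lead <= 0 or n_all <= 0:
        raise ValueError("counts must be non-negative with non-empty groups")
    table = np.array(
        [[n_sig_lead, n_lead - n_sig_lead], [n_sig_all, n_all - n_sig_all]], dtype=float
    )
    if np.any(table < 0) or np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        raise ValueError("degenerate 2x2 table")
    chi2, p_chi2, _, _ = stats.chi2_contingency(table, correction=True)
    out = {
        "prop_lead": n_sig_lead / n_lead,
        "prop_all": n_sig_all / n_all,
        "chi2": float(chi2),
        "p_chi2": float(p_chi2),
    }
    if lead_p_values is not None and all_p_values is not None:
        res = stats.mannwhitneyu(
            np.asarray(lead_p_values, dtype=float),
            np.asarray(all_p_values, dtype=float),
            alternative="less",
            method="asymptotic",
        )
        out["p_wilcoxon"] = float(res.pvalue)
    return out


def classify_tissue_specific(significance: pd.DataFrame) -> pd.DataFrame:
    """Tissue-specific eQTLs: SNP-gene pairs significant in exactly one
    tissue.

    ``significance`` is a boolean frame indexed by pair with one column per
    tissue.  Pairs significant nowhere are absent from the output.
    """
    if significance.shape[1] < 2:
        raise ValueError("need at least 2 tissues")
    counts = significance.sum(axis=1)
    specific = significance[counts == 1]
    return pd.DataFrame(
        {"tissue": specific.idxmax(axis=1)}, index=specific.index
    ).reset_index()


def subgroup_heterogeneity(
    slope1: float, se1: float, slope2: float, se2: float
) -> tuple[float, float]:
    """Two-sample z-test for a difference in eQTL effect between subgroups
    (e.g. tricuspid vs bicuspid valves).  Returns (z, two-sided p)."""
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    z = (slope1 - slope2) / np.hypot(se1, se2)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))
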