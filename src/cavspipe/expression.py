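"""Aortic-valve expression processing.

TPM computation, expressed-gene filtering, TMM between-sample normalization,
per-gene inverse-normal transformation, hidden expression covariates, and
cross-tissue expression-specificity scores (ESS) with the valve
high-expression flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compute_tpm",
    "filter_expressed",
    "tmm_normalize",
    "log_cpm",
    "inverse_normal",
    "inverse_normal_matrix",
    "expression_covariates",
    "ess_table",
    "specificity_scores",
    "flag_high_expression",
]


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: length-normalized read rates rescaled so
    every sample column sums to 1e6.  Zero-library columns come back as all
    zeros (flagged by the caller via the column sum)."""
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        raise ValueError("gene lengths must be positive and cover all genes")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    tpm = rate.div(denom.where(denom > 0), axis=1) * 1e6
    return tpm.fillna(0.0)


def filter_expressed(
    counts: pd.DataFrame,
    tpm: pd.DataFrame,
    min_tpm: float = 0.1,
    min_reads: int = 6,
    min_frac: float = 0.2,
) -> list[str]:
    """Genes kept for eQTL mapping: TPM strictly greater than ``min_tpm`` in
    at least ``min_frac`` of samples AND at least ``min_reads`` reads in at
    least ``min_frac`` of samples."""
    frac_tpm = (tpm > min_tpm).mean(axis=1)
    frac_reads = (counts >= min_reads).mean(axis=1)
    keep = (frac_tpm >= min_frac) & (frac_reads >= min_frac)
    return list(counts.index[keep])


def _tmm_factor_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    logratio_trim: float = 0.3,
    abs_expr_trim: float = 0.05,
) -> float:
    """TMM factor of one sample against the reference (canonical edgeR
    construction): double-trimmed, precision-weighted mean of M-values."""
    n_obs, n_ref = obs.sum(), ref.sum()
    ok = (obs > 0) & (ref > 0)
    if not ok.any():
        return np.nan
    o, r = obs[ok], ref[ok]
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, w = m[finite], a[finite], w[finite]
    if len(m) == 0:
        return np.nan
    if np.max(np.abs(m)) < 1e-6:  # identical composition
        return 1.0
    n = len(m)
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
    lo_a, hi_a = np.floor(n * abs_expr_trim) + 1, n - np.floor(n * abs_expr_trim)
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0**f)


def tmm_normalize(
    counts: pd.DataFrame,
    reference_sample: str | None = None,
) -> pd.Series:
    """Trimmed-mean-of-M-values scale factors, one per sample.

    The reference sample is the column whose 75th count-fraction percentile
    is closest to the mean across samples (unless given).  M-values are
    trimmed 30% from each tail, A-values 5%, and the surviving M-values are
    averaged with inverse-delta-method precision weights.  Factors are
    rescaled so their log mean is zero; all-zero samples get NaN.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0)
    if reference_sample is None:
        with np.errstate(invalid="ignore", divide="ignore"):
            f75 = counts.div(lib, axis=1).quantile(0.75)
        reference_sample = (f75 - f75.mean()).abs().idxmin()
    ref = counts[reference_sample].to_numpy(dtype=float)
    factors = pd.Series(
        {
            s: _tmm_factor_pair(counts[s].to_numpy(dtype=float), ref)
            for s in counts.columns
        }
    )
    valid = factors.dropna()
    if len(valid):
        factors = factors / np.exp(np.log(valid).mean())
    return factors


def log_cpm(counts: pd.DataFrame, factors: pd.Series | None = None, prior: float = 0.5) -> pd.DataFrame:
    """log2 counts per million on TMM-effective library sizes."""
    lib = counts.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * factors.reindex(counts.columns).fillna(1.0)
    return np.log2((counts + prior).div(lib + 1.0, axis=1) * 1e6)


def inverse_normal(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform, offset (rank - 0.5)/n, ties by
    average rank.  Constant vectors are rejected (no rank information)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples")
    if np.all(x == x[0]):
        raise ValueError("constant vector has no rank information")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - 0.5) / len(x))


def inverse_normal_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Apply the inverse normal transform per gene (row); constant genes are
    dropped."""
    rows = {}
    for gene, row in expr.iterrows():
        vals = row.to_numpy(dtype=float)
        if np.all(vals == vals[0]):
            continue
        rows[gene] = inverse_normal(vals)
    return pd.DataFrame.from_dict(rows, orient="index", columns=expr.columns)


def expression_covariates(normalized: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k hidden expression factors as principal components.

    Rows of ``normalized`` are genes, columns samples.  Genes are centered,
    and the top-k right singular vectors (orthonormal sample loadings,
    ordered by variance explained) are returned as columns ``EC1..ECk``.
    """
    n_genes, n_samples = normalized.shape
    if k >= min(n_genes, n_samples):
        raise ValueError("k must be smaller than both the gene and sample counts")
    x = normalized.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    return pd.DataFrame(
        vt[:k].T, index=normalized.columns, columns=[f"EC{i + 1}" for i in range(k)]
    )


def ess_table(tissue_medians: pd.DataFrame) -> pd.DataFrame:
    """Tissue x gene expression-specificity scores.

    Each tissue's score is its median log2 TPM divided by the sum of the
    medians over all tissues (negatives clamped to zero first), so scores
    lie in [0, 1] and sum to 1 per gene wherever any tissue expresses it.
    """
    clamped = tissue_medians.clip(lower=0.0)
    total = clamped.sum(axis=0)
    return clamped.div(total.where(total > 0), axis=1)


def specificity_scores(
    tissue_medians: pd.DataFrame,
    valve_tissue: str = "aortic_valve",
    ess_threshold: float = 0.1,
) -> pd.DataFrame:
    """Expression specificity scores per tissue and gene.

    ``tissue_medians`` is tissue x gene median log2 TPM.  ESS of a tissue is
    its median divided by the sum of medians over all tissues; negative
    medians are clamped to zero before division (the ratio is undefined for
    negative values).  Returns a tidy per-gene frame with the valve ESS and
    the valve-specific flag (ESS strictly above ``ess_threshold``); genes
    with zero total expression get NaN ESS and are flagged unusable.
    """
    if valve_tissue not in tissue_medians.index:
        raise ValueError(f"{valve_tissue!r} not in tissue table")
    total = tissue_medians.clip(lower=0.0).sum(axis=0)
    ess = ess_table(tissue_medians)
    defined = ess.columns[ess.notna().any(axis=0)]
    max_tissue = pd.Series(pd.NA, index=ess.columns, dtype=object)
    if len(defined):
        max_tissue[defined] = ess[defined].idxmax(axis=0)
    out = pd.DataFrame(
        {
            "valve_ess": ess.loc[valve_tissue],
            "max_ess": ess.max(axis=0),
            "max_tissue": max_tissue,
        }
    )
    out["undefined"] = total <= 0
    out["valve_specific"] = (out["valve_ess"] > ess_threshold).fillna(False) & ~out["undefined"]
    out.index.name = "gene_id"
    return out


def flag_high_expression(valve_medians: pd.Series, percentile: float = 90.0) -> pd.Series:
    """Flag genes whose valve median log2 TPM lies strictly above the given
    empirical percentile of all genes."""
    if len(valve_medians) < 10:
        raise ValueError("need at least 10 genes for a stable percentile")
    cut = np.percentile(valve_medians.to_numpy(dtype=float), percentile)
    return valve_medians > cut
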