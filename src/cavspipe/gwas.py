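"""Per-cohort logistic GWAS, QC, inverse-variance-weighted meta-analysis,
genomic inflation, LD clumping / locus definition, and single-causal-variant
credible sets.

Conventions
-----------
* Effects are log odds ratios per effect-allele dose; p-values two-sided.
* Coordinates are 1-based inclusive.
* Significance threshold 5e-8; independent-significant variants at r² ≥ 0.6;
  lead variants at r² < 0.1; leads within 500 kb merged into one locus.
* Ties broken everywhere by ascending p, then position, then variant id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from cavspipe.simulate import SimulatedCohort

__all__ = [
    "run_cohort_gwas",
    "qc_filter",
    "meta_analyze",
    "genomic_inflation",
    "clump_and_define_loci",
    "fine_map_credible_set",
    "Locus",
    "wakefield_log_abf",
]

#: median of the chi-squared distribution with 1 df
CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))

ASSOC_COLUMNS = [
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "p",
    "info",
    "n_cases",
    "n_controls",
    "flag",
]


def run_cohort_gwas(
    cohort: SimulatedCohort,
    covariate_names: list[str] | None = None,
) -> pd.DataFrame:
    """Per-variant logistic regression of case status on dosage.

    Each variant is fitted by maximum likelihood with an intercept and the
    cohort covariates (age, sex, principal components by default).  Variants
    that are monomorphic or whose fit fails (e.g. perfect separation) are
    returned with NaN estimates and a non-empty ``flag`` instead of being
    dropped, so the caller controls exclusion.
    """
    y = np.asarray(cohort.phenotype, dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("phenotype must be binary 0/1")
    if covariate_names is None:
        covariate_names = list(cohort.covariates.columns)
    cov = cohort.covariates[covariate_names].to_numpy(dtype=float)
    base = np.column_stack([np.ones(len(y)), cov])
    if np.linalg.matrix_rank(base) < base.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    n_cases = int(y.sum())
    n_controls = int(len(y) - n_cases)

    rows = []
    meta = cohort.genotypes.variants
    for j, vid in enumerate(cohort.genotypes.variant_ids):
        g = cohort.genotypes.dosages[:, j]
        eaf = float(g.mean() / 2.0)
        rec = {
            "variant_id": vid,
            "chrom": meta["chrom"].iloc[j],
            "pos": int(meta["pos"].iloc[j]),
            "effect_allele": meta["effect_allele"].iloc[j],
            "other_allele": meta["other_allele"].iloc[j],
            "eaf": eaf,
            "beta": np.nan,
            "se": np.nan,
            "p": np.nan,
            "info": float(meta["info"].iloc[j]),
            "n_cases": n_cases,
            "n_controls": n_controls,
            "flag": "",
        }
        if g.std() == 0:
            rec["flag"] = "monomorphic"
            rows.append(rec)
            continue
        X = np.column_stack([base, g])
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            beta, se = fit.params[-1], fit.bse[-1]
            if not (np.isfinite(beta) and np.isfinite(se) and se > 0) or abs(beta) > 20:
                rec["flag"] = "unstable_fit"
            else:
                rec.update(beta=float(beta), se=float(se), p=float(fit.pvalues[-1]))
        except Exception:
            rec["flag"] = "fit_failed"
        rows.append(rec)
    return pd.DataFrame(rows, columns=ASSOC_COLUMNS)


def qc_filter(
    records: pd.DataFrame,
    info_min: float = 0.3,
    maf_min: float = 0.001,
    mac_cases_min: float = 5.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude variants failing summary-statistic QC.

    Rules (all strict inequalities): imputation INFO < ``info_min``; minor
    allele frequency < ``maf_min``; minor allele count in cases corrected
    for imputation quality (MAF x 2 x n_cases x INFO) < ``mac_cases_min``.
    Unusable records (non-empty ``flag``) are also excluded.  Returns the
    retained records and an exclusion log naming the violated rule.
    """
    rec = records.copy()
    maf = np.minimum(rec["eaf"], 1.0 - rec["eaf"])
    mac_cases = maf * 2.0 * rec["n_cases"] * rec["info"]
    reasons = pd.Series("", index=rec.index)
    reasons[rec["flag"].astype(str) != ""] = "flagged:" + rec["flag"].astype(str)
    reasons[(reasons == "") & (rec["info"] < info_min)] = "low_info"
    reasons[(reasons == "") & (maf < maf_min)] = "low_maf"
    reasons[(reasons == "") & (mac_cases < mac_cases_min)] = "low_mac_cases"
    excluded = rec[reasons != ""].assign(exclusion_rule=reasons[reasons != ""])
    kept = rec[reasons == ""].reset_index(drop=True)
    return kept, excluded.reset_index(drop=True)


def _harmonize(row: pd.Series, ref: pd.Series) -> pd.Series | None:
    """Flip a cohort record onto the reference allele orientation.

    Returns None when the allele pairs neither match nor swap.
    """
    if (row["effect_allele"], row["other_allele"]) == (ref["effect_allele"], ref["other_allele"]):
        return row
    if (row["effect_allele"], row["other_allele"]) == (ref["other_allele"], ref["effect_allele"]):
        out = row.copy()
        out["beta"] = -row["beta"]
        out["eaf"] = 1.0 - row["eaf"]
        out["effect_allele"] = ref["effect_allele"]
        out["other_allele"] = ref["other_allele"]
        return out
    return None


_PALINDROMIC = {frozenset(("A", "T")), frozenset(("G", "C"))}


def meta_analyze(
    cohort_tables: list[pd.DataFrame],
    drop_palindromic_maf: float = 0.4,
) -> pd.DataFrame:
    """Inverse-variance-weighted fixed-effect meta-analysis across cohorts.

    Variants are keyed by (chrom, pos); a cohort record whose alleles are
    swapped relative to the first cohort carrying the variant is sign-flipped.
    Strand-ambiguous A/T and G/C variants with MAF > ``drop_palindromic_maf``
    are dropped, as are records whose allele pairs cannot be reconciled.

    Per variant: ``beta = sum(w_i b_i)/sum(w_i)`` with ``w_i = 1/se_i^2``,
    ``se = sum(w_i)^-1/2``, Cochran's ``Q = sum(w_i (b_i - beta)^2)`` with
    heterogeneity p from chi-squared(k-1) and ``I^2 = max(0, (Q-(k-1))/Q)``
    in percent.
    """
    groups: dict[tuple, list[pd.Series]] = {}
    order: list[tuple] = []
    for tab in cohort_tables:
        usable = tab[(tab["flag"].astype(str) == "") & tab["se"].gt(0) & tab["beta"].notna()]
        for _, row in usable.iterrows():
            key = (row["chrom"], row["pos"])
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(row)

    out = []
    for key in order:
        rows = groups[key]
        ref = rows[0]
        alleles = frozenset((ref["effect_allele"], ref["other_allele"]))
        maf = min(ref["eaf"], 1.0 - ref["eaf"])
        if alleles in _PALINDROMIC and maf > drop_palindromic_maf:
            continue
        harmonized = [h for h in (_harmonize(r, ref) for r in rows) if h is not None]
        if not harmonized:
            continue
        b = np.array([r["beta"] for r in harmonized], dtype=float)
        se = np.array([r["se"] for r in harmonized], dtype=float)
        w = 1.0 / se**2
        beta = float(np.sum(w * b) / np.sum(w))
        se_meta = float(np.sum(w) ** -0.5)
        z = beta / se_meta
        k = len(b)
        q = float(np.sum(w * (b - beta) ** 2))
        p_het = float(stats.chi2.sf(q, k - 1)) if k > 1 else 1.0
        i2 = max(0.0, (q - (k - 1)) / q) * 100.0 if q > 0 else 0.0
        out.append(
            {
                "variant_id": ref["variant_id"],
                "chrom": ref["chrom"],
                "pos": int(ref["pos"]),
                "effect_allele": ref["effect_allele"],
                "other_allele": ref["other_allele"],
                "eaf": float(np.mean([r["eaf"] for r in harmonized])),
                "beta": beta,
                "se": se_meta,
                "p": float(2.0 * stats.norm.sf(abs(z))),
                "q_stat": q,
                "p_het": p_het,
                "i2": i2,
                "n_cohorts": k,
                "direction": "".join("+" if bi > 0 else "-" if bi < 0 else "0" for bi in b),
            }
        )
    return pd.DataFrame(out)


def genomic_inflation(p_values: np.ndarray) -> float:
    """Genomic inflation factor: median association chi-squared over the
    null chi-squared(1) median (0.4549)."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if len(p) < 100:
        raise ValueError("need at least 100 p-values for a stable median")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_MEDIAN_1DF)


@dataclass
class Locus:
    """A merged genomic risk locus."""

    locus_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    lead_variant: str
    lead_p: float
    independent_significant: list[str] = field(default_factory=list)
    members: list[str] = field(default_factory=list)


def _sorted_by_significance(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["p", "pos", "variant_id"], kind="mergesort")


def clump_and_define_loci(
    meta: pd.DataFrame,
    ld: pd.DataFrame | np.ndarray,
    variant_ids: list[str] | None = None,
    p_threshold: float = 5e-8,
    r2_independent: float = 0.6,
    r2_lead: float = 0.1,
    merge_kb: float = 500.0,
) -> list[Locus]:
    """Greedy LD clumping and locus definition.

    Working through genome-wide-significant variants in order of ascending
    p-value: a variant in LD (r² ≥ ``r2_independent``) with an existing
    independent-significant variant joins its clump, otherwise it becomes a
    new independent-significant variant.  Independent-significant variants
    are then greedily collapsed to lead variants at r² < ``r2_lead``, and
    leads within ``merge_kb`` kilobases on the same chromosome are merged
    into a single locus keeping the smallest-p lead.  Variants missing from
    the LD matrix are treated as unlinked and start their own clumps.
    """
    if isinstance(ld, pd.DataFrame):
        ld_ids = list(ld.index)
        ld_mat = ld.to_numpy()
    else:
        if variant_ids is None:
            raise ValueError("variant_ids required when ld is an array")
        ld_ids = list(variant_ids)
        ld_mat = np.asarray(ld)
    pos_in_ld = {v: i for i, v in enumerate(ld_ids)}

    def r2(a: str, b: str) -> float:
        ia, ib = pos_in_ld.get(a), pos_in_ld.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(ld_mat[ia, ib])

    sig = _sorted_by_significance(meta[meta["p"] < p_threshold])
    if sig.empty:
        return []

    # pass 1: independent significant variants (clump at r2 >= r2_independent)
    ind_sig: list[pd.Series] = []
    clump_members: dict[str, list[str]] = {}
    for _, row in sig.iterrows():
        host = next(
            (s["variant_id"] for s in ind_sig if r2(row["variant_id"], s["variant_id"]) >= r2_independent),
            None,
        )
        if host is None:
            ind_sig.append(row)
            clump_members[row["variant_id"]] = [row["variant_id"]]
        else:
            clump_members[host].append(row["variant_id"])

    # pass 2: lead variants among independent significant (r2 < r2_lead)
    leads: list[pd.Series] = []
    lead_group: dict[str, list[str]] = {}
    for row in ind_sig:  # already in significance order
        host = next(
            (s["variant_id"] for s in leads if r2(row["variant_id"], s["variant_id"]) >= r2_lead),
            None,
        )
        if host is None:
            leads.append(row)
            lead_group[row["variant_id"]] = [row["variant_id"]]
        else:
            lead_group[host].append(row["variant_id"])

    # pass 3: merge leads within merge_kb on the same chromosome
    lead_df = pd.DataFrame(leads).sort_values(["chrom", "pos"], kind="mergesort")
    merged: list[list[pd.Series]] = []
    for _, row in lead_df.iterrows():
        if (
            merged
            and merged[-1][-1]["chrom"] == row["chrom"]
            and row["pos"] - merged[-1][-1]["pos"] <= merge_kb * 1000.0
        ):
            merged[-1].append(row)
        else:
            merged.append([row])

    loci = []
    for i, group in enumerate(merged):
        group_sorted = sorted(group, key=lambda r: (r["p"], r["pos"], r["variant_id"]))
        lead = group_sorted[0]
        ind = [v for g in group for v in lead_group[g["variant_id"]]]
        members = sorted({m for v in ind for m in clump_members[v]})
        positions = sig.set_index("variant_id").loc[members, "pos"]
        loci.append(
            Locus(
                locus_id=f"locus{i + 1}",
                chrom=str(lead["chrom"]),
                start=int(positions.min()),
                end=int(positions.max()),
                lead_variant=str(lead["variant_id"]),
                lead_p=float(lead["p"]),
                independent_significant=sorted(ind),
                members=members,
            )
        )
    loci.sort(key=lambda L: (L.lead_p, L.start, L.locus_id))
    for i, L in enumerate(loci):
        L.locus_id = f"locus{i + 1}"
    return loci


def wakefield_log_abf(beta: np.ndarray, se: np.ndarray, prior_sd: float) -> np.ndarray:
    """Wakefield log approximate Bayes factor for association vs null.

    With ``V = se^2``, ``W = prior_sd^2``, ``r = W/(V+W)`` and ``z = beta/se``:
    ``log ABF = 0.5*(log(1 - r) + z^2 * r)``.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0) or prior_sd <= 0:
        raise ValueError("se and prior_sd must be positive")
    v = se**2
    w = prior_sd**2
    r = w / (v + w)
    z = beta / se
    return 0.5 * (np.log1p(-r) + z**2 * r)


def fine_map_credible_set(
    locus_records: pd.DataFrame,
    prior_sd: float = 0.2,
    coverage: float = 0.95,
) -> pd.DataFrame:
    """Single-causal-variant credible set from approximate Bayes factors.

    Assuming exactly one causal variant in the locus with a flat prior over
    variants, the posterior probability of each variant is its ABF
    normalized over the locus.  The credible set is the smallest prefix of
    variants, ordered by descending posterior, whose cumulative posterior
    reaches ``coverage``.  Returns the full locus table with ``posterior``,
    ``cumulative`` and ``in_credible_set`` columns, posterior-descending.
    """
    rec = locus_records[np.isfinite(locus_records["beta"]) & locus_records["se"].gt(0)].copy()
    if rec.empty:
        raise ValueError("no usable records in locus")
    labf = wakefield_log_abf(rec["beta"].to_numpy(), rec["se"].to_numpy(), prior_sd)
    labf = labf - labf.max()
    post = np.exp(labf)
    post /= post.sum()
    rec["log_abf"] = labf
    rec["posterior"] = post
    rec = rec.sort_values(
        ["posterior", "p", "pos", "variant_id"], ascending=[False, True, True, True], kind="mergesort"
    ).reset_index(drop=True)
    rec["cumulative"] = rec["posterior"].cumsum()
    cut = int(np.searchsorted(rec["cumulative"].to_numpy(), coverage - 1e-12) + 1)
    rec["in_credible_set"] = np.arange(len(rec)) < cut
    rec["uninformative"] = bool(np.allclose(rec["posterior"], 1.0 / len(rec)))
    return rec
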