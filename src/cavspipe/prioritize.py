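"""Gene prioritization: LD-aware gene-level association test, positional
gene mapping, the ten-feature evidence ledger, and hypergeometric pathway
enrichment.

The ten per-gene features are: (1) nearest gene to a lead GWAS SNP,
(2) lead SNP intronic for the gene, (3) lead SNP in LD (r² ≥ 0.8) with a
missense/nonsense variant of the gene, (4) significant in the gene-level
association test, (5) valve expression above the 90th percentile of all
protein-coding genes, (6) valve-specific expression (ESS > 0.1),
(7) the lead SNP is a significant valve eQTL for the gene, (8) significant
in the TWAS, (9) colocalization PP4 > 0.75, and (10) MR support
(IVW p < 0.05, WM p < 0.05 and heterogeneity p > 0.01).  Genes with four
or more features are prioritized.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "gene_level_test",
    "map_positional_genes",
    "gene_test_fdr",
    "build_evidence_matrix",
    "hypergeometric_enrichment",
    "FEATURES",
]

FEATURES = [
    "nearest_gene",
    "intronic_lead",
    "missense_ld",
    "gene_test_significant",
    "high_expression",
    "valve_specific",
    "valve_eqtl",
    "twas_significant",
    "coloc_pp4",
    "mr_significant",
]


def gene_level_test(z_scores: np.ndarray, ld: np.ndarray) -> dict[str, float]:
    """LD-aware gene-level association test (mean-chi-squared statistic).

    The statistic is the mean of squared variant z-scores over the gene
    window.  Under the null the z vector is N(0, R) with R the LD
    correlation matrix, so the statistic is a weighted sum of independent
    chi-squared(1) variables with weights the eigenvalues of R divided by
    the variant count.  The p-value comes from Satterthwaite moment
    matching to a scaled chi-squared distribution; tiny or negative
    eigenvalues are clipped at 1e-8.  With one variant this reduces exactly
    to the variant's two-sided test.
    """
    z = np.atleast_1d(np.asarray(z_scores, dtype=float))
    k = len(z)
    if k == 0:
        raise ValueError("need at least one SNP in the gene window")
    R = np.atleast_2d(np.asarray(ld, dtype=float))
    if R.shape != (k, k):
        raise ValueError("LD matrix shape must match the z-score count")
    stat = float(np.mean(z**2))
    lam = np.clip(np.linalg.eigvalsh(R), 1e-8, None) / k
    mean = float(lam.sum())
    var = float(2.0 * np.sum(lam**2))
    scale = var / (2.0 * mean)
    df = 2.0 * mean**2 / var
    p = float(stats.chi2.sf(stat / scale, df))
    return {"stat": stat, "p": p, "df": df, "scale": scale, "n_snps": k}


def gene_test_fdr(gene_p: pd.Series, fdr: float = 0.05) -> pd.Series:
    """BH significance flags for the gene-level test across tested genes."""
    rej, _, _, _ = multipletests(gene_p, alpha=fdr, method="fdr_bh")
    return pd.Series(rej, index=gene_p.index)


def _intronic(lead_pos: int, gene: pd.Series, exon_blocks: list[tuple[int, int]] | None) -> bool:
    inside = int(gene["start"]) <= lead_pos <= int(gene["end"])
    if not inside:
        return False
    if not exon_blocks:
        return True  # no exon model: whole-body containment counts
    return not any(s <= lead_pos <= e for s, e in exon_blocks)


def map_positional_genes(
    loci: list,
    significant_variants: pd.DataFrame,
    annotations: pd.DataFrame,
    window: int = 10_000,
    exon_blocks: dict[str, list[tuple[int, int]]] | None = None,
) -> pd.DataFrame:
    """Positional gene mapping around GWAS loci.

    For each locus: genes within ``window`` bp of any genome-wide
    significant SNP; when the lead SNP is intergenic (outside every gene
    body) the nearest flanking gene on each side is added.  The nearest
    gene to the lead SNP and the intronic flag for genes containing the
    lead are recorded.
    """
    exon_blocks = exon_blocks or {}
    sig = significant_variants.set_index("variant_id")
    rows = []
    for locus in loci:
        ann = annotations[annotations["chrom"].astype(str) == str(locus.chrom)]
        if ann.empty:
            continue
        lead_pos = int(sig.loc[locus.lead_variant, "pos"])
        member_pos = sig.loc[[m for m in locus.members if m in sig.index], "pos"].astype(int)
        gene_hits: dict[str, dict] = {}

        dist_to_lead = np.minimum(
            np.abs(ann["start"].astype(int) - lead_pos), np.abs(ann["end"].astype(int) - lead_pos)
        ).where(~((ann["start"].astype(int) <= lead_pos) & (ann["end"].astype(int) >= lead_pos)), 0)
        nearest_gene = ann.loc[dist_to_lead.idxmin(), "gene_id"]

        for _, gene in ann.iterrows():
            gstart, gend = int(gene["start"]), int(gene["end"])
            near = ((member_pos >= gstart - window) & (member_pos <= gend + window)).any()
            if near:
                gene_hits[gene["gene_id"]] = {"reason": "within_10kb"}

        intergenic = not ((ann["start"].astype(int) <= lead_pos) & (ann["end"].astype(int) >= lead_pos)).any()
        if intergenic:
            left = ann[ann["end"].astype(int) < lead_pos]
            right = ann[ann["start"].astype(int) > lead_pos]
            if not left.empty:
                flank = left.loc[left["end"].astype(int).idxmax(), "gene_id"]
                gene_hits.setdefault(flank, {"reason": "flanking"})
            if not right.empty:
                flank = right.loc[right["start"].astype(int).idxmin(), "gene_id"]
                gene_hits.setdefault(flank, {"reason": "flanking"})

        for gid, info in gene_hits.items():
            gene = ann.set_index("gene_id").loc[gid]
            rows.append(
                {
                    "locus_id": locus.locus_id,
                    "gene_id": gid,
                    "reason": info["reason"],
                    "nearest_gene": gid == nearest_gene,
                    "intronic_lead": _intronic(lead_pos, gene, exon_blocks.get(gid)),
                }
            )
    return pd.DataFrame(rows, columns=["locus_id", "gene_id", "reason", "nearest_gene", "intronic_lead"])


def build_evidence_matrix(
    genes: list[str],
    positional: pd.DataFrame | None = None,
    missense_ld_genes: set[str] | None = None,
    gene_test_significant: set[str] | None = None,
    high_expression: set[str] | None = None,
    valve_specific: set[str] | None = None,
    valve_eqtl: set[str] | None = None,
    twas: pd.DataFrame | None = None,
    coloc_pp4: dict[str, float] | None = None,
    mr: pd.DataFrame | None = None,
    min_features: int = 4,
    pp4_threshold: float = 0.75,
) -> pd.DataFrame:
    """Assemble the ten-feature evidence ledger.

    Missing upstream tables simply contribute ``False`` for their features.
    ``twas`` needs gene_id/z/significant; ``mr`` needs gene_id/mr_feature
    and the IVW estimate for the direction of association.
    """
    ev = pd.DataFrame(False, index=pd.Index(genes, name="gene_id"), columns=FEATURES)
    direction = pd.Series("", index=ev.index)
    if positional is not None and not positional.empty:
        pos = positional.groupby("gene_id").agg(
            nearest_gene=("nearest_gene", "any"), intronic_lead=("intronic_lead", "any")
        )
        for col in ("nearest_gene", "intronic_lead"):
            hit = pos.index[pos[col]].intersection(ev.index)
            ev.loc[hit, col] = True
    for col, names in [
        ("missense_ld", missense_ld_genes),
        ("gene_test_significant", gene_test_significant),
        ("high_expression", high_expression),
        ("valve_specific", valve_specific),
        ("valve_eqtl", valve_eqtl),
    ]:
        if names:
            ev.loc[ev.index.intersection(list(names)), col] = True
    if twas is not None and not twas.empty:
        t = twas.set_index("gene_id")
        hit = t.index[t["significant"].astype(bool)].intersection(ev.index)
        ev.loc[hit, "twas_significant"] = True
        for g in hit:
            direction[g] = "+" if t.loc[g, "z"] > 0 else "-"
    if coloc_pp4:
        hit = [g for g, pp4 in coloc_pp4.items() if pp4 > pp4_threshold and g in ev.index]
        ev.loc[hit, "coloc_pp4"] = True
    if mr is not None and not mr.empty:
        m = mr.set_index("gene_id")
        hit = m.index[m["mr_feature"].astype(bool)].intersection(ev.index)
        ev.loc[hit, "mr_significant"] = True
        for g in hit:
            direction[g] = "+" if m.loc[g, "ivw_estimate"] > 0 else "-"
    out = ev.copy()
    out["feature_count"] = ev.sum(axis=1).astype(int)
    out["prioritized"] = out["feature_count"] >= min_features
    out["direction"] = direction
    return out.reset_index()


def hypergeometric_enrichment(
    query: set[str] | list[str],
    gene_sets: dict[str, set[str]],
    background: set[str] | list[str],
    min_overlap: int = 5,
    p_threshold: float = 0.001,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of the query in each gene set.

    The background is the sampling universe; query and sets are restricted
    to it.  A term is reported when its overlap is at least ``min_overlap``
    and its p-value below ``p_threshold``.
    """
    bg = set(background)
    q = set(query) & bg
    if set(query) - bg:
        raise ValueError("query contains genes outside the background")
    rows = []
    for term, members in gene_sets.items():
        members = set(members) & bg
        if not members:
            raise ValueError(f"gene set {term!r} is empty within the background")
        if len(members) > len(bg):
            raise ValueError(f"gene set {term!r} larger than the background")
        overlap = len(q & members)
        p = float(stats.hypergeom.sf(overlap - 1, len(bg), len(members), len(q)))
        rows.append(
            {
                "term": term,
                "set_size": len(members),
                "overlap": overlap,
                "p": p,
                "reported": overlap >= min_overlap and p < p_threshold,
            }
        )
    return pd.DataFrame(rows).sort_values("p", kind="mergesort").reset_index(drop=True)
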