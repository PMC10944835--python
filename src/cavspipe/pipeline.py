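"""End-to-end orchestration of the synthetic-to-prioritization run.

Each stage reads its inputs from the output directory, computes, and
writes its artifacts back there, so stages are individually re-runnable
from the command line.  ``run_pipeline`` executes the stages in dependency
order and writes a manifest recording the configuration, seeds and a
digest of every artifact.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from cavspipe import coloc as coloc_mod
from cavspipe import eqtl as eqtl_mod
from cavspipe import expression as expr_mod
from cavspipe import gwas as gwas_mod
from cavspipe import io as io_mod
from cavspipe import mr as mr_mod
from cavspipe import prioritize as prio_mod
from cavspipe import simulate as sim_mod
from cavspipe import twas as twas_mod
from cavspipe.config import PipelineConfig

__all__ = ["run_pipeline", "build_truth", "STAGES"]


def build_truth(cfg: PipelineConfig) -> sim_mod.SimTruth:
    """Assemble the generating truth of the reference mediation scenario."""
    effects = [
        sim_mod.EqtlEffect(cfg.causal_gene, cfg.primary_eqtl_variant, cfg.primary_eqtl_pve)
    ]
    effects += [
        sim_mod.EqtlEffect(cfg.causal_gene, v, cfg.secondary_eqtl_pve)
        for v in cfg.secondary_eqtl_variants
    ]
    causal = {cfg.direct_variant: cfg.direct_log_or} if cfg.direct_variant else {}
    return sim_mod.SimTruth(
        causal_variants=causal,
        eqtl_effects=effects,
        mediation_effects={cfg.causal_gene: cfg.mediation_effect},
        prevalence=cfg.prevalence,
        expression_log_sd=cfg.expression_log_sd,
        count_dispersion=cfg.nb_dispersion,
    )


def _ld_spec(cfg: PipelineConfig) -> sim_mod.LdSpec:
    """Variant layout: all blocks near the gene cluster except the last,
    which sits in a distant region so a direct-effect variant there forms
    its own locus (>500 kb from the mediated one)."""
    positions = 1_000_000 + cfg.variant_spacing * np.arange(cfg.n_variants)
    last_block = cfg.n_variants - cfg.block_size
    if cfg.direct_region_start and last_block > 0:
        positions = positions.copy()
        positions[last_block:] = cfg.direct_region_start + cfg.variant_spacing * np.arange(
            cfg.n_variants - last_block
        )
    return sim_mod.LdSpec(
        n_variants=cfg.n_variants,
        maf_low=cfg.maf_low,
        maf_high=cfg.maf_high,
        rho=cfg.rho,
        block_size=cfg.block_size,
        positions=positions,
    )


def _read_tsv(path: Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> None:
    """Generate genotype panel, cohorts, expression study and tissue panel."""
    truth = build_truth(cfg)
    spec = _ld_spec(cfg)
    panel_n = cfg.n_cohorts * cfg.n_gwas_per_cohort + cfg.n_eqtl_samples
    panel = sim_mod.simulate_genotypes(spec, panel_n, seed=cfg.seed)
    annotations = sim_mod.make_gene_annotations(
        cfg.n_genes, spacing=cfg.gene_spacing, length=cfg.gene_length
    )
    cohorts = sim_mod.simulate_case_control(
        panel,
        truth,
        n_cohorts=cfg.n_cohorts,
        n_samples_per_cohort=cfg.n_gwas_per_cohort,
        seed=cfg.seed + 1,
    )
    rng = np.random.default_rng(cfg.seed + 2)
    rows = rng.integers(0, panel.n_samples, size=cfg.n_eqtl_samples)
    eqtl_panel = sim_mod.SimulatedGenotypes(
        dosages=panel.dosages[rows], variants=panel.variants.copy(), ld=panel.ld
    )
    study = sim_mod.simulate_expression(
        eqtl_panel, truth, n_genes=cfg.n_genes, seed=cfg.seed + 3, annotations=annotations
    )
    tissue = sim_mod.simulate_tissue_panel(
        cfg.n_tissues,
        genes=list(annotations["gene_id"]),
        specificity_pattern={cfg.causal_gene: ("aortic_valve", cfg.valve_share)},
        seed=cfg.seed + 4,
    )

    panel.variants.to_csv(outdir / "panel_variants.tsv", sep="\t", index=False)
    pd.DataFrame(panel.ld, index=panel.variant_ids, columns=panel.variant_ids).to_csv(
        outdir / "panel_ld.tsv", sep="\t"
    )
    for i, coh in enumerate(cohorts):
        df = pd.DataFrame(coh.genotypes.dosages, columns=coh.genotypes.variant_ids)
        df.insert(0, "phenotype", coh.phenotype)
        pd.concat([df, coh.covariates], axis=1).to_csv(
            outdir / f"cohort{i + 1}.tsv", sep="\t", index=False
        )
    edf = pd.DataFrame(
        study.genotypes.dosages,
        index=study.counts.columns,
        columns=study.genotypes.variant_ids,
    )
    edf.index.name = "sample_id"
    edf.to_csv(outdir / "eqtl_dosages.tsv", sep="\t")
    io_mod.write_counts_tsv(study.counts, study.gene_lengths, outdir / "counts.tsv")
    study.covariates.set_axis(study.counts.columns, axis=0).to_csv(
        outdir / "base_covariates.tsv", sep="\t", index_label="sample_id"
    )
    io_mod.write_bed(annotations, outdir / "genes.bed")
    tissue.to_csv(outdir / "tissue_medians.tsv", sep="\t", index_label="tissue")
    io_mod.write_truth(truth, outdir / "truth.json")


def stage_gwas(cfg: PipelineConfig, outdir: Path) -> None:
    """Per-cohort logistic association with QC filtering."""
    variants = _read_tsv(outdir / "panel_variants.tsv", dtype={"chrom": str})
    for i in range(cfg.n_cohorts):
        tab = _read_tsv(outdir / f"cohort{i + 1}.tsv")
        vids = list(variants["variant_id"])
        cov_cols = [c for c in tab.columns if c not in vids + ["phenotype"]]
        panel = sim_mod.SimulatedGenotypes(
            dosages=tab[vids].to_numpy(dtype=float), variants=variants, ld=np.eye(len(vids))
        )
        cohort = sim_mod.SimulatedCohort(
            genotypes=panel,
            phenotype=tab["phenotype"].to_numpy(dtype=int),
            covariates=tab[cov_cols],
            truth=sim_mod.SimTruth(prevalence=cfg.prevalence),
            name=f"cohort{i + 1}",
        )
        assoc = gwas_mod.run_cohort_gwas(cohort)
        kept, excluded = gwas_mod.qc_filter(
            assoc, cfg.info_min, cfg.maf_min_gwas, cfg.mac_cases_min
        )
        io_mod.write_summary_stats(kept, outdir / f"cohort{i + 1}_assoc.tsv")
        excluded.to_csv(outdir / f"cohort{i + 1}_excluded.tsv", sep="\t", index=False)


def stage_meta(cfg: PipelineConfig, outdir: Path) -> None:
    tables = [
        _read_tsv(outdir / f"cohort{i + 1}_assoc.tsv", dtype={"chrom": str}).assign(flag="")
        for i in range(cfg.n_cohorts)
    ]
    meta = gwas_mod.meta_analyze(tables)
    meta.to_csv(outdir / "meta.tsv", sep="\t", index=False)
    lam = gwas_mod.genomic_inflation(meta["p"].to_numpy()) if len(meta) >= 100 else None
    (outdir / "inflation.json").write_text(json.dumps({"lambda": lam}))


def stage_clump(cfg: PipelineConfig, outdir: Path) -> None:
    meta = _read_tsv(outdir / "meta.tsv", dtype={"chrom": str})
    ld = _read_tsv(outdir / "panel_ld.tsv", index_col=0)
    loci = gwas_mod.clump_and_define_loci(
        meta,
        ld,
        p_threshold=cfg.p_threshold,
        r2_independent=cfg.r2_independent,
        r2_lead=cfg.r2_lead,
        merge_kb=cfg.merge_kb,
    )
    rows = [
        {
            "locus_id": L.locus_id,
            "chrom": L.chrom,
            "start": L.start,
            "end": L.end,
            "lead_variant": L.lead_variant,
            "lead_p": L.lead_p,
            "n_independent": len(L.independent_significant),
            "independent_significant": ",".join(L.independent_significant),
            "members": ",".join(L.members),
        }
        for L in loci
    ]
    pd.DataFrame(
        rows,
        columns=[
            "locus_id",
            "chrom",
            "start",
            "end",
            "lead_variant",
            "lead_p",
            "n_independent",
            "independent_significant",
            "members",
        ],
    ).to_csv(outdir / "loci.tsv", sep="\t", index=False)


def _load_loci(outdir: Path) -> list[gwas_mod.Locus]:
    df = _read_tsv(outdir / "loci.tsv", dtype={"chrom": str})
    loci = []
    for _, r in df.iterrows():
        loci.append(
            gwas_mod.Locus(
                locus_id=r["locus_id"],
                chrom=str(r["chrom"]),
                start=int(r["start"]),
                end=int(r["end"]),
                lead_variant=r["lead_variant"],
                lead_p=float(r["lead_p"]),
                independent_significant=str(r["independent_significant"]).split(","),
                members=str(r["members"]).split(","),
            )
        )
    return loci


def stage_finemap(cfg: PipelineConfig, outdir: Path) -> None:
    meta = _read_tsv(outdir / "meta.tsv", dtype={"chrom": str})
    loci = _load_loci(outdir)
    out = []
    for locus in loci:
        rec = meta[meta["variant_id"].isin(locus.members)]
        cs = gwas_mod.fine_map_credible_set(
            rec, prior_sd=cfg.finemap_prior_sd, coverage=cfg.credible_coverage
        )
        cs.insert(0, "locus_id", locus.locus_id)
        out.append(cs)
    cols = ["locus_id", "variant_id", "pos", "p", "log_abf", "posterior", "cumulative", "in_credible_set"]
    if out:
        pd.concat(out, ignore_index=True)[cols].to_csv(
            outdir / "credible_sets.tsv", sep="\t", index=False
        )
    else:
        pd.DataFrame(columns=cols).to_csv(outdir / "credible_sets.tsv", sep="\t", index=False)


def stage_expression(cfg: PipelineConfig, outdir: Path) -> None:
    counts, lengths = io_mod.read_counts_tsv(outdir / "counts.tsv")
    tpm = expr_mod.compute_tpm(counts, lengths)
    tpm.to_csv(outdir / "tpm.tsv", sep="\t", index_label="gene_id")
    keep = expr_mod.filter_expressed(counts, tpm, cfg.min_tpm, cfg.min_reads, cfg.min_frac)
    (outdir / "expressed_genes.txt").write_text("\n".join(keep) + "\n")
    counts_f = counts.loc[keep]
    factors = expr_mod.tmm_normalize(counts_f)
    factors.rename("tmm_factor").to_csv(outdir / "tmm_factors.tsv", sep="\t", index_label="sample_id")
    cpm = expr_mod.log_cpm(counts_f, factors)
    normalized = expr_mod.inverse_normal_matrix(cpm)
    normalized.to_csv(outdir / "normalized_expression.tsv", sep="\t", index_label="gene_id")
    base = _read_tsv(outdir / "base_covariates.tsv", index_col="sample_id")
    k = min(cfg.n_expression_covariates, min(normalized.shape) - 1)
    if k > 0:
        comps = expr_mod.expression_covariates(normalized, k)
        covariates = pd.concat([base, comps], axis=1)
    else:
        covariates = base
    covariates.to_csv(outdir / "eqtl_covariates.tsv", sep="\t", index_label="sample_id")

    # cross-tissue specificity from the tissue-median panel (valve row
    # included); high-expression flag from the observed valve medians on
    # log2(TPM + 1)
    valve_median = np.log2(tpm + 1.0).median(axis=1)
    tissue = _read_tsv(outdir / "tissue_medians.tsv", index_col="tissue")
    scores = expr_mod.specificity_scores(tissue, ess_threshold=cfg.ess_threshold)
    scores["valve_median_log2_tpm"] = valve_median.reindex(scores.index)
    scores["high_expression"] = expr_mod.flag_high_expression(
        valve_median, cfg.high_expression_percentile
    ).reindex(scores.index)
    scores.to_csv(outdir / "ess.tsv", sep="\t")


def stage_eqtl(cfg: PipelineConfig, outdir: Path) -> None:
    dosages = _read_tsv(outdir / "eqtl_dosages.tsv", index_col="sample_id")
    normalized = _read_tsv(outdir / "normalized_expression.tsv", index_col="gene_id")
    covariates = _read_tsv(outdir / "eqtl_covariates.tsv", index_col="sample_id")
    variants = _read_tsv(outdir / "panel_variants.tsv", dtype={"chrom": str})
    annotations = io_mod.read_bed(outdir / "genes.bed")
    perm, nominal = eqtl_mod.permutation_pass(
        dosages,
        normalized,
        covariates,
        variants,
        annotations,
        n_permutations=cfg.n_permutations,
        seed=cfg.seed + 10,
        window=cfg.cis_window,
        maf_min=cfg.eqtl_maf_min,
        info_min=cfg.eqtl_info_min,
    )
    nominal.to_csv(outdir / "eqtl_nominal.tsv", sep="\t", index=False)
    egenes = eqtl_mod.egene_fdr(perm, fdr=cfg.eqtl_fdr)
    egenes.to_csv(outdir / "eqtl_egenes.tsv", sep="\t", index=False)
    sig = eqtl_mod.call_significant_pairs(nominal, egenes)
    sig.to_csv(outdir / "eqtl_significant_pairs.tsv", sep="\t", index=False)


def stage_twas(cfg: PipelineConfig, outdir: Path) -> None:
    dosages = _read_tsv(outdir / "eqtl_dosages.tsv", index_col="sample_id")
    normalized = _read_tsv(outdir / "normalized_expression.tsv", index_col="gene_id")
    variants = _read_tsv(outdir / "panel_variants.tsv", dtype={"chrom": str})
    annotations = io_mod.read_bed(outdir / "genes.bed")
    meta = _read_tsv(outdir / "meta.tsv", dtype={"chrom": str})
    meta_z = pd.Series(
        (meta["beta"] / meta["se"]).to_numpy(), index=meta["variant_id"]
    )
    ann = annotations.set_index("gene_id")
    eligible = variants[(variants["maf"] >= cfg.eqtl_maf_min) & (variants["info"] >= cfg.eqtl_info_min)]

    model_rows, weight_rows, assoc_rows = [], [], []
    for gene in normalized.index:
        if gene not in ann.index:
            continue
        g = ann.loc[gene]
        cis = eqtl_mod.cis_window_variants(
            eligible, int(g["tss"]), g["chrom"], g["strand"], cfg.cis_window
        )
        if len(cis) < 2:
            continue
        model = twas_mod.train_expression_model(
            gene,
            dosages[list(cis["variant_id"])],
            normalized.loc[gene].to_numpy(),
            seed=cfg.seed + 20,
        )
        model_rows.append(
            {
                "gene_id": gene,
                "cv_r": model.cv_r,
                "cv_p": model.cv_p,
                "sigma_g": model.sigma_g,
                "qualified": model.qualified,
            }
        )
        for v, w, s in zip(model.variant_ids, model.weights, model.sigma_l):
            if w != 0.0:
                weight_rows.append({"gene_id": gene, "variant_id": v, "weight": w, "sigma_l": s})
        if model.qualified:
            try:
                assoc_rows.append(twas_mod.spredixcan(model, meta_z))
            except ValueError:
                pass
    pd.DataFrame(model_rows).to_csv(outdir / "twas_models.tsv", sep="\t", index=False)
    pd.DataFrame(weight_rows).to_csv(outdir / "twas_weights.tsv", sep="\t", index=False)
    assoc = twas_mod.twas_fdr(pd.DataFrame(assoc_rows), fdr=cfg.twas_fdr)
    assoc.to_csv(outdir / "twas.tsv", sep="\t", index=False)


def stage_coloc(cfg: PipelineConfig, outdir: Path) -> None:
    """Colocalize GWAS and eQTL signals for the TWAS-significant genes."""
    meta = _read_tsv(outdir / "meta.tsv", dtype={"chrom": str})
    nominal = _read_tsv(outdir / "eqtl_nominal.tsv")
    twas = _read_tsv(outdir / "twas.tsv")
    annotations = io_mod.read_bed(outdir / "genes.bed").set_index("gene_id")
    genes = list(twas[twas.get("significant", pd.Series(dtype=bool)) == True]["gene_id"]) if len(twas) else []
    rows = []
    for gene in genes:
        pairs = nominal[nominal["gene_id"] == gene]
        track_eqtl = coloc_mod.AbfTrack.from_summary(
            pairs.rename(columns={"slope": "beta", "slope_se": "se"}), "quantitative"
        )
        g = annotations.loc[gene]
        window = meta[
            (meta["chrom"].astype(str) == str(g["chrom"]))
            & ((meta["pos"] - int(g["tss"])).abs() <= cfg.cis_window)
        ]
        track_gwas = coloc_mod.AbfTrack.from_summary(window, "binary")
        res = coloc_mod.coloc_abf(
            track_gwas, track_eqtl, gene_id=gene, p1=cfg.coloc_p1, p2=cfg.coloc_p2, p12=cfg.coloc_p12
        )
        rows.append(
            {
                "gene_id": gene,
                "pp0": res.pp0,
                "pp1": res.pp1,
                "pp2": res.pp2,
                "pp3": res.pp3,
                "pp4": res.pp4,
                "colocalized": coloc_mod.colocalization_call(res, cfg.pp4_threshold),
            }
        )
    pd.DataFrame(
        rows, columns=["gene_id", "pp0", "pp1", "pp2", "pp3", "pp4", "colocalized"]
    ).to_csv(outdir / "coloc.tsv", sep="\t", index=False)


def stage_mr(cfg: PipelineConfig, outdir: Path) -> None:
    """Two-sample MR of expression on disease for the TWAS genes."""
    meta = _read_tsv(outdir / "meta.tsv", dtype={"chrom": str})
    nominal = _read_tsv(outdir / "eqtl_nominal.tsv")
    ld = _read_tsv(outdir / "panel_ld.tsv", index_col=0)
    twas = _read_tsv(outdir / "twas.tsv")
    genes = list(twas[twas.get("significant", pd.Series(dtype=bool)) == True]["gene_id"]) if len(twas) else []
    results = []
    for gene in genes:
        exposure = nominal[nominal["gene_id"] == gene]
        instruments = mr_mod.select_instruments(
            exposure,
            meta,
            ld,
            p_max=cfg.mr_p_exposure,
            r2_max=cfg.mr_clump_r2,
            min_instruments=cfg.mr_min_instruments,
            f_min=cfg.mr_f_min,
        )
        if instruments is None:
            continue
        results.append(
            mr_mod.mr_estimates(instruments, gene_id=gene, seed=cfg.seed + 30)
        )
    if results:
        screened = mr_mod.gene_screen(results, fdr=cfg.mr_fdr, q_alpha=cfg.mr_q_alpha)
    else:
        screened = pd.DataFrame(
            columns=["gene_id", "n_instruments", "ivw_estimate", "ivw_se", "ivw_p",
                     "egger_intercept_p", "wm_estimate", "wm_p", "q_stat", "q_p",
                     "heterogeneous", "candidate", "mr_feature"]
        )
    screened.to_csv(outdir / "mr.tsv", sep="\t", index=False)


def stage_prioritize(cfg: PipelineConfig, outdir: Path) -> None:
    meta = _read_tsv(outdir / "meta.tsv", dtype={"chrom": str})
    ld = _read_tsv(outdir / "panel_ld.tsv", index_col=0)
    annotations = io_mod.read_bed(outdir / "genes.bed")
    loci = _load_loci(outdir)
    ess = _read_tsv(outdir / "ess.tsv", index_col="gene_id")
    twas = _read_tsv(outdir / "twas.tsv")
    coloc = _read_tsv(outdir / "coloc.tsv")
    mr = _read_tsv(outdir / "mr.tsv")
    sig_pairs = _read_tsv(outdir / "eqtl_significant_pairs.tsv")

    # gene-level LD-aware association test
    meta_idx = meta.set_index("variant_id")
    rows = []
    for _, g in annotations.iterrows():
        window = meta[
            (meta["chrom"].astype(str) == str(g["chrom"]))
            & (meta["pos"] >= int(g["start"]) - cfg.gene_window)
            & (meta["pos"] <= int(g["end"]) + cfg.gene_window)
        ]
        if window.empty:
            continue
        vids = list(window["variant_id"])
        z = (window["beta"] / window["se"]).to_numpy()
        sub = ld.loc[vids, vids].to_numpy()
        corr = np.sign(sub) * np.sqrt(np.abs(sub))  # r from r^2 (dosage r >= 0 here)
        res = prio_mod.gene_level_test(z, corr)
        rows.append({"gene_id": g["gene_id"], "stat": res["stat"], "p": res["p"], "n_snps": res["n_snps"]})
    gene_tests = pd.DataFrame(rows)
    if len(gene_tests):
        gene_tests["significant"] = prio_mod.gene_test_fdr(
            gene_tests.set_index("gene_id")["p"], cfg.gene_test_fdr
        ).to_numpy()
    gene_tests.to_csv(outdir / "gene_tests.tsv", sep="\t", index=False)

    sig_variants = meta[meta["p"] < cfg.p_threshold]
    positional = prio_mod.map_positional_genes(loci, sig_variants, annotations, cfg.gene_window)
    positional.to_csv(outdir / "positional_genes.tsv", sep="\t", index=False)

    # missense proxies: lead SNP in LD (r2 >= threshold) with an annotated missense variant
    missense_genes = set()
    for locus in loci:
        for mv, gene in cfg.missense_variants.items():
            if mv in ld.index and locus.lead_variant in ld.index:
                if float(ld.loc[locus.lead_variant, mv]) >= cfg.missense_r2:
                    missense_genes.add(gene)

    # valve eQTL feature: a lead GWAS SNP is a significant eQTL for the gene
    lead_ids = {L.lead_variant for L in loci}
    valve_eqtl_genes = set(
        sig_pairs[sig_pairs["variant_id"].isin(lead_ids)]["gene_id"]
    ) if len(sig_pairs) else set()

    genes = list(annotations["gene_id"])
    evidence = prio_mod.build_evidence_matrix(
        genes,
        positional=positional,
        missense_ld_genes=missense_genes,
        gene_test_significant=set(gene_tests[gene_tests.get("significant", False) == True]["gene_id"])
        if len(gene_tests)
        else set(),
        high_expression=set(ess.index[ess["high_expression"].fillna(False)]),
        valve_specific=set(ess.index[ess["valve_specific"].fillna(False)]),
        valve_eqtl=valve_eqtl_genes,
        twas=twas if len(twas) else None,
        coloc_pp4=dict(zip(coloc["gene_id"], coloc["pp4"])) if len(coloc) else None,
        mr=mr if len(mr) else None,
        min_features=cfg.min_features,
        pp4_threshold=cfg.pp4_threshold,
    )
    evidence.to_csv(outdir / "evidence.tsv", sep="\t", index=False)


STAGES = {
    "simulate": stage_simulate,
    "gwas": stage_gwas,
    "meta": stage_meta,
    "clump": stage_clump,
    "finemap": stage_finemap,
    "expression": stage_expression,
    "eqtl": stage_eqtl,
    "twas": stage_twas,
    "coloc": stage_coloc,
    "mr": stage_mr,
    "prioritize": stage_prioritize,
}


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    cfg: PipelineConfig, outdir: str | Path, stages: list[str] | None = None
) -> dict:
    """Run the pipeline stages in dependency order and write a manifest.

    A stage failure raises with the failing stage named; artifacts written
    by earlier stages are preserved.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    todo = list(STAGES) if stages is None else stages
    unknown = set(todo) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    for name in todo:
        try:
            STAGES[name](cfg, outdir)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    from dataclasses import asdict

    manifest = {
        "config": {**asdict(cfg), "secondary_eqtl_variants": list(cfg.secondary_eqtl_variants)},
        "stages": todo,
        "artifacts": {
            p.name: _digest(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
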