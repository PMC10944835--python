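"""Plain-text readers and writers for the pipeline's external formats.

Summary statistics, dosages, counts and covariates travel as TSV with a
single header line and ``NA`` for missing values; genotypes can also be
written as VCF with GT:DS; gene annotations as BED (0-based half-open,
name = gene id, score = 0, strand in column 6); simulation truth as JSON.
All genomic coordinates inside the pipeline are 1-based inclusive.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cavspipe.simulate import EqtlEffect, SimTruth, SimulatedGenotypes

__all__ = [
    "read_summary_stats",
    "write_summary_stats",
    "write_dosages_tsv",
    "read_dosages_tsv",
    "write_vcf",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_bed",
    "read_bed",
    "write_truth",
    "read_truth",
    "read_gmt",
]

SUMMARY_COLUMNS = [
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
]


def write_summary_stats(records: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in SUMMARY_COLUMNS if c in records.columns]
    cols += [c for c in records.columns if c not in cols]
    records[cols].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read a summary-stats TSV; columns are matched by name, so order is
    free.  Missing values are ``NA``."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"chrom": str})
    missing = {"variant_id", "chrom", "pos", "beta", "se", "p"} - set(df.columns)
    if missing:
        raise ValueError(f"summary stats missing required columns: {sorted(missing)}")
    return df


def write_dosages_tsv(genotypes: SimulatedGenotypes, path: str | Path) -> None:
    """Sample x variant dosage table with sample ids in the first column."""
    df = pd.DataFrame(
        genotypes.dosages,
        index=[f"S{i + 1}" for i in range(genotypes.n_samples)],
        columns=genotypes.variant_ids,
    )
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_dosages_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_vcf(genotypes: SimulatedGenotypes, path: str | Path) -> None:
    """Minimal VCF 4.2 with GT (hard call from rounded dosage) and DS."""
    samples = [f"S{i + 1}" for i in range(genotypes.n_samples)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, (_, var) in enumerate(genotypes.variants.iterrows()):
            ds = genotypes.dosages[:, j]
            calls = [f"{gt_codes[int(round(min(max(d, 0), 2)))]}:{d:g}" for d in ds]
            fh.write(
                f"{var['chrom']}\t{var['pos']}\t{var['variant_id']}\t"
                f"{var['other_allele']}\t{var['effect_allele']}\t.\tPASS\t.\tGT:DS\t"
                + "\t".join(calls)
                + "\n"
            )


def write_counts_tsv(counts: pd.DataFrame, lengths: pd.Series, path: str | Path) -> None:
    """Gene counts TSV with a ``length`` column before the sample columns."""
    out = counts.copy()
    out.insert(0, "length", lengths.reindex(counts.index))
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    lengths = df.pop("length")
    return df, lengths


def write_bed(annotations: pd.DataFrame, path: str | Path) -> None:
    """BED6: 0-based half-open intervals, name = gene id.

    The TSS convention (start for + strand, end for − strand) is recovered
    on read from the strand column.
    """
    with open(path, "w") as fh:
        for _, g in annotations.iterrows():
            fh.write(
                f"{g['chrom']}\t{int(g['start']) - 1}\t{int(g['end'])}\t"
                f"{g['gene_id']}\t0\t{g['strand']}\n"
            )


def read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "bed_start", "bed_end", "gene_id", "score", "strand"],
        dtype={"chrom": str},
    )
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "chrom": df["chrom"],
            "start": df["bed_start"] + 1,
            "end": df["bed_end"],
            "strand": df["strand"],
        }
    )
    out["tss"] = np.where(out["strand"] == "+", out["start"], out["end"])
    return out


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Gene sets from a GMT file: name, description, then member genes."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[fields[0]] = set(fields[2:])
    return sets


def write_truth(truth: SimTruth, path: str | Path) -> None:
    payload = {
        "causal_variants": truth.causal_variants,
        "eqtl_effects": [e.__dict__ for e in truth.eqtl_effects],
        "mediation_effects": truth.mediation_effects,
        "prevalence": truth.prevalence,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_truth(path: str | Path) -> SimTruth:
    payload = json.loads(Path(path).read_text())
    return SimTruth(
        causal_variants=payload["causal_variants"],
        eqtl_effects=[EqtlEffect(**e) for e in payload["eqtl_effects"]],
        mediation_effects=payload["mediation_effects"],
        prevalence=payload["prevalence"],
    )
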