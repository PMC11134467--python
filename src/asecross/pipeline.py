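"""End-to-end drivers chaining discovery, counting and testing."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .annotation import read_genes
from .counting import (
    GeneAlleleTable,
    SampleInfo,
    aggregate_gene_counts,
    annotate_genes,
    extract_diagnostic_counts,
    filter_informative_genes,
    read_basecounts,
    read_sample_sheet,
)
from .simulate import SimData
from .stats import ClassifyThresholds, run_ase_tests
from .variants import DiagnosticVariant, FilterThresholds, discover


def run_from_simulation(
    data: SimData,
    thresholds: ClassifyThresholds = ClassifyThresholds(),
    min_depth: int = 10,
    min_reps: int = 2,
) -> tuple[GeneAlleleTable, pd.DataFrame]:
    """Count and test an in-memory simulated dataset (planted SNPs known)."""
    samples = [
        SampleInfo(r.sample_id, r.cross) for r in data.sample_sheet.itertuples()
    ]
    snps = [
        DiagnosticVariant(r.chrom, int(r.pos), r.ref, r.alt, r.diagnostic_ecotype)
        for r in data.snps.itertuples()
    ]
    basecounts = pd.concat(
        [df.assign(sample_id=sid) for sid, df in data.counts.items()],
        ignore_index=True,
    )
    snp_counts = annotate_genes(extract_diagnostic_counts(basecounts, snps), data.genes)
    table = filter_informative_genes(
        aggregate_gene_counts(snp_counts, samples), min_depth=min_depth, min_reps=min_reps
    )
    return table, run_ase_tests(table, thresholds)


def run_from_directory(
    directory: str | Path,
    vcf_thresholds: FilterThresholds = FilterThresholds(),
    thresholds: ClassifyThresholds = ClassifyThresholds(),
    min_depth: int = 10,
    min_reps: int = 2,
) -> tuple[GeneAlleleTable, pd.DataFrame]:
    """Full pipeline over a dataset directory laid out like simulator output:
    head.vcf, body.vcf, genes.gff3, sample_sheet.tsv, counts/<sample>.tsv."""
    d = Path(directory)
    snps = discover(d / "head.vcf", d / "body.vcf", vcf_thresholds)
    samples = read_sample_sheet(d / "sample_sheet.tsv")
    basecounts = pd.concat(
        [
            read_basecounts(d / "counts" / f"{s.sample_id}.tsv", s.sample_id)
            for s in samples
        ],
        ignore_index=True,
    )
    genes = read_genes(d / "genes.gff3")
    snp_counts = annotate_genes(extract_diagnostic_counts(basecounts, snps), genes)
    table = filter_informative_genes(
        aggregate_gene_counts(snp_counts, samples), min_depth=min_depth, min_reps=min_reps
    )
    return table, run_ase_tests(table, thresholds)


def recovery_metrics(results: pd.DataFrame, truth: pd.DataFrame) -> dict:
    """Sensitivity per planted class and empirical FDR of the bias calls."""
    merged = results.set_index("gene_id").join(
        truth.set_index("gene_id")["bias_class"]
    )
    calls = {
        "maternal": merged["category"].isin(["maternal_biased", "maternal_limited"]),
        "cis_head": merged["category"].isin(["head_biased", "head_limited"]),
        "cis_body": merged["category"].isin(["body_biased", "body_limited"]),
    }
    out = {}
    for klass, called in calls.items():
        mask = merged["bias_class"] == klass
        out[f"sensitivity_{klass}"] = float(called[mask].mean()) if mask.any() else float("nan")
    any_call = merged["category"] != "biparental"
    n_calls = int(any_call.sum())
    false = int(((merged["bias_class"] == "unbiased") & any_call).sum())
    out["n_calls"] = n_calls
    out["fdr"] = false / n_calls if n_calls else 0.0
    return out
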