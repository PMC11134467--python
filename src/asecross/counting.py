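"""From per-position base counts to gene x sample allele-count tables.

At every diagnostic SNP each sample's pileup gives counts of the four
nucleotides. The ecotype whose unique alternative allele defines the SNP
claims the alt-base reads; ref-base reads belong to the other ecotype; the
remaining two bases are sequencing error (``other``). Head/body counts are
re-oriented to maternal/paternal using the sample's cross direction (HB =
head mother, BH = body mother), summed over each gene's SNPs, and genes
without enough informative coverage in both cross directions are dropped:
a gene is kept only if at least one of its SNPs has >= ``min_depth``
allele-assignable reads in >= ``min_reps`` replicates of *each* direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .variants import DiagnosticVariant

CROSSES = ("HB", "BH")


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    cross: str  # first letter = maternal ecotype

    def __post_init__(self):
        if self.cross not in CROSSES:
            raise ValueError(f"cross must be one of {CROSSES}, got {self.cross!r}")

    @property
    def maternal_ecotype(self) -> str:
        return "head" if self.cross == "HB" else "body"


@dataclass
class GeneAlleleTable:
    """Gene-level allele counts plus the SNP-level detail behind them.

    ``gene_counts``: one row per (gene_id, sample_id) with head/body and
    maternal/paternal counts. ``snp_counts``: the per-SNP rows they were
    summed from, retained because the informativeness filter is defined at
    SNP resolution.
    """

    gene_counts: pd.DataFrame
    snp_counts: pd.DataFrame
    samples: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return sorted(self.gene_counts["gene_id"].unique())


def read_sample_sheet(path: str | Path) -> list[SampleInfo]:
    df = pd.read_csv(path, sep="\t")
    return [SampleInfo(str(r.sample_id), str(r.cross)) for r in df.itertuples()]


def read_basecounts(path: str | Path, sample_id: str) -> pd.DataFrame:
    """Read one per-base pileup TSV (chrom, pos, ref, depth, A, C, G, T)."""
    df = pd.read_csv(path, sep="\t")
    df["sample_id"] = sample_id
    return df


def extract_diagnostic_counts(
    basecounts: pd.DataFrame, snps: list[DiagnosticVariant]
) -> pd.DataFrame:
    """Per-SNP head/body/other counts for every sample in ``basecounts``.

    SNPs with no pileup row in a sample get all-zero counts, so every
    (SNP, sample) pair is represented.
    """
    snp_df = pd.DataFrame(
        {
            "chrom": [s.chrom for s in snps],
            "pos": [s.pos for s in snps],
            "ref": [s.ref_base for s in snps],
            "alt": [s.alt_base for s in snps],
            "diagnostic_ecotype": [s.diagnostic_ecotype for s in snps],
        }
    )
    sample_ids = sorted(basecounts["sample_id"].unique())
    full = snp_df.merge(pd.Series(sample_ids, name="sample_id"), how="cross")
    merged = full.merge(
        basecounts[["sample_id", "chrom", "pos", "A", "C", "G", "T"]],
        on=["sample_id", "chrom", "pos"],
        how="left",
    )
    mat = merged[["A", "C", "G", "T"]].fillna(0).to_numpy(dtype=np.int64)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    rows = np.arange(len(merged))
    ref_c = mat[rows, [base_idx[b] for b in merged["ref"]]]
    alt_c = mat[rows, [base_idx[b] for b in merged["alt"]]]
    is_head = (merged["diagnostic_ecotype"] == "head").to_numpy()
    head = np.where(is_head, alt_c, ref_c)
    body = np.where(is_head, ref_c, alt_c)
    out = merged[["sample_id", "chrom", "pos", "ref", "alt", "diagnostic_ecotype"]].copy()
    out["head"] = head
    out["body"] = body
    out["other"] = mat.sum(axis=1) - head - body
    return out


def annotate_genes(snp_counts: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Attach gene_id where a SNP lies within a gene span (1-based inclusive).

    A SNP inside overlapping genes yields one row per gene; SNPs outside all
    genes keep gene_id = NA (and are dropped by aggregation downstream).
    """
    trees: dict[str, IntervalTree] = {}
    for r in genes.itertuples():
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end + 1, r.gene_id)
    sites = snp_counts[["chrom", "pos"]].drop_duplicates()
    assign_rows = []
    for r in sites.itertuples():
        hits = trees.get(r.chrom, IntervalTree())[r.pos]
        if hits:
            for h in sorted(hits, key=lambda iv: iv.data):
                assign_rows.append((r.chrom, r.pos, h.data))
        else:
            assign_rows.append((r.chrom, r.pos, pd.NA))
    assign = pd.DataFrame(assign_rows, columns=["chrom", "pos", "gene_id"])
    return snp_counts.merge(assign, on=["chrom", "pos"], how="left")


def aggregate_gene_counts(
    snp_counts: pd.DataFrame, samples: list[SampleInfo]
) -> GeneAlleleTable:
    """Sum head/body counts over each gene's SNPs and orient by parent.

    Every (gene, sample) pair appears in the output, zero-filled where the
    sample had no reads, so per-direction replicate logic is well defined.
    """
    known = {s.sample_id: s.cross for s in samples}
    unknown = set(snp_counts["sample_id"].unique()) - set(known)
    if unknown:
        raise KeyError(f"samples not in sample sheet: {sorted(unknown)}")
    annotated = snp_counts.dropna(subset=["gene_id"])
    agg = (
        annotated.groupby(["gene_id", "sample_id"], sort=True)
        .agg(head=("head", "sum"), body=("body", "sum"), n_informative_snps=("pos", "nunique"))
        .reset_index()
    )
    idx = pd.MultiIndex.from_product(
        [sorted(annotated["gene_id"].unique()), [s.sample_id for s in samples]],
        names=["gene_id", "sample_id"],
    )
    agg = (
        agg.set_index(["gene_id", "sample_id"])
        .reindex(idx, fill_value=0)
        .reset_index()
    )
    agg["cross"] = agg["sample_id"].map(known)
    hb = agg["cross"] == "HB"
    agg["maternal"] = np.where(hb, agg["head"], agg["body"])
    agg["paternal"] = np.where(hb, agg["body"], agg["head"])
    sample_df = pd.DataFrame(
        {"sample_id": [s.sample_id for s in samples], "cross": [s.cross for s in samples]}
    )
    return GeneAlleleTable(gene_counts=agg, snp_counts=annotated, samples=sample_df)


def filter_informative_genes(
    table: GeneAlleleTable, min_depth: int = 10, min_reps: int = 2
) -> GeneAlleleTable:
    """Keep genes with a SNP covered by >= min_depth allele-assignable reads
    in >= min_reps replicates of each cross direction.

    Depth counts only head+body reads; error-base reads carry no allelic
    information.
    """
    snp = table.snp_counts.merge(table.samples, on="sample_id")
    snp = snp.assign(ok=(snp["head"] + snp["body"]) >= min_depth)
    per_dir = (
        snp.groupby(["gene_id", "chrom", "pos", "cross"], sort=False)["ok"]
        .sum()
        .unstack("cross", fill_value=0)
    )
    for c in CROSSES:
        if c not in per_dir.columns:
            per_dir[c] = 0
    snp_ok = (per_dir["HB"] >= min_reps) & (per_dir["BH"] >= min_reps)
    kept_genes = set(snp_ok[snp_ok].index.get_level_values("gene_id"))
    return GeneAlleleTable(
        gene_counts=table.gene_counts[
            table.gene_counts["gene_id"].isin(kept_genes)
        ].reset_index(drop=True),
        snp_counts=table.snp_counts[
            table.snp_counts["gene_id"].isin(kept_genes)
        ].reset_index(drop=True),
        samples=table.samples,
    )


def build_gene_table(
    counts_by_sample: dict[str, pd.DataFrame],
    snps: list[DiagnosticVariant],
    genes: pd.DataFrame,
    samples: list[SampleInfo],
    min_depth: int = 10,
    min_reps: int = 2,
) -> GeneAlleleTable:
    """Full counting stage: extract, annotate, aggregate, filter."""
    basecounts = pd.concat(
        [df.assign(sample_id=sid) for sid, df in counts_by_sample.items()],
        ignore_index=True,
    )
    snp_counts = extract_diagnostic_counts(basecounts, snps)
    annotated = annotate_genes(snp_counts, genes)
    table = aggregate_gene_counts(annotated, samples)
    return filter_informative_genes(table, min_depth=min_depth, min_reps=min_reps)
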