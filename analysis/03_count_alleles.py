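"""Build the filtered gene x sample allele-count table.

Joins each sample's per-base pileup to the diagnostic SNPs, annotates SNPs
with the gene they fall in, orients head/body counts to maternal/paternal by
cross direction, and keeps only genes with a SNP covered by >=10
allele-assignable reads in >=2 replicates of each cross direction.
"""

from pathlib import Path

import pandas as pd

from asecross.annotation import read_genes
from asecross.counting import build_gene_table, read_basecounts, read_sample_sheet
from asecross.variants import snps_from_frame

ROOT = Path(__file__).resolve().parents[1]
DATASET = ROOT / "scratch" / "dataset"


def main() -> None:
    samples = read_sample_sheet(DATASET / "sample_sheet.tsv")
    counts = {
        s.sample_id: read_basecounts(DATASET / "counts" / f"{s.sample_id}.tsv", s.sample_id)
        for s in samples
    }
    snps = snps_from_frame(pd.read_csv(DATASET / "diagnostic_snps.tsv", sep="\t"))
    table = build_gene_table(counts, snps, read_genes(DATASET / "genes.gff3"), samples)
    table.gene_counts.to_csv(DATASET / "gene_counts.tsv", sep="\t", index=False)
    n_genes = len(table.gene_ids)
    per_dir = (
        table.gene_counts.groupby("cross")[["maternal", "paternal"]].sum()
    )
    per_dir["prop_maternal"] = per_dir["maternal"] / (per_dir["maternal"] + per_dir["paternal"])
    per_dir.reset_index().to_csv(
        ROOT / "results" / "03_counting_summary.tsv", sep="\t", index=False
    )
    print(f"{n_genes} genes pass the informativeness filter -> {DATASET/'gene_counts.tsv'}")
    print(per_dir.to_string())


if __name__ == "__main__":
    main()
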