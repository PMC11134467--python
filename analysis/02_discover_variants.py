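"""Derive ecotype-diagnostic SNPs and the N-masked genome.

Reads the two parental VCFs from scratch/dataset, filters sites on depth and
quality (>=10 reads, QUAL >= 20), keeps homozygous-alternative SNPs unique
to one ecotype, and masks those positions to N in the reference so
downstream alignment carries no reference-allele advantage.
"""

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from asecross.variants import discover, mask_genome, read_fasta, snps_to_frame

ROOT = Path(__file__).resolve().parents[1]
DATASET = ROOT / "scratch" / "dataset"


def main() -> None:
    snps = discover(DATASET / "head.vcf", DATASET / "body.vcf")
    df = snps_to_frame(snps)
    df.to_csv(DATASET / "diagnostic_snps.tsv", sep="\t", index=False)
    masked = mask_genome(read_fasta(DATASET / "genome.fa"), snps)
    SeqIO.write(
        [SeqRecord(Seq(s), id=c, description="") for c, s in masked.items()],
        str(DATASET / "genome_masked.fa"),
        "fasta",
    )
    summary = df["ecotype"].value_counts().rename_axis("ecotype").reset_index(name="n_snps")
    summary.to_csv(ROOT / "results" / "02_diagnostic_snps_summary.tsv", sep="\t", index=False)
    n_masked = sum(s.count("N") for s in masked.values())
    print(f"{len(df)} diagnostic SNPs; {n_masked} positions masked to N")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
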