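"""Generate the synthetic reciprocal-cross dataset the analysis runs on.

Emulates the study's shape: ~500 testable genes, five HB and four BH F1
males, a small maternally biased fraction and a small cis-biased fraction in
each direction. The full dataset (genome, VCFs, GFF, per-sample pileups)
lands in scratch/dataset; a truth summary goes to results/.
"""

from pathlib import Path

from asecross import SimConfig, simulate_dataset

ROOT = Path(__file__).resolve().parents[1]

CONFIG = SimConfig(
    n_genes=500,
    frac_maternal=0.04,      # ~20 maternally biased genes
    frac_cis_head=0.06,      # ~30 head-allele biased
    frac_cis_body=0.05,      # ~25 body-allele biased
    effect_prop=0.9,
    depth_mean=30,
    overdispersion_rho=0.05,
    error_rate=0.001,
    seed=2024,
)


def main() -> None:
    outdir = ROOT / "scratch" / "dataset"
    data = simulate_dataset(CONFIG, outdir)
    truth = data.truth_frame()
    summary = truth["bias_class"].value_counts().rename_axis("bias_class").reset_index(name="n_genes")
    (ROOT / "results").mkdir(exist_ok=True)
    summary.to_csv(ROOT / "results" / "01_truth_summary.tsv", sep="\t", index=False)
    print(f"wrote dataset ({CONFIG.n_genes} genes, {len(data.snps)} diagnostic SNPs) to {outdir}")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
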