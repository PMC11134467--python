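"""Synthetic reciprocal-cross allele-specific expression data.

Builds a toy genome with ecotype-diagnostic SNPs planted inside gene models,
and draws per-sample per-SNP base counts for F1 hybrid males from a
beta-binomial allele model with a known per-gene truth class:

* ``unbiased``   — maternal-allele proportion mu = 0.5 in every sample;
* ``maternal``   — mu = ``effect_prop`` regardless of cross direction
  (a parent-of-origin, imprinting-like signal);
* ``cis_head`` / ``cis_body`` — the head (resp. body) allele is favoured, so
  mu = ``effect_prop`` when that ecotype is the mother and
  ``1 - effect_prop`` otherwise (a cis-regulatory, ecotype signal).

The emitted files mirror what the real pipeline consumes: two parental VCFs
whose unique homozygous-alternative SNPs are exactly the planted diagnostic
sites, the toy genome FASTA, a GFF3 with gene/mRNA/exon features, one
per-base count TSV per sample, a sample sheet giving each sample's cross
direction, and a ground-truth table for parameter-recovery tests.

Each sample draws from its own RNG stream derived from the master seed, so
adding samples never perturbs existing ones, and a fixed seed reproduces
every file byte for byte.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

BIAS_CLASSES = ("unbiased", "maternal", "cis_head", "cis_body")


class SimConfigError(ValueError):
    """Raised for inconsistent simulation parameters."""


@dataclass
class SimConfig:
    """Parameters of the synthetic reciprocal-cross experiment.

    Defaults reproduce the study's replicate structure: five F1 males from
    the head-mother (HB) cross and four from the body-mother (BH) cross.
    """

    n_genes: int = 100
    snps_per_gene: float = 3.0       # mean of the per-gene SNP count (>=1 enforced)
    reps_hb: int = 5
    reps_bh: int = 4
    depth_mean: float = 30.0         # expected reads per SNP per sample
    frac_maternal: float = 0.0
    frac_cis_head: float = 0.0
    frac_cis_body: float = 0.0
    effect_prop: float = 0.9         # biased-allele proportion, in (0.5, 1]
    overdispersion_rho: float = 0.05  # beta-binomial intraclass correlation
    error_rate: float = 0.001        # per-read miscall probability
    seed: int = 0
    n_intergenic_snps: int = 2       # diagnostic SNPs planted outside genes
    chrom: str = "toy1"

    def validate(self) -> None:
        if self.n_genes < 1:
            raise SimConfigError("n_genes must be positive")
        if self.snps_per_gene <= 0:
            raise SimConfigError("snps_per_gene must be positive")
        if self.depth_mean <= 0:
            raise SimConfigError("depth_mean must be positive")
        total = self.frac_maternal + self.frac_cis_head + self.frac_cis_body
        if min(self.frac_maternal, self.frac_cis_head, self.frac_cis_body) < 0 or total > 1 + 1e-12:
            raise SimConfigError("bias-class fractions must be non-negative and sum to <= 1")
        if not 0.5 < self.effect_prop <= 1:
            raise SimConfigError("effect_prop must lie in (0.5, 1]")
        if not 0 <= self.overdispersion_rho < 1:
            raise SimConfigError("overdispersion_rho must lie in [0, 1)")
        if not 0 <= self.error_rate <= 0.1:
            raise SimConfigError("error_rate must lie in [0, 0.1]")


@dataclass
class SimTruth:
    """Ground-truth bias class of one simulated gene."""

    gene_id: str
    bias_class: str
    effect_prop: float


@dataclass
class SimData:
    """Everything one simulation run produced, in memory.

    ``counts`` holds the observed per-base pileup tables the downstream
    pipeline reads; ``true_counts`` holds the error-free per-SNP head/body
    allele counts, kept for round-trip and recovery oracles.
    """

    config: SimConfig
    truth: list[SimTruth]
    genome: dict[str, str]
    snps: pd.DataFrame          # chrom,pos,ref,alt,diagnostic_ecotype,gene_id
    genes: pd.DataFrame         # gene_id,chrom,start,end,strand
    sample_sheet: pd.DataFrame  # sample_id,cross
    counts: dict[str, pd.DataFrame]       # sample_id -> chrom,pos,ref,depth,A,C,G,T
    true_counts: pd.DataFrame   # sample_id,gene_id,chrom,pos,head,body

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [t.gene_id for t in self.truth],
                "bias_class": [t.bias_class for t in self.truth],
                "effect_prop": [t.effect_prop for t in self.truth],
            }
        )

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        _write_vcfs(self, outdir)
        _write_gff(self.genes, self.genome, outdir / "genes.gff3")
        self.sample_sheet.to_csv(outdir / "sample_sheet.tsv", sep="\t", index=False)
        cdir = outdir / "counts"
        cdir.mkdir(exist_ok=True)
        for sid, df in self.counts.items():
            df.to_csv(cdir / f"{sid}.tsv", sep="\t", index=False)
        self.truth_frame().to_csv(outdir / "truth.tsv", sep="\t", index=False)


def generate_truth(config: SimConfig) -> list[SimTruth]:
    """Assign each gene a bias class, honouring the configured fractions.

    Class counts are ``round(fraction * n_genes)``; which genes get which
    class is a seed-determined permutation.
    """
    config.validate()
    n = config.n_genes
    n_mat = round(config.frac_maternal * n)
    n_ch = round(config.frac_cis_head * n)
    n_cb = round(config.frac_cis_body * n)
    if n_mat + n_ch + n_cb > n:
        raise SimConfigError("rounded class counts exceed n_genes")
    labels = np.array(
        ["maternal"] * n_mat
        + ["cis_head"] * n_ch
        + ["cis_body"] * n_cb
        + ["unbiased"] * (n - n_mat - n_ch - n_cb)
    )
    rng = np.random.default_rng([config.seed, 0])
    labels = labels[rng.permutation(n)]
    width = max(4, len(str(n)))
    return [
        SimTruth(
            gene_id=f"g{i + 1:0{width}d}",
            bias_class=str(lab),
            effect_prop=config.effect_prop if lab != "unbiased" else 0.5,
        )
        for i, lab in enumerate(labels)
    ]


def _layout(truth: list[SimTruth], config: SimConfig, rng: np.random.Generator):
    """Place genes and diagnostic SNPs on a single toy contig.

    Diagnostic SNPs alternate head-unique / body-unique along each gene,
    mirroring the two one-sided parental SNP sets of a real cross.
    """
    snp_spacing, flank, gap = 40, 20, 60
    gene_rows, snp_rows = [], []
    pos = 1
    for i, t in enumerate(truth):
        n_snps = max(1, int(rng.poisson(config.snps_per_gene)))
        start = pos + gap
        end = start + flank + n_snps * snp_spacing
        strand = "+" if i % 2 == 0 else "-"
        gene_rows.append((t.gene_id, config.chrom, start, end, strand))
        for j in range(n_snps):
            snp_rows.append(
                (config.chrom, start + flank + j * snp_spacing,
                 "head" if j % 2 == 0 else "body", t.gene_id)
            )
        pos = end
    # intergenic diagnostic SNPs, planted downstream of the last gene
    for j in range(config.n_intergenic_snps):
        snp_rows.append((config.chrom, pos + gap + j * snp_spacing,
                         "head" if j % 2 == 0 else "body", None))
    genome_len = pos + gap + (config.n_intergenic_snps + 1) * snp_spacing
    genome = "".join(np.array(list(BASES))[rng.integers(0, 4, genome_len)])
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    snps = pd.DataFrame(snp_rows, columns=["chrom", "pos", "diagnostic_ecotype", "gene_id"])
    snps["ref"] = [genome[p - 1] for p in snps["pos"]]
    # alt differs from ref: pick uniformly among the other three bases
    alt_off = rng.integers(1, 4, len(snps))
    snps["alt"] = [BASES[(BASE_INDEX[r] + o) % 4] for r, o in zip(snps["ref"], alt_off)]
    snps = snps[["chrom", "pos", "ref", "alt", "diagnostic_ecotype", "gene_id"]]
    return {config.chrom: genome}, genes, snps


def _beta_binomial(rng: np.random.Generator, n: np.ndarray, mu: np.ndarray,
                   rho: float) -> np.ndarray:
    """Draw maternal counts ~ BetaBinomial(n, mu, rho); binomial when rho=0.

    Parameterisation: alpha = mu(1-rho)/rho, beta = (1-mu)(1-rho)/rho, so the
    count variance is n*mu*(1-mu)*(1 + (n-1)*rho). Degenerate mu in {0,1}
    gives deterministic counts.
    """
    m = np.zeros(len(n), dtype=np.int64)
    fixed = (mu <= 0) | (mu >= 1)
    m[fixed] = (n[fixed] * mu[fixed]).astype(np.int64)
    free = ~fixed
    if rho == 0:
        m[free] = rng.binomial(n[free], mu[free])
    else:
        a = mu[free] * (1 - rho) / rho
        b = (1 - mu[free]) * (1 - rho) / rho
        m[free] = rng.binomial(n[free], rng.beta(a, b))
    return m


def simulate_counts(truth: list[SimTruth], config: SimConfig) -> SimData:
    """Simulate the full dataset for a given ground truth."""
    config.validate()
    if len(truth) != config.n_genes:
        raise SimConfigError("truth length does not match config.n_genes")
    layout_rng = np.random.default_rng([config.seed, 1])
    genome, genes, snps = _layout(truth, config, layout_rng)

    samples = [(f"HB{i + 1}", "HB") for i in range(config.reps_hb)] + [
        (f"BH{i + 1}", "BH") for i in range(config.reps_bh)
    ]
    sheet = pd.DataFrame(samples, columns=["sample_id", "cross"])

    effect = {t.gene_id: t.effect_prop for t in truth}
    klass = {t.gene_id: t.bias_class for t in truth}
    n_snp = len(snps)
    gene_ids = snps["gene_id"].to_numpy()
    is_head_diag = (snps["diagnostic_ecotype"] == "head").to_numpy()
    ref_idx = np.array([BASE_INDEX[b] for b in snps["ref"]])
    alt_idx = np.array([BASE_INDEX[b] for b in snps["alt"]])
    head_base_idx = np.where(is_head_diag, alt_idx, ref_idx)
    body_base_idx = np.where(is_head_diag, ref_idx, alt_idx)
    # the two non-allele bases at each SNP, targets for miscalled reads
    others = np.array(
        [[i for i in range(4) if i != r and i != a] for r, a in zip(ref_idx, alt_idx)]
    )

    counts: dict[str, pd.DataFrame] = {}
    true_rows = []
    for k, (sid, cross) in enumerate(samples):
        rng = np.random.default_rng([config.seed, 2, k])
        mu = np.full(n_snp, 0.5)
        for j, g in enumerate(gene_ids):
            if g is None or klass.get(g, "unbiased") == "unbiased":
                continue
            c = klass[g]
            if c == "maternal":
                mu[j] = effect[g]
            else:  # cis bias follows the ecotype, not the parent
                biased_is_mother = (c == "cis_head") == (cross == "HB")
                mu[j] = effect[g] if biased_is_mother else 1 - effect[g]
        depth = rng.poisson(config.depth_mean, n_snp)
        maternal = _beta_binomial(rng, depth, mu, config.overdispersion_rho)
        head = maternal if cross == "HB" else depth - maternal
        body = depth - head
        # per-read miscalls leave the allele bases for the two error bases
        err_h = rng.binomial(head, config.error_rate)
        err_b = rng.binomial(body, config.error_rate)
        err_h0 = rng.binomial(err_h, 0.5)
        err_b0 = rng.binomial(err_b, 0.5)
        base = np.zeros((n_snp, 4), dtype=np.int64)
        rows = np.arange(n_snp)
        np.add.at(base, (rows, head_base_idx), head - err_h)
        np.add.at(base, (rows, body_base_idx), body - err_b)
        np.add.at(base, (rows, others[:, 0]), err_h0 + err_b0)
        np.add.at(base, (rows, others[:, 1]), (err_h - err_h0) + (err_b - err_b0))
        df = pd.DataFrame(
            {
                "chrom": snps["chrom"].to_numpy(),
                "pos": snps["pos"].to_numpy(),
                "ref": snps["ref"].to_numpy(),
                "depth": base.sum(axis=1),
                "A": base[:, 0],
                "C": base[:, 1],
                "G": base[:, 2],
                "T": base[:, 3],
            }
        )
        counts[sid] = df
        true_rows.append(
            pd.DataFrame(
                {
                    "sample_id": sid,
                    "gene_id": gene_ids,
                    "chrom": snps["chrom"].to_numpy(),
                    "pos": snps["pos"].to_numpy(),
                    "head": head,
                    "body": body,
                }
            )
        )

    return SimData(
        config=config,
        truth=truth,
        genome=genome,
        snps=snps,
        genes=genes,
        sample_sheet=sheet,
        counts=counts,
        true_counts=pd.concat(true_rows, ignore_index=True),
    )


def simulate_dataset(config: SimConfig, outdir: str | Path | None = None) -> SimData:
    """Generate truth and counts in one call; optionally write all files."""
    data = simulate_counts(generate_truth(config), config)
    if outdir is not None:
        data.write(outdir)
    return data


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=c, description="") for c, s in genome.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def _write_vcfs(data: SimData, outdir: Path) -> None:
    """Emit one minimal VCF 4.2 per parental ecotype.

    Each file carries only that ecotype's unique hom-alt sites, with DP and
    QUAL drawn comfortably above the default filtering thresholds so every
    planted SNP survives discovery.
    """
    rng = np.random.default_rng([data.config.seed, 3])
    for ecotype in ("head", "body"):
        sub = data.snps[data.snps["diagnostic_ecotype"] == ecotype]
        dp = np.maximum(rng.poisson(30, len(sub)), 10)
        qual = np.round(60 + 40 * rng.random(len(sub)), 1)
        buf = io.StringIO()
        buf.write("##fileformat=VCFv4.2\n")
        for chrom, seq in data.genome.items():
            buf.write(f"##contig=<ID={chrom},length={len(seq)}>\n")
        buf.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">\n')
        buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        buf.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        buf.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{ecotype}\n")
        for (_, row), d, q in zip(sub.iterrows(), dp, qual):
            buf.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t{q}\tPASS\t"
                f"DP={d}\tGT:DP\t1/1:{d}\n"
            )
        (outdir / f"{ecotype}.vcf").write_text(buf.getvalue())


def _write_gff(genes: pd.DataFrame, genome: dict[str, str], path: Path) -> None:
    """Write gene/mRNA/exon features; each gene has two exons and one intron."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, seq in genome.items():
            fh.write(f"##sequence-region {chrom} 1 {len(seq)}\n")
        for row in genes.itertuples():
            g, t = row.gene_id, f"{row.gene_id}.t1"
            mid = (row.start + row.end) // 2
            fh.write(f"{row.chrom}\tsim\tgene\t{row.start}\t{row.end}\t.\t{row.strand}\t.\tID={g}\n")
            fh.write(
                f"{row.chrom}\tsim\tmRNA\t{row.start}\t{row.end}\t.\t{row.strand}\t.\t"
                f"ID={t};Parent={g}\n"
            )
            fh.write(
                f"{row.chrom}\tsim\texon\t{row.start}\t{mid - 5}\t.\t{row.strand}\t.\t"
                f"ID={t}.e1;Parent={t}\n"
            )
            fh.write(
                f"{row.chrom}\tsim\texon\t{mid + 5}\t{row.end}\t.\t{row.strand}\t.\t"
                f"ID={t}.e2;Parent={t}\n"
            )
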