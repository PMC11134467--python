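"""Ecotype-diagnostic SNP discovery and reference N-masking.

Starting from whole-genome variant calls of the two parental ecotypes, a
site is *diagnostic* for ecotype E when E is homozygous for the alternative
allele there and the other ecotype's (filtered) call set has no record at
the site, i.e. matches the reference. Every F1 read covering such a site can
then be assigned a parental ecotype. Masking all diagnostic positions to
'N' in the reference removes the alignment advantage of reference-allele
reads, so downstream allele counts are unbiased.

Call sets are pre-filtered on site depth and quality (defaults: depth >= 10,
QUAL >= 20, both inclusive). Only biallelic SNPs are considered; indels and
multi-nucleotide variants are dropped at parse time with a logged count,
since masking them to a single N is ill-defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

logger = logging.getLogger(__name__)

GENOTYPES = ("hom_ref", "het", "hom_alt", "missing")
_NUCS = frozenset("ACGT")


class InputInconsistencyError(ValueError):
    """The two parental call sets disagree on a site's reference base."""


class MaskError(ValueError):
    """A SNP does not fit the genome it is being masked into."""


@dataclass(frozen=True)
class VariantRecord:
    chrom: str
    pos: int              # 1-based
    ref_base: str
    alt_base: str
    qual: float
    depth: int
    genotype: str         # hom_ref | het | hom_alt | missing

    def __post_init__(self):
        if self.ref_base not in _NUCS or self.alt_base not in _NUCS:
            raise ValueError(f"non-ACGT allele at {self.chrom}:{self.pos}")
        if self.ref_base == self.alt_base:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError("positions are 1-based")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")


@dataclass(frozen=True)
class DiagnosticVariant:
    chrom: str
    pos: int              # 1-based
    ref_base: str
    alt_base: str
    diagnostic_ecotype: str   # head | body


@dataclass(frozen=True)
class FilterThresholds:
    min_depth: int = 10
    min_qual: float = 20.0

    def __post_init__(self):
        if self.min_depth < 0 or self.min_qual < 0:
            raise ValueError("thresholds must be non-negative")


# cyvcf2 gt_types codes -> our genotype labels
_GT_CODE = {0: "hom_ref", 1: "het", 2: "missing", 3: "hom_alt"}


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read biallelic SNPs from a VCF (plain or gzipped).

    Non-SNP and multi-allelic records are skipped (count logged). Genotype
    comes from the first sample's GT; without any sample, a site whose alt
    allele fraction is >= 0.9 of depth is treated as hom_alt (pooled-sample
    calls), otherwise missing.
    """
    from cyvcf2 import VCF

    records: list[VariantRecord] = []
    skipped = 0
    vcf = VCF(str(path))
    has_samples = len(vcf.samples) > 0
    for v in vcf:
        if not v.is_snp or len(v.ALT) != 1 or len(v.REF) != 1:
            skipped += 1
            continue
        depth = _site_depth(v)
        if has_samples:
            genotype = _GT_CODE.get(int(v.gt_types[0]), "missing")
        else:
            af = _alt_fraction(v, depth)
            genotype = "hom_alt" if af is not None and af >= 0.9 else "missing"
        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref_base=v.REF.upper(),
                alt_base=v.ALT[0].upper(),
                qual=float(v.QUAL) if v.QUAL is not None else 0.0,
                depth=depth,
                genotype=genotype,
            )
        )
    if skipped:
        logger.info("%s: skipped %d non-biallelic-SNP records", path, skipped)
    return records


def _site_depth(v) -> int:
    try:
        d = v.format("DP")
        if d is not None:
            return int(d[0][0])
    except Exception:
        pass
    dp = v.INFO.get("DP")
    return int(dp) if dp is not None else 0


def _alt_fraction(v, depth: int) -> float | None:
    ao = v.INFO.get("AO")
    if ao is None or depth == 0:
        return None
    return float(ao) / depth


def filter_variants(
    records: list[VariantRecord], thresholds: FilterThresholds = FilterThresholds()
) -> list[VariantRecord]:
    """Keep sites with depth >= min_depth and QUAL >= min_qual (inclusive)."""
    return [
        r
        for r in records
        if r.depth >= thresholds.min_depth and r.qual >= thresholds.min_qual
    ]


def diagnostic_snps(
    head_variants: list[VariantRecord], body_variants: list[VariantRecord]
) -> list[DiagnosticVariant]:
    """Sites hom-alt in exactly one ecotype and absent from the other.

    Sites present in both call sets — whatever their genotypes — are not
    unique and are excluded; so are het and missing-genotype sites. A site
    whose reference base differs between the two files signals a coordinate
    or reference mismatch and raises :class:`InputInconsistencyError`.
    """
    head_by_site = {(r.chrom, r.pos): r for r in head_variants}
    body_by_site = {(r.chrom, r.pos): r for r in body_variants}
    for site in head_by_site.keys() & body_by_site.keys():
        if head_by_site[site].ref_base != body_by_site[site].ref_base:
            raise InputInconsistencyError(
                f"reference base disagrees between call sets at {site[0]}:{site[1]}"
            )
    out: list[DiagnosticVariant] = []
    for ecotype, own, other in (
        ("head", head_by_site, body_by_site),
        ("body", body_by_site, head_by_site),
    ):
        for (chrom, pos), r in own.items():
            if r.genotype == "hom_alt" and (chrom, pos) not in other:
                out.append(
                    DiagnosticVariant(chrom, pos, r.ref_base, r.alt_base, ecotype)
                )
    out.sort(key=lambda d: (d.chrom, d.pos))
    return out


def mask_genome(
    genome: dict[str, str], snps: list[DiagnosticVariant]
) -> dict[str, str]:
    """Replace each diagnostic position with 'N'; everything else untouched."""
    masked = {c: bytearray(s, "ascii") for c, s in genome.items()}
    for snp in snps:
        if snp.chrom not in masked:
            raise MaskError(f"contig {snp.chrom!r} not in genome")
        contig = masked[snp.chrom]
        if not 1 <= snp.pos <= len(contig):
            raise MaskError(
                f"{snp.chrom}:{snp.pos} beyond contig length {len(contig)}"
            )
        found = chr(contig[snp.pos - 1]).upper()
        if found != snp.ref_base:
            raise MaskError(
                f"reference mismatch at {snp.chrom}:{snp.pos}: "
                f"genome has {found}, variant says {snp.ref_base}"
            )
        contig[snp.pos - 1] = ord("N")
    return {c: s.decode("ascii") for c, s in masked.items()}


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def snps_to_frame(snps: list[DiagnosticVariant]):
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in snps],
            "pos": [s.pos for s in snps],
            "ref": [s.ref_base for s in snps],
            "alt": [s.alt_base for s in snps],
            "ecotype": [s.diagnostic_ecotype for s in snps],
        }
    )


def snps_from_frame(df) -> list[DiagnosticVariant]:
    return [
        DiagnosticVariant(r.chrom, int(r.pos), r.ref, r.alt, r.ecotype)
        for r in df.itertuples()
    ]


def discover(
    head_vcf: str | Path,
    body_vcf: str | Path,
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[DiagnosticVariant]:
    """Read, filter and intersect the two parental call sets."""
    head = filter_variants(read_vcf(head_vcf), thresholds)
    body = filter_variants(read_vcf(body_vcf), thresholds)
    return diagnostic_snps(head, body)
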