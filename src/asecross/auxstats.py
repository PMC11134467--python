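"""Auxiliary analyses: term enrichment, up/down chi-square, CpG o/e.

These accompany the allelic-bias calls: hypergeometric over-representation
of ontology terms among biased genes (BH-corrected), a 1-df goodness-of-fit
test for whether up- and down-regulated gene counts split evenly, and the
CpG observed/expected ratio — depletion of CpG dinucleotides below the value
expected from base composition is a classic proxy for germline DNA
methylation in insects.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import derive_introns, read_exons, read_genes


class UndefinedCpGError(ValueError):
    """CpG o/e has no value (sequence too short, or no C or no G)."""


@dataclass(frozen=True)
class TermAnnotation:
    term_id: str
    gene_ids: frozenset


def hypergeometric_enrichment(
    study: set, background: set, annotations: list[TermAnnotation]
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of each term in the study set.

    p = P(X >= k) for X ~ Hypergeom(N=|background|, K=|term & background|,
    n=|study|); BH correction across tested terms; terms with no background
    gene are skipped.
    """
    study, background = set(study), set(background)
    if not study <= background:
        raise ValueError("study set must be a subset of the background set")
    N, n = len(background), len(study)
    rows = []
    for t in annotations:
        term_bg = set(t.gene_ids) & background
        K = len(term_bg)
        if K == 0:
            continue
        k = len(term_bg & study)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append((t.term_id, k, n, K, N, p))
    df = pd.DataFrame(rows, columns=["term_id", "k", "n", "K", "N", "p_value"])
    if len(df):
        from .stats import bh_adjust

        df["q_value"] = bh_adjust(df["p_value"].to_numpy())
        df["enriched"] = df["q_value"] < 0.05
    else:
        df["q_value"] = pd.Series(dtype=float)
        df["enriched"] = pd.Series(dtype=bool)
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)


def chisq_gof(observed) -> tuple[float, float]:
    """1-df chi-square test of an even split between two counts."""
    obs = np.asarray(observed, dtype=float)
    if obs.shape != (2,) or np.any(obs < 0):
        raise ValueError("expected two non-negative counts")
    if obs.sum() == 0:
        raise ValueError("total count must be positive")
    stat, p = sps.chisquare(obs)
    return float(stat), float(p)


def cpg_oe(sequence: str) -> float:
    """CpG observed/expected: (#CG * L) / (#C * #G).

    Case-insensitive; characters outside ACGT are excluded from L and from
    the C/G counts, and break CpG adjacency. Raises
    :class:`UndefinedCpGError` when the ratio is undefined.
    """
    seq = sequence.upper()
    L = sum(seq.count(b) for b in "ACGT")
    if L < 2:
        raise UndefinedCpGError("sequence shorter than 2 usable bases")
    n_c, n_g = seq.count("C"), seq.count("G")
    if n_c == 0 or n_g == 0:
        raise UndefinedCpGError("no C or no G in sequence")
    n_cg = seq.count("CG")
    return n_cg * L / (n_c * n_g)


_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def cpg_oe_features(
    genome: dict[str, str],
    gff_path: str | Path,
    feature_types: set = frozenset({"exon", "intron"}),
) -> pd.DataFrame:
    """CpG o/e per exon and/or intron of every transcript.

    Introns are the gaps between consecutive exons of a transcript.
    Reverse-strand features are evaluated on the reverse complement (CpG is
    strand-symmetric, so this equals the forward value). Features whose
    ratio is undefined get NaN.
    """
    exons = read_exons(gff_path)
    parts = []
    if "exon" in feature_types:
        parts.append(exons.assign(feature_type="exon"))
    if "intron" in feature_types:
        parts.append(derive_introns(exons).assign(feature_type="intron"))
    if not parts:
        return pd.DataFrame(
            columns=["transcript_id", "feature_type", "chrom", "start", "end", "strand", "cpg_oe"]
        )
    feats = pd.concat(parts, ignore_index=True)
    values = []
    for r in feats.itertuples():
        if r.chrom not in genome:
            raise ValueError(f"contig {r.chrom!r} not in genome")
        contig = genome[r.chrom]
        if r.start < 1 or r.end > len(contig):
            raise ValueError(f"feature {r.chrom}:{r.start}-{r.end} beyond contig bounds")
        seq = contig[r.start - 1 : r.end]
        if r.strand == "-":
            seq = revcomp(seq)
        try:
            values.append(cpg_oe(seq))
        except UndefinedCpGError:
            values.append(np.nan)
    feats["cpg_oe"] = values
    return feats[
        ["transcript_id", "feature_type", "chrom", "start", "end", "strand", "cpg_oe"]
    ]


def read_term_map(path: str | Path) -> list[TermAnnotation]:
    """Read a two-column TSV (term_id, gene_id) into term annotations."""
    df = pd.read_csv(path, sep="\t")
    return [
        TermAnnotation(term_id=str(t), gene_ids=frozenset(g["gene_id"].astype(str)))
        for t, g in df.groupby("term_id", sort=True)
    ]
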