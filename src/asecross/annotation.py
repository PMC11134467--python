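"""GFF3 access helpers: gene spans, transcript exons, derived introns.

All coordinates are 1-based inclusive, as in GFF3. Introns are the gaps
between consecutive exons of the same transcript; two exons that touch or
overlap contribute no intron.
"""

from __future__ import annotations

from pathlib import Path

import gffutils
import pandas as pd


class GffParseError(ValueError):
    pass


def _open_db(gff_path: str | Path) -> gffutils.FeatureDB:
    try:
        return gffutils.create_db(
            str(gff_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # surface the offending line if gffutils knows it
        raise GffParseError(f"failed to parse {gff_path}: {exc}") from exc


def read_genes(gff_path: str | Path) -> pd.DataFrame:
    """One row per gene feature: gene_id, chrom, start, end, strand."""
    db = _open_db(gff_path)
    rows = [
        (f.id, f.seqid, f.start, f.end, f.strand)
        for f in db.features_of_type("gene")
    ]
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def read_exons(gff_path: str | Path) -> pd.DataFrame:
    """One row per exon with its parent transcript id."""
    db = _open_db(gff_path)
    rows = []
    for f in db.features_of_type("exon"):
        parents = f.attributes.get("Parent", [f.id])
        for p in parents:
            rows.append((p, f.seqid, f.start, f.end, f.strand))
    df = pd.DataFrame(
        rows, columns=["transcript_id", "chrom", "start", "end", "strand"]
    )
    return df.sort_values(["transcript_id", "start"], kind="stable").reset_index(drop=True)


def derive_introns(exons: pd.DataFrame) -> pd.DataFrame:
    """Gaps between consecutive exons of each transcript."""
    rows = []
    for tid, grp in exons.groupby("transcript_id", sort=True):
        grp = grp.sort_values("start")
        prev_end = None
        for i, r in enumerate(grp.itertuples()):
            if prev_end is not None and r.start > prev_end + 1:
                rows.append((tid, r.chrom, prev_end + 1, r.start - 1, r.strand))
            prev_end = max(prev_end, r.end) if prev_end is not None else r.end
    return pd.DataFrame(
        rows, columns=["transcript_id", "chrom", "start", "end", "strand"]
    )
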