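"""Auxiliary analyses over the simulated run.

1. Term enrichment of the maternally biased genes against all tested genes,
   using a synthetic term map in which one term is deliberately loaded with
   maternal genes (so enrichment should flag it) and the rest are random.
2. The chi-square goodness-of-fit worked example on a 34/13 up/down split
   of 47 ecotype-differential genes.
3. CpG observed/expected per exon and intron of the toy genome.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from asecross.auxstats import TermAnnotation, chisq_gof, cpg_oe_features, hypergeometric_enrichment
from asecross.variants import read_fasta

ROOT = Path(__file__).resolve().parents[1]
DATASET = ROOT / "scratch" / "dataset"


def synthetic_term_map(background, loaded_genes, rng, n_terms=30, term_size=25):
    """Random gene sets plus one term enriched for the loaded genes."""
    bg = sorted(background)
    terms = [
        TermAnnotation(f"T{i:03d}", frozenset(rng.choice(bg, term_size, replace=False)))
        for i in range(n_terms)
    ]
    loaded = set(loaded_genes) | set(rng.choice(bg, 5, replace=False))
    terms.append(TermAnnotation("T_loaded", frozenset(loaded)))
    return terms


def main() -> None:
    results = pd.read_csv(DATASET / "ase_results.tsv", sep="\t")
    background = set(results["gene_id"])
    maternal = set(
        results.loc[results["category"].isin(["maternal_biased", "maternal_limited"]), "gene_id"]
    )
    rng = np.random.default_rng(7)
    enr = hypergeometric_enrichment(
        maternal, background, synthetic_term_map(background, maternal, rng)
    )
    enr.to_csv(ROOT / "results" / "05_enrichment.tsv", sep="\t", index=False)
    print(f"enrichment: {int(enr['enriched'].sum())} of {len(enr)} terms at q<0.05; top term:")
    print(enr.head(1).to_string(index=False))

    stat, p = chisq_gof((34, 13))
    pd.DataFrame([{"up": 34, "down": 13, "chisq": stat, "df": 1, "p_value": p}]).to_csv(
        ROOT / "results" / "05_chisq_updown.tsv", sep="\t", index=False
    )
    print(f"up/down chi-square: X2 = {stat:.3f}, p = {p:.4f}")

    cpg = cpg_oe_features(read_fasta(DATASET / "genome.fa"), DATASET / "genes.gff3")
    by_type = cpg.groupby("feature_type")["cpg_oe"].describe()[["count", "mean", "std"]]
    by_type.reset_index().to_csv(ROOT / "results" / "05_cpg_oe_summary.tsv", sep="\t", index=False)
    print(by_type.to_string())


if __name__ == "__main__":
    main()
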