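"""Per-gene allelic-ratio tests on the parent and ecotype axes.

Each gene is tested twice on the same counts, once per axis:

* parent axis — successes are maternal-allele reads; a deviation that is
  consistent across both cross directions indicates parent-of-origin
  (imprinting-like) bias;
* ecotype axis — successes are head-allele reads; a consistent deviation
  indicates a cis-regulatory ecotype effect.

The test is an intercept-only quasi-binomial logistic regression: the MLE of
the intercept is logit of the pooled proportion, the dispersion phi is the
Pearson statistic over N - 1 degrees of freedom, the standard error is
inflated by sqrt(phi), and significance uses a two-sided t test — the exact
behaviour of a quasi-binomial ``glm`` fit with only an intercept. Raw
p-values are Benjamini-Hochberg adjusted separately within each axis.

A gene is called biased on an axis when the adjusted p-value is below
``alpha`` AND the biased allele's mean per-sample proportion exceeds
``prop_cutoff`` in BOTH cross directions; it is called *limited*
(monoallelic) when additionally the silenced allele has zero reads in every
informative sample. With ``prop_cutoff`` > 0.5 the two axes are mutually
exclusive: a gene can satisfy the both-directions rule on at most one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .counting import GeneAlleleTable

logger = logging.getLogger(__name__)

CATEGORIES = (
    "biparental",
    "maternal_biased",
    "maternal_limited",
    "paternal_biased",
    "paternal_limited",
    "head_biased",
    "head_limited",
    "body_biased",
    "body_limited",
)


class NotTestableError(ValueError):
    """Fewer than two samples carry reads for this gene."""


@dataclass(frozen=True)
class QuasiBinomialFit:
    p_hat: float      # pooled success proportion
    beta: float       # logit(p_hat), after continuity correction if degenerate
    se: float         # dispersion-scaled standard error of beta
    phi: float        # Pearson dispersion estimate
    df_resid: int
    p_value: float    # two-sided t test of beta = 0


@dataclass(frozen=True)
class ClassifyThresholds:
    alpha: float = 0.05
    prop_cutoff: float = 0.6
    limited_tol: int = 0   # max reads of the "silenced" allele still called limited

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.5 < self.prop_cutoff <= 1:
            raise ValueError("prop_cutoff must lie in (0.5, 1]")


@dataclass
class GeneTestResult:
    gene_id: str
    p_parent: float
    p_ecotype: float
    prop_maternal_hb: float
    prop_maternal_bh: float
    prop_head_hb: float
    prop_head_bh: float
    max_sample_maternal: int
    max_sample_paternal: int
    max_sample_head: int
    max_sample_body: int
    q_parent: float = np.nan
    q_ecotype: float = np.nan
    category: str | None = None


def fit_quasibinomial_intercept(successes, totals) -> QuasiBinomialFit:
    """Closed-form intercept-only quasi-binomial fit.

    For an intercept-only binomial GLM the IRLS fixed point is the pooled
    proportion, so the fit is available in closed form:

        p_hat = S / T,  beta = logit(p_hat),  I = T * p_hat * (1 - p_hat)
        phi   = (1 / (N - 1)) * sum (s_i - n_i p_hat)^2 / (n_i p_hat (1 - p_hat))
        se    = sqrt(phi / I),  p from t = beta / se on N - 1 df

    over the N samples with n_i > 0. A pooled proportion of exactly 0 or 1
    gets a 0.5 continuity addition to pooled successes and failures before
    beta, I and phi are computed (such genes are handled by the monoallelic
    "limited" path anyway).
    """
    s = np.asarray(successes, dtype=float)
    n = np.asarray(totals, dtype=float)
    if np.any(s < 0) or np.any(n < s):
        raise ValueError("need 0 <= successes <= totals")
    keep = n > 0
    s, n = s[keep], n[keep]
    if len(n) < 2:
        raise NotTestableError("fewer than 2 samples with reads")
    S, T = s.sum(), n.sum()
    p_hat = S / T
    if p_hat in (0.0, 1.0):
        p_work = (S + 0.5) / (T + 1.0)
    else:
        p_work = p_hat
    beta = np.log(p_work / (1 - p_work))
    info = T * p_work * (1 - p_work)
    df_resid = len(n) - 1
    phi = float(np.sum((s - n * p_work) ** 2 / (n * p_work * (1 - p_work))) / df_resid)
    se = float(np.sqrt(phi / info))
    if beta == 0.0:
        p_value = 1.0
    elif se == 0.0:
        p_value = 0.0
    else:
        p_value = float(2 * sps.t.sf(abs(beta / se), df_resid))
    return QuasiBinomialFit(
        p_hat=float(p_hat),
        beta=float(beta),
        se=se,
        phi=phi,
        df_resid=df_resid,
        p_value=p_value,
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _direction_prop(numer, denom) -> float:
    """Unweighted mean of per-sample proportions over samples with reads."""
    numer = np.asarray(numer, dtype=float)
    denom = np.asarray(denom, dtype=float)
    keep = denom > 0
    if not keep.any():
        return np.nan
    return float(np.mean(numer[keep] / denom[keep]))


def test_all_genes(table: GeneAlleleTable) -> list[GeneTestResult]:
    """Fit both axes for every gene and BH-adjust within each axis.

    Genes with fewer than two read-bearing samples are excluded (logged).
    Categories are not assigned here; see :func:`classify_gene` /
    :func:`classify_all`.
    """
    results: list[GeneTestResult] = []
    dropped = []
    for gene_id, grp in table.gene_counts.groupby("gene_id", sort=True):
        mat = grp["maternal"].to_numpy()
        pat = grp["paternal"].to_numpy()
        head = grp["head"].to_numpy()
        body = grp["body"].to_numpy()
        tot = mat + pat
        try:
            fit_parent = fit_quasibinomial_intercept(mat, tot)
            fit_ecotype = fit_quasibinomial_intercept(head, tot)
        except NotTestableError:
            dropped.append(gene_id)
            continue
        hb = (grp["cross"] == "HB").to_numpy()
        informative = tot > 0
        results.append(
            GeneTestResult(
                gene_id=str(gene_id),
                p_parent=fit_parent.p_value,
                p_ecotype=fit_ecotype.p_value,
                prop_maternal_hb=_direction_prop(mat[hb], tot[hb]),
                prop_maternal_bh=_direction_prop(mat[~hb], tot[~hb]),
                prop_head_hb=_direction_prop(head[hb], tot[hb]),
                prop_head_bh=_direction_prop(head[~hb], tot[~hb]),
                max_sample_maternal=int(mat[informative].max(initial=0)),
                max_sample_paternal=int(pat[informative].max(initial=0)),
                max_sample_head=int(head[informative].max(initial=0)),
                max_sample_body=int(body[informative].max(initial=0)),
            )
        )
    if dropped:
        logger.info("excluded %d genes with <2 informative samples", len(dropped))
    if results:
        q_par = bh_adjust([r.p_parent for r in results])
        q_eco = bh_adjust([r.p_ecotype for r in results])
        for r, qp, qe in zip(results, q_par, q_eco):
            r.q_parent = float(qp)
            r.q_ecotype = float(qe)
    return results


def classify_gene(
    result: GeneTestResult, thresholds: ClassifyThresholds = ClassifyThresholds()
) -> str:
    """Assign the final bias category for one gene.

    Bias requires adjusted p < alpha and a biased-allele proportion beyond
    the cutoff in both cross directions; "limited" additionally requires the
    other allele to be (near-)absent in every informative sample.
    """
    a, c, tol = thresholds.alpha, thresholds.prop_cutoff, thresholds.limited_tol
    pm = (result.prop_maternal_hb, result.prop_maternal_bh)
    ph = (result.prop_head_hb, result.prop_head_bh)

    def both(props, above):
        if any(np.isnan(p) for p in props):
            return False
        return all(p > c for p in props) if above else all(p < 1 - c for p in props)

    if result.q_parent < a and both(pm, above=True):
        return "maternal_limited" if result.max_sample_paternal <= tol else "maternal_biased"
    if result.q_parent < a and both(pm, above=False):
        return "paternal_limited" if result.max_sample_maternal <= tol else "paternal_biased"
    if result.q_ecotype < a and both(ph, above=True):
        return "head_limited" if result.max_sample_body <= tol else "head_biased"
    if result.q_ecotype < a and both(ph, above=False):
        return "body_limited" if result.max_sample_head <= tol else "body_biased"
    return "biparental"


def classify_all(
    results: list[GeneTestResult],
    thresholds: ClassifyThresholds = ClassifyThresholds(),
) -> list[GeneTestResult]:
    for r in results:
        r.category = classify_gene(r, thresholds)
    return results


def results_frame(results: list[GeneTestResult]) -> pd.DataFrame:
    """One row per gene with all statistics and the category."""
    return pd.DataFrame([vars(r) for r in results])


def run_ase_tests(
    table: GeneAlleleTable,
    thresholds: ClassifyThresholds = ClassifyThresholds(),
) -> pd.DataFrame:
    """Test, adjust and classify every gene; return the results table."""
    return results_frame(classify_all(test_all_genes(table), thresholds))


def category_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Counts per bias category (the stacked-bar view of the results)."""
    counts = results["category"].value_counts()
    return pd.DataFrame(
        {"category": CATEGORIES, "n_genes": [int(counts.get(c, 0)) for c in CATEGORIES]}
    )
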