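# Methods

## Design of the analysis

A reciprocal cross between two ecotypes (head, H; body, B) produces F1 males
of two kinds: HB (head mother) and BH (body mother). At an
ecotype-diagnostic SNP every RNA-seq read has both a parental and an ecotype
label, and the two cross directions disentangle the axes: a maternally
favoured allele is the *head* allele in HB samples but the *body* allele in
BH samples, whereas a cis-favoured allele is the same ecotype's allele in
both. The pipeline therefore tests each gene on both axes with the same
counts and lets the both-directions proportion rule decide which axis, if
either, explains the imbalance.

## Diagnostic SNP discovery

Parental variant calls are filtered on site depth >= 10 and QUAL >= 20 (both
inclusive minima). A site is diagnostic for an ecotype when that ecotype is
homozygous-alternative there and the *filtered* call set of the other
ecotype has no record at the site. This is a literal set difference: a site
dropped from one ecotype only by the depth/quality filter can appear
diagnostic. That behaviour reproduces interval-tool set operations on
filtered VCFs, the standard way such lists are built; the trade-off is a
small false-diagnostic rate proportional to the fraction of borderline
sites, which the downstream both-directions rule absorbs. Only biallelic
SNPs are used; indels/MNVs are dropped at parse (masking them to a single N
is ill-defined). Masking replaces every diagnostic position with `N` and
errors on any reference-base mismatch, which would indicate a coordinate
convention bug. All internal coordinates are 1-based inclusive.

## Counting and informativeness

At a head-diagnostic SNP the alt-base reads are head-allele reads and the
ref-base reads body-allele reads (vice versa for body-diagnostic); the two
remaining bases are sequencing error and carry no allelic information. SNP
counts are summed over each gene's full span (introns included; a SNP in
overlapping genes counts once per gene), then oriented maternal/paternal by
the sample's cross. A gene is kept when at least one of its SNPs has >= 10
allele-assignable (head+body) reads in >= 2 replicates of each direction;
requiring the *same* SNP in both directions matches a per-SNP coverage
reading of the replicate rule, and the filter is monotone in both
thresholds. Summation across SNPs is the simplest aggregation consistent
with per-position counting; reads spanning two SNPs can be counted twice —
a known, documented limitation of pileup-based ASE.

## The allelic-ratio test

Intercept-only quasi-binomial logistic regression per gene per axis. For an
intercept-only binomial GLM the IRLS fixed point is the pooled proportion,
so the fit is computed in closed form (pooled p̂, β = logit p̂, Pearson
dispersion over N−1 df, dispersion-scaled SE, two-sided t test); the test
suite verifies equivalence with an independently coded IRLS solver to 1e-8
and with a statsmodels GLM under Pearson scaling. No floor is placed on the
dispersion. Degenerate pooled proportions (0 or 1) receive a 0.5 continuity
addition to pooled successes and failures before β, the information and the
dispersion are computed — these genes are classified through the
monoallelic "limited" path regardless, so the correction only keeps the
statistics finite. Genes with fewer than two read-bearing samples are
excluded and logged. BH adjustment is applied separately within each axis
(two test families over the same genes); the cross-direction consistency
that a covariate would model is instead enforced by the classification rule
below, the simplest model consistent with per-direction proportions being
reported separately.

## Classification

Per-direction proportions are unweighted means of per-sample proportions
over read-bearing samples — robust to depth imbalance between replicates (a
pooled-count variant would let one deep sample dominate a direction).
maternal_biased: adjusted p_parent < 0.05 and maternal proportion > 0.6 in
both directions; paternal mirrored with proportions < 0.4; head/body the
same on the ecotype axis. *Limited* additionally requires zero reads of the
silenced allele in every informative sample (a tolerance is exposed,
default 0, for error-tolerant calling); limited calls still require the
significance and proportion criteria, the stricter of the two possible
readings of "meet the above criteria". Because the head proportion equals
the maternal proportion in HB and its complement in BH, a cutoff above 0.5
makes the two axes mutually exclusive — property-tested over randomized
tables.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
the sequencing: a single toy contig, genes of a few hundred bp with
diagnostic SNPs planted alternately head- and body-unique, two exons and one
intron per gene, and per-SNP depths Poisson around `depth_mean`. Maternal
counts are beta-binomial with mean 0.5 (unbiased), `effect_prop` (maternal
class), or `effect_prop`/`1−effect_prop` by cross (cis classes), with
intraclass correlation rho under the parameterisation alpha = mu(1−rho)/rho,
beta = (1−mu)(1−rho)/rho, so Var = n·mu(1−mu)(1+(n−1)rho); rho = 0 falls
back to binomial and mu ∈ {0,1} is deterministic. Each read is miscalled
with probability `error_rate` to one of the two non-allele bases, so error
reads land in the `other` bin rather than flipping alleles. Each sample has
its own RNG stream derived from the master seed, so adding samples leaves
existing ones untouched and fixed seeds give byte-identical files.

Defaults are the study's conditions: 5 HB + 4 BH samples, ~3 SNPs per gene,
mean depth 30. The study reports no overdispersion estimate; rho defaults to
0.05, a mild intraclass correlation typical of bulk allelic counts, at which
the null simulation stays well calibrated. What the generator does *not*
model: alignment and reference-mapping bias (the N-masking motivation is
honoured by consuming already-unbiased counts), reads spanning multiple
SNPs, per-SNP effect heterogeneity within a gene, library-size differences,
and tissue mixtures — so passing recovery tests demonstrate correctness of
the statistical machinery under its own assumptions, not robustness to
those artefacts.

## Auxiliary statistics

Term enrichment is the plain upper-tail hypergeometric P(X >= k) per term
against a configurable background (default: all tested genes), BH-corrected
across terms; no ontology-graph decorrelation. The up/down test is the
1-df equal-expectation chi-square. CpG observed/expected is
(#CpG × L)/(#C × #G) with case folding; non-ACGT characters are excluded
from L and the counts and break dinucleotide adjacency, and an undefined
ratio (no C or no G) raises rather than returning 0. Introns for the
feature-level table are per-transcript gaps between consecutive exons.
Reverse-strand features are evaluated on the reverse complement, which is a
no-op for CpG (strand-symmetric) and is asserted as a test.

## Problem sizes and numerical choices

The calibration and recovery analyses use 2,000 genes at mean depths 30-50
with the study's 5+4 replicate structure — large enough for stable
fractions (binomial SE on a 1% rate at n=2000 is ~0.2%) while the whole
suite runs in seconds. Tolerances: oracle equivalence of the GLM at 1e-8
(closed form vs iterative); BH and hypergeometric checks at 1e-10..1e-12
(identical arithmetic up to floating point); Monte-Carlo variance checks at
5% relative. Ties in BH are handled by the step-up suffix minimum, which
makes tied p-values receive equal adjusted values regardless of sort order.
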