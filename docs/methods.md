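# Methods

`mirqtl` implements a genome-wide scan for effects of pri-miRNA SNPs
(miSNPs) on gene expression in a single cell type: marginal additive eQTL
analysis with cis/trans classification and conditional adjustment, a
pairwise miSNP x 3'UTR-SNP interaction scan with a variance-prioritized
(Levene-weighted) Bonferroni correction, and a two-locus haplotype-effect
model used to illustrate detected interactions. This note records the
models, the defaults and why they were chosen, the numerical decisions, and
what the synthetic-data tests do and do not establish.

## Data model and conventions

Genotypes are minor-allele dosages in {0, 1, 2}, with NaN for missing
calls. The minor allele is defined per dataset from observed frequency;
exact ties go to the alphabetically-first allele, so orientation is
deterministic. Expression values are normalized log-scale intensities
(array preprocessing is out of scope; the package consumes the normalized
matrix). Intervals are held 0-based half-open internally (BED-compatible);
anything that mirrors published tables — probe spans, SNP positions — is
1-based inclusive at the I/O boundary, and the conversion is a bijection.
Strand is ignored for all interval membership tests.

## Selection of analysis units

A miSNP is a SNP inside an annotated pri-miRNA interval; a 3utrSNP is a SNP
inside a gene's (pre-merged) 3'UTR interval. Probes enter the analysis only
if their re-annotation quality is "perfect" and their genomic sequence
harbours no SNP, which avoids hybridisation artefacts masquerading as
eQTLs. Each target SNP participates through a genotyped proxy: itself when
genotyped, otherwise the candidate with maximal EM-based r^2 provided it
reaches 0.90 (ties broken by genomic distance, then id). One genotyped
proxy may tag several 3utrSNPs, so the per-gene 3utrSNP histogram's derived
total can exceed the number of distinct studied proxies; the selection
report carries both numbers. Genes represented by several eligible probes
contribute every probe as a separate test unit.

## Genotype QC

SNPs are filtered on MAF > 0.01, call rate > 0.98, and Hardy-Weinberg
exact-test p > 1e-4, in that order (each SNP is attributed to the first
filter it fails). The HWE test is the exact test conditional on allele
counts, enumerating heterozygote counts in log space; it is the field
standard and is checked against a direct enumeration oracle. A
replication-style profile (call rate > 0.95, HWE p > 1e-5) is available
through the same thresholds object. QC is idempotent.

## Two-locus haplotypes and LD

Haplotype frequencies for a SNP pair are maximum-likelihood estimates from
unphased dosages via EM. Only double heterozygotes are phase-ambiguous, so
the likelihood has one free parameter; the EM starts at linkage equilibrium
(product of allele frequencies), is deterministic with no restarts, and
stops when the largest frequency change falls below 1e-10 or after 1000
iterations. A 1-D likelihood-grid oracle in the test suite guards against
local optima. LD statistics follow from the frequencies: D = f_AB - p_A
p_B, D' = |D| / D_max, r^2 = D^2 / (p_A p_a p_B p_b). r^2 between SNPs is
always computed from EM haplotype frequencies, not genotype correlation,
matching how reference-panel LD tools report it.

## Marginal association scan

Each (miSNP proxy, probe) pair is tested by OLS of expression on dosage
under additive allele effects, adjusted for age and sex (plus disease
status in a replication cohort). Missing data are handled complete-case
per test, with no imputation. The reported per-SNP R^2 is the increment in
model R^2 due to the dosage term over the covariate-only model (the
published tables do not define their R^2 precisely; the increment is the
natural per-SNP quantity). A SNP is cis to a probe iff it lies on the same
chromosome within 1 Mb of the nearest edge of the probe's annotated
interval, with a closed boundary (distance exactly 1 Mb is cis); otherwise
trans. The best cis eSNP of a probe is the cis SNP with the smallest
association p-value below 5.5e-5 (configurable; the tested SNP itself may
win). Conditional models append the best cis eSNP dosage and/or mediator
expression vectors as covariates; an adjuster perfectly collinear with the
dosage is a degenerate-predictor error. The genome-wide threshold is always
alpha divided by the product of SNPs tested and probes tested — derived
from executed counts, never hard-coded.

## Interaction scan and Levene-weighted Bonferroni

For every (3utrSNP proxy, probe) unit and every miSNP proxy, expression is
regressed on [1, g_utr, g_mi, g_utr x g_mi, covariates] and the product
coefficient is tested two-sided. Pairs whose design is rank-deficient
(e.g. SNPs in perfect LD) or has a constant predictor are skipped with a
recorded reason and excluded from the test count N.

Each unit receives one Levene statistic: expression is residualized on the
same covariate set as the regressions, and the classic Levene test (one-way
ANOVA on absolute deviations from group means across the three genotype
classes of the 3utrSNP proxy) yields a p-value q_u. Mean-centering is the
default because the procedure is named after Levene's statistic;
median-centering (Brown-Forsythe) is available. The weighting unit is the
(3utrSNP proxy, probe) pair — two probes of one gene can have different
variance signatures. Weights are standardized as

    w_u = (-log q_u) * N / sum over executed tests of (-log q of its unit),

so the weights assigned over the N executed tests sum to N (mean 1), the
log base cancels, and when all q are equal every weight is 1 and the
procedure reduces to plain Bonferroni. Each interaction p-value is divided
by its unit's weight, P* = P / w, and declared genome-wide significant iff
P* < alpha / N. If every q equals 1 the normalization is 0/0 and the
weights fall back to uniform.

The functional form w proportional to -log q with mean-1 normalization was
fixed by internal consistency of a published 51-row results table: the
ratio (P / P*) / (-log10 q) is a single constant across rows (CV about
0.2%), and calibrating it on one row reproduces every other internally
consistent row's weighted p-value within 2%. One row of that table is off
by exactly 10x — an exponent misprint — and the validation routine flags it
rather than silently absorbing it.

### Robust product-term inference

The weighting scheme deliberately routes the multiple-testing budget toward
units whose residual variance differs across genotype classes. That is
precisely the regime in which the classical homoskedastic OLS t-test on the
product term is anti-conservative: the product term's information is
concentrated in the rare-homozygote cells, and genotype-dependent variance
inflates its far tail several-fold (measured about 5x at the 1e-3 tail at
n = 300 with per-genotype sd 1/1.5/2). A weighted-Bonferroni procedure only
controls family-wise error if the per-test p-values are valid, so the scan
defaults to heteroskedasticity-robust inference for the product term: the
HC2 sandwich variance with Satterthwaite degrees of freedom (the
Bell-McCaffrey small-sample correction), which restores far-tail
calibration at the cost of a little power under homoskedasticity. The
Satterthwaite trace is computed in O(n k^2) using the rank-k structure of
the hat matrix. Classical and HC3 standard errors remain available
(`se="classical"` / `"hc3"`), and the operation-level
`interaction_model` default is classical, matching the scan's published
description; the scan and replication default to `"bm"`. Simulated
family-wise error of the full weighted scan under a global null with
planted variance heterogeneity is re-measured by `scripts/acceptance.py`.

### Replication

Discovery hits are re-fitted in an independent cohort with disease status
appended to the covariates, using replication proxies supplied by a map
(identity by default). Hits without a replication proxy or probe are
non-replicable and excluded from the Bonferroni denominator k; a hit
replicates iff p < alpha / k and (by default) the product coefficient keeps
the discovery sign.

## Haplotype-effect model

For a detected SNP pair, each sample receives posterior-expected counts of
the four two-locus haplotypes under the EM frequencies; only double
heterozygotes get fractional dosages, and every complete sample's dosages
sum to 2. Expression is regressed on the non-reference haplotype dosages
plus covariates; the reference is the most frequent haplotype (ties broken
lexicographically), coefficients are per-copy effects versus the reference
with t-based 95% CIs, the global p is the F-test of all haplotype terms,
and the global R^2 is their increment over the covariate-only model.
Haplotype columns that are absent or numerically inestimable are collapsed
out with a warning.

This deterministic expected-dosage substitution replaces stochastic-EM
multiple imputation. It is reproducible and testable, but it ignores phase
uncertainty, so standard errors are slightly optimistic when the
double-heterozygote fraction is large; in the hardest simulated contrast
(two near-tied common haplotypes, about 33% double heterozygotes) CI
coverage dips to about 93% instead of 95%. This is the accepted trade-off.

The effect-homogeneity test is a Wald contrast on the coefficient
covariance matrix: beta(AB) - beta(aB) = beta(Ab) - beta(ab), i.e. the
locus-1 allele effect is the same on both locus-2 backgrounds. It is the
haplotype-scale parameterization of the dosage-product interaction, and its
p-values agree in rank order with the product-term test in simulation. A
Wald form was chosen over a likelihood ratio because the model is linear
and the contrast is exact given the fit.

## Synthetic-data generator

The generator emulates every structure the analysis assumes: HWE genotypes
at specified MAFs; LD pairs drawn as two haplotypes per sample from
specified four-haplotype frequencies; expression assembled from additive
effects, product-term interactions, sequentially generated mediator chains
(SNP -> mediator gene -> downstream gene, so "adjust for the mediator"
scenarios are directly testable), per-genotype residual sds (to exercise
the Levene prioritization), and age/sex/status covariate effects; and
optional genotype missingness. One global seed expands into per-component
substreams via `numpy.random.SeedSequence` spawning, so bundles are
bit-reproducible.

Cosmetic defaults: age ~ Uniform(35, 74) years, sex ~ Bernoulli(0.5),
disease status ~ Bernoulli(0.48) for replication-style cohorts, baseline
probe intensity 8.0, residual sd 1.0, age slope 0.005 per year and sex
offset 0.05 expression units. These mirror a middle-aged population cohort
profile and are all configurable.

Two canned scenarios define the study conditions used by the tests:

- `make_paper_like_scenario`: a miniature genome-wide scan with 30 miSNPs
  (one per pri-miRNA), 60 genes carrying about 100 3utrSNPs with a
  decreasing per-gene histogram, about 200 probes including non-"perfect"
  and SNP-harbouring probes that the filters must drop, two planted
  interactions (beta_int = 0.5), one mediation chain, variance
  heterogeneity (per-genotype sd 1/1.5/2) at two units, and high-LD proxy
  pairs (r^2 just above 0.9) for a subset of targets. Default n = 800,
  chosen so the planted interactions sit well past the scan threshold while
  a full discovery run stays in the seconds range.
- `make_global_null_scenario`: 10 units x 20 miSNPs at n = 300 with no
  interaction effects and per-genotype sd 1/1.5/2 at 20% of units, for
  family-wise-error calibration.

What passing these tests shows: the estimators are unbiased at the planted
effect sizes, the weighting arithmetic is exact, and the scan's error
control holds under genotype-keyed heteroskedasticity. What they do not
show: behaviour under realistic genome-wide LD structure, array-level
noise, population stratification, or non-normal expression residuals —
none of which the generator emulates.

## Numerical decisions

- OLS is a QR-based normal-equations solve with explicit rank checking;
  constant non-intercept columns and rank-deficient designs raise a
  degenerate-predictor error naming the offending columns. Estimates agree
  with statsmodels OLS to 1e-8 relative in the test suite.
- Levene q-values are floored at 1e-300 before taking logs so an
  underflowed q cannot produce an infinite weight.
- The EM convergence criterion is max frequency change < 1e-10; haplotype
  frequency vectors must sum to 1 within 1e-9.
- Deterministic output ordering everywhere: interaction records by weighted
  p ascending, ties by (probe, 3utrSNP, miSNP); re-running a pipeline with
  identical config and inputs is byte-identical.
- Monomorphic loci: LD is an error (undefined), EM returns degenerate
  frequencies with a flag, QC removes zero-call SNPs with a log entry.

## Problem sizes

The shipped scenarios are miniatures: hundreds of samples, tens of SNPs and
probes, thousands of interaction tests, chosen so a full discovery run
completes in seconds and the 500-replicate FWER calibration in about a
minute on one core. All thresholds are derived from executed-test counts,
so nothing in the code depends on the scenario scale.

## Known limitations

- Expected-dosage haplotype regression understates uncertainty at high
  double-heterozygote fractions (see above).
- Proxies are computed from the supplied genotypes, not from an external
  reference panel, so proxy r^2 values can differ from panel-based ones.
- The package consumes pre-merged 3'UTR intervals and probe annotations; it
  does not fetch or reconcile annotation sources.
- Only biallelic SNPs and two-locus haplotypes are supported.
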