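# Methods

## The model

For one CpG probe, the M value of individual *i* is

    Y_i = mu + X_i beta + g_i + eps_i

where X collects the fixed effects (age in years, sex coded 0 = female /
1 = male, and five of the six estimated blood cell proportions), *g* is an
additive polygenic effect and *eps* iid noise. The polygenic covariance is
proportional to expected allele sharing:

    cov(Y_i, Y_j) = 2 phi_ij sigma_g^2        (i != j)
    var(Y_i)      = sigma_g^2 + sigma_eps^2   (non-inbred individuals)

with phi_ij the kinship coefficient computed by the standard recursion over
the pedigree (phi_ii = 1/2 + phi_fm/2; phi_ij = (phi_fj + phi_mj)/2 on the
later-generation member; founders unrelated). This conditions the age-effect
estimate on family structure instead of pretending relatives are independent.

**Fitting.** All parameters are estimated by maximum likelihood. The
covariance 2 Phi sigma_g^2 + I sigma_eps^2 is diagonalized once per cohort:
with 2 Phi = U diag(lam) U', rotating y and X by U' gives independent
observations with variances sigma^2 (h2 lam_k + 1 - h2), where
h2 = sigma_g^2 / (sigma_g^2 + sigma_eps^2) and sigma^2 the total. For fixed
h2 the GLS coefficients and sigma^2 have closed forms, so the optimization is
a bounded 1-D search over h2 in [0, 1 - 1e-6] (tolerance 1e-8); the h2 = 0
endpoint is evaluated explicitly because the bounded search never touches its
boundaries. Non-convergence (optimizer failure or non-finite likelihood) is
flagged per probe and never aborts a scan; flagged probes surface as
"convergence failure" rows in the outputs.

**Testing.** The age P value is a likelihood-ratio chi-square with 1 df
comparing ML fits with and without the age column, the convention
variance-component packages use for fixed-effect tests; a Wald z test is
available (`test="wald"`) as a cross-check. ML (not REML) is used throughout
because both nested fits must be comparable in a likelihood ratio; the
resulting mild anti-conservatism at small n is quantified by simulation in
the test suite (type-I error within [0.04, 0.06] at n = 100 over 5,000 null
probes). Genome-wide significance is Bonferroni: alpha / n_tests, e.g.
0.05 / 137,168 = 3.65e-7 for a full 450K-scale scan.

A covariate column that is constant (e.g. age in a degenerate subset) is
dropped from the design with a warning; a test on a dropped column reports a
zero likelihood ratio and P = 1 by convention. Samples with missing age or
sex are removed globally before the scan (complete-case) — no imputation.

## QC chain

* beta = I_m / (I_u + I_m + alpha); M = log2((I_m + alpha)/(I_u + alpha)).
  The offset alpha defaults to 100, the platform convention (configurable).
  With alpha = 0, M is exactly logit2(beta); beta-to-M conversion clamps
  beta in {0, 1} to [1e-6, 1 - 1e-6] with a warning rather than emitting
  infinities.
* Detection filter: a probe is dropped when its detection P is >= 0.01 in
  strictly more than 5 % of samples.
* Exclusion list: user-supplied probe ids (cross-reactive probes and
  polymorphic CpGs); the published lists are citations, not shipped content,
  so an empty list is valid.
* Range filter: a probe whose beta range (max - min across samples) is
  strictly below 0.17 is dropped; a range of exactly 0.17 is retained
  (literal reading of "ranged < 0.17 excluded"). 0.17 is the smallest beta
  difference the platform reliably discriminates.
* The three filters commute; the retained set is order-independent
  (property-tested).
* Quantile normalization (optional, off by default) maps every sample column
  onto the mean of order statistics, ties receiving the mean of their
  spanned quantiles. Color-bias adjustment and BMIQ probe-type correction
  are *not* reimplemented: real inputs are expected to be pre-normalized
  beta values.

## Cell-type deconvolution

Bulk blood beta values at discriminating probes are modeled as a non-negative
mixture of six reference profiles (monocytes, granulocytes, CD8+ T, CD4+ T,
NK, B). Per sample we solve min ||R w - b|| s.t. w >= 0 (scipy NNLS) and
rescale w to sum to one — equivalent in contract to the constrained
quadratic-programming formulation of the standard reference-based estimator,
with a smaller dependency surface. A collinear reference degrades to a
pseudo-inverse fit with clipping, under a warning. Granulocytes (the largest
blood fraction) are dropped by default when forming the five covariate
columns; the choice is configurable and, because the six proportions sum to
one, the fitted model is invariant to it (property-tested).

## aDMC calling

Significant probes are sorted within each chromosome and chained: a new
candidate starts when the gap to the previous significant site exceeds
10 kb (<= 10,000 bp joins, boundary inclusive). For each candidate, the
probe-density ("array bias") correction counts **all post-QC probes** whose
position falls in the inclusive [min, max] span of the candidate's members;
the candidate is an aDMC when that count is >= 10 and the significant
fraction is >= 50 %. Direction is positive/negative when every significant
member's slope shares the sign, else varying (an exactly zero slope counts
as neither sign and forces varying, with a warning); the three labels
partition the cluster set.

Two published descriptions of the adjacency rule differ: "clusters are
formed if two positions are within 10 kb of each other" (chained,
consecutive-pair — what the clusterMaker-style algorithm does) versus "the
distance between any pair ... no greater than 10 kb" (all-pairs, which
bounds the total span). The chained rule is the default because it describes
the algorithm actually used; `all_pairs=True` provides the stricter variant.

## Differential aging by MetS status

MetS (adult ATPIII classification) is a 0/1 input; children have no status
and are excluded. Three nested ML fits per probe, all retaining the kinship
random effect (the conservative, internally consistent choice; a
`use_kinship=False` OLS mode exists for comparison):

* pooled: M ~ age + covariates -> beta_age_all,
* additive: M ~ age + MetS + covariates -> LRT of the MetS term =
  p_diff_intercept (equal-intercepts test),
* interaction: M ~ age + MetS + age x MetS + covariates -> LRT of the
  interaction = p_diff_slope (equal-slopes test); the non-MetS slope is the
  age coefficient, the MetS slope adds the interaction coefficient.

Both P values are reported separately (the published candidate-gene table
shows one "P_diff" without stating which comparison; reporting both avoids
guessing). Nominal 0.05 is used for candidate probes, without multiplicity
correction, matching the candidate-screen design. Groups smaller than 5 are
flagged unreliable; a constant indicator (one group empty) is an error, not
a silent answer. An opposite-sign flag fires when the two group slopes
disagree in sign.

## Enrichment

One-sided over-representation only: P(X >= k) for X ~ Hypergeom(N, K, n).
The default background is the set of genes carrying at least one post-QC
probe — the same array-coverage correction the cluster caller applies —
rather than a whole-genome annotation (available by flag). BH (FDR)
adjustment across sets by default, Bonferroni optional; the original web
tool's exact correction procedure is unspecified, so it is a configuration
choice rather than a guess. Gene sets are user-supplied GMT files; no
GO/KEGG content is shipped.

## Synthetic cohorts

The generator states a world resembling the cohort the method was designed
for, and keeps it fixed:

* 7 extended families, 4 generations, 2-3 offspring per mating; the first
  two children of each mating marry incoming founder spouses (guaranteeing
  sibling, avuncular, cousin, grand-avuncular and great-grandparent pairs),
  later children marry with probability 1/2. That yields ~180 individuals,
  on the order of the ~190-member, 7-family design. No inbred matings.
* Ages by generation: founders near 82, each later generation ~24 years
  younger with +-5-year jitter, clipped to [6, 85] — the cohort's span.
* MetS assigned to adults (age >= 18) at 24 % prevalence; undefined for
  children.
* 2,000 probes, 60 age-associated with |slope| uniform in 0.02-0.04
  M-units/year (the magnitude range of the published candidate-table betas)
  and 64 % positive (= 14,155 / 22,122, the observed directional
  imbalance); 36 of them sit in three planted 12-probe regions at 1 kb
  spacing (background probes are 20,001 bp apart, beyond the 10 kb rule);
  each region carries one slope sign so its direction label is known.
* 4 designated probes get MetS-specific slopes: MetS slope = -0.37 x
  non-MetS slope, the ratio of the headline published pair
  (-0.010 / +0.027), reproducing the slower-and-opposite pattern.
* Non-fixed variance: residual_sd (default 0.3 M-units, a typical residual
  scale for M values) is split by heritability_h2 (default 0.4, a free
  choice — per-probe variance components are not published for this design)
  into polygenic and iid parts; the polygenic draw uses the symmetric
  eigendecomposition square root of 2 Phi, robust to semidefiniteness.
  residual_sd = 0 is the exact noiseless limit (together with
  sex_effect_sd = 0 and cell_effect_sd = 0), under which OLS recovers
  slopes to machine precision — used as an oracle in tests.
* Cell proportions per sample are Dirichlet with mean at typical blood
  composition (granulocytes 60 %, CD4 15 %, ...; concentration 50) and act
  on probes through N(0, cell_effect_sd) loadings; a separate 60-probe
  6-type reference with uniform(0.05, 0.95) profiles plus sd-0.02 noise
  feeds the deconvolution stage. True proportions are emitted as truth.
* One global seed drives all stages through keyed, independent generator
  streams, so `simulate_pedigree(cfg)` standalone equals the pedigree inside
  `simulate_cohort(cfg)` and identical seeds give byte-identical files.

What the simulator does **not** emulate: two-color intensity chemistry,
probe type I/II differences, batch/chip effects, realistic genomic probe
spacing, age-dependent variance, or non-linear age trajectories. A green
end-to-end test therefore establishes the statistical machinery
(calibration, recovery, cluster logic) under the stated model, not
robustness to array artifacts.

## Numerical choices

* Kinship: exact rational arithmetic emerges from the recursion on floats
  (powers of two), so relationship-class checks are equality, not
  approximate.
* PSD tolerance for 2 Phi eigenvalues: -1e-8 (clipped to zero below that in
  magnitude).
* h2 search: scipy bounded Brent, xatol 1e-8; profiled sigma^2 floored at
  the smallest positive float to keep the log-likelihood finite on exact
  fits.
* LRT statistics are floored at 0 (numerical jitter can make the restricted
  fit infinitesimally better); zero statistic reports P = 1.
* Cluster boundary: distance <= 10,000 bp joins (inclusive); beta-range
  boundary: exactly 0.17 retained; detection boundary: exactly 5 % failing
  retained.

## Known limitations

* ML variance components are biased at small n; heritability output is a
  nuisance parameter here, not a scientific estimate.
* The scan is serial per probe; a 450K-scale run is feasible (~2 ms/probe)
  but not optimized for it.
* Cohort-scale published counts (22,122 significant sites, 290 clusters,
  specific pathway P values) depend on undeposited data and database
  versions; they are design context, not reproduction targets.
* The two published aDMC totals (246 in one section, 290 elsewhere) cannot
  be reconciled without the original data; the caller's criteria follow the
  stated definition and the discrepancy is simply documented.
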