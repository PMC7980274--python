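# Methods

This note documents the models and estimators implemented in `panmix`,
the choices made where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Data model and filtering

The working object is a diploid genotype matrix (individuals x biallelic
SNPs, ALT-allele counts 0/1/2 with missing entries) with per-site and
per-sample metadata; the chromosome label doubles as the RAD-locus
label. Filtering runs in a fixed order so removal counts are
reproducible: genotype calls failing GQ < 30 or DP < 8 are set missing,
non-biallelic/indel records are dropped, sites below MAF 0.01 (computed
on called alleles only) are dropped, then sites and finally individuals
above 10% missingness. The order of the two missingness cuts is not
dictated by anything in the underlying protocol; sites-before-individuals
was fixed arbitrarily and documented. Filtering is idempotent, which
the tests check.

## Panmixia battery

* **Kinship** — the KING-robust between-family estimator,
  phi = (N_het,het − 2 N_oppHom) / (N_het(i) + N_het(j)) over jointly
  called sites. Self-pairs evaluate to exactly 0.5; unrelated pairs
  scatter around 0. One member of each pair above 0.177 (the
  first/second-degree midpoint) is removed — the member with more
  missing genotypes, ties broken to the lexicographically larger id.
  Which member the original workflow removed is unknowable from the
  outputs; any deterministic rule yields the same downstream counts.
* **PCA** — missing genotypes mean-imputed per site, sites centred and
  scaled by sqrt(p(1−p)), eigendecomposition of the individual
  covariance. "Visually removing outliers" is replaced by a
  deterministic rule (|PC1 or PC2 score| > 6 SD, iterated), because a
  testable pipeline cannot depend on eyes. Note a single outlier can
  contribute at most sqrt(n−1) SDs to the component it dominates, so
  the 6-SD rule is only able to fire for n > 37 — appropriate for the
  ~150-sample datasets this targets.
* **Diversity** — per colony: H_O is the mean per-site heterozygote
  fraction among called genotypes; H_E uses 2p(1−p) with the 2n/(2n−1)
  small-sample factor; F_IS = 1 − sum(H_O)/sum(H_E) over sites with
  H_E > 0 (a global ratio; a per-site-averaged F_IS differs only in
  weighting and was not used).
* **F_ST** — Weir & Cockerham's (1984) theta for each pair of groups
  with n >= 3, as a ratio of sums of the a/(a+b+c) variance components
  over sites. Slightly negative estimates are kept (a known property of
  the estimator, not an error). The Mantel plot can use raw F_ST or the
  linearized F_ST/(1−F_ST); raw is the default.
* **Tajima's D** — pi and Watterson's theta accumulate per site at the
  site's called allele count (so missing data change the weights, not
  the validity), and the variance normalization evaluates the classical
  constants at the harmonic-mean sample size. With complete data the
  statistic reduces to the textbook formula exactly (tested to 1e-12);
  the published description of the missing-data correction is not
  detailed enough to guarantee agreement in the missing-data case, so
  the complete-data limit is the contract. The CI is a bootstrap over
  sites; the p-value compares |D| against neutral constant-size
  datasets with matched S and matched per-site n, site frequencies
  drawn from the 1/k law (an independent-sites approximation, noted
  since linked sites within loci make it slightly anti-conservative).
* **Mantel** — great-circle (haversine, R = 6371 km) distances between
  colony coordinates; one-sided (greater) permutation test via
  scikit-bio. Under the null its p-values are uniform (KS-tested).

## Expected SFS under epoch models

For m sampled haplotypes under any single-population history, the
expected unfolded spectrum is xi_j ∝ sum_k k E[T_k] P(j|k,m) with
P(j|k,m) = C(m−j−1, k−2)/C(m−1, k−1). E[T_k] — the expected time while
k ancestral lineages exist — is computed exactly for piecewise-constant
histories by integrating the lineage-count pure-death process: within
an epoch the occupancy integral is read off a block matrix exponential
([[Q, I], [0, 0]]), and the infinite ancestral epoch contributes
P(A >= k)/lambda_k. This is numerically robust where the classical
spectral (alternating-sum) formula for P(A(t)=k) catastrophically
cancels at m ~ 38. At theta = 1 the constant-size model reproduces the
1/j law to 1e-14, and a time-change to nu = 1 reproduces it for the
two-epoch model — both are tests. A diffusion-PDE solver is
deliberately not used: for these models the coalescent expectation is
exact, and the Monte-Carlo backend plays the role of the independent
cross-check (the two backends agree within 3 MC standard errors in the
tests, and independently against msprime's branch-mode AFS).

The **Monte-Carlo backend** simulates genealogies: standard-exponential
interval variates mapped through the inverse time-rescaling of the
history, and random Kingman merge topologies; mutations weight branches
by length, so E[xi_j] is the mean over genealogies of
0.5 sum_k T_k x (branches subtending j). The same genealogy set (fixed
seed) is reused for every parameter evaluation — common random numbers —
so the optimizer sees a smooth surface. Default 100,000 genealogies per
evaluation; the recovery experiments use 10,000, which costs ~25 ms per
evaluation after a one-off topology precomputation.

## Likelihood, fitting, model choice, scaling

The multinomial log-likelihood over unmasked folded bins (bin 0 — the
projected-monomorphic mass — is masked) omits the data-only additive
constant; theta is profiled analytically as sum(x)/sum(M). Fits run a
Nelder-Mead simplex on log10 parameters from 50 log-uniform random
starts (nu in [1e-3, 1e2], T in [1e-4, 5]); all replicates are kept.
The three-epoch fit can be seeded additionally with the two-epoch MLE
(nu, T/2, nu, T/2), which enforces the nesting inequality by
construction. Nested models are compared by chi-square LRT; because
SNPs within a RAD locus are linked this is a composite likelihood and
the LRT is anti-conservative in principle — it is retained as the
field-standard procedure, and the recovery experiments show it behaves
well at these data scales. Scaling: Ne_anc = theta_hat/(4 mu L), sizes
nu Ne_anc, times 2 Ne_anc T generations, times g for years
(mu = 4.6e-9, g = 2 y, L = 60,429,389 bp by default; Ne and times scale
exactly as 1/mu, the basis of the mutation-rate sensitivity check).
The grid search evaluates a 100x100 log10-even (nu, T) lattice and
reports the min/max of each parameter over {delta LL <= 5}, flagged
open when the region touches the grid edge.

## ABC scenario ladder

Scenarios are event structures (expansion, single or double
contraction) with log-uniform priors on diploid sizes (1e2–1e6) and
uniform event times within a window; ordering constraints make the
structure (post < pre, etc.) hold by construction. No canonical prior
exists for this kind of scenario test; the log-uniform default is
scale-free and covers the plausible range of songbird population sizes,
and both bounds and windows are configurable. Four summary statistics per simulated dataset
(proportion of monomorphic loci; Nei's unbiased gene diversity
n/(n−1)(1 − sum p²) at each locus's most variable site: mean and
variance over polymorphic loci, mean over all loci) are standardized by
pooled SD; the direct posterior is the scenario composition of the
nearest 1% of simulations (tolerance configurable), the logistic
posterior a multinomial logistic regression on the retained set
evaluated at the observed point. Whether gene diversity should be
scored per SNP or per RAD locus is ambiguous in the source material;
per locus was adopted as that is what the DIY-ABC locus model computes.

At desk scale (hundreds to thousands of simulations, ~200 loci, ~25
diploids instead of 100,000 / 1,000 / 153) the contraction-vs-expansion
and single-vs-double rounds resolve, and cross-validation assigns
pseudo-observed datasets to their true scenario well above chance; the
four timing windows, however, are only weakly separated by these four
statistics at this budget, so the timing round's posterior is reported
but not asserted in tests.

## LD-based contemporary Ne

r² between SNPs on different loci uses Burrows' composite
disequilibrium Delta (sample covariance of genotype scores / 2 with the
n/(n−1) factor) normalized by Weir's (p(1−p) + D_A) terms, where D_A is
the within-locus Hardy–Weinberg departure. This composite form is the
one whose null sampling expectation matches the published large-sample
correction 1/S + 3.19/S² (S >= 30) — with plain p(1−p) denominators the
subtraction is off by a noticeable fraction of the drift signal
1/(3Ne) when Ne is in the thousands. Missing data are handled per pair
(pairwise-complete individuals), S is the harmonic mean of per-pair
sizes, pairs are weighted by their sample size, and
Ne = (1/3 + sqrt(1/9 − 2.76 r²_drift))/(2 r²_drift); non-positive drift
(or a negative discriminant) reports infinity. CIs are a
delete-one-locus jackknife on the weighted mean r², transformed through
the monotone estimator. The small-sample (S < 30) correction branch is
not implemented, and "unlinked" is proxied by distinct locus labels, as
appropriate for scattered RAD loci.

## Synthetic-data generators

The coalescent generator samples genealogies per locus (continuous-time
Kingman with piecewise-constant rates via time-rescaling — exact, and
appropriate because N >> sample size throughout), places Poisson
mutations on branches under infinite sites within a locus, pairs
haplotypes into diploids, and adds MCAR missingness, random colony
labels/coordinates (panmixia is true by construction), and optional
parent-offspring pairs by Mendelian transmission from one sampled and
one unsampled parent. Multiple SNPs per locus share a genealogy, giving
realistic within-locus LD for the per-locus ABC statistics. The forward
Wright–Fisher generator (random mating with selfing — the model the LD
corrections assume; Ne equals census N) transmits one random allele per
parent per unlinked locus, drops loci fixed at sampling, and defaults
to 1/x-shaped initial frequencies. Checks: n=2 pairwise diversity
= 4 N mu, E[TMRCA] = 2N, heterozygosity decay (1 − 1/(2Ne)) per
generation, allele-frequency martingale, and SFS agreement with the
analytic backend and with msprime.

## Experiment scales

The recovery experiments run at sizes chosen for a single CPU: spectra
at a 10 Mb callable length (~125k SNPs instead of the ~700k a 60.4 Mb
genome scan yields — the estimator's bias does not depend on S, only
the replicate scatter does), 10 replicates with 50 optimizer starts
each, 10,000 genealogies per MC evaluation, and Wright–Fisher
populations of 3,100 with ~1,200 post-MAF SNPs. Synthetic data are
idealized in ways real RAD data are not: no genotyping error or allele
dropout, MCAR (not coverage-correlated) missingness, truly unlinked
loci, no population structure, and exactly known mutation rate. Passing
recovery therefore demonstrates correctness of the estimators and the
internal consistency of the pipeline — not robustness to the model
violations (cryptic linkage, overlapping generations, mutation-rate
error) that dominate the uncertainty of real-data estimates.

## Known limitations

* The Tajima's D missing-data recipe is pinned only by its
  complete-data limit; other reasonable per-site weightings differ at
  the third decimal under heavy missingness.
* The chi-square LRT on composite likelihoods is anti-conservative;
  with ~10^5 unlinked synthetic SNPs this is immaterial, but on real
  RAD data with intra-locus linkage the stated p-values overstate
  certainty.
* ABC timing windows are under-identified at desk budgets (above).
* The LD-Ne small-sample branch (S < 30) and overlapping-generation
  corrections are out of scope.
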