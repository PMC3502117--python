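# Methods

`poolgen` implements the statistical machinery of an individual-participant-data
(IPD) pooled analysis of candidate-gene case-control studies: K independent
studies each contribute subject-level outcomes, genotypes at named variant
sites, phenotypes and exposures; the package harmonizes them onto a common
schema, QCs the genotypes, estimates per-study and pooled genotype-disease
associations under random-effects models, searches for joint gene-phenotype
risk rules, and plans sample sizes. This note records the models, the
defaults and why they were chosen, and what the bundled synthetic data does
and does not establish.

## The two-stage random-effects model

Stage one fits, separately in each study k, an ordinary logistic regression

    logit P(Y_ik = 1 | X, Z) = alpha_k + beta_k X_ik + gamma_k' Z_ik,

where X is the genetic exposure under a chosen inheritance model (dominant
carrier indicator by default) and Z_k is a *study-specific* confounder set —
pooled studies rarely share covariates, and the two-stage formulation is
exactly what makes that harmless. Estimation is maximum likelihood
(`statsmodels` Newton/IRLS); the exposure variance comes from the inverse
observed information. Separation (|beta| > 15 or non-convergence within 100
iterations) flags the study; for univariable fits a 0.5
continuity-corrected 2x2 estimate can be substituted instead
(`separation="continuity"`).

Stage two assumes the estimated log-ORs vary as

    beta_hat_k = beta + b_k + e_k,   b_k ~ N(0, sigma2_b),   e_k ~ N(0, sigma2_k),

and pools with inverse marginal-variance weights w_k = 1/(sigma2_k +
sigma2_b):

    beta_hat = sum(w_k beta_hat_k) / sum(w_k),   var(beta_hat) = 1 / sum(w_k).

Two estimators of sigma2_b are provided:

- **moment** — DerSimonian-Laird: sigma2_b = max(0, (Q - (K-1)) /
  (sum v - sum v^2 / sum v)) with v_k = 1/sigma2_k and Q the fixed-effect
  heterogeneity statistic. We floor at zero (the usual convention; note
  `statsmodels.combine_effects` reports the unfloored moment value, which
  the tests account for).
- **pml** — an iterated weighted moment equation, sigma2_b <-
  sum(w_k^2 [(beta_hat_k - beta_hat)^2 - sigma2_k]) / sum(w_k^2), weights
  refreshed each step, floored at zero, tolerance 1e-8, at most 200
  iterations. The pseudo-maximum-likelihood family is named in the
  literature without a canonical closed form; this fixed-point
  interpretation is documented here as this package's definition and
  coincides with DL in the homogeneous case.

Heterogeneity is summarized by Cochran's Q against chi-square(K-1) and
I2 = max(0, (Q - df)/Q) x 100%. Meta-regression regresses beta_hat_k on
study-level covariates by weighted least squares with a method-of-moments
residual sigma2_b (the usual trace-corrected extension of DL, fixed-effect
weights in the residual Q), refit once after the variance update. Egger's
test regresses beta_hat_k/se_k on 1/se_k by OLS with a K-2-df t-test on the
intercept. The Breslow-Day homogeneity test uses the Mantel-Haenszel common
OR, per-stratum expected counts from the standard quadratic, and the Tarone
correction; it matches `statsmodels.StratifiedTable.test_equal_odds(adjust=True)`
to machine precision in the tests.

## The one-stage alternative

`fit_one_stage` maximizes the marginal likelihood of the random-slope
logistic model

    logit P(Y_ik = 1 | X) = alpha_k + (beta + b_k) X_ik,   b_k ~ N(0, sigma2_b),

integrating b_k out by Gauss-Hermite quadrature (21 nodes by default; the
integrand is smooth and unimodal at these scales, and doubling the nodes
moves the log-likelihood by < 1e-6 on the test problems). sigma_b is
parameterized on the log scale with a floor near 2e-4 so the optimizer can
approach but not cross zero. By default every study gets its own fixed
intercept: under case-control sampling the intercept absorbs the
design-determined case fraction, so a shared intercept is statistically
wrong for pooled case-control data; a `strict_common_intercept` flag
restores the single-alpha textbook form for comparison. The reported SE of
beta is from the numerical second derivative at the optimum with the other
parameters held fixed; it slightly understates uncertainty when intercepts
and slope are correlated, and the two-stage SE is preferred for formal
inference.

The one-stage route is the first-choice model when all studies share
covariates; the two-stage route is preferred when covariate availability
differs by study (which the missing-by-design generator reproduces), and
the two agree asymptotically — a property the tests check directly.

## Harmonization rules

Sun exposure is standardized to hours/day on [0, 6]:

- m ordered classes map to 6(j-1)/(m-1) for class j — the four-class
  instance (never/seldom/often/always -> 0/2/4/6) fixes the two endpoints,
  and linear spacing is the minimal generalization between them;
- other continuous codings (days/year, hours/year) are rescaled by
  x_hat_i = nu * x_i / mu, where mu is the study mean over non-missing
  values and nu is the subject-weighted mean of the studies natively coded
  in hours/day, then capped at 6. nu deliberately uses native hours/day
  studies only, to avoid the circularity of recoded studies feeding their
  own reference; an override is available. mu uses non-missing subjects
  only, and missing exposures stay missing (complete-case downstream —
  imputation of missing-by-design covariates biases against the complete
  cases, which is the very reason the two-stage route exists);
- exposures reported over several time periods are averaged weighting by
  years per period;
- class-interval variables (e.g. nevus counts) recode to interval
  midpoints, with an explicit maximum required for the open top category.

Subject exclusions (multiple-primary cases, all genotypes missing,
non-skin melanoma, atypical-mole-syndrome non-cases, non-first-primary
cases, familial cases — two or more first-degree or three or more
any-degree affected relatives — and invalid status) apply in that fixed
order with first-match-wins, so per-rule counts are disjoint and the audit
log reconciles exactly: initial = final + sum(removed), asserted on every
run.

## Genotype QC and haplotypes

HWE is tested per variant by the 1-df Pearson chi-square with the allele
frequency estimated from the same counts, among controls and per study
(controls only, because case enrichment distorts genotype proportions under
a true effect; the pipeline driver enforces this). No exact test is
provided; a small-expected-cell flag (< 5) marks results whose asymptotic
p-value is unreliable.

Haplotype frequencies over L sites come from the standard EM for unphased
diplotypes: the E-step distributes each multi-site heterozygote over its
compatible haplotype pairs proportional to current pair probabilities, the
M-step re-estimates frequencies from expected counts. Convergence is
max |delta f| < 1e-8 or 5000 iterations; 5 restarts (the first at linkage
equilibrium, the rest Dirichlet(1), seeded) keep the best final
log-likelihood. The log-likelihood path is stored and its monotone
non-decrease asserted in tests; when no subject is heterozygous at two or
more sites the EM answer equals direct counting exactly, and on ambiguous
toys it dominates a 0.01-step grid over the frequency simplex.

The variant classification table (e.g. strong-"R" vs weak-"r" alleles) is
user-supplied semantics: the package ships no default claim about which of
the nine canonical variants is which, only the machinery to score them.

## Logic regression

Boolean trees over binary predictors enter a logistic model
logit P(Y=1) = alpha + sum_j beta_j L_j and are scored by binomial deviance.
Scoring exploits the fact that n subjects collapse onto at most 2^k
distinct tree-evaluation patterns, so each annealing step refits a tiny
aggregated GLM; fitted linear predictors are capped at +-30 so perfectly
predictive trees score ~0 deviance with a flag rather than diverging.

The annealer uses the six standard moves (alternate leaf, alternate
operator, grow/prune branch, split/delete leaf), Metropolis acceptance
exp(-delta/T), and geometric cooling with ratio rho = 0.999 over a default
50,000 iterations; T0 is auto-tuned from a 60-move pre-pass so early uphill
acceptance is about 0.9. Defaults of at most 2 trees and 8 leaves per tree
bound the search space. Everything is deterministic given the schedule
seed, including cross-validation folds and permutations.

Two points deserve emphasis:

- **Rule identity is up to complement.** (L, beta) and (not-L, -beta) are
  the same fitted model, so De Morgan rewritings (e.g. `X1^C AND X2^C`
  found for a planted `X1 OR X2`) count as recovering the rule;
  `trees_equivalent` implements this and the recovery experiments use it.
- **In-sample deviance always prefers larger trees**, so the annealer is
  run at a size bound and model *size* is chosen by stratified
  cross-validation with the one-standard-error rule; overall signal is
  tested by re-running the search on permuted outcomes, p = (1 + #{permuted
  best <= observed best}) / (permutations + 1).

`exhaustive_search` enumerates all expressions up to 3 leaves (deduplicated
by truth table over the observed rows, guard 10^4 candidates) and serves as
an exact optimizer: the annealed deviance can never legitimately undercut
it, and tests assert it does not. Ties break toward smaller trees, then
lexicographic canonical serialization, making results reproducible.

## Power and sample size

Main effects use the classical log-OR method with Woolf variance (see the
`power` module docstring for the formula). Interactions use the Woolf-type
variance of the interaction log-OR in the 2x2x2 design — the sum of
reciprocal expected cell probabilities among cases and controls, with gene
and environment independent among controls and case cells tilted by the
main-effect and interaction ORs. Both are cross-checked by
`power_by_simulation`, which draws case-control samples under the same
generative model and counts Wald rejections (0.5 continuity correction on
zero cells); analytic sizes land empirical power within a few points of
nominal across the tested grid (carrier 3-16%, ORs 1.5-2.0). Published
sample-size figures for comparable designs were produced by external
programs under assumptions that are not recoverable, so they are treated as
order-of-magnitude context only, never as test expectations.

## The synthetic-data generator

`generate_multistudy` inverts the one-stage model: per study, a source
population of `source_multiplier` x the requested cases (default 20x) is
simulated with HWE genotypes at the configured allele frequencies (defaults
span rare 1-2% and common 8-10% sites), disease drawn from
logit(p) = alpha_k + sum_v (beta_v + b_kv) carrier_v + sum_c gamma_c Z_c
with b_kv ~ N(0, sigma_b^2), and the requested numbers of cases and
controls sampled without replacement — preserving the OR interpretation
under case-control sampling. Study intercepts are N(0, 0.3^2) on the
case-control scale (baseline variation without touching ORs). Defaults:
8 studies of 300 cases/500 controls, beta = log 1.5 per variant,
sigma_b = 0.15 — the scale of effect and heterogeneity a pooled
candidate-gene analysis is designed around.

Phenotypes are genotype-correlated: red hair probability 0.4 for carriers
of a designated variant (R151C by default) vs 0.08 otherwise; fair skin
probability increases with total variant burden; nevus counts are negative
binomial (mean ~18); freckling is commoner in carriers. No distributional
choices here are empirical claims — they are declared defaults that give
the stratified and logic-regression machinery realistic structure to find.
Exposure is generated as a latent hours/day value (gamma, clipped to
[0, 6]) and delivered per study as hours/day, four ordered classes, or
days/year (a fixed 52x linear scale), cycling across studies by default.
`degrade` adds missing-by-design covariates, excess homozygosity via an
inbreeding-style coefficient (redrawing genotypes, which severs that
study's genotype-outcome link — it is a QC fixture, not an epidemiological
scenario), and coding switches. `plant_logic_outcome` replaces the outcome
with one driven by a known Boolean rule for recovery experiments.

What passing tests on this generator do *not* show: robustness to
confounding structures the generator lacks (population stratification,
differential genotyping error between cases and controls, linkage
disequilibrium between sites, selection/participation bias correlated with
genotype), to misclassified outcomes, or to real pigmentation genetics —
sites are drawn independently, so haplotype structure is degenerate by
construction.

All randomness flows from one integer seed through
`numpy.random.SeedSequence.spawn`, so equal seeds give byte-identical
datasets and every pipeline stage is replayable.

## Problem sizes used in the checks

The test suite and the acceptance script size their simulations to run on
one CPU in a few minutes while keeping Monte-Carlo error well inside the
asserted tolerances: 500 replicates for CI coverage (K=20 studies of 250
cases/250 controls at the effect level), 20 seeded annealing runs of 4,000
iterations at n=5,000/p=12 for rule recovery, 10 small instances against
the exhaustive oracle, 1,000 replicates per point of the power grid, and a
10-study end-to-end pipeline recovery. Larger runs reproduce the same
behaviour with tighter intervals.

## Known limitations

- No exact HWE test and no exact conditional logistic regression for
  matched sets.
- The PML variance estimator is a documented fixed-point interpretation,
  not a likelihood maximizer; profile-likelihood or REML variants are not
  implemented.
- The one-stage model supports a random slope on one exposure at a time.
- Logic regression implements the binomial deviance score only, and the
  exhaustive oracle stops at 3 leaves.
- `fisher_exact_rx2` enumerates r x 2 tables only (dynamic pruning keeps
  moderate margins tractable; a guard suggests Monte-Carlo beyond that).
- Multiple-testing control across variants is left to the caller
  (per-variant results are reported unadjusted by default).
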