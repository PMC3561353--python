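# Methods

## The experiment being modelled

Three origins of Atlantic salmon — farmed, wild, and F1 hybrids produced by
crossing farmed dams with wild sires — are represented by 10, 10 and 9
full-sib families. Because the hybrids reuse the farmed dams and wild sires,
each hybrid family is a maternal half-sib family of one farmed family and a
paternal half-sib family of one wild family; the additive relationship matrix
therefore contains 0.25 entries linking hybrid offspring to the
corresponding pure-family offspring. All families are reared communally in
four tanks, two under standard hatchery conditions (control) and two under a
repeated acute stressor (stress). At termination ~550–565 fish per tank are
weighed, measured and genotyped at six microsatellite loci for family
assignment.

## Synthetic data generator

Phenotypes follow, on the log10-gram scale,

    log10 W = mu[group, treatment] + tank + a_i + e
    tank ~ N(0, V_tank),  e ~ N(0, V_E[treatment])
    a_parent ~ N(0, V_A[parent's group])
    a_offspring = (a_sire + a_dam)/2 + N(0, V_A[family group]/2)

The Mendelian-sampling variance V_A/2 treats parents as non-inbred founders.
For hybrid families the parental term is inherited from the farmed-dam and
wild-sire distributions, so the *realized* between-family additive variance
of hybrids is (V_A_farm + V_A_wild)/4 regardless of the hybrid V_A
parameter, which only scales the within-family (Mendelian) part. This is a
structural property of the half-sib design, not a tunable choice; it caps
the wild:hybrid contrast in realized V_A at 2:1.

Defaults (chosen once):

- `mu_logw` is back-computed from published group-by-treatment mean weights
  of such an experiment (11.98/8.10 g wild, 22.85/17.19 g hybrid,
  35.08/27.77 g farmed for control/stress) via the log-normal identity
  `E[W] = 10^mu * exp(ln(10)^2 V_P / 2)`, so simulated cell means are
  unbiased for those targets at any variance setting.
- `V_A = {farm 0.002, hybrid 0.004, wild 0.016}` and
  `V_E = {control 0.012, stress 0.014}`, `V_tank = 0.0005` (all log10²
  units). These give realized additive variances ordered farm < hybrid <
  wild and cell heritabilities in the 0.1–0.6 range reported for growth in
  salmonids, with wild highest. Because `V_E` varies only by treatment, the
  group-specific phenotypic variances of the real data (wild noisiest)
  cannot all be matched simultaneously; means are matched exactly,
  variances only in magnitude.
- Genotypes: six loci with 10 equifrequent alleles (microsatellite-like
  diversity), genotyping-error rate 0.001 per locus (the marker panel is
  reported to be very clean), and a 70/2256 ≈ 3.1% per-fish trisomy rate.
  Trisomy duplicates one *inherited* allele at one locus, so trisomic fish
  remain compatible with their true parents — matching the decision to keep
  trisomic fish in the data set.
- Condition factor: length is back-computed from weight through Fulton's
  K = 100·W/L³ with K ~ N(1.28, 0.08²) per fish, the salmonid standard.
- Seeding: one master seed; each stage (pedigree, parent genotypes,
  offspring genotypes, phenotypes) draws from its own `SeedSequence`
  substream, so stages are independently reproducible.

What the generator does *not* emulate: maternal/common-environment effects,
egg-size carry-over, mortality, growth trajectories through time,
competition and size hierarchies within tanks, linkage between loci, and
family-by-treatment genetic covariance below 1 (family effects are perfectly
correlated across treatments unless group means differ). Passing tests on
this generator therefore validate the estimation machinery, not these
real-data complications.

## Parentage assignment

Strict exclusion: a parental pair is compatible with an offspring only if
every locus can be explained by one allele from each parent. One
incompatible locus excludes the pair (`max_mismatch_loci` can relax this).
A three-allele (trisomic) locus is compatible if its alleles partition as
one allele from one parent plus two (with repetition) from the other — a
documented rule chosen so that duplicated parental alleles never exclude
true offspring; the program used in the original workflow does not describe
its trisomy handling. Missing loci are wildcards, logged as
reduced-evidence. Ties are never broken: fish compatible with ≥2 families
are reported ambiguous, mirroring the removal of such fish from analysis.

## Reaction-norm mixed model

Response: log10 terminal weight. Fixed effects: treatment, origin ("type"),
interaction (treatment coded control=0, stress=1, so "slope" is the
stress-induced change). Family random structures: none; a random intercept;
a bivariate (control, stress) family effect with unstructured 2×2 covariance
shared across groups; or a group-specific 2×2 (block-diagonal "6×6")
version. An optional scalar tank effect models tanks nested in treatments.
Residual variance is homogeneous — treatment heterogeneity lives in the
family covariance.

Estimation profiles the REML deviance over the relative Cholesky factor of
the random-effect covariance (penalized least squares on precomputed
crossproducts), optimized by L-BFGS-B from three starts with a Nelder-Mead
polish; tolerance on the profiled deviance ~1e-13. The single-parameter
(intercept) path is polished to agree with closed-form balanced-ANOVA
components to better than 1e-6 relative error, and the 2×2 path reproduces
lme4 fits to all printed digits on test data. Singular fits (a zero variance
or |correlation| = 1) are returned with a boundary flag, not an error.

AIC = −2·REML-loglik + 2·(fixed + covariance + residual parameters), ranked
ascending with ties broken by parsimony. Comparing REML AICs across models
with different fixed effects is statistically awkward (the restricted
likelihoods live on different contrast spaces) but is replicated as-is
because it is the selection procedure the analysis defines.

F statistics use type-II sums of squares (each term tested against the model
containing all terms not including it) from GLS residual sums at the
estimated covariance, scaled by the REML residual variance. The anova
decomposition type is not stated in the source analysis; type II is the
package's choice and is noted here. Denominator degrees of freedom follow
the study's own rule `df2 = N − k`, with N the smallest group-by-treatment
cell size and k the tested factor's level count (numerator df = k − 1);
pairwise two-group re-fits keep the N of the full data set, as the printed
F subscripts do. Under the generator's null (parallel slopes) the
interaction test's empirical size at α = 0.05 is within [0.03, 0.08] (500
replicates in the acceptance suite) — the bespoke df convention is close to
calibrated at these sample sizes because the family-slope variance is
estimated near zero there.

## Performance ratio

For each family, four points: both stress-tank summaries divided by both
control-tank summaries, ratio = mean log10 weight (stress tank) / mean log10
weight (control tank), plotted against the raw mean control-tank weight.
The ratio uses the mean of log weights; the x-axis uses the raw mean (both
modes are exposed via `ratio_mode`). Tank means must exceed 1 g — below
that, log10 changes sign and the ratio is meaningless; real data are an
order of magnitude above this. The simulated null draws n = 120 independent
(control, stress) values around fixed treatment means with SD = 10% of the
mean and correlates ratio with the control draw: because the control value
enters the denominator, the null correlation is negative
(d/dc [log s / log c] < 0), so only a *positive* observed correlation
indicates that heavy families genuinely resist stress better. Which means
seed the null is configurable; the default is the observed treatment means.

## Animal model and heritability

One univariate animal model per group × treatment cell:
`y = mu (+ tank) + a + e`, `a ~ N(0, V_A A)`. A and its sparse inverse are
built from the pedigree by the tabular method and Henderson's rules
(inbreeding-aware; a fast path skips the O(n²) inbreeding computation for
two-generation pedigrees). `h² = V_A / (V_A + V_E (+ V_tank))` per sample.

The Gibbs sampler updates all breeding values in one Gaussian block: with
individuals that are nobody's parent ordered first, the full-conditional
precision matrix has a diagonal leaf block, so sampling costs one dense
Cholesky of the (small) parental block per iteration. Variance components
use scaled-inverse-chi-squared full conditionals with weakly informative
priors: scale = partition·V_P (partition 0.5, V_P estimated from the data)
and belief ν = 0.002; an optional tank component gets 5% of V_P as its
scale. Because each fish has a single record, centered Gibbs alone can
stall on the V_E → 0 ridge (breeding values absorbing the residual); an
interweaved non-centered move — treating sqrt(V_A) as a regression
coefficient on the whitened breeding values, Metropolis-corrected for the
prior — restores mixing and removes the trap.

Desk-scale defaults are 20,000 iterations, 2,000 burn-in, thinning 10
(1,800 retained samples): the block updates mix fast enough (lag-1
autocorrelation of V_A ≈ 0.4–0.8 thinned) that the Monte-Carlo error on the
posterior mean h² is well under 0.02 at study-scale n. Production-scale
settings (millions of iterations) are available through `MCMCSettings`.
Summaries: posterior mean and KDE mode of h², 95% HPD interval (shortest
window over sorted samples), DIC = mean conditional deviance + p_D with
p_D = mean deviance − deviance at the posterior means, and lag-k
autocorrelations as the convergence check. Whether a point estimate should
be the posterior mean or mode is not fixed by the source analysis; the mean
is the default and the mode is reported alongside.

## Known limitations

- Cell-level heritability from 9–10 full-sib families is intrinsically
  noisy: HPD intervals are broad and the wild > hybrid ordering of h² is
  recovered in only ~60% of simulated replicates (wild > farm in
  essentially all), consistent with the structural 2:1 cap on the realized
  wild:hybrid V_A contrast noted above.
- Full-sib-only data cannot separate additive variance from
  maternal/common-environment variance; the generator contains none, real
  data usually do, so real-data h² would be inflated.
- The `N − k` denominator-df rule is a convention of the original analysis,
  not a derived approximation; its calibration is demonstrated under the
  generator's conditions only.
- DIC with deviance conditional on random effects has a large, noisy p_D;
  tank-effect selection by DIC is reliable only in aggregate (majority of
  replicates), not per data set.
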