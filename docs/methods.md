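# Methods

`famh2` estimates the narrow-sense heritability of a binary trait — and,
centrally, its difference between males and females — from registry-style
family data containing full-sibling and first-cousin clusters. It was
built around the design of large Scandinavian autism cohorts (children
followed to a fixed age, diagnoses from patient registers, pedigrees from
a multi-generation register), with a synthetic registry generator standing
in for register data that cannot be redistributed.

## The liability threshold model

Child *j* of group *i* carries a latent liability

    eta_ij = x_ij' beta + sigma_A(s_ij) A_ij + sigma_C(s_ij) C_ij + eps_ij

and is affected iff `eta_ij >= 0`. The pieces:

* `x_ij' beta` — fixed effects: sex (male = 1), birth-year category,
  parental-age categories, optionally gestational age, and sex
  interactions. These absorb the diagnostic threshold, so no separate
  threshold parameter exists.
* `A_ij` — additive-genetic factor, standard normal, correlated 0.5
  between full siblings and 0.125 between first cousins, 0 otherwise.
* `C_ij` — shared-environment factor, standard normal, correlated 1
  between full siblings, 0 otherwise.
* `eps_ij` — residual, iid standard normal. Its unit variance anchors the
  scale: all other parameters are expressed in residual standard
  deviations.
* `sigma_A, sigma_C` — non-negative scales, optionally sex-specific
  (`s_ij` is the child's sex). Sex-specific scales let the *variance* of
  liability differ between sexes while the latent factors themselves are
  shared: a brother and sister load on the same A with relatedness 0.5,
  each scaled by their own sigma. This is the minimal model in which
  "greater male variability" is expressible.

Heritability on the liability scale is

    h2(s) = sigma_A(s)^2 / (1 + sigma_A(s)^2 + sigma_C(s)^2)

and the marginal prevalence implied by a linear predictor is
`Phi(x'beta / sqrt(1 + sigma_A^2 + sigma_C^2))`.

## Pseudolikelihood over grandparent groups

Dependence is handled by partitioning the cohort into groups of
grandchildren of each grandparent couple. A child with both grandparent
couples known appears in exactly two groups, so the objective — the sum of
log group probabilities — is a composite (pseudo) likelihood, not a
likelihood. Consequences drawn in the code:

* The per-group term is the multivariate-normal rectangle probability of
  the observed affection pattern. Dimension 1 uses the normal CDF;
  dimension 2 a 64-node Gauss-Legendre reduction of the bivariate normal
  CDF (~1e-14 accurate); dimensions 3+ the separation-of-variables
  transform evaluated with scrambled Sobol points. Point sets are drawn
  once per group size from the configured seed and reused for every
  parameter value (common random numbers), which makes the objective a
  smooth deterministic function amenable to quasi-Newton optimization.
* Group probabilities depend only on the members' design rows, sexes,
  outcomes and relatedness matrices, so identical patterns are collapsed
  with multiplicity counts before evaluation. This is an exact algebraic
  rewrite — registry cohorts are dominated by all-control groups with a
  handful of distinct compositions — and is what makes national-registry
  sample sizes tractable on one CPU.
* Parameter uncertainty uses the sandwich estimator (bread: inverse
  observed information of the composite objective; meat: outer products of
  per-group scores), since the information identity fails for
  pseudolikelihoods. Scores and information are computed by central
  differences at the optimum.
* Confidence intervals for h2 are delta-method on the logit scale and
  back-transformed, keeping them inside (0, 1); the male-female difference
  uses the plain delta method with the full cross-sex covariance.
* AIC is `2k - 2 * log-pseudolikelihood` of the fitted objective, and is
  only compared between models fitted to identical row sets (models using
  gestational age drop rows with missing values, so their AIC column is
  not comparable to the others and the ladder omits those deltas).

The scale surface has a characteristic soft ridge: sibling pairs constrain
the full-sib liability covariance `s = 0.5 sigma_A^2 + sigma_C^2` tightly,
while only the rarer cousin pairs separate `sigma_A` from `sigma_C`. The
optimizer therefore works in a ridge-aligned parameterization — per sex,
`log s` and the logit of the additive share `f = 0.5 sigma_A^2 / s` —
with L-BFGS-B and exact central-difference gradients evaluated in a single
vectorized pass over the de-duplicated patterns. Starting values are data
driven: probit regression for the fixed effects, the sibling tetrachoric
for `s`, and a small set of candidate shares (the moment estimate
`4 r_cousin / r_sib`, a near-1 share, and an intermediate one) screened by
one batched likelihood evaluation. Because the surface flattens toward
share 1, a first fit that settles in the interior is re-optimized once
from the share-1 end and the higher pseudolikelihood kept. Alternative
`log sigma` / `log sigma^2` parameterizations are available and yield the
same heritabilities on well-identified data (tested). On small cohorts the
ridge is genuinely flat — point estimates there inherit real sampling
wildness, not optimizer noise — and the convergence and boundary flags
should be taken seriously.

## Cohort construction

Raw registry rows are filtered sequentially, counting removals per rule:
rows missing a parent identifier; births outside the configured window;
twins (same mother and birth date — zygosity is not in the schema, so all
multiple births are excluded); children whose parents are not flagged
native-origin; children not of each parent's first partnership (partner
order = birth date of the parent's earliest child, ties broken by partner
id); birth order above 3 within a mother; and children with no known
grandparent. The filter is idempotent. Half-siblings are retained but
carry relatedness (0, 0): single-partner filtering makes them rare and
their shared-environment correlation would be a modeling guess.

## The synthetic registry

The generator emulates a two-generation register: grandparent couples
produce 1-3 parents; parents pair across families; each pair has 1-3
children (configurable, including >3 and twin rates to exercise the
filters). Outcomes are drawn from the union pedigree: a child's A is the
mean of its parents' A plus Mendelian noise of variance 1/2, which yields
sibling/cousin correlations of exactly 0.5/0.125 and standard-normal
margins — children shared between two grandparent groups are simulated
once, so the data-generating process is a coherent joint distribution even
though estimation is by pseudolikelihood.

Defaults reproduce the study conditions the package models: 51.38% male
births; prevalence 1.51% (male) / 0.80% (female), rising by birth cohort
from 0.46% (1985-1989) to 2.36% (1995-1998) via cohort fixed effects; and
sex-specific additive scales corresponding to h2 = 0.870 (male) / 0.757
(female) with no shared environment. Intercepts are calibrated exactly on
the liability scale via `threshold_for_prevalence`. Sibship-size
distributions are not known for the original analytic cohort; the default
{1: 0.25, 2: 0.45, 3: 0.30} approximates completed family sizes in a
Nordic setting and is configurable. Parental ages are drawn from normal
distributions (maternal 28.5 +/- 4.8, paternal 31 +/- 5.5 years at first
birth) and gestational age from N(39.4, 1.8) weeks, truncated to plausible
ranges.

What the generator does *not* emulate: migration/death censoring (the real
cohort is uniformly followed, so this is immaterial to final prevalence),
assortative mating, diagnostic misclassification, and zygosity. Passing
recovery tests therefore demonstrates correctness of the estimation
machinery under the model's own assumptions, not robustness to their
violation.

## Problem sizes and numerical choices

* Parameter-recovery experiments (`scripts/acceptance.py`) run 6
  replicates of 120 000 grandparent couples (~250 000 children, ~3 000
  cases) for the sex-specific model and 2 replicates of 200 000 couples
  for the shared-scale model, with 256 quasi-Monte-Carlo points per group
  probability. The sex split is genuinely information-hungry: the
  additive-vs-shared direction is pinned only by concordant cousin pairs,
  so a single replicate's per-sex heritability carries a standard error
  of 5-10 points at these case counts and occasional replicates wander
  far along the ridge. Because the additive share cannot exceed 1, that
  wandering is one-sided and the replicate mean sits a few points below
  the generating value at desk scale; per-replicate information (not
  replicate count) is what shrinks this, so the layout favors large
  replicates at the highest integration accuracy the runtime allows.
* QMC defaults: 4096 points and 8 scrambles for one-off probabilities
  (standard errors reported); fits use smaller budgets (128-1024 points).
  Integration accuracy matters more than raw point count: members are
  ordered affected-first (the most restrictive coordinates enter the
  sequential-conditioning transform first) and the scrambled Sobol points
  are antithetically paired, which together cut the per-pattern error by
  more than an order of magnitude at fixed cost. Point sets are fixed per
  group size from the seed, so repeated evaluations share the same error
  surface (common random numbers) and the objective stays smooth.
* Degenerate covariances (correlations ~1 at extreme scales) get a 1e-10
  diagonal jitter before factorization. Probabilities are floored at
  1e-300 before logs; group sums use compensated (fsum) accumulation.
* The CI-calibration test runs at a higher prevalence (25%/18%) and
  moderate heritability with small cohorts: at 1% prevalence and desk-size
  samples the delta-method interval is far from its asymptotic regime, and
  the test is meant to validate the interval machinery, not to re-run the
  full study.

## Scenario calculations

The exploratory module asks how a female-specific residual could mimic the
observed heritability sex difference. With male-valued genetic variance
`sigma_A,m^2` fixed, the extra female residual variance X solves
`h2_f = sigma_A,m^2 / (1 + sigma_A,m^2 + sigma_C^2 + X)` (closed form,
cross-checked by root finding). The share of female prevalence
attributable to X compares threshold-model prevalences with and without X
at a fixed threshold. If X is carried by a single Bernoulli(p) factor
adding delta to liability, `p(1-p) delta^2 = X` determines delta, and the
required relative risk is the carrier/non-carrier risk ratio under a
threshold re-calibrated so the overall prevalence is unchanged
(mean-centered variant; an un-centered variant with the threshold fixed at
the no-factor baseline illustrates the prevalence shift among carriers).
All calculations are on the natural liability scale (residual variance 1).
The required RR falls steeply with p over the rare-factor range and is
minimized for factors near 50% prevalence; as p -> 0 it diverges. The
original description of this analysis leaves its exact scale conventions
unstated, so these outputs are reported as the package's reconstruction
and tested for their qualitative structure (monotonicity, conservation,
dual-path agreement), with magnitudes treated as order-of-magnitude
anchors only.

## Known limitations

* The pseudolikelihood weights children unevenly (those in two groups
  count twice); the point estimator remains consistent under the model,
  but efficiency is below a full-likelihood treatment.
* Sex-specific fits on cohorts with fewer than a few thousand cases are
  noisy and can sit on the sigma_A/sigma_C ridge; inspect `converged_`
  and `boundary` flags.
* Double first cousins receive relatedness 0.125 like ordinary cousins,
  mirroring the three-valued relatedness convention of the design.
* The tetrachoric descriptives use overlapping pairs from sibships of
  three; their confidence intervals ignore that overlap and are
  descriptive only.
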