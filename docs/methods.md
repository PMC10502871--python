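# Methods

## Model and assumptions

`penetrax` estimates penetrance P(D|A) — the probability of dominant
cardiomyopathy by late adulthood given one copy of a risk allele — from
cross-sectional allele counts via Bayes' theorem:

    P(D|A) = P(D) · P(A|D) / P(A)

where P(D) is the population prevalence of the disease, P(A|D) the allele
frequency in a case series, and P(A) the allele frequency in population
reference cohorts. All three are modelled as binomial proportions x/n, with
n the allele number (2 × individuals at autosomal diploid loci; per-variant
allele numbers may be supplied to reflect per-site coverage).

Assumptions worth keeping in mind:

* **Independence of the three terms.** The CI treats prevalence, case AF and
  population AF as independent random variables. In reality they share some
  dependence (the same population underlies all three); the interval is an
  approximation.
* **Unrelated individuals.** Cryptic relatedness in a case series inflates
  case AF and hence penetrance; nothing in the model corrects for it.
* **Representative referral.** Case AF reflects who gets referred for
  diagnostic sequencing. Conservative referral (only high-confidence cases)
  biases penetrance up; indiscriminate testing biases it down.
* **Ancestry matching.** A variant common in one ancestral subpopulation and
  absent elsewhere has its population AF diluted by pooling mismatched
  reference cohorts, inflating the estimate (see the mixture property tests).

## Confidence intervals

On the log scale the estimate decomposes as
log P(D|A) = log P(D) + log P(A|D) − log P(A). For each proportion the delta
method gives var[ln p̂] ≈ 1/x − 1/n, and the second-order bias-corrected mean
ln p̂ + (1 − p̂)/(2x). The CI is exp(mean ± z·√variance) with z = 1.959964 at
the default 95% level (configurable; no small-sample t adjustment), truncated
at 1 with a `clamped` flag.

**Degeneracy policy.** As allele frequency tends to zero the log-scale
variance estimate collapses. The policy, isolated in
`estimator.degeneracy_adjust` so it can be swapped wholesale:

* a population allele count of 0 never yields an estimate (the variant is
  routed to recurrence groups G1/G4 as unreliable);
* any contributing integer count of 1 or 2 is shifted to (x + 0.5, n + 1)
  inside the CI computation only — the point estimate is untouched;
* estimates with population AC ≤ 1 carry `reliable = False`.

**Exact oracle.** `binom_ci_exact` (Clopper–Pearson, via
`scipy.stats.binomtest`) is the small-count oracle: with prevalence and
population AF effectively known, the delta-method CI converges to
`p_D/popAF` times the exact case-proportion interval (within 5% relative at
case AC ≥ 50; verified in tests).

## Prevalence handling

Published prevalence arrives as a point estimate with an asymmetric CI. The
CI endpoints are log-consistent, so effective pseudo-counts are derived on
the log scale: SE = (ln hi − ln lo)/(2z), x_eff = 1/SE², n_eff = x_eff/p.
Feeding (x_eff, n_eff) back into the variance formula reproduces SE up to a
(1 − p) factor, negligible for rare diseases; the round-trip is tested at 5%.

Proportion studies are pooled with DerSimonian–Laird random effects on the
logit scale (`statsmodels.stats.meta_analysis.combine_effects`), fixed
effects by flag. τ² is truncated at zero, so with no excess heterogeneity the
random-effects pool equals the fixed-effects one. Zero-count studies require
an explicit 0.5 continuity correction and always emit a warning.

Packaged constants (fractions, 95% CI): HCM overall 0.0018 (0.0015–0.0023),
female 0.0008, male 0.0028; DCM overall 0.0045 (0.0039–0.0053), female
0.0030, male 0.0063. Effective counts are derived on load.

## Stratification recipes

* **Sex** — every term replaced by its sex-specific value. A conservative
  screen flags variants whose male and female 95% CIs do not overlap; no
  formal z-test is attempted, since CI non-overlap is the stricter criterion.
* **Ancestry** — prevalence is shared (too few ancestry-specific prevalence
  studies exist); case and population AFs are proportioned by reported
  ancestry. Strata with AC < 5 on either side carry a sparse-data note; a
  zero population stratum is omitted per the degeneracy policy.
* **Age** — cumulative renormalisation, not hazard modelling: at each decade
  upper bound a (bins labelled "20s" are evaluated at 30; half-open
  [lower, upper)), prevalence is scaled by the cumulative fraction of the
  case cohort diagnosed by a, case counts are cumulative carriers over
  2 × individuals with known age ≤ a (individuals with missing age are
  excluded), and population AF stays fixed. The final decade reproduces the
  unstratified estimate by construction. A decade with zero cumulative
  carriers reports point 0 with an upper bound from a single pseudo-carrier,
  flagged unreliable, so late-onset curves start near zero instead of
  erroring.

## Synthetic cohorts

The generator runs the estimation model forward: implied case AF =
penetrance × pop AF / prevalence, case and population allele counts drawn
binomially at 2 × cohort size. Because the generative and inferential models
coincide, recovery and coverage tests are directly interpretable — they
validate the statistics, **not** robustness to model misspecification
(referral bias, relatedness, ancestry mismatch or coverage gaps in real
data are deliberately absent).

Design choices:

* Sex strata are primary binomial draws, so they sum to the totals exactly;
  the case cohort's sex composition defaults to the disease sex ratio
  p_F/(p_F + p_M). The population AF splits by the male:female AF ratio r as
  af_F = 2·af/(1+r), af_M = r·af_F.
* Ancestry strata are a multinomial split of the total allele count with
  weights composition × ancestry AF (capped at stratum allele numbers), so
  both the sex and ancestry axes sum exactly — independent binomials per
  axis could not satisfy both.
* Ages at diagnosis are truncated normal on [0, 100] per variant
  (default mean 50 y, SD 12 y; cohort-wide mean 50 y, SD 13 y for the
  denominator). No onset model is implied by the estimator; this is a
  fixture-modelling choice.

## Precision simulation

For each (n_case, n_pop) grid cell, replicate allele counts are drawn under
known truth and the mean 95% CI width reported, along with the fraction of
replicates with width < 0.2 (both readings of "certainty" are inspectable).
Replicates with population AC ≤ 1 or case AC = 0 are skipped and counted,
mirroring the degeneracy policy. Each cell derives its RNG stream from
(seed, n_case, n_pop), so grid subsets reproduce cell-for-cell. Default runs
use 500 replicates; the width ordering in n_case and n_pop is stable at that
size, and the floor as both cohorts grow is the width implied by prevalence
uncertainty alone.

## Problem sizes used in the shipped checks

Coverage is evaluated over 10,000 replicates at cohort sizes of 10,000 cases
and 300,000 reference participants (population AF 1e-4, penetrance 0.25),
with the prevalence observation itself re-drawn per replicate at the
effective sample size implied by the packaged HCM CI, and replicates kept
only when every contributing count is ≥ 10. Parameter recovery uses 200
variants × 500 replicates at penetrance 0.15. These sizes give stable
Monte-Carlo estimates of the tested proportions while keeping the default
suite quick to run.

## Known limitations

* No Bayesian posterior over penetrance; intervals are frequentist and
  approximate.
* No linkage/haplotype or relatedness modelling.
* The degeneracy adjustment is a pragmatic small-count policy, not an exact
  finite-sample correction; alternatives can be swapped in via
  `degeneracy_adjust`.
* Aggregate estimates pool allele counts and therefore weight variants by
  observation count, not uniformly.
* Percent display uses one decimal, round-half-even.
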