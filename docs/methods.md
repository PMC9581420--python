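# Methods

`urbanbirds` implements the inference chain used to ask whether restaurant
density shapes urban bird communities once land cover and general
urbanisation are controlled for: random-intercept GLMMs per species and per
site, exhaustive-subset AIC model averaging with a randomised-null
calibration of relative importance, and permutation statistics on
presence/absence community matrices. This note records the models, the
numerical choices, and what the synthetic data generator does and does not
emulate.

## The mixed models

Every response is modelled as

    g(E[y_ij]) = x_ij' beta + u_i,   u_i ~ N(0, sigma_u^2),

with one random intercept per survey site and canonical links: logit for
presence (Bernoulli), log for counts (Poisson), identity for the
community-turnover score (gaussian). All predictors are z-scored (mean 0,
SD 1, n-1 denominator) across the modeling frame before fitting, so
coefficients are comparable across predictors; year enters as a scaled
numeric covariate, not a factor. Fits are maximum likelihood, never REML,
because AIC comparison across fixed-effect subsets requires the full
likelihood.

**Gaussian.** The marginal likelihood is evaluated in closed form (the
within-site covariance is compound symmetric), beta and the residual
variance are profiled out, and a bounded one-dimensional search over the
log variance ratio finds the MLE; the ratio-zero boundary (no site
variance) is tested explicitly.

**Binomial and Poisson.** The site intercepts are integrated out with a
Laplace approximation. For a candidate sigma_u, a penalised iteratively
reweighted least-squares Newton solver finds the joint mode of (beta, u)
— the (p + m)-dimensional system is solved by a Schur complement against
the diagonal random-effect block, so each step is O(np^2) — and the
Laplace log-likelihood adds the usual half-log-determinant correction,
which is a per-site scalar for a single random intercept. The outer
maximisation over log sigma_u uses bracketing plus successive parabolic
interpolation, stopping when the bracket is narrower than 0.02 in log
sigma or the profile is flat to 1e-7 across the bracket; because the
profile is flat to second order at its maximum, the resulting
log-likelihood error is ~1e-7, far below AIC resolution. Against a
2000-point grid of the profile the fitted log-likelihoods agree to better
than 1e-6. We chose this profile search (rather than a joint quasi-Newton
over beta and log sigma) because with a single scalar variance it is both
faster and free of the step-size pathologies near the sigma_u = 0
boundary; the boundary itself is admissible, and the parameter count k is
*not* reduced there, so AIC stays comparable across subsets within a
family.

A dense Gauss-Hermite quadrature oracle (201 nodes per site, refusing
more than 8 sites) validates the Laplace approximation in the test suite:
on Poisson toys the two agree within 0.05 log-likelihood units, and at
sigma_u = 0 both reduce exactly to the independent GLM likelihood.

Fitted standard errors are conditional: the inverse Schur complement of
the fixed-effect block of the joint penalised Hessian at the mode (the
same quantity lme4-style software reports). Separation in binomial fits
(|beta| > 30) and Newton failures mark the fit non-converged; such fits
are excluded from model sets with a warning.

**Non-integer Poisson responses.** Species abundance is defined as the
*mean* count over a season's visits, which is not an integer. The default
rounds to the nearest integer with a logged note before Poisson fitting;
the underlying model object also accepts refusal (`round_poisson=False`).
We do not claim either choice reproduces any particular published fit;
both are exposed.

## All-subsets selection, averaging, importance

For K candidate fixed terms all 2^K subsets are fitted (intercept and the
random intercept always retained; K <= 15 enforced). Models are ranked by
AIC = -2 logL + 2k with k = fixed effects + intercept + sigma_u (+ sigma_e
for gaussian); delta = AIC - min AIC; Akaike weights w = exp(-delta/2),
normalised. Plain AIC is the default; AICc is deliberately not silently
substituted. Ties in AIC are broken by the lexicographic key of the term
set, so output order is deterministic.

The averaging universe is the delta <= 2 top set. For each term:

* conditional beta: weights renormalised over the *containing* top models,
  beta_bar = sum w'_m beta_m;
* unconditional SE: sum w'_m sqrt(se_m^2 + (beta_m - beta_bar)^2), the
  standard model-averaging variance that folds in between-model spread;
  95% CI is normal-based;
* relative importance (RI): by default the classic Akaike-weight sum —
  full-set weights summed over *every* model containing the term
  (`weights_on="full"`). A top-set-renormalised variant
  (`weights_on="top"`, under which RI = 1 iff the term is in every top
  model) is also provided, because both conventions circulate in the
  multimodel-inference literature. The full-set sum is the default
  because it is the scale on which the published null thresholds for this
  kind of analysis (≈0.4–0.7 for ~10 candidate terms at this sample
  size) live; under top-set renormalisation the same null experiment
  concentrates near 1 whenever the top set is small, which makes
  thresholds of that magnitude unattainable.

**Null calibration.** RI has no universal scale, so the pipeline
calibrates it per response kind: each of n_iter = 100 iterations replaces
the response with i.i.d. draws — a single Bernoulli draw per row with p =
the observed mean presence; one Poisson draw per row with lambda = the
observed mean for abundance/richness/total-abundance; a gaussian draw
with the observed mean and SD for the turnover score (this gaussian
choice for the dissimilarity null is our assumption; no published
convention exists) — re-runs the entire enumerate/average chain with
predictors untouched, and records the maximum RI over terms. The
threshold is the mean of the 100 maxima. A term is called meaningful only
when its RI *strictly* exceeds the threshold. Under pure noise the
identity of the winning term is uniform over exchangeable candidates
(verified by a chi-square test in the suite), and at study scale
(57 sites x 3 years, 11 candidates, binomial p = 0.5) the threshold lands
in the 0.4-0.8 band.

## Community statistics

Presence/absence matrices (site-year rows, one season at a time; species
universe = species that ever met the inclusion rule in that season) are
compared with Sørensen dissimilarity (b + c)/(2a + b + c), the binary
form of Bray-Curtis and the common default for presence data; Jaccard is
switchable. A pair of empty communities is undefined and raises unless
explicitly scored 0.

* **MRPP** (authored here): delta = sum_g (n_g/N) x mean within-group
  dissimilarity; p = plus-one-corrected fraction of label permutations
  with delta <= observed; A = 1 - delta/E[delta] with the expectation
  over permutations; (n_g - 1) weighting switchable. Exactness is checked
  against full enumeration of all 20 assignments on a 6-observation toy.
* **Per-site-year turnover scores**: the within-site dissimilarities MRPP
  aggregates, disaggregated — a site-year's score is the mean
  dissimilarity between that year's community and the same site's other
  years. The group mean of the scores equals the MRPP within-group mean
  exactly (handshake identity), which the suite asserts. The per
  site-*year* (rather than per site) resolution is used because the
  turnover model includes year; this is our reading of an ambiguous
  convention, exposed in one place.
* **PERMANOVA**: scikit-bio's seeded implementation; R^2 is recovered from
  the pseudo-F as F(k-1) / (F(k-1) + (N-k)). Checked against a
  full-enumeration oracle on the same toy.
* **Dispersion**: scikit-bio permdisp with *centroid* (not spatial-median)
  distances; principal-coordinate embedding with the
  negative-eigenvalue convention d^2 = (positive-axis SS) - (negative-axis
  SS), clamped at zero.
* **NMDS**: scikit-learn's SMACOF non-metric MDS (majorisation with
  isotonic regression), best of n random starts, Kruskal stress-1;
  goodness of fit reported as the non-metric R^2 = 1 - stress^2. An
  all-zero distance matrix (identical communities) short-circuits to a
  zero embedding with stress 0.
* **Strata**: restaurant count 0 -> none, 1-2 -> low, >2 -> high;
  composition questions are asked as the three pairwise PERMANOVA /
  dispersion contrasts.

## Ingestion rules

* Flyover records are always excluded. Heard-only detections are excluded
  from *abundance* responses but retained for *presence* (counting birds
  by ear alone is unreliable; detecting them is not).
* Buffer counts use a closed ball (distance <= radius, 1 km default) on
  projected coordinates; a record at exactly the radius counts.
* The inclusion rule "observed at least twice" is interpreted as detected
  on >= 2 *distinct visits* within the season-year; the
  >= 2 *individuals* reading is available as `presence_rule=
  "individuals"`. Richness counts species meeting the rule; presence is
  the per-species indicator of the same rule.
* Species abundance = mean count over all visits (zeros included); total
  abundance = per-species maximum across visits, summed over included
  species (summing one overall maximum would discard composition; that
  reading is available as `total_rule="overall_max"`).
* LULC fraction columns with Spearman rho > 0.7 are iteratively summed
  (highest-rho pair first) until no pair exceeds the threshold; the
  published 11-to-7 Phoenix merge is available as a preset. Merging
  conserves total cover per row. Constant columns are excluded from
  merging with a warning, since their rank correlation is undefined.

## The synthetic generator

The generator is the package's test bed and emulates the study design:
57 sites x 3 survey years x 2 seasons x 3 visits, ~24 species. Businesses
per site-year are Poisson draws around a site-level gamma frailty
(negative binomial marginally, correlated across years) with mean 25 and
a 12% per-survey-year trend; restaurants are a binomial thinning of
businesses with logit-linear-in-log-business thinning probability plus
site-year noise, which guarantees restaurants <= businesses, makes the
restaurant-business relationship monotone, and with the default
coefficients yields a rank correlation near 0.59, ~2 restaurants per
site-year and ~60% zero-restaurant site-years — the regime the strata
analysis needs. LULC fractions are Dirichlet per site (alphas roughly
matching a desert metropolitan mix), constant across years unless a drift
parameter is set. Species counts follow exactly the generative model the
GLMMs assume, with named urban-exploiter species given the published
signs of restaurant association (+0.31 for the rock-pigeon analogue's
abundance, etc.) and detection modes/flyovers attached so the ingest
filters are exercised on synthetic data too.

What the generator does *not* emulate — and hence what passing tests do
not establish about field data: spatial autocorrelation between sites,
migratory phenology and genuine season differences (both seasons share
generative parameters), observer effects beyond the flyover flag,
overdispersion beyond the site intercept, and detection probability
varying with habitat. Recovery results here certify the *inference
machinery*, not the ecology.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed; fixed seeds give
bit-identical outputs (asserted in the suite). The test suite and the
acceptance script size their Monte-Carlo experiments to what the
questions need rather than more: null calibrations use the stated 100
iterations at the study's own scale (57 sites x 3 years, 10-11
candidates, 1024-2048 fits per iteration); recovery checks use 20
replicates; permutation tests use 999-10,000 permutations. The GLMM
engine is written so a single subset fit costs ~1-2 ms at that scale,
which is what makes 100 x 2^K refits per calibration practical.
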