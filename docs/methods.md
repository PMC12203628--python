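# Methods

## The problem

National household surveys such as India's NFHS (a DHS-family survey) sample
women within communities (the survey's primary sampling units — villages or
census enumeration blocks), communities within districts, and districts
within states. Women's empowerment, measured by the SWPER index, varies at
every one of those levels, and the policy question — where should an
intervention be targeted? — turns on *how much* of the geographic variation
sits at each level and on *which specific communities* have a high prevalence
of low empowerment. This package implements that analysis: outcome
construction, a four-level variance-components logistic model, variance
partitioning, precision-weighted (shrunken) community prevalence estimation,
and the classification/mapping layer, together with a synthetic-data
generator so every stage is testable without restricted survey data.

## Outcome construction (swper)

The SWPER summarises 14 items into three domains: attitude to violence
(5 items on whether wife-beating is justified), social independence (6 items:
education, age at first marriage/birth, media exposure, spousal age and
education gaps), and decision-making (3 items on household decisions). Each
domain score is a weighted sum of recoded item responses, standardised and
cut into terciles; the bottom tercile is the binary outcome "low level of
empowerment".

* **Codebook.** Recodes and weights live in a columnar text file with
  provenance metadata; scoring refuses to run without a `source` entry. The
  shipped default (`swper_codebook_synthetic.csv`) reproduces the 5/6/3
  domain structure and recode signs but deliberately not the published
  principal-component weights, which belong to the original SWPER
  publications; analyses of real data should drop in the published table.
* **Standardisation.** Within-sample moments by default; external constants
  (for comparability across surveys) via codebook metadata. It is not
  documented in the source study which was used; both are supported.
* **Terciles.** Boundaries at the empirical 33.33/66.67 percentile ranks.
  Ties at a boundary are broken by stable rank after a pre-sort on woman key
  (first key goes to the lower tercile) — deterministic and order-invariant.
* **Eligibility cascade.** (1) not currently married/in union, (2) not
  selected for the relevant question modules, (3) any missing index item,
  applied in that order with per-step tallies.

## The four-level model (mlm)

For woman *i* in community *j*, district *k*, state *l*:

    logit P(Y_ijkl = 1) = beta0 + u_j + v_k + f_l
    u_j ~ N(0, sigma2_community),  v_k ~ N(0, sigma2_district),
    f_l ~ N(0, sigma2_state)

The Bernoulli level-1 variance is not freely estimated. Since the model has
no woman-level covariates, per-community counts (n_j, y_j) are exact
sufficient statistics; all estimation works on that collapse, which makes
run time independent of the number of women given the community structure.

**Initialisation.** An iterative linearised (first-order PQL) fit: the
likelihood is linearised at the current predictor, yielding a community-level
working response with known sampling variance 1/(n_j w_j); the resulting
three-level *linear* mixed model is fitted by exact maximum likelihood
(dense Cholesky per state block, profile over the intercept), BLUPs update
the predictor, and the cycle repeats to convergence. A second-order
correction pass was considered and dropped: only starting values depend on
the linearisation, and the first-order fit already starts the sampler well
(on null data its starting variances are below 0.05; on informative 2-level
data it lands within 50% of the quadrature MLE). A method-of-moments
decomposition of empirical logits is the logged fallback if the inner
optimiser fails. Constant outcomes raise a separation error.

**Sampler.** Metropolis-within-Gibbs with vectorised single-site random-walk
updates for the intercept and all residuals, conjugate inverse-gamma draws
for the three variances, and likelihood-invariant *translation moves* that
propose shifting a constant between adjacent levels (beta0 <-> f, f <-> v,
v <-> u; the likelihood cancels, only the Gaussian priors enter the
acceptance ratio). The translation moves are essential: without them the
level means mix by random walk and the intercept's effective sample size
collapses. Proposal scales adapt toward 44% acceptance during burn-in only,
so monitored draws come from a fixed kernel. Defaults mirror the study's
stated run: burn-in 500, monitored 5000.

**Priors.** Flat on the intercept; inverse-gamma(0.001, 0.001) on each
variance (close to log-uniform), configurable. The quasi-likelihood
estimates are starting values by default; a switch (`init_as_prior`)
instead converts them into weakly informative inverse-gamma priors (prior
mean at the starting value, shape 3), since the two-stage convention this
mirrors is ambiguous between the two readings.

**Degenerate levels.** A level with a single unit has its variance fixed at
zero with a logged warning; this is how two- and three-level reductions are
fitted.

**Validation.** The sampler was checked against a brute-force independent
oracle: on two-level data the marginal likelihood is computed by 40-node
Gauss–Hermite quadrature and the exact posterior over (beta0, sigma2) by
two-dimensional grid integration; the sampler's posterior means agree to
within Monte-Carlo error (test suite). Note a deliberate distinction: the
posterior *mean* of a variance with few clusters (e.g. 20) sits visibly
above the maximum-likelihood estimate because the posterior is right-skewed;
this is a property of the estimand, not a sampler artefact.

## Post-estimation (postest)

* **VPC.** Share of each level in the total *geographic* variance
  sigma2_state + sigma2_district + sigma2_community (shares sum to 100%);
  a latent-threshold mode adds pi^2/3 to the denominator for readers who
  want the individual-level share included.
* **Precision-weighted prevalence.** antilogit(beta0 + f + v + u) x 100 at
  posterior means. Posterior means of hierarchical residuals are shrinkage
  predictions: a community observed on 1 woman borrows almost everything
  from its district/state/nation, a 200-woman community almost nothing. A
  closed-form empirical-Bayes mode on the empirical-logit scale
  (variance-ratio weight w_j = sigma2_u / (sigma2_u + s2_j)) cross-checks
  the MCMC route.
* **Summaries.** Unweighted mean/SD/min/max of community estimates per
  district and state; sample (n-1) SD for within-district dispersion.
* **Dispersion correlation.** Pearson r between district mean prevalence and
  within-district SD; single-community districts are excluded and counted.
* **Classification.** A community is under-empowered when its estimate is
  *equal to or higher than* the national mean (boundary included); the
  national mean defaults to the unweighted community mean, with a
  woman-weighted option. A district enters the headline tally when
  *strictly more than* 90% of its communities are under-empowered. The 2x2
  quadrant cross-tabulation (prevalence vs its mean x SD vs its mean) uses
  >= on both axes.

## Reporting (report)

Equal-interval choropleth classification over the observed range (k = 10 by
default; lower-closed bins, maximum in the top bin), Tukey-whisker box-plot
exports per state, polygon dissolve (union of child geometries per parent,
numeric attributes summed — the operation used to rebuild district
boundaries from assembly-constituency polygons), and matplotlib map
rendering from plain GeoJSON. The package ships no boundary data.

## Synthetic data (synth)

The generator emulates the analytic structure of NFHS-5: 36 states, 20
districts per state (720), Poisson(12.64) communities per district (~9104),
Poisson(79.54) sampled women per community (~724k), with the eligibility
cascade removing the fractions (211707, 435498, 227)/724115 of the initial
sample at its three steps, leaving ~76 683 analytic women (~8.4 per
community). Exclusion rates are parameterised as fractions of the *initial*
sample removed per sequential step, so the defaults reproduce the published
cascade exactly in expectation. Outcomes come from the four-level logit with
default truth beta0 = logit(0.292) and variances (0.86, 0.23, 0.97) — the
attitude-to-violence column of the study's variance table. Random effects
use per-level seed substreams, so unit effects are stable when the number of
women is scaled.

Item responses are a stand-in: an ordinal thresholding of
`loading x latent + noise`, where the latent propensity is minus the woman's
random-effect contribution. This exercises the scoring path and yields
scores that correlate with the generative truth, but it does not reproduce
the real surveys' item marginals or inter-item correlation structure — no
such generative model is published. Tests passing on these items therefore
validate the *machinery* (recoding, weighting, terciles, cascade), not any
claim about real item distributions.

## Problem sizes used in the automated checks

Chosen to keep the full suite fast while leaving each check informative:
parameter recovery uses 100 replicates of a 36 x 5 x 5 x 8 design (7200
women, 900 communities) with burn-in 500 / monitored 2000 per fit; null
calibration uses 10 x 10 x 10 x 4 with the full 500/5000 run; the
two-level oracle comparisons use 20 clusters x 20 observations; cascade
calibration uses 100 000 women. The full national scale (~724k women
generated, ~76.7k analytic) is exercised structurally (generation, cascade,
scoring, indexing) but not MCMC-fitted in the automated checks; the run
configuration for a full fit is `pipeline.StudyConfig()` with its published
defaults.

## Known limitations

* The shipped codebook's weights are placeholders with the correct structure;
  published-scale score distributions require the published weight table.
* Survey design weights and covariate adjustment are out of scope (the
  modelled analysis is an unweighted variance-components model).
* The item generator does not emulate probability-proportional-to-size
  sampling or real item dependence.
* Reproducing the published national estimates themselves requires the
  restricted individual-level survey data; synthetic runs reproduce the
  method's behaviour under known truth instead.
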