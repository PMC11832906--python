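# Methods

## Scope and data model

`ctmsom` implements a complete analysis path for multi-species camera-trap
surveys: image records → independent events → daily detection histories →
multivariate-Bernoulli occupancy models with pairwise co-occurrence →
AIC model selection → derived occupancy/detection quantities, plus a
synthetic-data generator that reproduces the statistical structure of a
56-site winter study so every stage can be validated without field data.

Image records arrive as one row per classified photo (camera, timestamp,
species, count); photos showing two species are assumed to have been
duplicated upstream, one row per species. A deployment table gives one
camera per site with a closed date interval; `trap_days = end − start + 1`.

## Event grouping

Within each (camera, species) stream, a photo opens a new event iff it
follows its predecessor by at least `gap_minutes` (default 5). The gap is
measured from the *previous image*, not from the event's first image, so an
animal lingering in the field of view extends one event indefinitely. This
is a deliberate reading of the field protocol: visual re-identification of
individuals (the usual first criterion) is not implementable from
timestamps, so the time rule is applied uniformly and the threshold is
configurable. Unsorted input is rejected rather than silently re-sorted,
because silent re-sorting can mask upstream data corruption.

Occasions are calendar days on a globally aligned study window, with the day
boundary at local midnight; an event is attributed to the day(s) its images
fall on. Days outside a site's deployment are missing (NaN) and contribute
nothing to the likelihood. Capture rate is events per 100 trap days; naive
occupancy is the share of surveyed sites (≥ 1 non-missing day) with ≥ 1
detection.

## Covariate preparation

Continuous covariates are standardized to mean 0, sample (n−1) SD 1;
binary indicators (on/off trail, day-level human presence, hunting days)
are left on their 0/1 scale so their coefficients read as contrasts.
Collinearity screening is pairwise: when |Pearson r| ≥ 0.6 the
lower-priority covariate of the pair is dropped. The priority order is a
required user decision — which member of a correlated pair to keep is a
modelling judgement, not a statistic — and VIFs of the retained set are
reported diagnostically rather than used as the drop rule.

## The occupancy model

The community state **z** ∈ {0,1}^S at a site follows a multivariate
Bernoulli with log-linear natural parameters: first-order fᵢ (one per
species) and second-order fᵢⱼ (one per pair), each a linear function of
site covariates. Third- and higher-order terms are fixed at zero — a model
restriction, adopted because a three-species survey contains very little
information about a three-way interaction and the candidate sets of
interest only vary pairwise structure. fᵢⱼ = 0 gives conditional
independence; with all pairwise terms zero the marginal occupancy reduces
exactly to ψᵢ = logistic(fᵢ).

Detection is daily Bernoulli conditional on presence, logit-linear in site-
and occasion-level covariates. With constant p this is equivalent to the
binomial detection-frequency formulation up to a binomial coefficient that
does not involve parameters, so MLEs coincide (tested). The site likelihood
marginalizes the 2^S states: states contradicted by an observed detection
get probability zero; missing occasions contribute factor one.

## Numerics

* All state marginalizations use log-sum-exp; impossible states carry a log
  weight of −1e30, which exponentiates to exactly 0.0 in double precision.
* The gradient is analytic: for occupancy natural parameters it is the
  posterior-minus-prior moment of the corresponding state monomial
  (E[zᵢ | data] − E[zᵢ]); for detection coefficients it is the posterior
  presence probability times the Bernoulli score. This makes a J = 600,
  K = 60, 33-parameter fit take ~2 s, which is what keeps the replicated
  simulation studies tractable.
* Optimization: L-BFGS-B (memory 25) from logit(naive ψ) occupancy
  intercepts, logit(0.1) detection intercepts, zero slopes; additional
  starts jitter the initial point N(0, 0.5²). The quasi-Newton stage stops
  near the optimum; damped Newton steps using the observed Hessian then
  drive the gradient ∞-norm below 1e-6, which is the convergence criterion
  the `converged` flag reports. Non-convergence flags the result instead of
  raising.
* Standard errors: inverse observed Hessian (central finite differences of
  the analytic gradient, relative step 1e-5). A non-positive-definite
  Hessian yields NaN SEs and `se_ok=False`. p-values are two-sided Wald,
  matching the single-p-per-coefficient reporting convention of the field.
* AIC = −2 logL + 2K; ties within 1e-6 rank the more parsimonious model
  first; non-converged candidates are listed last and flagged, never
  silently dropped.

## Derived quantities

Marginal ψᵢ, conditional ψᵢ|ⱼ and co-occurrence probabilities all come from
the fitted state distribution at each site's observed covariates. The
species-level summary reports the *mean of per-site predictions* (and mean
of per-site-day detection predictions) rather than the prediction at
covariate means — the two differ under nonlinearity and the field reports
do not say which they use; the mean-of-predictions reading is implemented
and its SE is a delta-method SE of that mean through the coefficient
covariance. Detection prediction curves over covariate grids carry
delta-method CIs computed on the logit scale and back-transformed, keeping
bands inside [0,1].

## The synthetic world

Defaults state the emulated study: J = 56 sites, study window 2021-11-01 to
2022-04-30, one deployment per site running to the window's end with
staggered starts drawn so trap days are ≈ Normal(112, 38²) clipped to
[14, 181] — reproducing the study's 6244 total trap days within 10%.
Site covariates: forest % ~ clipped N(65, 20²); open % negatively coupled
to forest (≈ 55 − 0.4·forest + noise, clipped to [0,100], |r| ≈ 0.5 —
correlated as in real landscapes but below the screening threshold);
terrain ruggedness ~ Gamma(4, 2); road and building distances ~
Exponential(400 m) and Exponential(700 m); visibility ~ U(10, 100); trail
categories with P(off trail) = 0.5. Day-level covariates: hunting active
two fixed weekdays (Thu, Sun) through 2022-01-31; human presence per
site-day Bernoulli with a per-site Beta-distributed rate of mean 0.15, from
which the human-passage site covariate (events per 100 trap days) is
derived. True coefficients are on the standardized scale, with magnitudes
and signs echoing published estimates for this community (ungulates avoid
rugged terrain and trails, wolves prefer both; hunting suppresses roe deer
detection; detection intercepts between −1.4 and −2.2).

Image fabrication: each detected site-day receives max(1, Poisson(1.2))
events at distinct slots on a 6-minute grid (so consecutive events are
always ≥ the 5-minute threshold apart), each event a burst of 3 photos
0.1 s apart. This makes the event-grouping rule invertible by construction:
re-grouping the fabricated records recovers the simulated detection array
exactly, which is the pipeline-faithfulness check. What the generator does
*not* emulate: camera failures mid-deployment, spatial autocorrelation
between neighbouring sites, animal movement/home ranges, within-day
activity rhythms, or misclassified images. A green pipeline test therefore
establishes correctness of the bookkeeping and the estimator under the
stated model, not robustness to those field realities.

## Validation design

The test suite checks every computational claim by an independent route:
probability-domain brute-force enumeration for the marginalized likelihood
(to 1e-10), closed forms for single-species reductions, an exhaustive 2-D
grid search for a toy MLE, an independent binomial-form optimizer for the
detection-frequency equivalence, and replicated simulation studies for
frequentist calibration (200 replicates at J = 600: 95% Wald CI coverage
required within [90%, 98%] per coefficient, |bias| < 0.1 for moderate
coefficients) and for AIC behaviour (interaction truth → interaction model
wins ≥ 70/100; independence truth → independence wins ≥ 50/100). The
replicated studies run with a single optimizer start — at those sample
sizes the likelihood is effectively unimodal, and multi-start behaviour is
exercised separately on small problems.

## Known limitations

* Only pairwise dependence; no three-way term.
* Single-season (static) occupancy; no dynamics, no spatial random effects.
* Wald inference only; no profile likelihoods or bootstrap.
* The screening step forces the user to choose drop priorities; it does not
  arbitrate ecological importance.
* Exact reproduction of any particular field study's coefficient tables
  additionally depends on that study's data and unstated optimizer details;
  the workflow supports such data as CSV inputs but ships none.
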