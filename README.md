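# ctmsom

Camera-trap **m**ulti-**s**pecies **o**ccupancy **m**odelling: from classified
image records to independent detection events, daily detection histories,
maximum-likelihood co-occurrence models, AIC model selection, and derived
occupancy/detection summaries.

The package is aimed at wildlife ecologists analysing camera-trap surveys of
small interacting communities — typically a predator and its prey sharing a
human-dominated landscape — who want to ask whether species co-occurrence,
rather than environmental covariates alone, drives where each species occurs,
while properly accounting for imperfect detection.

## The model

The community state at site *j* is a binary vector **z**ⱼ ∈ {0,1}^S
distributed as a multivariate Bernoulli in natural-parameter form

  P(**z**) ∝ exp( Σᵢ fᵢ zᵢ + Σᵢ<ⱼ fᵢⱼ zᵢ zⱼ ),

where each first-order natural parameter fᵢ and each pairwise parameter fᵢⱼ
is a linear function of (standardized) site covariates. fᵢⱼ = 0 recovers
conditional independence of species *i* and *j*; a positive fᵢⱼ means the
two species occur together more often than their environments alone predict.
Third- and higher-order interactions are fixed at zero. Conditional on
presence, daily detections are Bernoulli with logit(pᵢⱼₖ) linear in site-
and day-level covariates (visibility, terrain, on/off-trail placement,
human presence, hunting-season days); conditional on absence a species is
never detected. The marginal likelihood sums the 2^S latent states per site
and is maximized by a multi-start quasi-Newton optimizer with analytic
gradients; standard errors come from the inverse observed Hessian and
candidate models are ranked by AIC = −2 logL + 2K.

Upstream of the model, consecutive photos of the same species at the same
camera are collapsed into one independent *event* whenever each photo
follows its predecessor by less than 5 minutes, and events are binned into
calendar-day detection histories with missing entries outside each camera's
deployment window.

## Worked example

```python
import ctmsom as cm

# a synthetic winter study: 56 sites, staggered deployments, 3 species
sim = cm.simulate(cm.SimConfig(seed=42))

events = cm.group_events(sim.records, gap_minutes=5)
array = cm.build_detection_array(
    events, sim.deployments, ["roe", "red", "wolf", "human"],
    study_start="2021-11-01", study_end="2022-04-30")
print(cm.summary_table(events, sim.deployments, array))
```

```text
  species  events  capture_rate  naive_occupancy
0     roe    1542     24.237661         0.714286
1   human    1150     18.076077         0.982143
2    wolf     869     13.659227         0.571429
3     red     388      6.098711         0.553571
```

Each row gives the number of independent events, the capture rate
(events per 100 trap days — a relative activity index), and the naive
occupancy (share of sites with ≥ 1 detection, uncorrected for imperfect
detection). Fitting the nine-model candidate set and ranking by AIC:

```python
data = sim.model_data()
specs = cm.build_candidate_set(sim.site_covariates.columns.tolist())
fits = [cm.fit(s, data, n_starts=2, seed=1) for s in specs]
print(cm.rank(fits).head(3)[["model", "AIC", "dAIC", "n_params"]])
```

```text
  model          AIC      dAIC  n_params
0    M3  9738.991629  0.000000        30
1    M6  9740.512711  1.521082        33
2    M1  9741.206823  2.215194        22
```

The best-supported candidates (ΔAIC < 2) are the ones modelling pairwise
dependence with covariates (M3, M6) — the structure the data were generated
under. `cm.derived_summary(best_fit, data)` then reports mean
marginal occupancy ψ and mean daily detection p per species with
delta-method standard errors, and `cm.predict_detection` produces detection
curves over covariate grids (e.g. trail category × hunting) with
confidence bands.

A `ctmsom` console script exposes the pipeline stages
(`events group|summary|histories`, `covariates prep`, `select run`,
`simulate`) for shell use.

## Acceptance script

`scripts/acceptance.py` re-runs the whole pipeline from scratch on a
seed-controlled synthetic study — simulation, event grouping, history
construction, candidate-set fitting, AIC ranking and derived summaries —
and writes its results JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
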