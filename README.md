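# malnutmap

District-level mapping of child (<5 y) malnutrition — stunting,
thinness/wasting and obesity — from complex household-survey data, with
Bayesian space-time smoothing and WHO-2025 target assessment.

National panel surveys are powered for national or provincial estimates, not
for the ~52 district councils an intervention planner actually works with:
at district level many survey waves contain a few dozen children per
district and some districts none at all, so crude prevalence estimates are
noisy or undefined. `malnutmap` implements the standard small-area remedy —
a Bayesian hierarchical binomial model with spatially structured random
effects — together with everything around it: LMS anthropometric z-scoring,
design-based survey estimation, Moran's I screening, exceedance
probabilities against the WHO 2025 nutrition targets, and a synthetic-data
generator that emulates the survey's district-panel structure so the whole
pipeline is testable without access-controlled microdata.

## The model

For each outcome independently, with `Y_ij` the survey-weighted number of
affected children among `n_ij` sampled in district `i = 1..I` and wave
`j = 1..J`:

    Y_ij ~ Binomial(n_ij, pi_ij)
    logit(pi_ij) = alpha + phi_i + gamma_j + nu_ij

* `alpha` — intercept, improper flat prior;
* `phi` — intrinsic CAR (ICAR) spatial effects over the district contiguity
  graph: conditionally, `phi_i | phi_-i ~ N(mean of neighbours, 1/(tau_phi m_i))`;
* `gamma` — first-order random-walk (RW1) wave effects;
* `nu` — exchangeable `N(0, 1/tau_nu)` space-time interactions;
* `tau_phi, tau_gamma, tau_nu ~ Gamma(0.5, 0.0005)` (shape–rate, on the
  precisions).

`phi` and `gamma` carry sum-to-zero constraints for identifiability.
Estimation is Metropolis-within-Gibbs (conjugate Gamma updates for the
precisions, adaptive scalar random-walk Metropolis for the location
parameters) run as two overdispersed chains; convergence is monitored with
Gelman–Rubin statistics and a batch-means Monte Carlo error rule (MC error
below 5% of the posterior SD for every monitored parameter).  Model fit is
summarised by the DIC and out-of-sample validation on a random 10% holdout
of observed cells.  Posterior exceedance probabilities translate the fit
into WHO-2025 target language, with probabilities strictly above 0.8 deemed
significant.

## Worked example

```python
from malnutmap import McmcConfig, SpaceTimeCARModel
from malnutmap.simulate import (make_district_graph, simulate_truth,
                                simulate_counts, default_cell_sizes)
from malnutmap.targets import assess_all_districts

graph = make_district_graph(52, seed=1)              # 4 x 13 lattice stand-in
truth = simulate_truth(graph, J=5, alpha=-2.3, gamma_trend=-0.2, seed=2)
panel = simulate_counts(truth, default_cell_sizes(52, 5, seed=3), seed=4,
                        outcome="stunting")
cfg = McmcConfig(n_chains=2, burn_in=2000, n_keep=4000, thin=1, seed=5,
                 extend_until_converged=False)
results = SpaceTimeCARModel(panel, graph).fit(cfg)
print(results.summary())
```

```
Space-time binomial CAR model results
================================================
Outcome:            stunting
Districts x waves:  52 x 5  (255 observed cells)
Chains:             2 x 4000 kept draws (thin 1, burn-in 2000)
Converged:          False (max R-hat 1.312, max MC-error/SD 0.151)
DIC:                1078.5  (pD = 41.2)
Acceptance rates:   alpha=0.48, phi=0.45, gamma=0.43, nu=0.34
------------------------------------------------
alpha      mean   -2.2090   sd    0.0304
tau_phi    mean    3.7835   sd    1.0782
tau_gamma  mean   19.9101   sd   13.7548
tau_nu     mean 1584.3015   sd 1654.8474
```

The intercept is recovered near its generating value (−2.3 before the
constrained effects absorb part of the level), and the cell-level prevalence
estimates are well mixed — the strict convergence flag is `False` only
because `tau_nu`, the precision of an interaction that is essentially absent
from these data, is weakly identified; at this scaled-down chain length its
MC-error rule is not yet met.  The fit converts to target language directly:

```python
ta = assess_all_districts(results, "stunting", baseline_wave=3, interim_wave=5)
print(f"{ta.count_met}/52 districts met ({ta.percent_met}%)")
```

```
21/52 districts met (40%)
```

i.e. under this simulated decline, 21 districts achieved the 17% interim
relative reduction in stunting between waves 3 and 5 on the posterior
median, none of them with exceedance probability above 0.8.

`results.summary_frame()` gives the per-district-wave posterior medians and
95% credibility intervals; `holdout_validation` and `prior_sensitivity`
provide the validation loops.

## Command line

The same analysis runs end-to-end from a shell with a YAML config:

```bash
malnutmap --outdir sim --seed 7 simulate          # synthetic inputs
malnutmap --config pipeline.yaml run              # zscore -> ... -> targets
```

Subcommands `zscore | prevalence | moran | fit | targets | validate` run
individual stages; every stage reads and writes files only, so the pipeline
is resumable and reruns with identical seeds are byte-identical.

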