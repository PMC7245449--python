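# Methods

## Outcome definitions and z-scoring

Measurements are converted to z-scores by the LMS method: given the Box-Cox
power L, median M and coefficient of variation S of the reference
distribution at the child's sex and age (or length),

    z = ((x/M)^L - 1) / (L S)   for L != 0,      z = ln(x/M) / S   for L = 0.

Both branches are evaluated through `expm1`/`log1p`, which makes the power
branch numerically exact arbitrarily close to L = 0 (the two branches agree
to far better than 1e-4 over x/M in [0.5, 2]).  L, M and S are each linearly
interpolated in the indexing variable between tabulated rows; a query at a
grid point returns the row verbatim, and queries outside the tabulated range
are errors rather than extrapolations.

Height-for-age z defines stunting (z < -2, strict).  The weight-based
indicator switches at 24.0 months exactly: weight-for-length, indexed by
length in cm per WHO convention, below 2 years; BMI-for-age (BMI computed
as kg/m^2 from the measured height) at 2 years and older.  Thinness/wasting
is weight-based z < -2.  Obesity is weight-based z >= +2 at *all* ages: the
source definitions are inconsistent at the boundary between the two age
groups (inclusive under 2, apparently exclusive above), and a uniform
inclusive rule was adopted since the boundary carries zero probability in
continuous data.  Implausible scores (|HAZ| > 6, |weight z| > 5 by default)
are flagged invalid and excluded downstream, mirroring common
biological-plausibility screens; the limits are configurable and infinite
limits disable the screen.  Missing measurements yield missing z-scores and
missing classification flags — never errors.

## Survey estimation

Prevalence is the weighted ratio estimator p = sum(w y)/sum(w) over valid
records in the domain.  Variances come from Taylor linearization with the
with-replacement approximation at the first stage: linearized scores are
summed to PSU totals within strata and the stratified between-PSU variance
is accumulated.  Domain (subpopulation) estimation keeps all records in the
design and zeroes the scores outside the domain, the standard treatment.
Confidence intervals are Wald intervals on the logit scale, back-transformed
(so they respect [0, 1]), with t critical values on `#PSUs - #strata`
degrees of freedom; degenerate estimates (p = 0 or 1, or zero variance)
collapse the interval to the point.  Strata containing a single PSU
contribute nothing to the variance and are counted in a
`single_psu_strata` flag marking the SE as an underestimate.

Tests of association use the weighted Pearson chi-square with the
Rao-Scott second-order (Satterthwaite) correction: the generalized design
effects are the eigenvalues of `(H V0 H')^{-1} (H V H')`, where V is the
linearized design covariance of the cell proportions, V0 the multinomial
covariance, and H the Jacobian of the independence residuals; the corrected
statistic `X^2 / sum(lambda)` is referred to F(d0, d0 * design df) with
`d0 = (sum lambda)^2 / sum(lambda^2)`.  With one record per PSU, a single
stratum and equal weights the eigenvalues are ~1 and the test collapses to
the classical Pearson chi-square.  Missing covariate values form an
explicit `Missing` category.

## Moran screening

The district graph is a symmetric common-boundary adjacency (supplied as an
edge list, not derived from geometry).  Moran's I uses row-standardized
weights; isolated nodes stay in the graph but are excluded from the
statistic's sums, including the centring.  Inference is permutation-based:
values are randomly reassigned to nodes, and the two-sided pseudo p-value
is `(1 + #{|I*| >= |I|}) / (n_perm + 1)` under a mandatory seed.  Constant
vectors raise an error (the statistic is undefined at zero variance).

## The space-time model

For each outcome independently, `Y_ij ~ Binomial(n_ij, pi_ij)` with
`logit(pi_ij) = alpha + phi_i + gamma_j + nu_ij`; priors as in the README.
Key choices:

* **Independent models per outcome.**  The pre-modelling bivariate Moran
  screen motivates fitting stunting, thinness/wasting and obesity
  separately; no shared spatial component is fitted.
* **Identifiability.**  The ICAR and RW1 priors are improper (invariant to
  level shifts).  After each phi and gamma sweep the block mean is moved
  into alpha, which changes neither the linear predictor nor the
  shift-invariant priors (alpha is flat) and realises the sum-to-zero
  constraint exactly — checked to |sum| < 1e-10 every sweep.  nu is left
  unconstrained; its mean trades off against alpha and is monitored through
  the cell-level prevalences rather than separately.
* **Sampler.**  Metropolis-within-Gibbs.  The three precisions have
  conjugate Gamma full conditionals `Gamma(a + r/2, b + q/2)` with q the
  structure's quadratic form and r its rank (I - #components for the ICAR
  plus one per isolated node under the exchangeable fallback; J - 1 for the
  RW1; I*J for the iid block).  Location parameters use scalar Gaussian
  random-walk Metropolis.  Scalar sites are swept in graph-colour classes:
  sites within a colour class are conditionally independent given the rest,
  so their accept/reject steps can run simultaneously as vectorized
  operations without changing the single-site kernel.  Proposal scales
  adapt every 50 sweeps during burn-in only (multiplicative updates toward
  a 44% acceptance rate, clipped to [1e-3, 10]), preserving ergodicity of
  the post-burn-in chain.
* **Starts and seeds.**  Chains start from the empirical logit of the
  pooled prevalence plus chain-indexed Gaussian spread; all randomness
  derives from one seed via `SeedSequence.spawn`.
* **Convergence.**  Monitored set: alpha, the three log precisions and all
  cell prevalences.  Criteria: Gelman-Rubin R-hat < 1.1 (between/within
  formula) and batch-means MC error < 5% of the pooled posterior SD for
  every monitored parameter with non-degenerate draws.  If either fails the
  sampler extends each chain in blocks (up to `max_extra_blocks` additional
  blocks of `n_keep` draws); exhausting the cap returns a result flagged
  `converged=False` — never a silent success.
* **Missing cells.**  `n_ij = 0` contributes no likelihood; the cell's
  prevalence is purely model-smoothed, which is exactly how district-waves
  without sampled children are handled (and why the model exists).
* **Isolated districts** receive an exchangeable N(0, 1/tau_phi) prior in
  place of the undefined neighbour average, with a warning.
* **Degenerate inputs.**  A 1-district, 1-wave panel is rejected; J = 1
  requires freezing the temporal block; prevalences are clipped away from
  {0,1} by 1e-12 only inside log-likelihood evaluations.

DIC is `Dbar + pD` with `pD = Dbar - D(theta_bar)`, the plug-in deviance
evaluated at the posterior mean of the cell logits; binomial coefficients
are included so the deviance matches `-2 log` of the exact likelihood.
Holdout validation masks a random 10% of observed cells (setting their n to
0), refits, and reports RMSE, correlation, and the coverage of 95%
posterior *predictive* intervals for the held-out crude rates Y/n —
predictive rather than prevalence intervals, because the held-out rate
carries binomial sampling noise on top of the uncertainty in the smoothed
prevalence.  Prior sensitivity refits under alternative
Gamma hyperpriors (default alternative Gamma(1, 0.01)) and reports the
maximum and mean absolute change in posterior median prevalence.

Default MCMC settings follow the source protocol (two chains, 10 000
burn-in, Gamma(0.5, 0.0005) hyperpriors).  The test suite and the
acceptance script run scaled-down chains — typically 2 chains x 2 000-5 000
kept draws after 1 500-2 000 burn-in, thin 1 — which the package treats as
its standard screening sizes; at these lengths the cell prevalences are
well mixed while the weakly identified interaction precision may not yet
meet the strict MC-error rule, which the convergence flag reports honestly.

## WHO-2025 target logic

Per district: stunting requires an interim relative reduction
`(pi_base - pi_interim)/pi_base >= f` between the 2012 and 2017 waves,
where f defaults to the published 17% constant; linear (15.4%) and
geometric (17.8%) pro-ratings of the 40%-by-2025 goal are available
because the published constant matches neither exactly.  Wasting requires
prevalence below 5% at the assessment wave.  Obesity requires no increase,
with ties counting as met ("no increase" includes equality).  "Met" is
judged on posterior medians (matching mapped point estimates); the
exceedance probability of the same event is reported alongside, and is
deemed significant only when strictly above 0.8 — a probability of exactly
0.8 is not significant.  Draws with a zero baseline are excluded from the
stunting reduction probability (the ratio is undefined there).  National
roll-ups report the count and the integer-rounded percentage of districts.

## What the synthetic generator emulates — and what it does not

The generator is the forward counterpart of the fitted model plus a
child-level survey layer:

* **District graph.**  A 4 x 13 rook lattice stands in for the 52 district
  councils (style `random_planar` gives a Delaunay alternative).  It
  reproduces the *degree structure* of a contiguity map, not South African
  geography.
* **Spatial effects** are exact draws from the sum-to-zero-constrained
  intrinsic CAR: sampling through the Laplacian eigenbasis with zero modes
  dropped realises precisely the proper Gaussian the constrained prior
  defines, component by component.  (A spanning-tree increment construction
  was considered and rejected: it samples the ICAR of the tree, whose
  marginal spread on this lattice is roughly twice the graph-ICAR's at the
  same precision, which inflates national prevalences through the logit
  nonlinearity.)  The default tau_phi = 2.5 gives a marginal logit-scale
  spread of ~0.58 on the lattice (mean marginal variance 0.832/tau),
  consistent with the several-fold district-level prevalence differences
  that motivate mapping; tau_gamma = 45 (wave-effect increments ~0.15) and
  tau_nu = 100 (interaction sd 0.1) complete the generic defaults.  The
  acceptance script overrides these with per-outcome values backed out of
  the study's observed district spreads and trend heterogeneity, and drives
  gamma with the study's national per-wave trajectories via
  `gamma_profile`.
* **Cell sizes** mimic the survey's sparsity: lognormal-Poisson around ~55
  children per district-wave with ~4% empty cells — the condition that
  makes crude district estimates unstable and smoothing necessary.
* **Children.**  Ages uniform on [0, 60) months, sexes balanced, districts
  allocated by a Dirichlet share vector, PSUs nested in districts (8 per
  district by default, ~400 nationally), strata as 9 contiguous district
  groups, design weights equal to a population-scale base times lognormal
  noise (cv 0.5).  Anthropometry is generated by inverting the LMS
  transform from latent z-draws: the height-for-age z is normal with unit
  SD and mean chosen so the < -2 tail equals the cell's stunting
  prevalence, and the weight-based z is normal with mean and SD solving
  *both* tail conditions (thinness below -2, obesity at or above +2)
  simultaneously in closed form.  Classifying the generated measurements
  therefore reproduces the generating prevalences exactly up to binomial
  noise, which the survey-loop tests verify.  Covariates are drawn from
  marginal category frequencies shaped like the study population; an
  optional correlated mode tilts household income by a configurable odds
  ratio against the child's stunting status, giving the association tests
  something to detect.
* **The reference table is synthetic**: smooth monotone-median L, M, S
  curves by sex, explicitly labelled a stand-in for real growth standards.
  Real WHO tables in the same CSV layout can be supplied by the user; the
  package never downloads them.

Not emulated: panel attrition and refreshment between waves, real
contiguity geometry, within-household covariate dependence, measurement
error in age, seasonality, or calibrated (post-stratified) weights.
Passing tests therefore demonstrate the estimators' correctness under the
model's own assumptions and survey structure — not robustness to the many
ways real anthropometric survey data violate them.

## Known limitations

* Under sparse cells the interaction nu is heavily shrunk, so district
  trends pull strongly toward the national trend; roll-up counts of
  districts meeting trend-based targets are correspondingly less dispersed
  than crude counting would suggest.
* The precision of a near-absent random effect (typically tau_nu) mixes
  slowly under scalar Metropolis; the MC-error rule flags this honestly,
  and longer runs — not different kernels — are the supported remedy.
* Single-PSU strata make design SEs underestimates; they are flagged, not
  repaired.
* The exceedance-based "significant" count depends on chain length through
  Monte Carlo error in tail probabilities near 0.8.
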