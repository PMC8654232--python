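# Methods

## The study design

`aircco` implements a Bayesian time-stratified case-crossover analysis of
short-term air-pollution exposure and asthma emergency-department (ED)
visits, exercised end to end on synthetic data with known effect sizes.

In a case-crossover design each ED visit (case) is contrasted with the same
child's exposure at nearby non-event times (referents), so every
time-invariant characteristic — demographics, neighbourhood, chronic disease
severity — is controlled by construction.  Time stratification selects
referents from the same year, month and day of week as the case, which
controls day-of-week structure, seasonality and long-term trends and is the
least-biased referent scheme for this family of designs.  Exposure for every
case and referent window is a 3-day moving average (3DMA) over lag days 0,
1 and 2 relative to the window's centre date.

Seasons throughout are *asthma seasons*, intra-annual periods of relative ED
burden rather than astronomical quarters: winter Jan 1–Feb 28/29, spring
Mar 1–May 31, summer Jun 1–Aug 19, fall Aug 20–Dec 31 (the fall season opens
at the approximate start of the school year and carries the back-to-school
surge and the largest burden).  A window's season is always determined by
the case day; referents near a boundary may physically fall in the adjacent
season and are deliberately not re-labelled.

## The model

For visit `i` and its windows `j = 1..4` (one case, up to three referents):

    y_ij ~ Bernoulli(pi_ij)
    logit(pi_ij) = alpha + d_c + beta_p' X_ij + beta_w' W_ij

    beta_k | tau_k ~ Normal(0, tau_k^-1),  tau_k ~ Gamma(2, 1)
    alpha | tau_a  ~ Normal(0, tau_a^-1),  tau_a = 1/sd_alpha^2,
                                           sd_alpha ~ Uniform(0, 4)
    d_c | tau_d    ~ Normal(0, tau_d^-1),  tau_d ~ Gamma(2, 0.5)

`X` collects pollutant 3DMAs (NOx, O3, SO2, PM2.5 and the coarse fraction
PM10-2.5; CO is screened out, see below), `W` temperature, dewpoint and
their interaction, and `d_c` is a random effect for the window's
year-month-day-of-week stratum (a 10-year study has 840 such combinations;
only occupied strata carry a parameter).  Gammas are parameterized as
(shape, rate), the BUGS convention.  Each coefficient has its own precision
`tau_k`; a config switch (`ModelSpec.shared_tau_beta`) provides the shared
variant.  Covariates are mean-centred within the model's scope before
fitting, and the temperature x dewpoint interaction is the product of the
centred main effects, itself re-centred; it stays in the model even when the
dewpoint main effect is removed by the collinearity screen.

Coefficients are reported as odds ratios per interquartile-range increase,
`OR_IQR = exp(beta * IQR)`, with the IQR computed over case + referent
window values within the model's scope by the linear-interpolation
percentile rule, and equal-tailed 95% credible intervals from the 2.5th and
97.5th posterior percentiles of the per-draw `exp(beta * IQR)`.  The point
estimate is the posterior median (config switch for the mean).

## Sampling

The sampler is blockwise MCMC, fully seeded and reproducible:

* `tau_k` and `tau_d` by conditionally conjugate Gibbs draws
  (`Gamma(shape + m/2, rate + sum(squares)/2)`);
* `alpha`, each `beta` and `sd_alpha` by adaptive random-walk Metropolis,
  step sizes tuned during burn-in toward a 0.35 acceptance rate
  (Robbins–Monro, frozen after burn-in);
* the stratum effects by a vectorized Metropolis sweep: given the other
  parameters the strata contribute independent likelihood factors, so all
  `d_c` are proposed and accepted in parallel with per-stratum step sizes.

Defaults are 4 chains, 10,000 iterations, 5,000 burn-in, no thinning, with
overdispersed starts; validation experiments use 2 chains of 2,200/800 at
their smaller problem size.  Convergence is monitored with split R-hat
(flag at 1.05) and effective sample size via ArviZ; model comparison uses
DIC = Dbar + pD with pD = Dbar − D(posterior mean).  The sampler is checked
against a dense 2-d grid-integration oracle on a reduced model and against
classical conditional-logistic fits (statsmodels) on full designs.

## Exposure processing

Gridded daily pollutant fields are interpolated to tract centroids by
inverse distance weighting over the k nearest grid points (defaults:
power 2, k = 4, the conventional GIS choices; both config-exposed since the
original analysis names IDW without parameters).  Coordinates are planar —
at a 12 km grid scale over one state, projection distortion is irrelevant to
the arithmetic.  A centroid coinciding with a grid point takes that point's
value exactly; days on which all neighbours are missing propagate as
flagged-missing (NaN), never as zero.

The coarse particulate fraction is PM10 − PM2.5; negative differences
(possible when the two are estimated independently) are clamped to zero and
counted in a diagnostic, since a mass fraction is physically nonnegative.
3DMA windows whose lag days are unavailable (the first two study days) are
dropped rather than shortened, keeping the window definition exact.
Season-stratified Spearman correlation matrices are computed after averaging
each variable across tracts and collapsing by day of year on a fixed
365-bin scale, with Feb 29 sharing bin 59 with Feb 28.

## Collinearity screen

Before fitting, covariates are screened pairwise: while any |Pearson r|
exceeds 0.9, one member of the worst pair is dropped — by a fixed priority
list (CO before NOx, dewpoint before temperature, SO2 before NOx, mirroring
the removals the source analysis reports: CO and NOx share a fuel-combustion
source, dewpoint tracks temperature) or, for unlisted pairs, the member with
the larger variance inflation factor.  The numeric threshold is this
package's choice; the original analysis reports removals without a rule.

## The synthetic generator

Each exposure series is `annual mean + seasonal sinusoid + AR(1) deviation
+ fixed tract offset`, truncated at zero for pollutants.  Defaults emulate a
low-air-pollution southeastern US state at study scale: 1,079 tracts,
2005–2014 daily, with means/amplitudes chosen so 3DMA IQRs land near the
magnitudes the study reports (NOx ~15 ppb, O3 ~0.017 ppm, SO2 ~4 ppb, PM
~4.5 ug/m3, temperature ~14 degC).  Combustion pollutants peak in winter,
O3 and fine PM in summer; CO is generated as an affine function of NOx plus
small noise, reproducing their shared-source collinearity so the screen has
something real to remove.  PM10 is constructed as PM2.5 plus a nonnegative
coarse component, so PM10 >= PM2.5 holds everywhere by construction.
Temperature and dewpoint share correlated AR(1) anomalies (rho 0.85).

Visits are drawn as a thinned Poisson per tract-day whose log intensity is
the model's own linear predictor: a day-of-year baseline (piecewise seasonal
burden levels plus a smooth Gaussian back-to-school bump centred on
day 236, Aug 24) plus year-month-day-of-week stratum noise plus
`sum(true_beta * 3DMA)`.  A per-child Bernoulli scheme would need a
population register; conditioning on cases only, the Poisson scheme induces
the same retrospective case-crossover likelihood.  The intensity is
normalized so the expected total matches a target daily visit rate
(default 18.1/day, the study-scale average), and counts are expanded to one
record per visit with pass-through demographic labels drawn from the
study's marginal frequencies.  Demographic strata are labels only — the
generator does not model demographic effect modification.

What the generator does not emulate: real geography (centroids are uniform
in a planar box), population-weighted exposure assignment, measurement
error in the exposure model, pollen and viral cycles, and any dependence of
visit behaviour on past visits.  Passing recovery tests therefore
demonstrate correctness of the pipeline's statistics, not transportability
of any particular OR to real data.

## Validation experiments and their conditions

Parameter recovery and null calibration (`aircco.validation`) repeatedly
simulate a reduced study — 25 tracts, 2005–2006, ~2,000 visits, matching
the scale at which replicated MCMC is desk-feasible — refit it, and compare
posteriors to the known truth.  The recovered effect is anchored to
published IQRs: the NOx effect is `log(1.15)/14.641` per ppb (OR_IQR 1.15),
the temperature effect `log(1.10)/14.26` per degC.

These experiments run under a *calibration configuration*: seasonal
amplitudes and tract offset gradients are zero and the visit baseline is
averaged within calendar months.  The reason is structural, not cosmetic.
Every visit contributes exactly one case and three referent windows, so the
outcome contrast lives entirely within visits: between-tract and
between-stratum covariate variance carries no information about `beta` and
acts as pure regression dilution on any unconditional estimator.  The
stratum effects absorb between-stratum variation only to the extent they
are free, and the Gamma(2, 0.5) precision prior concentrates `tau_d` high
when the true stratum effects are small, partially pooling the strata.
Measured on full-realism data, the NOx estimate is attenuated to ~0.67 of
truth by pooled logistic regression, ~0.84 with free stratum effects, while
conditional logistic regression (the matched-set estimator) is unbiased;
the hierarchical model lands between the pooled and free-strata limits.
Under the calibration configuration every covariate contrast the design
uses is within-stratum and within-tract, the model's identifying
assumptions hold, and recovery is unbiased to within Monte Carlo error for
the pollutant effect.  Temperature, whose AR(1) persistence (rho 0.8)
leaves appreciable between-month variance even without a seasonal cycle,
retains some dilution in the hierarchical fit (its credible intervals still
cover truth); this is a documented property of the unconditional
formulation, pinned by the conditional-logistic cross-check test, and a
known limitation to keep in mind when interpreting weather coefficients
from models of this family.

## Numerical choices

* Log-likelihood via the stable identity `sum(y*eta − log1pexp(eta))`.
* Percentiles (IQRs and credible intervals) by linear interpolation between
  order statistics.
* Centring tolerance 1e-10; duplicate-draw DIC yields pD = 0 exactly.
* Negative coarse-fraction clamp at 0 with a count, rather than propagating
  negative mass.
* Referent sampling: if more than three matches exist, three are drawn
  uniformly without replacement from a caller-supplied seeded generator;
  one sampling is reused across model scopes.
* Centring means are computed over case + referent rows (flagged as a
  sensitivity: case-only centring shifts only the intercept).
* Degenerate inputs: constant covariates give IQR 0 and are rejected by
  `or_iqr`; all-collinear covariate sets retain one covariate with a
  warning; an expected visit total of zero returns an empty table with a
  warning.

## Problem sizes

The test suite and the acceptance script run the full generator and sampler
at reduced sizes chosen as this package's validation scale: single-year
6-tract studies for design mechanics, 400-observation reduced models for
the grid-integration oracle, and 25-tract two-year ~2,000-visit studies
(2 chains, 2,200 iterations) for the replicated recovery and null
experiments.  Full-scale defaults (1,079 tracts, 10 years, 4 chains,
10,000 iterations) are the package defaults and run unchanged, just longer.
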