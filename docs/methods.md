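# Methods

## Study design and likelihood

The unit of analysis is the county-month.  Each (county, calendar month)
pair forms a stratum whose members are the same calendar month across the
study years; a member is a *case* when it contains at least one
cyclone-exposed day (sustained winds ≥ 34 kt at the county population mean
center).  Conditioning the Poisson likelihood of the member counts on the
stratum total yields a within-stratum multinomial whose cell log-odds are
the linear predictor differences between member months.  Every covariate
constant within a stratum — all time-invariant county characteristics and
mean seasonality — cancels exactly; the package asserts this translation
invariance numerically in its test suite.

The linear predictor contains:

* **Distributed lags** `beta_0..beta_L` (default L = 3): the log rate
  ratio per additional exposure day in the index month and each of the L
  months after.  Unconstrained — no smoothness is imposed across lags.
  Exposure can be all exposed days, gale-only (34–63 kt) or hurricane-only
  (≥ 64 kt) via `ModelConfig.exposure_class`.
* **Piecewise trend**: natural cubic regression splines of the month
  index, built separately on the months up to and after a breakpoint
  (default December 2015) with *no* continuity constraint across it.
  Default flexibility is one internal knot per three years of each
  period (basis df = knots + 2, minimum 2).  A period too short to
  support a cubic basis falls back to a linear column, which is the
  natural-spline limit with no internal knots.
* **Temperature**: monthly mean temperature is binned into 20 equal-width
  bins over the observed range; bin effects get a second-order
  random-walk (RW2) smoothness prior under a hard sum-to-zero constraint
  (orthonormal reparametrization).  Observations outside the binning
  range are clamped to the boundary bins.  If temperature is constant
  the term drops with a warning.
* **Offset**: log monthly population.  Annual counts are anchored to
  June and interpolated linearly; months outside the first/last June
  extrapolate the adjacent segment's slope, floored at one person.
  Offsets matter only through within-stratum differences, so rescaling
  every population leaves the posterior unchanged (tested exactly).

## Overdispersion

"Quasi-Poisson" has no generative Bayesian analogue, so overdispersion is
given a proper likelihood in one of three modes:

* `lognormal_olre` (default): a Gaussian observation-level random effect
  `u_it ~ N(0, 1/tau_olre)` on the linear predictor.
* `negative_binomial`: the exact conditional of independent
  negative-binomial counts sharing a within-stratum probability
  parameter, i.e. a Dirichlet-multinomial with concentrations
  `exp(eta)/phi`; `phi -> 0` recovers the plain multinomial.
* `none`: plain conditional Poisson.  Used by the oracle-equivalence
  tests, where the flat-prior posterior mode must match the conditional
  maximum-likelihood estimate.

## Priors

* `beta`, spline coefficients: independent N(0, 10²) (configurable;
  `inf` gives flat priors).
* RW2 precision and OLRE precision: Gamma(shape 1, rate 0.01) — weakly
  informative, spanning several orders of magnitude around 1.
* Optional spatial pooling (`spatial_pooling=True`): an intrinsic-CAR
  random effect on the county-specific lag-0 sensitivity, built from the
  county adjacency graph Laplacian under a sum-to-zero constraint (the
  ICAR null space would otherwise absorb the global lag-0 coefficient).
  Off by default: the default model is the exact conditional
  case-crossover with no spatial sharing.

## Inference

* `map_laplace` (default): damped Newton on the joint penalized
  log-likelihood over (fixed effects, OLRE).  The OLRE block of each
  Newton system is block-diagonal by stratum and is eliminated by Schur
  complements, so each step solves only a (fixed-effects)² system.
  Precisions are set by empirical Bayes: Nelder-Mead on the
  Laplace-approximate log marginal posterior of the log-precisions, with
  warm-started inner solves.  The Gaussian approximation at the mode
  supplies the posterior draws (default 4 × 1000) from which equal-tailed
  95% intervals are taken.  Hyperparameter uncertainty is not propagated
  into the intervals; at the default study scale this is a second-order
  effect (coverage is checked empirically, below).
* `mcmc`: an affine-invariant ensemble sampler (emcee) over the fixed
  effects and log-precisions, with the OLRE integrated out by a
  per-stratum Laplace approximation inside the likelihood (an INLA-like
  hybrid).  Walkers initialize at the MAP solution scattered by the
  Laplace covariance.  Effective sample sizes per lag come from
  integrated autocorrelation times; a fit with low ESS is flagged
  `converged=False` but still reports intervals.  The two modes agree on
  posterior means within tolerance on fixtures (tested); they can differ
  on very sparse strata where the conditional posterior is skewed, since
  the Laplace mean is the mode.

Degenerate designs refuse loudly: a panel with no exposure variation
within any stratum raises "exposure not identifiable under conditioning";
an empty outcome subset raises "no outcome events".  Single-member strata
are excluded (counted in `results.info`); non-informative strata are kept
by default since they still inform trend, temperature, and overdispersion,
with a config flag to drop them for speed.

## Post-processing

Percent change per additional exposure day is `100*(exp(beta)-1)` applied
draw-wise; additional deaths per million (DPM) scales each percent draw by
`R0/100`, where `R0` is a baseline age-standardized monthly death rate per
million (a required user input; `baseline_rate_per_million` computes it
from a panel's final-year data by direct standardization, defaulting the
standard to the pooled age distribution, and takes the median across
counties).  DPM is proportional to percent change at the mean and both
interval endpoints by construction (asserted on every summary table).
The CrI-sign rule labels an association positive iff the lower bound
is ≥ 0, negative iff the upper is ≤ 0, else null.

Subgroup contrasts pair independent draws from the two groups' separate
fits (the fits share no parameters; independence is an approximation)
and summarize the per-lag differences.  Disadvantage categories
cross-classify counties by county-level poverty % and racial/ethnic
minority % dichotomized at the medians of the included counties; ties at
the median go to "low", and counties missing a covariate are excluded and
counted.

## Synthetic data

The generator emulates the structure of the restricted inputs:

* **Exposure**: exposed county-months fall in May–November with a fixed
  month-weight profile peaking in September; day counts per exposed month
  are zero-truncated geometric (p = 0.3, median 2 days) capped at the
  days in the month; each exposed day is a hurricane day with probability
  0.045, otherwise gale (matching the observed mix of 233 hurricane days
  among 5305).  Default exposure rate is 1 exposed county-month per
  county per year — sparse (≤ 8% of months, all in season) while giving
  every county exposure information; with any positive rate each county
  is guaranteed ≥ 1 exposed month.
* **Deaths**: negative-binomial counts (var = mu + theta·mu², default
  theta = 0.05) around a log-mean with county effects (sd 0.2), cosine
  seasonality (amplitude 0.1), a piecewise log-linear trend (default
  +5%/yr before December 2015, +10%/yr after, continuous at the break),
  a smooth monotone temperature effect (PCHIP through configurable
  knots), the planted per-lag log rate ratios (default 0.05 at lag 0,
  zero after), and a baseline of 1e-4 deaths per person-month (≈ 10
  monthly deaths in a county of 100 000, the magnitude of recent US
  psychoactive-death rates).  Counts split multinomially into overdose /
  mental-behavioral / alcohol-induced categories (58/17/25%), with
  overdose as the acute subclass.  Per-subgroup planted effects (e.g.
  sex-specific lag-0 log RRs) are supported for stratified-recovery
  tests.
* **Counties**: contiguous state blocks, a connected chain-plus-shortcut
  adjacency graph, poverty ~ N(16, 6)% and minority ~ logN(log 18, 0.6)%
  so empirical medians sit near 16%/18%; populations log-normal around
  80 000 with small county-specific growth, split by fixed age × sex
  fractions.
* **Temperature**: county-specific annual sinusoid (peak July) plus unit
  Gaussian noise — only smoothness matters to the RW2 term.

One global seed feeds a documented substream per stage, so the full panel
is bit-identical under a fixed seed and stages regenerate independently.
The truth record stores every planted component plus the expected counts
used for sampling; an internal-consistency test recomputes the log-mean
from the stored components.

What the generator does **not** emulate: hurricane track physics and
spatially correlated wind fields, migration/displacement, within-month
exposure timing (monthly counts are treated as sufficient, as in the
model), ICD coding-practice drift, and county-level reporting artifacts.
Passing tests therefore demonstrate that the estimator recovers effects
under the model's own data-generating assumptions — parameter recovery,
interval calibration, and the arithmetic of the reporting pipeline — not
that those assumptions hold in any particular real dataset.

## Validation scale

Replicate studies (parameter-recovery bias, interval coverage, the
acceptance script) use 30 counties × 10 years with a planted lag-0 log
rate ratio of 0.05 — a scale chosen so that a single fit carries enough
exposed strata (~300 cases) for stable estimation while 50–100 replicates
run in minutes on one CPU.  At this scale the per-replicate posterior sd
of `beta_0` is ≈ 0.005, so 50-replicate mean bias is resolvable well below
the 0.01 acceptance bound.

## Known limitations

* Empirical-Bayes precisions understate hyperparameter uncertainty; the
  measured CrI coverage at the default scale (≈ 92–95%) brackets the
  nominal level within binomial error, but severe sparsity could widen
  the gap.  The `mcmc` mode samples the log-precisions.
* The Dirichlet-multinomial mode fixes the RW2 precision at a weakly
  informative value rather than estimating it.
* Subgroup contrasts assume independent subgroup posteriors.
* Exposure is wind-only by construction; rainfall/flood hazards and
  distance-to-track metrics are out of scope.
* The conditional design estimates within-county associations; it says
  nothing about individual-level risk.
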