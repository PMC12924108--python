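# windlag

Time-stratified case-crossover analysis of tropical-cyclone wind exposure
and county-level psychoactive drug–related death rates.

## The problem

Tropical cyclones disrupt health care access, drug markets, and mental
health at the county scale.  A natural question for environmental
epidemiology is whether months containing cyclone-exposed days (days with
modeled sustained winds ≥ 34 kt at the county population mean center) see
elevated rates of psychoactive drug–related deaths — overdoses, mental and
behavioral disorders due to psychoactive substance use, and alcohol-induced
conditions — and for how long after exposure the elevation persists.

`windlag` implements that analysis as a reusable pipeline for
epidemiologists working with county-month panels: exposure assembly from
daily winds, ICD-9/ICD-10 outcome classification, the Bayesian conditional
quasi-Poisson case-crossover model with distributed lags, the
post-processing that turns lag posteriors into percent changes and deaths
per million, and the standard robustness drivers.  Because the real inputs
(restricted vital-statistics death records, county wind-exposure histories)
cannot be redistributed, the package ships a synthetic-data generator that
reproduces the statistical structure of those inputs with known planted
effects, so every stage is testable end to end.

## The model

Let $Y_{it}$ be deaths in county $i$, month $t$, and $x_{it}$ the number of
cyclone-exposed days.  The log death rate is modeled as

$$\log \mu_{it} = \alpha_{i,m(t)} + \sum_{\ell=0}^{L} \beta_\ell\, x_{i,t-\ell}
  + s(t) + f(\mathrm{temp}_{it}) + \log P_{it} + u_{it},$$

where $\alpha_{i,m(t)}$ is a stratum effect for county $i$ × calendar month
$m(t)$, $\beta_\ell$ are unconstrained distributed-lag log rate ratios per
additional exposure day (default $L = 3$), $s(t)$ is a piecewise
natural-cubic-spline long-term trend fitted separately before and after a
breakpoint (default December 2015, reflecting the national shift in opioid
mortality), $f$ is a second-order random walk over binned monthly mean
temperature, $P_{it}$ is the June-anchored interpolated monthly population,
and $u_{it}$ is a log-normal observation-level random effect carrying
overdispersion (a Dirichlet-multinomial conditional is available as a
negative-binomial-style alternative).

Conditioning each stratum on its total count removes $\alpha_{i,m(t)}$
exactly — every exposed county-month is compared with the same calendar
month of the same county in other years (a time-stratified case-crossover),
eliminating time-invariant confounding and mean seasonality.  Posteriors
come from a Laplace/empirical-Bayes approximation (`map_laplace`, fast) or
an ensemble MCMC sampler (`mcmc`); equal-tailed 95% credible intervals are
reported throughout, and effects are translated to percent changes
$100(e^{\beta_\ell}-1)$ and to additional monthly deaths per million by
scaling with a baseline age-standardized monthly death rate.

## Worked example

```python
import windlag as w
from windlag.model import CaseCrossoverModel, ModelConfig

cfg = w.GeneratorConfig(seed=1)          # 30 counties, 2010-2019,
panel = w.generate_panel(cfg)            # planted lag-0 log RR = 0.05
inputs = w.PanelInputs.from_synthetic(panel)
res = CaseCrossoverModel.from_inputs(inputs, config=ModelConfig(seed=1)).fit()
print(res.summary().round(4).to_string(index=False))
```

```
 lag    mean     sd  lower95  upper95    ess
   0  0.0437 0.0046   0.0347   0.0526 4000.0
   1 -0.0069 0.0051  -0.0168   0.0034 4000.0
   2  0.0036 0.0049  -0.0061   0.0133 4000.0
   3 -0.0057 0.0049  -0.0151   0.0038 4000.0
```

The lag-0 posterior mean (0.0437, CrI 0.0347–0.0526) recovers the planted
log rate ratio of 0.05 within its credible interval; the other lags, where
nothing was planted, are compatible with zero.  Translating to the reported
scales with a baseline rate computed from the generated 2019 data:

```python
r0 = w.baseline_rate_per_million(panel.deaths, panel.counties.population,
                                 year=2019, start_year=2010)   # 157.4 DPM
print(res.effect_summary(r0).round(2).to_string(index=False))
```

```
group strength_class  lag  pct_mean  pct_lo  pct_hi  dpm_mean  dpm_lo  dpm_hi    label
  all          total    0      4.47    3.53    5.40      7.03    5.56    8.51 positive
  all          total    1     -0.67   -1.67    0.34     -1.05   -2.62    0.54     null
  all          total    2      0.37   -0.61    1.34      0.58   -0.96    2.10     null
  all          total    3     -0.56   -1.50    0.38     -0.87   -2.36    0.60     null
```

A 4.47% increase per additional exposure day in the month of exposure,
7.0 additional monthly deaths per million, labeled positive because the
CrI is entirely non-negative; later lags are null.  The same surface
handles subgroup fits (`subset={"sex": "female"}`, age bands, acute vs
chronic subcauses, disadvantage categories via
`windlag.categorize_disadvantage`) and the sensitivity drivers in
`windlag.sensitivity` (lag-window grids, breakpoint variants,
leave-one-state-out, period restriction).

A command-line pipeline wraps the same steps:

```bash
windlag simulate --out study/ --seed 1
windlag fit --data study/ --out fit/ --seed 1
windlag postprocess --fit fit/ --r0 157.4 --out effects.csv
```

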