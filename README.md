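# joinpoint-survival

Joinpoint proportional-hazards modelling of cancer survival trends from
grouped life-table data.

Cancer registries usually report progress by comparing 5-year survival
between blocks of diagnosis years, which hides *when* survival started to
change and *how fast* it is changing. This package analyses grouped
(relative, cause-specific or overall) survival by **single calendar year of
diagnosis**: it fits a proportional-hazards model whose calendar-year effect
is piecewise linear on the log-hazard scale, finds the years at which the
trend changed (the *joinpoints*), and summarises each trend segment with
interpretable year-over-year measures and confidence intervals. It is aimed
at cancer surveillance researchers working with registry life-table exports
(e.g. grouped survival produced by SEER\*Stat), and at anyone who needs
trend-aware survival projections.

## The model

For patients diagnosed in calendar year $x$, the hazard of cancer death at
time $t$ since diagnosis is

$$\lambda(t\mid x) = \lambda_0(t)\,e^{h(x)},\qquad
h(x) = \beta x + \sum_{k=1}^{K}\delta_k (x-\tau_k)^+ ,$$

with joinpoints $\tau_1<\dots<\tau_K$ and $(u)^+=\max(u,0)$; with $K=0$ this
is a Cox model with diagnosis year as the covariate. Follow-up is discrete
(annual intervals $j$), the baseline entering as one log cumulative-hazard
mass $\alpha_j$ per interval, so the net interval survival is
$s_j(x)=\exp\{-e^{\alpha_j+h(x)}\}$ and cumulative survival satisfies
$S(t\mid x)=S_0(t)^{\exp h(x)}$.

Estimation maximises a grouped binomial likelihood on the life-table counts
(complementary log-log link, actuarial effective denominators as weights,
expected-survival multiplier in relative mode) by IRLS, with an exhaustive
grid search over integer joinpoint years for each $K$ and selection of $K$
by BIC (default) or AIC.

Each segment with slope $\beta^*$ is summarised by

* **APC_D** $=100\,(e^{\beta^*}-1)$ — annual percent change in the
  conditional probability of cancer death (constant over follow-up time);
* **AAC_S(t)** — average annual absolute change of cumulative $t$-year
  survival over the segment, in percentage points,
  $\tfrac{100}{x_1-x_0}\left[S(t\mid x_1)-S(t\mid x_0)\right]$;

both with delta-method 95% CIs. Survival can be projected beyond the data
by extending the last segment's trend.

## Worked example

No external data are needed — the bundled simulator draws registry-style
life tables from a known truth (here: 3000 diagnoses/year over 1995–2014,
five annual follow-up intervals, a mild decline in the hazard of death that
accelerates at a joinpoint in 2004):

```python
from joinpoint_survival import JoinpointSurvivalModel, SimulationConfig, simulate_table

cfg = SimulationConfig(
    year_range=(1995, 2014), n_intervals=5, cohort_size=3000,
    baseline_interval_survival=[0.80, 0.90, 0.93, 0.95, 0.96],
    beta=-0.01, deltas=(-0.06,), taus=(2004,), seed=7,
)
model = JoinpointSurvivalModel(max_joinpoints=2).fit(simulate_table(cfg))
print(model.summary())
```

```
 n_joinpoints joinpoints           bic           aic        loglik  converged  final_model
            0            146157.995433 146142.364412 -73065.182206       True        False
            1       2003 146096.268529 146075.427168 -73029.713584       True         True
            2 2000, 2004 146102.733435 146076.681733 -73028.340867       True        False
```

BIC selects one joinpoint, placed in 2003 — one year from the generative
truth. The per-segment trend measures:

```
segment 1995-2003: APC_D = -0.8% (95% CI -1.5 to -0.1), AAC_S(5) = +0.23 pp (95% CI 0.02 to 0.45)
segment 2003-2014: APC_D = -5.7% (95% CI -6.3 to -5.2), AAC_S(5) = +1.40 pp (95% CI 1.26 to 1.53)
```

Read: before 2003 the annual probability of cancer death fell 0.8% per later
year of diagnosis and 5-year survival gained 0.23 percentage points per
year; after 2003 the decline steepened to 5.7% per year (close to the
generative $100(e^{-0.07}-1)=-6.8\%$ with sampling noise), i.e. 1.4
percentage points of 5-year survival gained per year of diagnosis.
`model.project(horizon=3, t_values=[5])` extends the surface past 2014 by
continuing the last segment (`S_model` 0.800, 0.811, 0.821 for 2015–2017,
flagged `projected`).

The same pipeline runs from the shell:

```bash
joinpoint-survival simulate --config sim.yaml --out data/
joinpoint-survival fit --input data/table.csv --mode relative \
    --max-joinpoints 2 --t 5,1 --project 5 --out results/
```

`fit` writes, per cohort, the model ladder, fitted coefficients, a trend
table and tidy datasets for the three standard plots (survival by diagnosis
year, annual death probability by diagnosis year, survival curves by year
of diagnosis).

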