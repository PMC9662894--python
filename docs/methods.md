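# Methods

## Model and likelihood

The data are grouped life tables: for each calendar year of diagnosis $x$
and annual follow-up interval $j$ (1-based, covering $(j-1, j]$ years since
diagnosis), the number alive at the interval's start $n_{xj}$, the number
lost to follow-up $l_{xj}$, the number of deaths $d_{xj}$, and — for
relative survival — the expected interval survival $e_{xj}$ of a matched
general population. The hazard of cancer death is modelled as
$\lambda_0(t)\exp h(x)$ with the piecewise-linear calendar effect
$h(x)=\beta x+\sum_k \delta_k (x-\tau_k)^+$. Discretising time, the
baseline contributes one log cumulative-hazard mass $\alpha_j$ per interval,
giving net interval survival $s_j(x)=\exp\{-e^{\alpha_j+h(x)}\}$.

The likelihood is grouped binomial on the observed death fractions with the
actuarial effective denominators $w_{xj}=n_{xj}-l_{xj}/2$ as prior weights:
cell $(x,j)$ contributes $w_{xj}\{y\log\pi+(1-y)\log(1-\pi)\}$ with
$y=d_{xj}/w_{xj}$ and all-cause death probability
$\pi=1-e_{xj}\,s_j(x)$ in relative mode ($\pi=1-s_j(x)$ otherwise). The
effective denominators are non-integer and the death fractions accordingly
fractional (a quasi-binomial form); this preserves the actuarial information
without rounding bias. Because the expected-survival multiplier makes the
mean function non-standard, the fitter is a purpose-built Fisher-scoring
IRLS on this likelihood rather than an off-the-shelf GLM routine: the score
and expected-information weights are computed analytically from
$\partial\pi/\partial\eta = e\,s\,e^{\eta}$ (with $\eta=\alpha_j+h(x)$),
each step solved by weighted least squares, with step-halving whenever a
step would lower the likelihood. With all $e_{xj}=1$ this reduces exactly
to a binomial complementary-log-log GLM, which the test suite exploits by
cross-checking the optimum against a generic numerical maximiser of the
same likelihood.

Numerical choices: convergence is a relative log-likelihood change below
$10^{-8}$ (at most 100 iterations); $\eta$ is clipped at $\pm 30$ inside
the weight computation and cell probabilities at
$[10^{-12},\,1-10^{-12}]$ (clipped cells are counted in the fit result);
when a cell is pinned at a survival boundary (observed relative survival
above 1 drives $\alpha_j\to-\infty$) its weight vanishes and the scoring
step falls back to a pseudo-inverse, yielding a finite boundary fit whose
predicted survival remains inside $(0,1]$. The year anchor (the year
treated as $x=0$) is the first diagnosis year, chosen purely for numerical
conditioning; an invariance test asserts that shifting it changes no
prediction, criterion, or trend measure beyond $10^{-10}$.

The covariance of the free coefficients $(\alpha_1..\alpha_J,\beta,
\delta_1..\delta_K)$ is the inverse *observed* information (analytic
Hessian, validated against finite differences in the tests). Joinpoint
locations are treated as fixed when computing standard errors.

## Grid search and selection

For each $K$ up to the configured maximum (at most 5), every strictly
increasing $K$-tuple of integer years is fitted, subject to placement
constraints: at least 3 joinpoint-free years at the start of the range, 5
at the end, and 2 between consecutive joinpoints (all configurable). These
margins keep every segment identifiable and are deliberately conservative
defaults for registry series of 20–40 years. A segment containing fewer
than two diagnosis years is rejected before fitting. The best converged fit
per $K$ (ties broken toward the lexicographically earliest tuple) enters
the model ladder; the final model minimises
$\mathrm{BIC}=-2\ell_k+p_k\log n$ by default, or
$\mathrm{AIC}=-2\ell_k+2p_k$, where $n$ is the number of $(x,j)$ cells
(the total follow-up years across diagnosis years) and
$p_k=J+1+2K$ — each joinpoint is charged two parameters, its slope change
and its searched location. BIC is the default because it is the more
parsimonious criterion and the more reliable at recovering the true number
of joinpoints in simulation; AIC tends to select more joinpoints, so on any
one dataset the AIC-selected $K$ is at least the BIC-selected $K$.

## Trend measures

With segment slope $\beta^*=\beta+\sum_{k\le m}\delta_k$:

* $\mathrm{APC\_D}=100(e^{\beta^*}-1)$, the annual percent change in the
  conditional probability of cancer death; exact on the cumulative-hazard
  scale (the interval hazard-mass ratio between adjacent diagnosis years is
  $e^{\beta^*}$ for every interval) and a small-hazard approximation on the
  probability scale. SE by the delta method, $100\,e^{\beta^*}\,
  \mathrm{se}(\beta^*)$.
* $\mathrm{AAC\_S}(t)$: the average over a year window (by default a
  joinpoint segment; any window, including projected years, is accepted) of
  the consecutive-year differences in $t$-year survival, in percentage
  points. The average telescopes exactly to
  $100\,[S(t\mid x_1)-S(t\mid x_0)]/(x_1-x_0)$, which is what is computed;
  the implementation keeps the direct averaged form alongside and asserts
  their identity to $10^{-12}$. The SE propagates the analytic gradient of
  the telescoped form through the coefficient covariance via
  $S(t\mid x)=\exp\{-e^{h(x)}\sum_{j\le t}e^{\alpha_j}\}$; a
  central-finite-difference gradient (relative step $10^{-6}$) is kept as a
  cross-validation fallback. Within a segment the two measures always have
  opposite signs; no ordering between $|\mathrm{AAC\_S}(1)|$ and
  $|\mathrm{AAC\_S}(5)|$ holds in general and none is asserted.

Significance markers use normal 95% intervals
($\hat\theta\pm1.96\,\mathrm{se}$); a trend whose CI spans zero is reported
as not significant. The trend table optionally highlights segments with
AAC_S above 1 percentage point or APC_D below −5% — a presentation
convention, not an inferential threshold.

Projection evaluates the same $h(x)$ beyond the last data year $L$, which
extends the last segment linearly; the surface is continuous at $L$ by
construction. Projections, and in-sample $(x,t)$ cells with no observed
follow-up, are flagged. A long extrapolation is least trustworthy when the
last joinpoint sits close to $L$, since the last-segment slope then rests
on few years.

## Synthetic data

The simulator draws tables from the model itself: per year and interval,
scheduled losses are Binomial($n$, loss probability), then deaths are drawn
among the remaining $n-l$ at the cell's all-cause death probability $\pi$,
plus deaths among the scheduled-lost at $1-\sqrt{1-\pi}$ (death in the
first half of the interval under a constant within-interval hazard); a
scheduled-lost case that dies is recorded as a death, not a loss. This
realises the actuarial half-exposure convention, so the $n-l/2$ life-table
estimator is unbiased for the generative interval survival (verified at
$n=5\times10^5$/year with 10% losses) and recovery tests compare like with
like. Defaults: expected interval survival 0.97 (a typical annual expected
survival for an elderly cancer population), loss probability 0.02 per
interval, five follow-up intervals. The optional non-proportionality switch
multiplies $h(x)$ by a factor for late intervals after a break year,
mimicking a treatment that chiefly benefits patients who have already
survived several years.

What the generator does not emulate: covariate heterogeneity within a
cohort, period effects in follow-up time (everything is a diagnosis-cohort
effect), informative censoring, registry artefacts such as autopsy/death-
certificate cases, and misspecified expected survival. Passing recovery
tests therefore demonstrate correctness of estimation under the model's own
assumptions, not robustness to their violation — with the exception of the
proportionality violation, which is simulated explicitly and diagnosed via
the residual pattern of the annual-death-probability surface (opposite
signs at early vs late intervals) disappearing when follow-up is
restricted to two years.

## Validation design and problem sizes

The validation suite uses simulated study conditions of 20 diagnosis years,
five follow-up intervals and 2000–5000 diagnoses per year: joinpoint
recovery and slope-CI coverage run 50 replicates at 5000/year (coverage is
evaluated on fits at the true joinpoint, the estimand for which the
nominal 95% level is defined, while selection accuracy is evaluated on the
full grid search); the delta-method AAC_S SE is checked against a
200-replicate parametric bootstrap (resimulate from the fitted model, refit
at the same joinpoints); large-sample consistency checks use single tables
of $10^5$–$10^6$ diagnoses per year. These sizes make the full suite run in
well under a minute while leaving Monte-Carlo error far smaller than the
asserted tolerances.

## Known limitations

* Proportionality of the baseline hazard across diagnosis years is assumed;
  violations bias trend measures (restrict follow-up to diagnose, as above).
* Joinpoints are restricted to integer calendar years inside the observed
  range, and their locations are treated as known when computing standard
  errors, so CIs are slightly anti-conservative near a weakly identified
  joinpoint.
* No covariates besides diagnosis year; cohorts are modelled independently
  with no pooling or formal comparison between trend lines.
* Relative survival uses the supplied expected interval survival as fixed
  and error-free; age-standardisation and period/hybrid estimation are out
  of scope.
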