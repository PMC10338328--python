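# Methods

## The model

An intensity bioassay exposes `n_i` mosquitoes in tube `i` to a
concentration `c_i` of insecticide (% active ingredient, with `c_i = 0`
for control tubes) and records the dead count `y_i`.  We model

    y_i ~ Binomial(n_i, p_i)

with the mean mortality given by an asymmetric five-parameter logistic
(5PL) in the log of the square-root concentration:

    p_i = D + (A − D) / [1 + exp(B (ln x_i − C))]^E,   x_i = sqrt(c_i).

The square-root transform compresses the doubling dose series used in
practice so the curve is not dominated by the highest concentrations; all
lethal-concentration outputs are squared back to the raw % a.i. scale.

Parameter roles, restrictions and default priors (scales are standard
deviations; `N+` denotes a normal truncated to its support):

| parameter | role                           | restriction | prior        |
|-----------|--------------------------------|-------------|--------------|
| A         | background (control) mortality | 0 < A < 1   | N+(0, 0.1)   |
| B         | slope / shape                  | B > 0       | N+(5, 10)    |
| C         | location on ln sqrt(c) axis    | —           | N(0, 5)      |
| D         | upper asymptote                | fixed       | D = 1        |
| E         | asymmetry                      | E > 0       | N+(7, 10)    |
| F, G      | temporal intercept / slope     | —           | N(0, 5)      |

`D = 1` encodes the assumption that a sufficient dose kills every
mosquito; it can be freed (`PriorSpec` accepts a `D` entry) when that
assumption is doubtful, at the cost of extrapolation ability.  Estimating
`A` jointly replaces the classical Abbott pre-correction — the
`abbott_correct` utility is provided only for comparison with
conventional workflows.

The zero-dose limit of the curve is exactly `A`; control tubes enter the
likelihood through that limit rather than through `ln 0`.  Inside the
likelihood, `p` is clamped to `[1e-9, 1 − 1e-9]` so that impossible
observations under extreme parameter proposals keep finite
log-probability and gradients.

### Temporal variants

Resistance drift across survey years `t` (coded `t = year − first year`,
so `F` is the first-year location; any affine recoding merely
reparameterises `F, G` and leaves all reported quantities unchanged):

* **linear_time** — `C → F + G·t`: a steady shift of the curve location;
  the LC50 grows by the factor `exp(2G)` per year.
* **individual_time** — a free `C_t` per year, shared `A, B, E`.
* **base_time** — an independent full parameter set per year.  Because
  the likelihood and priors factorise by year, this is fitted as
  independent per-year base-model fits whose draws are reassembled in
  record order.

With degenerate parameters (`G = 0`, equal `C_t`, equal per-year sets)
every variant reproduces the base curve bit-for-bit; this is covered by
tests.

## Inference

Posteriors are sampled by an adaptive random-walk Metropolis sampler on
an unconstrained scale (logit for `A`, log for `B` and `E`), with the
appropriate Jacobian terms.  Four chains run in lockstep (vectorised);
during the 50% warmup each chain adapts a full proposal covariance from
its running history (Haario-type) and a global step size targeting ~30%
acceptance; both are frozen for the retained half, so kept draws come
from a fixed kernel.  Runs are fully deterministic given the
configuration seed.

Defaults are 4 chains × 5000 iterations; convergence is declared when
every parameter's rank-normalised split-R̂ is below 1.01.  A fit that
fails the criterion is still returned but flagged, and callers can
escalate to 10000 iterations.  Distributional correctness is verified
two ways rather than by parity with any particular sampling engine: a
conjugate-reduction oracle (a binomial proportion under the truncated
background prior, checked against deterministic grid integration) and
simulation-based recovery (95% interval coverage of the true LC50 across
seeded replicates).

Posterior predictive checks simulate replicate counts per retained draw
and report per-concentration residuals and randomised PIT tail
probabilities, which are uniform when the model is calibrated.

## Derived metrics

**LC_q.**  Solving the background-corrected mortality
`(p − A)/(1 − A) = q` gives the closed form

    x* = exp(C + ln((1 − q)^(−1/E) − 1) / B),   LC_q = (x*)²,

independent of `A` (the `1 − A` factors cancel; verified to 1e-12 in
tests, and the closed form is checked against numerical curve inversion
to 1e-8 over 1000 random parameter sets).  Note the background-corrected
reading means LC_q is the dose at which a fraction `q` of mosquitoes die
*of the insecticide*; solving the raw curve `p = q` instead would be
undefined for `q ≤ A`.  Applied per posterior draw, summarised by the
median and 2.5–97.5% quantiles (the mean is also carried, since
strain-level tables are often reported as means across draws).  Temporal
fits require an explicit year; the linear variant uses `C = F + G·t`.

**Heterogeneity.**  `LC90 − LC10` (means across draws): the span of
concentrations over which most of the population dies.  Wide spans flag
heterogeneous resistance.

**Lethal-dose density.**  Inverse transform sampling: pair a uniformly
chosen posterior draw with `u ~ U(0,1)` and return `LC_u`.  The
empirical distribution integrates parameter uncertainty over the
population distribution of individual lethal doses.

**Variability.**  Per draw `j`:  `v_j = Σ_i |y_i − y'_ij| / n` on the
percent-mortality scale, where `y'_ij` is the fitted-curve mortality at
record `i` (an alternative mode uses binomial posterior-predictive
replicates instead; the curve reading is the default because the metric
is meant to measure distance of the data from the best-fit line).
Summarised by median and 95% interval, read as "percent variability in
mortality from the best-fit line".

**Fit statistics.**  R² and RMSE between observed percent mortality and
the posterior-median curve, with residuals grouped by concentration.

**Comparisons.**  `P[LC_a > LC_b]` by resampling independent draw pairs
(default 10000 pairs, seeded).

## Model comparison

Out-of-sample predictive quality is scored by PSIS-LOO (delegated to
arviz' `loo`; pointwise contributions sum exactly to the total, and
points with Pareto k̂ > 0.7 are counted as unreliable).  On a four-record
fixture the approximation is validated against brute-force exact
leave-one-out refitting.  Two nested workflows:

* **strain difference** — pooled base model vs independent per-strain
  fits whose pointwise log-likelihoods are reassembled in pooled record
  order for a paired comparison;
* **temporal change** — fixed vs linear vs individual vs base-time, in
  order of free-parameter count; a more complex model is selected only
  when the paired elpd Z-test is significant (default threshold 0.05,
  configurable; the comparison table is always emitted so a stricter
  cutoff can be applied).

The P-value is the two-sided normal tail of the Z-score of the paired
elpd difference.  We use the standard orientation — higher elpd is
better — and print the negated (deviance-scale) value alongside to avoid
sign confusion.

## Synthetic data

The generator draws `y ~ Binomial(n, p_truth(c, t))` on a specified
design: it reproduces exactly the variability structure the model
assumes (binomial tube-level noise), which is what makes parameter
recovery and calibration tests meaningful.  It deliberately does **not**
simulate features of real field data such as extra-binomial
overdispersion (environmental and batch effects), species-composition
drift, or operator error; passing tests therefore demonstrate
correctness of the machinery, not robustness to misspecification.

Preset designs: two laboratory strains (steep curves, true LC50 4.9e-5
and 4.8e-3 % — the susceptible/strongly-resistant colony scale), one
heterogeneous strain (slope 2 instead of 5, so a much wider LC10–LC90
span), and two six-year field series (stable, and a linear drift giving
a 2.8-fold LC50 increase from first to last year).  Defaults of 25
mosquitoes per tube and 4 replicate tubes per concentration (lab), and
30 × 2 (field), reflect typical WHO-tube practice; concentration grids
are doubling series including a control, chosen to span
background-to-near-total mortality (the generator warns when a custom
grid does not).

## Numerical choices and problem sizes

* `(1 + e^z)^(−E)` is computed as `exp(−E·softplus(z))` with an
  overflow-safe softplus; the control limit returns `A` exactly.
* Likelihood clamp 1e-9; prior densities include truncation constants
  (the ×2 of a half-normal, and A's upper truncation at 1, negligible at
  scale 0.1 but applied).
* Warmup discards exactly `floor(warmup_fraction × n_iterations)` draws
  per chain; retained draws are pooled across chains for all metrics.
* Degenerate inputs: zero-variance observations give `R² = NaN` with a
  warning; identical chains give `R̂ = NaN`; flat mortality data fit but
  carry a "no dose-response signal" warning.
* Test and acceptance runs use reduced sampler budgets (1500–8000
  iterations) and 10–20 replicate simulations per property; these sizes
  give stable pass/fail behaviour for the properties checked while
  keeping the full suite fast.

## Known limitations

* Strictly binomial observation noise; real field assays are often
  overdispersed, which will show up as elevated variability and poor
  posterior-predictive calibration rather than being modelled.
* Random-walk Metropolis mixes more slowly than gradient-based samplers;
  high-dimensional variants (individual/base-time over many years) may
  need the 10000-iteration escalation.
* The `base_time` variant shares no information across years, so
  single-year LC estimates can be wide where data are sparse.
* LC values beyond the tested dose range are prior-driven
  extrapolations; treat LC90 with particular caution when top doses do
  not approach full mortality.
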