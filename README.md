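# bioassayfit

Bayesian dose-response analysis of insecticide **intensity bioassays** —
assays in which batches of mosquitoes are exposed to a series of
insecticide concentrations (plus unexposed controls) and mortality is
recorded per tube.  The package is aimed at entomologists and
vector-control analysts who need more from these data than a discriminating
dose "resistant / susceptible" call: lethal-concentration estimates with
honest uncertainty, population-heterogeneity summaries, assay-noise
quantification, and formal tests of whether resistance differs between
strains or drifts over years.

## Model

Dead counts are binomial around a five-parameter logistic (5PL) curve with
background mortality:

    y_i ~ Binomial(n_i, p_i)
    p_i = D + (A − D) / [1 + exp(B (ln x_i − C))]^E,   x_i = sqrt(c_i)

where `c_i` is the concentration in % active ingredient (entered on the
square-root scale to compress the doubling series typical of these
assays), `A` is control (background) mortality, `B` the slope, `C` the
location, `D` the upper asymptote (fixed at 1), and `E` the asymmetry.
Background mortality is estimated jointly rather than Abbott-corrected
away.  Weakly-informative priors: `A ~ N+(0, 0.1)`, `B ~ N+(5, 10)`,
`C ~ N(0, 5)`, `E ~ N+(7, 10)`.

Temporal variants let the curve change across survey years: a linear
drift in `C` (`C → F + G·t`), a free location per year, or a fully
independent curve per year.  Posteriors are sampled with a seeded
adaptive-Metropolis MCMC (4 chains, 50% warmup, rank-normalised split-R̂
convergence check), and derived metrics — LC₅₀ and any other LC_q (closed
form, background-corrected), the LC₁₀–LC₉₀ heterogeneity span, the
lethal-dose density by inverse transform sampling, per-draw mean-absolute
assay variability, R²/RMSE — are computed draw-by-draw.  Competing models
(pooled vs per-strain; fixed vs temporal) are compared by PSIS-LOO elpd
with a paired Z-test.

## Worked example

```python
import bioassayfit as bf

spec = bf.preset_scenarios()["lab_resistant"]     # true LC50 = 4.8e-3 %
data = bf.simulate_bioassay(spec, seed=2024)      # 40 tubes, 25 mosquitoes each
res = bf.DoseResponseModel(data, "base").fit(seed=17)

print(res.lc(0.5))
print(res.background_mortality()["mean"])
print(res.variability().median)
```

prints (draws vary slightly with the seed):

```
LC50 = 0.00452 (95% CI 0.004073-0.005051)
7.8478793403841784
3.8606303134898456
```

i.e. the median lethal concentration is estimated at 0.0045% permethrin
with a 95% credible interval comfortably covering the simulation truth
0.0048%, background mortality is estimated near the true 9%, and the
typical distance between observed tube mortality and the fitted curve is
about 3.9 percentage points.  `res.summary()` gives the posterior table
with R̂ per parameter; `bf.temporal_change_test(...)` and
`bf.strain_difference_test(...)` run the hypothesis workflows and report
elpd differences, Z-scores and P-values.

The same pipeline is available from the shell:

```sh
bioassayfit simulate --preset field_drift --seed 1 --out sim/
bioassayfit fit --data sim/field_drift.csv --model linear-time --seed 1 --out fit/
bioassayfit compare --data sim/field_drift.csv --mode temporal --seed 1 --out report.json
```

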