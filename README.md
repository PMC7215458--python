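# htarisk

Characteristics, cause and severity analysis for road **h**azmat
**t**ransportation **a**ccidents (HTAs): F-N societal-risk curves under
slope uncertainty with ALARP zoning, a CHAID cause–consequence decision
tree, and spatial clustering of regions with statistical validation.

The package is aimed at transportation-safety analysts who hold a survey of
accident records (one row per accident: time, region, dangerous-goods
classes, collision taxonomy, cause factor, road level, deaths, serious
injuries, economic loss) and want to answer three questions:

1. **Characteristics** — what do the accidents look like in time, space and
   hazmat class? (descriptive summaries, accident rate per unit freight
   volume, k-means clustering of provinces on socio-economic features with
   ANOVA + Tukey HSD validation of the cluster count)
2. **Cause** — which factors drive consequence severity? (a chi-squared
   automatic interaction detection tree over Levels II–V, evaluated with a
   confusion matrix)
3. **Severity** — how severe is the societal risk? (an F-N curve with an
   uncertainty band, judged against ALARP criterion lines)

## The core method

For fatal accidents grouped by exact death count, the F-N curve plots the
cumulative frequency of *N*-or-more deaths,

```
F(N) = Σ_{i ≥ j} n_i / Σ_i n_i ,
```

against *N* on log–log axes, and a power-law criterion curve is
`F = C·N^(−a)`, i.e. `lg F = −a·lg N + lg C`. A single fitted steepness
`a` hides the scatter of the per-point slopes `−a_i = lg F_i / lg N_i`, so
the slope is treated as an uncertain quantity and three descriptions are
fitted and ranked by R² and dof-adjusted RMSE:

* **normal**: slope mean μ and sample sd σ, with the population interval
  μ ± 1.96σ;
* **improved normal**: `f(x) = B + D/(σ√(π/2)) · exp(−2(x−μ)²/σ²)` fitted
  to the slope histogram by least squares;
* **power law**: `F = C·N^(−a)` fitted directly (log–log OLS, and
  unweighted nonlinear least squares in linear F space), with 95%
  intervals on `(a, C)` that define a confidence band around the curve.

The band is then classified against two ALARP limit lines (`a = 1`,
tolerable intercept 0.1, acceptable intercept 0.001): above the tolerable
line the risk is unacceptable, below the acceptable line broadly
acceptable, in between tolerable only if reduced as low as reasonably
practicable. The band edges give optimistic/pessimistic readings, e.g. the
death count beyond which the curve drops into the acceptable zone.

A 19-group fatality table from a published 15-year survey of 371 Chinese
road HTAs (2004–2018) ships as a packaged fixture, together with the
survey's expanded-case categorical marginals and its published confusion
matrix; the `htarisk.synthetic` module generates record sets and region
tables with planted structure for everything the fixture does not cover.

## Worked example

```
$ htarisk --out demo --seed 11 simulate --n 371        # synthetic survey
$ python -c "from htarisk.datasets import fn_table_china; \
             fn_table_china().to_csv('fn.csv', index=False)"
$ htarisk --out demo fncurve fn.csv
$ htarisk --out demo alarp demo/fn_fit.json --n-max 58
central-curve verdict over N in [1, 58]: unacceptable
```

`demo/fn_fit.json` then contains, for the packaged China series:

| model            | parameters                        | R²     | RMSE   |
|------------------|-----------------------------------|--------|--------|
| normal           | μ = −1.3424, σ = 0.0915           | 0.6468 | 1.6169 |
| improved normal  | μ = −1.3810, σ = 0.1252           | 0.9872 | 0.4360 |
| power law (NLS)  | a = 1.3035, C = 1.0164            | 0.9936 | 0.0197 |

The power law wins the ranking. Its 95% intervals, a ∈ (1.2286, 1.3785)
and C ∈ (0.9757, 1.0570), form the uncertainty band; the normal fit's
population interval (−1.5217, −1.1631) implies that accidents with ≥10
deaths are 14.56–33.25 times as frequent as accidents with ≥100 deaths.
The central curve sits above the tolerable line throughout the observed
range (F ≈ 1 at N = 1 versus the tolerable 0.1), hence the *unacceptable*
verdict; it would only cross the tolerable line near N ≈ 2080, far beyond
the data, so the extrapolated crossing is reported but flagged.

The remaining stages run the same way: `htarisk chaid records.csv` prints
the tree with per-node class percentages and writes the confusion matrix,
and `htarisk --seed 11 cluster regions.csv` screens features, runs the
elbow scan and reports which cluster counts pass the ANOVA + Tukey
validation (for the default synthetic regions: recommended k = 4).

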