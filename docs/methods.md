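# Methods

## Severity grading

Accidents are graded on China's five-level production-safety scale from
three consequence criteria, taking the most severe level any criterion
triggers:

| level | deaths | serious injuries | direct loss (10⁴ yuan) |
|-------|--------|------------------|------------------------|
| I     | 0      | 0                | < 1000                 |
| II    | 1–2    | 1–9              | —                      |
| III   | 3–9    | 10–49            | 1000–4999              |
| IV    | 10–29  | 50–99            | 5000–9999              |
| V     | ≥ 30   | ≥ 100            | ≥ 10000                |

The byelaw's prose leaves the exact cut points ambiguous ("more than 3 but
less than 10" vs "less than 3"); we close every interval on the more-severe
side, which makes the classification total and monotone: increasing any
input never lowers the level. One consequence worth noting: an accident
with no casualties is Level I *unless* its loss reaches 10 million yuan, in
which case the loss criterion raises it to Level III or above — economic
loss alone never produces Level II.

## F-N series

Only fatal accidents enter the series. Accidents are grouped by exact
death count; the cumulative frequency at group *j* is the tail count sum
divided by the total, so F = 1 at the smallest death count and the series
is strictly decreasing across groups. Per-point slopes are lgF/lgN and are
undefined at N = 1 (lgN = 0); all fits of the slope distribution use the
remaining points.

Published tables are treated as first-class inputs: an `FNSeries` can carry
a table's printed F, log and slope columns verbatim, because printed values
are typically rounded or lightly renormalised relative to the raw count
ratios (in the packaged China table the counts sum to 370 while the printed
F(N≥2) = 0.480 ≠ 177/370) and published downstream statistics are anchored
to the printed columns. New data always take the full-precision count
pathway.

## Slope-uncertainty fits

* **Normal.** μ and σ are the arithmetic mean and sample (n−1) standard
  deviation of the per-point slopes. `interval_95 = μ ± 1.96σ` is a
  *population dispersion* interval — the central 95% range of the slope
  distribution, not a standard-error interval on μ. It is the interval
  that propagates into fatality-ratio bounds ((n2/n1)^a evaluated at the
  endpoints) and slope-fit bands. R²/RMSE compare the implied density with
  the slope histogram and therefore depend on the binning.
* **Improved normal.** `f(x) = B + D/(σ√(π/2))·exp(−2(x−μ)²/σ²)` is
  least-squares fitted to the histogram densities with all four parameters
  free (initialised at B = 0, D = 0.5, sample moments). The baseline B
  absorbs heavy shoulders the pure Gaussian cannot reach. Note the σ in
  this parameterisation is not the Gaussian sd (the exponent is −2x²/σ²,
  not −x²/2σ²).
* **Binning.** Histogram-space metrics require an explicit binning;
  the default is Sturges' rule. On the packaged 18-slope sample, five
  equal-width bins reproduce the published improved-normal parameters
  (μ ≈ −1.370, σ ≈ 0.118) almost exactly, while Sturges (6 bins) gives
  μ ≈ −1.381, σ ≈ 0.125 — the binning is the one free parameter a
  published histogram fit does not pin down.

## Power-law fits and the band

Two estimators are exposed and labelled by `fit_space`:

* `loglog_ols` — OLS of lgF on lgN over all points including the (0, 0)
  origin of the N = 1 group, with textbook t-based intervals (n−2 dof).
* `linear_nls` — unweighted nonlinear least squares of `F = C·N^(−a)` on F
  itself, initialised from the log-log fit; R² = 1 − SSE/SST on F and
  RMSE = √(SSE/(n−2)); intervals from the Jacobian linearisation with a
  t(n−2) quantile.

The linear-space fit is what published F-N goodness-of-fit numbers
correspond to (the log-log fit down-weights the large-F head where the
absolute residuals live), and on the packaged series its Jacobian
intervals — a ∈ (1.2286, 1.3785), C ∈ (0.9757, 1.0570) — are the
band actually published for that survey. Bands pair the steepest slope
with the smallest C (lower edge) and the shallowest slope with the largest
C (upper edge), so the envelope nests the central line for all N ≥ 1.

**Caveat on the OLS intervals.** Empirical cumulative frequencies are
strongly autocorrelated along N, so the iid-error assumption behind both
t-interval constructions is wrong for raw accident data: in simulation the
slope estimate is essentially unbiased but its true sampling sd is several
times the OLS standard error, and nominal 95% intervals cover the true
exponent far less than 95% of the time. For calibrated uncertainty on new
data use `bootstrap_slope_interval`, which resamples whole accidents,
regroups and refits; its percentile interval covers a planted exponent at
roughly the nominal rate (≈93–96% in simulation at survey-scale n). The
analytic intervals are kept for published-table reproduction and as
conditional-on-groups summaries.

## ALARP zoning

Default lines: tolerable `F = 0.1·N^(−1)`, acceptable `F = 0.001·N^(−1)`
(slope 1 = neutral risk attitude; acceptable intercept 1% of tolerable).
Points exactly on a line belong to the less severe zone. A curve's summary
verdict is the worst zone its central line attains over the evaluated N
range; the range defaults to the observed data support, and any evaluation
beyond the largest observed N must be explicitly requested because the
verdict out there rests on the fitted tail, not on data. Crossings
`N* = (C_c/C_line)^(1/(a_c−a_line))` are computed in log space; a crossing
beyond the float range (near-parallel lines) reports as infinity.

## CHAID

Standard chi-squared automatic interaction detection with Kass's
Bonferroni correction: per node and predictor, the least-distinguishable
pair of categories (adjacent only for ordinal predictors — here the
day-part period) is merged while its 2×C chi-square p exceeds
`alpha_merge`; the merged table's Pearson p is multiplied by the number of
ways the original categories reduce to the merged groups (Stirling number
for nominal, binomial coefficient for ordinal); the most significant
predictor splits the node if its adjusted p ≤ the split threshold and all
children have at least `min_child` cases.

With several predictors each tested at `alpha_split`, the node-level
probability of a *false* split inflates to roughly `1 − (1−α)^p` (≈ 0.26
for six predictors at 0.05). `adjust_predictors` (default on) divides the
split threshold by the number of predictors tested at the node, the
Bonferroni step that restores node-level control: on target-independent
data the tree then stays a single leaf in ~95% of simulations. A rejected
best split (child-size violation) makes the node a leaf rather than
falling through to a weaker predictor, which keeps pruning monotone in
`min_child`. Prediction routes by merged-group membership, sends unseen
categories to the largest sibling child, and breaks modal-class ties
toward the more severe level — conservative for risk management. The
algorithm contains no randomness: identical inputs give identical trees.

Accidents carrying k hazmat classes are expanded to k single-class cases
before tree building, so per-level totals are conserved with class
multiplicity (371 survey accidents → 569 cases).

## Spatial stage

Candidate region features (population, GDP, road freight volume,
road-network length) are screened by Pearson correlation with the accident
counts (threshold 0.6); among the survivors the least mutually correlated
pair is selected so the two cluster features carry complementary
information. Features are z-scored before k-means (they live on
incommensurate scales), and each k uses the best of 10 restarts. The elbow
scan reports SSE per k with discrete-curvature candidates, advisory only;
competing k are adjudicated by one-way ANOVA and Tukey HSD on a per-region
summary score — by default the first principal component of the z-scored
selected features, oriented so larger features score higher ("comprehensive
factor score"); any other per-region score array can be supplied. A
solution passes only if the ANOVA and *every* pairwise comparison reject
at 0.05; the offending pair is reported otherwise. Identical scores
everywhere short-circuit to a failed verdict. Note the validation is
meaningful for *planted or externally given* assignments; validating a
partition derived from the same score axis invites a selection effect that
overstates separation.

## Synthetic data

`generate_deaths` draws i.i.d. death counts with survival function exactly
`P(deaths ≥ N) = N^(−a*)` via inverse transform (`floor(U^(−1/a*))`),
truncated at `max_deaths = 60` to mirror the observed range of the
packaged survey (max 58) — the planted a* *is* the F-N slope a fit should
recover. `generate_records` (defaults: 371 accidents, a* = 1.34, the
expanded-case categorical marginals of the survey) draws categorical
attributes independently; the severity level follows its marginal unless a
planted cause→consequence rule fires, and the death count is then drawn
from the tail law conditioned on the level's death range, so classified
severity matches by construction. `generate_regions` draws Gaussian
features around four well-separated province tiers (31 regions) and links
accident counts to the features at a configurable correlation.

What the generator does *not* emulate: dependence between predictors,
temporal seasonality or spatial autocorrelation beyond marginals, economic
losses correlated with casualties, and the reporting biases of a real
survey. Passing tests demonstrate that the machinery recovers structure it
can see at these sample sizes, not that real accident data satisfy the
power-law or independence assumptions.

## Problem sizes and numerical choices

Simulation-based tests use survey-scale problems: 200 replicates of
371-accident samples for slope-interval coverage (199 bootstrap resamples
each), 100 null replicates for the tree's false-split rate, 569-case
samples for marginal fidelity. Optimiser starts come from closed-form
fits (log-log OLS for the power law, sample moments for the histogram
densities); exact fits with singular Jacobians report zero-width
intervals; model ranking sorts by descending R² with RMSE as the
tie-break, stable in input order.

## Known limitations

* The power-law fit is least squares on the cumulative curve, matching the
  published methodology; it is not a maximum-likelihood discrete power-law
  estimator, and no tail-cutoff selection is attempted.
* Histogram-space R²/RMSE are binning-dependent by nature; they are
  reported with the binning that produced them and should not be compared
  across binnings.
* The published 14-node tree for the China survey cannot be reconstructed
  exactly because the underlying 569-case records were never deposited;
  the packaged marginals and confusion matrix support arithmetic and
  structural checks only.
* Figure-derived fatality thresholds quoted for external survey datasets
  are not reproduced; the pipeline accepts any such series as input but
  ships none of the digitised values.
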