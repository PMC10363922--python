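# Methods

## The multiverse

A specification is one analysis cell: an OxMET metric (x), a comparator
metric from the Trails or rule-finding catalogues (y), a sample group
(healthy, stroke, combined = simple union, no group covariate), and a
covariate condition (plain Spearman, or partial Spearman with age and
education).  Enumeration is the full Cartesian product in fixed order
(x, then y, then group, then covariate condition), so spec ids are
stable across runs and outputs are diffable.  The default catalogues
give 10 × 37 × 3 × 2 = 2,220 specifications.

## Metric catalogue and scoring rules

The catalogue holds 47 metrics (10 OxMET, 30 Trails, 7 rule finding),
each tagged with a category (time / accuracy / error / composite) and a
direction.  Direction metadata is informational only: values are never
sign-flipped before correlation, which is why between-category
correlations are typically negative.

Decisions embodied in the formula registry (each rule is overridable):

* Unlabelled Trails subtraction/ratio composites (B−A, B/A and variants)
  operate on completion **time** — the classic TMT derived scores are
  time-based.  Rows that explicitly name accuracy or errors use those
  fields.
* `trails_b_over_a_sum` territory is occupied by the named executive
  ratio score `trails_exec_ratio` = Trail B accuracy / (Trail A circles
  accuracy + Trail A squares accuracy) × 100, the one ratio defined as
  accuracy-based "as a percentage" by its source battery.
* "Mean Trail A" is the arithmetic mean of the circles and squares
  values; the "median" of the two conditions equals that mean.
* A time-over-itself ratio (Trail B time / Trail B time) is identically
  1 and cannot enter a correlation; it is excluded from the catalogue,
  which is why the Trails block has 30 entries rather than 31 candidate
  rows.
* `trails_err_b_per_time_a_squares` pairs Trail B errors with Trail A
  squares time.  The pairing looks like a typographical artifact of the
  source metric list but is implemented verbatim; treat with care.
* Zero denominators produce missing values, never ±inf, keeping rank
  statistics well defined.  Missing ingredients propagate (no
  imputation).  Times are in seconds; counts are raw unless a rule says
  "as a percentage".  No timeout cap is applied to completion times.

## Correlation conventions

* **Spearman**: pairwise-complete deletion, average ranks, ρ = Pearson
  correlation of ranks, p from t = ρ√((n−2)/(1−ρ²)) with n−2 df, 95% CI
  from Fisher's z with SE 1/√(n−3).  The Bonett–Wright SE
  √((1+ρ²/2)/(n−3)) is available via `ci_method="bonett-wright"`.  The
  CI method behind the source study's intervals is unknown, so interval
  reproduction on real data is approximate by construction.
* **Partial Spearman**: listwise-complete over x, y and covariates
  (standard partial-correlation practice; plain correlations stay
  pairwise), average ranks computed on the complete cases, x- and
  y-ranks residualized on the covariate ranks by least squares,
  residuals correlated; p with n−2−k df, CI SE 1/√(n−3−k).  Constant
  covariates are dropped with a warning.  If a variable is exactly
  collinear with the covariates its rank residual is numerically zero;
  the result is reported as ρ = 0, p = 1 (no remaining association)
  rather than noise.
* Fewer than 4 complete pairs (4 + k for partials) gives a
  missing-marked result, not an exception; missing-marked cells are
  excluded from curve medians and significance shares but counted and
  reported.  α = .05 throughout (configurable).

## Two-sample tests

* **Wilcoxon rank sum with continuity correction**: normal approximation
  with tie correction; |Z| = (|U − n_a n_b/2| − 0.5)/σ.  The reported
  statistic is U of the first sample — the first sample's rank sum R_a
  minus n_a(n_a+1)/2 — which is exactly what R's `wilcox.test` prints as
  W, so published W values are directly comparable.  Effect size
  r = |Z|/√N with a seeded percentile-bootstrap 95% CI (default 2,000
  resamples); the bootstrap is method-agnostic since no analytic CI for
  this r is standard.
* **Welch t** on coefficient distributions, Welch–Satterthwaite df; its
  effect r = √(t²/(t²+df)) is reported without a CI by default.
* The covariate contrast is unpaired by default (matching the named
  rank-sum test) even though the design is paired over an identical spec
  universe; `paired=True` switches to a Wilcoxon signed-rank.
* The within/between and per-category contrasts use the combined sample
  without covariates; the group contrast pools both covariate
  conditions.  Display rounding of medians (2 dp) is separate from
  computation precision.

## Permutation null and curve test

The default scheme (`task_blocks_within_group`) shuffles each comparator
task's raw observations as whole participant blocks within each sample
group, leaving the x side, group labels, ages and educations untouched.
This is the weakest intervention that destroys every x–y association
while preserving each variable's marginal distribution, the within-task
dependence between a task's metrics, and the group structure.  Two
consequences worth knowing:

* In the **combined** sample the group-mean structure survives the
  shuffle, so combined-arm null multiverses retain group-confounded
  association and their significance shares sit well above α.  That is
  deliberate — the null answers "no individual-level x–y relationship",
  not "no group differences".  Alternative schemes
  (`task_blocks_pooled`, which also breaks the group structure, and
  `fields_within_group`, which additionally breaks within-task
  dependence) are selectable in the config.
* The curve test rounds both medians to two decimals before comparing
  (decimal half-up, so .195 and .2049 both compare as .20), counts null
  medians ≥ the observed median, and halves the proportion; zero counts
  are reported as the bound p < 1/B.  This halved one-sided rule is kept
  verbatim for fidelity; it is conservative when the observed median
  sits high in the null distribution and anticonservative near the
  middle, and the 2-dp ties make it lean conservative overall.  A
  standard two-sided permutation p, (1+#{|null| ≥ |obs|})/(B+1), is
  available (`two_sided_permutation_p`) for comparison.  The
  significance-share comparison is halved symmetrically by default, with
  a switch to disable halving.  B defaults to 500 (p floor .002).

Because curve medians mix positively and negatively signed pairs, the
median-of-curve test has little power when the observed median is near
zero; the significance-share test is the discriminating one in that
regime.  Both are always reported.

## Synthetic cohort generator

Single-factor linear-Gaussian model — the minimal structure that yields
the qualitative pattern the analysis studies (within-category
correlations positive and strong, between-category negative through
direction coding):

    g_i  ~ Normal(shift_group, latent_sd)
    p_i  = g_i + age_effect (age_i − 70) + education_effect (edu_i − 14)
    z_if = loading(category f) p_i + Normal(0, noise_sd)

raw field = increasing transform of z (exp for times/errors, affine for
accuracies), so the rank structure of the raw fields is exactly that of
the z scores, and the large-n Spearman correlation between fields with
loadings l_x, l_y approaches
l_x l_y Var(p) / √((l_x²Var(p)+σ²)(l_y²Var(p)+σ²)).

Defaults (chosen once; units in parentheses): n = 88 healthy + 117
stroke; latent_sd 1; group_shift −1 (stroke performs one latent SD
worse); loadings accuracy +0.7, time −0.7, error −0.7; noise_sd 0.5;
age_effect −0.02 and education_effect +0.03 latent-SD per year —
field-typical magnitudes, free parameters of the generator, *not*
estimates from any participant data; missing_rate 0.02 MCAR (real
missingness is marginal 0.5–5%; no mechanism is modelled); demographics
per group: age 66.69 (SD 11.67) / 72.40 (SD 12.47) years, education
15.56 (SD 3.63) / 12.89 (SD 3.51) years.  All draws flow from one
seeded generator in fixed order (ages, educations, latent abilities,
noise matrix, missingness mask).

What the generator does **not** emulate: lesion laterality or
time-since-stroke effects, sex/handedness/ethnicity structure, integer
or bounded score supports (fields are continuous, so real-data tie
handling is exercised only via the rank machinery's tie tests),
floor/ceiling effects, informative missingness, and task-specific
residual correlations beyond the single factor.  Passing tests therefore
establish that the machinery is correct and calibrated under a clean
factor model, not that real test batteries follow one; with the default
loadings the synthetic within-category correlations (~.6–.75) are
stronger than typically observed in real validation data.

## Problem sizes and numerical choices

The test suite exercises: exhaustive Spearman-vs-closed-form agreement
on all untied vectors of length ≤ 8; a rank-sum enumeration oracle at
n = 4 + 4 (the continuity-corrected normal p agrees with the exact
enumerated p to < .005 there); type-I calibration of the full
2,220-spec multiverse on a zero-loading cohort of n = 205; and curve-test
calibration over 200 replicate experiments at B = 99 on a reduced
6-specification universe with n = 120 — sizes chosen to make the
calibration bands sharp while the whole suite stays quick.  pingouin's
`partial_corr` serves as an independent cross-check of the partial
Spearman (agreement to ~1e−12 on complete data).

Numerical notes: average ranks are computed by a vectorized midrank
routine (verified against `scipy.stats.rankdata`); curve ordering breaks
ties by spec id; the permutation p floor 1/B guarantees no reported
p = 0; decimal half-up rounding is applied to the shortest float repr so
printed-precision ties behave as a reader of decimals expects.

## Known limitations

* The exact permutation scheme and CI method behind any given published
  multiverse are often unstated; real-data p-values and intervals may
  not reproduce exactly under any single scheme offered here.
* The halved one-sided curve test is reported verbatim and is not a
  calibrated two-sided test; use the two-sided alternative for
  methodological work.
* Bootstrap CIs for r are percentile intervals; they can undercover at
  small n or extreme r.
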