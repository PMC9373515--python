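# Methods

This note documents the models, estimators and numerical conventions the
package implements, the design choices that were genuinely open, and
what the synthetic-data tests do and do not establish about real survey
data.

## Scoring model

NRF9.3 is computed exactly as defined in the README: per-2000-kcal
normalization by the scored window's own energy, qualifying fractions
capped at 1, limiting fractions counted only in excess of the MRV, and
`(NR − LIM) × 100`. Two readings of the published algebra had to be
fixed:

* **Excess-only LIM per nutrient.** The "−1" is applied inside the sum
  with a floor at zero, `max(0, x̃_j/MRV_j − 1)`, not once after the
  sum. A single post-sum subtraction would let a nutrient below its
  ceiling offset another above it, contradicting the requirement that
  only the portion in excess of the recommended quantity counts.
* **Energy normalization.** "Normalized for 2000 kcal" is read as
  amount per 2000 kcal of the scored window, i.e. division by the
  window's total energy. This makes the score a pure density measure,
  invariant under scaling the whole intake vector (property-tested).

The NR cap has an uncapped escape hatch (`cap_nr=False`) for
sensitivity analysis. No ceiling is applied to LIM. Zero-energy windows
are a hard error rather than a zero score: the scoring population is
breakfast *consumers*, and the <50 kcal exclusion happens upstream.

The scoring window is the breakfast intake averaged over the
individual's available recall days (day 1 only when no replicate
exists). Whether the original analysis used day 1 or the two-day mean
is not stated anywhere we could check; the two-day mean is the default
because the index is meant to capture habitual quality, and a
`day_mode="day1"` flag preserves the alternative.

**Tertiles** are assigned by ranks, not interpolated quantiles: sort by
(score, id) and cut at ⌈n/3⌉ and ⌈2n/3⌉. This sidesteps the
quantile-interpolation differences between software packages, makes tie
handling deterministic, and guarantees |size differences| ≤ 1 and
min(T3) ≥ max(T1). Ranks are unweighted by default (weighted ranking is
not implemented; with near-self-weighting designs the difference is
cosmetic, and the original choice is unknowable).

## Breakfast classification

Skipper ⇔ breakfast energy < 50 kcal on the classification window,
with absent breakfast records contributing 0 kcal days (a day with
other meals but no meal-code-1 lines is a zero breakfast, not missing
data). Classification is monotone in energy by construction.

## Usual-intake estimator

The two-day design permits a variance decomposition on a transformed
scale (log1p by default, since intakes are skewed and may be zero):

* within-person: `σ²_w = mean over replicated individuals of
  (x_i1 − x_i2)² / 2` — estimated *only* from two-day individuals;
* between-person: `σ²_b = max(0, var(person means) − σ²_w · mean(1/k_i))`
  by moment matching, where `k_i ∈ {1, 2}` is the individual's day count;
* usual intake: the best linear predictor
  `m + (mean_i − m) · σ²_b / (σ²_b + σ²_w/k_i)`, back-transformed.

This is explicitly a simplified stand-in for measurement-error
deconvolution software: it reproduces the defining behaviour (the
usual-intake distribution is strictly narrower than single-day intakes
when both variance components are positive; population mean preserved
on the transformed scale when the shrinkage factor is constant) without
estimating percentiles of the deconvolved distribution. Degenerate
cases: `σ²_w = 0` returns observed means; `σ²_b = 0` returns the grand
mean for everyone; both zero returns the (constant) person means.
Fewer than 30 replicated individuals triggers a warning; none at all is
an error.

## Outlier substitution

Per nutrient within each sex × age-group stratum: values above
`1.5 × P99` are replaced by draws from `Uniform(P95, 1.5 × P99)`, with
both percentiles computed once from the *pre-replacement* values using
linear interpolation between order statistics (the most common
percentile convention; recorded in the audit log since no convention is
published). Single-pass substitution makes the operation idempotent on
its own output. Strata under 20 individuals are skipped with a warning
(unstable percentiles); energy is never cleaned by this rule. The
pathological case P95 > 1.5 × P99 (possible for extremely heavy-tailed
inputs under a nonstandard rule) raises with diagnostics rather than
drawing from an empty interval.

## Weighted statistics

Weights are expansion factors normalized to mean 1; the multistage
design of a real survey is deliberately out of scope, so all standard
errors are simple weighted linearizations without design effects.

* **Weighted mean ± SE**: `se = sqrt(n/(n−1) · Σ (w̃(x−x̄_w))²) / Σw̃`.
  The n/(n−1) factor makes the estimator collapse exactly to the
  classical `s/√n` at equal weights.
* **Chi-square association** (breakfast status × covariate; consumer
  score × tertile in the report layer): Pearson chi-square on the
  weighted contingency table rescaled to the *Kish effective sample
  size* `(Σw)²/Σw²`, without continuity correction. Rescaling to the
  raw n would inflate type-I error by the design effect `1 + CV(w)²`
  (~6% rejection at this package's default weight variability); the
  effective-n rescale is the first-order correction, equals n under
  equal weights, and is still far short of a full design-based
  adjustment.
* **Trend test across tertiles**: weighted least squares of the value
  on the tertile index (1, 2, 3), two-sided p from the slope with HC1
  heteroscedasticity-robust standard errors. Robust errors are the
  appropriate choice when weights are expansion factors rather than
  precision weights; the model-based covariance remains available via
  `robust=False`. Constant inputs return slope 0 and direction "none";
  reversing the tertile labels flips the slope sign exactly. The exact
  trend construction used in published analyses of this kind is rarely
  named; the linear-contrast reading is documented as this package's
  choice.
* **Rank-biserial association** (food-group consumer score vs tertile):
  Mann–Whitney formulation `r = 2U/(n₁n₀) − 1` comparing consumers'
  tertile ranks against non-consumers', p-value from the asymptotic
  two-sided Mann–Whitney test with tie correction. For a 3-level
  ordinal factor this is one defensible construction, not the only one.

ANOVA across age groups and covariate-adjusted ANCOVA with post-hoc
pairwise comparisons are intentionally not implemented; the report
tables carry unadjusted weighted means ± SE with the trend and
chi-square tests, and leave room for externally computed p-values.

## Synthetic survey generator

The generator emulates the *structure* of a two-day national dietary
survey, not any country's actual intake distributions:

* four age groups (children 6–12, adolescents 13–18, adults 19–59,
  elderly 60+), default 2000 individuals each;
* day 1 for everyone, day 2 for a Bernoulli(0.5) subset;
* meal codes 1–5 (breakfast, lunch, dinner, two snacks) over a built-in
  13-food menu covering 13 food groups typical of a Philippine
  breakfast table (rice, coffee, sugars, cooking oil, fresh fish, green
  leafy and other vegetables, chicken egg, bread/cereal products,
  powdered milk, chocolate beverages, fresh meat, fruit) with plausible
  — synthetic, not excerpted — per-100-g nutrient amounts;
* portion grams `exp(μ_{f,m} + shift_age + b_i + w_id + ε)` with
  person effect SD 0.4, day effect SD 0.3, per-line noise SD 0.1
  (log scale), and age-group portion shifts (−0.35 children … +0.10
  adults) so energy ordering across ages looks survey-like;
* skipper probability 2% (children/adolescents) and 4% (adults/elderly)
  by default, matching the range such surveys report.

**Breakfast selection is a person-level habit**: each person's
breakfast menu is drawn once (Bernoulli per food) and repeated on both
days, while lunch/dinner/snack foods are re-drawn daily. This choice is
substantive. If breakfast composition were re-drawn each day, the
compositional variance of log breakfast energy would load on the
within-person component and inflate the recovered day-effect SD by
40–80%, destroying the variance-decomposition recovery the generator
exists to support; as a model of behaviour it is also the more
realistic reading (habitual coffee drinkers drink coffee daily). With
habits, the compositional variance loads on the between-person
component (≈ +9% on the recovered σ_b, ≈ +3% on σ_w at n = 2000 per
group — inside the ±20% recovery band the tests assert).

Two small truth-consistency repairs keep the generator's labels exact
under the 50 kcal rule: flagged skippers are thinned (30% lose all
breakfast lines; the rest keep their lowest-energy line rescaled to
5–45 kcal on every day), and the ~0.1% of consumer person-days whose
drawn breakfast falls below 50 kcal are rescaled into 55–120 kcal.
Sampling weights are `0.4 + Gamma(6, 0.1)` rescaled to mean 1 (CV ≈
0.25) — enough variability to exercise weighted estimators while
keeping weighted tests near nominal level.

What passing tests on this generator show: the pipeline's algebra,
boundaries, determinism, and statistical calibration are correct, and
its estimators recover known ground truth at realistic sample sizes.
What they do not show: agreement with any published survey's numbers.
Real recall data have features the generator omits — correlated food
choices beyond single-food habits, cluster sampling, interviewer and
day-of-week effects, energy misreporting — so published means and
percentages are not reproducible from it, by design.

## Problem sizes and runtime

The default test suite simulates 150 individuals per age group for
shared fixtures; the deepest end-to-end checks use 2000 per age group
(8000 individuals, ≈180k recall lines) for parameter recovery and 500
replicates of n = 300 for null calibration. These sizes were chosen as
the smallest at which the asserted tolerances (binomial 99% interval,
±20% on variance components, ±0.02 on rejection rates) are comfortably
identifiable; the whole suite runs in well under a minute on one CPU.

## Known limitations

* Simple weighted estimates only — no design-based variance, no
  replicate weights.
* The usual-intake stand-in does not estimate percentiles of the usual
  intake distribution and is not a substitute for deconvolution when
  those are needed.
* Age/sex-specific reference values are supported through the YAML
  override mechanism but no built-in stratified table ships with the
  package; the single default table applies everywhere unless
  overridden.
* Added sugar is approximated by total sugar throughout, as in the
  survey coding the package targets.
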