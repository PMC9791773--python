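# Methods

## The index

The Chinese Preschooler Dietary Index (CPDI) scores the diet quality of
children aged 2–5 completed years on 11 components: nine food groups plus
vitamin A and iron. Every component is assessed as a *density* — the
amount consumed per 1000 kcal of energy intake — so the score reflects
dietary composition rather than quantity, and a child who simply eats
more of everything is not rewarded. Cutoffs are age-stratified: one set
for ages 2–3 (guideline energy band 1000–1200 kcal/d) and one for ages
4–5 (1200–1400 kcal/d). Fractional ages are floored to completed years
before stratum assignment, matching survey age banding; ages outside
[2, 5] are outside the index's domain and are rejected, not clamped.

Components carry weights of 10 points (the eight food groups), 2.5 points
(vitamin A and iron, down-weighted to limit collinearity with the food
groups that supply them), and 5 points (high-sugar/high-fat snacks, the
sole limitation component), for a 0–90 total.

### Scoring rules

With density `d`, maximum score `M`:

* **Adequacy** (vegetables, fruits, dairy, soybeans, aquatic products),
  recommended density `R`: `min(d / R, 1) × M`. The cap is inclusive:
  `d = R` earns full marks.
* **Moderation** (cereals, eggs, red meat & poultry, vitamin A, iron),
  interval `[L, U]`: `M` inside the interval; `0` at `d = 0` and for
  `d > 2U` (strict, as the minimum-score criteria are printed with a
  strict ">"); otherwise `(1 − |1 − d/B|) × M` where `B` is the *nearest*
  bound (`L` below the interval, `U` above). The nearest-bound reading is
  the only one that is continuous at both interval ends and reproduces
  the published worked example `(1 − |1 − 150/100|) × 10 = 5`. The
  zero-score density is constrained to equal `2U` at validation time —
  every published cutoff row satisfies it, and the linear decay reaches
  exactly zero there, so any other value would contradict the formula.
  The rule is additionally clamped to `[0, M]` against floating-point
  edge cases; the only discontinuity is the deliberate jump at `d = 0`
  (no consumption of a recommended food scores 0, not the limit of the
  decay).
* **Limitation** (snacks), limit density `T = 100 g/1000 kcal`:
  `0` for `d ≥ T`, else `(1 − d/T) × M`. The denominator is the limit
  density itself, as forced by the worked example
  `(1 − 45/100) × 5 = 2.75` and the "> 100 g/1000 kcal" zero criterion.
  The German Optimized Mixed Diet reference that motivates the snack
  allowance is stated per day (50 g/d), not per 1000 kcal; the source of
  the 100 g/1000 kcal figure is not documented, so the implementation
  follows the cutoff table and the worked example and records the
  discrepancy here rather than attempting a derivation. Similarly, the
  vitamin A and iron interval densities are taken verbatim; the mapping
  from per-day RNI/UL values to densities is not reproduced.

### From recalls to densities

Each child contributes one or more (typically three consecutive) 24-h
recall days. Intakes are averaged *before* densifying: density =
(mean daily amount / mean daily energy) × 1000 — a ratio of means, scored
once per child. The alternative (scoring each day and averaging the three
daily scores) is deliberately not the default: averaging intakes first
matches how multi-day recalls are conventionally collapsed, and the
piecewise-linear rules are nonlinear, so the two orders differ. Callers
who want per-day scoring can score single-day record lists themselves.

Components absent from every recall day are scored as zero consumption
and flagged in the result; skipping them would silently shrink the 0–90
scale. Record amounts whose ids are not in the standard are ignored by
scoring and reported. Mean energy of zero is a degenerate input and
raises. No rounding is applied internally; file writers format scores to
2 decimals and densities to 1, with full precision available in the audit
output.

### Plausibility filter

Children whose mean daily energy is strictly below 400 kcal or strictly
above 4000 kcal are excluded before scoring, with machine-readable
reasons. Bounds are strict as printed; a mean of exactly 400 kcal is
kept. Whether boundary cases in the original survey were kept is not
determinable from the text, so the printed inequalities are implemented
literally.

## Standards as data

All cutoffs live in a YAML document (`src/cpdi/data/cpdi_default.yaml`)
parsed into frozen dataclasses; variant indexes (different components,
weights or cutoffs) need no code changes. Validation enforces: unique
component ids, positive cutoffs, `lower ≤ upper`, `zero_above = 2 ×
upper` for moderation rows, category/cutoff-shape agreement. Units are
declared per component (g, mg, μg RAE) and never coerced; in particular
vitamin A must already be in retinol activity equivalents — no
retinol/β-carotene conversion is attempted because conversion factors are
specific to the food-composition table in use. Serialization is
deterministic and `load(save(s)) = s` exactly (property-tested over
randomized valid standards).

## Cohort analysis

* **Categorization**: low (< P25), medium (P25–P75 inclusive), high
  (> P75) of the cohort's totals. Percentiles use numpy's
  linear-interpolation convention; conventions differ across software, so
  counts near boundaries may differ by ±1 child from analyses done
  elsewhere. Ties at a boundary fall in the medium band, per the
  inclusive definition.
* **Nutrient adequacy ratio**: daily intake over the recommended amount,
  truncated at 1.
* **Item-rest correlations**: Spearman rank correlation (average ranks
  for ties) of each component subscore against the total minus that
  component. Zero-variance columns are reported as undefined (NaN) and
  flagged, never fabricated.
* **Cronbach's alpha**: raw form `k/(k−1) × (1 − Σ item variances /
  var(total))` with sample variances (ddof = 1), and standardized form
  `k·r̄ / (1 + (k−1)·r̄)` with `r̄` the mean pairwise Pearson
  correlation. The literature's "standard" vs "nonstandard" labels are
  not used consistently, so both forms are always reported side by side.
* **PCA dimensionality**: eigendecomposition of the subscore
  *correlation* matrix (components have unequal ranges — 10 vs 2.5
  points — so covariance would be scale-dominated). Reported: sorted
  eigenvalues, the count with eigenvalue > 1 (Kaiser's rule), and that
  count's cumulative variance share. Constant columns are dropped with a
  warning. Eigenvalues are clipped at 0 against round-off; their sum
  equals the number of retained components by trace conservation.

## Synthetic cohorts

The generator produces survey-like cohorts (profiles + 3-day recalls)
with known ground truth, because the multi-province recall survey the
index was developed on is application-gated and cannot be bundled.

Per child: demographics from configurable marginals (defaults: age mix
22.5/24.7/25.0/27.8% over ages 2–5, 54.1% boys, 28.0% urban, income
bands 41.2/27.5/21.0/5.7/4.6%); true mean energy log-normal with median
at the age group's guideline band midpoint (σ_log = 0.15); true
component densities from zero-inflated log-normals. Zero inflation
captures genuine non-consumption (the dairy default is 69.3% zero over
three days, the reported level); log-normality captures the right skew
of intake data. Urban residence and each income step add configured
shifts to the log-density location of affluence-sensitive components, so
simulated diet quality rises with urbanicity and income. Recall days
apply multiplicative log-normal noise (σ_log = 0.20) to energy and
amounts; at zero noise, densification inverts generation exactly
(to float round-off), which the tests exploit as a round-trip property.

Component density medians were set once so the default cohort is
qualitatively faithful — cereal-heavy diets, widespread zero consumption
of dairy/fruits/aquatic products, generous red meat, near-zero snack
reporting, adequate iron, low vitamin A — and the default mean total
lands near 40 points, in the plausible range for this population. This
is a plausibility default, not a calibration claim.

What the generator does **not** emulate: inter-component correlation
structure (densities are conditionally independent given demographics,
so synthetic cohorts have near-zero internal-consistency reliability by
construction — reliability statistics are instead validated on the
one-factor subscore generator with its Spearman–Brown closed form);
food-item-level reporting (densities are drawn at component level; the
food→nutrient conversion path is exercised with a small synthetic
composition-table fixture); seasonality, weekday/weekend structure, and
recall measurement error. Passing tests therefore demonstrate
correctness of the pipeline's arithmetic and statistics, not
cohort-level agreement with any real survey; published cohort-level
values (mean score, alpha, PCA variance shares) require the original
data and are out of scope.

Randomness is one root seed split hierarchically into an independent
stream per child, so enlarging a cohort never perturbs earlier
children's draws, and identical configs are bit-reproducible.

The one-factor subscore generator (`generate_factor_subscores`) draws
`X_j = λF + √(1−λ²)ε_j`, giving inter-item correlation λ² and
standardized alpha `kλ²/(1+(k−1)λ²)` — the closed form the reliability
recovery tests target (±0.03 at n = 5000, k = 11, λ = 0.6).

## Problem sizes in the test suite

Grid comparisons against the independently coded rule oracle use 10⁴
densities per component × age group (1e-9 tolerance). Stochastic checks
use n = 1000 subjects for energy-rescaling invariance (1e-9 points),
n = 4000–5000 for law-of-large-numbers and reliability-recovery
tolerances, and n = 200–500 cohorts for end-to-end report demonstrations.

## Known limitations

* No usual-intake (measurement-error) modelling, no imputation of
  missing recall days, no seasonal adjustment.
* Trend tests across demographic strata and regression modelling of
  score determinants are intentionally not implemented; the scores CSV is
  exported in a shape any statistics environment can consume.
* The snack limitation applies a per-1000-kcal limit whose provenance is
  undocumented (see above); users comparing against per-day snack
  allowances should convert explicitly.
* Income-band handling is categorical; no currency inflation adjustment
  is provided.
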