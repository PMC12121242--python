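# Methods

## The scoring model

The Dietary Guideline Index (DGI; DGI-CA for children) summarises how closely
a day's food-group intake tracks the Australian Dietary Guidelines (ADG)
recommended daily serves for the eater's age/sex/life-stage group. Eleven
indicators sum to 100 points:

| indicator              | max | rule                                                    |
|------------------------|-----|---------------------------------------------------------|
| vegetables             | 10  | `10 × min(1, intake/recommended)`                       |
| fruit                  | 10  | proportional, as above                                  |
| breads & cereals       | 5   | proportional                                            |
| wholegrain quality     | 5   | step: 0 below `low_cut`, 2.5 below `high_cut`, else 5   |
| meat & alternatives    | 10  | proportional                                            |
| dairy                  | 10  | proportional; **excluded under 2 years**                |
| dietary variety        | 10  | `10 × min(1, count/5)` core food groups eaten           |
| healthy fats           | 10  | `10 × use` for graded use in [0, 1] (binary optional)   |
| plain water            | 5   | consumed → 5, else 0                                    |
| SSB                    | 5   | `5 × max(0, 1 − intake/limit)`                          |
| discretionary foods    | 20  | `20 × max(0, 1 − intake/limit)`                         |

Under-2 totals (maximum 90) are multiplied by 10/9 so every reported score is
out of 100 and age groups are comparable. Scores are computed in full
precision; rounding to two decimals happens only when tables are formatted.

Assumptions: intakes are daily serves already expressed in ADG serve units;
indicators are independent given the recommendation row; there is no energy
adjustment or nutrient-level modelling.

## Reference data

The recommendation table is a versioned YAML file
(`mrsdat/data/adg_recommendations.yaml`), not hard-coded constants, so any
scoring run is reproducible under a declared reference table. The packaged
default has 14 groups covering 6 months to 120 years with ADG
foundation-diet serve counts (e.g. adult fruit 2 serves/day, male 19–50
vegetables 6 serves/day). Age bands are half-open `[lo, hi)` in months so
boundaries like "6–<24 months" are unambiguous; a pregnant/breastfeeding
life-stage flag supersedes the age/sex lookup. Validation enforces: positive
recommendations for every core food group, positive penalty limits,
non-overlapping bands per sex/life-stage stratum, and `dairy_applicable`
false exactly for under-2 groups.

Penalty limits are configurable per group. Defaults: SSB limit 1 serve/day
everywhere (the linear /5 scale then puts 0.43 serves at 2.85 points);
discretionary limit 2.5 serves/day for younger children and 3.0 from
adolescence up, following the children's-index precedent of small
age-graded allowances. These defaults are declared, not claimed to be any
particular study's internal values.

## Intake conversion

FFQ response options are serve ranges. A range maps to its midpoint
("0.5–1 serve" → 0.75), a bounded-below option to the midpoint of
[0, bound] ("0.5 serves or less" → 0.25), and an open-top option to its
floor ("5 serves or more" → 5): deterministic and conservative. Questions
with a fortnightly reference period are divided by 14. Unanswered questions
abort scoring for that participant by default; a permissive mode imputes
zero with a non-suppressible warning, because silent imputation would bias
scores invisibly.

Recall days average arithmetically per food group. Plain water is "any day
yes"; healthy-fat use averages to the fraction of days used (a graded 0–1
value); the variety count averages and rounds half-up. Dietary variety is
operationalised as the number of the five core food groups with non-zero
intake — one of several defensible definitions, chosen because it is
computable identically from both methods.

Plausibility checking flags (never drops) serves outside generous per-group
bounds and totals below 0.5 serves/day ("near-zero intake", the signature of
an ill or non-reporting participant); exclusion is an analyst decision
surfaced through the `--exclude` flag of the compare command.

## Agreement statistics

* **Lin's CCC** uses population (1/n) moments:
  `rc = 2·cov(x,y) / (var x + var y + (mean x − mean y)²)`. The confidence
  interval is the Fisher-z asymptotic form with Lin's variance,
  back-transformed; a percentile bootstrap was considered and left out as
  the asymptotic CI is standard at these sample sizes. Samples below 10
  pairs trigger a robustness warning rather than an error.
* **Bland–Altman**: differences d = x − y; limits `bias ± 1.96·sd(d)`
  (sample SD); proportional bias is the OLS slope of d on the pairwise
  means with its two-sided p (via `scipy.stats.linregress`). Constant
  differences give slope 0, p 1 exactly; constant means are an error.
* **Tertiles** cut at the empirical 1/3 and 2/3 quantiles (NumPy linear
  interpolation); values at a cut take the lower tertile; an all-tied vector
  collapses to tertile 1 with a warning. The convention is recorded so
  disagreements with other software are attributable.
* **Weighted kappa** defaults to linear weights `1 − |i−j|/(k−1)` (the common
  SPSS-style choice), quadratic optional; chance agreement from marginal
  products.
* **Paired tests**: the t-test reports the mean difference with scipy's
  two-sided p (a zero-variance difference vector short-circuits to p = 1 at
  zero mean); the Wilcoxon signed-rank test reports the normal-approximation
  Z with zeros dropped, midranks and the tie-corrected variance — verified
  in the suite against `scipy.stats.wilcoxon(method="approx")`. Bonferroni
  adjustment is `min(1, m·p)` with the family size m always explicit in the
  output.

CCC and weighted kappa are implemented in this package (no installed
dependency provides Lin's CCC; scikit-learn's kappa serves as an independent
cross-check in the tests, never as the implementation).

## Synthetic cohorts

The generator emulates the data structure of an FFQ-vs-recall validation
study in a remote-community setting, where participant-level data are
restricted: a mix of ADG groups from infants to older adults (defaults
weighted toward young children, pregnant/breastfeeding women and adults,
n = 100); one to three recalls per participant (60% have two); log-normal
usual intakes with medians on the observed scale of such cohorts
(vegetables 1.4, breads 5.0, SSB 0.5 serves/day, …); zero-inflated days for
episodic foods (SSB 40%, discretionary 20%, fruit 25% zero-days, with the
non-zero days scaled so a day's expectation equals usual intake);
multiplicative log-normal day-to-day noise (sd 0.4); and FFQ reporting
error as per-food-group bias times log-normal within-person noise (sd 0.25),
snapped to the FFQ's own response options.

Quality traits are habits: wholegrain behaviour is drawn at the FFQ's
option levels {0, 0.3, 0.7, 1}, healthy-fat use is a binary habit, plain
water is near-universal (98%). Day-level departures from habit (healthy-fat
flips, wholegrain jitter) are driven by the day-effect parameter, so setting
all noise parameters to zero produces a genuinely degenerate cohort in
which the only FFQ-vs-recall disagreement is option granularity. This is a
deliberate design constraint: it makes the noise-free limit a sharp
correctness check on the whole pipeline.

All randomness flows from one seed through per-participant spawned
substreams, so output is reproducible and invariant to generation order.
Replicate seeds in `recovery_experiment` are spawned the same way and kept
below 2³¹.

What the generator does **not** emulate: cross-food-group correlation
(independence by default; a correlation hook is future work), seasonal or
pay-cycle day types, differential reporting by age group, and real
instrument idiosyncrasies. Passing recovery tests therefore demonstrate
that the pipeline recovers agreement structure under the stated generative
model, not that any particular FFQ is valid in the field.

## Problem sizes and tolerances

The suite's statistical checks use sizes chosen to keep Monte-Carlo error
well below the asserted margins: oracle equivalence on 120 random fixtures
(n = 5–50) at 1e-10 relative tolerance; noise-free recovery with 10
replicates of n = 200 (CCC > 0.95, |bias| < 2 points against an observed
snapping offset near 0.4); a 3-point FFQ-noise grid at 50 replicates of
n = 100 (mean CCC Monte-Carlo SE ≈ 0.01 against grid separations ≈ 0.05);
and limits-of-agreement coverage at n = 10⁴ Gaussian differences
(95% ± 0.7%, a ±3σ band for the binomial coverage estimate).

## Known limitations

* The packaged FFQ schema is a faithful skeleton of a short-item
  instrument's structure (ranged serve options, combined meat question,
  multiple-choice fortnightly SSB question), not a full 32-item facsimile.
* The healthy-fats and variety operationalisations, wholegrain cuts and
  discretionary limits are declared defaults; studies differ and all are
  configurable.
* The CCC confidence interval is asymptotic; for n ≲ 15 a bootstrap would
  be preferable.
* Exact Wilcoxon p-values are not implemented; the normal approximation is
  used at all n, matching the large-sample reporting convention.
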