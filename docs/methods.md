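# Methods

This note documents the models and conventions behind `plantshift`, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot establish.

## Protein arithmetic

All protein quantities derive from amino-acid masses. A food's total protein
per 100 g is the sum of its nine indispensable-amino-acid (IAA) masses plus
a pooled dispensable remainder, divided by 1000. Nitrogen-based conversion
(N × 6.25 or 6.38) is deliberately not offered: those factors overstate
protein for most food groups, and label (N-based) protein values, where
present, are carried as metadata only and never enter the arithmetic.

Sulfur amino acids (Met + Cys) and aromatic amino acids (Phe + Tyr) are
pooled, as is standard in PDCAAS scoring, giving the nine scored keys
`his, ile, leu, lys, saa, aaa, thr, trp, val`.

Digestibility is a per-food-group faecal factor in (0, 1], applied
multiplicatively to every amino acid of every food in the group. A food
whose group has no factor is rejected at load time; the loader never imputes.

## The similarity factor and utilizable protein

For each of the 7 eating occasions of a recall day (breakfast, lunch,
dinner, four between-meal moments), the digested amino acids of all foods
eaten at that occasion are pooled. The similarity factor is

    SF = min(1, min_i (AA_i / P) / R_i)

with `AA_i` the pooled digested mass of IAA *i* (mg), `P` the occasion's
protein (g, sum of all pooled amino acids / 1000) and `R_i` the reference
pattern (mg per g protein). Utilizable protein for the occasion is
`SF × digestible protein`; daily utilizable protein is the sum over
occasions. Scoring per occasion rather than per day is the operative
modelling choice: amino acids are credited as complementing each other only
when eaten within the same meal, so a lysine-poor breakfast cannot borrow
lysine from dinner. Pooling the whole day can only raise utilizable protein;
a test asserts this dominance.

Open choices resolved here:

* **Denominator of the ratio.** Both `AA_i` and `P` come from the *digested*
  pool, keeping the computation self-consistent within the
  after-digestibility amounts. Because digestibility multiplies all amino
  acids of a food equally, single-food meals are unaffected by this choice;
  multi-food meals with unequal group factors are affected only marginally.
* **Zero-protein occasions** score SF = 1.0 by convention, so
  `utilizable = SF × digestible` holds with both sides zero and empty
  snack occasions never produce 0/0.
* **Reference pattern.** The packaged default is the WHO/FAO/UNU 2007 adult
  scoring pattern (his 15, ile 30, leu 59, lys 45, saa 22, aaa 38, thr 23,
  trp 6, val 39 mg/g protein), loaded from a config file so an alternative
  (e.g. an older-adult pattern) can be swapped in without code changes.
* Capping each ratio at 1 before the minimum or capping only the minimum is
  equivalent; the minimum is capped.

Numerical tolerances: the pipeline is pure floating-point arithmetic;
invariants (utilizable ≤ digestible ≤ total, SF ≤ 1) are checked at relative
1e-9.

## Scenario engine

A scenario is a set of disqualifying category flags, an optional exemption
set, a replacement fraction, and a replacement-table family:

| scenario       | disqualifies                      | fraction | family     |
|----------------|-----------------------------------|----------|------------|
| original       | —                                 | —        | —          |
| flexitarian-40 | meat, fish                        | 0.40     | vegetarian |
| flexitarian-80 | meat, fish                        | 0.80     | vegetarian |
| pescetarian    | meat                              | 1.0      | vegetarian |
| vegetarian     | meat, fish                        | 1.0      | vegetarian |
| vegan          | meat, fish, dairy, egg, cheese    | 1.0      | vegan      |

The vegan scenario exempts items flagged `minor_animal_content` (cake,
chocolate sprinkles): their animal protein is negligible, and leaving them
is why a vegan transform lands just below 100% plant protein. The
flexitarian scenarios include fish in the replaced pool by default (a
config switch restricts them to meat only).

Replacement mechanics, in one seeded RNG stream per scenario run:

1. flexitarian selection first — a uniform without-replacement draw of
   `round_half_up(fraction × n)` events from the disqualified events pooled
   across all participants (events, not unique products: this keeps each
   participant's diet a realistic mixture);
2. then one independent uniform draw per affected event, in dataset row
   order, from the ≤ 12 same-food-group alternatives. The same product eaten
   twice may map to two different alternatives.

Substitution is gram-for-gram; amounts are never altered (no satiety/volume
adjustment — a deliberate non-goal). A disqualified food whose group has no
table entry is a hard error: silently keeping meat in a vegan diet would
corrupt every downstream number. Identical inputs and seed give
byte-identical outputs and logs.

The plant-protein share of a dataset is
`Σ(event protein × (1 − animal fraction)) / Σ(event protein)` with protein
from amino-acid sums.

## Habitual intake, adjusted EAR, prevalence

Two recall days confound between-person variation with day-to-day noise.
Two estimators of each person's habitual intake are provided:

* `two_day_mean`: the mean of available days. Simple and unbiased for the
  person mean, but the population SD is inflated by within-person
  variance/2.
* `shrinkage` (default for distributions): a one-part lognormal
  variance-components model. Daily intakes are log-transformed (offset 0.01
  guards zero days); the within-person variance is pooled across
  participants with repeat days, the between-person variance estimated by
  moments (clipped at 0); person means are shrunk toward the survey-weighted
  stratum mean by `λ = between / (between + within / n_days)` and
  back-transformed. With zero within-person variance it equals the two-day
  mean. Like any best-linear predictor it *deflates* the between-person SD
  (by √λ), which is the price of removing the within-person inflation; the
  tests assert it lands closer to the true between-person SD than the raw
  mean, not that it is unbiased. This transparent estimator stands in for
  external usual-intake software (spline-based one-part models); it
  preserves the analysis structure while remaining testable against closed
  forms.

Percentiles are survey-weighted: the inverse of the weighted empirical CDF
with linear interpolation, sorted value *k* sitting at cumulative position
`(cumw_k − w_k) / (W − w_k)`, which reduces exactly to numpy's default
linear percentile at equal weights. (numpy's own weighted quantiles support
only the staircase `inverted_cdf` method, hence the explicit
implementation.)

The adjusted EAR derives from the unmodified diet: each participant's
relative loss is `1 − utilizable/total` of habitual intake (two-day mean by
default; the habitual-method and weighting toggles are exposed), the
survey-weighted median loss is applied to the 0.66 g/kg bw/day standard, and
the result is rounded to two decimals *before* prevalence is computed —
requirements are quoted and used at that precision. Prevalence below the EAR
is the survey-weighted fraction of per-person habitual utilizable intakes
(g/kg bw/day) strictly below it. Strata with fewer than two participants
are an estimation error, not a silent NaN.

## Synthetic data generator

The generator emulates the structure of a two-recall national survey of
older adults; its defaults are the study conditions, set once:

* 600 participants (51% men), ages 65–79, body weight lognormal with median
  86 kg (men) / 72 kg (women) and log-SD 0.11 — medians back-solved from
  target median intakes of 82.5 g/day at 0.96 g/kg (men) and 67.9 g/day at
  0.94 g/kg (women);
* per-occasion median protein targets (g): breakfast 11.5/9.5, lunch 22/18,
  dinner 33/26 (men/women), snacks 4.0/3.6 each; occasion class mixes give
  ~55/50% plant protein at breakfast/lunch, ~25% at dinner and ~39% overall;
* between-person CV 0.20 and day-to-day CV 0.25, applied as median-one
  lognormal multipliers on all of a person-day's targets, so daily total
  protein is exactly lognormal with known components (the ground-truth
  record stores them);
* each snack occasion is habitually skipped with probability 0.20 as a
  per-person trait (so zero day-to-day CV means identical day totals, and
  empty occasions exercise the zero-protein branch);
* eleven food classes with known quality structure: animal classes meet the
  reference pattern exactly (SF = 1 as single-item meals, digestibility
  0.90–0.95); cereals are lysine-limited (lysine at 55–62% of requirement);
  legumes lysine-rich but SAA-limited; meat substitutes mildly
  lysine-limited with plant digestibility (0.75–0.88); sweets carry the
  `minor_animal_content` flag with a 5–15% animal fraction.

Replacement tables are built from the generated database: vegetarian-family
alternatives for meat/fish mix substitutes with cheese and egg; vegan
alternatives are flagless plant items only (substitutes, legumes, plant
dairy alternatives).

What the generator does **not** emulate: real food-coding granularity
(thousands of items vs ~66), composite-dish decomposition, seasonal and
week/weekend weighting construction, correlations between body weight and
intake, energy balance beyond rough per-class kcal ranges, and the exact
severity of the vegan quantity drop (the synthetic vegan scenario loses
roughly 20–25% of total protein where a real replacement catalogue can lose
more). Passing tests therefore establish the correctness and the qualitative
behaviour of the pipeline — orderings across scenarios, the breakfast/lunch
quality penalty under a vegan diet, prevalence shifts — not the numerical
levels a specific real survey would produce.

## Problem sizes and determinism

The shipped test suite runs the full pipeline at 500 participants and
calibration/recovery checks at 2000; `scripts/acceptance.py` uses 600 —
sizes chosen to keep Monte-Carlo error well inside the asserted bands while
the whole suite stays fast. All randomness flows from explicit
`numpy.random.default_rng` seeds: one stream for bundle generation, one per
scenario transform; reruns are byte-identical and each run's manifest
records the seed and a hash of the analysis-relevant config.

## Known limitations

* Faecal-digestibility PDCAAS only; no DIAAS/ileal scoring.
* One-part habitual model; no episodically-consumed-food (two-part)
  machinery, no age-dependent splines, and point estimates only (no
  uncertainty intervals around prevalence).
* Replacement realism is bounded by the catalogue: no optimisation toward
  "smart" high-lysine combinations, no portion-size adjustment.
* The packaged replacement catalogue (`data/replacement_catalogue.csv`)
  documents names, label protein and kcal per food group; it carries no
  amino-acid profiles, so runnable analyses use replacement tables defined
  over the loaded food database (the synthetic tables, or user-supplied
  ones).
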