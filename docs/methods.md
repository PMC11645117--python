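# Methods

`hcesfort` estimates apparent micronutrient intakes and the modelled
contribution of large-scale food fortification (LSFF) from household
consumption and expenditure survey (HCES) data of the kind collected by
national panel surveys in East Africa: a 7-day recall of sixty predefined
food items per household, with quantities in kg, g, L, mL or pieces and a
source (purchase, own production, gift), joined to a household roster with
age, sex, measured weight where available, mother–child links, and a
stratified-cluster design (four analytical strata, eight households per
cluster, survey weights).

## From records to nutrients

1. **Unit conversion.** Quantities are converted to grams: volume units
   via item densities (g/mL), pieces via portion masses. A record whose
   unit cannot be resolved for its food is a hard error naming the code.
2. **Refuse.** Non-edible fractions (peels, bones, shells) are subtracted:
   `edible = grams × (1 − refuse)`.
3. **Daily scale.** Edible grams are divided by the recall period
   (7 days). The survey reports one total per item per week; no
   within-week structure is modelled.
4. **Cleaning.** Quantities are strongly right-skewed, so outlier
   screening happens on the log scale, per food item pooled nationally
   (pooling maximises the stability of the spread estimate; per-stratum
   screening would leave thin cells). A value is an outlier when its log
   deviates from the *median* of the item's logs by more than 3 standard
   deviations, where the SD is computed *leave-one-out* — excluding the
   candidate value itself. The leave-one-out form matters in small
   samples: a gross recording error (say, 10⁶ g against a background of
   ~10 g) contributes most of the full-sample SD and would otherwise mask
   itself. Outliers and missing quantities are replaced by the median
   quantity among consuming households of that item. Items with fewer
   than three observed consumers cannot support the rule and pass
   through; items with no observed quantity at all are dropped with a
   warning. Households reporting no food at all are excluded before
   analysis (their count is logged).
5. **Composition.** Each food code is matched to a per-100 g
   edible-portion composition row carrying a provenance label that mirrors
   the regional FCT priority protocol (Kenya > West Africa > US >
   Tanzania). Matching itself is input data — the package validates
   completeness rather than re-deriving matches. Concatenated survey items
   ("onions, tomatoes, … other viungo") take the consumption-frequency
   weighted mean of their component foods, with weights from a
   household-budget-survey table.
6. **Vehicle equivalents.** Fortifiable-vehicle consumption counts direct
   purchases plus the vehicle embedded in processed products via recipe
   mass fractions: wheat flour and cooking oil flow through bread,
   buns/cakes/biscuits and sweets; maize flour is direct-only.
   Macaroni/spaghetti is excluded from wheat-flour equivalents because the
   provenance of its flour (domestic, hence fortifiable, or imported) is
   unknown.

## Adult female equivalents

Household totals are standardised by the household's number of adult
female equivalents: the sum of members' estimated energy requirements
(EER) divided by the EER of a non-pregnant, non-lactating woman aged
18–29.9 y. Assumptions:

* food is shared in proportion to energy requirements (the central
  HCES assumption; real intra-household allocation is not observed);
* EER = Schofield basal metabolic rate × physical activity level, with
  PAL 1.85 ("active or moderately active") for everyone aged ≥ 2 y;
* children under 24 months contribute only the energy required from
  complementary (non-breastmilk) foods: 0 kcal/d at 0–2 months, 76 at
  3–5, 269 at 6–8, 451 at 9–11 and 746 at 12–23 months;
* a woman linked as the biological mother of a child under 24 months is
  assumed lactating and receives +500 kcal/d (surveys rarely record
  lactation directly); pregnancy is not modelled;
* missing body weights are resolved by documented fallbacks: adult males
  take a global-database reference weight (65 kg); males aged 16–17 are
  interpolated at the two midpoints between the survey mean weight at 15
  and the 18-y reference; females above 50 take the survey mean of
  measured females aged 19–49; anything else falls back to a
  weight-for-age reference table.

The reference woman's weight defaults to 55 kg, giving a reference EER of
(14.818·55 + 486.6) × 1.85 ≈ 2408 kcal/d. The whole table (coefficients,
complementary energies, PAL, reference weight, fallback anchors) is a
configurable object, so alternative requirement sets can be swapped in
without touching code.

## Fortification scenarios

Each (vehicle, nutrient) pair carries three parameters: **A**, the
legislated mean content (mg/kg); **B**, compliance — the fraction of
marketed samples fortified to standard; **C**, the fraction of an added
*vitamin* lost between production and consumption (0 for minerals).
Added content per kg of vehicle:

| scenario          | added content        |
|-------------------|----------------------|
| no fortification  | 0                    |
| status quo        | A × B × (1 − C)      |
| full              | A × (1 − C)          |
| full, no maize    | as full; 0 for maize |

Defaults follow the East African standards (oil: vitamin A 25 mg RE/kg as
retinyl palmitate; wheat and maize flour: Fe 33, Zn 44, B12 0.013, folic
acid 2 mg/kg) and market-assessment compliance (oil 0.28, wheat 0.47,
maize 0 — maize is overwhelmingly milled in small facilities without
fortification equipment). The loss fractions are package defaults
(vitamin A 0.30, folic acid 0.25, B12 0.10) pending country-specific
measurements; the spec file accepts replacements verbatim.

Additions propagate through each household's vehicle grams/day
(recipe-inclusive), are divided by household AFE, and accrue to the
nutrient ledgers: vitamin A to both total retinol activity equivalents
(adequacy) and preformed retinol (excess risk); folic acid to dietary
folate equivalents at ×1.7 (adequacy) and to folic-acid mass (excess
risk). All reported consumption of a vehicle is treated as potentially
fortifiable — the upper bound of programme reach; an optional
`purchased_only` flag restricts fortification to purchased quantities.

## Adequacy and excess

* **Fixed cut-point** (Zn, vitamin A, folate, B12): prevalence = weighted
  share of households with per-AFE intake below the harmonised average
  requirement (H-AR) for women 18–29.9 y — Zn 10.2 mg, vitamin A 490 µg
  RAE, folate 250 µg DFE, B12 2 µg.
* **Full probability** (Fe): menstrual losses skew the requirement
  distribution, so iron prevalence is the weighted mean of each
  household's probability of inadequacy under a requirement distribution
  at 5% dietary bioavailability. The default curve is lognormal with
  dietary median 29.2 mg/d and σ_log 0.426 (absorbed-requirement median
  1.46 mg/d, 95th percentile 2.94, scaled by 1/0.05); it ships as a
  tabulated, overridable config object (2001 grid points to 350 mg/d;
  linear interpolation, so agreement with the exact CDF is at the 10⁻³
  prevalence-point level). No confidence interval is produced for this
  estimator. A degenerate step curve reduces it exactly to the cut-point
  estimator, which the tests exploit as a cross-check.
* **Excess**: weighted share above the harmonised upper level — Fe 45 mg,
  Zn 25 mg (EFSA) and 40 mg (IOM, both reported), preformed retinol
  3000 µg, folic acid 1000 µg. Folate and B12 are refused explicitly
  (low toxicity potential).
* **Gaps**: micronutrient gap = P25(intake) − H-AR (negative = shortfall);
  safety gap = H-UL − P75(intake) (positive = safe).

**Weighted quantiles** generalise the linearly interpolated (type-7)
sample quantile to a weighted index scale: the target index is
q·(Σw − 1), looked up through the cumulative-weight step function.
Weights therefore carry *frequency* semantics — with positive integer
weights every estimator in the package agrees exactly with its unweighted
counterpart on the weight-replicated sample, and unit weights reduce to
numpy's default quantile. Survey weights in the hundreds make the
interpolation term negligible. Prevalence estimators are weight-share
ratios and are scale-invariant. Design-based standard errors under the
cluster design are out of scope.

All summaries are produced for national, urban, rural and the four
analytical strata; vehicle-consumption medians and interquartile ranges
are computed among consumers only.

## The synthetic survey generator

The generator emulates the structure of the real microdata so every stage
is testable without a registration-gated download. It draws: 419 clusters
across the four strata (≈3350 households, ≈3290 analysed after the ~2%
of households reporting no food are excluded); rosters from a young
age-sex pyramid with measured weights only where the real survey measures
them (females to 50 y, males to 15 y); per-(stratum, item) Bernoulli
coverage and lognormal 7-day quantities with urban/rural and Zanzibar
shifts for the fortification-relevant items; survey weights as
stratum base weights × uniform noise on [0.8, 1.2]; and a 0.2% missing
rate plus a 0.1% outlier-injection rate.

Defaults were calibrated once to the study conditions of the Tanzanian
setting — national vehicle coverage near 91/88/53% (oil/maize/wheat,
recipe products included), median energy ≈ 2400 kcal/d per AFE, very high
vitamin A inadequacy (~91%) falling by ~14 percentage points under
status-quo oil fortification — and are not tuned per test.

Three constructions keep the generator's bookkeeping exact:

* natural log-draws are truncated at ±2.5 SD, so individual draws cannot
  trip the >3 SD rule within their own stratum-item cell;
* a deterministic *pull-in* pass then handles the stratum-mixture effect:
  in the nationally pooled distribution, a stratum whose mean is shifted
  (Zanzibar maize flour sits ~1.4 log-SD below the national median) can
  still produce legitimate-looking extremes, so any value that would flag
  is nudged to 0.85× the threshold before ground truth is captured. The
  generated tables therefore contain, by construction, no natural
  outliers — injected artifacts are the only values cleaning may replace;
* injected outliers multiply a consuming household's quantity by exp(k·s),
  raising k until an independent recomputation of the flag rule fires, so
  every injection is guaranteed detectable.

Alongside each survey the generator returns ground truth — per-household
per-scenario intakes, AFEs, national prevalence and coverage — computed by
a deliberately separate straight-line implementation (plain loops over
rows and members in `hcesfort.ground_truth`) that shares only constant
tables with the pipeline, never code paths. Parameter-recovery tests
compare the vectorised pipeline against these loops.

What the generator does **not** emulate, hence what passing tests do not
show about real data: intra-household allocation (the energy-proportional
sharing assumption is baked into both generator and pipeline, so it is
untested); item quantities independent of household size; no seasonality,
no correlation between items beyond stratum effects, no reporting bias,
no genuine recording errors other than the injected ones; Swahili food
labels and the panel/refresh longitudinal structure are out of scope.

## Numerical choices

* Outlier SD: leave-one-out, centred on the median of logs (see above);
  z-limit 3.0.
* Weighted quantile: weighted-index type-7 generalisation, frequency
  semantics (see above).
* Iron curve: tabulated, 2001 points, linear interpolation; risk clamped
  to its endpoint values outside the grid; risk(0) = 1.
* Breastmilk-offset floor: complementary-food energies are non-negative by
  construction; the floor at zero is enforced anyway.
* Pieces quantities are integer counts (minimum one piece).
* Degenerate inputs: zero-variance items flag nothing; single-consumer
  items pass through; empty estimator inputs raise.
* CSV round-trips are float-exact at 1e-9 relative tolerance; identical
  seeds give byte-identical outputs.

## Problem sizes used in the test suite

Oracle suites run on hundreds of random instances of size ≤ 60; scenario
monotonicity on ten 1000-household surveys; parameter recovery on ten
full-size (~3300-household) surveys; the full suite completes in a few
minutes on one CPU.

## Known limitations

Apparent intake is a household-level proxy, not observed individual
intake; 60-item food lists under-resolve oils and mixed dishes; single
composition values ignore geographic variation; compliance enters only as
the scalar B (no market heterogeneity or time dynamics); absolute iron
prevalence depends on the assumed requirement distribution, which should
be replaced with a country-appropriate table when one is available.
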