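# Methods

`plantshift` simulates how diets of older adults change when animal-based
foods are replaced by plant-based alternatives, and what that does to the
amount of *utilizable* protein — protein counted after digestibility and
amino-acid quality — and to the prevalence of inadequate intake. This
note documents the models, the numerical choices, and what the synthetic
data does and does not represent.

## Protein accounting

All protein mass is the **total amino-acid mass** of a food (mg per
100 g edible portion), not nitrogen × 6.25. Nitrogen conversion factors
overestimate protein for most food groups because not all food nitrogen
is protein-bound and amino acids differ in nitrogen content; an
amino-acid-based protein definition avoids that bias and is the natural
basis for quality scoring. Three metrics are computed per consumption
event and aggregated upward:

* **total** protein: `grams/100 × total_aa_mg / 1000`;
* **digestible** protein: total × the food's per-group digestibility
  factor (a fraction in (0, 1], treated as an opaque per-group
  coefficient);
* **utilizable** protein: digestible protein × the meal's *similarity
  factor*.

### Per-meal similarity factor (PDCAAS-style)

Amino-acid complementation is credited only within one meal occasion
(seven slots: breakfast, lunch, dinner, four snack moments), on the
premise that indispensable amino acids (IAA) must be co-ingested within
a limited time frame to be used for synthesis. For each occasion the
digestible masses of the nine IAA scoring groups (His, Ile, Leu, Lys,
Met+Cys, Phe+Tyr, Thr, Trp, Val) are **pooled over all foods first**,
expressed per gram of digestible protein, and divided by a reference
pattern `ref_i` (mg/g protein):

    ratio_i   = (digestible IAA_i / digestible protein) / ref_i
    similarity = min(1, min_i ratio_i)

The IAA attaining an uncapped minimum below 1 is the *limiting amino
acid*. Pool-then-score makes lysine-poor bread plus lysine-rich legumes
score better than either alone (superadditivity of utilizable protein is
property-tested). Two deliberate conventions:

* the similarity denominator is **digestible** protein, with digestible
  IAA in the numerator — both axes on the post-absorption scale; the
  alternative (total-protein denominator) is a one-line change in
  `meal_similarity` but is not the default;
* a zero-protein meal has similarity 1 and utilizable 0, avoiding 0/0
  without affecting any aggregate.

Daily figures are sums over the day's occasions; per-kg variants divide
by body weight. The invariant `0 ≤ utilizable ≤ digestible ≤ total`
holds everywhere.

The shipped reference pattern is the WHO/FAO/UNU (2007) adult scoring
pattern (His 15, Ile 30, Leu 59, Lys 45, SAA 22, AAA 38, Thr 23, Trp 6,
Val 39 mg/g protein). Any nine-key pattern can be supplied instead via
YAML; results should always be read as conditional on the chosen
pattern.

## Scenario engine

Six scenarios: `original` (no change), `flexitarian40`/`flexitarian80`
(40%/80% of meat-and-fish consumption events replaced with vegetarian
alternatives), `pescetarian` (meat replaced, fish kept), `vegetarian`
(meat and fish replaced), `vegan` (all animal-based products replaced).
Foods carry explicit per-scenario conformity flags; products with only
trace animal content (cake, sprinkles) are flagged vegan-conforming and
left unchanged, which is why the vegan plant-protein share is ~99.5%,
not 100%.

Replacement is **gram-for-gram**: a targeted event keeps its consumed
quantity and swaps its item for a uniform random draw from the up-to-12
alternatives registered for its food group. Choices are independent per
event. Flexitarian selection samples events **pooled across the whole
dataset** without replacement, with sample size `round(fraction ×
n_eligible)` (half-up); "meat and fish" is operationalised as
non-conforming under the vegetarian flag. Per-participant sampling and
re-use of one product→alternative map per participant are plausible
alternatives; pooled-independent is the simplest faithful reading and is
isolated in `select_flexitarian_events` / `apply_scenario` if a user
wants to change it. One seeded generator per scenario application drives
selection then replacement in documented order, so runs reproduce
exactly.

## Usual-intake estimation

Two recall days per person overstate the spread of habitual intake.
The one-part estimator in `plantshift.usual` is the classic
transform → decompose → shrink → back-transform chain:

1. transform daily values (identity, **log** — the default, since daily
   protein is positive and right-skewed — or Box-Cox by maximum
   likelihood);
2. decompose variance into between-person `σ²_b` and within-person
   `σ²_w` by a weighted one-way random-effects fit (persons with two
   days identify `σ²_w`; `σ²_b = var(person means) − σ²_w·mean(1/nᵢ)`,
   floored at 0);
3. shrink each person mean toward the weighted stratum mean by
   `sqrt(σ²_b / (σ²_b + σ²_w/nᵢ))` — the square root targets the
   *population distribution* (the shrunken means have variance `σ²_b`)
   rather than best individual prediction;
4. back-transform and read percentiles / tail probabilities as weighted
   statistics.

Survey weights have frequency semantics: doubling a person's weight is
exactly equivalent to entering the person twice, both in the variance
components (denominator `W − 1`) and in the weighted quantile, which
generalises the linear type-7 sample quantile via min-normalised "copy"
nodes and reduces exactly to `numpy.quantile` for unit weights. No age
trend is modelled: the target population is a single 65–79 stratum.
This is deliberately simpler than full survey-grade usual-intake
software (no covariates, no spline back-transformation); its acceptance
surface is parameter recovery on data with known components, which the
test suite verifies (variance components within 15% relative, median
bias < 3% at n = 500 over 20 seeds).

## Adequacy

The protein EAR (0.66 g/kg bw/day) presumes high-quality protein, so it
is re-expressed on the utilizable scale using the reference diet's own
quality loss: per person-day of the *original* diet,
`loss = 1 − utilizable/total`; the weighted median loss `m` gives
`adjusted EAR = 0.66 × (1 − m)`, rounded to 2 decimals for reporting
(the worked example: median loss 11.9% → 0.58 g/kg bw/day). The
multiplicative form is used because subtracting the loss *fraction*
from a g/kg quantity would mix units. Prevalence of inadequacy is the
EAR cut-point method on the **usual-intake** distribution of utilizable
protein per kg (day-level prevalence would overstate inadequacy), using
the rounded adjusted EAR as the cutoff.

## Synthetic data: what it emulates, what it does not

The generator (`plantshift.synth`) stands in for restricted national
food-consumption microdata. Its defaults are the study conditions:
607 participants (51% male) aged 65–79, two recall days, seven
occasions, target animal-protein share 0.62, per-sex median intake
targets 0.96/0.94 g/kg bw/day, unit survey weights, per-sex body-weight
distributions (82 ± 11 / 70 ± 11 kg), and education distributions of
the surveyed stratum.

Daily protein is lognormal: `weight × target × exp(b_i + w_ij)` with
`b_i ~ N(0, σ_b)`, `w_ij ~ N(0, σ_w)`, `σ = sqrt(ln(1+CV²))`; default
between- and within-person CVs are 0.20 and 0.28, typical magnitudes
for protein intake in repeated-recall studies. Protein is allocated to
occasions by fixed shares (dinner 40%, lunch 24%, breakfast 17%, snacks
19%), split per occasion into an animal and a plant slot, and realised
as grams of one uniformly drawn food per slot. The dinner animal
fraction is solved so the expected animal-protein share equals the
target; infeasible targets raise a calibration error.

The food catalogue is archetype-based: meat/fish (complete IAA,
digestibility 0.94), dairy/egg (complete, 0.95), cereal
(lysine-limited, 26 mg/g vs 45 reference, 0.84), legume (lysine-rich,
SAA-limited, 0.78), soy-based processed alternatives (0.90), vegetables
and nuts. Replacement-alternative entries carry the names, protein and
kcal densities of published vegetarian/vegan replacement lists
(including zero-protein drink alternatives such as tea in the vegan
dairy-drink pool); their IAA profiles follow their archetype.

Not represented: real food-name frequencies, portion-size and satiety
behaviour, seasonality beyond carried labels, correlated food choices
across occasions, energy from protein-free foods (reported kcal
therefore underestimates true diets and is used only for relative
comparisons between scenarios), and non-unit survey weights by default.
Passing tests on this generator demonstrate correctness of the
*pipeline mechanics and estimators* under known conditions — not that
any particular national survey's numbers are reproduced. Population
results on synthetic data (e.g. the prevalence gradient original <
vegetarian < vegan with vegan above 50%) should be read as directional.

## Numerical conventions

* Amino-acid bookkeeping in mg; grams only at reporting.
* Weighted quantiles: linear interpolation, exact type-7 at unit
  weights, exact duplication semantics for integer weight ratios.
* Flexitarian sample size: round-half-up.
* Replacement draws: `rng.integers(k)` per event on a per-scenario
  `SeedSequence([seed, offset])` stream.
* Variance floors at zero; degenerate inputs (all values equal, single
  effective observation) return point masses rather than erroring.
* Zero-gram events are retained (they contribute nothing) to keep
  replacement provenance simple.

## Problem sizes used in the shipped checks

Statistical tests run at n = 500 participants (20 seeds for estimator
recovery, 10 seeds for the scenario gradient); the end-to-end report
and acceptance script use the default n = 607 with all six scenarios.
These sizes give sub-minute runtimes per check while keeping Monte
Carlo error well inside the asserted tolerances.

## Known limitations

* PDCAAS-style scoring caps quality at 1 and ignores IAA-specific ileal
  digestibility (no DIAAS).
* No cross-meal amino-acid carry-over: the one-occasion window may
  underestimate utilizable protein, most visibly in the vegan scenario.
* The one-part intake model is inappropriate for episodically consumed
  nutrients (protein is consumed daily, so this is safe here).
* Gram-for-gram substitution ignores volume/satiety differences between
  animal products and their alternatives.
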