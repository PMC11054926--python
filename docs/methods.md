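# Methods

## Model and assumptions

The pipeline answers a scaling question: take the nutrient composition of
a dietary pattern as actually eaten (densities per 2000 kcal/day), and ask
what happens when an athlete eats proportionally more of exactly that diet
to hit a hypercaloric energy target. The core assumption is
proportionality — every mass-unit nutrient scales linearly with energy
intake, and %-of-energy descriptors do not change with portion size. That
assumption ignores food substitution, satiety-driven selection and
per-meal timing; it is the deliberate idealization that makes "larger
portions of the same diet" a well-posed model.

### Energy

RMR comes from a linear body-mass equation validated in male competitive
bodybuilders (slope 24.8 kcal/kg, intercept 10 kcal). Age and sex appear
in the anthropometric profile for interface completeness but do not enter
this equation; supplying a female profile logs a warning because the
equation's validation population was male. Other linear equations can be
registered (`LinearRmrEquation`), since no single prediction equation is
canonical across athletic populations.

TDEE multiplies RMR by a physical activity level. The default PAL is 1.75
("active": roughly an hour of hard training daily), with 1.60–1.89 the
documented admissible band; the type-level invariant admits 1.0–2.5 so
sedentary and extreme cases remain expressible. The bulking surplus is a
fraction of TDEE, default 0.15 (mid-range of the 10–20 % recommended for
advanced trainees, admissible 0.10–0.20, hard cap 0.5).

### Rounding policy

Published desk calculations typically round each reported stage and feed
the rounded number forward. The default `report_then_propagate` policy
reproduces that chain: RMR is rounded to integer kcal, TDEE and ES are
computed from the rounded RMR and themselves rounded, and EER is their
sum. For an 84.5 kg athlete this gives 2106 → 3686 + 553 → 4239 kcal/day;
carrying full precision instead gives 4237.5 (the policies may disagree by
about a rounding unit per stage). All rounding is half-away-from-zero
(commercial rounding) on the shortest decimal representation — Python's
default banker's rounding would turn 3685.5 into 3686 only by accident of
parity and mis-round some .5 ties. The divergence between the two
policies is bounded: a seeded randomized test over the admissible activity
band (PAL 1.60–1.89, surplus 0.10–0.20, masses 50–120 kg) asserts
|EER_report − EER_full| ≤ 2 kcal. The bound is a property of that band; at
the extreme corner of the type invariants (PAL 2.5, surplus 0.5) the
stagewise-rounding drift can exceed it, which is why the test samples the
band the model is actually used in.

### Diet profiles and scaling

Profiles serialize to a small CSV dialect: `# key = value` metadata
(name, reference energy, protein/saturated-fat energy fractions, leucine
share) above a `nutrient_id,amount,unit,precision` table. Units are a
closed set (g, mg, mcg, mcg_RAE, IU, pct_kcal) and are never converted;
comparisons require like units and fail loudly otherwise. Scaled amounts
are reported at each nutrient's display precision (integers except
vitamin B12, vitamin B6 and ω3 PUFA, which carry one decimal, matching
the source table's printed precision); the full-precision products are
retained alongside, so composition of scalings is exact and only the
final report rounds.

The packaged fixture is the AHS-2 strict-vegetarian (vegan) column per
2000 kcal/day. Fiber is stored as the cohort mean 46.7 g per 2000 kcal —
the reading under which the scaled value reproduces the reported 99 g at
4239 kcal — and displays as 47 at integer precision. Four scaled cells in
the source publication (vitamin D 536, iron 67, zinc 35, potassium 8973)
were evidently computed from unrounded cohort densities that were never
printed; scaling the printed densities gives 534, 68, 34 and 8974. The
package scales what the fixture contains, and no adequacy verdict depends
on the difference. Similarly, the modeled protein level of 151 g/day is
not derivable from the %-energy pathway (4239 × 0.145 / 4 = 153.7 g/day);
the protein plan therefore takes its level as an explicit input (default
151) and reports which source was used, with the %-energy pathway exposed
as `protein_level_from_energy`.

### Protein and leucine

Requirement: 1.6 g/kg/day × body mass, integer grams. Leucine: a fixed
share of total protein — 7.1 % for plant proteins (default), 8.8 % for
animal proteins — rounded to integer grams under the report policy, then
divided evenly across meals (default 4, admissible 3–6) and reported to
two decimals. Thresholds: intake ≥ requirement, relative intake ≥ 1.6
g/kg/day, leucine ≥ 8 g/day and ≥ 2 g/meal. All comparisons are inclusive
(reaching a threshold counts as meeting it) and act on reported values,
matching how such tables are read. Per-meal distribution is modeled as
perfectly even; real meal-to-meal variation is out of scope because the
source cohort has no per-meal data.

### Adequacy

Each reference carries a direction. Minima (RDA, AI) are met when the
reported scaled amount reaches the target. Limits are met below the
target: the saturated-fat guideline is strict (`< 10 %` of calories,
printed with a "<"), the sodium CDRR non-strict (≤ 2300 mg passes;
exceeding the level fails) — the CDRR's own wording does not settle
strictness, so ≤ was chosen and is configurable per row via the `strict`
column. The fiber AI is energy-relative (14 g per 1000 kcal) and is
recomputed from the EER at evaluation time rather than stored. Profile
nutrients without a reference (the calories row) are untargeted;
reference nutrients missing from the profile are listed as `missing`, not
counted as failures.

### Synthetic data

The cohort generator draws body mass and age uniformly over the observed
ranges (75–94 kg, 22–35 y). Only ranges and medians are known for the
modeled population; uniform is the maximum-entropy distribution given a
range, and its median matches the reported 84.5 kg. The profile generator
multiplies each density by an independent lognormal factor with mean
exactly 1 (σ² = ln(1 + cv²), μ = −σ²/2) at a default coefficient of
variation of 0.2 — a typical between-subject spread for FFQ-derived
nutrient densities — with pct_kcal entries clipped to [0, 100]. One
global seed drives everything; cohort and profile draws use distinct
derived streams, so they are independently reproducible. The generator
emulates range, location and multiplicative spread only: it does not
emulate FFQ measurement-error structure, nutrient-nutrient correlation, or
survey weights, so passing tests demonstrate pipeline correctness under
the stated statistical structure, not validity of the source cohort data.

## Numerical choices

- Ties round away from zero everywhere, via `decimal` on the float's
  shortest repr (avoids `2.675 → 2.67` binary artefacts).
- Scaling keeps full-precision amounts internally; rounding happens once,
  at reporting precision.
- Degenerate inputs: zero surplus and PAL 1.0 collapse EER to RMR; an
  empty nutrient table is a valid (vacuous) profile; an empty reference
  set skips the adequacy stage rather than failing the run.
- Problem sizes in the test suite (10⁴-athlete cohorts, 2000 profile
  replicates, 1000-profile adequacy sweeps) keep the full suite under a
  few seconds while making Monte-Carlo tolerances (±0.5 kg on a median,
  2 % on a mean, ±30 kcal on EER) comfortably non-flaky at fixed seeds.

## Known limitations

- Proportional scaling cannot capture substitution or satiety effects;
  the 99 g/day scaled fiber value illustrates intakes that may be
  practically difficult even if arithmetically implied.
- No protein-quality modeling (DIAAS-type scores) and no creatine
  modeling; leucine share is a population constant, not food-resolved.
- Unit systems are never interconverted (IU vs mcg for vitamin D, mcg RAE
  for vitamin A), so references must be supplied in the profile's units.
- The energy model is validated for male bodybuilders in the hypercaloric
  phase; hypocaloric (contest-prep) modeling is explicitly out of scope.
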