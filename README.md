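# plantbulk

Can a commonplace, completely plant-based (vegan) diet — eaten in larger
portions, with no special planning — supply the protein, leucine and
micronutrients a male bodybuilder needs to maximize muscle hypertrophy
during the hypercaloric "bulking" phase? `plantbulk` implements that
dietary-modeling question as a tested, reusable pipeline for sports
dietitians, nutrition researchers and quantified athletes.

## The model

Four stages, each exposed as an importable module:

1. **Energy** (`plantbulk.energy`). Resting metabolic rate from a linear
   equation validated in male bodybuilders,

   RMR = 24.8 · mass(kg) + 10 (kcal/day),

   then TDEE = RMR · PAL (physical activity level, default 1.75,
   "active"), an energy surplus ES = TDEE · s (default s = 0.15, mid-range
   of the 10–20 % recommended for advanced trainees), and the estimated
   energy requirement EER = TDEE + ES. The default
   `report_then_propagate` policy rounds each reported stage before the
   next (ties away from zero); `full_precision` keeps exact floats, where
   EER = RMR · PAL · (1 + s) holds identically. Other linear RMR
   equations can be plugged in via `LinearRmrEquation`.

2. **Diet scaling** (`plantbulk.profiles`). A nutrient-density profile per
   reference energy — the packaged fixture is the Adventist Health Study-2
   strict-vegetarian column, per 2000 kcal/day — is scaled proportionally
   to the EER: mass-unit densities are multiplied by EER/2000;
   %-of-calories entries (saturated fat) are scale-invariant.

3. **Protein & leucine** (`plantbulk.protein`). Requirement = 1.6 g/kg/day
   (consensus rate for maximal hypertrophy) times body mass. The modeled
   intake level is converted to leucine via the plant-protein share
   (7.1 %; animal 8.8 % selectable), split evenly across 4 meals, and
   checked against the muscle-protein-synthesis triggers of ≥2 g
   leucine/meal and ≥8 g/day.

4. **Adequacy** (`plantbulk.adequacy`). Direction-aware comparison against
   Dietary Reference Intakes for adult males 19–30: RDA/AI minima must be
   reached; the sodium CDRR is an at-or-below limit; the saturated-fat
   guideline is a strict <10 %-of-calories limit; the fiber AI is
   energy-relative (14 g / 1000 kcal) and recomputed from the EER.

A seeded synthetic-data module (`plantbulk.synth`) generates cohorts
uniform over the observed anthropometric ranges (75–94 kg, 22–35 y) and
noisy profile replicates (mean-one lognormal noise), so the whole pipeline
is testable without external data. `plantbulk.pipeline` orchestrates
everything, and a thin CLI (`plantbulk model|energy|scale|protein|adequacy|synth`)
wraps the library.

## Worked example

```python
from plantbulk import run_model, render_report
print(render_report(run_model(), "text"))
```

or `python examples/energy_requirements.py`, which prints

```
RMR  = 2106 kcal/day   (resting metabolism)
TDEE = 3686 kcal/day   (RMR x PAL 1.75)
ES   = 553 kcal/day   (15% bulking surplus)
EER  = 4239 kcal/day   (target intake = TDEE + ES)
```

An 84.5 kg athlete (the cohort median) needs about 4239 kcal/day while
bulking. Scaling the vegan profile to that intake
(`examples/scale_diet.py`, `examples/protein_leucine.py`) yields 151 g/day
protein (1.8 g/kg/day, above the 135 g/day requirement) and 11 g/day
leucine (2.75 g per meal, above the 2 g trigger), and the adequacy report
(`examples/adequacy_report.py`) ends with

```
16 of 18 targets met; failures: sodium, vitamin_d
```

i.e. every micronutrient clears its target except vitamin D (534 IU vs
the 600 IU RDA) and sodium (7484 mg vs the 2300 mg CDRR limit), while
saturated fat (5 % of calories) stays below the 10 % guideline. The
message of the model: portion size alone closes the protein and leucine
gap; vitamin D and sodium deserve separate attention.

## Scope

Off-season (hypercaloric) modeling only — results do not transfer to
contest preparation. No protein-quality scoring (DIAAS), no per-meal
intake distribution data, no unit conversions between IU/mcg systems, and
no food-item-level composition; see `docs/methods.md` for assumptions and
limitations.
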