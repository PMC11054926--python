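"""Protein and leucine plan against hypertrophy thresholds.

The requirement is 1.6 g protein per kg body mass. The modeled intake
(151 g/day, the level the scaled vegan diet supplies) is converted to
leucine using the 7.1 % plant-protein share and split over four daily
meals, then checked against the muscle-protein-synthesis triggers of
2 g leucine per meal and 8 g per day.
"""

from plantbulk import AnthropometricProfile, build_protein_plan

athlete = AnthropometricProfile(body_mass=84.5, age=28.5)
plan = build_protein_plan(athlete, level_g_day=151)

print(f"requirement      = {plan.requirement_g_day} g/day (1.6 g/kg at 84.5 kg)")
print(f"modeled level    = {plan.level_g_day} g/day = {plan.relative_g_kg_day} g/kg/day")
print(f"leucine          = {plan.leucine_g_day} g/day at the 7.1 % plant share")
print(f"leucine per meal = {plan.leucine_g_meal} g over {plan.meals_per_day} meals")
for name, ok in plan.thresholds_met.items():
    print(f"  {name.replace('_', ' '):<35} {'met' if ok else 'NOT MET'}")
print("\nAll four thresholds are met: the scaled plant-based diet supplies more")
print("protein and leucine than maximal hypertrophy requires.")
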