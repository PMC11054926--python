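"""Scale the strict-vegetarian nutrient-density profile to bulking energy.

The packaged profile expresses the AHS-2 vegan dietary pattern per
2000 kcal/day. Eating proportionally more of the same diet multiplies every
mass-unit nutrient by the energy ratio; %-of-calories entries (saturated
fat) are unchanged because composition does not depend on portion size.
"""

from plantbulk import packaged_profile, scale_profile

profile = packaged_profile()
scaled = scale_profile(profile, target_energy=4239)

print(f"{profile.name}: {profile.reference_energy:.0f} -> {scaled.target_energy:.0f} kcal "
      f"(factor {scaled.scale_factor:.4f})\n")
print(f"{'nutrient':<16}{'per 2000 kcal':>14}{'scaled':>10}  unit")
for q in profile.densities:
    s = scaled.amount(q.nutrient_id)
    print(f"{q.nutrient_id:<16}{q.reported_amount:>14}{s.amount:>10}  {s.unit}")
print("\nSodium lands at 7484 mg and vitamin B12 at 49.4 mcg — larger portions")
print("scale every density, helpful ones and excessive ones alike.")
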