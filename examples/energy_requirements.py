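"""Energy chain for the median competitive bodybuilder.

Feeds the cohort-median anthropometrics (84.5 kg) through the
bodybuilder-validated RMR equation, applies the "active" PAL of 1.75 and a
15 % bulking surplus, and prints the resulting chain. EER is the daily
intake that supports maximal hypertrophy in the off-season.
"""

from plantbulk import ActivityParameters, AnthropometricProfile, energy_requirement

athlete = AnthropometricProfile(body_mass=84.5, age=28.5)
activity = ActivityParameters(pal=1.75, surplus_fraction=0.15)

req = energy_requirement(athlete, activity)
print(f"RMR  = {req.rmr} kcal/day   (resting metabolism)")
print(f"TDEE = {req.tdee} kcal/day   (RMR x PAL {activity.pal})")
print(f"ES   = {req.es} kcal/day   ({activity.surplus_fraction:.0%} bulking surplus)")
print(f"EER  = {req.eer} kcal/day   (target intake = TDEE + ES)")
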