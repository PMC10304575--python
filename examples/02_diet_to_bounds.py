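"""Convert the measured feeding experiment into exchange-reaction bounds.

The feeding trial applied known masses of glucose and egg-white protein
over nine days; assuming linear consumption, each dietary compound becomes
a per-larva molar uptake limit (mmol/larva/day) on its exchange reaction.
Uptake is a negative flux, so a limit u is applied as lower_bound = -u.
"""

from larvaflux import data, reference_exchange_bounds

bounds = reference_exchange_bounds()

print(f"implied larva count: {data.implied_larva_count():.0f}")
print(f"duration: {data.DIET_DURATION_DAYS} days\n")
print(f"{'exchange':<22}{'uptake limit (mmol/larva/day)':>32}")
for ex in sorted(bounds.bounds):
    print(f"{ex:<22}{bounds.bounds[ex]:>32.5f}")

# the limits round to the measured per-larva molar transport rates
assert round(bounds.bounds["EX_lysine_e"], 3) == 0.012
assert round(bounds.bounds["EX_glycine_e"], 3) == 0.013
print("\nlysine rounds to 0.012 and glycine to 0.013 mmol/larva/day, "
      "matching the measured transport rates.")
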