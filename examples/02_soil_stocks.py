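"""Soil inorganic-N stocks from layered concentration measurements.

Builds a 0-60 cm profile (three 20 cm layers), computes per-layer and
profile NO3-N / NH4-N stocks (gamma * h * N / 10) and the total
inorganic-N reserve.
"""

from nbudget import (NSpecies, SoilLayerObservation, SoilProfile,
                     inorganic_n_reserve, layer_stock, profile_stock)

layers = (
    SoilLayerObservation(0, 20, no3=12.0, nh4=5.0, bulk_density=1.45),
    SoilLayerObservation(20, 40, no3=8.0, nh4=3.5, bulk_density=1.45),
    SoilLayerObservation(40, 60, no3=5.0, nh4=2.0, bulk_density=1.45),
)
profile = SoilProfile(layers)

for layer in layers:
    print(f"{layer.depth_top:>2.0f}-{layer.depth_bottom:<2.0f} cm: "
          f"NO3-N {layer_stock(layer, NSpecies.NO3):6.2f}  "
          f"NH4-N {layer_stock(layer, NSpecies.NH4):6.2f}  kg/ha")

print(f"\nprofile NO3-N stock: {profile_stock(profile, NSpecies.NO3):.2f} kg/ha")
print(f"profile NH4-N stock: {profile_stock(profile, NSpecies.NH4):.2f} kg/ha")
print(f"0-60 cm inorganic-N reserve: {inorganic_n_reserve(profile):.2f} kg/ha")
print("\nThe reserve is the pre-season input (or end-season residue) term "
      "of the nitrogen ledger.")
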