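"""Stomate-seeded diffusion geometry and airspace conductance.

Computes geodesic/Euclidean distance fields from the phantom's stomata,
derives leaf tortuosity and lateral path lengthening, and converts them
with porosity and mesophyll thickness into the gas-phase conductance
g_IAS, plus the share of the total mesophyll resistance it represents
for a typical mesophyll conductance.
"""

import leafgas as lg

volume, truth = lg.generate_leaf_volume(lg.LeafPhantomParams(seed=11))
traits = lg.diffusion_traits(volume, truth.stomate_centers)

print(f"tau_leaf (tortuosity)       {traits.tau_leaf:.2f}  (>= 1; 1 = unobstructed)")
print(f"lambda_leaf (lateral path)  {traits.lambda_leaf:.2f}  (>= 1; grows as stomata thin out)")
print(f"theta_IAS                   {traits.theta_ias:.3f}")
print(f"mesophyll thickness         {traits.l_mes_um:.0f} um")
print(f"g_IAS                       {traits.g_ias:.3f} mol m-2 s-1 bar-1")
print(f"IAS reachable from stomata  {traits.reachable_fraction:.1%}")

g_m = 0.15  # mol m-2 s-1, a typical well-watered broadleaf value
share = lg.gias_contribution(g_m, traits.g_ias * traits.pressure_bar)
print(f"gas-phase share of 1/g_m    {share:.1%} for g_m = {g_m}")
print("The share is the fraction of the mesophyll diffusion resistance that")
print("lies in the airspace; the remainder is liquid-phase.")
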