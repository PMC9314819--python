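"""Generate a synthetic leaf volume and extract its anatomical traits.

Builds the default walnut-like phantom (215 um leaf, palisade of
vertical cylinders over a spongy blob layer, BSE slabs, abaxial
stomata), then recovers porosity, thicknesses, surface area and the BSE
share from the label stack and compares them with the generator's
counted ground truth.
"""

import leafgas as lg

params = lg.LeafPhantomParams(seed=11)
volume, truth = lg.generate_leaf_volume(params)

theta = lg.porosity(volume)
ratio = lg.vias_to_vcell(volume)
sa_v = lg.sa_mes_per_vmes(volume)
l_leaf, l_mes, l_ad, l_ab = lg.thicknesses(volume)
bse = lg.bse_area_fraction(volume)
diam = lg.paradermal_palisade_diameter(volume, (0.2, 0.4, 0.6))

print(f"porosity theta_IAS        {theta:.3f}   (truth {truth.porosity_mesophyll:.3f})")
print(f"V_IAS / V_mes-cell        {ratio:.3f}   (= theta/(1-theta))")
print(f"SA_mes / V_mes            {sa_v:.3f} um2/um3")
print(f"thicknesses (um)          leaf {l_leaf:.0f}  mes {l_mes:.1f}  "
      f"adaxial epi {l_ad:.1f}  abaxial epi {l_ab:.1f}")
print(f"BSE area fraction         {bse:.2f} %  (truth {truth.bse_area_fraction_pct:.2f} %)")
for f, d in diam.items():
    print(f"palisade diameter @{f:.0%}   {d:.1f} um  (truth {truth.palisade_diameter_um:.1f})")
print("Porosity and the airspace/cell ratio are voxel-count fractions of the")
print("mesophyll; the BSE percentage is its share of the cross-section.")
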