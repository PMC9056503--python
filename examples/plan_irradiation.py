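"""Plan the nine-spot irradiation and compute its fluence and surface dose.

Builds the 3×3 spot grid (1.2-mm pitch, 10 s per spot at 6.0 nA) behind an
8-µm kapton window and 7.5 cm of air, then prints the energy reaching the
target, the central proton fluence and the surface dose averaged over the
first 100 µm of water-equivalent tissue.
"""

from actipet import (
    BeamlineGeometry,
    csda_range,
    energy_after_layers,
    fluence_map,
    load_table,
    reference_plan,
    surface_dose,
)

geom = BeamlineGeometry.from_names([("kapton", 8e-4), ("air", 7.5)], 8.0)
target_energy, loss = energy_after_layers(geom)
print(f"beam energy at target : {target_energy:.2f} MeV "
      f"(loss in window + air: {loss:.3f} MeV)")

water = load_table("water")
print(f"range in water        : {csda_range(water, target_energy)*10:.2f} mm "
      "(activation confined to the last millimetre)")

plan = reference_plan()
fmap = fluence_map(plan, sigma_x_mm=0.78, sigma_y_mm=0.89)
central = fmap.value_at_centre()
print(f"protons per spot      : {plan.spots[0].protons:.3e}")
print(f"central fluence       : {central:.3e} protons/cm^2")
print(f"surface dose (100 um) : {surface_dose(central, target_energy, 100, water):.3e} Gy")
# The fluence and dose are what drive isotope production in the tumour;
# the grid integral conserves the delivered protons to < 0.1 %.
print(f"fluence integral      : {fmap.integral_protons():.3e} of "
      f"{plan.total_protons:.3e} delivered protons")
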