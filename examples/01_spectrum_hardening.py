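"""Generate a filtered 120 kVp spectrum and show how filtration hardens it.

Builds the Kramers-law bremsstrahlung surrogate, applies 1 mm of copper
filtration, and prints mean energies: the filter preferentially absorbs
low-energy photons, raising the mean — the root cause of beam-hardening
artifacts when reconstruction assumes a single energy.
"""

import polyct as pc

bare = pc.generate_bremsstrahlung(kvp=120.0, delta=1.0)
copper = pc.load_material("copper")
filtered = pc.generate_bremsstrahlung(120.0, 1.0, copper, filter_thickness_mm=1.0)
perturbed = pc.apply_efficiency_error(filtered)

print(f"unfiltered 120 kVp mean energy : {pc.mean_energy(bare):6.2f} keV")
print(f"after 1 mm Cu filtration       : {pc.mean_energy(filtered):6.2f} keV")
print(f"with detector-efficiency error : {pc.mean_energy(perturbed):6.2f} keV")
print()
print("Filtration raises the mean energy by tens of keV: the beam 'hardens'.")
print("The perturbed spectrum (1 - 0.25 sin(2 pi E / E_max) efficiency) is the")
print("error model used to probe the reconstruction's spectrum tolerance.")
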