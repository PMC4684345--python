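"""Reconstruct the phantom with SART and with the iterative BHC method.

SART assumes a single energy, so polychromatic data give it cupped, streaky
images; the segmentation-aware E-ART solver models the spectrum explicitly
and recovers the 50 keV attenuation values of all three materials.
"""

import numpy as np

import polyct as pc

geom = pc.FanBeamGeometry(sod_mm=1000, sdd_mm=1200, n_cells=128,
                          cell_size_mm=2.4, n_views=60, n_pixels=64)
spectrum = pc.generate_bremsstrahlung(120.0, 1.0, pc.load_material("copper"), 1.0)
spec = pc.default_phantom()
model = pc.default_model(spectrum, spec)
labels, mu0 = pc.make_disk_phantom(spec, geom, model)
sino = pc.simulate_sinogram(labels, mu0, geom, spectrum, model)

sart = pc.reconstruct_sart(sino, geom)
bhc = pc.reconstruct_bhc(sino, geom, spectrum, model)

regions = np.where(mu0 > 0, labels, -1)
print(f"SART: {sart.iteration} sweeps;  BHC: {bhc.iteration} sweeps "
      f"(e(r) < 1e-4)")
print(f"{'material':13s} {'truth':>7s} {'SART':>7s} {'BHC':>7s}   (cm^-1)")
for name in model.names:
    lab = model.label_of(name)
    # the 10 mm titanium disks are only ~2 px across at this scale
    erosion = 0 if name == "titanium" else 1
    rs = pc.region_stats(sart.mu, regions, erosion_px=erosion,
                         include_labels=[lab]).mean(lab)
    rb = pc.region_stats(bhc.mu, regions, erosion_px=erosion,
                         include_labels=[lab]).mean(lab)
    print(f"{name:13s} {spec.mu_e0[name]:7.3f} {rs:7.3f} {rb:7.3f}")
print(f"MSE vs ground truth: SART {pc.mse(sart.mu, mu0):.5f}, "
      f"BHC {pc.mse(bhc.mu, mu0):.5f}")
print()
print("SART underestimates everything (beam hardening); BHC recovers the")
print("pinned 50 keV values for water, bone and titanium.")
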