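import numpy as np
import pytest

import polyct as pc
from polyct._kernels import ray_endpoints


def analytic_chord(geometry, view, cell):
    """Independent chord length of a ray segment inside the image square,
    by closed-form slab (Liang-Barsky) interval intersection."""
    beta = float(geometry.view_angles[view])
    sx, sy, ex, ey = ray_endpoints(beta, geometry.sod_mm, geometry.sdd_mm,
                                   geometry.n_cells, geometry.cell_size_mm,
                                   cell)
    half = 0.5 * geometry.n_pixels * geometry.pixel_size_mm
    d = np.array([ex - sx, ey - sy])
    p0 = np.array([sx, sy])
    t0, t1 = 0.0, 1.0
    for axis in (0, 1):
        if d[axis] == 0:
            if not (-half <= p0[axis] < half):
                return 0.0
            continue
        ta = (-half - p0[axis]) / d[axis]
        tb = (half - p0[axis]) / d[axis]
        lo, hi = min(ta, tb), max(ta, tb)
        t0, t1 = max(t0, lo), min(t1, hi)
    return max(0.0, t1 - t0) * float(np.hypot(*d))


@pytest.fixture(scope="session")
def water():
    return pc.load_material("water")


@pytest.fixture(scope="session")
def bone():
    return pc.load_material("bone_cortical")


@pytest.fixture(scope="session")
def titanium():
    return pc.load_material("titanium")


@pytest.fixture(scope="session")
def copper():
    return pc.load_material("copper")


@pytest.fixture(scope="session")
def spectrum_120kvp(copper):
    """120 kVp bremsstrahlung with 1 mm Cu filtration, 5 keV bins (fast)."""
    return pc.generate_bremsstrahlung(120.0, 5.0, copper, 1.0)


@pytest.fixture(scope="session")
def model(water, bone, titanium, spectrum_120kvp):
    """Water/bone/titanium model at E0 = 50 keV with pinned ground truths."""
    return pc.build_material_model(
        [water, bone, titanium], e0=50.0,
        spectrum_grid=spectrum_120kvp.energies,
        mu_at_e0={"water": 0.236, "bone_cortical": 0.837, "titanium": 5.518},
    )


@pytest.fixture(scope="session")
def small_geometry():
    """Miniature scan: same SOD/SDD ratio as the reference study, 64 px grid."""
    return pc.FanBeamGeometry(
        sod_mm=1000.0, sdd_mm=1200.0, n_cells=128, cell_size_mm=2.4,
        n_views=60, n_pixels=64,
    )


@pytest.fixture(scope="session")
def small_phantom(small_geometry, model):
    labels, mu0 = pc.make_disk_phantom(pc.default_phantom(), small_geometry, model)
    return labels, mu0


@pytest.fixture(scope="session")
def small_sinogram(small_phantom, small_geometry, spectrum_120kvp, model):
    labels, mu0 = small_phantom
    return pc.simulate_sinogram(labels, mu0, small_geometry, spectrum_120kvp, model)
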