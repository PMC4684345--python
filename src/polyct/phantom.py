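"""Multi-material disk phantom and polychromatic sinogram simulation.

The default phantom mirrors a classic beam-hardening test object: a 240 mm
water disk containing two 40 mm cortical-bone disks and two 10 mm titanium
disks, all centred on the horizontal axis.  Ground-truth mu(E0) values at
E0 = 50 keV are pinned to 0.236 (water), 0.837 (bone) and 5.518 (titanium)
cm^-1, with each material's energy dependence taken from its tabulated
curve shape normalised at 50 keV.

Pixels are labelled by their centre point (one material per point, no
partial-volume mixing), so the piecewise-constant material assumption of
the reconstruction model holds exactly for simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .materials import MaterialModel, build_material_model, load_material
from .projector import FanBeamGeometry, fov_diameter
from .spectrum import Spectrum

__all__ = [
    "Disk",
    "PhantomSpec",
    "Sinogram",
    "default_phantom",
    "reference_geometry",
    "default_model",
    "make_disk_phantom",
    "simulate_sinogram",
]

E0_DEFAULT_KEV = 50.0
MU_E0_DEFAULT = {"water": 0.236, "bone_cortical": 0.837, "titanium": 5.518}
DEFAULT_FLUX = 1.0e5


@dataclass(frozen=True)
class Disk:
    cx_mm: float
    cy_mm: float
    diameter_mm: float
    material: str


@dataclass(frozen=True)
class PhantomSpec:
    """Disk layout plus per-material ground-truth mu(E0) in cm^-1.

    Later disks override earlier ones where they overlap, so inclusions are
    listed after the disk that contains them.
    """

    disks: tuple
    mu_e0: dict
    e0_keV: float = E0_DEFAULT_KEV

    def materials(self) -> list[str]:
        return sorted(self.mu_e0, key=self.mu_e0.get)


def default_phantom() -> PhantomSpec:
    """240 mm water disk, two 40 mm bone disks, two 10 mm titanium disks.

    Bone centres at x = +/-65 mm, titanium at x = +/-25 mm; the layout is
    mirror-symmetric about both axes.
    """
    return PhantomSpec(
        disks=(
            Disk(0.0, 0.0, 240.0, "water"),
            Disk(-65.0, 0.0, 40.0, "bone_cortical"),
            Disk(65.0, 0.0, 40.0, "bone_cortical"),
            Disk(-25.0, 0.0, 10.0, "titanium"),
            Disk(25.0, 0.0, 10.0, "titanium"),
        ),
        mu_e0=dict(MU_E0_DEFAULT),
    )


def reference_geometry(n_pixels: int = 512, n_views: int = 720) -> FanBeamGeometry:
    """The reference scan: SOD 1000 mm, SDD 1200 mm, 512 x 0.6 mm cells.

    Grid size and view count are free parameters (the acceptance runs use a
    reduced 256 px / 360 view scale); the scan geometry itself is fixed and
    yields a 256 mm field of view.
    """
    return FanBeamGeometry(
        sod_mm=1000.0, sdd_mm=1200.0, n_cells=512, cell_size_mm=0.6,
        n_views=n_views, n_pixels=n_pixels,
    )


def default_model(spectrum: Spectrum, spec: PhantomSpec | None = None) -> MaterialModel:
    """Material model matching a phantom spec, sampled on a spectrum's grid."""
    if spec is None:
        spec = default_phantom()
    tables = [load_material(name) for name in spec.mu_e0]
    return build_material_model(
        tables, e0=spec.e0_keV, spectrum_grid=spectrum.energies, mu_at_e0=spec.mu_e0
    )


def make_disk_phantom(spec: PhantomSpec, geometry: FanBeamGeometry,
                      model: MaterialModel) -> tuple:
    """Rasterise a phantom spec: (labels image, mu(E0) image).

    Pixels take the label of the last disk whose interior contains their
    centre; uncovered background keeps label 0 (least attenuating) with
    mu0 = 0.  Raises if any disk extends outside the field of view.
    """
    fov_r = 0.5 * fov_diameter(geometry)
    for d in spec.disks:
        if np.hypot(d.cx_mm, d.cy_mm) + 0.5 * d.diameter_mm > fov_r + 1e-9:
            raise ValueError(f"disk {d} extends outside the {2*fov_r:g} mm FOV")
    x, y = geometry.pixel_centers()
    labels = np.zeros(geometry.image_shape, dtype=np.int64)
    mu0 = np.zeros(geometry.image_shape, dtype=np.float64)
    for d in spec.disks:
        inside = (x - d.cx_mm) ** 2 + (y - d.cy_mm) ** 2 < (0.5 * d.diameter_mm) ** 2
        labels[inside] = model.label_of(d.material)
        mu0[inside] = spec.mu_e0[d.material]
    return labels, mu0


@dataclass(frozen=True)
class Sinogram:
    """Polychromatic projections p_i on a (n_views, n_cells) grid."""

    values: np.ndarray
    geometry: FanBeamGeometry
    noisy: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if v.shape != (self.geometry.n_views, self.geometry.n_cells):
            raise ValueError("sinogram shape must be (n_views, n_cells)")
        if not np.all(np.isfinite(v)):
            raise ValueError("sinogram contains non-finite values")
        object.__setattr__(self, "values", v)


def simulate_sinogram(
    labels: np.ndarray,
    mu0: np.ndarray,
    geometry: FanBeamGeometry,
    spectrum: Spectrum,
    model: MaterialModel,
    noise: str | None = None,
    flux: float = DEFAULT_FLUX,
    rng: np.random.Generator | int | None = None,
) -> Sinogram:
    """Simulate a fan-beam polychromatic sinogram of a labelled mu(E0) image.

    noise=None gives the exact projections; noise='poisson' draws photon
    counts ~ Poisson(flux * exp(-p)) per measurement and re-logs them
    (zero counts are clamped to one count so the log stays finite).
    """
    sd = spectrum.weights * spectrum.delta
    clean = _kernels.poly_sinogram(
        np.ascontiguousarray(mu0, dtype=np.float64).ravel(),
        np.ascontiguousarray(labels, dtype=np.int64).ravel(),
        model.mu_hat, sd, geometry.view_angles,
        geometry.sod_mm, geometry.sdd_mm, geometry.n_cells,
        geometry.cell_size_mm, geometry.n_pixels, geometry.pixel_size_mm,
    )
    if noise is None or noise == "off":
        return Sinogram(clean, geometry, noisy=False)
    if noise != "poisson":
        raise ValueError(f"unknown noise model {noise!r}")
    if not flux > 0:
        raise ValueError("poisson noise requires flux > 0")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    counts = gen.poisson(flux * np.exp(-clean)).astype(np.float64)
    counts = np.maximum(counts, 1.0)
    return Sinogram(-np.log(counts / flux), geometry, noisy=True)
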