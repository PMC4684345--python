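"""Fan-beam geometry and projection operators.

The scanner is an equally-spaced linear (flat) detector fan-beam system: a
point source at distance ``sod`` from the rotation centre, a detector line at
``sdd``, both rotating counter-clockwise around the centre.  The image is a
square pixel grid centred on the rotation centre; view angle 0 places the
source on the +x axis.

Per-ray operations here are plain NumPy and define the projection semantics;
whole-sinogram loops live in the numba kernels of :mod:`polyct._kernels`.
Lengths are mm, attenuation cm^-1; optical depths apply an explicit
mm->cm factor of 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .materials import MaterialModel
from .spectrum import Spectrum

__all__ = [
    "FanBeamGeometry",
    "ProjectorRow",
    "fov_diameter",
    "trace_ray",
    "material_line_integrals",
    "poly_projection",
    "mono_projection",
]

MM_TO_CM = _kernels.MM_TO_CM


@dataclass(frozen=True)
class FanBeamGeometry:
    """Fan-beam scan parameters plus the reconstruction grid.

    Parameters
    ----------
    sod_mm : float
        Source to rotation-centre distance.
    sdd_mm : float
        Source to detector distance (> sod_mm).
    n_cells : int
        Number of detector cells.
    cell_size_mm : float
        Detector cell pitch.
    n_views : int
        Projections over one full turn, uniformly spaced.
    n_pixels : int
        Image grid side length in pixels.
    pixel_size_mm : float, optional
        Pixel pitch; defaults to fov_diameter / n_pixels so the grid square
        inscribes the field of view.
    """

    sod_mm: float
    sdd_mm: float
    n_cells: int
    cell_size_mm: float
    n_views: int
    n_pixels: int
    pixel_size_mm: float = None  # type: ignore[assignment]

    def __post_init__(self):
        # sdd == sod (detector through the centre) is degenerate but legal:
        # it leaves the FOV formula at unit magnification
        if not (self.sdd_mm >= self.sod_mm > 0):
            raise ValueError("require sdd >= sod > 0")
        if min(self.n_cells, self.n_views, self.n_pixels) < 1:
            raise ValueError("counts must be positive")
        if self.pixel_size_mm is None:
            object.__setattr__(
                self, "pixel_size_mm", fov_diameter(self) / self.n_pixels
            )

    @property
    def view_angles(self) -> np.ndarray:
        """Uniform view angles over one full turn, radians."""
        return 2.0 * np.pi * np.arange(self.n_views) / self.n_views

    @property
    def grid_origin_mm(self) -> float:
        """Lower-left corner coordinate of the image grid (both axes)."""
        return -0.5 * self.n_pixels * self.pixel_size_mm

    @property
    def image_shape(self) -> tuple:
        return (self.n_pixels, self.n_pixels)

    def pixel_centers(self) -> tuple:
        """(x, y) coordinate arrays (mm) of pixel centres, indexable [iy, ix]."""
        c = self.grid_origin_mm + (np.arange(self.n_pixels) + 0.5) * self.pixel_size_mm
        return np.meshgrid(c, c)


def fov_diameter(geometry: FanBeamGeometry) -> float:
    """Field-of-view diameter (mm): detector extent scaled back to the centre."""
    return geometry.n_cells * geometry.cell_size_mm * geometry.sod_mm / geometry.sdd_mm


@dataclass(frozen=True)
class ProjectorRow:
    """Sparse system-matrix row for one ray: pixel indices and lengths R_ij.

    ``pixel_indices`` are flat C-order indices into the image;
    ``lengths_mm`` are the exact ray-pixel intersection lengths, which sum
    to the chord length of the ray through the grid.
    """

    pixel_indices: np.ndarray
    lengths_mm: np.ndarray

    @property
    def chord_mm(self) -> float:
        return float(np.sum(self.lengths_mm))


def trace_ray(geometry: FanBeamGeometry, view: int, cell: int) -> ProjectorRow:
    """Exact intersection-length row for the ray (view, cell).

    Returns an empty row if the ray misses the image grid.
    """
    if not (0 <= view < geometry.n_views and 0 <= cell < geometry.n_cells):
        raise IndexError("view or cell index out of range")
    beta = float(geometry.view_angles[view])
    sx, sy, ex, ey = _kernels.ray_endpoints(
        beta, geometry.sod_mm, geometry.sdd_mm, geometry.n_cells,
        geometry.cell_size_mm, cell,
    )
    n = geometry.n_pixels
    idx = np.empty(2 * n + 4, np.int64)
    lens = np.empty(2 * n + 4, np.float64)
    m = _kernels.trace(sx, sy, ex, ey, geometry.grid_origin_mm,
                       geometry.pixel_size_mm, n, idx, lens)
    return ProjectorRow(idx[:m].copy(), lens[:m].copy())


def material_line_integrals(row: ProjectorRow, mu0: np.ndarray,
                            labels: np.ndarray, n_materials: int) -> np.ndarray:
    """Per-material optical depths t_k = 0.1 * sum_{j: label=k} R_ij mu_j.

    All K values come from a single pass over the row.  Output is
    dimensionless (mm lengths x cm^-1 attenuation, with the mm->cm factor).
    """
    mu_flat = np.asarray(mu0, float).ravel()
    lab_flat = np.asarray(labels).ravel()
    t = np.zeros(n_materials)
    np.add.at(t, lab_flat[row.pixel_indices],
              MM_TO_CM * row.lengths_mm * mu_flat[row.pixel_indices])
    return t


def poly_projection(t: np.ndarray, spectrum: Spectrum, model: MaterialModel) -> float:
    """Polychromatic projection -log sum_n S_n delta exp(-sum_k muhat_kn t_k).

    ``t`` holds the per-material optical depths at the reference energy.
    Evaluated with a max-shift so large depths cannot overflow the exponent.
    """
    t = np.asarray(t, float)
    if model.mu_hat.shape[1] != spectrum.energies.size:
        raise ValueError("material model not sampled on this spectrum's grid")
    s = t @ model.mu_hat  # (N,) spectral optical depths
    s_min = float(np.min(s))
    sd = spectrum.weights * spectrum.delta
    return s_min - float(np.log(np.sum(sd * np.exp(-(s - s_min)))))


def mono_projection(row: ProjectorRow, mu0: np.ndarray) -> float:
    """Linear (single-energy) projection: optical depth 0.1 * sum_j R_ij mu_j."""
    mu_flat = np.asarray(mu0, float).ravel()
    return float(MM_TO_CM * np.sum(row.lengths_mm * mu_flat[row.pixel_indices]))
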