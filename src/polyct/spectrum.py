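"""Sampled polychromatic X-ray spectra.

A spectrum is a density S(E) sampled on a uniform energy grid with spacing
delta and normalised so that sum_n S_n * delta = 1 (rectangle rule).  The
polychromatic projection model consumes exactly this sampled form.

A measured tube spectrum can be loaded from CSV; for self-contained
simulation a Kramers-law bremsstrahlung surrogate with Beer-Lambert
filtration is provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import MaterialTable, _loglog_interp

__all__ = [
    "Spectrum",
    "generate_bremsstrahlung",
    "normalize",
    "mean_energy",
    "apply_efficiency_error",
    "monochromatic",
]


class SpectrumError(ValueError):
    pass


@dataclass(frozen=True)
class Spectrum:
    """Normalised sampled spectrum on a uniform energy grid.

    Attributes
    ----------
    energies : ndarray, keV — uniform grid, spacing ``delta``
    weights : ndarray — S_n >= 0; after :func:`normalize`, sum S_n delta = 1
    kvp : float, keV — tube potential; no support above it
    """

    energies: np.ndarray
    weights: np.ndarray
    kvp: float

    def __post_init__(self):
        e = np.asarray(self.energies, float)
        w = np.asarray(self.weights, float)
        if e.ndim != 1 or e.shape != w.shape or e.size < 1:
            raise SpectrumError("energies and weights must be equal-length 1-D")
        d = np.diff(e)
        if e.size > 1 and not np.allclose(d, d[0], rtol=1e-9, atol=1e-12):
            raise SpectrumError("energy grid must be uniform")
        if np.any(w < 0):
            raise SpectrumError("weights must be nonnegative")
        if np.any(e > self.kvp + 1e-9):
            raise SpectrumError("energies must not exceed kvp")
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "weights", w)

    @property
    def delta(self) -> float:
        """Grid spacing in keV (1.0 for a single-bin spectrum)."""
        return float(self.energies[1] - self.energies[0]) if self.energies.size > 1 else 1.0

    @property
    def is_normalized(self) -> bool:
        return abs(float(np.sum(self.weights) * self.delta) - 1.0) < 1e-9

    @classmethod
    def from_csv(cls, path, kvp: float | None = None) -> "Spectrum":
        data = np.genfromtxt(path, delimiter=",", names=True)
        e = np.atleast_1d(data["energy_keV"]).astype(float)
        w = np.atleast_1d(data["weight"]).astype(float)
        return cls(energies=e, weights=w, kvp=float(kvp if kvp is not None else e.max()))

    def to_csv(self, path) -> None:
        arr = np.column_stack([self.energies, self.weights])
        np.savetxt(path, arr, delimiter=",", header="energy_keV,weight", comments="")


def generate_bremsstrahlung(
    kvp: float,
    delta: float = 1.0,
    filter_material: MaterialTable | None = None,
    filter_thickness_mm: float = 0.0,
) -> Spectrum:
    """Kramers-law bremsstrahlung spectrum with optional inherent filtration.

    The unfiltered shape is S(E) proportional to (kvp/E - 1) on (0, kvp),
    zero at and above kvp.  A filter of the given material and thickness
    attenuates each bin by Beer-Lambert, exp(-mu_filter(E) * thickness);
    bins below the filter table's energy range are treated as fully absorbed.
    The result is normalised.

    This is a surrogate for a measured or simulated tube spectrum: it omits
    characteristic lines and anode effects, but reproduces the filtration
    hardening that drives beam-hardening artifacts.
    """
    if kvp <= 0 or delta <= 0:
        raise SpectrumError("kvp and delta must be positive")
    if delta >= kvp:
        raise SpectrumError("delta must be smaller than kvp (grid would be empty)")
    energies = np.arange(delta, kvp + 0.5 * delta, delta)
    w = np.clip(kvp / energies - 1.0, 0.0, None)
    if filter_material is not None and filter_thickness_mm > 0:
        mu = _loglog_interp(filter_material, energies, clamp=True) * filter_material.density
        w = w * np.exp(-mu * filter_thickness_mm * 0.1)  # mm -> cm
        w[energies < filter_material.energy_keV[0]] = 0.0
    return normalize(Spectrum(energies=energies, weights=w, kvp=float(kvp)))


def normalize(spectrum: Spectrum) -> Spectrum:
    """Rescale weights so that sum_n S_n delta = 1."""
    total = float(np.sum(spectrum.weights) * spectrum.delta)
    if total <= 0:
        raise SpectrumError("cannot normalize an all-zero spectrum")
    return Spectrum(spectrum.energies, spectrum.weights / total, spectrum.kvp)


def mean_energy(spectrum: Spectrum) -> float:
    """Mean photon energy sum_n E_n S_n delta of a normalised spectrum (keV)."""
    s = spectrum if spectrum.is_normalized else normalize(spectrum)
    return float(np.sum(s.energies * s.weights) * s.delta)


def apply_efficiency_error(spectrum: Spectrum) -> Spectrum:
    """Perturb a spectrum by the detector-efficiency error model.

    Multiplies the weights pointwise by 1 - 0.25 sin(2 pi E / E_max) with
    E_max = kvp, then renormalises.  Models a plausible unknown detector
    response, used to probe a reconstruction's tolerance to spectrum error.
    """
    factor = 1.0 - 0.25 * np.sin(2.0 * np.pi * spectrum.energies / spectrum.kvp)
    return normalize(Spectrum(spectrum.energies, spectrum.weights * factor, spectrum.kvp))


def monochromatic(energy_keV: float) -> Spectrum:
    """Single-bin (delta) spectrum at one energy; normalised by convention."""
    return Spectrum(np.array([float(energy_keV)]), np.array([1.0]), float(energy_keV))
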