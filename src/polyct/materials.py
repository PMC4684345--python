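"""Attenuation physics for multi-material CT.

A scanned object made of K known materials, each occupying its own region,
has a linear attenuation coefficient that factorises per pixel as

    mu(E, x) = muhat_k(E) * mu(E0, x),      k = material at x,

where ``muhat_k(E) = mu_mk(E) / mu_mk(E0)`` is material k's mass attenuation
curve normalised to 1 at a reference energy E0.  Provided the K linear
attenuation values at E0 are pairwise distinct, the material label of a pixel
can be recovered from its mu(E0) value alone by thresholding.  This module
holds the tabulated attenuation data, the normalised curves, and that
classification machinery.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import yaml

__all__ = [
    "MaterialTable",
    "MaterialModel",
    "available_materials",
    "load_material",
    "interp_mass_attenuation",
    "build_material_model",
    "classify",
    "synthesize_mu",
]

_DATA = importlib.resources.files("polyct") / "data"


class MaterialError(ValueError):
    """Invalid material table or model."""


@dataclass(frozen=True)
class MaterialTable:
    """Tabulated mass attenuation curve for one material.

    Parameters
    ----------
    name : str
        Material identifier.
    energy_keV : ndarray
        Strictly increasing energy grid in keV.
    mass_attenuation : ndarray
        Mass attenuation coefficient mu/rho in cm^2/g at each grid point.
    density : float
        Nominal density in g/cm^3.
    """

    name: str
    energy_keV: np.ndarray
    mass_attenuation: np.ndarray
    density: float

    def __post_init__(self):
        e = np.asarray(self.energy_keV, dtype=float)
        m = np.asarray(self.mass_attenuation, dtype=float)
        if e.ndim != 1 or e.shape != m.shape:
            raise MaterialError("energy grid and attenuation must be equal-length 1-D")
        if not np.all(np.diff(e) > 0):
            raise MaterialError(f"{self.name}: energy grid must be strictly increasing")
        if not np.all(m > 0):
            raise MaterialError(f"{self.name}: mass attenuation must be positive")
        if not self.density > 0:
            raise MaterialError(f"{self.name}: density must be positive")
        object.__setattr__(self, "energy_keV", e)
        object.__setattr__(self, "mass_attenuation", m)

    @classmethod
    def from_csv(cls, path, name: str, density: float) -> "MaterialTable":
        """Read a two-column CSV (energy_keV, mass_attenuation_cm2_per_g)."""
        data = np.genfromtxt(path, delimiter=",", names=True)
        return cls(
            name=name,
            energy_keV=np.atleast_1d(data["energy_keV"]),
            mass_attenuation=np.atleast_1d(data["mass_attenuation_cm2_per_g"]),
            density=density,
        )

    def linear_attenuation(self, energy_keV):
        """Linear attenuation mu = (mu/rho) * rho in cm^-1 at the given energies."""
        return interp_mass_attenuation(self, energy_keV) * self.density


def available_materials() -> list[str]:
    """Names of the packaged material tables."""
    manifest = yaml.safe_load((_DATA / "materials.yaml").read_text())
    return sorted(manifest)


def load_material(name: str) -> MaterialTable:
    """Load a packaged material table (e.g. ``'water'``, ``'titanium'``)."""
    manifest = yaml.safe_load((_DATA / "materials.yaml").read_text())
    if name not in manifest:
        raise KeyError(f"unknown material {name!r}; available: {available_materials()}")
    entry = manifest[name]
    with importlib.resources.as_file(_DATA / entry["table"]) as path:
        return MaterialTable.from_csv(path, name=name, density=float(entry["density"]))


def _loglog_interp(table: MaterialTable, energy_keV, clamp: bool) -> np.ndarray:
    e = np.asarray(energy_keV, dtype=float)
    lo, hi = table.energy_keV[0], table.energy_keV[-1]
    if clamp:
        e = np.clip(e, lo, hi)
    elif np.any(e < lo) or np.any(e > hi):
        raise MaterialError(
            f"{table.name}: energy outside tabulated range [{lo}, {hi}] keV"
        )
    out = np.exp(
        np.interp(np.log(e), np.log(table.energy_keV), np.log(table.mass_attenuation))
    )
    return out


def interp_mass_attenuation(table: MaterialTable, energy_keV) -> np.ndarray:
    """Mass attenuation (cm^2/g) at arbitrary energies by log-log interpolation.

    Log-log linear interpolation is the standard scheme for attenuation
    tables: between grid nodes the curve is a power law, and grid nodes are
    reproduced exactly.  Energies outside the tabulated range raise.
    """
    out = _loglog_interp(table, energy_keV, clamp=False)
    return out if np.ndim(energy_keV) else float(out)


@dataclass(frozen=True)
class MaterialModel:
    """Reference-energy material model for a K-material object.

    Materials are stored sorted by ascending linear attenuation at ``e0``, so
    label ``k`` (0-based) is the (k+1)-th least attenuating material and the
    K-1 ``thresholds`` interleave the sorted ``mu_at_e0`` values.
    ``mu_hat`` is the K x N matrix of E0-normalised mass attenuation curves
    sampled on ``energies`` (a spectrum's grid): ``mu_hat[k] == 1`` at E0.
    """

    e0: float
    names: tuple
    mu_at_e0: np.ndarray        # (K,) cm^-1, ascending
    thresholds: np.ndarray      # (K-1,) cm^-1, strictly increasing
    energies: np.ndarray        # (N,) keV
    mu_hat: np.ndarray          # (K, N) dimensionless

    def __post_init__(self):
        mu = np.asarray(self.mu_at_e0, float)
        th = np.asarray(self.thresholds, float)
        if mu.size < 1:
            raise MaterialError("need at least one material")
        if np.any(np.diff(mu) <= 0):
            raise MaterialError("mu_at_e0 must be strictly increasing")
        if th.size != mu.size - 1 or (th.size and np.any(np.diff(th) <= 0)):
            raise MaterialError("need K-1 strictly increasing thresholds")
        if th.size and not (np.all(th > mu[:-1]) and np.all(th < mu[1:])):
            raise MaterialError("thresholds must interleave sorted mu_at_e0")
        object.__setattr__(self, "mu_at_e0", mu)
        object.__setattr__(self, "thresholds", th)
        object.__setattr__(self, "energies", np.asarray(self.energies, float))
        object.__setattr__(self, "mu_hat", np.asarray(self.mu_hat, float))

    @property
    def n_materials(self) -> int:
        return self.mu_at_e0.size

    def label_of(self, name: str) -> int:
        return self.names.index(name)


def build_material_model(
    tables,
    e0: float,
    spectrum_grid,
    mu_at_e0=None,
    thresholds=None,
) -> MaterialModel:
    """Build a :class:`MaterialModel` from attenuation tables.

    Parameters
    ----------
    tables : sequence of MaterialTable
        One table per material in the object.
    e0 : float
        Reference energy (keV).  The materials' linear attenuations at e0
        must be pairwise distinct, otherwise classification by value is
        impossible and a :class:`MaterialError` is raised.
    spectrum_grid : ndarray
        Energies (keV) on which to sample the normalised curves, normally a
        spectrum's grid.  Points outside a table's range are evaluated at the
        nearest table endpoint; in practice those bins carry zero spectral
        weight after filtration.
    mu_at_e0 : mapping, optional
        Override ``name -> mu(E0) [cm^-1]``; e.g. to pin ground-truth values
        while keeping tabulated curve *shapes*.  Defaults to
        mass attenuation at e0 times nominal density.
    thresholds : array-like, optional
        K-1 increasing classification cut values in cm^-1.  Defaults to
        midpoints between consecutive sorted mu(E0) values.
    """
    tables = list(tables)
    grid = np.asarray(spectrum_grid, dtype=float)
    mu0 = []
    for t in tables:
        if mu_at_e0 is not None and t.name in mu_at_e0:
            mu0.append(float(mu_at_e0[t.name]))
        else:
            mu0.append(float(interp_mass_attenuation(t, e0)) * t.density)
    mu0 = np.asarray(mu0)
    if np.unique(mu0).size != mu0.size:
        raise MaterialError(f"materials indistinguishable at E0={e0} keV (equal mu)")
    order = np.argsort(mu0)
    mu0 = mu0[order]
    tables = [tables[i] for i in order]
    # normalised curve: shape from the table, anchored to 1 at e0
    mu_hat = np.empty((len(tables), grid.size))
    for k, t in enumerate(tables):
        at_e0 = float(interp_mass_attenuation(t, e0))
        mu_hat[k] = _loglog_interp(t, grid, clamp=True) / at_e0
    if thresholds is None:
        thresholds = 0.5 * (mu0[:-1] + mu0[1:])
    return MaterialModel(
        e0=float(e0),
        names=tuple(t.name for t in tables),
        mu_at_e0=mu0,
        thresholds=np.asarray(thresholds, dtype=float),
        energies=grid,
        mu_hat=mu_hat,
    )


def classify(model: MaterialModel, mu_value) -> np.ndarray:
    """Map mu(E0) value(s) to material label(s) by thresholding.

    Values below the lowest threshold — including zero and negatives — take
    the label of the least attenuating material, so unoccupied background
    classifies as label 0.  Total on finite inputs.
    """
    labels = np.searchsorted(model.thresholds, np.asarray(mu_value, float), side="left")
    return labels if np.ndim(mu_value) else int(labels)


def synthesize_mu(model: MaterialModel, labels, mu0, e_index: int) -> np.ndarray:
    """Image of mu(E_n, x) = muhat_{label(x)}(E_n) * mu(E0, x) at grid index n."""
    labels = np.asarray(labels)
    mu0 = np.asarray(mu0, float)
    if labels.shape != mu0.shape:
        raise MaterialError("labels and mu0 must have the same shape")
    if labels.min() < 0 or labels.max() >= model.n_materials:
        raise MaterialError("label outside the model's label set")
    return model.mu_hat[labels, e_index] * mu0
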