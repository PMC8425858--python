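"""Photon interaction coefficients for the transport engine.

Per-material tables of mass attenuation components (photoelectric, incoherent,
coherent) and mass energy-absorption, bundled as CSV fixtures spanning
10-350 keV and queried by log-log interpolation (exact at grid nodes).  The
tables are produced by ``scripts/generate_xs_tables.py`` (see its docstring
for the underlying model and provenance).
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import NamedTuple

import numpy as np
import pandas as pd

from .source import Material, load_material

__all__ = ["MuCoefficients", "CrossSectionTable", "load_xs"]


class MuCoefficients(NamedTuple):
    """Mass coefficients in cm^2/g at one energy (or arrays of energies)."""

    pe: np.ndarray
    incoh: np.ndarray
    coh: np.ndarray
    total: np.ndarray
    en: np.ndarray


@dataclass
class CrossSectionTable:
    material: Material
    energy_kev: np.ndarray
    mu_pe: np.ndarray
    mu_incoh: np.ndarray
    mu_coh: np.ndarray
    mu_total: np.ndarray
    mu_en: np.ndarray

    def __post_init__(self):
        e = self.energy_kev
        if not (np.all(np.diff(e) > 0)):
            raise ValueError("energy grid must be strictly increasing")
        if e[0] > 10.0 or e[-1] < 310.0:
            raise ValueError("energy grid must span [10, 310] keV")
        if np.any(self.mu_en > self.mu_total + 1e-12) or np.any(self.mu_en < 0):
            raise ValueError("require mu_total >= mu_en >= 0 at all energies")
        self._loge = np.log(e)
        self._logs = {k: np.log(np.clip(getattr(self, k), 1e-300, None))
                      for k in ("mu_pe", "mu_incoh", "mu_coh", "mu_total", "mu_en")}

    def _interp(self, key: str, energy_kev) -> np.ndarray:
        e = np.asarray(energy_kev, float)
        if np.any(e < self.energy_kev[0]) or np.any(e > self.energy_kev[-1]):
            raise ValueError(
                f"energy outside table span [{self.energy_kev[0]}, {self.energy_kev[-1]}] keV")
        return np.exp(np.interp(np.log(e), self._loge, self._logs[key]))

    def mu_lookup(self, energy_kev) -> MuCoefficients:
        """All mass coefficients at the given energy, log-log interpolated."""
        return MuCoefficients(*(self._interp(k, energy_kev) for k in
                                ("mu_pe", "mu_incoh", "mu_coh", "mu_total", "mu_en")))

    def mu_total_lookup(self, energy_kev) -> np.ndarray:
        return self._interp("mu_total", energy_kev)

    def mu_en_lookup(self, energy_kev) -> np.ndarray:
        return self._interp("mu_en", energy_kev)

    def linear_mu(self, energy_kev) -> np.ndarray:
        """Linear attenuation coefficient in cm^-1."""
        return self._interp("mu_total", energy_kev) * self.material.density_g_cm3

    @classmethod
    def from_csv(cls, path, material: Material) -> "CrossSectionTable":
        df = pd.read_csv(path, comment="#")
        return cls(material, df["energy_keV"].to_numpy(), df["mu_pe"].to_numpy(),
                   df["mu_incoh"].to_numpy(), df["mu_coh"].to_numpy(),
                   df["mu_total"].to_numpy(), df["mu_en"].to_numpy())


@lru_cache(maxsize=None)
def load_xs(name: str) -> CrossSectionTable:
    """Load the bundled table for a material name (water, air, titanium, ...)."""
    mat = load_material(name)
    path = resources.files("ybrachy") / "data" / f"xs_{name}.csv"
    with resources.as_file(path) as p:
        return CrossSectionTable.from_csv(p, mat)
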