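"""Physical description of the double-encapsulated Yb-169 HDR source.

The source is a ytterbia (Yb2O3) ceramic cylinder, laser-welded into a
titanium tube, itself welded into an SS 316L tube with a hemispherical distal
tip and an SS 304L drive cable on the proximal side.  This module holds the
emission spectrum (13 gamma lines between 49.77 and 307.74 keV), the material
compositions, and the geometric model, and provides spectrum statistics and
emission sampling for the transport engine.

Coordinate convention: the source center (center of the active core) is the
origin, the polar angle theta is measured from the distal-tip axis (+z), so
theta = 0 deg points through the hemispherical tip and theta = 180 deg toward
the cable.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PhotonLine",
    "PhotonSpectrum",
    "Material",
    "CapsuleLayer",
    "SourceGeometry",
    "load_material",
    "yb169_spectrum",
    "yb169_source",
]

log = logging.getLogger(__name__)

_DATA = resources.files("ybrachy") / "data"


@dataclass(frozen=True)
class PhotonLine:
    """One gamma line: energy in keV, intensity in photons per 100 decays."""

    energy_kev: float
    intensity_pct: float
    uncertainty_pct: float = 0.0

    def __post_init__(self):
        if self.intensity_pct <= 0:
            raise ValueError(f"line intensity must be positive, got {self.intensity_pct}")


class PhotonSpectrum:
    """Discrete photon emission spectrum with a low-energy cutoff delta.

    Lines below the cutoff (10 keV by default: such photons do not survive
    the double capsule and are excluded from kerma-strength tallies) are
    rejected at construction.  The total intensity may exceed 100% because a
    single decay emits several photons.
    """

    def __init__(self, lines: Sequence[PhotonLine], cutoff_energy_kev: float = 10.0):
        lines = list(lines)
        if not lines:
            raise ValueError("spectrum must contain at least one line")
        energies = [ln.energy_kev for ln in lines]
        if any(e <= cutoff_energy_kev for e in energies):
            raise ValueError(f"all line energies must exceed the {cutoff_energy_kev} keV cutoff")
        if any(b <= a for a, b in zip(energies, energies[1:])):
            raise ValueError("line energies must be strictly increasing")
        self.lines = tuple(lines)
        self.cutoff_energy_kev = float(cutoff_energy_kev)
        self._e = np.array(energies)
        self._i = np.array([ln.intensity_pct for ln in lines])

    @property
    def energies_kev(self) -> np.ndarray:
        return self._e.copy()

    @property
    def intensities_pct(self) -> np.ndarray:
        return self._i.copy()

    def total_intensity(self) -> float:
        """Summed line intensity in percent (photons per 100 decays)."""
        return float(self._i.sum())

    @property
    def i_gamma(self) -> float:
        """Photon yield per disintegration (total intensity / 100)."""
        return self.total_intensity() / 100.0

    def total_intensity_uncertainty(self) -> float:
        """Quadrature-combined absolute uncertainty of the total, percent."""
        u = np.array([ln.uncertainty_pct for ln in self.lines])
        return float(np.sqrt((u**2).sum()))

    def mean_energy(self) -> float:
        """Intensity-weighted mean photon energy in keV."""
        tot = self._i.sum()
        if tot <= 0:
            raise ValueError("zero total intensity")
        return float((self._e * self._i).sum() / tot)

    def sample(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        """Draw ``n`` emission energies with probability I_i / sum(I)."""
        p = self._i / self._i.sum()
        idx = rng.choice(len(self._e), size=n, p=p)
        return self._e[idx]

    # ---- I/O -------------------------------------------------------------
    @classmethod
    def from_csv(cls, path, cutoff_energy_kev: float = 10.0) -> "PhotonSpectrum":
        df = pd.read_csv(path, comment="#")
        expected = {"energy_keV", "intensity_pct", "uncertainty_pct"}
        if set(df.columns) != expected:
            raise ValueError(f"spectrum file must have columns {sorted(expected)}, got {list(df.columns)}")
        lines = [PhotonLine(r.energy_keV, r.intensity_pct, r.uncertainty_pct)
                 for r in df.itertuples()]
        return cls(lines, cutoff_energy_kev)

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "energy_keV": self._e,
            "intensity_pct": self._i,
            "uncertainty_pct": [ln.uncertainty_pct for ln in self.lines],
        }).to_csv(path, index=False)


#: atomic number and standard atomic weight of the elements appearing in the
#: source, phantom and tally materials
ELEMENT_Z_A = {
    "H": (1, 1.008), "C": (6, 12.011), "N": (7, 14.007), "O": (8, 15.999),
    "Ar": (18, 39.948), "Ti": (22, 47.867), "Cr": (24, 51.996),
    "Fe": (26, 55.845), "Ni": (28, 58.693), "Cu": (29, 63.546),
    "Mo": (42, 95.95), "Yb": (70, 173.045),
}


@dataclass(frozen=True)
class Material:
    """Homogeneous material: density and elemental mass fractions.

    Mass fractions are normalized on construction; the raw sum must already
    be within 0.005 of unity (published composition tables carry small
    rounding excesses, e.g. the SS 316L row sums to 100.05%).
    """

    name: str
    density_g_cm3: float
    composition: Mapping[str, float]

    def __post_init__(self):
        if self.density_g_cm3 <= 0:
            raise ValueError("density must be positive")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 0.005:
            raise ValueError(f"mass fractions of {self.name} sum to {total:.4f}, outside 1 +- 0.005")
        if abs(total - 1.0) > 1e-12:
            log.info("normalizing %s mass fractions (raw sum %.5f)", self.name, total)
        object.__setattr__(self, "composition",
                           {el: w / total for el, w in self.composition.items()})

    @property
    def effective_z(self) -> float:
        """Electron-fraction-weighted effective atomic number (exponent 2.94),
        used by the coherent-scattering angular model."""
        fe = np.array([w * ELEMENT_Z_A[el][0] / ELEMENT_Z_A[el][1]
                       for el, w in self.composition.items()])
        z = np.array([ELEMENT_Z_A[el][0] for el in self.composition])
        fe = fe / fe.sum()
        return float((fe @ z**2.94) ** (1.0 / 2.94))


def load_material(name: str) -> Material:
    """Load one of the bundled materials (yb2o3, titanium, ss316l, ss304l, water, air)."""
    data = json.loads((_DATA / "materials.json").read_text())
    if name not in data:
        raise KeyError(f"unknown material {name!r}; bundled: {sorted(data)}")
    d = data[name]
    return Material(d["name"], d["density_g_cm3"], d["composition"])


@dataclass(frozen=True)
class CapsuleLayer:
    material: str
    radial_thickness_cm: float
    endcap_thickness_cm: float


@dataclass(frozen=True)
class SourceGeometry:
    """Cylindrical double-capsule source model, all dimensions in cm.

    ``layers`` are listed inside-out.  The distal tip is a hemisphere of the
    outermost layer material with radius equal to the external radius; the
    drive cable is a solid cylinder extending from the proximal end.
    """

    active_length_cm: float = 0.26
    active_diameter_cm: float = 0.048
    external_diameter_cm: float = 0.090
    total_length_cm: float = 0.473
    cable_diameter_cm: float = 0.090
    cable_length_cm: float = 2.0
    core_material: str = "yb2o3"
    cable_material: str = "ss304l"
    layers: tuple = (
        CapsuleLayer("titanium", 0.006, 0.006),
        CapsuleLayer("ss316l", 0.015, 0.015),
    )
    name: str = "yb169-hdr-double-capsule-prototype"

    def __post_init__(self):
        dims = (self.active_length_cm, self.active_diameter_cm, self.external_diameter_cm,
                self.total_length_cm, self.cable_diameter_cm)
        if any(d <= 0 for d in dims):
            raise ValueError("all source dimensions must be positive")
        walls = 2.0 * sum(l.radial_thickness_cm for l in self.layers)
        if self.external_diameter_cm < self.active_diameter_cm + walls - 1e-12:
            raise ValueError(
                f"external diameter {self.external_diameter_cm} cm cannot hold a "
                f"{self.active_diameter_cm} cm core plus {walls} cm of walls")

    @property
    def core_radius_cm(self) -> float:
        return self.active_diameter_cm / 2.0

    @property
    def external_radius_cm(self) -> float:
        return self.external_diameter_cm / 2.0

    @property
    def half_length_cm(self) -> float:
        return self.active_length_cm / 2.0

    def layer_outer_radii_cm(self) -> np.ndarray:
        """Outer radius of the core and of each capsule layer, inside-out."""
        r = [self.core_radius_cm]
        for l in self.layers:
            r.append(r[-1] + l.radial_thickness_cm)
        return np.array(r)

    def layer_cap_z_cm(self) -> np.ndarray:
        """Axial extent (+z) of the core and of each layer end cap."""
        z = [self.half_length_cm]
        for l in self.layers:
            z.append(z[-1] + l.endcap_thickness_cm)
        return np.array(z)

    def sample_emission_point(self, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        """Points uniform in the active core cylinder; shape (n, 3), cm."""
        u = rng.random(n)
        r = self.core_radius_cm * np.sqrt(u)
        phi = rng.random(n) * 2 * np.pi
        z = (rng.random(n) - 0.5) * self.active_length_cm
        return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])

    # ---- I/O -------------------------------------------------------------
    @classmethod
    def from_json(cls, path) -> "SourceGeometry":
        d = json.loads(Path(path).read_text()) if not hasattr(path, "read_text") \
            else json.loads(path.read_text())
        layers = tuple(CapsuleLayer(l["material"], l["radial_thickness_cm"],
                                    l["endcap_thickness_cm"]) for l in d["layers"])
        return cls(
            active_length_cm=d["active_length_cm"],
            active_diameter_cm=d["active_diameter_cm"],
            external_diameter_cm=d["external_diameter_cm"],
            total_length_cm=d["total_length_cm"],
            cable_diameter_cm=d["cable_diameter_cm"],
            cable_length_cm=d.get("cable_length_cm", 2.0),
            core_material=d.get("core_material", "yb2o3"),
            cable_material=d.get("cable_material", "ss304l"),
            layers=layers,
            name=d.get("name", "custom"),
        )

    def to_json(self, path) -> None:
        d = {
            "name": self.name,
            "active_length_cm": self.active_length_cm,
            "active_diameter_cm": self.active_diameter_cm,
            "external_diameter_cm": self.external_diameter_cm,
            "total_length_cm": self.total_length_cm,
            "cable_diameter_cm": self.cable_diameter_cm,
            "cable_length_cm": self.cable_length_cm,
            "core_material": self.core_material,
            "cable_material": self.cable_material,
            "layers": [{"material": l.material,
                        "radial_thickness_cm": l.radial_thickness_cm,
                        "endcap_thickness_cm": l.endcap_thickness_cm} for l in self.layers],
        }
        Path(path).write_text(json.dumps(d, indent=2))

    def with_(self, **kw) -> "SourceGeometry":
        return replace(self, **kw)


def yb169_spectrum(cutoff_energy_kev: float = 10.0) -> PhotonSpectrum:
    """The bundled Yb-169 line spectrum (49.77-307.74 keV, 13 lines)."""
    with resources.as_file(_DATA / "yb169_spectrum.csv") as p:
        return PhotonSpectrum.from_csv(p, cutoff_energy_kev)


def yb169_source() -> SourceGeometry:
    """The bundled geometry of the double-encapsulated prototype."""
    return SourceGeometry.from_json(_DATA / "source_model.json")
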