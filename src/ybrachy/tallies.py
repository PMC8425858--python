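"""Tally containers exchanged between the transport engine and the TG-43
parameter extraction: the spherical (r, theta) scoring mesh, dose-rate tables
and the air-kerma shell tallies.

Serialization is plain CSV with ``#``-prefixed header lines carrying the unit
tag and the mesh edges; round trips are lossless at 9 significant digits.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["TallyMesh", "DoseRateTable", "AirKermaTally", "table_radii_mesh"]

#: unit tags a DoseRateTable may carry
RAW = "raw"              # MeV g^-1 per emitted photon
CONVERTED = "converted"  # cGy mCi^-1 h^-1


@dataclass(frozen=True)
class TallyMesh:
    """Spherical scoring mesh: shells in r crossed with cones in theta.

    Edges must be strictly increasing; angles are degrees from the distal-tip
    axis and must stay within [0, 180].  The voxel "position" reported to the
    TG-43 formalism is the (r, theta) bin center.
    """

    r_edges_cm: np.ndarray
    theta_edges_deg: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.r_edges_cm, float)
        t = np.asarray(self.theta_edges_deg, float)
        if r.ndim != 1 or t.ndim != 1 or len(r) < 2 or len(t) < 2:
            raise ValueError("mesh needs at least one radial and one angular bin")
        if np.any(np.diff(r) <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("mesh edges must be strictly increasing")
        if r[0] < 0 or t[0] < 0 or t[-1] > 180:
            raise ValueError("require r >= 0 and theta within [0, 180] deg")
        object.__setattr__(self, "r_edges_cm", r)
        object.__setattr__(self, "theta_edges_deg", t)

    @property
    def r_centers_cm(self) -> np.ndarray:
        return 0.5 * (self.r_edges_cm[:-1] + self.r_edges_cm[1:])

    @property
    def theta_centers_deg(self) -> np.ndarray:
        return 0.5 * (self.theta_edges_deg[:-1] + self.theta_edges_deg[1:])

    @property
    def shape(self):
        return (len(self.r_edges_cm) - 1, len(self.theta_edges_deg) - 1)

    def voxel_volumes_cm3(self) -> np.ndarray:
        """Volume of each shell-cone intersection, shape (n_r, n_theta)."""
        r3 = np.diff(self.r_edges_cm**3)
        mu = np.cos(np.radians(self.theta_edges_deg))
        dmu = mu[:-1] - mu[1:]          # cos is decreasing in theta
        return (2.0 * np.pi / 3.0) * r3[:, None] * dmu[None, :]

    def index_of(self, r_cm: float, theta_deg: float, tol: float = 1e-9):
        """Indices of the voxel whose *center* matches (r, theta), or None."""
        ir = np.where(np.abs(self.r_centers_cm - r_cm) <= tol + 1e-6)[0]
        it = np.where(np.abs(self.theta_centers_deg - theta_deg) <= tol + 1e-6)[0]
        if len(ir) == 0 or len(it) == 0:
            return None
        return int(ir[0]), int(it[0])


def table_radii_mesh(radii_cm=None, half_width_cm: float = 0.1,
                     theta_step_deg: float = 10.0) -> TallyMesh:
    """Mesh whose radial bin centers sit exactly on a requested radius list.

    Each requested radius r becomes a bin [r - w, r + w]; the gaps between
    them are kept as ordinary (byproduct) bins so the edge list stays
    contiguous.  The angular edges are laid out so bin centers hit
    10, 20, ..., 170 and exactly 90 deg, with narrow end bins near the poles.
    """
    if radii_cm is None:
        radii_cm = [0.5 + 0.5 * i for i in range(20)]   # 0.5 ... 10.0
    edges = []
    for r in radii_cm:
        lo, hi = r - half_width_cm, r + half_width_cm
        if lo <= 0:
            raise ValueError("radial bin extends below zero")
        if edges and lo < edges[-1] - 1e-12:
            raise ValueError("requested radii closer than twice the half width")
        if edges and abs(lo - edges[-1]) < 1e-12:
            edges.append(hi)
        else:
            edges.extend([lo, hi])
    half = theta_step_deg / 2.0
    t_edges = [0.0] + list(np.arange(half, 180.0 - half + 1e-9, theta_step_deg)) + [180.0]
    return TallyMesh(np.array(edges), np.array(t_edges))


@dataclass
class DoseRateTable:
    """Per-voxel tally values with relative statistical errors.

    ``unit`` is 'raw' (MeV/g per emitted photon) straight from the transport
    engine, or 'converted' (cGy/mCi/h) after multiplying by the activity
    conversion and photon yield.  Voxels inside the source or cable are
    flagged invalid and carry NaN.
    """

    mesh: TallyMesh
    values: np.ndarray
    rel_err: np.ndarray
    valid: np.ndarray
    unit: str = RAW
    n_histories: int = 0
    seed: Optional[int] = None

    def __post_init__(self):
        shape = self.mesh.shape
        for arr_name in ("values", "rel_err", "valid"):
            a = np.asarray(getattr(self, arr_name))
            if a.shape != shape:
                raise ValueError(f"{arr_name} shape {a.shape} != mesh shape {shape}")
        if self.unit not in (RAW, CONVERTED):
            raise ValueError(f"unit must be '{RAW}' or '{CONVERTED}'")
        v = np.asarray(self.values, float)
        if np.any(v[np.asarray(self.valid, bool)] < 0):
            raise ValueError("tally values must be non-negative")
        self.values = v
        self.rel_err = np.asarray(self.rel_err, float)
        self.valid = np.asarray(self.valid, bool)

    def value_at(self, r_cm: float, theta_deg: float) -> float:
        idx = self.mesh.index_of(r_cm, theta_deg)
        if idx is None or not self.valid[idx]:
            raise KeyError(f"no valid voxel centered at (r={r_cm} cm, theta={theta_deg} deg)")
        return float(self.values[idx])

    def rel_err_at(self, r_cm: float, theta_deg: float) -> float:
        idx = self.mesh.index_of(r_cm, theta_deg)
        if idx is None:
            raise KeyError(f"no voxel centered at (r={r_cm} cm, theta={theta_deg} deg)")
        return float(self.rel_err[idx])

    # ---- serialization ---------------------------------------------------
    def to_csv(self, path) -> None:
        rr, tt = np.meshgrid(self.mesh.r_centers_cm, self.mesh.theta_centers_deg,
                             indexing="ij")
        lines = [f"# unit={self.unit}",
                 f"# n_histories={self.n_histories} seed={self.seed}",
                 "# r_edges_cm=" + ",".join(f"{v:.9g}" for v in self.mesh.r_edges_cm),
                 "# theta_edges_deg=" + ",".join(f"{v:.9g}" for v in self.mesh.theta_edges_deg),
                 "r_cm,theta_deg,value,rel_err,valid"]
        for i in range(rr.shape[0]):
            for j in range(rr.shape[1]):
                lines.append(f"{rr[i, j]:.9g},{tt[i, j]:.9g},{self.values[i, j]:.9g},"
                             f"{self.rel_err[i, j]:.9g},{int(self.valid[i, j])}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path) -> "DoseRateTable":
        path = Path(path)
        header = {}
        with path.open() as fh:
            for line in fh:
                if not line.startswith("#"):
                    cols = line.strip().split(",")
                    break
                for part in line[1:].strip().split():
                    k, _, v = part.partition("=")
                    header[k] = v
        expected = ["r_cm", "theta_deg", "value", "rel_err", "valid"]
        if cols != expected:
            raise ValueError(f"malformed dose-table header: expected columns {expected}, got {cols}")
        if "unit" not in header:
            raise ValueError("malformed dose-table header: missing '# unit=' line")
        mesh = TallyMesh(np.array([float(x) for x in header["r_edges_cm"].split(",")]),
                         np.array([float(x) for x in header["theta_edges_deg"].split(",")]))
        df = pd.read_csv(path, comment="#")
        shape = mesh.shape
        seed = header.get("seed")
        return cls(mesh,
                   df["value"].to_numpy().reshape(shape),
                   df["rel_err"].to_numpy().reshape(shape),
                   df["valid"].to_numpy().astype(bool).reshape(shape),
                   unit=header["unit"],
                   n_histories=int(header.get("n_histories", 0) or 0),
                   seed=None if seed in (None, "None", "") else int(seed))


@dataclass
class AirKermaTally:
    """Shell-averaged air kerma per emitted photon at 50-150 cm.

    Each record is a spherical shell [d - hw, d + hw] intersected with the
    transverse cone band (88-92 deg by default), kerma in MeV/g per emitted
    photon plus its relative statistical error.
    """

    distances_cm: np.ndarray
    values: np.ndarray
    rel_err: np.ndarray
    shell_half_width_cm: float = 2.5
    cone_deg: tuple = (88.0, 92.0)
    n_histories: int = 0
    seed: Optional[int] = None

    def __post_init__(self):
        d = np.asarray(self.distances_cm, float)
        if len(d) == 0:
            raise ValueError("air-kerma tally needs at least one distance")
        if np.any(np.asarray(self.rel_err, float) < 0):
            raise ValueError("relative errors must be non-negative")
        self.distances_cm = d
        self.values = np.asarray(self.values, float)
        self.rel_err = np.asarray(self.rel_err, float)

    def to_csv(self, path) -> None:
        lines = ["# unit=MeV_per_g_per_photon",
                 f"# shell_half_width_cm={self.shell_half_width_cm:.9g}",
                 f"# cone_deg={self.cone_deg[0]:.9g},{self.cone_deg[1]:.9g}",
                 f"# n_histories={self.n_histories} seed={self.seed}",
                 "d_cm,value,rel_err"]
        for d, v, e in zip(self.distances_cm, self.values, self.rel_err):
            lines.append(f"{d:.9g},{v:.9g},{e:.9g}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path) -> "AirKermaTally":
        path = Path(path)
        header = {}
        with path.open() as fh:
            for line in fh:
                if not line.startswith("#"):
                    cols = line.strip().split(",")
                    break
                if "=" in line:
                    for part in line[1:].strip().split():
                        k, _, v = part.partition("=")
                        header[k] = v
        if cols != ["d_cm", "value", "rel_err"]:
            raise ValueError(f"malformed air-kerma header: got columns {cols}")
        df = pd.read_csv(path, comment="#")
        cone = tuple(float(x) for x in header.get("cone_deg", "88,92").split(","))
        seed = header.get("seed")
        return cls(df["d_cm"].to_numpy(), df["value"].to_numpy(), df["rel_err"].to_numpy(),
                   shell_half_width_cm=float(header.get("shell_half_width_cm", 2.5)),
                   cone_deg=cone,
                   n_histories=int(header.get("n_histories", 0) or 0),
                   seed=None if seed in (None, "None", "") else int(seed))
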