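"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator inverts the corresponding analysis: dose-rate tables are built
from a chosen (S_k*, Lambda*, g*, F*) through the TG-43 equation with
controlled per-voxel Gaussian noise; air-kerma tallies from S_k* through the
shell-average inverse-square factor; film scans from a dose map through the
inverse of the calibration curve with pixel noise.  Extraction on noise-free
output recovers the ground truth to machine precision, which is the
back-to-back identity the test suite leans on.

The default ground truth mirrors the published characterization of the
double-encapsulated Yb-169 HDR source (Lambda* = 1.21 cGy/(h U),
S_k* = 1.03 U/mCi, g* the fifth-order polynomial fitted to the published
radial dose values, F* bilinear in the published anisotropy table), so
synthetic tables look like the real thing.  The default noise model grows
with radius like sqrt(r), mimicking the loss of tally statistics with
distance from the source.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .film import CalibrationCurve, FilmScan
from .source import SourceGeometry, yb169_source
from .tallies import AirKermaTally, DoseRateTable, TallyMesh, CONVERTED, table_radii_mesh
from .tg43 import KERMA_TO_DOSE_RATE, geometry_function_line, fit_radial_polynomial
from .uncertainty import shell_average_inverse_square

__all__ = ["GroundTruth", "default_ground_truth", "cable_shadow",
           "generate_dose_table", "generate_air_kerma", "generate_film_scan",
           "tg43_plane_dose_map", "reference_g_table", "reference_f_table"]

_DATA = resources.files("ybrachy") / "data"


def reference_g_table() -> pd.DataFrame:
    """Published radial dose function values (this source and literature models)."""
    with resources.as_file(_DATA / "reference_g.csv") as p:
        return pd.read_csv(p, comment="#")


def reference_f_table() -> pd.DataFrame:
    """Published 2-D anisotropy values; NaN marks cable-shadowed cells."""
    with resources.as_file(_DATA / "reference_F.csv") as p:
        return pd.read_csv(p, comment="#")


def cable_shadow(r_cm, theta_deg) -> np.ndarray:
    """Default invalid-voxel rule behind the drive cable: theta > 174 deg at
    r <= 0.5 cm, theta > 176 deg at r <= 1 cm, theta > 178 deg at r <= 2 cm."""
    r = np.asarray(r_cm, float)
    th = np.asarray(theta_deg, float)
    return ((r <= 0.5) & (th > 174.0)) | ((r <= 1.0) & (th > 176.0)) \
        | ((r <= 2.0) & (th > 178.0))


def _f_interpolator() -> Callable:
    df = reference_f_table()
    radii = np.array([float(c[1:]) for c in df.columns[1:]])
    grid = df.iloc[:, 1:].to_numpy()
    # fill shadowed cells with the nearest valid value in theta so the
    # interpolant is defined everywhere (those voxels are invalid anyway)
    for j in range(grid.shape[1]):
        col = grid[:, j]
        bad = np.isnan(col)
        if bad.any():
            col[bad] = col[~bad][-1]
    interp = RegularGridInterpolator((df["theta_deg"].to_numpy(), radii), grid,
                                     method="linear", bounds_error=False, fill_value=None)

    def f_star(r, theta_deg):
        r = np.clip(np.asarray(r, float), radii[0], radii[-1])
        pts = np.column_stack([np.ravel(np.asarray(theta_deg, float)), np.ravel(r)])
        return interp(pts).reshape(np.shape(theta_deg))

    return f_star


@dataclass
class GroundTruth:
    """Known-truth dosimetric parameter set driving the generators."""

    lambda_star: float = 1.21          # cGy / (h U)
    sk_star: float = 1.03              # U per mCi
    g_coeffs: np.ndarray = None        # a0..a5, ascending
    f_star: Callable = None            # (r_cm, theta_deg) -> F
    sigma_of_r: Callable = None        # relative tally noise per voxel
    shadow: Callable = cable_shadow
    active_length_cm: float = 0.26
    i_gamma: float = 3.322

    def __post_init__(self):
        if self.g_coeffs is None:
            ref = reference_g_table()
            self.g_coeffs = fit_radial_polynomial(ref.r_cm, ref.this_work).coeffs
        self.g_coeffs = np.asarray(self.g_coeffs, float)
        # pin g*(1 cm) = 1 exactly
        g1 = np.polynomial.polynomial.polyval(1.0, self.g_coeffs)
        self.g_coeffs = self.g_coeffs / g1
        if self.f_star is None:
            self.f_star = _f_interpolator()
        if self.sigma_of_r is None:
            self.sigma_of_r = lambda r: 0.002 * np.sqrt(np.asarray(r, float))

    def g_star(self, r):
        return np.polynomial.polynomial.polyval(np.asarray(r, float), self.g_coeffs)

    def dose_rate(self, r, theta_deg):
        """Noise-free TG-43 dose rate in cGy/(mCi h) at (r, theta)."""
        gl = geometry_function_line(r, theta_deg, self.active_length_cm)
        gl0 = geometry_function_line(1.0, 90.0, self.active_length_cm)
        return (self.sk_star * self.lambda_star * gl / gl0
                * self.g_star(r) * self.f_star(r, theta_deg))


def default_ground_truth(**kw) -> GroundTruth:
    return GroundTruth(**kw)


def generate_dose_table(truth: GroundTruth, mesh: Optional[TallyMesh] = None,
                        seed: int = 0, noise: Optional[float] = None) -> DoseRateTable:
    """Synthetic converted dose-rate table on the mesh, with Gaussian relative
    noise (``noise`` overrides the truth's sigma(r) with a constant)."""
    if mesh is None:
        mesh = table_radii_mesh()
    rng = np.random.default_rng(seed)
    rr, tt = np.meshgrid(mesh.r_centers_cm, mesh.theta_centers_deg, indexing="ij")
    clean = truth.dose_rate(rr, tt)
    sig = np.full_like(rr, noise) if noise is not None else \
        np.broadcast_to(truth.sigma_of_r(rr), rr.shape).copy()
    values = clean * (1.0 + sig * rng.standard_normal(rr.shape))
    valid = ~truth.shadow(rr, tt)
    return DoseRateTable(mesh, np.where(valid, np.clip(values, 0.0, None), np.nan),
                         sig, valid, unit=CONVERTED, n_histories=0, seed=seed)


def generate_air_kerma(truth: GroundTruth,
                       distances_cm: Sequence[float] = tuple(range(50, 151, 10)),
                       seed: int = 0, noise: float = 0.0,
                       shell_half_width_cm: float = 2.5) -> AirKermaTally:
    """Synthetic shell tally whose extraction recovers S_k* exactly when
    noise-free: K(d) = S_k* <1/r^2>_shell / (conversion * I_gamma)."""
    rng = np.random.default_rng(seed)
    d = np.asarray(sorted(distances_cm), float)
    avg = np.array([shell_average_inverse_square(dd - shell_half_width_cm,
                                                 dd + shell_half_width_cm) for dd in d])
    clean = truth.sk_star * avg / (KERMA_TO_DOSE_RATE * truth.i_gamma)
    values = clean * (1.0 + noise * rng.standard_normal(len(d)))
    return AirKermaTally(d, values, np.full(len(d), noise),
                         shell_half_width_cm=shell_half_width_cm, seed=seed)


def tg43_plane_dose_map(truth: GroundTruth, extent_cm: float = 3.0,
                        dpi: float = 300.0, dwell_scale: float = 1.0,
                        r_min_cm: float = 0.15) -> np.ndarray:
    """Noise-free dose image (Gy) in a plane through the source axis.

    ``dwell_scale`` converts the TG-43 rate into an absorbed dose for a
    notional dwell (units Gy per cGy/(mCi h), i.e. exposure time times
    activity over 100); pixels inside ``r_min_cm`` are clipped to the dose at
    r_min to avoid the singularity at the source.
    """
    pitch = 2.54 / dpi
    n = int(round(2 * extent_cm / pitch)) + 1
    c = (n - 1) / 2.0
    idx = np.arange(n)
    x = (idx - c) * pitch
    z = (c - idx[:, None]) * pitch
    rr = np.hypot(x[None, :], z)
    th = np.degrees(np.arctan2(np.abs(x[None, :]) + 0 * z, z))
    rr_c = np.clip(rr, r_min_cm, None)
    th_c = np.where(np.abs(np.sin(np.radians(th))) * rr_c < 1e-6, 90.0, th)
    dose = truth.dose_rate(rr_c, th_c) * dwell_scale
    return dose


def generate_film_scan(dose_map_gy: np.ndarray, curve: CalibrationCurve,
                       dpi: float = 300.0, pv_before: float = 40000.0,
                       pv_bckg: float = 2000.0, pixel_noise: float = 0.01,
                       seed: int = 0) -> tuple:
    """Synthetic before/after scan pair consistent with the netOD model.

    PV_after = PV_bckg + (PV_before - PV_bckg) 10^(-netOD(D)) where netOD(D)
    is the numerical inverse of the calibration curve; independent Gaussian
    pixel noise (relative, ``pixel_noise``) is added to both scans.  The red
    channel carries the dose signal; green and blue get reduced responses.
    """
    rng = np.random.default_rng(seed)
    dose = np.asarray(dose_map_gy, float)
    nod = curve.inverse(np.clip(dose, 0.0, None))
    span = pv_before - pv_bckg

    def make(scale_od):
        after = pv_bckg + span * 10.0 ** (-nod * scale_od)
        before = np.full_like(after, pv_before)
        a = after * (1.0 + pixel_noise * rng.standard_normal(after.shape))
        b = before * (1.0 + pixel_noise * rng.standard_normal(before.shape))
        return a, b

    a_r, b_r = make(1.0)
    a_g, b_g = make(0.4)
    a_b, b_b = make(0.15)
    to_u16 = lambda arr: np.clip(arr, 0, 65535).astype(np.uint16)
    before_px = np.stack([to_u16(b_r), to_u16(b_g), to_u16(b_b)], axis=-1)
    after_px = np.stack([to_u16(a_r), to_u16(a_g), to_u16(a_b)], axis=-1)
    return (FilmScan(before_px, dpi=dpi), FilmScan(after_px, dpi=dpi))
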