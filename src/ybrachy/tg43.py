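"""TG-43 parameter extraction and dose-rate reconstruction.

The brachytherapy dose-rate formalism factorizes the dose rate around a
sealed source as

    D(r, theta) = S_k * Lambda * [G_L(r,theta) / G_L(r0,theta0)] * g_L(r) * F(r,theta)

with the reference point (r0, theta0) = (1 cm, 90 deg): S_k the air-kerma
strength (U = cGy cm^2 / h), Lambda the dose-rate constant (cGy / (h U)),
G_L the line-source geometry function, g_L the radial dose function and F
the 2-D anisotropy function.  This module extracts all of these from
dose-rate and air-kerma tables produced by the transport engine (or the
synthetic generator) and reconstructs dose rates from a parameter set.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from . import uncertainty as unc
from .tallies import AirKermaTally, DoseRateTable, CONVERTED, RAW

__all__ = [
    "KERMA_TO_DOSE_RATE",
    "geometry_function_line",
    "convert_kerma_to_dose_rate",
    "convert_dose_table",
    "air_kerma_strength",
    "SkEstimate",
    "dose_rate_constant",
    "radial_dose_function",
    "anisotropy_function",
    "fit_radial_polynomial",
    "PolynomialFit",
    "TG43ParameterSet",
    "extract_parameters",
    "reconstruct_dose_rate",
]

# ---------------------------------------------------------------------------
# activity / unit conversion
# ---------------------------------------------------------------------------
_MCI_TO_BQ = 3.7e7
_SECONDS_PER_HOUR = 3600.0
_MEV_PER_G_TO_CGY = 1.602176634e-13 / 1e-3 * 100.0   # J/MeV / (kg/g) * cGy/Gy

#: 1 MeV g^-1 Bq^-1 s^-1 expressed in cGy mCi^-1 h^-1 (= 2.134e3)
KERMA_TO_DOSE_RATE = _MCI_TO_BQ * _SECONDS_PER_HOUR * _MEV_PER_G_TO_CGY

assert abs(KERMA_TO_DOSE_RATE / 2.134e3 - 1.0) < 5e-4, KERMA_TO_DOSE_RATE

R0_CM = 1.0
THETA0_DEG = 90.0


def convert_kerma_to_dose_rate(k_mc, i_gamma: float):
    """Convert a raw tally (MeV/g per emitted photon) to cGy mCi^-1 h^-1.

    ``i_gamma`` is the photon yield per disintegration (3.322 for the
    bundled Yb-169 spectrum).
    """
    if i_gamma <= 0:
        raise ValueError("photon yield i_gamma must be positive")
    k = np.asarray(k_mc, float)
    if np.any(k[np.isfinite(k)] < 0):
        raise ValueError("tally values must be non-negative")
    out = KERMA_TO_DOSE_RATE * k * i_gamma
    return float(out) if np.ndim(out) == 0 else out


def convert_dose_table(table: DoseRateTable, i_gamma: float) -> DoseRateTable:
    """Return a converted copy of a raw dose-rate table."""
    if table.unit == CONVERTED:
        raise ValueError("table already converted; refusing to convert twice")
    vals = np.where(table.valid, table.values, np.nan)
    return DoseRateTable(table.mesh, KERMA_TO_DOSE_RATE * vals * i_gamma,
                         table.rel_err.copy(), table.valid.copy(), unit=CONVERTED,
                         n_histories=table.n_histories, seed=table.seed)


# ---------------------------------------------------------------------------
# geometry function
# ---------------------------------------------------------------------------
def geometry_function_line(r_cm, theta_deg, L_cm: float = 0.26):
    """Line-source geometry function G_L(r, theta) in cm^-2.

    beta, the angle the active line subtends at the field point, is computed
    as a sum of two arctangents (stable near the poles); on the long axis
    (sin theta below 1e-9) the closed-form limit 1/(r^2 - L^2/4) is used.
    Points on or inside the active line raise a domain error.
    """
    r = np.asarray(r_cm, float)
    th = np.radians(np.asarray(theta_deg, float))
    r, th = np.broadcast_arrays(r, th)
    if np.any(r <= 0):
        raise ValueError("require r > 0")
    half = L_cm / 2.0
    rho = r * np.sin(th)        # distance from the source axis
    z = r * np.cos(th)
    on_axis = np.abs(np.sin(th)) < 1e-9
    inside = (rho < 1e-12) & (np.abs(z) <= half + 1e-15)
    if np.any(inside):
        raise ValueError("field point lies on or inside the active line segment")
    beta = np.arctan2(half - z, rho) + np.arctan2(half + z, rho)
    with np.errstate(divide="ignore", invalid="ignore"):
        g = beta / (L_cm * rho)
        g_axis = 1.0 / (r * r - half * half)
    out = np.where(on_axis, g_axis, g)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# air-kerma strength and dose-rate constant
# ---------------------------------------------------------------------------
@dataclass
class SkEstimate:
    """Air-kerma strength in U (cGy cm^2/h) per mCi with its statistics."""

    value: float
    rel_stat_err: float
    per_distance: pd.DataFrame
    shell_correction: str = "line"

    def rel_uncertainty(self, sigma_cs=unc.SIGMA_CS_DEFAULT, sigma_igamma=0.0) -> float:
        return unc.sk_rel_uncertainty(self.rel_stat_err, sigma_cs, sigma_igamma)


def air_kerma_strength(tally: AirKermaTally, i_gamma: float,
                       shell_correction: str = "line") -> SkEstimate:
    """S_k = Kdot_delta(d) * d^2, averaged over the tally distances.

    Each shell-averaged kerma rate is referred back to its nominal distance
    before multiplying by d^2.  ``shell_correction`` selects the radial line
    average 1/(ab) of 1/r^2 (default), the volume average 3/(a^2+ab+b^2),
    or 'none' (plain 1/d^2).
    """
    d = tally.distances_cm
    hw = tally.shell_half_width_cm
    a, b = d - hw, d + hw
    if shell_correction == "line":
        avg = np.array([unc.shell_average_inverse_square(ai, bi) for ai, bi in zip(a, b)])
    elif shell_correction == "volume":
        avg = 3.0 / (a * a + a * b + b * b)
    elif shell_correction == "none":
        avg = 1.0 / d**2
    else:
        raise ValueError(f"unknown shell_correction {shell_correction!r}")
    kdot = convert_kerma_to_dose_rate(tally.values, i_gamma)   # cGy/mCi/h, shell avg
    sk_d = kdot / avg                                          # U per mCi
    n = len(d)
    mean = float(np.mean(sk_d))
    rel_stat = float(np.sqrt(np.sum(tally.rel_err**2)) / n)
    per = pd.DataFrame({"d_cm": d, "sk_u_per_mci": sk_d, "rel_err": tally.rel_err})
    return SkEstimate(mean, rel_stat, per, shell_correction)


def dose_rate_constant(d_ref: float, sk: float) -> float:
    """Lambda = D(r0, theta0) / S_k in cGy h^-1 U^-1."""
    if sk <= 0:
        raise ValueError("air-kerma strength must be positive")
    return d_ref / sk


# ---------------------------------------------------------------------------
# radial dose function and anisotropy function
# ---------------------------------------------------------------------------
def _reference_voxel(table: DoseRateTable):
    idx = table.mesh.index_of(R0_CM, THETA0_DEG)
    if idx is None or not table.valid[idx]:
        raise ValueError("dose table lacks a valid voxel centered at the "
                         "(1 cm, 90 deg) reference point")
    return idx


def radial_dose_function(table: DoseRateTable, L_cm: float = 0.26,
                         sigma_cs: float = unc.SIGMA_CS_DEFAULT,
                         radii_cm=None) -> pd.DataFrame:
    """g_L(r): transverse-axis dose fall-off with the geometry factor removed,
    normalized to 1 at r0 = 1 cm.  Returns columns r_cm, g, rel_err."""
    i0, j0 = _reference_voxel(table)
    d_ref = table.values[i0, j0]
    s_ref = table.rel_err[i0, j0]
    r_all = table.mesh.r_centers_cm
    if radii_cm is None:
        sel = np.arange(len(r_all))
    else:
        sel = []
        for r in radii_cm:
            k = np.where(np.abs(r_all - r) < 1e-6)[0]
            if len(k) == 0:
                raise ValueError(f"no radial bin centered at r={r} cm")
            sel.append(k[0])
        sel = np.array(sel)
    rows = []
    g0 = geometry_function_line(R0_CM, THETA0_DEG, L_cm)
    for i in sel:
        if not table.valid[i, j0]:
            continue
        r = r_all[i]
        g = (table.values[i, j0] / d_ref) * (g0 / geometry_function_line(r, THETA0_DEG, L_cm))
        at_ref = i == i0
        rel = unc.g_rel_uncertainty(table.rel_err[i, j0], s_ref, sigma_cs, at_reference=at_ref)
        rows.append((r, 1.0 if at_ref else g, rel))
    return pd.DataFrame(rows, columns=["r_cm", "g", "rel_err"])


def anisotropy_function(table: DoseRateTable, L_cm: float = 0.26,
                        sigma_cs: float = unc.SIGMA_CS_DEFAULT,
                        radii_cm=None) -> pd.DataFrame:
    """F(r, theta): angular dose variation at fixed radius relative to the
    transverse axis, geometry factor removed; F(r, 90 deg) = 1 exactly.
    Invalid voxels (cable/source shadow) yield NaN entries."""
    r_all = table.mesh.r_centers_cm
    t_all = table.mesh.theta_centers_deg
    j0s = np.where(np.abs(t_all - THETA0_DEG) < 1e-6)[0]
    if len(j0s) == 0:
        raise ValueError("mesh has no angular bin centered at 90 deg")
    j0 = int(j0s[0])
    if radii_cm is None:
        sel = np.arange(len(r_all))
    else:
        sel = []
        for r in radii_cm:
            k = np.where(np.abs(r_all - r) < 1e-6)[0]
            if len(k) == 0:
                raise ValueError(f"no radial bin centered at r={r} cm")
            sel.append(k[0])
        sel = np.array(sel)
    rows = []
    for i in sel:
        r = r_all[i]
        if not table.valid[i, j0]:
            raise ValueError(f"missing transverse-axis (90 deg) voxel at r={r} cm")
        d0 = table.values[i, j0]
        s0 = table.rel_err[i, j0]
        g_t0 = geometry_function_line(r, THETA0_DEG, L_cm)
        for j, th in enumerate(t_all):
            if not table.valid[i, j]:
                rows.append((r, th, np.nan, np.nan))
                continue
            at_ref = j == j0
            f = (table.values[i, j] / d0) * (g_t0 / geometry_function_line(r, th, L_cm))
            rel = unc.f_rel_uncertainty(table.rel_err[i, j], s0, sigma_cs, at_reference=at_ref)
            rows.append((r, th, 1.0 if at_ref else f, rel))
    return pd.DataFrame(rows, columns=["r_cm", "theta_deg", "F", "rel_err"])


# ---------------------------------------------------------------------------
# polynomial fit of g_L(r)
# ---------------------------------------------------------------------------
@dataclass
class PolynomialFit:
    coeffs: np.ndarray            # a0..a5, ascending powers
    max_rel_residual: float
    residual_ok: bool             # max relative residual within 2%

    def __call__(self, r):
        return np.polynomial.polynomial.polyval(np.asarray(r, float), self.coeffs)


def fit_radial_polynomial(r_cm, g, max_residual: float = 0.02) -> PolynomialFit:
    """Unweighted least-squares fifth-order polynomial g(r) = a0 + ... + a5 r^5,
    for treatment-planning interpolation; requires at least 7 radii."""
    r = np.asarray(r_cm, float)
    gv = np.asarray(g, float)
    if len(r) < 7:
        raise ValueError(f"need at least 7 radii to fit a fifth-order polynomial, got {len(r)}")
    coeffs = np.polynomial.polynomial.polyfit(r, gv, 5)
    resid = np.abs(np.polynomial.polynomial.polyval(r, coeffs) - gv) / np.abs(gv)
    mx = float(resid.max())
    return PolynomialFit(coeffs, mx, mx <= max_residual)


# ---------------------------------------------------------------------------
# the assembled parameter set
# ---------------------------------------------------------------------------
@dataclass
class TG43ParameterSet:
    sk_u_per_mci: float
    sk_rel_unc: float
    lambda_cgy_per_hu: float
    lambda_rel_unc: float
    g_table: pd.DataFrame                 # r_cm, g, rel_err
    poly: PolynomialFit
    f_table: pd.DataFrame                 # r_cm, theta_deg, F, rel_err (NaN = missing)
    active_length_cm: float = 0.26
    r0_cm: float = R0_CM
    theta0_deg: float = THETA0_DEG
    g_interpolation: str = "polynomial"   # or "linear"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.sk_u_per_mci <= 0 or self.lambda_cgy_per_hu <= 0:
            raise ValueError("S_k and Lambda must be positive")
        g0 = self.g_table.loc[np.isclose(self.g_table.r_cm, self.r0_cm), "g"]
        if len(g0) and not np.isclose(float(g0.iloc[0]), 1.0, atol=1e-12):
            raise ValueError("g(r0) must be exactly 1")
        f0 = self.f_table.loc[np.isclose(self.f_table.theta_deg, self.theta0_deg), "F"]
        if len(f0) and not np.allclose(f0.dropna(), 1.0, atol=1e-12):
            raise ValueError("F(r, theta0) must be exactly 1 for every r")

    # ---- evaluation ------------------------------------------------------
    def g_of_r(self, r):
        r = np.asarray(r, float)
        if self.g_interpolation == "polynomial":
            return self.poly(r)
        return np.interp(r, self.g_table.r_cm.to_numpy(), self.g_table.g.to_numpy())

    def f_of(self, r, theta_deg):
        piv = self.f_table.pivot(index="r_cm", columns="theta_deg", values="F")
        interp = RegularGridInterpolator(
            (piv.index.to_numpy(), piv.columns.to_numpy()), piv.to_numpy(),
            method="linear", bounds_error=True)
        pts = np.column_stack([np.ravel(np.asarray(r, float)),
                               np.ravel(np.asarray(theta_deg, float))])
        out = interp(pts)
        return float(out[0]) if out.size == 1 and np.ndim(r) == 0 else out.reshape(np.shape(r))

    # ---- serialization ---------------------------------------------------
    def to_dir(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        scalars = {
            "sk_u_per_mci": self.sk_u_per_mci,
            "sk_rel_unc": self.sk_rel_unc,
            "lambda_cgy_per_hu": self.lambda_cgy_per_hu,
            "lambda_rel_unc": self.lambda_rel_unc,
            "active_length_cm": self.active_length_cm,
            "reference_point": {"r_cm": self.r0_cm, "theta_deg": self.theta0_deg},
            "g_polynomial_a0_a5": list(self.poly.coeffs),
            "g_poly_max_rel_residual": self.poly.max_rel_residual,
            "g_interpolation": self.g_interpolation,
            "f_interpolation": "bilinear",
            "meta": self.meta,
        }
        (path / "parameters.json").write_text(json.dumps(scalars, indent=2))
        self.g_table.to_csv(path / "g_r.csv", index=False, float_format="%.9g")
        self.f_table.to_csv(path / "F_rtheta.csv", index=False, float_format="%.9g")

    @classmethod
    def from_dir(cls, path) -> "TG43ParameterSet":
        path = Path(path)
        s = json.loads((path / "parameters.json").read_text())
        g = pd.read_csv(path / "g_r.csv")
        f = pd.read_csv(path / "F_rtheta.csv")
        coeffs = np.array(s["g_polynomial_a0_a5"])
        resid = s["g_poly_max_rel_residual"]
        return cls(s["sk_u_per_mci"], s["sk_rel_unc"], s["lambda_cgy_per_hu"],
                   s["lambda_rel_unc"], g, PolynomialFit(coeffs, resid, resid <= 0.02),
                   f, s["active_length_cm"], s["reference_point"]["r_cm"],
                   s["reference_point"]["theta_deg"], s.get("g_interpolation", "polynomial"),
                   s.get("meta", {}))


def extract_parameters(dose_table: DoseRateTable, airkerma: AirKermaTally,
                       i_gamma: float, active_length_cm: float = 0.26,
                       sigma_cs: float = unc.SIGMA_CS_DEFAULT,
                       sigma_igamma: float = 0.015,
                       g_radii_cm=None, f_radii_cm=None,
                       shell_correction: str = "line") -> TG43ParameterSet:
    """Run the full extraction chain on a dose table plus air-kerma tally."""
    if dose_table.unit == RAW:
        dose_table = convert_dose_table(dose_table, i_gamma)
    sk = air_kerma_strength(airkerma, i_gamma, shell_correction)
    i0, j0 = _reference_voxel(dose_table)
    d_ref = dose_table.values[i0, j0]
    lam = dose_rate_constant(d_ref, sk.value)
    lam_rel = unc.lambda_rel_uncertainty(dose_table.rel_err[i0, j0], sk.rel_stat_err, sigma_cs)
    g = radial_dose_function(dose_table, active_length_cm, sigma_cs, g_radii_cm)
    f = anisotropy_function(dose_table, active_length_cm, sigma_cs, f_radii_cm)
    poly = fit_radial_polynomial(g.r_cm, g.g)
    return TG43ParameterSet(
        sk.value, sk.rel_uncertainty(sigma_cs, sigma_igamma), lam, lam_rel,
        g, poly, f, active_length_cm,
        meta={"d_ref_cgy_per_mci_h": d_ref, "i_gamma": i_gamma,
              "shell_correction": shell_correction,
              "n_histories": dose_table.n_histories, "seed": dose_table.seed})


def reconstruct_dose_rate(params: TG43ParameterSet, r_cm, theta_deg,
                          per: str = "U", allow_extrapolation: bool = False):
    """Dose rate from a parameter set at (r, theta).

    ``per='U'`` returns cGy/h per unit air-kerma strength; ``per='mCi'``
    multiplies by S_k to give cGy/h per mCi.  Requests outside the tabulated
    (r, theta) hull raise unless ``allow_extrapolation``.
    """
    r = np.asarray(r_cm, float)
    th = np.asarray(theta_deg, float)
    rmin, rmax = params.f_table.r_cm.min(), params.f_table.r_cm.max()
    tmin, tmax = params.f_table.theta_deg.min(), params.f_table.theta_deg.max()
    if not allow_extrapolation:
        if np.any(r < rmin) or np.any(r > rmax) or np.any(th < tmin) or np.any(th > tmax):
            raise ValueError(f"request outside table hull r in [{rmin},{rmax}], "
                             f"theta in [{tmin},{tmax}]; pass allow_extrapolation=True to override")
    gl = geometry_function_line(r, th, params.active_length_cm)
    gl0 = geometry_function_line(params.r0_cm, params.theta0_deg, params.active_length_cm)
    out = params.lambda_cgy_per_hu * gl / gl0 * params.g_of_r(r) * params.f_of(r, th)
    if per == "mCi":
        out = out * params.sk_u_per_mci
    elif per != "U":
        raise ValueError("per must be 'U' or 'mCi'")
    return float(out) if np.ndim(out) == 0 else out
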