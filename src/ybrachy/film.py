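"""Radiochromic-film dosimetry chain.

EBT3-style film darkens with dose; scanning it in transmission before and
after exposure gives a net optical density

    netOD = log10[(PV_before - PV_bckg) / (PV_after - PV_bckg)]

per region of interest, where PV are mean pixel values and PV_bckg the
zero-light-transmission reading.  A calibration set exposed to known doses
(0.25-6 Gy here) is fitted with

    D_fit = a netOD + b netOD^n

and scans of film exposed around the source are converted pixel-by-pixel to
2-D dose maps, from which depth-dose profiles, isodose contours and the
film-measured anisotropy function at fixed radius are derived.

Conventions: the red channel is used by default (the sensitive channel for
this dose range); image columns map to the transverse axis and rows to the
source axis, with the source center at a stated origin pixel; the pixel
pitch is 2.54/dpi cm.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from scipy.optimize import brentq, curve_fit
from skimage import measure

from .tg43 import geometry_function_line

__all__ = ["FilmScan", "ROI", "CalibrationCurve", "DoseMap", "net_od",
           "fit_calibration", "dose_from_netod", "dose_map_from_scans",
           "pdd_profile", "isodose_contours", "anisotropy_from_film"]

log = logging.getLogger(__name__)

_CHANNELS = {"red": 0, "green": 1, "blue": 2}


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest in pixel coordinates (top-left corner)."""

    col: int
    row: int
    width: int
    height: int


@dataclass
class FilmScan:
    """RGB transmission scan: (rows, cols, 3) array, 8 or 16 bits per channel."""

    pixels: np.ndarray
    dpi: float = 300.0
    channel: str = "red"
    rois: List[ROI] = field(default_factory=list)

    def __post_init__(self):
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError("film scan must be an RGB array of shape (rows, cols, 3)")
        if self.dpi <= 0:
            raise ValueError("resolution must be positive")
        if self.channel not in _CHANNELS:
            raise ValueError(f"channel must be one of {sorted(_CHANNELS)}")
        self.pixels = p

    @property
    def pitch_cm(self) -> float:
        return 2.54 / self.dpi

    def channel_image(self, channel: Optional[str] = None) -> np.ndarray:
        return self.pixels[:, :, _CHANNELS[channel or self.channel]].astype(float)

    def roi_mean(self, roi: ROI, channel: Optional[str] = None,
                 mad_cut: float = 3.0) -> float:
        """Mean pixel value in a ROI with outlier rejection at ``mad_cut``
        median absolute deviations (dust and scratches read as outliers)."""
        img = self.channel_image(channel)
        if (roi.row < 0 or roi.col < 0 or roi.row + roi.height > img.shape[0]
                or roi.col + roi.width > img.shape[1]):
            raise ValueError(f"ROI {roi} outside image bounds {img.shape[:2]}")
        patch = img[roi.row:roi.row + roi.height, roi.col:roi.col + roi.width].ravel()
        med = np.median(patch)
        mad = np.median(np.abs(patch - med))
        if mad > 0:
            patch = patch[np.abs(patch - med) <= mad_cut * 1.4826 * mad]
        else:   # perfectly flat patch except outliers
            patch = patch[patch == med]
        return float(patch.mean())

    # ---- I/O -------------------------------------------------------------
    def to_tiff(self, path) -> None:
        import tifffile
        tifffile.imwrite(path, self.pixels, resolution=(self.dpi, self.dpi))

    @classmethod
    def from_tiff(cls, path, dpi: Optional[float] = None,
                  channel: str = "red") -> "FilmScan":
        import tifffile
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            arr = page.asarray()
            if dpi is None:
                try:
                    xres = page.tags["XResolution"].value
                    dpi = xres[0] / xres[1]
                except (KeyError, TypeError, ZeroDivisionError):
                    dpi = 300.0
        return cls(arr, dpi=float(dpi), channel=channel)


def net_od(pv_before: float, pv_after: float, pv_bckg: float = 0.0) -> float:
    """Net optical density from background-corrected mean pixel values."""
    b = pv_before - pv_bckg
    a = pv_after - pv_bckg
    if np.any(np.asarray(b) <= 0) or np.any(np.asarray(a) <= 0):
        raise ValueError("background-corrected pixel values must be positive "
                         "(saturated or overexposed film?)")
    out = np.log10(np.asarray(b, float) / np.asarray(a, float))
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class CalibrationCurve:
    """Fitted dose response D = a netOD + b netOD^n with parameter errors."""

    a: float
    b: float
    n: float
    sigma_a: float = 0.0
    sigma_b: float = 0.0
    sigma_n: float = 0.0
    cov: Optional[np.ndarray] = None
    dose_range_gy: Tuple[float, float] = (0.25, 6.0)
    netod_range: Tuple[float, float] = (0.0, 1.0)
    max_abs_residual_gy: float = 0.0
    monotone: bool = True

    def __post_init__(self):
        if self.a < 0 or self.b < 0 or self.n <= 1:
            raise ValueError("require a >= 0, b >= 0 and n > 1 for a physical "
                             "monotone film response")

    def __call__(self, netod):
        x = np.asarray(netod, float)
        out = self.a * x + self.b * np.where(x > 0, x, 0.0) ** self.n
        return float(out) if np.ndim(out) == 0 else out

    def inverse(self, dose_gy):
        """netOD producing a given dose (vectorized, safeguarded Newton).

        The response is strictly increasing for a, b >= 0, n > 1, so Newton
        from a linear initial guess converges quickly at every pixel.
        """
        d = np.asarray(dose_gy, float)
        shape = d.shape
        d = np.ravel(d)
        if np.any(d < 0):
            raise ValueError("dose must be non-negative")
        x = d / max(self.a + self.b, 1e-12)
        for _ in range(100):
            fx = self(x) - d
            dfx = self.a + self.b * self.n * np.where(x > 0, x, 1e-30) ** (self.n - 1.0)
            step = fx / dfx
            x = np.clip(x - step, 0.0, None)
            if np.max(np.abs(fx)) < 1e-10:
                break
        if np.max(np.abs(self(x) - d)) > 1e-6 * max(1.0, float(d.max(initial=0.0))):
            raise RuntimeError("calibration-curve inversion failed to converge")
        out = x.reshape(shape)
        return float(out) if out.ndim == 0 else out


def fit_calibration(points: Sequence[Tuple[float, float]],
                    p0=(10.0, 40.0, 2.5)) -> CalibrationCurve:
    """Nonlinear least-squares fit of the dose-response curve.

    ``points`` are (dose Gy, netOD) pairs; at least 5 spanning the range are
    required.  A non-monotone fit only flags the curve (a, b >= 0 and n > 1
    already guarantee monotonicity on netOD >= 0).
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 5:
        raise ValueError("need at least 5 (dose, netOD) calibration points")
    dose, x = pts[:, 0], pts[:, 1]

    def model(xx, a, b, n):
        return a * xx + b * np.where(xx > 0, xx, 0.0) ** n

    try:
        popt, pcov = curve_fit(model, x, dose, p0=p0,
                               bounds=([0.0, 0.0, 1.0 + 1e-9], np.inf), maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"calibration fit did not converge: {exc}") from exc
    resid = model(x, *popt) - dose
    sig = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    return CalibrationCurve(*popt, sigma_a=sig[0], sigma_b=sig[1], sigma_n=sig[2],
                            cov=pcov, dose_range_gy=(float(dose.min()), float(dose.max())),
                            netod_range=(float(x.min()), float(x.max())),
                            max_abs_residual_gy=float(np.abs(resid).max()))


def dose_from_netod(curve: CalibrationCurve, netod, sigma_netod=0.0):
    """Dose in Gy with relative uncertainty by first-order propagation.

    The gradient of D = a x + b x^n with respect to (a, b, n, x) is combined
    with the fit covariance plus an independent netOD variance.  Requests
    outside the calibrated netOD range are honored but logged.
    """
    x = np.asarray(netod, float)
    if np.any(x < 0):
        raise ValueError("netOD must be non-negative")
    if np.any(x > curve.netod_range[1] * 1.001):
        log.warning("netOD beyond the calibrated range %s: extrapolating",
                    curve.netod_range)
    xs = np.where(x > 0, x, 1.0)       # guard the log/power at x = 0
    d = curve(x)
    xn = xs ** curve.n
    jac = np.stack([xs, xn, curve.b * xn * np.log(xs)], axis=-1)
    if curve.cov is not None:
        var = np.einsum("...i,ij,...j->...", jac, curve.cov, jac)
    else:
        var = (xs * curve.sigma_a) ** 2 + (xn * curve.sigma_b) ** 2 \
            + (curve.b * xn * np.log(xs) * curve.sigma_n) ** 2
    ddx = curve.a + curve.b * curve.n * xs ** (curve.n - 1.0)
    var = var + (ddx * np.asarray(sigma_netod, float)) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(d > 0, np.sqrt(var) / np.where(d > 0, d, 1.0), 0.0)
    if np.ndim(netod) == 0:
        return float(d), float(rel)
    return d, rel


@dataclass
class DoseMap:
    """Per-pixel dose image with the source center at ``origin_px`` (row, col)."""

    dose_gy: np.ndarray
    rel_unc: np.ndarray
    pitch_cm: float
    origin_px: Tuple[float, float]

    def __post_init__(self):
        if self.pitch_cm <= 0:
            raise ValueError("pixel pitch must be positive")
        d = np.asarray(self.dose_gy, float)
        if np.any(d[np.isfinite(d)] < 0):
            raise ValueError("dose must be non-negative where defined")
        self.dose_gy = d
        self.rel_unc = np.asarray(self.rel_unc, float)

    def sample(self, x_cm, z_cm):
        """Bilinear dose at physical (transverse x, axial z) in cm."""
        r0, c0 = self.origin_px
        rows = r0 - np.asarray(z_cm, float) / self.pitch_cm
        cols = c0 + np.asarray(x_cm, float) / self.pitch_cm
        h, wid = self.dose_gy.shape
        if np.any(rows < 0) or np.any(rows > h - 1) or np.any(cols < 0) \
                or np.any(cols > wid - 1):
            raise ValueError("requested point outside the dose map")
        return map_coordinates(self.dose_gy, [np.atleast_1d(rows),
                                              np.atleast_1d(cols)], order=1)

    def to_csv(self, path) -> None:
        h, wid = self.dose_gy.shape
        lines = [f"# pitch_cm={self.pitch_cm:.9g} origin_row={self.origin_px[0]:.9g} "
                 f"origin_col={self.origin_px[1]:.9g}",
                 "row,col,dose_gy,rel_unc"]
        rr, cc = np.meshgrid(np.arange(h), np.arange(wid), indexing="ij")
        for r, c, d, e in zip(rr.ravel(), cc.ravel(), self.dose_gy.ravel(),
                              self.rel_unc.ravel()):
            lines.append(f"{r},{c},{d:.9g},{e:.9g}")
        Path(path).write_text("\n".join(lines) + "\n")


def dose_map_from_scans(before: FilmScan, after: FilmScan, pv_bckg: float,
                        curve: CalibrationCurve, origin_px: Tuple[float, float],
                        sigma_netod: float = 0.0, uniform_before: bool = True,
                        smooth_px: int = 0) -> DoseMap:
    """Convert a before/after scan pair into a 2-D dose map.

    ``uniform_before`` replaces the unexposed scan by its image-wide mean
    (the standard practice: one pre-irradiation reading per film batch);
    otherwise the conversion is pixel-by-pixel.  ``smooth_px`` applies a
    uniform box filter of that width (pixels) to the netOD image before
    conversion -- the usual scanner-noise suppression step (5 px is ~0.4 mm
    at 300 dpi, below the dose-gradient scale away from the source).
    """
    if before.pixels.shape != after.pixels.shape:
        raise ValueError("before/after scans must have identical shape")
    img_b = before.channel_image()
    img_a = after.channel_image()
    pvb = img_b.mean() if uniform_before else img_b
    num = pvb - pv_bckg
    den = img_a - pv_bckg
    with np.errstate(divide="ignore", invalid="ignore"):
        nod = np.where(den > 0, np.log10(np.maximum(num, 1e-12) / np.maximum(den, 1e-12)),
                       np.nan)
    nod = np.clip(nod, 0.0, None)
    if smooth_px and smooth_px > 1:
        from scipy.ndimage import uniform_filter
        nod = np.clip(uniform_filter(np.nan_to_num(nod, nan=0.0), size=smooth_px),
                      0.0, None)
    dose, rel = dose_from_netod(curve, np.nan_to_num(nod, nan=0.0), sigma_netod)
    dose = np.where(np.isfinite(nod), dose, np.nan)
    return DoseMap(dose, rel, after.pitch_cm, origin_px)


def pdd_profile(dmap: DoseMap, direction=(1.0, 0.0), step_cm: Optional[float] = None,
                r_start_cm: float = 0.1) -> pd.DataFrame:
    """Percent depth dose along a ray from the origin.

    ``direction`` is (x, z); the profile runs from ``r_start_cm`` to the map
    edge and is normalized to 100% at its maximum sample.  Returns columns
    distance_cm, dose_gy, pdd_pct.
    """
    dx, dz = direction
    norm = np.hypot(dx, dz)
    if norm == 0:
        raise ValueError("direction must be non-zero")
    dx, dz = dx / norm, dz / norm
    step = step_cm or dmap.pitch_cm
    h, wid = dmap.dose_gy.shape
    r0, c0 = dmap.origin_px
    # distance to the image border along the ray
    tmax = np.inf
    if dx > 0:
        tmax = min(tmax, (wid - 1 - c0) * dmap.pitch_cm / dx)
    elif dx < 0:
        tmax = min(tmax, c0 * dmap.pitch_cm / -dx)
    if dz > 0:
        tmax = min(tmax, r0 * dmap.pitch_cm / dz)
    elif dz < 0:
        tmax = min(tmax, (h - 1 - r0) * dmap.pitch_cm / -dz)
    if not np.isfinite(tmax) or tmax <= r_start_cm:
        raise ValueError("profile axis leaves the dose map immediately")
    t = np.arange(r_start_cm, tmax, step)
    d = dmap.sample(t * dx, t * dz)
    good = np.isfinite(d)
    t, d = t[good], d[good]
    if len(d) == 0 or np.nanmax(d) <= 0:
        raise ValueError("no valid dose along the requested axis")
    return pd.DataFrame({"distance_cm": t, "dose_gy": d,
                         "pdd_pct": 100.0 * d / d.max()})


def isodose_contours(dmap: DoseMap, levels: Sequence[float],
                     percent: bool = False) -> dict:
    """Closed isodose polylines per level by marching squares.

    ``percent=True`` interprets levels as percent of the map maximum.
    Returns {level: [poly (N, 2) arrays of (x_cm, z_cm)]}.
    """
    if len(levels) == 0:
        raise ValueError("empty level set")
    img = np.nan_to_num(self_dose := dmap.dose_gy, nan=0.0)
    ref = np.nanmax(self_dose)
    out = {}
    r0, c0 = dmap.origin_px
    for lev in levels:
        val = lev / 100.0 * ref if percent else lev
        polys = []
        if val <= img.max():
            for contour in measure.find_contours(img, val):
                x = (contour[:, 1] - c0) * dmap.pitch_cm
                z = (r0 - contour[:, 0]) * dmap.pitch_cm
                polys.append(np.column_stack([x, z]))
        out[lev] = polys
    return out


def anisotropy_from_film(dmap: DoseMap, r_cm: float, active_length_cm: float = 0.26,
                         theta_step_deg: float = 10.0) -> pd.DataFrame:
    """Film-measured anisotropy function on a circle of radius r.

    The dose is sampled on the circle (bilinear), the line-source geometry
    factor is removed, and the result is normalized so F(90 deg) = 1 exactly.
    Returns columns theta_deg, F.
    """
    theta = np.arange(0.0, 180.0 + 1e-9, theta_step_deg)
    th = np.radians(theta)
    x = r_cm * np.sin(th)
    z = r_cm * np.cos(th)
    d = dmap.sample(x, z)          # raises if the circle exits the map
    gl = geometry_function_line(np.full_like(theta, r_cm), theta, active_length_cm)
    gl0 = geometry_function_line(r_cm, 90.0, active_length_cm)
    i90 = int(np.argmin(np.abs(theta - 90.0)))
    if d[i90] <= 0 or not np.isfinite(d[i90]):
        raise ValueError("no valid dose at the 90 deg reference direction")
    f = (d / d[i90]) * (gl0 / gl)
    f[i90] = 1.0
    return pd.DataFrame({"theta_deg": theta, "F": f})
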