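"""Film dosimetry: netOD, calibration fitting, dose maps, profiles, contours."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ybrachy.film import (ROI, CalibrationCurve, DoseMap, FilmScan,
                          anisotropy_from_film, dose_from_netod,
                          dose_map_from_scans, fit_calibration,
                          isodose_contours, net_od, pdd_profile)
from ybrachy.tg43 import geometry_function_line


class TestNetOD:
    def test_factor_of_two_is_log10_two(self):
        assert net_od(40000, 20000, 0) == pytest.approx(np.log10(2), rel=1e-12)

    def test_unexposed_film_reads_zero(self):
        assert net_od(31234, 31234, 500) == 0.0

    def test_decade_attenuation(self):
        assert net_od(40000, 4000, 0) == pytest.approx(1.0, rel=1e-12)

    @given(st.floats(1.01, 50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariance_under_common_rescaling(self, scale):
        a = net_od(40000, 17000, 2000)
        b = net_od(40000 * scale, 17000 * scale, 2000 * scale)
        assert b == pytest.approx(a, rel=1e-9)

    def test_saturated_film_rejected(self):
        with pytest.raises(ValueError):
            net_od(1000, 2000, 1500)


class TestCalibrationFit:
    TRUE = (10.0, 40.0, 2.5)

    def points(self, noise=0.0, seed=0, n=10):
        curve = CalibrationCurve(*self.TRUE)
        doses = np.linspace(0.25, 6.0, n)
        x = curve.inverse(doses)
        if noise:
            x = x * (1 + noise * np.random.default_rng(seed).standard_normal(n))
        return list(zip(doses, x))

    def test_noise_free_recovery(self):
        c = fit_calibration(self.points())
        assert c.a == pytest.approx(10.0, rel=1e-6)
        assert c.b == pytest.approx(40.0, rel=1e-6)
        assert c.n == pytest.approx(2.5, rel=1e-6)

    def test_linear_data_recovers_degenerate_submodel(self):
        doses = np.linspace(0.25, 6.0, 10)
        x = doses / 10.0          # purely linear response, b* = 0
        c = fit_calibration(list(zip(doses, x)))
        assert c.a == pytest.approx(10.0, rel=1e-3)
        # b itself is unidentifiable when the data are linear (any (b, n)
        # with a vanishing power term fits); the term's contribution is what
        # must vanish over the calibrated range
        assert abs(c.b * x.max() ** c.n) < 1e-3

    def test_noisy_fit_recovers_dose_response(self):
        # with 1% netOD noise the (a, b, n) parameters are strongly
        # correlated, but the fitted response itself stays tight
        c = fit_calibration(self.points(noise=0.01, seed=4))
        true = CalibrationCurve(*self.TRUE)
        xx = np.linspace(0.05, 0.34, 40)
        assert np.max(np.abs(c(xx) / true(xx) - 1)) < 0.05

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration(self.points()[:4])

    def test_monotone_on_calibrated_range(self):
        c = fit_calibration(self.points())
        xx = np.linspace(0.0, c.netod_range[1], 100)
        assert np.all(np.diff(c(xx)) > 0)


class TestDoseFromNetOD:
    def test_zero_netod_is_zero_dose(self):
        d, _ = dose_from_netod(CalibrationCurve(10, 40, 2.5), 0.0)
        assert d == 0.0

    def test_direct_evaluation(self):
        d, _ = dose_from_netod(CalibrationCurve(10, 40, 2.5), 0.3)
        assert d == pytest.approx(4.972, abs=5e-4)

    def test_linear_case_uncertainty_is_netod_uncertainty(self):
        curve = CalibrationCurve(10.0, 0.0, 2.5)
        d, rel = dose_from_netod(curve, 0.2, sigma_netod=0.01)
        assert rel == pytest.approx(0.01 / 0.2, rel=1e-9)

    def test_negative_netod_rejected(self):
        with pytest.raises(ValueError):
            dose_from_netod(CalibrationCurve(10, 40, 2.5), -0.1)

    def test_inverse_round_trip(self):
        curve = CalibrationCurve(10, 40, 2.5)
        doses = np.array([0.0, 0.3, 1.7, 5.9])
        assert np.allclose(curve(curve.inverse(doses)), doses, atol=1e-8)


class TestFilmScan:
    def test_roi_mean_rejects_dust(self, rng):
        img = np.full((50, 50, 3), 30000, dtype=np.uint16)
        img[10, 10, 0] = 100      # a scratch in the red channel
        scan = FilmScan(img)
        roi = ROI(0, 0, 50, 50)
        assert scan.roi_mean(roi) == pytest.approx(30000, abs=1.0)

    def test_roi_outside_bounds_rejected(self):
        scan = FilmScan(np.zeros((10, 10, 3), dtype=np.uint16))
        with pytest.raises(ValueError):
            scan.roi_mean(ROI(5, 5, 10, 10))

    def test_tiff_round_trip(self, tmp_path, rng):
        px = rng.integers(0, 65535, size=(20, 30, 3), dtype=np.uint16)
        scan = FilmScan(px, dpi=300.0)
        p = tmp_path / "scan.tiff"
        scan.to_tiff(p)
        back = FilmScan.from_tiff(p)
        assert np.array_equal(back.pixels, px)
        assert back.dpi == pytest.approx(300.0)


def radial_map(field, extent=3.0, pitch=0.02):
    n = int(2 * extent / pitch) + 1
    c = (n - 1) / 2
    x = (np.arange(n) - c) * pitch
    z = (c - np.arange(n)[:, None]) * pitch
    rr = np.hypot(x[None, :], z)
    vals = field(np.clip(rr, 0.2, None), x[None, :] + 0 * z, z)
    return DoseMap(vals, np.zeros_like(vals), pitch, (c, c))


class TestPDD:
    def test_inverse_square_profile(self):
        dm = radial_map(lambda r, x, z: 1.0 / r**2)
        pdd = pdd_profile(dm, r_start_cm=0.5)
        v1 = float(pdd.pdd_pct[np.isclose(pdd.distance_cm, 1.0, atol=0.011)].iloc[0])
        v2 = float(pdd.pdd_pct[np.isclose(pdd.distance_cm, 2.0, atol=0.011)].iloc[0])
        assert v2 / v1 == pytest.approx(0.25, rel=0.03)

    def test_uniform_map_is_flat_100(self):
        dm = radial_map(lambda r, x, z: np.ones_like(r))
        pdd = pdd_profile(dm)
        assert np.allclose(pdd.pdd_pct, 100.0, atol=1e-9)

    def test_axis_leaving_map_rejected(self):
        dm = radial_map(lambda r, x, z: 1.0 / r**2)
        with pytest.raises(ValueError):
            pdd_profile(dm, direction=(0.0, 0.0))


class TestIsodose:
    def test_inverse_square_contour_is_a_circle(self):
        dm = radial_map(lambda r, x, z: 1.0 / r**2, extent=2.0, pitch=0.01)
        level = 1.0          # dose value at r = 1 cm
        polys = isodose_contours(dm, [level])[level]
        assert len(polys) >= 1
        radii = np.hypot(*np.concatenate(polys).T)
        assert np.all(np.abs(radii - 1.0) < 0.011)   # within one pixel

    def test_level_above_maximum_is_empty(self):
        dm = radial_map(lambda r, x, z: 1.0 / r**2)
        out = isodose_contours(dm, [1e9])
        assert out[1e9] == []

    def test_empty_level_set_rejected(self):
        dm = radial_map(lambda r, x, z: 1.0 / r**2)
        with pytest.raises(ValueError):
            isodose_contours(dm, [])

    def test_elliptical_map_eccentricity(self):
        ab = (1.0, 0.6)
        dm = radial_map(lambda r, x, z: 1.0 / ((x / ab[0])**2 + (z / ab[1])**2 + 1e-9),
                        extent=2.0, pitch=0.01)
        polys = isodose_contours(dm, [1.0])[1.0]
        pts = np.concatenate(polys)
        width = pts[:, 0].max() - pts[:, 0].min()
        height = pts[:, 1].max() - pts[:, 1].min()
        assert height / width == pytest.approx(ab[1] / ab[0], rel=0.02)


class TestFilmAnisotropy:
    def test_geometry_built_map_gives_unity(self):
        dm = radial_map(lambda r, x, z: geometry_function_line(
            np.clip(r, 0.2, None),
            np.degrees(np.arctan2(np.abs(x), z))), extent=2.0, pitch=0.01)
        out = anisotropy_from_film(dm, 1.0)
        assert np.allclose(out.F, 1.0, atol=0.01)

    def test_known_anisotropy_recovered(self):
        f_true = lambda th: 0.6 + 0.4 * np.sin(np.radians(th))
        def field(r, x, z):
            th = np.degrees(np.arctan2(np.abs(x), z))
            return geometry_function_line(np.clip(r, 0.2, None), th) * f_true(th)
        dm = radial_map(field, extent=2.0, pitch=0.01)
        out = anisotropy_from_film(dm, 1.0)
        for th, fv in zip(out.theta_deg, out.F):
            assert fv == pytest.approx(f_true(th), rel=0.02)

    def test_circle_must_fit_inside_map(self):
        dm = radial_map(lambda r, x, z: 1.0 / r**2, extent=1.0)
        with pytest.raises(ValueError):
            anisotropy_from_film(dm, 5.0)
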