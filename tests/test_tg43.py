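"""Geometry function, unit conversion, parameter extraction and reconstruction."""
import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from ybrachy import (KERMA_TO_DOSE_RATE, air_kerma_strength, anisotropy_function,
                     convert_dose_table, convert_kerma_to_dose_rate,
                     dose_rate_constant, extract_parameters, fit_radial_polynomial,
                     geometry_function_line, radial_dose_function,
                     reconstruct_dose_rate, table_radii_mesh)
from ybrachy.synthetic import (default_ground_truth, generate_air_kerma,
                               generate_dose_table, reference_g_table)
from ybrachy.tallies import AirKermaTally, DoseRateTable, CONVERTED


def line_kernel_oracle(r, theta_deg, L):
    """Brute-force line-source geometry function by numerical integration."""
    th = np.radians(theta_deg)
    rho, z = r * np.sin(th), r * np.cos(th)
    val, _ = quad(lambda l: 1.0 / (rho**2 + (z - l) ** 2), -L / 2, L / 2,
                  epsabs=1e-14, epsrel=1e-13)
    return val / L


class TestGeometryFunction:
    @pytest.mark.parametrize("r,theta,expected", [
        (1.0, 90.0, 0.9944), (0.5, 0.0, 4.2900), (0.5, 90.0, 3.9134),
        (3.0, 0.0, 0.1113), (10.0, 90.0, 0.0100)])
    def test_reference_values(self, r, theta, expected):
        assert geometry_function_line(r, theta, 0.26) == pytest.approx(expected, abs=1e-4)

    def test_on_axis_closed_form(self):
        # exact limit 1/(r^2 - L^2/4); the published table rounds this cell low
        assert geometry_function_line(1.0, 0.0, 0.26) == pytest.approx(
            1.0 / (1.0 - 0.0169), rel=1e-12)

    def test_point_source_limit(self):
        r, th = 2.7, 34.0
        assert geometry_function_line(r, th, 1e-9) == pytest.approx(1 / r**2, rel=1e-6)

    def test_fore_aft_symmetry(self, rng):
        r = rng.uniform(0.3, 10, 50)
        th = rng.uniform(1, 89, 50)
        a = geometry_function_line(r, th, 0.26)
        b = geometry_function_line(r, 180.0 - th, 0.26)
        assert np.allclose(a, b, rtol=1e-12)

    def test_against_numerical_line_integral(self, rng):
        for _ in range(100):
            r = rng.uniform(0.2, 10.0)
            th = rng.uniform(0.5, 179.5)
            ours = geometry_function_line(r, th, 0.26)
            assert ours == pytest.approx(line_kernel_oracle(r, th, 0.26), rel=1e-6)

    def test_continuity_at_the_pole(self):
        g_axis = geometry_function_line(1.0, 0.0, 0.26)
        g_near = geometry_function_line(1.0, 0.01, 0.26)
        assert abs(g_near / g_axis - 1.0) < 1e-6

    def test_point_on_segment_rejected(self):
        with pytest.raises(ValueError):
            geometry_function_line(0.05, 0.0, 0.26)
        with pytest.raises(ValueError):
            geometry_function_line(0.1, 180.0, 0.26)


class TestUnitConversion:
    def test_constant_from_physical_constants(self):
        mci_bq, s_per_h, mev_to_cgy_g = 3.7e7, 3600.0, 1.602176634e-8
        assert KERMA_TO_DOSE_RATE == pytest.approx(mci_bq * s_per_h * mev_to_cgy_g)
        assert KERMA_TO_DOSE_RATE == pytest.approx(2.134e3, rel=5e-4)

    def test_zero_and_direct_multiplication(self):
        assert convert_kerma_to_dose_rate(0.0, 3.322) == 0.0
        assert convert_kerma_to_dose_rate(1e-4, 3.322) == pytest.approx(0.7089, abs=5e-5)

    def test_negative_tally_rejected(self):
        with pytest.raises(ValueError):
            convert_kerma_to_dose_rate(-1.0, 3.322)
        with pytest.raises(ValueError):
            convert_kerma_to_dose_rate(1.0, 0.0)


class TestAirKermaStrength:
    def test_exact_inverse_square_tally(self):
        d = np.arange(50.0, 151.0, 10.0)
        c = 3.4e-4
        tally = AirKermaTally(d, c / d**2 / (KERMA_TO_DOSE_RATE * 3.322),
                              np.zeros(len(d)))
        sk = air_kerma_strength(tally, 3.322, shell_correction="none")
        assert np.allclose(sk.per_distance.sk_u_per_mci, c, rtol=1e-12)

    def test_shell_average_correction_gives_flat_sk(self):
        d = np.arange(50.0, 151.0, 10.0)
        c = 1.0
        vals = np.array([c / ((dd - 2.5) * (dd + 2.5)) for dd in d])
        tally = AirKermaTally(d, vals / (KERMA_TO_DOSE_RATE * 3.322), np.zeros(len(d)))
        sk = air_kerma_strength(tally, 3.322, shell_correction="line")
        spread = sk.per_distance.sk_u_per_mci.max() - sk.per_distance.sk_u_per_mci.min()
        assert spread < 1e-6

    def test_empty_tally_rejected(self):
        with pytest.raises(ValueError):
            AirKermaTally(np.array([]), np.array([]), np.array([]))


class TestDoseRateConstant:
    def test_published_worked_example(self):
        assert round(dose_rate_constant(1.25, 1.03), 2) == 1.21

    def test_identity(self):
        assert dose_rate_constant(0.7, 0.7) == 1.0

    def test_nonpositive_sk_rejected(self):
        with pytest.raises(ValueError):
            dose_rate_constant(1.0, 0.0)


def table_from_field(field, mesh=None, rel=0.0):
    """DoseRateTable whose voxel values follow field(r, theta)."""
    mesh = mesh or table_radii_mesh()
    rr, tt = np.meshgrid(mesh.r_centers_cm, mesh.theta_centers_deg, indexing="ij")
    vals = field(rr, tt)
    return DoseRateTable(mesh, vals, np.full(rr.shape, rel), np.ones(rr.shape, bool),
                         unit=CONVERTED)


class TestRadialDoseFunction:
    def test_normalized_at_reference(self):
        tab = table_from_field(lambda r, t: geometry_function_line(r, t) * (1 + 0.1 * r))
        g = radial_dose_function(tab)
        assert float(g.g[np.isclose(g.r_cm, 1.0)].iloc[0]) == 1.0

    def test_pure_geometry_gives_unity(self):
        tab = table_from_field(lambda r, t: geometry_function_line(r, t))
        g = radial_dose_function(tab)
        assert np.allclose(g.g, 1.0, atol=1e-12)

    def test_synthetic_inversion_is_exact(self):
        g_true = lambda r: 1.0 + 0.07 * (r - 1.0)     # g*(2) = 1.07
        tab = table_from_field(lambda r, t: geometry_function_line(r, t) * g_true(r))
        g = radial_dose_function(tab)
        assert float(g.g[np.isclose(g.r_cm, 2.0)].iloc[0]) == pytest.approx(1.07, rel=1e-12)

    def test_missing_reference_voxel_rejected(self):
        mesh = table_radii_mesh([2.0, 3.0])
        tab = table_from_field(lambda r, t: np.ones_like(r), mesh)
        with pytest.raises(ValueError):
            radial_dose_function(tab)


class TestAnisotropyFunction:
    def test_unity_on_transverse_axis(self):
        tab = table_from_field(lambda r, t: geometry_function_line(r, t) * (2 - t / 180))
        f = anisotropy_function(tab)
        on_axis = f[np.isclose(f.theta_deg, 90.0)]
        assert np.allclose(on_axis.F, 1.0, atol=1e-12)

    def test_synthetic_inversion_is_exact(self):
        f_true = lambda r, t: 0.55 + 0.45 * np.sin(np.radians(t))
        tab = table_from_field(
            lambda r, t: geometry_function_line(r, t) * f_true(r, t))
        f = anisotropy_function(tab)
        cell = f[np.isclose(f.r_cm, 1.0) & np.isclose(f.theta_deg, 10.0)]
        assert float(cell.F.iloc[0]) == pytest.approx(f_true(1.0, 10.0), rel=1e-10)

    def test_invalid_voxels_become_nan(self):
        mesh = table_radii_mesh([1.0, 2.0])
        rr, tt = np.meshgrid(mesh.r_centers_cm, mesh.theta_centers_deg, indexing="ij")
        vals = geometry_function_line(rr, tt)
        valid = ~((rr <= 1.0) & (tt > 176))
        tab = DoseRateTable(mesh, np.where(valid, vals, np.nan),
                            np.zeros(rr.shape), valid, unit=CONVERTED)
        f = anisotropy_function(tab)
        masked = f[np.isclose(f.r_cm, 1.0) & (f.theta_deg > 176)]
        assert masked.F.isna().all()


class TestRadialPolynomial:
    def test_exact_polynomial_recovered(self):
        coeffs = np.array([0.9, 0.1, -0.02, 0.003, -2e-4, 5e-6])
        r = np.linspace(0.5, 10, 12)
        g = np.polynomial.polynomial.polyval(r, coeffs)
        fit = fit_radial_polynomial(r, g)
        assert np.allclose(fit.coeffs, coeffs, atol=1e-9)
        assert fit.max_rel_residual < 1e-9

    def test_constant_profile(self):
        r = np.linspace(0.5, 10, 11)
        fit = fit_radial_polynomial(r, np.ones_like(r))
        assert fit.coeffs[0] == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(fit.coeffs[1:], 0.0, atol=1e-9)

    def test_published_profile_fits_within_two_percent(self):
        ref = reference_g_table()
        fit = fit_radial_polynomial(ref.r_cm, ref.this_work)
        assert fit.max_rel_residual <= 0.02
        assert fit.residual_ok

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_radial_polynomial([1, 2, 3, 4, 5, 6], [1] * 6)


@pytest.fixture(scope="module")
def params():
    gt = default_ground_truth()
    tab = generate_dose_table(gt, seed=3, noise=0.0)
    ak = generate_air_kerma(gt, seed=3, noise=0.0)
    return gt, extract_parameters(tab, ak, gt.i_gamma)


class TestReconstruction:
    def test_reference_point_returns_sk_lambda(self, params):
        gt, ps = params
        assert reconstruct_dose_rate(ps, 1.0, 90.0, per="mCi") == pytest.approx(
            gt.sk_star * gt.lambda_star, rel=1e-6)

    def test_round_trip_reproduces_table(self, params):
        gt, ps = params
        mesh = table_radii_mesh()
        for r in (0.5, 2.0, 5.0, 7.0):
            for th in (10.0, 50.0, 90.0, 150.0):
                rec = reconstruct_dose_rate(ps, r, th, per="mCi")
                truth = gt.dose_rate(r, th)
                assert rec == pytest.approx(truth, rel=5e-3)

    def test_transverse_ratio_structure(self, params):
        _, ps = params
        num = reconstruct_dose_rate(ps, 2.0, 90.0)
        den = reconstruct_dose_rate(ps, 1.0, 90.0)
        expected = (ps.g_of_r(2.0) / ps.g_of_r(1.0)
                    * geometry_function_line(2.0, 90.0) / geometry_function_line(1.0, 90.0))
        assert num / den == pytest.approx(expected, rel=1e-12)

    def test_extrapolation_refused(self, params):
        _, ps = params
        with pytest.raises(ValueError):
            reconstruct_dose_rate(ps, 50.0, 90.0)


class TestFullExtraction:
    def test_unit_tag_guard(self):
        tab = table_from_field(lambda r, t: geometry_function_line(r, t))
        with pytest.raises(ValueError):
            convert_dose_table(tab, 3.322)   # already converted

    def test_sk_lambda_consistency(self):
        gt = default_ground_truth()
        tab = generate_dose_table(gt, seed=5, noise=0.0)
        ak = generate_air_kerma(gt, seed=5, noise=0.0)
        ps = extract_parameters(tab, ak, gt.i_gamma)
        # Sk * Lambda must equal the reference-point dose rate (identity)
        assert ps.sk_u_per_mci * ps.lambda_cgy_per_hu == pytest.approx(
            tab.value_at(1.0, 90.0), rel=1e-12)
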