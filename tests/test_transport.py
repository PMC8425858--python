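"""Transport-engine benchmarks against closed-form oracles (small runs)."""
import numpy as np
import pytest

from ybrachy.source import PhotonLine, PhotonSpectrum
from ybrachy.tallies import table_radii_mesh
from ybrachy.transport import (PhantomSpec, _SourceModel, sample_compton,
                               simulate_air_kerma, simulate_dose_table,
                               trace_photon)
from ybrachy.xsections import load_xs


def mono(energy=100.0):
    return PhotonSpectrum([PhotonLine(energy, 100.0)])


@pytest.fixture(scope="module")
def vacuum_table():
    mesh = table_radii_mesh([1.0, 2.0, 5.0], half_width_cm=0.1)
    return simulate_dose_table(None, mono(), PhantomSpec(None, 50.0), mesh,
                               n_histories=60_000, seed=7), mesh


class TestPointSourceVacuum:
    def test_inverse_square_falloff(self, vacuum_table):
        tab, _ = vacuum_table
        men = float(load_xs("water").mu_en_lookup(100.0))
        for r in (1.0, 2.0, 5.0):
            expected = 0.1 * men / (4 * np.pi * r * r)
            v = tab.value_at(r, 90.0)
            sigma = v * tab.rel_err_at(r, 90.0)
            assert abs(v - expected) < 3 * sigma + 1e-3 * expected

    def test_isotropy_within_noise(self, vacuum_table):
        tab, mesh = vacuum_table
        i = mesh.index_of(2.0, 90.0)[0]
        vals = tab.values[i, :]
        errs = tab.rel_err[i, :] * vals
        mean = np.average(vals, weights=1 / errs**2)
        assert np.all(np.abs(vals - mean) < 4 * errs)

    def test_determinism_under_seed(self):
        mesh = table_radii_mesh([1.0], half_width_cm=0.1)
        kw = dict(phantom=PhantomSpec(None, 50.0), mesh=mesh,
                  n_histories=5_000, seed=99)
        a = simulate_dose_table(None, mono(), **kw)
        b = simulate_dose_table(None, mono(), **kw)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.rel_err, b.rel_err)


class TestPrimaryKermaOracle:
    def test_exponential_attenuation_in_water(self):
        mesh = table_radii_mesh([1.0, 5.0], half_width_cm=0.1)
        tab = simulate_dose_table(None, mono(), PhantomSpec("water", 50.0), mesh,
                                  n_histories=80_000, seed=8, primaries_only=True)
        xs = load_xs("water")
        mu = float(xs.linear_mu(100.0))
        men = float(xs.mu_en_lookup(100.0))
        for r in (1.0, 5.0):
            expected = 0.1 * men * np.exp(-mu * r) / (4 * np.pi * r * r)
            v = tab.value_at(r, 90.0)
            sigma = v * tab.rel_err_at(r, 90.0)
            assert abs(v - expected) < 3 * sigma + 2e-3 * expected


class TestInteractionSampling:
    def test_compton_mean_energy_matches_klein_nishina(self, rng):
        e0 = 200.0
        es, _ = sample_compton(np.full(400_000, e0), rng)
        k = e0 / 510.99895
        mu = np.linspace(-1, 1, 40001)
        eps = 1 / (1 + k * (1 - mu))
        dsig = eps**2 * (eps + 1 / eps - (1 - mu**2))
        oracle = np.trapezoid(dsig * eps, mu) / np.trapezoid(dsig, mu)
        assert es.mean() / e0 == pytest.approx(oracle, rel=0.01)

    def test_compton_energy_below_incident(self, rng):
        es, ct = sample_compton(np.full(10_000, 300.0), rng)
        assert np.all(es <= 300.0 + 1e-9)
        assert np.all(es >= 300.0 / (1 + 2 * 300.0 / 510.99895) - 1e-9)
        assert np.all((ct >= -1) & (ct <= 1))

    def test_beer_lambert_first_flight(self, rng):
        # uncollided transmission through 1 cm of water at 100 keV
        mu = float(load_xs("water").linear_mu(100.0))
        n = 4000
        survived = 0
        for _ in range(n):
            ev = trace_photon([0, 0, 0], [0, 0, 1.0], 100.0, "water", rng)
            if ev and ev[0]["pos"][2] > 1.0:
                survived += 1
        p = np.exp(-mu)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(survived / n - p) < 3.5 * se

    def test_photon_in_vacuum_does_not_interact(self):
        mesh = table_radii_mesh([1.0], half_width_cm=0.1)
        tab = simulate_dose_table(None, mono(), PhantomSpec(None, 50.0), mesh,
                                  n_histories=20_000, seed=1)
        # every history contributes exactly its straight-line track, so the
        # transverse voxel is tightly determined
        assert tab.value_at(1.0, 90.0) > 0
        assert tab.rel_err_at(1.0, 90.0) < 0.05


class TestStatisticalErrors:
    def test_error_scales_as_inverse_sqrt_histories(self):
        mesh = table_radii_mesh([2.0], half_width_cm=0.1)
        errs = []
        for n in (20_000, 80_000):
            tab = simulate_dose_table(None, mono(), PhantomSpec("water", 50.0), mesh,
                                      n_histories=n, seed=17)
            errs.append(tab.rel_err_at(2.0, 90.0))
        ratio = errs[0] / errs[1]
        assert 2.0 * 0.8 < ratio < 2.0 * 1.2


class TestAirKerma:
    def test_point_source_inverse_square_consistency(self):
        tally = simulate_air_kerma(None, mono(), n_histories=60_000, seed=21)
        from ybrachy.tg43 import air_kerma_strength
        sk = air_kerma_strength(tally, 1.0)
        per = sk.per_distance.sk_u_per_mci.to_numpy()
        rel = sk.per_distance.rel_err.to_numpy()
        mean = per.mean()
        assert np.all(np.abs(per - mean) < 4 * rel * per + 1e-3 * mean)


class TestSourceModel:
    def test_classify_regions(self, source):
        sm = _SourceModel(source)
        pts = np.array([
            [0.0, 0.0, 0.0],        # core center
            [0.027, 0.0, 0.0],      # Ti wall
            [0.04, 0.0, 0.0],       # SS wall
            [0.0, 0.0, 0.2],        # solid SS tip
            [0.0, 0.0, -1.0],       # cable
            [0.2, 0.0, 0.0],        # outside
        ])
        assert list(sm.classify(pts)) == [0, 1, 2, 2, 3, -1]

    def test_exit_and_entry_distances(self, source):
        sm = _SourceModel(source)
        x = np.array([[0.0, 0.0, 0.0]])
        u = np.array([[1.0, 0.0, 0.0]])
        assert sm.exit_distance(x, u)[0] == pytest.approx(sm.env_r, rel=1e-9)
        x_out = np.array([[0.2, 0.0, 0.0]])
        u_in = np.array([[-1.0, 0.0, 0.0]])
        assert sm.entry_distance(x_out, u_in)[0] == pytest.approx(0.2 - sm.env_r, rel=1e-9)
        u_away = np.array([[1.0, 0.0, 0.0]])
        assert np.isinf(sm.entry_distance(x_out, u_away)[0])

    def test_source_voxels_marked_invalid(self, source, spectrum):
        mesh = table_radii_mesh([0.5, 1.0, 2.0], half_width_cm=0.1)
        tab = simulate_dose_table(source, spectrum, PhantomSpec("water", 50.0), mesh,
                                  n_histories=2_000, seed=3)
        # voxels behind the 2 cm cable at 177.5 deg centers are inside it
        i, j = mesh.index_of(0.5, 177.5)
        assert not tab.valid[i, j]
        assert tab.valid[mesh.index_of(0.5, 90.0)]


def test_mesh_beyond_phantom_rejected(spectrum):
    mesh = table_radii_mesh([5.0], half_width_cm=0.1)
    with pytest.raises(ValueError):
        simulate_dose_table(None, spectrum, PhantomSpec("water", 4.0), mesh,
                            n_histories=1_000, seed=0)


def test_too_few_histories_rejected(spectrum):
    with pytest.raises(ValueError):
        simulate_dose_table(None, spectrum, n_histories=10, seed=0)
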