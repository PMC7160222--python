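import numpy as np
import pytest
from scipy.stats import chisquare

from lutebg.nuclear_data import AttenuationTable
from lutebg.photon_mc import (
    DetectorGeometry,
    GeometryError,
    _isotropic,
    _uniform_in_crystal,
    estimate_absorption,
    klein_nishina_eps_pdf,
    sample_compton_fraction,
    transport_batch,
    transport_photon,
)


@pytest.fixture(scope="module")
def geometry():
    return DetectorGeometry(distance=2.5)


class TestGeometry:
    def test_crystal_bounds_symmetric_about_gap(self, geometry):
        lo1, hi1 = geometry.crystal_bounds(0)
        lo2, hi2 = geometry.crystal_bounds(1)
        assert hi1[2] == -lo2[2]  # faces at -d/2 and +d/2
        assert hi1[2] - lo1[2] == geometry.thickness
        assert lo2[2] - hi1[2] == geometry.gap_mm

    def test_validation(self):
        with pytest.raises(GeometryError):
            DetectorGeometry(side=-1.0)
        with pytest.raises(GeometryError):
            DetectorGeometry(distance=-0.5)

    def test_transport_preconditions(self, geometry, attenuation):
        with pytest.raises(GeometryError):
            transport_photon([0, 0, 0], [0, 0, 2.0], 307.0, geometry, attenuation)
        with pytest.raises(GeometryError):
            transport_photon([0, 0, 0], [0, 0, 1.0], 307.0, geometry, attenuation)


class TestTransportPhysics:
    def test_pencil_beam_attenuation_law(self, attenuation):
        # interaction frequency through the 10 mm thickness must follow
        # 1 - exp(-mu * t) within 3 binomial standard errors
        # beam enters at the inner face and crosses the thickness away from
        # the partner crystal, so only one 10 mm traversal is in play
        geo = DetectorGeometry(distance=1000.0)
        n = 50_000
        z0 = geo.crystal_bounds(0)[1][2] - 1e-9
        origins = np.tile([0.0, 0.0, z0], (n, 1))
        dirs = np.tile([0.0, 0.0, -1.0], (n, 1))
        for e in (88.0, 202.0, 307.0):
            dep, esc, _ = transport_batch(
                origins, dirs, np.full(n, e), geo, attenuation,
                np.random.default_rng(1), include_coherent=False,
            )
            la = attenuation.linear(e)
            p = 1.0 - np.exp(-(float(la.photoelectric + la.incoherent)) * 1.0)
            interacted = (dep.sum(axis=1) > 0) | (esc < e)
            se = np.sqrt(p * (1 - p) / n)
            assert abs(interacted.mean() - p) < 3 * se

    def test_photoelectric_only_medium_absorbs_at_first_interaction(self):
        table = AttenuationTable(
            energy=[10.0, 1200.0], photoelectric=[0.5, 0.5],
            incoherent=[0.0, 0.0], coherent=[0.0, 0.0], total=[0.5, 0.5],
        )
        geo = DetectorGeometry(distance=2.5)
        rng = np.random.default_rng(5)
        n = 5_000
        o = _uniform_in_crystal(geo, 0, n, rng)
        d = _isotropic(n, rng)
        dep, esc, nsc = transport_batch(o, d, np.full(n, 307.0), geo, table, rng)
        interacted = dep.sum(axis=1) > 0
        # every interacting photon is absorbed in one crystal in full
        full1 = np.abs(dep[:, 0] - 307.0) < 1e-9
        full2 = np.abs(dep[:, 1] - 307.0) < 1e-9
        assert np.all(full1[interacted] | full2[interacted])
        assert np.all(nsc == 0)

    def test_parallel_photon_outside_crystal_escapes(self, geometry, attenuation):
        # grazing ray displaced just outside the facing surface
        z_face = geometry.crystal_bounds(0)[1][2]
        hist_origin = np.array([[0.0, 0.0, z_face + 1e-6]])
        dep, esc, _ = transport_batch(
            hist_origin, np.array([[1.0, 0.0, 0.0]]), [202.0], geometry,
            attenuation, np.random.default_rng(0),
        )
        assert dep.sum() == 0.0
        assert esc[0] == 202.0

    def test_energy_bookkeeping_exact(self, geometry, attenuation):
        rng = np.random.default_rng(9)
        n = 20_000
        o = _uniform_in_crystal(geometry, 0, n, rng)
        d = _isotropic(n, rng)
        e0 = np.full(n, 307.0)
        dep, esc, _ = transport_batch(o, d, e0, geometry, attenuation, rng)
        np.testing.assert_allclose(dep.sum(axis=1) + esc, e0, rtol=0, atol=1e-9)
        assert np.all(dep >= 0)

    def test_single_photon_history(self, geometry, attenuation):
        hist = transport_photon([0.0, 0.0, -15.0], [0.0, 0.0, 1.0], 307.0,
                                geometry, attenuation, rng=4)
        assert hist.fate in {"absorbed_C1", "absorbed_C2", "escaped_lost", "partial"}
        assert hist.deposit_c1 + hist.deposit_c2 + hist.escaped_energy == \
            pytest.approx(307.0, abs=1e-9)


class TestKleinNishina:
    @pytest.mark.parametrize("energy", [88.0, 307.0])
    def test_sampler_matches_analytic_density(self, energy):
        # chi-square on 20 bins, 1e5 draws, against the integrated
        # Klein-Nishina density of the scattered-energy fraction
        rng = np.random.default_rng(12)
        draws = sample_compton_fraction(np.full(100_000, energy), rng)
        lo = 1.0 / (1.0 + 2.0 * energy / 510.99895)
        edges = np.linspace(lo, 1.0, 21)
        obs, _ = np.histogram(draws, bins=edges)
        fine = np.linspace(lo, 1.0, 4001)
        pdf = klein_nishina_eps_pdf(energy, fine)
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1])
                                               * np.diff(fine))])
        cdf /= cdf[-1]
        expected = np.diff(np.interp(edges, fine, cdf)) * len(draws)
        assert chisquare(obs, expected).pvalue > 0.01

    def test_fraction_bounds(self):
        rng = np.random.default_rng(2)
        e = np.full(10_000, 202.0)
        eps = sample_compton_fraction(e, rng)
        lo = 1.0 / (1.0 + 2.0 * 202.0 / 510.99895)
        assert np.all(eps >= lo) and np.all(eps <= 1.0)


class TestEstimateAbsorption:
    def test_p_c2_monotone_in_distance(self, attenuation):
        probs = estimate_absorption(
            energies=(202.0,), distances=(0.0, 2.5, 10.0, 21.0),
            n_histories=20_000, seed=8, attenuation=attenuation,
        )
        vals = [probs.p2(202.0, d) for d in (0.0, 2.5, 10.0, 21.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert 0.0 < probs.p1(202.0) < 1.0

    def test_far_detector_sees_nothing(self, attenuation):
        probs = estimate_absorption(
            energies=(307.0,), distances=(1000.0,), n_histories=20_000,
            seed=3, attenuation=attenuation,
        )
        assert probs.p2(307.0, 1000.0) < 5e-4

    def test_degenerate_thin_crystal_absorbs_nothing(self, attenuation):
        probs = estimate_absorption(
            energies=(307.0,), distances=(0.0,), n_histories=2_000,
            geometry=DetectorGeometry(thickness=1e-6), seed=3,
            attenuation=attenuation,
        )
        assert probs.p1(307.0) < 1e-3

    def test_exchange_symmetry(self, attenuation):
        # photons born uniformly in C2 must be fully absorbed there with the
        # same probability as the C1 estimate (identical crystals)
        geo = DetectorGeometry(distance=2.5)
        n = 30_000
        probs = estimate_absorption(
            energies=(202.0,), distances=(2.5,), n_histories=n, seed=21,
            geometry=geo, attenuation=attenuation,
        )
        rng = np.random.default_rng(22)
        o = _uniform_in_crystal(geo, 1, n, rng)
        d = _isotropic(n, rng)
        dep, _, _ = transport_batch(o, d, np.full(n, 202.0), geo, attenuation, rng)
        p_swapped = np.mean(np.abs(dep[:, 1] - 202.0) < 1e-6)
        se = np.sqrt(2 * p_swapped * (1 - p_swapped) / n)
        assert abs(p_swapped - probs.p1(202.0)) < 3 * se

    def test_preconditions(self):
        with pytest.raises(ValueError):
            estimate_absorption(n_histories=500)

    def test_round_trip_through_frame(self, ref_absprobs):
        frame = ref_absprobs.to_frame()
        back = type(ref_absprobs).from_frame(frame)
        assert back.p1(307.0) == ref_absprobs.p1(307.0)
        assert back.p2(88.0, 21.0) == ref_absprobs.p2(88.0, 21.0)
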