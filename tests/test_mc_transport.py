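"""Monte Carlo transport: probe generation, sampling, and depth profiles."""

import numpy as np
import pytest
from scipy import stats

from mevstem import mc_transport as mc
from mevstem import xsec


def zero_rates():
    return xsec.ScatteringCoefficients(0.0, 0.0)


class TestProbeGeneration:
    def test_waist_at_entry_when_focused_on_top(self, rng):
        cfg = mc.ProbeConfig(n_electrons=50_000, focus_depth_um=0.0, seed=1)
        ens = mc.generate_probe(cfg, rng)
        assert np.std(ens.x_nm) == pytest.approx(1.0, rel=0.03)

    def test_backpropagated_envelope(self, rng):
        # waist 1 nm, alpha 1 mrad, focus 5 um deep -> entry RMS ~ 5.1 nm
        cfg = mc.ProbeConfig(n_electrons=50_000, focus_depth_um=5.0, seed=1)
        ens = mc.generate_probe(cfg, rng)
        expected = np.sqrt(1.0 + (5.0 * 1.0) ** 2)
        assert np.std(ens.x_nm) == pytest.approx(expected, rel=0.03)

    def test_seed_determinism(self):
        cfg = mc.ProbeConfig(n_electrons=100, seed=7)
        a = mc.generate_probe(cfg)
        b = mc.generate_probe(cfg)
        np.testing.assert_array_equal(a.x_nm, b.x_nm)
        np.testing.assert_array_equal(a.dirx, b.dirx)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            mc.generate_probe(mc.ProbeConfig(n_electrons=0))
        with pytest.raises(ValueError):
            mc.ProbeConfig(focus_depth_um=5.0).validate(sample_thickness_um=2.0)


class TestEventSampling:
    def test_binomial_count(self, rng):
        rates = xsec.ScatteringCoefficients(0.001, 0.0)
        events = mc.sample_event(rates, 1.0, rng, n=1_000_000)
        count = int(np.sum(events == 1))
        assert abs(count - 1000) < 3 * np.sqrt(1000)

    def test_inelastic_to_elastic_ratio(self, rng):
        k = 1e-3
        rates = xsec.ScatteringCoefficients(k, 3 * k)
        events = mc.sample_event(rates, 10.0, rng, n=500_000)
        n_el = np.sum(events == 1)
        n_inel = np.sum(events == 2)
        assert n_inel / n_el == pytest.approx(3.0, rel=0.05)

    def test_vanishing_slice(self, rng):
        rates = xsec.ScatteringCoefficients(0.001, 0.003)
        events = mc.sample_event(rates, 1e-9, rng, n=100_000)
        assert np.all(events == 0)

    def test_saturated_probability_rejected(self, rng):
        rates = xsec.ScatteringCoefficients(0.5, 0.5)
        with pytest.raises(ValueError):
            mc.sample_event(rates, 2.0, rng)


class TestAngleSampling:
    def test_empirical_median_matches_characteristic_angle(self, model_300kev, rng):
        draws = mc.sample_polar_angle(model_300kev.elastic, rng, 100_000)
        med = np.median(draws) * 1e3
        # self-consistency with the tabulated CDF, and agreement with the
        # printed oxygen characteristic angle (the hydrogen share of the ice
        # sum pulls the molecular median ~7% below the pure-oxygen value)
        assert med == pytest.approx(model_300kev.elastic.median() * 1e3, rel=0.02)
        assert med == pytest.approx(11.84, rel=0.10)

    def test_histogram_goodness_of_fit(self, model_300kev, rng):
        # chi-square against the tabulated bin masses on quantile bins
        dist = model_300kev.elastic
        draws = mc.sample_polar_angle(dist, rng, 100_000)
        qs = np.linspace(0.0, 1.0, 21)
        cum = np.concatenate(([0.0], dist.cumulative))
        bin_edges = np.interp(qs, cum, dist.edges)
        counts, _ = np.histogram(draws, bins=bin_edges)
        _, p = stats.chisquare(counts)
        assert p > 0.01

    def test_degenerate_single_bin(self, rng):
        edges = np.array([0.0, 1e-3, 2e-3, 3e-3])
        xs = np.array([0.0, 1.0, 0.0])
        dist = xsec.AngularDistribution(edges=edges, diff_xs=xs)
        draws = dist.sample(rng, 1000)
        assert np.all((draws >= 1e-3) & (draws <= 2e-3))


class TestBeamRadius:
    def _ens(self, x, y):
        n = len(x)
        return mc.ElectronEnsemble(
            x_nm=np.asarray(x, float), y_nm=np.asarray(y, float),
            dirx=np.zeros(n), diry=np.zeros(n), dirz=np.ones(n),
            n_elastic=np.zeros(n, np.int32), n_inelastic=np.zeros(n, np.int32),
            undetected=np.zeros(n, bool),
        )

    def test_common_radius_returned(self):
        phi = np.linspace(0, 2 * np.pi, 50, endpoint=False)
        ens = self._ens(3.0 * np.cos(phi), 3.0 * np.sin(phi))
        assert mc.beam_radius_68(ens) == pytest.approx(3.0)

    def test_isotropic_gaussian_rayleigh_quantile(self, rng):
        n = 200_000
        ens = self._ens(rng.normal(0, 2.0, n), rng.normal(0, 2.0, n))
        # 68% disc radius of a 2D Gaussian: sqrt(-2 ln 0.32) sigma = 1.51 sigma
        assert mc.beam_radius_68(ens) == pytest.approx(1.5096 * 2.0, rel=0.01)

    def test_tail_robustness(self, rng):
        x = rng.normal(0, 1.0, 10_001)
        ens = self._ens(x, np.zeros_like(x))
        r68 = mc.beam_radius_68(ens)
        r = np.abs(x)
        x2 = np.where(r > np.quantile(r, 0.75), x * 1e4, x)
        assert mc.beam_radius_68(self._ens(x2, np.zeros_like(x2))) == r68

    def test_empty_selection_rejected(self):
        ens = self._ens([1.0], [0.0])
        ens.undetected[:] = True
        with pytest.raises(ValueError):
            mc.beam_radius_68(ens, mode="detected_only")


@pytest.fixture(scope="module")
def thin_run_10mev(model_10mev):
    """1 um of ice at 10 MeV, full 3D, paper-standard dt."""
    probe = mc.ProbeConfig(n_electrons=5000, focus_depth_um=0.0, seed=11)
    transport = mc.TransportConfig(sample_thickness_um=1.0,
                                   geometry_mode="full_3d")
    return mc.run_transport(probe, transport, model_10mev,
                            return_ensemble=True)


class TestTransport:
    @pytest.mark.parametrize("geometry", ["planar_2d", "full_3d"])
    def test_ballistic_envelope_without_scattering(self, model_10mev, geometry):
        probe = mc.ProbeConfig(n_electrons=10_000, focus_depth_um=1.0, seed=3)
        transport = mc.TransportConfig(
            sample_thickness_um=2.0, slice_thickness_nm=5.0,
            geometry_mode=geometry, record_interval=80,
        )
        profile = mc.run_transport(probe, transport, model_10mev,
                                   rates=zero_rates())
        factor = mc.radius_quantile_factor(geometry)
        expected = factor * mc.ballistic_envelope(profile.depths_um, probe)
        np.testing.assert_allclose(profile.beam_radius_68_nm, expected, rtol=0.03)

    def test_channel_fractions_sum_to_one(self, thin_run_10mev):
        profile, _ = thin_run_10mev
        np.testing.assert_allclose(profile.channel_fractions.sum(axis=1), 1.0,
                                   atol=1e-12)

    def test_unscattered_fraction_follows_poisson_process(self, thin_run_10mev,
                                                          model_10mev, ice):
        profile, _ = thin_run_10mev
        rates = xsec.scattering_coefficient(model_10mev.totals, ice)
        t_nm = profile.depths_um * 1e3
        expected = np.exp(-rates.total_per_nm * t_nm)
        frac = profile.channel_fractions[:, 0]
        n = profile.n_electrons
        sigma = np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(frac - expected) <= 3.0 * sigma + 1e-9)

    def test_category_counts_consistent_with_histories(self, thin_run_10mev):
        profile, ens = thin_run_10mev
        counts = ens.channel_counts()
        assert counts.sum() == ens.n
        det = ~ens.undetected
        assert counts[3] == np.sum(det & (ens.n_inelastic > 0))
        np.testing.assert_allclose(profile.channel_fractions[-1],
                                   counts / ens.n, atol=1e-12)

    def test_seed_determinism(self, model_10mev):
        probe = mc.ProbeConfig(n_electrons=500, seed=9)
        transport = mc.TransportConfig(sample_thickness_um=0.2)
        p1 = mc.run_transport(probe, transport, model_10mev)
        p2 = mc.run_transport(probe, transport, model_10mev)
        np.testing.assert_array_equal(p1.beam_radius_68_nm, p2.beam_radius_68_nm)
        np.testing.assert_array_equal(p1.channel_fractions, p2.channel_fractions)

    def test_probability_guard(self, model_10mev, ice):
        rates = xsec.ScatteringCoefficients(0.3, 0.0)
        probe = mc.ProbeConfig(n_electrons=10, seed=0)
        transport = mc.TransportConfig(sample_thickness_um=0.1)
        with pytest.raises(ValueError):
            mc.run_transport(probe, transport, model_10mev, rates=rates)

    def test_single_scattering_limit_matches_input_distribution(
            self, model_300kev, rng):
        # collimated zero-emittance probe through 0.1 um: the trajectory
        # angle of single-elastic electrons is one draw of the elastic form
        probe = mc.ProbeConfig(waist_rms_size_nm=1e-9,
                               semi_convergence_mrad=1e-9,
                               n_electrons=20_000, seed=5)
        transport = mc.TransportConfig(sample_thickness_um=0.1,
                                       max_detector_angle_mrad=3000.0)
        _, ens = mc.run_transport(probe, transport, model_300kev,
                                  return_ensemble=True)
        sel = (ens.n_elastic == 1) & (ens.n_inelastic == 0)
        angles = ens.trajectory_angle_rad()[sel]
        assert angles.size > 300
        dist = model_300kev.elastic
        qs = np.linspace(0.0, 1.0, 11)
        cum = np.concatenate(([0.0], dist.cumulative))
        bin_edges = np.interp(qs, cum, dist.edges)
        counts, _ = np.histogram(angles, bins=bin_edges)
        _, p = stats.chisquare(counts)
        assert p > 0.01


class TestFreePathEquivalence:
    def test_bernoulli_vs_exponential_first_event(self, model_10mev, ice, rng):
        rates = xsec.scattering_coefficient(model_10mev.totals, ice)
        a = mc.first_scatter_depths_slices(rates, 0.5, 4000, rng)
        b = mc.first_scatter_depths_exponential(rates, 4000, rng)
        _, p = stats.ks_2samp(a, b)
        assert p > 0.01


class TestDetectorOperations:
    def test_wide_detector_collects_everything(self, thin_run_10mev):
        _, ens = thin_run_10mev
        det = mc.DetectorConfig(0.0, 3000.0)
        assert mc.detector_fraction(ens, det, 1.0) == pytest.approx(1.0)

    def test_zero_thickness_disc(self, model_10mev):
        probe = mc.ProbeConfig(n_electrons=100, seed=2)
        ens = mc.generate_probe(probe)
        det = mc.DetectorConfig(0.0, 1.0)
        assert mc.detector_fraction(ens, det, 0.0) == 1.0

    def test_10mev_standard_detector_near_unity(self, thin_run_10mev):
        # 0-10 mrad at 10 MeV: essentially all electrons collected
        _, ens = thin_run_10mev
        det = mc.DetectorConfig(0.0, 10.0)
        assert mc.detector_fraction(ens, det, 1.0) >= 0.98
        assert mc.detector_fraction(ens, det, 1.0, criterion="angle") >= 0.98

    def test_invalid_angle_range_rejected(self):
        with pytest.raises(ValueError):
            mc.DetectorConfig(5.0, 5.0)


class TestPeakIntensity:
    def _exit_ens(self, model, thickness_um, n=20_000, energy_seed=13):
        probe = mc.ProbeConfig(n_electrons=n, focus_depth_um=0.0,
                               seed=energy_seed)
        transport = mc.TransportConfig(sample_thickness_um=thickness_um,
                                       geometry_mode="planar_2d")
        _, ens = mc.run_transport(probe, transport, model,
                                  return_ensemble=True)
        return ens

    def test_zero_thickness_normalises_to_one(self, model_10mev):
        probe = mc.ProbeConfig(n_electrons=5000, seed=4)
        ens = mc.generate_probe(probe, geometry_mode="planar_2d")
        val = mc.peak_intensity_on_axis(ens, geometry_mode="planar_2d",
                                        reference=ens)
        assert val == 1.0

    def test_monotone_decrease_with_thickness(self, model_300kev):
        # at 300 keV the beam broadens fast, so the on-axis peak decays
        ref = self._exit_ens(model_300kev, 0.05)
        vals = [
            mc.peak_intensity_on_axis(self._exit_ens(model_300kev, t),
                                      geometry_mode="planar_2d", reference=ref)
            for t in (0.2, 0.5, 1.0)
        ]
        assert vals[0] > vals[1] > vals[2]

    def test_higher_energy_keeps_higher_peak(self, model_300kev, model_10mev):
        ref_lo = self._exit_ens(model_300kev, 0.05)
        ref_hi = self._exit_ens(model_10mev, 0.05)
        lo = mc.peak_intensity_on_axis(self._exit_ens(model_300kev, 1.0),
                                       geometry_mode="planar_2d",
                                       reference=ref_lo)
        hi = mc.peak_intensity_on_axis(self._exit_ens(model_10mev, 1.0),
                                       geometry_mode="planar_2d",
                                       reference=ref_hi)
        assert hi > lo
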