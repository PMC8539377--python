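"""Depth spectrum, peak location, tilt/thickness recovery, focus statistic."""

import numpy as np
import pytest

from octsim.ascan_analysis import (DepthSpectrum, bscan_focus_statistic,
                                   depth_intensity, depth_transform,
                                   estimate_thickness, estimate_tilt,
                                   locate_peak, locate_peaks,
                                   reduced_model_transform,
                                   surrogate_peak_intensity)
from octsim.beam_optics import WavenumberGrid
from octsim.interferometry import AScan, BScan, ReducedModelParams, reduced_model

TABLE_GRID = WavenumberGrid(4.7835, 4.8973, 700)
SIGMA = 0.2753  # (w0/2) sin 2θΩ for the documented regime


def reduced_ascan(theta0, sigma=SIGMA, grid=TABLE_GRID, lateral=0.0):
    p = ReducedModelParams(K=1.0, sigma=sigma, theta0=theta0)
    return AScan(grid=grid, values=reduced_model(p, grid.k0),
                 lateral_position=lateral)


class TestDepthIntensity:
    def test_zero_spectrum_transforms_to_zero(self):
        a = AScan(grid=TABLE_GRID, values=np.zeros(700))
        spec = depth_intensity(a)
        assert np.all(spec.intensity == 0)

    def test_pure_cosine_peaks_at_its_frequency(self):
        theta_star = 420.0
        a = AScan(grid=TABLE_GRID, values=np.cos(TABLE_GRID.k0 * theta_star))
        spec = depth_intensity(a)
        peak = locate_peak(spec, refine=False)
        assert abs(peak.theta0 - theta_star) <= spec.pixel

    def test_even_in_kappa(self):
        a = reduced_ascan(300.0)
        kappa = np.linspace(-500, 500, 257)
        s = np.abs(depth_transform(a, kappa)) ** 2
        assert np.allclose(s, s[::-1], rtol=1e-10)

    def test_fft_route_matches_direct_transform(self):
        a = reduced_ascan(350.0)
        spec = depth_intensity(a)
        sel = slice(100, 5000, 397)
        direct = np.abs(depth_transform(a, spec.kappa[sel])) ** 2
        assert np.allclose(spec.intensity[sel], direct, rtol=1e-8)

    def test_parseval_scaling(self):
        """Total transform energy scales with the windowed signal norm."""
        a = reduced_ascan(350.0)
        kappa_nyq = np.pi / a.grid.spacing
        n = 700 * 8
        kappa = np.linspace(-kappa_nyq, kappa_nyq, n, endpoint=False)
        s = np.abs(depth_transform(a, kappa)) ** 2
        lhs = np.sum(s) * (kappa[1] - kappa[0])
        rhs = np.sum(a.values**2) * a.grid.spacing
        assert lhs == pytest.approx(rhs, rel=1e-2)


class TestLocatePeak:
    @pytest.mark.parametrize("theta0", [100.0, 220.0, 350.0, 480.0, 600.0])
    def test_reduced_model_peak_within_one_padded_pixel(self, theta0):
        spec = depth_intensity(reduced_ascan(theta0))
        peak = locate_peak(spec)
        assert abs(peak.theta0 - theta0) <= spec.pixel

    def test_scale_invariance_of_location(self):
        a = reduced_ascan(350.0)
        b = AScan(grid=TABLE_GRID, values=7.5 * a.values)
        pa = locate_peak(depth_intensity(a))
        pb = locate_peak(depth_intensity(b))
        assert pa.theta0 == pytest.approx(pb.theta0, abs=1e-9)

    def test_two_separated_surfaces_both_recovered(self):
        th1, th2 = 300.0, 750.0
        vals = (reduced_ascan(th1).values + 0.8 * reduced_ascan(th2).values)
        spec = depth_intensity(AScan(grid=TABLE_GRID, values=vals))
        p1, p2 = locate_peaks(spec, n_peaks=2)
        assert abs(p1.theta0 - th1) <= spec.pixel
        assert abs(p2.theta0 - th2) <= spec.pixel

    def test_all_zero_spectrum_reports_no_peak(self):
        spec = depth_intensity(AScan(grid=TABLE_GRID, values=np.zeros(700)))
        with pytest.raises(ValueError, match="no peak"):
            locate_peak(spec)

    def test_dc_region_excluded(self):
        """A strong zero-frequency component must not win the peak search."""
        vals = 2.0 + reduced_ascan(350.0).values
        spec = depth_intensity(AScan(grid=TABLE_GRID, values=vals))
        peak = locate_peak(spec, exclusion_halfwidth=60.0)
        assert abs(peak.theta0 - 350.0) <= spec.pixel


class TestReducedModelTransform:
    def test_squared_modulus_reproduces_three_term_form(self):
        """|F|² equals the symmetric two-sinc expansion with the
        cos(2 k̄ Θ0) cross term."""
        p = ReducedModelParams(K=1.3, sigma=SIGMA, theta0=260.0)
        kbar, delta = TABLE_GRID.kbar, TABLE_GRID.delta
        kappa = np.linspace(150, 400, 101)
        F = reduced_model_transform(p, TABLE_GRID, kappa)

        def si(x):
            return np.sinc(x / np.pi)

        pref = (p.K * delta / np.sqrt(2 * np.pi)
                * np.exp(-(kbar * p.sigma) ** 2) * kbar**2) ** 2
        s_m = si(delta * (kappa - p.theta0))
        s_p = si(delta * (kappa + p.theta0))
        expected = pref * (s_m**2 + s_p**2
                           + 2 * s_m * s_p * np.cos(2 * kbar * p.theta0))
        assert np.allclose(np.abs(F) ** 2, expected, rtol=1e-12)

    def test_regime_ratio_q(self):
        """σ k̄ and σ are the same order in the documented regime: the
        ratio Q = (1/k̄)/σ is order one."""
        q = (1.0 / TABLE_GRID.kbar) / SIGMA
        assert 0.5 < q < 1.5

    def test_matches_direct_transform_at_peak(self):
        """Two-sinc surrogate vs brute-force band-limited transform of the
        reduced model: peak height agrees within 10%."""
        for theta0 in (150.0, 350.0, 550.0):
            p = ReducedModelParams(K=1.0, sigma=SIGMA, theta0=theta0)
            a = reduced_ascan(theta0)
            direct = float(np.abs(depth_transform(a, theta0)[0]) ** 2)
            sur = float(np.abs(reduced_model_transform(p, TABLE_GRID,
                                                       theta0)) ** 2)
            assert sur == pytest.approx(direct, rel=0.10)

    def test_surrogate_peak_intensity_matches_transform(self):
        p = ReducedModelParams(K=1.0, sigma=SIGMA, theta0=350.0)
        via_transform = float(np.abs(reduced_model_transform(
            p, TABLE_GRID, 350.0)) ** 2)
        assert surrogate_peak_intensity(p, TABLE_GRID) == pytest.approx(
            via_transform, rel=1e-10)

    def test_regime_violation_warns(self):
        p = ReducedModelParams(K=1.0, sigma=20.0, theta0=350.0)
        with pytest.warns(UserWarning, match="regime"):
            reduced_model_transform(p, TABLE_GRID, 350.0)


class TestEstimateTilt:
    def _bscan(self, depths, laterals):
        ascans = [reduced_ascan(2 * d, lateral=x)
                  for d, x in zip(depths, laterals)]
        return BScan(ascans=ascans)

    def test_flat_surface_has_zero_tilt(self):
        laterals = np.linspace(-100, 100, 9)
        b = self._bscan(np.full(9, 150.0), laterals)
        est = estimate_tilt(b)
        assert est.tilt_deg == pytest.approx(0.0, abs=1e-3)

    def test_known_slope_recovered(self):
        laterals = np.linspace(-150, 150, 11)
        slope = np.tan(np.deg2rad(2.75))
        depths = 200.0 + slope * laterals
        est = estimate_tilt(self._bscan(depths, laterals))
        assert est.tilt_deg == pytest.approx(2.75, abs=0.05)

    def test_tilt_sign_antisymmetry(self):
        laterals = np.linspace(-150, 150, 11)
        slope = np.tan(np.deg2rad(1.5))
        up = estimate_tilt(self._bscan(200.0 + slope * laterals, laterals))
        down = estimate_tilt(self._bscan(200.0 - slope * laterals, laterals))
        assert up.tilt_deg == pytest.approx(-down.tilt_deg, abs=0.02)

    def test_single_ascan_rejected(self):
        b = self._bscan([150.0], [0.0])
        with pytest.raises(ValueError):
            estimate_tilt(b)


class TestEstimateThickness:
    def test_vacuum_slab_is_half_separation(self):
        assert estimate_thickness(200.0, 500.0, 1.0, 1.0) == pytest.approx(150.0)

    def test_unordered_peaks_rejected(self):
        with pytest.raises(ValueError):
            estimate_thickness(500.0, 500.0, 1.5, 1.0)

    def test_doubling_thickness_doubles_separation(self):
        """Synthetic slabs of thickness d and 2d produce peak separations
        in ratio two (slab round-trip phase)."""
        n1, cos_t = 1.5088, 0.999
        th0 = 300.0
        seps = []
        for d in (150.0, 300.0):
            sep = 2 * n1 * d * cos_t
            vals = (reduced_ascan(th0).values
                    + 0.9 * reduced_ascan(th0 + sep).values)
            spec = depth_intensity(AScan(grid=TABLE_GRID, values=vals))
            p1, p2 = locate_peaks(spec, n_peaks=2)
            seps.append(p2.theta0 - p1.theta0)
        assert seps[1] == pytest.approx(2 * seps[0], rel=0.01)


class TestFocusStatistic:
    def test_identical_ascans_have_zero_spread(self):
        a = reduced_ascan(350.0)
        b = BScan(ascans=[AScan(TABLE_GRID, a.values.copy(), lateral_position=i)
                          for i in range(4)])
        prof = bscan_focus_statistic([b])
        assert prof.std[0] == 0.0

    def test_invariant_under_ascan_ordering(self):
        ascans = [reduced_ascan(300.0 + 10 * i, lateral=i) for i in range(5)]
        p1 = bscan_focus_statistic([BScan(ascans=ascans)])
        p2 = bscan_focus_statistic([BScan(ascans=ascans[::-1])])
        assert p1.mean[0] == pytest.approx(p2.mean[0], rel=1e-12)
        assert p1.std[0] == pytest.approx(p2.std[0], rel=1e-12)

    def test_normalization_peaks_at_one(self):
        bscans = [BScan(ascans=[reduced_ascan(350.0, sigma=s)])
                  for s in (0.3, 0.25, 0.35)]
        prof = bscan_focus_statistic(bscans)
        assert prof.normalized_mean.max() == pytest.approx(1.0)
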