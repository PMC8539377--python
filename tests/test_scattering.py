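"""Scattered fields: near-field quadrature, closed form, far field,
acceptance filtering."""

import numpy as np
import pytest

from octsim._quadrature import (truncated_gaussian_integral,
                                truncated_gaussian_integral_quad)
from octsim.beam_optics import BeamParameters
from octsim.sample_model import LayeredSample, reflect_wavevector
from octsim.scattering import (AcceptanceSet, PhaseElements,
                               acceptance_contains,
                               closed_form_surface_field,
                               closed_form_surface_field_complex,
                               far_field_wavevector, scattered_field_far,
                               scattered_field_near)

K0 = 4.8404
E3 = np.array([0.0, 0.0, 1.0])


def tilted_normal(theta_deg):
    t = np.deg2rad(theta_deg)
    return np.array([np.sin(t), 0.0, np.cos(t)])


class TestTruncatedGaussianIntegral:
    @pytest.mark.parametrize("seed", range(6))
    def test_closed_form_matches_quadrature(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(10, 300)
        d = rng.uniform(-3000, 3000)
        psi1 = rng.uniform(-500, 500)
        lo, hi = np.sort(rng.uniform(-0.5, 0.5, 2))
        cf = truncated_gaussian_integral(a + 1j * d, psi1, lo, hi)
        q = truncated_gaussian_integral_quad(a + 1j * d, psi1, lo, hi,
                                             n_nodes=6000)
        assert abs(cf - q) <= 1e-9 * abs(q)


class TestAcceptanceSet:
    def test_level_mirror_membership_is_a_disk(self):
        B = AcceptanceSet(1.5709, E3, K0)
        r = K0 * np.sin(np.deg2rad(1.5709))
        assert acceptance_contains(B, 0.999 * r, 0.0)
        assert not acceptance_contains(B, 1.001 * r, 0.0)

    def test_full_halfspace_acceptance(self):
        B = AcceptanceSet(90.0, E3, K0)
        k = np.linspace(-0.9 * K0, 0.9 * K0, 21)
        K1, K2 = np.meshgrid(k, k)
        mask = K1**2 + K2**2 < (0.95 * K0) ** 2
        assert np.all(B.contains(K1, K2)[mask])

    def test_rectangle_at_zero_tilt(self):
        B = AcceptanceSet(1.5709, E3, K0)
        lo1, hi1, lo2, hi2 = B.rectangle()
        r = K0 * np.sin(np.deg2rad(1.5709))
        assert lo1 == pytest.approx(-r) and hi1 == pytest.approx(r)
        assert lo2 == pytest.approx(-r) and hi2 == pytest.approx(r)

    def test_rectangle_approximates_exact_set_area(self):
        """Dense-grid area of the exact (elliptical) set vs the rectangle."""
        B = AcceptanceSet(1.5709, tilted_normal(2.75), K0)
        lo1, hi1, lo2, hi2 = B.rectangle()
        s1, s2 = hi1 - lo1, hi2 - lo2
        g1 = np.linspace(lo1 - s1, hi1 + s1, 1200)
        g2 = np.linspace(lo2 - s2, hi2 + s2, 1200)
        K1, K2 = np.meshgrid(g1, g2, indexing="ij")
        frac = np.mean(B.contains(K1, K2))
        area_exact = frac * (g1[-1] - g1[0]) * (g2[-1] - g2[0])
        area_rect = s1 * s2
        # the exact set is the ellipse inscribed in the rectangle, so the
        # area ratio is 4/π; the half-widths themselves agree
        assert area_rect / area_exact == pytest.approx(4.0 / np.pi, rel=0.02)

    def test_rectangle_mirrors_under_tilt_sign(self):
        Bp = AcceptanceSet(1.5709, tilted_normal(2.75), K0)
        Bm = AcceptanceSet(1.5709, tilted_normal(-2.75), K0)
        lo1, hi1, _, _ = Bp.rectangle()
        lo1m, hi1m, _, _ = Bm.rectangle()
        assert lo1m == pytest.approx(-hi1)
        assert hi1m == pytest.approx(-lo1)


class TestClosedFormSurfaceField:
    def test_focused_untilted_value(self):
        beam = BeamParameters(w0=14.15, r0=0.0)
        # d = 0 and psi1 = 0: |E| = |beta0|/(4 pi a)
        val = closed_form_surface_field(beam, K0, E3, 0.0, beta0=0.5)
        assert val == pytest.approx(0.5 / (4 * np.pi * beam.a))

    def test_magnitude_decreases_with_defocus(self):
        beam = BeamParameters(w0=14.15, r0=0.0)
        vals = [closed_form_surface_field(beam, K0, E3, x3)
                for x3 in (0.0, -200.0, -800.0)]
        assert vals[0] > vals[1] > vals[2]

    @pytest.mark.parametrize("x3,tilt", [(-50.0, 0.0), (-200.0, 1.5),
                                         (-1000.0, 2.75), (-400.0, -2.0)])
    def test_matches_gaussian_integral_evaluation(self, x3, tilt):
        """Closed form equals the (separable) Gaussian-integral value of
        the paraxial field to near machine precision."""
        beam = BeamParameters(w0=14.15, r0=-300.0)
        nu = tilted_normal(tilt)
        pe = PhaseElements.from_geometry(beam, nu, x3)
        psi2 = pe.psi2(K0)
        R = np.sqrt(35.0 / beam.a)  # e^{-aR^2} ~ 6e-16: negligible tails
        i1 = truncated_gaussian_integral(psi2, pe.psi1, -R, R)
        i2 = truncated_gaussian_integral(psi2, 0.0, -R, R)
        quad_val = i1 * i2 * np.exp(-1j * K0 * pe.psi0) / (4 * np.pi**2)
        cf = closed_form_surface_field_complex(beam, K0, nu, x3)
        assert abs(quad_val - cf) <= 1e-10 * abs(cf)
        assert abs(cf) == pytest.approx(
            closed_form_surface_field(beam, K0, nu, x3), rel=1e-12)


class TestScatteredFieldNear:
    def test_matches_closed_form_for_focused_mirror(self):
        x3 = -1000.0
        beam = BeamParameters(w0=14.15, r0=x3)
        s = LayeredSample.mirror(0.0, x3)
        near = scattered_field_near(s, beam, K0, np.zeros(3))
        cf = closed_form_surface_field(beam, K0, s.normal, x3)
        assert abs(abs(near) - cf) <= 1e-3 * cf

    def test_zero_reflectivity_gives_zero(self):
        # index-matched interface reflects nothing
        s = LayeredSample.single_interface(1.0, 0.0, -100.0)
        beam = BeamParameters(w0=14.15, r0=-100.0)
        val = scattered_field_near(s, beam, K0, np.zeros(3))
        assert abs(val) <= 1e-20

    def test_restricting_domain_shrinks_nonnegative_integrand(self):
        """With the image focus at the evaluation point the integrand is a
        positive Gaussian; nested acceptance sets order the field."""
        x3 = -400.0
        beam = BeamParameters(w0=14.15, r0=2 * x3)
        s = LayeredSample.mirror(0.0, x3)
        full = abs(scattered_field_near(s, beam, K0, np.zeros(3)))
        vals = [abs(scattered_field_near(
            s, beam, K0, np.zeros(3),
            domain=AcceptanceSet(tm, s.normal, K0))) for tm in (3.0, 1.5709)]
        assert full >= vals[0] >= vals[1] > 0

    def test_invariant_under_sliding_surface_point(self):
        """xΩ may be any point of the top boundary plane."""
        nu = tilted_normal(2.75)
        x3 = -300.0
        beam = BeamParameters(w0=14.15, r0=-300.0)
        s1 = LayeredSample.mirror(2.75, x3)
        # slide xΩ within the plane <x, nu> = const
        shift = np.array([50.0, 20.0, 0.0])
        shift = shift - (shift @ nu) * nu
        s2 = LayeredSample(nu, s1.surface_point + shift,
                           s1.boundary_offsets, (), perfect_reflector=True)
        v1 = scattered_field_near(s1, beam, K0, np.zeros(3), n_nodes=400)
        v2 = scattered_field_near(s2, beam, K0, np.zeros(3), n_nodes=400)
        assert abs(v1 - v2) <= 1e-6 * abs(v1)


class TestFarField:
    def test_axial_direction_level_mirror(self):
        k1, k2, c3 = far_field_wavevector(E3, E3, K0)
        assert (k1, k2) == (0.0, 0.0)
        assert c3 == pytest.approx(-1.0)

    def test_reflected_direction_consistency(self):
        """Reflecting the returned wavevector points along ±s."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            s_dir = rng.normal(size=3)
            s_dir[2] = abs(s_dir[2]) + 1.0
            s_dir /= np.linalg.norm(s_dir)
            nu = tilted_normal(rng.uniform(-5, 5))
            k1, k2, c3 = far_field_wavevector(s_dir, nu, K0)
            if k1**2 + k2**2 >= K0**2:
                continue
            kz = np.sqrt(K0**2 - k1**2 - k2**2)
            kr = reflect_wavevector(np.array([k1, k2, -kz]), nu)
            assert np.allclose(kr / K0, -np.sign(c3) * s_dir, atol=1e-9)

    def test_tilted_mirror_axial_wavevector_magnitude(self):
        theta = 2.75
        k1, k2, c3 = far_field_wavevector(E3, tilted_normal(theta), K0)
        assert abs(k1) == pytest.approx(K0 * np.sin(np.deg2rad(2 * theta)))
        assert k2 == 0.0

    def test_r_times_field_is_r_independent(self):
        beam = BeamParameters(w0=14.15, r0=-500.0)
        s = LayeredSample.mirror(1.0, -1000.0)
        v1 = scattered_field_far(s, beam, K0, 1e5, E3)
        v2 = scattered_field_far(s, beam, K0, 3e5, E3)
        assert abs(1e5 * abs(v1) - 3e5 * abs(v2)) <= 1e-12 * (1e5 * abs(v1))

    def test_magnitude_independent_of_focus_position(self):
        s = LayeredSample.mirror(1.0, -1000.0)
        mags = [abs(scattered_field_far(
            s, BeamParameters(w0=14.15, r0=r0), K0, 2e5, E3))
            for r0 in (0.0, -500.0, -2000.0)]
        assert np.ptp(mags) <= 1e-12 * mags[0]

    def test_grazing_direction_rejected(self):
        with pytest.raises(ValueError):
            far_field_wavevector(np.array([1.0, 0.0, 0.0]), E3, K0)


def test_near_field_converges_to_far_field():
    """At large k0 r the near-field quadrature approaches the
    stationary-phase far field (within 1%)."""
    r = 1e5
    beam = BeamParameters(w0=14.15, r0=-r)
    s = LayeredSample.mirror(0.0, -r)
    far = scattered_field_far(s, beam, K0, r, E3)
    near = scattered_field_near(s, beam, K0, np.zeros(3))
    assert abs(abs(near) - abs(far)) <= 0.01 * abs(far)
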