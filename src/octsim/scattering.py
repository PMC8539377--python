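"""Scattered field of a Gaussian beam off a tilted layered sample.

Provides the near-field plane-wave superposition (numerical quadrature over
the angular spectrum), its stationary-phase far-field approximation, the
closed-form single-surface field used for cross-validation, and the scan-lens
acceptance filtering that discards reflected plane-wave components outside
the collection cone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._quadrature import gauss_legendre
from .beam_optics import BeamParameters, spectral_amplitude, support_radius
from .sample_model import LayeredSample, combined_reflection, reflect_wavevector

__all__ = [
    "PhaseElements",
    "AcceptanceSet",
    "acceptance_contains",
    "scattered_field_near",
    "closed_form_surface_field",
    "closed_form_surface_field_complex",
    "far_field_wavevector",
    "scattered_field_far",
]


@dataclass(frozen=True)
class PhaseElements:
    """Phase elements of the paraxial single-surface field.

    psi0 = r0 - 2 νΩ,3² xΩ,3 [μm] (constant optical path),
    psi1 = 2 νΩ,1 νΩ,3 xΩ,3 [μm] (tilt-induced linear phase),
    psi2(k0) = a + (i/k0)(νΩ,3² xΩ,3 - r0/2) [μm²] (Gaussian width plus
    defocus), with focus distance d = νΩ,3² xΩ,3 - r0/2 [μm].
    """

    a: float
    psi0: float
    psi1: float
    focus_distance: float

    @classmethod
    def from_geometry(cls, beam: BeamParameters, normal, x_omega3: float):
        nu = np.asarray(normal, dtype=float)
        if abs(nu[1]) > 1e-12:
            raise ValueError("phase elements require νΩ,2 = 0")
        psi0 = beam.r0 - 2.0 * nu[2] ** 2 * x_omega3
        psi1 = 2.0 * nu[0] * nu[2] * x_omega3
        d = nu[2] ** 2 * x_omega3 - beam.r0 / 2.0
        return cls(a=beam.a, psi0=psi0, psi1=psi1, focus_distance=d)

    def psi2(self, k0: float) -> complex:
        return self.a + 1j * self.focus_distance / k0


@dataclass(frozen=True)
class AcceptanceSet:
    """Scan-lens acceptance: reflected directions within θmax of +e3.

    The exact set is the preimage of a spherical cap under specular
    reflection; for the tilt parameterization νΩ = (sin θΩ, 0, cos θΩ) it is
    well approximated by the rectangle centred at k1 = -k0 sin 2θΩ with
    half-widths ``L1 = k0 (sin 2|θΩ| - sin(2|θΩ| - θmax))`` and
    ``L2 = k0 sin θmax`` (the half-width formula is evaluated at |θΩ| so the
    window mirrors with the exact set under θΩ → -θΩ).
    """

    theta_max_deg: float
    normal: np.ndarray
    k0: float

    def __post_init__(self):
        if not (0.0 < self.theta_max_deg <= 90.0):
            raise ValueError("theta_max must be in (0, 90] degrees")
        nu = np.asarray(self.normal, dtype=float)
        object.__setattr__(self, "normal", nu)

    def contains(self, k1, k2):
        """Exact membership: the reflected direction lies in the cap."""
        k1 = np.asarray(k1, dtype=float)
        k2 = np.asarray(k2, dtype=float)
        rho2 = k1 * k1 + k2 * k2
        inside = rho2 < self.k0**2
        kz = np.sqrt(np.where(inside, self.k0**2 - rho2, np.nan))
        nu = self.normal
        dot = k1 * nu[0] + k2 * nu[1] - kz * nu[2]
        kr3 = -kz - 2.0 * dot * nu[2]
        cos_max = np.cos(np.deg2rad(self.theta_max_deg))
        return np.where(inside, kr3 >= self.k0 * cos_max - 1e-15 * self.k0, False)

    def rectangle(self):
        """(k1_lo, k1_hi, k2_lo, k2_hi) of the rectangular approximation."""
        nu = self.normal
        if abs(nu[1]) > 1e-12:
            raise ValueError("rectangular approximation requires νΩ,2 = 0")
        theta = np.arctan2(nu[0], nu[2])
        tmax = np.deg2rad(self.theta_max_deg)
        center = -self.k0 * np.sin(2.0 * theta)
        at = abs(theta)
        half1 = self.k0 * (np.sin(2.0 * at) - np.sin(2.0 * at - tmax))
        half2 = self.k0 * np.sin(tmax)
        return (center - half1, center + half1, -half2, half2)


def acceptance_contains(B: AcceptanceSet, k1, k2):
    """True iff the reflected direction of (k1, k2) lies within θmax of e3."""
    return B.contains(k1, k2)


def _phase_function(sample, beam, k0, x, k1, k2):
    """Real phase of the near-field integrand (no 2π wrapping)."""
    rho2 = k1 * k1 + k2 * k2
    kz = np.sqrt(k0 * k0 - rho2)
    nu = sample.normal
    dot = k1 * nu[0] + k2 * nu[1] - kz * nu[2]
    kr1 = k1 - 2.0 * dot * nu[0]
    kr2 = k2 - 2.0 * dot * nu[1]
    kr3 = -kz - 2.0 * dot * nu[2]
    xo = sample.surface_point
    phase = -kz * beam.r0
    phase -= (k1 - kr1) * xo[0] + (k2 - kr2) * xo[1] + (-kz - kr3) * xo[2]
    phase -= kr1 * x[0] + kr2 * x[1] + kr3 * x[2]
    return phase


def _auto_nodes(sample, beam, k0, x, bounds, cap=4000):
    """Node count per dimension from the probed phase excursion."""
    lo1, hi1, lo2, hi2 = bounds
    g1 = np.linspace(lo1, hi1, 17)
    g2 = np.linspace(lo2, hi2, 17)
    K1, K2 = np.meshgrid(g1, g2, indexing="ij")
    rho2 = K1**2 + K2**2
    keep = rho2 < (0.999 * k0) ** 2
    if not np.any(keep):
        return 24
    phi = np.where(keep, _phase_function(sample, beam, k0, x,
                                         np.where(keep, K1, 0.0),
                                         np.where(keep, K2, 0.0)), np.nan)
    span = np.nanmax(phi) - np.nanmin(phi)
    return int(min(cap, max(24, 0.9 * span + 32)))


def scattered_field_near(sample: LayeredSample, beam: BeamParameters, k0: float,
                         x, domain=None, n_nodes: int | None = None,
                         exact_mask: bool = False, mode: str = "scalar"):
    """Near-field scattered field at a point by angular-spectrum quadrature.

    Evaluates ``(1/4π²) ∫ βS ǧS e^{-i kz r0} e^{-i⟨k-kr, xΩ⟩}
    e^{-i⟨kr, x⟩} d(k1,k2)`` (scalar detection chain: the Gaussian spectral
    weight without the polarization lift) over either the effective support
    of the Gaussian weight (``domain=None``) or the rectangle of an
    :class:`AcceptanceSet`; with ``exact_mask=True`` nodes outside the exact
    acceptance set are dropped.  Returns a complex scalar.
    """
    if mode != "scalar":
        raise NotImplementedError("the detection chain is scalar")
    x = np.asarray(x, dtype=float)
    rho0 = min(support_radius(beam), 0.999 * k0)
    if domain is None:
        bounds = (-rho0, rho0, -rho0, rho0)
        B = None
    elif isinstance(domain, AcceptanceSet):
        bounds = domain.rectangle()
        B = domain if exact_mask else None
    else:
        bounds = tuple(float(b) for b in domain)
        B = None
    if n_nodes is None:
        n_nodes = _auto_nodes(sample, beam, k0, x, bounds)
    u, w = gauss_legendre(int(n_nodes))
    lo1, hi1, lo2, hi2 = bounds
    k1 = 0.5 * (hi1 + lo1) + 0.5 * (hi1 - lo1) * u
    k2 = 0.5 * (hi2 + lo2) + 0.5 * (hi2 - lo2) * u
    w1 = 0.5 * (hi1 - lo1) * w
    w2 = 0.5 * (hi2 - lo2) * w
    total = 0.0 + 0.0j
    # row-chunked to bound memory for large node counts
    chunk = max(1, int(4e6 // n_nodes))
    for start in range(0, n_nodes, chunk):
        K1 = k1[start:start + chunk, None]
        W1 = w1[start:start + chunk, None]
        K2 = k2[None, :]
        rho2 = K1 * K1 + K2 * K2
        inside = rho2 < (0.999 * k0) ** 2
        K1c = np.where(inside, K1 + 0.0 * K2, 0.0)
        K2c = np.where(inside, K2 + 0.0 * K1, 0.0)
        if B is not None:
            inside = inside & B.contains(K1c, K2c)
        beta = combined_reflection(sample, K1c, K2c, k0, mode="scalar")
        amp = spectral_amplitude(beam, K1c, K2c, k0)
        phi = _phase_function(sample, beam, k0, x, K1c, K2c)
        vals = np.where(inside, beta * amp * np.exp(1j * phi), 0.0)
        total += np.sum(vals * (W1 * w2[None, :]))
    return total / (4.0 * np.pi**2)


def closed_form_surface_field_complex(beam: BeamParameters, k0: float,
                                      normal, x_omega3: float, beta0=1.0):
    """Exact Gaussian-integral value of the paraxial single-surface field,

        E(0) = β0/(4π ψ2) e^{-ψ1²/(4 ψ2)} e^{-i k0 ψ0}.
    """
    pe = PhaseElements.from_geometry(beam, normal, x_omega3)
    psi2 = pe.psi2(k0)
    return (beta0 / (4.0 * np.pi * psi2)
            * np.exp(-pe.psi1**2 / (4.0 * psi2))
            * np.exp(-1j * k0 * pe.psi0))


def closed_form_surface_field(beam: BeamParameters, k0: float, normal,
                              x_omega3: float, beta0=1.0) -> float:
    """Closed-form magnitude of the paraxial single-surface field,

        |E(0)| = |β0| k0 / (4π √(k0²a² + d²)) ·
                 exp(-k0² ψ1² a / (4 (k0²a² + d²))).
    """
    pe = PhaseElements.from_geometry(beam, normal, x_omega3)
    a, d = pe.a, pe.focus_distance
    denom = k0 * k0 * a * a + d * d
    return (abs(beta0) * k0 / (4.0 * np.pi * np.sqrt(denom))
            * np.exp(-k0 * k0 * pe.psi1**2 * a / (4.0 * denom)))


def far_field_wavevector(s, normal, k0: float):
    """Transverse wavevector whose reflected direction is ±s.

    Returns ``(k1, k2, c3)`` with ``c3 = s3 - 2⟨νΩ, s⟩νΩ,3`` and
    ``(k1, k2) = -k0 sign(c3) (s1 - 2⟨νΩ,s⟩νΩ,1, s2 - 2⟨νΩ,s⟩νΩ,2)``.
    Grazing directions (c3 = 0) are rejected.
    """
    s = np.asarray(s, dtype=float)
    if abs(np.linalg.norm(s) - 1.0) > 1e-9:
        raise ValueError("s must be a unit vector")
    nu = np.asarray(normal, dtype=float)
    dot = float(s @ nu)
    c3 = s[2] - 2.0 * dot * nu[2]
    if abs(c3) < 1e-12:
        raise ValueError("grazing direction: c3 = 0 has no defined branch")
    sgn = np.sign(c3)
    k1 = -k0 * sgn * (s[0] - 2.0 * dot * nu[0])
    k2 = -k0 * sgn * (s[1] - 2.0 * dot * nu[1])
    return float(k1), float(k2), float(c3)


def scattered_field_far(sample: LayeredSample, beam: BeamParameters, k0: float,
                        r: float, s) -> complex:
    """Stationary-phase far field of the scattered beam at ``r·s``.

        E∞(r s) = -i k0 c3/(2π r) βS ǧS e^{-i kz r0} e^{-i⟨k-kr, xΩ⟩}
                  e^{i k0 sign(c3) r}

    evaluated at the single transverse wavevector whose reflection points
    along ``s``; ``r |E∞|`` is independent of ``r`` and of the focus
    position.
    """
    if r <= 0:
        raise ValueError("r must be positive")
    k1, k2, c3 = far_field_wavevector(s, sample.normal, k0)
    rho2 = k1 * k1 + k2 * k2
    if rho2 >= k0 * k0:
        raise ValueError("stationary wavevector is evanescent")
    kz = np.sqrt(k0 * k0 - rho2)
    nu = sample.normal
    kvec = np.array([k1, k2, -kz])
    kr = reflect_wavevector(kvec, nu)
    xo = sample.surface_point
    beta = combined_reflection(sample, k1, k2, k0, mode="scalar")
    amp = spectral_amplitude(beam, k1, k2, k0)
    phase = (-kz * beam.r0
             - (kvec - kr) @ xo
             + k0 * np.sign(c3) * r)
    return (-1j * k0 * c3 / (2.0 * np.pi * r) * beta * amp
            * np.exp(1j * phase))
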