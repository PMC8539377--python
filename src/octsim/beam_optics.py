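"""Gaussian-beam illumination as an angular spectrum of plane waves.

The incident beam is a monochromatic solution of the vector Helmholtz
equation, written as a superposition of downward-travelling plane waves
indexed by the transverse wavevector ``(k1, k2)``.  The spectral weight is a
Gaussian ``exp(-a (k1² + k2²))`` with ``a = w0²/4`` set by the beam-waist
radius ``w0``; the polarization of each plane-wave component is lifted from
the transverse polarization vector ``p`` so that the field is divergence
free.  Lengths are micrometres, wavenumbers inverse micrometres; angles are
degrees at every public interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._quadrature import gauss_legendre

__all__ = [
    "BeamParameters",
    "WavenumberGrid",
    "spectral_amplitude",
    "polarization_lift",
    "incident_field",
    "support_radius",
]

#: relative level of the Gaussian spectral weight below which the angular
#: spectrum is treated as zero (effective-support truncation of the
#: compactly supported amplitude).
SUPPORT_TOL = 1e-8


def _check_finite(name, *values):
    for v in values:
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite value in {name}")


@dataclass(frozen=True)
class BeamParameters:
    """Gaussian beam: waist radius, focal plane, polarization, amplitude.

    Attributes
    ----------
    w0 : float
        Waist (1/e field) radius at the focus [μm].
    r0 : float
        Third coordinate of the focal plane [μm]; the beam propagates toward
        negative x3, the sample sits at x3 < 0.
    polarization : tuple
        Real transverse polarization vector (p1, p2); the third component is
        zero by construction.
    amplitude : complex
        Overall complex scale of the spectral amplitude (arbitrary units; all
        data comparisons are made after peak normalization).
    """

    w0: float
    r0: float = 0.0
    polarization: tuple = (1.0, 0.0)
    amplitude: complex = 1.0 + 0.0j

    def __post_init__(self):
        _check_finite("BeamParameters", self.w0, self.r0, *self.polarization)
        if self.w0 <= 0:
            raise ValueError("waist radius w0 must be positive")
        if len(self.polarization) == 3 and self.polarization[2] != 0:
            raise ValueError("polarization must lie in the transverse plane")

    @property
    def a(self) -> float:
        """Spectral half-width a = w0²/4 [μm²]."""
        return self.w0 * self.w0 / 4.0

    @property
    def p(self) -> np.ndarray:
        """Polarization as a real 3-vector with vanishing third component."""
        p1, p2 = self.polarization[0], self.polarization[1]
        return np.array([p1, p2, 0.0])


@dataclass(frozen=True)
class WavenumberGrid:
    """Closed, equally spaced wavenumber sweep [kmin, kmax] with J samples."""

    kmin: float
    kmax: float
    count: int = 700

    def __post_init__(self):
        _check_finite("WavenumberGrid", self.kmin, self.kmax)
        if not (0 < self.kmin < self.kmax):
            raise ValueError("need 0 < kmin < kmax")
        if self.count < 2:
            raise ValueError("grid needs at least two samples")

    @property
    def kbar(self) -> float:
        """Central wavenumber (kmax + kmin)/2 [μm⁻¹]."""
        return 0.5 * (self.kmax + self.kmin)

    @property
    def delta(self) -> float:
        """Half bandwidth (kmax - kmin)/2 [μm⁻¹]."""
        return 0.5 * (self.kmax - self.kmin)

    @property
    def spacing(self) -> float:
        return (self.kmax - self.kmin) / (self.count - 1)

    @property
    def k0(self) -> np.ndarray:
        """The sweep samples, closed at both ends."""
        return np.linspace(self.kmin, self.kmax, self.count)


def support_radius(beam: BeamParameters, tol: float = SUPPORT_TOL) -> float:
    """Radius ρ0 of the disk where the Gaussian weight exceeds ``tol``·peak."""
    return float(np.sqrt(np.log(1.0 / tol) / beam.a))


def spectral_amplitude(beam: BeamParameters, k1, k2, k0):
    """Gaussian angular-spectrum amplitude, truncated to propagating modes.

    Returns ``amplitude * exp(-a (k1² + k2²))`` for ``k1² + k2² < k0²`` and
    exactly 0 outside (the amplitude is compactly supported inside the
    propagating disk).
    """
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    _check_finite("spectral_amplitude", k1, k2, k0)
    if np.any(np.asarray(k0) <= 0):
        raise ValueError("k0 must be positive")
    rho2 = k1 * k1 + k2 * k2
    env = beam.amplitude * np.exp(-beam.a * rho2)
    return np.where(rho2 < k0 * k0, env, 0.0 * env)


def polarization_lift(p, k1, k2, k0, branch: int = +1):
    """Lift a transverse polarization to the plane wave with wavevector
    ``(k1, k2, ∓kz)``.

    Returns ``(1/2)(p1, p2, ±(p1 k1 + p2 k2)/kz)`` with
    ``kz = sqrt(k0² - k1² - k2²)``; the result is orthogonal to the
    wavevector ``(k1, k2, ∓kz)``, so each component is divergence free.
    Scalar and array ``(k1, k2)`` are supported; the vector index is last.
    """
    if branch not in (+1, -1):
        raise ValueError("branch must be +1 or -1")
    p = np.asarray(p, dtype=float)
    if p.shape != (3,) or p[2] != 0.0:
        raise ValueError("polarization must be a 3-vector with zero third component")
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    rho2 = k1 * k1 + k2 * k2
    if np.any(rho2 >= k0 * k0):
        raise ValueError("evanescent component: k1² + k2² must be < k0²")
    kz = np.sqrt(k0 * k0 - rho2)
    third = branch * (p[0] * k1 + p[1] * k2) / kz
    out = np.stack(
        [np.broadcast_to(0.5 * p[0], third.shape).copy(),
         np.broadcast_to(0.5 * p[1], third.shape).copy(),
         0.5 * third],
        axis=-1,
    )
    return out


def incident_field(beam: BeamParameters, k0, x, n_nodes: int | None = None):
    """Evaluate the incident (downward) beam at a point by quadrature.

    Computes ``(1/4π²) ∫ ǧ(k1,k2) e^{-i(k1 x1 + k2 x2)}
    e^{-i kz (r0 - x3)} d(k1,k2)`` with ``ǧ`` the lifted Gaussian spectrum,
    over the effective support disk, using a tensor-product Gauss-Legendre
    rule on the enclosing square.  Returns a complex 3-vector.

    The node count is chosen from a bound on the phase excursion of the
    integrand (kz curvature times the focus distance plus the transverse
    oscillation); pass ``n_nodes`` to override.
    """
    x = np.asarray(x, dtype=float)
    _check_finite("incident_field", x, k0)
    if k0 <= 0:
        raise ValueError("k0 must be positive")
    rho0 = min(support_radius(beam), 0.999 * k0)
    if n_nodes is None:
        # phase bound: transverse oscillation rho0*(|x1|+|x2|) plus the
        # curvature of kz over the support acting on |r0 - x3|
        excursion = rho0 * (abs(x[0]) + abs(x[1]))
        excursion += (rho0 * rho0 / (2.0 * k0)) * abs(beam.r0 - x[2])
        n_nodes = int(min(4000, max(48, 1.2 * excursion + 32)))
    u, w = gauss_legendre(n_nodes)
    kk = rho0 * u
    ww = rho0 * w
    K1, K2 = np.meshgrid(kk, kk, indexing="ij")
    W = np.outer(ww, ww)
    rho2 = K1 * K1 + K2 * K2
    inside = rho2 < k0 * k0
    kz = np.sqrt(np.where(inside, k0 * k0 - rho2, 1.0))
    env = beam.amplitude * np.exp(-beam.a * rho2)
    phase = np.exp(-1j * (K1 * x[0] + K2 * x[1]) - 1j * kz * (beam.r0 - x[2]))
    scal = np.where(inside, env * phase * W, 0.0)
    p = beam.p
    third = (p[0] * K1 + p[1] * K2) / kz
    field = np.empty(3, dtype=complex)
    field[0] = 0.5 * p[0] * scal.sum()
    field[1] = 0.5 * p[1] * scal.sum()
    field[2] = 0.5 * np.sum(scal * third)
    return field / (4.0 * np.pi**2)
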