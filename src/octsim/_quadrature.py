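"""Shared quadrature helpers for oscillatory Gaussian integrals.

The integrals that appear throughout the forward model are of the form

    ∫ exp(-psi2*k**2 - 1j*psi1*k) dk

with Re(psi2) > 0.  The imaginary part of ``psi2`` (defocus) and ``psi1``
(surface tilt times depth) can make the integrand strongly oscillatory, so
both a numerically stable closed form (complex error function via the
Faddeeva function) and a node-adaptive Gauss-Legendre rule are provided.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.special import wofz

__all__ = [
    "gauss_legendre",
    "truncated_gaussian_integral",
    "truncated_gaussian_integral_quad",
]

_SQRT_PI = np.sqrt(np.pi)


@lru_cache(maxsize=64)
def gauss_legendre(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Nodes and weights of the ``n``-point Gauss-Legendre rule on [-1, 1]."""
    if n < 1:
        raise ValueError("node count must be positive")
    x, w = np.polynomial.legendre.leggauss(int(n))
    return x, w


def _stable_erf_term(psi1, psi2, sqrt_psi2, b):
    """exp(-psi1^2/(4 psi2)) * erf(sqrt(psi2)*b + i*psi1/(2*sqrt(psi2))),
    evaluated without overflow.

    Uses erf(z) = s*(1 - exp(-z^2) w(i s z)) with s = sign(Re z); the products
    of exponentials reduce to exp(-psi2*b^2 - i*psi1*b), which is bounded
    because Re(psi2) > 0, and Re(psi1^2/(4 psi2)) >= 0 bounds the prefactor.
    """
    z = sqrt_psi2 * b + 1j * psi1 / (2.0 * sqrt_psi2)
    s = np.where(np.real(z) >= 0.0, 1.0, -1.0)
    pref = np.exp(-(psi1**2) / (4.0 * psi2))
    tail = np.exp(-psi2 * b**2 - 1j * psi1 * b) * wofz(1j * s * z)
    return s * (pref - tail)


def truncated_gaussian_integral(psi2, psi1, lo, hi):
    """Closed form of ``∫_lo^hi exp(-psi2 k² - i psi1 k) dk`` (Re psi2 > 0).

    All arguments broadcast.  Stable for arbitrarily large |Im psi2| and
    |psi1| (highly defocused / strongly tilted configurations).
    """
    psi2 = np.asarray(psi2, dtype=complex)
    psi1 = np.asarray(psi1, dtype=complex)
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    if np.any(np.real(psi2) <= 0):
        raise ValueError("Re(psi2) must be positive")
    sqrt_psi2 = np.sqrt(psi2)  # principal branch, Re > 0 since |arg psi2| < pi/2
    upper = _stable_erf_term(psi1, psi2, sqrt_psi2, hi)
    lower = _stable_erf_term(psi1, psi2, sqrt_psi2, lo)
    return _SQRT_PI / (2.0 * sqrt_psi2) * (upper - lower)


def truncated_gaussian_integral_quad(psi2, psi1, lo, hi, n_nodes=None):
    """Gauss-Legendre evaluation of the same integral (independent route).

    The node count defaults to a Nyquist-type bound on the total phase
    excursion ``|Im psi2| max(lo², hi²) + |psi1| (hi - lo)``.
    """
    psi2 = complex(psi2)
    psi1 = complex(psi1)
    lo = float(lo)
    hi = float(hi)
    if n_nodes is None:
        excursion = abs(psi2.imag) * max(lo * lo, hi * hi) + abs(psi1) * (hi - lo)
        n_nodes = int(min(8000, max(80, 1.5 * excursion + 40)))
    x, w = gauss_legendre(int(n_nodes))
    half = 0.5 * (hi - lo)
    mid = 0.5 * (hi + lo)
    k = mid + half * x
    vals = np.exp(-psi2 * k**2 - 1j * psi1 * k)
    return half * np.sum(w * vals)
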