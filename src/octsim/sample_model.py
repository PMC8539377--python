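"""Tilted layered sample and plane-wave reflection coefficients.

A sample is locally a stack of parallel planar layers with unit normal νΩ
(tilted against the beam axis by θΩ via νΩ = (sin θΩ, 0, cos θΩ)).  For each
plane-wave component of the incident beam the reflected wavevector is the
specular image ``k - 2⟨k, νΩ⟩ νΩ`` and the reflected amplitude follows from
the Fresnel coefficients of the interface stack.  A perfect mirror is a flag
(formally an infinite refractive index) rather than a large finite index.

Sign convention: normal-incidence reflection off a denser medium has a
negative s-polarization amplitude; detection uses magnitudes and relative
phases only, so the convention never leaks into observables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LayeredSample",
    "ReflectionCoefficients",
    "reflect_wavevector",
    "fresnel_interface",
    "slab_reflection",
    "combined_reflection",
    "reflect_amplitude",
]

_UNIT_TOL = 1e-12


@dataclass(frozen=True)
class ReflectionCoefficients:
    """Amplitude reflection coefficients of one interface.

    ``beta_par`` is the transverse-magnetic (p, ∥) and ``beta_perp`` the
    transverse-electric (s, ⊥) coefficient; ``cos_theta_t`` is the cosine of
    the Snell transmission angle (complex beyond a critical angle).
    """

    beta_par: complex
    beta_perp: complex
    cos_theta_t: complex


@dataclass(frozen=True)
class LayeredSample:
    """Layered sample description.

    Attributes
    ----------
    normal : array
        Unit outward normal νΩ with νΩ,3 > 0.
    surface_point : array
        A point xΩ on the top boundary [μm] (so ⟨xΩ, νΩ⟩ is the first
        boundary offset).
    boundary_offsets : tuple
        Strictly increasing offsets a_j of the layer boundaries along νΩ
        [μm]; one entry for a single surface, two for a slab.
    refractive_indices : tuple
        Refractive index of each layer below the corresponding boundary
        (all ≥ 1); empty for a perfect reflector.
    perfect_reflector : bool
        Mirror flag; mutually exclusive with finite indices.
    """

    normal: np.ndarray
    surface_point: np.ndarray
    boundary_offsets: tuple = ()
    refractive_indices: tuple = ()
    perfect_reflector: bool = False

    def __post_init__(self):
        nu = np.asarray(self.normal, dtype=float)
        if nu.shape != (3,) or abs(np.linalg.norm(nu) - 1.0) > 1e-9:
            raise ValueError("normal must be a unit 3-vector")
        if nu[2] <= 0:
            raise ValueError("normal must have positive third component")
        object.__setattr__(self, "normal", nu)
        xo = np.asarray(self.surface_point, dtype=float)
        if xo.shape != (3,):
            raise ValueError("surface_point must be a 3-vector")
        object.__setattr__(self, "surface_point", xo)
        offs = tuple(float(a) for a in self.boundary_offsets)
        if any(b <= a for a, b in zip(offs, offs[1:])):
            raise ValueError("boundary offsets must be strictly increasing")
        object.__setattr__(self, "boundary_offsets", offs)
        idx = tuple(float(n) for n in self.refractive_indices)
        if self.perfect_reflector:
            if idx:
                raise ValueError("perfect reflector excludes finite indices")
        else:
            if len(idx) != len(offs):
                raise ValueError("need one refractive index per boundary layer")
            if any(n < 1.0 for n in idx):
                raise ValueError("refractive indices must be >= 1")
        object.__setattr__(self, "refractive_indices", idx)

    # -- constructors ------------------------------------------------------
    @staticmethod
    def _tilt_normal(tilt_deg: float) -> np.ndarray:
        t = np.deg2rad(tilt_deg)
        return np.array([np.sin(t), 0.0, np.cos(t)])

    @classmethod
    def mirror(cls, tilt_deg: float = 0.0, surface_x3: float = 0.0):
        """Perfectly reflecting plane, tilted by ``tilt_deg`` about x2."""
        nu = cls._tilt_normal(tilt_deg)
        xo = np.array([0.0, 0.0, surface_x3])
        return cls(nu, xo, (float(xo @ nu),), (), perfect_reflector=True)

    @classmethod
    def single_interface(cls, n1: float, tilt_deg: float = 0.0,
                         surface_x3: float = 0.0):
        """Half space of index ``n1`` below one tilted boundary."""
        nu = cls._tilt_normal(tilt_deg)
        xo = np.array([0.0, 0.0, surface_x3])
        return cls(nu, xo, (float(xo @ nu),), (float(n1),))

    @classmethod
    def slab(cls, n1: float, thickness: float, tilt_deg: float = 0.0,
             surface_x3: float = 0.0):
        """Plane-parallel slab (e.g. a coverglass) of index ``n1``.

        The slab extends from the top boundary downward (along -νΩ) by
        ``thickness``; the medium below is again vacuum.
        """
        if thickness <= 0:
            raise ValueError("thickness must be positive")
        nu = cls._tilt_normal(tilt_deg)
        xo = np.array([0.0, 0.0, surface_x3])
        a1 = float(xo @ nu)
        # offsets ordered top boundary first; layer j sits below boundary j
        return cls(nu, xo, (a1, a1 + float(thickness)), (float(n1), 1.0))

    # -- derived -----------------------------------------------------------
    @property
    def tilt_deg(self) -> float:
        """Tilt angle θΩ [deg] for normals of the form (sin θ, 0, cos θ)."""
        return float(np.rad2deg(np.arctan2(self.normal[0], self.normal[2])))

    @property
    def thickness(self) -> float | None:
        """Slab thickness a2 - a1 [μm], if two boundaries are present."""
        if len(self.boundary_offsets) == 2:
            return self.boundary_offsets[1] - self.boundary_offsets[0]
        return None

    @property
    def top_index(self) -> float:
        """Refractive index of the layer below the top boundary."""
        if self.perfect_reflector:
            return np.inf
        return self.refractive_indices[0]


def reflect_wavevector(k, normal):
    """Specular reflection ``Φ(k) = k - 2 ⟨k, νΩ⟩ νΩ`` (an involution).

    ``k`` may be a 3-vector or an array with the vector index last.
    """
    nu = np.asarray(normal, dtype=float)
    if abs(np.linalg.norm(nu) - 1.0) > _UNIT_TOL:
        raise ValueError("normal must be a unit vector (tolerance 1e-12)")
    k = np.asarray(k, dtype=float if np.isrealobj(k) else complex)
    dot = k @ nu
    return k - 2.0 * dot[..., None] * nu if k.ndim > 1 else k - 2.0 * dot * nu


def fresnel_interface(n_in, n_out, cos_theta_i) -> ReflectionCoefficients:
    """Fresnel amplitude coefficients for incidence from ``n_in`` onto
    ``n_out`` with incidence-angle cosine ``cos_theta_i``.

    ``n_out = inf`` (or ``perfect_reflector``) gives the mirror limit with
    unit-magnitude coefficients.  Arrays broadcast through ``cos_theta_i``.
    """
    c_i = np.asarray(cos_theta_i, dtype=float)
    if np.any(c_i <= 0) or np.any(c_i > 1.0 + 1e-12):
        raise ValueError("need 0 < cos_theta_i <= 1")
    c_i = np.minimum(c_i, 1.0)
    if np.isinf(n_out):
        one = np.ones_like(c_i)
        return ReflectionCoefficients(
            beta_par=+one + 0j, beta_perp=-one + 0j, cos_theta_t=one + 0j)
    if n_in < 1 or n_out < 1:
        raise ValueError("refractive indices must be >= 1")
    sin2_t = (n_in / n_out) ** 2 * (1.0 - c_i * c_i)
    c_t = np.sqrt((1.0 - sin2_t).astype(complex))
    r_s = (n_in * c_i - n_out * c_t) / (n_in * c_i + n_out * c_t)
    r_p = (n_out * c_i - n_in * c_t) / (n_out * c_i + n_in * c_t)
    return ReflectionCoefficients(beta_par=r_p, beta_perp=r_s, cos_theta_t=c_t)


def slab_reflection(beta0, n1, thickness_d, k0, cos_theta_t):
    """First-order two-boundary reflection coefficient of a slab,

        β0 - β0 (1 - β0²) exp(-i k0 2 n1 d cos θt),

    i.e. the top-boundary reflection plus the once-transmitted reflection
    off the back boundary with the slab round-trip phase.
    """
    if np.any(np.asarray(thickness_d) < 0):
        raise ValueError("thickness must be non-negative")
    beta0 = np.asarray(beta0, dtype=complex)
    phase = np.exp(-1j * 2.0 * k0 * n1 * np.asarray(thickness_d)
                   * np.asarray(cos_theta_t, dtype=complex))
    return beta0 - beta0 * (1.0 - beta0**2) * phase


def _incidence_cosine(sample: LayeredSample, k1, k2, k0):
    """cos θi = |⟨k, νΩ⟩| / k0 for the downward wavevector (k1, k2, -kz)."""
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    rho2 = k1 * k1 + k2 * k2
    if np.any(rho2 >= k0 * k0):
        raise ValueError("evanescent component: k1² + k2² must be < k0²")
    kz = np.sqrt(k0 * k0 - rho2)
    nu = sample.normal
    return np.abs(k1 * nu[0] + k2 * nu[1] - kz * nu[2]) / k0


def combined_reflection(sample: LayeredSample, k1, k2, k0, mode: str = "scalar"):
    """Reflection coefficient of the sample for one plane-wave component.

    ``mode='scalar'`` (the canonical detection pathway): 1 for a perfect
    reflector, the s-polarization Fresnel coefficient for a single boundary
    and the first-order slab formula for two boundaries.  ``mode='te'`` /
    ``'tm'`` select the respective polarization's coefficient instead.
    """
    if mode not in ("scalar", "te", "tm"):
        raise ValueError("mode must be scalar, te or tm")
    n_bound = len(sample.boundary_offsets)
    if n_bound > 2:
        raise NotImplementedError("more than two boundaries unsupported")
    if sample.perfect_reflector:
        shape = np.broadcast(np.asarray(k1), np.asarray(k2)).shape
        one = np.ones(shape, dtype=complex) if shape else complex(1.0)
        if mode == "scalar":
            return one
        coeff = fresnel_interface(1.0, np.inf, _incidence_cosine(sample, k1, k2, k0))
        return coeff.beta_perp if mode == "te" else coeff.beta_par
    c_i = _incidence_cosine(sample, k1, k2, k0)
    n1 = sample.top_index
    coeff = fresnel_interface(1.0, n1, c_i)
    beta0 = coeff.beta_perp if mode in ("scalar", "te") else coeff.beta_par
    if n_bound == 1:
        return beta0
    return slab_reflection(beta0, n1, sample.thickness, k0, coeff.cos_theta_t)


def reflect_amplitude(sample: LayeredSample, alpha, k1: float, k2: float,
                      k0: float) -> np.ndarray:
    """Polarized reflection of one plane-wave amplitude (3-vector).

    Decomposes the incident amplitude ``alpha`` into its transverse
    electric (s, perpendicular to the plane of incidence) and transverse
    magnetic (p) parts, applies the respective top-interface Fresnel
    coefficient of the sample, and rebuilds the reflected amplitude in the
    reflected-wave TM basis.  The result is orthogonal to the reflected
    wavevector.  At normal incidence the plane of incidence degenerates and
    an arbitrary transverse basis is used (both coefficients then act
    identically up to the convention sign).
    """
    alpha = np.asarray(alpha, dtype=complex)
    rho2 = k1 * k1 + k2 * k2
    if rho2 >= k0 * k0:
        raise ValueError("evanescent component: k1² + k2² must be < k0²")
    kz = np.sqrt(k0 * k0 - rho2)
    k_hat = np.array([k1, k2, -kz]) / k0
    nu = sample.normal
    kr_hat = reflect_wavevector(k_hat, nu)
    cross = np.cross(k_hat, nu)
    norm = np.linalg.norm(cross)
    if norm < 1e-12:
        # normal incidence: plane of incidence undefined
        e_s = np.array([1.0, 0.0, 0.0])
        if abs(k_hat[0]) > 0.9:
            e_s = np.array([0.0, 1.0, 0.0])
        e_s = e_s - (e_s @ k_hat) * k_hat
        e_s /= np.linalg.norm(e_s)
    else:
        e_s = cross / norm
    e_p_in = np.cross(e_s, k_hat)
    e_p_out = np.cross(e_s, kr_hat)
    cos_i = _incidence_cosine(sample, k1, k2, k0)
    if sample.perfect_reflector:
        coeff = fresnel_interface(1.0, np.inf, cos_i)
        b_perp, b_par = coeff.beta_perp, coeff.beta_par
    else:
        n1 = sample.top_index
        coeff = fresnel_interface(1.0, n1, cos_i)
        b_perp, b_par = coeff.beta_perp, coeff.beta_par
        if len(sample.boundary_offsets) == 2:
            b_perp = slab_reflection(b_perp, n1, sample.thickness, k0,
                                     coeff.cos_theta_t)
            b_par = slab_reflection(b_par, n1, sample.thickness, k0,
                                    coeff.cos_theta_t)
    lam_te = alpha @ e_s
    lam_tm = alpha @ e_p_in
    return b_perp * lam_te * e_s + b_par * lam_tm * e_p_out
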