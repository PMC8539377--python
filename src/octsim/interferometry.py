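"""Reference arm, dual-balanced detection and A-scan spectrum simulation.

An A-scan is the dual-balance detector (DBD) output over one wavenumber
sweep: the cross-correlation ``M(k0) = -Re⟨ES, conj ER⟩`` between the
acceptance-filtered scattered sample field and the reference field reflected
off the reference mirror.  For a single tilted surface the spectrum reduces
to the oscillation ``K k0² e^{-k0²σ²} cos(k0 Θ0)`` whose frequency Θ0
encodes the optical path difference to the zero-delay plane.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._quadrature import gauss_legendre
from .beam_optics import BeamParameters, WavenumberGrid
from .sample_model import LayeredSample
from .scattering import AcceptanceSet, _auto_nodes

__all__ = [
    "SystemGeometry",
    "AScan",
    "BScan",
    "ReducedModelParams",
    "reference_field",
    "dbd_signal",
    "simulate_ascan",
    "reduced_model",
    "stationary_depth",
]


@dataclass(frozen=True)
class SystemGeometry:
    """Detection geometry of the interferometer.

    Attributes
    ----------
    r_detector : float
        Distance rD of the detection point xD = rD e3 above the sample
        region [μm].  The model detects the field at a single point; keeping
        this point close to the sample retains the through-focus sensitivity
        that a detector deep in the far field would not see.
    x_ref_mirror : float
        Reference-mirror coordinate xM,3 [μm]; sets the zero-delay plane.
    theta_max_deg : float
        Scan-lens acceptance half-angle [deg].
    tau : complex
        Splitter/loss factor applied to the detected intensity scale.
    reference_amplitude : complex
        Product βR(0,0)·ǧR(0,0) of the reference mirror reflectivity and
        the reference beam's on-axis spectral amplitude.
    """

    r_detector: float = 500.0
    x_ref_mirror: float = 0.0
    theta_max_deg: float = 1.5709
    tau: complex = 1.0 + 0.0j
    reference_amplitude: complex = 1.0 + 0.0j

    def __post_init__(self):
        if self.r_detector <= 0:
            raise ValueError("detector distance must be positive")
        if not (0.0 < self.theta_max_deg <= 90.0):
            raise ValueError("theta_max must be in (0, 90] degrees")


@dataclass
class AScan:
    """One wavenumber sweep: real DBD signal values on a closed k0 grid."""

    grid: WavenumberGrid
    values: np.ndarray
    lateral_position: float = 0.0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.grid.count,):
            raise ValueError("values length must equal the grid count")
        if not np.all(np.isfinite(v)):
            raise ValueError("A-scan values must be finite")
        self.values = v


@dataclass
class BScan:
    """A lateral line of A-scans."""

    ascans: list

    def __post_init__(self):
        if not self.ascans:
            raise ValueError("B-scan must contain at least one A-scan")

    @property
    def lateral_positions(self) -> np.ndarray:
        return np.array([a.lateral_position for a in self.ascans])


@dataclass(frozen=True)
class ReducedModelParams:
    """Parameters of the reduced single-surface spectrum model.

    K is an overall amplitude, sigma = (w0/2) sin 2θΩ [μm] the tilt-induced
    Gaussian decay and theta0 = ψ/k0 [μm] the fringe frequency (optical
    path offset from zero delay).
    """

    K: float
    sigma: float
    theta0: float

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def reference_field(geometry: SystemGeometry, beam_ref: BeamParameters, k0):
    """Far-field reference field at the detection point,

        ER = -i k0/(2π rD) βR ǧR e^{-i k0 (r0 + rD - 2 xM,3)}.
    """
    k0 = np.asarray(k0, dtype=float)
    rd = geometry.r_detector
    phase = np.exp(-1j * k0 * (beam_ref.r0 + rd - 2.0 * geometry.x_ref_mirror))
    return -1j * k0 / (2.0 * np.pi * rd) * geometry.reference_amplitude * phase


def dbd_signal(Es, Er):
    """Dual-balance detector output ``-Re(Es conj(Er))``.

    Equals ``(|F1|² - |F2|²)/2`` for the two fiber fields
    F1 = (Es - Er)/√2 and F2 = (i Es + i Er)/√2.
    """
    return -np.real(np.asarray(Es) * np.conj(np.asarray(Er)))


def stationary_depth(sample_x3: float, tilt_deg: float, beam_r0: float,
                     x_ref3: float) -> float:
    """Fringe frequency Θ0 [μm] predicted by the stationary-phase point.

    For a top surface at xΩ,3 with tilt θΩ, focus r0 and reference mirror
    xM,3 the detected oscillation frequency is

        Θ0 = -(1 + cos 2θΩ) xΩ,3 - (1 - cos 2θΩ) r0 + 2 xM,3,

    independent of the detector distance (the detector-path phase vanishes
    at the stationary wavevector).  Reduces to 2(xM,3 - xΩ,3) for θΩ = 0.
    """
    c = np.cos(2.0 * np.deg2rad(tilt_deg))
    return -(1.0 + c) * sample_x3 - (1.0 - c) * beam_r0 + 2.0 * x_ref3


def _scaled_integrand(sample, beam, geometry, n_nodes):
    """Wavenumber-independent pieces of the acceptance-window integrand.

    With the window edges proportional to k0 and nodes written as
    (k1, k2) = k0 (u, v), every phase term of the detected-field integrand
    is exactly linear in k0 and the Gaussian weight is exp(-a k0² ρ²) with
    ρ² = u² + v².  Returns the quadrature weights combined with the
    k0-independent reflection amplitude, the scaled phase Ψ (so the phase
    is k0·Ψ), and ρ², one triple per reflection channel (two channels for
    a slab: top boundary and first-order back reflection).
    """
    B = AcceptanceSet(geometry.theta_max_deg, sample.normal, 1.0)
    lo1, hi1, lo2, hi2 = B.rectangle()
    u, w = gauss_legendre(int(n_nodes))
    U = (0.5 * (hi1 + lo1) + 0.5 * (hi1 - lo1) * u)[:, None]
    V = (0.5 * (hi2 - lo2) * u)[None, :]
    W = np.outer(w, w) * (0.25 * (hi1 - lo1) * (hi2 - lo2))
    rho2 = U * U + V * V
    inside = rho2 < 0.999**2
    kz = np.sqrt(np.where(inside, 1.0 - rho2, 1.0))
    nu = sample.normal
    dot = U * nu[0] + V * nu[1] - kz * nu[2]
    kr1 = U - 2.0 * dot * nu[0]
    kr2 = V - 2.0 * dot * nu[1]
    kr3 = -kz - 2.0 * dot * nu[2]
    xo = sample.surface_point
    psi = -kz * beam.r0
    psi -= (U - kr1) * xo[0] + (V - kr2) * xo[1] + (-kz - kr3) * xo[2]
    psi -= kr3 * geometry.r_detector
    W = np.where(inside, W, 0.0)
    if sample.perfect_reflector:
        return [(W.astype(complex), psi, rho2)]
    from .sample_model import fresnel_interface
    cos_i = np.abs(dot)
    coeff = fresnel_interface(1.0, sample.top_index, np.where(inside, cos_i, 1.0))
    beta0 = coeff.beta_perp
    if len(sample.boundary_offsets) == 1:
        return [(W * beta0, psi, rho2)]
    # slab: top reflection plus back-boundary term with the round-trip
    # phase -k0 · 2 n1 d cos θt folded into the scaled phase
    s = 2.0 * sample.top_index * sample.thickness * np.real(coeff.cos_theta_t)
    return [(W * beta0, psi, rho2),
            (-W * beta0 * (1.0 - beta0**2), psi - s, rho2)]


def scattered_field_sweep(sample: LayeredSample, beam: BeamParameters,
                          geometry: SystemGeometry, grid: WavenumberGrid,
                          n_nodes: int | None = None) -> np.ndarray:
    """Acceptance-filtered scattered field at xD = rD e3 for the whole sweep.

    Evaluates the rectangular-window quadrature for every k0 on the grid.
    Because the scaled phase Ψ and amplitude are k0-independent, the sweep
    is advanced with exact multiplicative recurrences
    (e^{i k0 Ψ} and the quadratic-exponent Gaussian factor), which costs a
    few complex multiplies per node and wavenumber instead of fresh
    exponentials.
    """
    xd = np.array([0.0, 0.0, geometry.r_detector])
    if n_nodes is None:
        B_mid = AcceptanceSet(geometry.theta_max_deg, sample.normal, grid.kbar)
        n_nodes = _auto_nodes(sample, beam, grid.kbar, xd, B_mid.rectangle(),
                              cap=512)
    channels = _scaled_integrand(sample, beam, geometry, int(n_nodes))
    kmin, h, J = grid.kmin, grid.spacing, grid.count
    a = beam.a
    Es = np.zeros(J, dtype=complex)
    for amp, psi, rho2 in channels:
        c = a * rho2 * h * h  # quadratic-exponent step
        cur = amp * np.exp(-a * kmin * kmin * rho2 + 1j * kmin * psi)
        q = np.exp((-2.0 * a * kmin * h) * rho2 + 1j * h * psi)
        t = np.ones_like(rho2)
        m = np.exp(-c)
        mm = np.exp(-2.0 * c)
        for j in range(J):
            Es[j] += np.sum(cur * t)
            if j + 1 < J:
                cur *= q
                t *= m
                m *= mm
    k0s = grid.k0
    Es *= beam.amplitude * k0s**2 / (4.0 * np.pi**2)
    return Es


def simulate_ascan(sample: LayeredSample, beam: BeamParameters,
                   geometry: SystemGeometry, grid: WavenumberGrid,
                   lateral_position: float = 0.0,
                   n_nodes: int | None = None) -> AScan:
    """Simulate one A-scan spectrum.

    For every k0 on the sweep the acceptance-filtered scattered field at the
    detection point xD = rD e3 is computed by Gauss-Legendre quadrature over
    the rectangular acceptance window (whose edges scale with k0), combined
    with the reference field and reduced to the DBD cross term.
    """
    Es = scattered_field_sweep(sample, beam, geometry, grid, n_nodes=n_nodes)
    Er = reference_field(geometry, beam, grid.k0)
    values = dbd_signal(Es, Er)
    return AScan(grid=grid, values=values, lateral_position=lateral_position)


def reduced_model(params: ReducedModelParams, k0):
    """Reduced single-surface measurement ``K k0² e^{-k0²σ²} cos(k0 Θ0)``."""
    k0 = np.asarray(k0, dtype=float)
    return (params.K * k0**2 * np.exp(-(k0 * params.sigma) ** 2)
            * np.cos(k0 * params.theta0))
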