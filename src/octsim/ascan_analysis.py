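"""Depth inference from A-scan spectra.

The band-limited Fourier intensity

    I(κ) = | (1/√(2π)) ∫_{kmin}^{kmax} M(k0) e^{-i k0 κ} dk0 |²

of a recorded spectrum peaks at the fringe frequency Θ0 of each reflecting
surface.  This module locates those peaks (with zero-padding and sub-grid
refinement), converts them to geometric depth with the small-tilt factor-2
relation, and recovers the surface tilt (line fit of depth versus lateral
position across a B-scan) and the slab thickness (inversion of the slab
round-trip phase 2 k0 n1 d cos θt).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.signal import find_peaks

from .interferometry import AScan, BScan

__all__ = [
    "DepthSpectrum",
    "Peak",
    "SurfaceEstimate",
    "FocusProfile",
    "depth_transform",
    "depth_intensity",
    "locate_peak",
    "locate_peaks",
    "reduced_model_transform",
    "surrogate_peak_intensity",
    "estimate_tilt",
    "estimate_thickness",
    "analyze_bscan",
    "bscan_focus_statistic",
]

#: default zero-padding factor of the FFT depth transform; the κ pixel is
#: then ≈ π/(zero_pad · δ) for half-bandwidth δ.
DEFAULT_ZERO_PAD = 8

#: default DC exclusion half-width in (zero-padded) κ pixels.
DC_EXCLUSION_PIXELS = 5


def _si(x):
    """Unnormalized sinc si(x) = sin(x)/x with si(0) = 1."""
    return np.sinc(np.asarray(x, dtype=float) / np.pi)


@dataclass
class Peak:
    theta0: float
    height: float


@dataclass
class DepthSpectrum:
    """Band-limited Fourier intensity on a κ grid with located peaks."""

    kappa: np.ndarray
    intensity: np.ndarray
    source: AScan | None = None
    peaks: list = field(default_factory=list)

    def __post_init__(self):
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")

    @property
    def pixel(self) -> float:
        return float(self.kappa[1] - self.kappa[0])


def _trapezoid_weights(n: int) -> np.ndarray:
    w = np.ones(n)
    w[0] = w[-1] = 0.5
    return w


def depth_transform(ascan: AScan, kappa):
    """Direct (trapezoid-rule) band-limited transform at arbitrary κ.

    Returns the complex S(κ) = (1/√(2π)) ∫ M(k0) e^{-i k0 κ} dk0; serves as
    the continuous reference for the FFT evaluation and for sub-grid peak
    refinement.
    """
    kappa = np.atleast_1d(np.asarray(kappa, dtype=float))
    k0 = ascan.grid.k0
    y = ascan.values * _trapezoid_weights(k0.size) * ascan.grid.spacing
    phases = np.exp(-1j * np.outer(kappa, k0))
    return (phases @ y) / np.sqrt(2.0 * np.pi)


def depth_intensity(ascan: AScan, kappa_grid=None,
                    zero_pad: int = DEFAULT_ZERO_PAD) -> DepthSpectrum:
    """Band-limited Fourier intensity I(κ) of an A-scan.

    With ``kappa_grid=None`` the transform is evaluated on the zero-padded
    FFT grid (κ pixel 2π/(zero_pad·J·Δk0), positive half-line); otherwise
    the requested κ values are computed directly by the trapezoid rule.
    """
    if kappa_grid is not None:
        s = depth_transform(ascan, kappa_grid)
        return DepthSpectrum(np.asarray(kappa_grid, float), np.abs(s) ** 2,
                             source=ascan)
    n = ascan.grid.count * int(zero_pad)
    dk = ascan.grid.spacing
    y = ascan.values * _trapezoid_weights(ascan.grid.count) * dk
    spec = np.fft.fft(y, n=n)
    m = np.arange(n // 2 + 1)
    kappa = 2.0 * np.pi * m / (n * dk)
    # e^{-i kmin κ} carrier has unit modulus; intensity is unaffected
    intensity = np.abs(spec[: n // 2 + 1] / np.sqrt(2.0 * np.pi)) ** 2
    return DepthSpectrum(kappa, intensity, source=ascan)


def _refine_peak(spectrum: DepthSpectrum, idx: int, refine: bool):
    """Sub-grid peak via quadratic interpolation, optionally polished on the
    continuous transform."""
    kap, inten = spectrum.kappa, spectrum.intensity
    if 0 < idx < kap.size - 1:
        y0, y1, y2 = inten[idx - 1], inten[idx], inten[idx + 1]
        denom = y0 - 2.0 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        shift = float(np.clip(shift, -1.0, 1.0))
    else:
        shift = 0.0
    theta0 = kap[idx] + shift * spectrum.pixel
    height = float(inten[idx])
    if refine and spectrum.source is not None:
        px = spectrum.pixel
        res = minimize_scalar(
            lambda k: -float(np.abs(depth_transform(spectrum.source, k)[0]) ** 2),
            bounds=(theta0 - 1.5 * px, theta0 + 1.5 * px), method="bounded",
            options={"xatol": 1e-4 * px})
        theta0 = float(res.x)
        height = float(-res.fun)
    return Peak(theta0=float(theta0), height=height)


def _exclusion_index(spectrum: DepthSpectrum, exclusion_halfwidth) -> int:
    if exclusion_halfwidth is None:
        return DC_EXCLUSION_PIXELS
    return int(np.searchsorted(spectrum.kappa, float(exclusion_halfwidth)))


def locate_peak(spectrum: DepthSpectrum, exclusion_halfwidth=None,
                refine: bool = True) -> Peak:
    """Locate Θ0 = argmax I(κ) on the positive-κ half-line.

    κ values within ``exclusion_halfwidth`` [μm] of the origin (default
    5 κ pixels) are excluded so the symmetric DC region cannot win; the
    grid argmax is refined by local quadratic interpolation and, when the
    source A-scan is attached, by a bounded maximization of the continuous
    transform.
    """
    start = _exclusion_index(spectrum, exclusion_halfwidth)
    inten = spectrum.intensity
    if start >= inten.size or not np.any(inten[start:] > 0):
        raise ValueError("no peak above the noise floor")
    idx = start + int(np.argmax(inten[start:]))
    peak = _refine_peak(spectrum, idx, refine)
    spectrum.peaks.append((peak.theta0, peak.height))
    return peak


def locate_peaks(spectrum: DepthSpectrum, n_peaks: int = 2,
                 min_separation: float = 50.0, exclusion_halfwidth=None,
                 refine: bool = True) -> list[Peak]:
    """Locate the ``n_peaks`` strongest well-separated peaks, sorted by κ."""
    start = _exclusion_index(spectrum, exclusion_halfwidth)
    inten = spectrum.intensity[start:]
    distance = max(1, int(min_separation / spectrum.pixel))
    idx, props = find_peaks(inten, distance=distance)
    if idx.size < n_peaks:
        raise ValueError(f"found only {idx.size} peaks, expected {n_peaks}")
    order = np.argsort(inten[idx])[::-1][:n_peaks]
    chosen = np.sort(idx[order] + start)
    out = [_refine_peak(spectrum, int(i), refine) for i in chosen]
    spectrum.peaks.extend((p.theta0, p.height) for p in out)
    return out


def reduced_model_transform(params, grid, kappa):
    """Two-sinc surrogate of the band-limited transform of the reduced
    model,

        F(κ) ≈ K δ/√(2π) e^{-k̄²σ²} k̄² [si(δ(κ-Θ0)) e^{-i k̄(κ+Θ0)}
                                         + si(δ(κ+Θ0)) e^{-i k̄(κ-Θ0)}].

    Valid in the regime σ ≈ 1/k̄ ≪ 1/δ (slow envelope over the band); a
    warning is emitted outside it.  Only the modulus is contractual — the
    printed phase pairing of the two sinc terms is kept as is, and drops
    out of |F|².
    """
    kbar, delta = grid.kbar, grid.delta
    sigma, theta0 = params.sigma, params.theta0
    if sigma * delta > 0.5:
        warnings.warn("regime violation: sigma is not small against 1/delta",
                      stacklevel=2)
    kappa = np.asarray(kappa, dtype=float)
    pref = params.K * delta / np.sqrt(2.0 * np.pi) * np.exp(-(kbar * sigma) ** 2) * kbar**2
    return pref * (_si(delta * (kappa - theta0)) * np.exp(-1j * kbar * (kappa + theta0))
                   + _si(delta * (kappa + theta0)) * np.exp(-1j * kbar * (kappa - theta0)))


def surrogate_peak_intensity(params, grid) -> float:
    """Closed-form surrogate for the peak intensity I(Θ0),

        I(Θ0) ≈ K²δ²/(2π) e^{-2k̄²σ²} k̄⁴ (1 + si(2δΘ0)²
                 + 2 si(2δΘ0) cos(2k̄Θ0)),

    the squared two-sinc surrogate evaluated at its maximum.
    """
    kbar, delta = grid.kbar, grid.delta
    s2 = _si(2.0 * delta * params.theta0)
    pref = params.K**2 * delta**2 / (2.0 * np.pi) * np.exp(-2.0 * (kbar * params.sigma) ** 2) * kbar**4
    return float(pref * (1.0 + s2 * s2
                         + 2.0 * s2 * np.cos(2.0 * kbar * params.theta0)))


@dataclass
class SurfaceEstimate:
    """Geometry recovered from one B-scan."""

    lateral_positions: np.ndarray
    depths: np.ndarray
    tilt_deg: float
    thickness: float | None = None
    back_depths: np.ndarray | None = None
    fit_residual: float = 0.0

    def __post_init__(self):
        if self.thickness is not None and self.thickness <= 0:
            raise ValueError("thickness must be positive when present")


def estimate_tilt(bscan: BScan, peak_depths=None,
                  zero_pad: int = DEFAULT_ZERO_PAD) -> SurfaceEstimate:
    """Surface tilt from the depth progression across a B-scan.

    Per-A-scan fringe frequencies Θ0 are converted to depth via the
    small-tilt relation depth = Θ0/2, and the tilt follows from the slope
    of the straight-line fit of depth against lateral position,
    θΩ = arctan(Δdepth/Δlateral).
    """
    x1 = bscan.lateral_positions
    if x1.size < 2:
        raise ValueError("tilt estimation needs at least two A-scans")
    if peak_depths is None:
        theta0s = np.array([
            locate_peak(depth_intensity(a, zero_pad=zero_pad)).theta0
            for a in bscan.ascans])
        depths = theta0s / 2.0
    else:
        depths = np.asarray(peak_depths, dtype=float)
    if np.ptp(x1) == 0:
        raise ValueError("lateral positions are collinear (all equal)")
    slope, intercept = np.polyfit(x1, depths, 1)
    resid = depths - (slope * x1 + intercept)
    return SurfaceEstimate(
        lateral_positions=x1, depths=depths,
        tilt_deg=float(np.rad2deg(np.arctan(slope))),
        fit_residual=float(np.sqrt(np.mean(resid**2))))


def estimate_thickness(theta0_front: float, theta0_back: float, n1: float,
                       cos_theta_t: float) -> float:
    """Slab thickness from the κ separation of the two surface peaks,

        d = (Θ0,back - Θ0,front) / (2 n1 cos θt),

    inverting the slab round-trip phase 2 k0 n1 d cos θt.
    """
    if n1 < 1:
        raise ValueError("n1 must be >= 1")
    if theta0_back <= theta0_front:
        raise ValueError("back-surface peak must lie beyond the front peak")
    return (theta0_back - theta0_front) / (2.0 * n1 * float(np.real(cos_theta_t)))


def analyze_bscan(bscan: BScan, n1: float | None = None,
                  n_surfaces: int = 1, zero_pad: int = DEFAULT_ZERO_PAD,
                  min_separation: float = 50.0) -> SurfaceEstimate:
    """Full geometry recovery from a B-scan.

    Locates one or two peaks per A-scan, estimates the tilt from the
    front-surface depths, and for ``n_surfaces=2`` converts the mean peak
    separation to thickness using the Snell transmission-angle cosine at
    the estimated tilt.
    """
    if n_surfaces not in (1, 2):
        raise ValueError("n_surfaces must be 1 or 2")
    fronts, backs = [], []
    for a in bscan.ascans:
        spec = depth_intensity(a, zero_pad=zero_pad)
        if n_surfaces == 1:
            fronts.append(locate_peak(spec).theta0)
        else:
            p1, p2 = locate_peaks(spec, n_peaks=2,
                                  min_separation=min_separation)
            fronts.append(p1.theta0)
            backs.append(p2.theta0)
    fronts = np.array(fronts)
    est = estimate_tilt(bscan, peak_depths=fronts / 2.0, zero_pad=zero_pad)
    thickness = None
    back_depths = None
    if n_surfaces == 2:
        if n1 is None:
            raise ValueError("thickness recovery needs the slab index n1")
        backs = np.array(backs)
        back_depths = backs / 2.0
        sin_t = np.sin(np.deg2rad(abs(est.tilt_deg))) / n1
        cos_t = float(np.sqrt(1.0 - sin_t**2))
        thickness = float(np.mean([
            estimate_thickness(f, b, n1, cos_t) for f, b in zip(fronts, backs)]))
    return SurfaceEstimate(lateral_positions=est.lateral_positions,
                           depths=est.depths, tilt_deg=est.tilt_deg,
                           thickness=thickness, back_depths=back_depths,
                           fit_residual=est.fit_residual)


@dataclass
class FocusProfile:
    """Mean-of-max statistic over a through-focus B-scan series."""

    stage_positions: np.ndarray
    mean: np.ndarray
    std: np.ndarray

    @property
    def normalized_mean(self) -> np.ndarray:
        return self.mean / np.max(self.mean)


def bscan_focus_statistic(bscans, stage_positions=None,
                          zero_pad: int = DEFAULT_ZERO_PAD) -> FocusProfile:
    """Per-stage mean and standard deviation of max_κ I(κ) over A-scans.

    The statistic suppresses per-A-scan noise before comparing a
    through-focus series against the model; the peak search excludes the
    DC region like the peak locator.
    """
    means, stds = [], []
    for b in bscans:
        maxima = []
        for a in b.ascans:
            spec = depth_intensity(a, zero_pad=zero_pad)
            maxima.append(np.max(spec.intensity[DC_EXCLUSION_PIXELS:]))
        maxima = np.array(maxima)
        means.append(maxima.mean())
        stds.append(maxima.std())
    if stage_positions is None:
        stage_positions = np.arange(len(bscans), dtype=float)
    return FocusProfile(stage_positions=np.asarray(stage_positions, float),
                        mean=np.array(means), std=np.array(stds))
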