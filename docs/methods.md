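# Methods

This note documents the model assumptions, the numerical choices, the
defaults of the synthetic experiments, and the known limitations of
`octsim`. Lengths are micrometres, wavenumbers μm⁻¹; angles are degrees at
every public interface and radians internally.

## Coordinate frame and model chain

The beam propagates toward negative x3; the sample lies at x3 < 0 and the
detection point at `xD = rD e3` above it. The chain is:

1. **Illumination.** A monochromatic Gaussian beam as an angular spectrum
   of plane waves. The spectral weight `amplitude · e^{-a(k1²+k2²)}`,
   `a = w0²/4`, is truncated to the propagating disk `k1²+k2² < k0²`; the
   polarization of each component is lifted so the field is divergence
   free. The overall amplitude is an arbitrary complex scale — no absolute
   radiometric normalisation is attempted, and every comparison involving
   "data" is made after peak normalisation.
2. **Reflection.** The sample is locally a stack of parallel planar layers
   (tilt normal `νΩ = (sin θΩ, 0, cos θΩ)`), non-absorbing, each with a
   constant index ≥ 1; a perfect mirror is a flag rather than a large
   finite index. Plane waves reflect specularly with Fresnel amplitude
   coefficients; for a slab only first-order internal reflections are
   kept, giving `βS = β0 − β0(1−β0²) e^{-i 2 k0 n1 d cos θt}`. The sign
   convention makes normal-incidence reflection off a denser medium
   negative in s-polarisation; detection uses magnitudes and relative
   phases only. The detection chain is scalar and uses the s coefficient;
   the TE/TM vector pathway exists (`reflect_amplitude`) but is not wired
   into detection.
3. **Collection.** The scan lens keeps reflected directions within `θmax`
   of the axis. The exact acceptance set is the preimage of a spherical
   cap; computations use the circumscribing rectangle centred at
   `k1 = -k0 sin 2θΩ` with half-widths
   `L1 = k0(sin 2|θΩ| − sin(2|θΩ| − θmax))` and `L2 = k0 sin θmax`. The
   half-width formula is evaluated at |θΩ| so the window mirrors with the
   exact set under θΩ → −θΩ (the printed asymmetric form would break the
   symmetry of the power-angle curve). The rectangle circumscribes the
   inscribed ellipse, overestimating its area by exactly 4/π; the window
   *edges* are what matter for the field, and those agree.
4. **Detection.** The dual-balanced detector output per wavenumber is the
   cross term `M(k0) = −Re(ES · conj ER)`; the reference field is the
   far-field reflection off a mirror at focus,
   `ER = −i k0/(2π rD) βR ǧR e^{-i k0 (r0 + rD − 2 xM,3)}`.

## Where the detection point sits (and why it matters)

The model detects the field at a single point. At the physical scan-lens
distance (~6 cm) that point is deep in the far-field regime of the
reflected beam, where the windowed integral collapses to its
stationary-phase value: the through-focus dependence disappears and the
acceptance angle drops out of the power-angle curve — a pointwise detector
cannot represent the confocal fibre-coupling that creates those
sensitivities in a real system. Both effects survive only while the
reflected beam's image focus stays within a Rayleigh-length scale
(`k0 a ≈ 240 μm` for the calibrated beam) of the detection point. The
package therefore places the detection point near the sample region:

* `SystemGeometry.r_detector` defaults to 500 μm for A-scan simulation;
* the power-angle model evaluates at the origin with the mirror and focus
  at `surface_x3 = −200 μm` below it (module default `DEFAULT_SURFACE_X3`).

These are model coordinates, not bench distances; they control a single
dimensionless ratio (image-focus distance over Rayleigh length) and are
documented defaults rather than fitted quantities.

## Numerical choices

* **Oscillatory Gaussian integrals.** All 1-D integrals
  `∫ e^{-ψ2 k² - i ψ1 k} dk` (Re ψ2 > 0) use a closed form via the complex
  error function, rewritten through the Faddeeva function so every
  exponent stays bounded for arbitrarily large defocus |Im ψ2| and tilt
  phase |ψ1|; an independent node-adaptive Gauss-Legendre route exists and
  the two agree to ≤1e−9 in tests.
* **2-D quadrature.** Tensor-product Gauss-Legendre over the effective
  support (the disk where the Gaussian weight exceeds 1e−8 of its peak,
  radius `ρ0 = sqrt(ln 1e8 / a)`) or over the acceptance rectangle. The
  node count follows a probed phase-excursion bound (≈0.9 nodes per
  radian, floor 24, cap 4000 per dimension).
* **Sweep evaluation.** With window nodes scaled as `(k1,k2) = k0 (u,v)`,
  every phase term of the A-scan integrand is exactly linear in k0 and the
  Gaussian weight is `e^{-a k0² ρ²}`, so the 700-point sweep advances by
  exact multiplicative recurrences (one complex and two real multiplies
  per node and wavenumber) instead of fresh exponentials.
* **Depth transform.** `I(κ)` uses the unitary-prefactor convention
  `|(1/√(2π)) ∫ M e^{-i k0 κ} dk0|²` — the convention under which the
  printed constants of the two-sinc surrogate and its squared form are
  mutually consistent; only ratios and peak positions are contractual.
  Evaluation is trapezoid-rule, via zero-padded FFT (default factor 8,
  κ pixel `2π/(8 J Δk0) ≈ 6.9 μm` on the default sweep) for the grid and
  directly for arbitrary κ.
* **Peak location.** Grid argmax on the positive-κ half-line (DC exclusion
  default 5 padded pixels), 3-point quadratic interpolation, then a
  bounded maximisation of the continuous transform within ±1.5 pixels when
  the source spectrum is attached. Sub-pixel accuracy is what makes the
  tilt and thickness recoveries sharp.
* **Calibration fit.** Deterministic 40×40 log-spaced grid over
  w0 ∈ [5, 40] μm × θmax ∈ [0.4, 5]°, amplitude profiled out in closed
  form per candidate, then Nelder-Mead in log-parameters. The objective
  can oscillate through the erf-edge fringes of the windowed Gaussian, so
  the global stage must bracket the optimum before polishing. Optional
  residual weighting: `"relative"` (1/power², the efficient choice under
  multiplicative power-meter noise) or `"inverse_variance"` from the
  recorded repeat scatter; the default objective is unweighted.

## Synthetic experiments (the study conditions)

* **Power-vs-angle:** 25 angles from −1° to 1° (5-arc-minute steps), 6
  repeats, multiplicative Gaussian noise (default sd 1%) on each repeat,
  per-angle mean and standard deviation returned. Zero noise reproduces
  the model evaluation bit for bit.
* **Through-focus series:** 11 stage positions for the mirror, 7 for the
  coverglass, spanning ±500 μm; tilt 2.75°; coverglass index 1.5088 with
  default thickness 150 μm (a typical #1 coverglass; the peaks are then
  separated by ≈452 μm in κ, far above the ≈55 μm sinc main-lobe width).
  Each B-scan holds 15 A-scans at 19.6 μm lateral spacing, every A-scan
  simulated in its own beam-centred frame with the surface depth
  progressing as −tan θΩ · x1. The 700-point sweep covers
  [4.7835, 4.8973] μm⁻¹. Additive Gaussian noise (default 0.5% of the
  series' peak spectral value) is drawn from one seeded generator per
  recipe; identical recipes give byte-identical files.
* The stage scan is centred on the model's focus-coincidence position: the
  surface depth maximising the detected amplitude, found by a bounded
  search of the windowed field magnitude at the central wavenumber. It
  lies within a Rayleigh length of the nominal focus `r0`; the offset
  (≈−86 μm at the defaults) is a property of the acceptance-edge
  truncation of the tilted-mirror spectrum. The sidecar records this
  stage index, the true per-A-scan fringe frequencies
  `Θ0 = −(1+cos 2θΩ) xΩ,3 − (1−cos 2θΩ) r0 + 2 xM,3` (front and, for the
  slab, back surface), tilt, thickness and seed — enough to score every
  recovery without re-reading the configuration.

What the generator does *not* emulate: speckle or diffuse scattering from
rough surfaces, detector quantisation and the digitiser height shift
(spectra are already centred, as after background subtraction), dispersion,
wavelength-dependent source power, and scan-lens field curvature. Passing
recoveries on this data therefore demonstrate the correctness of the
inversion chain under the model's own assumptions, not robustness to those
real-data effects.

## Accuracy observed at the defaults

Peak positions recovered from fully simulated A-scans carry a small
common-mode bias (≈1–3 μm) from the slowly varying spectral phase of the
windowed integral; it cancels in the tilt slope and nearly cancels in the
peak separation, leaving tilt errors ≲0.05° and thickness errors ≲0.6% at
the default conditions. Noise-free calibration recovers (w0, θmax)
essentially exactly; at 1% multiplicative noise the relative-weighted fit
stays within 5% over repeated seeds.

## Known limitations

* Pointwise detection (no fibre-mode overlap integral): focus and
  acceptance sensitivities require the detection-point placement described
  above; absolute scales are arbitrary.
* At most two layer boundaries; first-order internal reflections only;
  non-absorbing media; planar boundaries.
* The scalar chain ignores polarisation mixing (the s/p distinction is
  ≤0.3% at the ~2.75° tilts considered).
* The small-tilt factor-2 depth conversion biases the recovered tilt by
  ≈θΩ³/3 (0.008° at 2.75°), well below the quoted tolerance.
* The tilt estimate uses the slope form `arctan(Δdepth/Δlateral)`, which
  is regular for a level surface.
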