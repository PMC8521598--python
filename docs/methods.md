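# Methods

## Signal model

An en face OCT plane is modelled as a complex field on a regular grid
with pixel pitch `p` (µm/pixel, 0.4 by default — Nyquist radial frequency
`π/p = 7.85 rad/µm`). One acquisition is

```
f_j = IFFT[ FFT(o) · H(k) · exp(iΦ(k)) ]  (shifted/phase-rotated per frame)  +  n_j
```

where `o` is the object field, `H(kr) = exp(-kr²/(2σk²))` the radially
symmetric Gaussian *amplitude* transfer of a Gaussian illumination beam,
`Φ(k)` an optional pupil-phase aberration, and `n_j` per-frame i.i.d.
circular complex Gaussian noise with `E|n|² = σ_noise²`. The object field
is the sum of

* point scatterers, placed at *subpixel* positions via spectral phase
  ramps (band-limited placement, so FWHM metrology is not biased by the
  sampling grid), and
* an optional frozen per-pixel circular Gaussian scatterer field
  (single-scattering background): filtered by the same `H`, identical in
  every frame, hence phase-stable under averaging — unlike the noise.

`H` is parametrised by the FWHM of the *magnitude* PSF (2.1 µm default):
a magnitude PSF `exp(-r²/(2σx²))` has FWHM `2√(2 ln 2)·σx` and transfer
width `σk = 1/σx`. The convention is magnitude (not intensity) throughout
because resolution is measured by Gaussian fits to magnitude images.

Aberrations are sums of Noll-indexed, Noll-normalised Zernike polynomials
on `ρ = kr/k_pupil`, zero outside the pupil; the pupil radius defaults to
the Nyquist radius since the simulated aberrations carry no separate
physical pupil. Out of scope by design: axial/physical OCT forward
modelling (coherence gating, depth-dependent defocus), multiple
scattering, and any aberration correction beyond the paraxial defocus
phase `exp(-i z kr²/(2k0))`, `k0 = 2πn/λ`.

## Averaging and intensity metrics

Coherent average: element-wise complex mean of the first n frames; noise
power falls as 1/n. Incoherent average: mean of magnitudes; phase-blind.
"Noise intensity" is the **standard deviation of the pixel intensity** of
a signal-free noise image, not its mean — for circular Gaussian noise the
intensity is exponential, so std = mean = σ², and the metric falls as 1/n
(coherent) vs asymptotically 1/√n (incoherent). The delta-method constant
matters when quoting ratios: at n = 100 the incoherent reduction factor
is `√n/(2 μR σR) = 12.2` (Rayleigh moments `μR = σ√π/2`,
`σR = σ√(1−π/4)`), so the coherent/incoherent reduction ratio is 8.2,
even though the *slopes* are exactly −1 and −0.5.

Particle intensity is the 99th percentile of intensity (meaningful on
particle-rich planes); background intensity is the median intensity after
masking pixels above 5× the median magnitude and dilating the mask by
2 px (both configurable; the defaults are package choices — no reference
values exist for them).

## Spatial-frequency metrology

All public spectra are DC-centered unnormalised FFTs
(`Σ|f|² = Σ|F|²/(HW)`). Dynamic range: `10·log10` of the single central
(DC) bin's power of the signal image over the **mean** noise power across
the full 2D spectral domain of the paired noise image (the noise spectrum
is flat, so its mean summarises it).

Phase-correlation limit: crop an odd window (243 px default) around a
particle, FFT **with the spatial origin at the window center** (otherwise
the centering ramp of ~π/bin swamps the statistics), take the phase,
compute a sliding-kernel (3×3) *circular* standard deviation — subtract
the kernel's circular mean direction, wrap residuals to (−π, π], take the
RMS — truncating the kernel at window edges (padding would inject fake
decorrelation into border bins). Average the result in 0.1 rad/µm radial
bins from 0 to Nyquist; the limit is the center of the first bin whose
mean exceeds 0.2 rad, or the last bin center if none does
(Nyquist-limited). Circular statistics are a package decision: the raw
std of wrapped angles spuriously flags ±π crossings.

## Spectrum model and the BE mask

The radial magnitude model `M0(kr) = A·exp(-kr²/(2σk²))` is fitted by
linear least squares of `log(radial mean power − noise floor)` against
`kr²`, using bins whose power exceeds the noise floor by a 10 dB margin
(and a 1e−12 relative-to-DC floor against round-off). The noise floor is
the mean spectral power of the paired noise image. An analytic
Gaussian-ratio mask is used instead of per-bin division of measured
spectra because the latter is ill-conditioned in noise; the two coincide
in the noise-free limit.

The mask `gain(kr) = exp[(kr²/(2σk²))(1 − 1/b²)]` is defined on the full
grid (corners follow the same radial law), `gain(DC) = 1`, `b = 1 ⇒`
identity. **Gain cap:** the default is DR-adaptive — the gain is clipped
at its value at the radial frequency `kr_DR` where the fitted model power
meets the noise floor (`kr_DR = σk·√ln(A²/floor)`); beyond that point
there is no signal to boost, only noise to amplify. Noise-free data has
no floor and gets no cap, which preserves the exact Gaussian algebra
(FWHM → FWHM/b, efficiency 1). A fixed dB cap is available, but note a
low fixed cap truncates the *signal* tail: a 40 dB amplitude cap measured
efficiency 0.72 instead of ~1.0 at b = 2.4 on noise-free input, which is
why it is not the default. The adaptive cap also produces the expected
phenomenology with noise: resolution at fixed b improves with N (the
floor drops, the cap rises) and efficiency decreases with b.

Upsampling embeds the spectrum centrally in a factor×-larger zero array,
scaled by factor² so band-limited fields interpolate their original
samples exactly and physical energy (`Σ|f|²·pixel area`) is preserved.
Default factor 4 for metrology, 2 for export.

## PSF metrology

Particles are local maxima of the magnitude image (or its maximum
intensity projection across depths) above 10× the median magnitude
(floored at 2% of the image maximum so a signal-free background does not
pass everything; an absolute threshold is available for instrument
parity), at least one fitting window apart, in descending peak order.

Each particle is fitted on a 73 px (native; scaled by the upsampling
factor in the pipeline) window: 32 diameter profiles at equally spaced
angles over [0, π), bilinear interpolation, and a linear least-squares
fit of log-magnitude to a quadratic in the radial coordinate, restricted
to the contiguous run of samples above 20% of the profile peak (this
avoids log-of-noise bias and keeps neighbouring particles out of the
fit). Per-angle FWHM values are averaged (averaging fitted parameters per
angle, then the mean — the alternative of recomputing from an averaged σ
differs negligibly for near-isotropic spots); a measurement is flagged
bad when more than half the angles fail. Peak SBR is
`10·log10(peak_magnitude²/background_intensity)`.

Aggregation excludes particles whose *pre-enhancement* (coherent-average)
FWHM exceeds 2.4 µm — wider blobs are bubbles or aggregates, not single
scatterers — then reports mean ± std FWHM and SBR, the RE factor
(baseline mean FWHM / enhanced mean FWHM) and efficiency RE/b.

## Registration

Per-frame rigid correction only (bulk shift + global phase; the
perturbations relevant for stack averaging). Shift from the
cross-correlation of the **complex** fields with upsampled-DFT subpixel
refinement: complex fields are band-limited so the subpixel estimate is
unbiased, whereas magnitude images are not (a measured ~0.2 px bias), and
the correlation magnitude is insensitive to global phase. Phase is the
angle of `Σ conj(reference)·shifted(frame)`; quality is the normalised
magnitude correlation after alignment, with low-quality frames flagged
rather than rejected. The reference is the first frame by default.

## Synthetic-condition runner and default levels

The condition runner sweeps {noise-free, noise-only, noise+background} ×
{aberrated, unaberrated} over a BE grid at N = 100 (sharing one coherent
average across BE factors) and over N at fixed b = 2.4. Default levels,
chosen once as a realistic operating point and treated as configuration:
nine unit-amplitude particles on a jittered 3×3 grid of a 256² plane
(one fitting window apart), noise σ = 1.6×10⁻³ and background
σ = 3×10⁻³ in particle-amplitude units — giving a single-shot DR near
30 dB and phantom-like SBR in the tens of dB — and aberrations of 1.5 rad
vertical astigmatism (Noll 6) + 1.0 rad primary spherical (Noll 11) over
the Nyquist pupil. Quantitative claims tied to these levels are trend
claims (efficiency non-increasing in b; resolution improving with N;
aberrations degrading resolution at every b); only the noise-free
efficiency is asserted as an absolute number.

## What the simulator does and does not establish

The generator reproduces the statistical structure the method relies on —
Gaussian signal spectrum over a flat noise floor, phase-stable signal vs
decorrelating noise, aberrations as slowly varying pupil phase — so
passing tests establish the *computational* claims: averaging scalings,
DR accounting, the bandwidth-expansion algebra and its metrology. It does
not model shot-noise/intensity-noise specifics, multiple scattering,
depth-dependent defocus, sample motion within a frame, or
non-Gaussian beam profiles; absolute experimental values (e.g. a specific
achievable resolution on silicone) depend on instrument data and are out
of reach of the simulation. Volumes are handled as independent en face
planes; no axial processing is performed.

## Problem sizes and determinism

Default grids are 256×256 (fits and sweeps run in seconds); tests and the
reproduction script use N = 100 frames where averaging claims are made
and a ×4 upsampled 1024² grid for metrology. Every stochastic component
takes an explicit seed (`numpy.random.default_rng`); stacks record their
generator parameters in `provenance`, and pipeline reports echo the full
configuration, so identical configurations give bit-identical outputs.
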