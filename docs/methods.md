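# Methods

`lockinsim` reconstructs two-beam structured-illumination microscopy (SIM)
data with an explicit background-removal step between acquisition and the
standard Wiener reconstruction.  This note records the model, the estimators,
the defaults and why they are what they are, and what the bundled simulator
does and does not emulate.

## Image formation model

A raw frame at pattern orientation d and phase j is

    I_j(r) = { [1 + m·cos(2π k0·r + φ_j)] · O(r) } * H(r) + n(r),

with sample fluorophore density `O`, incoherent point-spread function `H`,
pattern wave vector `k0` (cycles/pixel), modulation depth `m ∈ [0, 1]`,
three phases `φ_j` per orientation (nominally 0°, 120°, 240°) and additive
Gaussian noise `n`.  Splitting the sample into in-focus and out-of-focus
parts, `O = O_in + O_out`, only `O_in` is modulated by the stripes; the frame
decomposes into a modulation-independent (DC) background

    I_dc = [O_out + (1 − m)·O_in] * H

and a modulation-dependent (AC) signal `[m + m·cos(2π k0·r + φ_j)]·O_in * H`.
Removing `I_dc` before reconstruction removes out-of-focus haze without
touching the information-carrying modulated bands.

### Optics

The OTF is the diffraction-limited scalar model — the normalised
autocorrelation of a circular pupil, `(2/π)(arccos ρ − ρ√(1−ρ²))` with
`ρ = |k| / k_cutoff` and `k_cutoff = 2·NA/λ` — sampled on the FFT grid in
cycles/pixel; a Gaussian approximation is selectable.  Refractive-index and
vectorial/high-NA effects are ignored (documented limitation).  The PSF is
the centred inverse transform, clipped at tiny negatives and renormalised to
unit sum.  Building a model with a pixel too coarse to hold the OTF support
(`k_cutoff ≥ 0.5 cycles/px`) is an error that names the maximum admissible
pixel, `λ/(4·NA)`.

Default acquisition parameters follow a high-NA TIRF-objective configuration:
λ = 488 nm, NA = 1.49, pixel 65 nm (giving k_cutoff ≈ 6.11 µm⁻¹), pattern
frequency 0.8·k_cutoff at orientations 0°/60°/120°, m = 0.9.

## Lock-in demodulation and background removal

With three phases per orientation, each pixel gives three samples of
`I_j = C + a·cos φ_j + b·sin φ_j`.  The exact 3×3 linear solve yields the
offset `C`, amplitude `A = √(a²+b²)` and phase `atan2(b, a)`; for equispaced
phases this reduces to the classical root-mean-square optical-sectioning
formulas `C = (I₁+I₂+I₃)/3`, `A = (√2/3)·√(ΣΔ²)`.  The phase mean contains
`I_dc + m·(O_in*H)` while `A` estimates the modulated contribution, so the
raw background estimate is `max(C − A, 0)`.  It is Gaussian-smoothed
(default σ = one pattern period, 1/|k0| px — backgrounds vary slowly across
the field, and smoothing keeps residual in-focus texture out of the
subtraction) and subtracted from every frame of the orientation, clipping
negatives (clipped mass is logged).  A flag replaces the per-orientation DC
maps with their pixel-wise median across orientations.

**Known bias and the OTF-equalisation flag.**  The demodulated amplitude is
the in-focus signal seen through the *shifted* OTF `H(k + k0)`; at the
default pattern frequency its on-axis response is H(|k0|) ≈ 0.10, so `A`
under-reports `m·(O_in*H)` on fine structure and the default estimator
counts part of the unmodulated in-focus intensity as background.  This is a
deliberate trade: it is maximally aggressive on haze (residuals of injected
unmodulated background are ~0.1% in the bundled simulations) and leaves the
modulated bands — which carry all super-resolution information — exactly
intact, because the subtracted map is common to the three phases.
`LockinSettings(equalize_otf=True)` enables the reserved compensation: the
complex envelope `a − i·b` is shifted to baseband and re-mapped through the
regularised transfer `H(k)·H(k+k0)/(H(k+k0)² + ε²)` (ε = 0.05), recovering
`m·(O_in*H)` within the band overlap.  Equalisation preserves the widefield
component of in-focus structure almost perfectly (lock-in and plain Wiener
reconstructions of background-free data then correlate at r > 0.99) but
leaves in-focus PSF tails in place, so suppression of haze measured near
structures is weaker.  Two estimator variants that weight the phase
correlation by the widefield or by an OTF-matched template were evaluated
and rejected: the envelope's spatial phase decorrelates from the widefield,
and deconvolving the noisy widefield amplifies high-frequency noise.

## Illumination-parameter estimation

Per orientation, non-iteratively:

* **k0** — bands are separated with the nominal equispaced phase matrix; the
  product of the real-space zeroth and first-order bands is Fourier
  transformed, its peak located on the integer grid (DC exclusion radius
  0.1·k_cutoff, search bounded by the OTF support, detection requires the
  peak to exceed 5× the median magnitude), then refined by maximising the
  continuous-frequency (DTFT) correlation magnitude with Nelder–Mead.
  Typical noiseless accuracy is ~5×10⁻⁵ cycles/px.  The sign of k0 is a
  gauge freedom; estimates are canonicalised to the upper frequency
  half-plane (1e-3 tolerance band at the boundary).
* **φ_j** — the complex argument of each widefield-subtracted frame's DTFT
  at k0.  Noiseless accuracy ~0.3°; at a noise level of one tenth of the
  mean structure intensity on a dense filament field, phase *spacings* are
  recovered to ~1.8° on average.  A Cramér–Rao computation shows this is
  within ~2.5× of the information-theoretic bound for a sparse scene at this
  pattern frequency — per-realization accuracy much below a few degrees is
  not attainable at low SNR, which is why the noise test asserts the mean
  over 20 seeded realizations.
* **m** — complex least-squares ratio of the OTF-compensated first-order
  band to the k0-shifted zeroth-order band over the spectral overlap region
  (OTF floor 0.05), clipped to (0, 1].  Typical error < 0.01 noiseless.

Because a wave-vector error Δk0 trades off against a compensating phase
offset of order 2π·Δk0·r across the field, a (k0, φ) pair is meaningful as a
pair; phases are validated at fixed k0.

## Wiener-SIM engine

Per orientation the 3×3 phase mixing matrix `M[j,n] = exp(i·n·φ_j)` is
inverted to separate the −1/0/+1 order spectra.  Each order is embedded in
an upsampled grid (default 2×; output pixel 32.5 nm for 65 nm input),
translated by −n·k0 with subpixel accuracy via a real-space phase ramp, and
all orders of all orientations are merged by a generalized Wiener filter

    SR(k) = Apo(k) · Σ g·H(k + n·k0)·S(k) / (Σ g²·H(k + n·k0)² + w²),

with band gains `g = 1` (order 0) and `m/2` (orders ±1) in both numerator
and denominator (the statistically consistent weighting), regularisation
`w = 0.15` relative to the unit-normalised OTF, and a triangular apodization
`max(0, 1 − |k|/(k_cutoff + max|k0|))` (exactly zero outside the extended
support; `none` available).  An optional notch suppresses residual pattern
peaks at ±k0 (off by default).  The result is inverse-transformed and
clipped at zero (clipped mass logged).  The lock-in variant estimates
parameters on the *raw* frames (pattern peaks are stronger before background
removal), strips the DC background, and runs the same engine.

Resolution accounting: at |k0| = 0.8·k_cutoff the passband extends 1.8×, an
ideal bead-image shrink of 1/1.8 ≈ 0.56×.  The triangular taper and the
finite 100-nm bead raise the measured shrink to ~0.64–0.69; without
apodization the engine reaches ~0.60 at the default `w`.  FWHM-based
resolution statements in the test suite are therefore made on untapered
reconstructions; the tapered output remains the default because the hard
band edge rings on real data.

Multi-plane stacks (z and/or t) are reconstructed per plane with shared
(default) or per-plane parameter estimation; optional `mean_match` intensity
correction rescales each plane's mean to the stack median (bleach /
illumination drift).  Z-stacks can be summarised by a depth-coded maximum
intensity projection (hue = argmax plane, brightness = normalised maximum).

## Metrics

* **SBR** (dB): `10·log10((max(signal) − mean(background)) / sd(background))`,
  background = all pixels without structural signal.  Default segmentation
  is Otsu's threshold on a σ = 1 px smoothed copy; the literal signal
  maximum is used, with a 99.9th-percentile robust mode behind a flag.
  Fewer than 100 background pixels or zero background spread are errors; a
  non-positive numerator reports −∞ flagged rather than raising.  A
  sliding-window variant recomputes the mask per window and marks
  undefined windows NaN.
* **FWHM** (nm): bilinear profile through the local maximum, profile-edge
  median subtracted as local background, half-max crossings by linear
  interpolation.
* **Radial spectrum**: azimuthal mean of log10 |FT| in annuli one grid step
  wide (lower-edge binned); noise floor = median of the outer 10% of annuli;
  cutoff = first annulus within 0.15 log10 units (≈3 dB power) of the floor.
  On noiseless images the "floor" is numerical, which can place the cutoff
  beyond the physical band edge; the estimator is intended for noisy data
  and for *relative* comparisons (widefield vs reconstruction).

## Fiber orientation

Per pixel, vectors run from the centre of an odd window (default 7×7 → 48
vectors) to every other window pixel.  Weights: `F1 = 1/|v|` and
`F2 = √(1/3) − √((1/2)·Σᵢ(Iᵢ − Ī)²)` from three bilinear samples at
fractional positions 0, ½, 1 along the vector on the [0, 1]-normalised
image (Ī is the 3-sample mean; F2 is maximal, √(1/3), for uniform intensity
along the vector).  The combined weight is `F1 + F2` clipped at zero (a
product variant exists for sensitivity analysis).  Because orientation is
axial, weighted unit vectors are summed in doubled-angle space and
θ = ½·atan2(Σsin, Σcos) mapped to [0°, 180°); the resultant length is the
confidence weight, and pixels below an intensity threshold are invalid.
Histograms are weight-weighted over [0°, 180°) with circular peak finding;
time series track the dominant θ of a region with seam-aware unwrapping
(each value chosen within ±90° of its predecessor).  Discrete vector
quantisation biases single-pixel-wide test lines by up to ~3° at angles far
from the grid axes; the bias is smallest on fiber-core (ridge) pixels,
where the test suite evaluates it.

## Simulator

The generator renders peak-normalised ground truth scenes — antialiased
bead disks (default 100 nm diameter), crossed filaments with Gaussian
cross-section, radial spoke targets, and multi-plane filament volumes —
then multiplies by the sinusoidal pattern, convolves with the PSF (cyclic
FFT convolution), adds optional Gaussian noise and clips at zero.
Out-of-focus haze is emulated by superimposing `level × blur(widefield)`
(blur = PSF re-applied, or a Gaussian).  Optional Poisson shot noise is
deliberately absent from defaults: the noise model is additive Gaussian.

The volumetric variant gives a slice at defocus Δz a pattern contrast
`m·exp(−(Δz/z_m)²)` (default z_m = 0.6 µm) and a PSF widened to total
Gaussian width `σ0·√(1 + (Δz/z_R)²)` (defaults σ0 = 2 px, z_R = 0.4 µm) —
implemented as an *additional* blur of `σ0·|Δz|/z_R` on top of the in-focus
PSF so the in-focus slice reduces exactly to the 2-D renderer.  These
axial envelopes are phenomenological (stripe contrast does decay with
defocus; the exact law of a real system depends on the illumination optics)
and both scales are exposed parameters.

What passing tests on these simulations do **not** show about real data:
camera gain/offset/read-noise structure, shot noise, aberrations and
field-dependent pattern distortion, refractive-index mismatch, sample
motion, and non-cyclic boundary effects are all outside the generator.

## Numerical choices and degenerate inputs

All frequencies are FFT-ordered cycles/pixel internally; physical units
(nm, µm⁻¹) appear only at reporting boundaries.  Phase design matrices with
condition number > 1e10 (coincident phases) are errors.  Unmodulated stacks
raise "pattern not detected" rather than silently reconstructing widefield.
Scenes, noise and backgrounds are bit-reproducible under fixed seeds.  TIFF
I/O validates page counts against the declared axis layout, rejects RGB
input, converts to float and clips float negatives at zero; provenance
sidecars carry every parameter needed to reproduce a reconstruction
bit-for-bit.

## Problem sizes

The test suite and example scripts use 64–256 px grids, 9-frame single
planes, two-plane volumes, and 5–20 seeded repetitions per stochastic
property — sizes at which every quantity they assert (background residuals,
SBR gains of +6–9 dB, FWHM shrink to ~0.60×, sectioning ratios > 25,
orientation errors ≤ 3°) is stable to well inside the asserted margins.
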