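# Methods

This note records the physical model, the numerical choices, and the design
decisions behind `holofoci`, together with what the simulation does and does
not establish about real hardware.

## Optical model

The SLM working area is an `N_pix x N_pix` square mapped to the objective
back aperture; pupil coordinates (u, v) are normalized so the pupil-edge
radius is 1. With the Abbe sine condition, a lateral focus shift of x um
corresponds to a pupil phase ramp of `alpha u x` cycles with
`alpha = NA / lambda`; a paraxial axial shift of z um corresponds to a
quadratic phase `gamma (u^2 + v^2) z` cycles with
`gamma = -NA^2 / (2 n lambda)` (n = immersion index). These are the default
values of the scaling factors; they are stored mutable in `OpticsConfig`
because on a real instrument they are calibration-adjustable (that is the
role of the similarity-transform fit in `characterize`).

Propagation is scalar Fourier optics: the focal-plane field at depth z is
the 2D FFT of `exp(i phase)` apodized by the pupil disk and multiplied by
the *conjugate* defocus factor `exp(-2 pi i gamma (u^2+v^2) z)`, so that a
hologram carrying the lens term for z_n comes to focus at the z = z_n
plane. With `pad_factor` P zero-padding, the image-plane sampling is
`2 dx_max / (P N_pix)` (~0.19 um at the defaults) and the unaliased image
extent is exactly the holographic FOV, +-dx_max. The orthonormal FFT makes
the transform energy-conserving to machine precision (the Parseval check in
the test suite).

Two hardware envelopes sit on top of the ideal transform:

* the sinc^2 pixel-footprint envelope of the SLM, applied analytically to
  the image-plane intensity. By the array theorem this is exact for
  unit-fill-factor pixels and avoids super-sampling the SLM grid;
* a hard square relay-aperture window of half-width
  `fov_aperture_halfwidth` (35 um by default, emulating a 20x profile with
  a ~70 x 70 um^2 usable window; 15 um emulates a 60x profile). The true
  relay-aperture shape and edge softness of any given instrument are not
  modelled; the hard window reproduces the operational behaviour that
  matters here — parked foci deliver zero power.

The axial Gaussian efficiency (width `axial_sigma`, default 50 um so that
efficiency stays >= 50% over +-35 um of defocus) is an empirical hardware
effect, not something scalar propagation produces; it is applied as a
per-spot weighting factor, not to the simulated volumes.

This is a paraxial model. It is self-consistent with the hologram's own
lens term and sufficient for every *relative* claim tested (power ratios,
flattening, parking, shift equivariance). Absolute PSF widths from it are
optimistic: the simulated two-photon FWHM (~0.27 um lateral / ~1.3 um axial
at 750 nm, NA 1.0) is treated only as a lower bound on what hardware can
measure, never as a prediction of a bench value.

## Hologram synthesis

Synthesis is the direct prism-lens superposition: sum the per-spot complex
exponentials, take the argument, quantize to 256 levels (level k encodes
phase 2 pi k / 256; round-trip error <= pi/256). No iterative optimizer
(Gerchberg-Saxton or similar) is included, deliberately: the engine models
a projector that computes holograms directly, and the cross-talk that
phase-only extraction introduces is part of what the characterization
procedures measure. Zero-magnitude pupil points (destructive-interference
nodes) have undefined phase and are assigned 0; the SLM must display
something there and any fixed choice is equivalent.

**Phase diversity.** The superposition's amplitude |psi| is discarded by
phase-only extraction. If all spots share the same initial phase, that
amplitude is strongly modulated and the extraction redistributes power
wildly between spots (for two symmetric spots the hologram degenerates to a
binary grating: 40.5% efficiency per order). Each spot therefore carries a
constant phase offset phi_n — physically the argument of a complex
amplitude A_n, a free parameter that moves no focus and changes no ideal
power. `gen_hologram` assigns the deterministic quadratic sequence
`phi_n = pi n^2 / sqrt(2)` (mod 2 pi) by index unless the caller has set
explicit phases. A quadratic sequence with an irrational coefficient was
selected, over random seeds and other deterministic schemes, by comparing
inter-spot power uniformity and the 1/N^2 scaling across the layouts used
in the characterization suite; it keeps the pipeline a pure function of its
inputs (bit-identical holograms for identical inputs).

Even with phase diversity, cross-talk is geometry-sensitive: spots on an
exact lattice (or equally spaced along a line) place the superposition's
intermodulation ghosts exactly on other spot positions. The fixture
generators therefore offer irregular geometries: `make_spot_grid` takes a
deterministic low-discrepancy `jitter`, and `make_flattening_line` uses
irregular span fractions (-1, -0.38, 0.21, 0.66, 1) with a 0.2 tilt. The
multiplexing efficiency of the direct algorithm is ~0.6-0.9 of the ideal
split, common to all spots; ratios and fitted exponents are unaffected.

**Amplitude weighting.** Each active spot's amplitude is multiplied by
`min(max_gain, 1/sqrt(lateral_eff * axial_eff))` — delivered intensity
scales as weight^2 x efficiency, so this flattens power across the pattern.
The cap (default 4) prevents far-off-axis spots from consuming unbounded
amplitude. Weights are renormalized to max 1 afterwards; whether a real
implementation renormalizes is an open convention, and max-1 keeps the
brightest spot's scale fixed.

**Parking.** `park_spots` keeps the first k spots and moves the rest just
outside the aperture window, spread on a golden-angle perimeter sequence at
1.25-1.48x the window half-width with a guaranteed 15% margin beyond the
window edge. Spreading is essential: coincident parked foci would merge
coherently into one focus of k-fold amplitude (k^2-fold intensity) and
steal the active spots' power budget, and collinear parked stacks put
strong ghosts back inside the window. With the spread layout the power per
active focus stays constant to within a few percent across k = 1..10.

## Zernike aberrations

OSA/ANSI double indexing (radial p, signed azimuthal q) with orthonormal
scaling: each polynomial has unit RMS over the pupil disk, so a coefficient
is directly its RMS phase contribution in radians (piston Z_0^0 = 1,
oblique astigmatism Z_2^{-2} = sqrt(6) rho^2 sin 2 theta — the dominant
aberration of an obliquely illuminated SLM). A Noll single-index converter
is provided for interoperability. Coefficients may be global or per-spot
(depth-dependent corrections). Because conventions for Zernike magnitude
and sign vary between instruments, coefficient values from any particular
system are not transferable and are not used as reference numbers anywhere
in the tests; the test of record is the closure property (injecting a pupil
aberration and encoding its negation on the hologram restores >= 99% of the
unaberrated two-photon peak).

## Characterization procedures

* `measure_fwhm` — half-maximum crossings by linear interpolation, no
  baseline subtraction (appropriate for background-free simulated
  profiles).
* `per_spot_power` — integral over a ball of radius 3x the lateral FWHM by
  default (the choice is the package's own; results are insensitive to the
  exact radius once it covers the main lobe). For two-photon volumes the
  square root of the integrated signal is reported as delivered power.
* `fit_power_law` — OLS on log F vs log N; the exponent is reported as a
  positive magnitude and r as the correlation magnitude.
* `power_error` — the operational formula `dP = 0.5 dF / P` exactly as
  used with normalized fluorescence readouts. It is dimensionally a hybrid;
  the homogeneous alternative `dP/P = 0.5 dF/F` (error propagation through
  F ~ P^2) is available via `relative=True`.
* `fit_axial_envelope` — nonlinear least squares of the Gaussian model;
  non-decaying data are rejected as unidentifiable.
* `fit_similarity_transform` — Umeyama's closed-form Procrustes solution.
  Reflections are admitted only on request (bead mirror images are
  reflected copies of the target pattern); otherwise the rotation is
  constrained to determinant +1.

## Synthetic data

`make_bead_volume` renders fluorescent beads as solid spheres convolved
with a supplied PSF volume, plus background and seeded Gaussian (default
sigma = 1% of peak) or Poisson noise. Beads are incoherent fluorescence
markers, so image-domain convolution is adequate; no coherent imaging, no
photon-physics, and no dendrite/spine morphology is modelled. Everything is
a pure function of parameters and seed. Consequently, passing tests show
that the *engine* behaves as designed under ideal scalar optics; they do
not certify any particular instrument's aberrations, relay losses, or
detection noise.

## Problem sizes

The characterization studies run at the full 600 px SLM resolution with
pad factor 2 (1200^2 FFTs); the lateral PSF measurement uses pad factor 8
(4800^2, ~0.05 um sampling) and the axial scan 61 planes at pad factor 2.
Unit tests use a reduced 128 px profile where only structural behaviour is
at stake.

## Known limitations

* Paraxial scalar model: no vectorial high-NA effects, no apodization
  beyond the hard pupil disk — absolute PSF widths are optimistic bounds.
* The relay aperture is a hard square window; real fall-off is gradual.
* Phase-only cross-talk is modelled but not corrected (no iterative
  optimizer by design); multi-spot efficiency is ~0.6-0.9 of ideal and
  geometry-dependent.
* The axial efficiency Gaussian is empirical and configurable, not derived.
* No hardware interfacing (SLM driving, microscope software) and no
  photochemistry or electrophysiology downstream of light delivery.
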