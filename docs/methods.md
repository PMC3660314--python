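# Methods

This note documents the models behind `qdti`, the defaults and why they were
chosen, what the synthetic data does and does not emulate, and the numerical
decisions a user should know before trusting a number.

## Optical model

**PSF models.** Two interchangeable models generate every PSF:

* *Gaussian*: separable Gaussian with lateral FWHM `0.51 λ/NA` and axial
  FWHM `0.88 λ/(n − √(n² − NA²))` — the standard confocal approximations.
  Closed-form, so the √n narrowing of an n-th-power PSF is exact and is used
  as the analytic oracle in the tests.
* *Scalar diffraction*: the paraxial Debye integral
  `I(v,u) = |2∫₀¹ J₀(vρ) e^{iuρ²/2} ρ dρ|²` in optical units
  `v = 2πNA·r/λ`, `u = 2πNA²z/(nλ)`, evaluated by 96-point Gauss–Legendre
  quadrature. It carries the Airy-ring structure the Gaussian lacks; the two
  models agree in lateral FWHM to within ~1% at NA 1.4.

Both are paraxial approximations. At NA 1.4 a vectorial model would predict
a slightly wider, polarization-asymmetric focus; index-mismatch aberrations
are likewise out of scope. The model used is recorded in each PSF's
metadata.

**Confocal detection.** The pinhole is applied as a lateral convolution of
the emission PSF with a uniform disk of diameter `pinhole_au × 1.22 λ_em/NA`
(1 Airy unit = Airy-disk diameter). No additional axial pinhole term is
modeled beyond what the excitation × detection product provides; for the
0.7 AU default this underestimates optical sectioning slightly but keeps
the model analytic.

**n-exciton PSF.** `PSF_n = h_excⁿ · h_det(λ_n)`, normalized. Default
detection wavelengths per order are 655 / 620 / 580 nm — the TX *detection*
value (580) corresponds to the blue edge of the 580–610 nm filter, whereas
the TX *emission component* is centered at 590 nm; both are configurable and
deliberately distinct.

**Immersion/embedding indices.** Not specified by the source workflow;
defaults are 1.515 (oil) with the embedding medium assumed index-matched.
Flagged in `OpticalConfig` so users can override.

**Nyquist factor.** Maximum admissible voxel spacing is FWHM/2.3 per axis —
the deconvolution-community convention, slightly stricter than the textbook
factor 2. Configurable.

## Photophysics

QD655 is modeled as three Gaussian spectral components (MX 655 nm, BX
620 nm, TX 590 nm) with a saturating power law for the state populations:

    w_n(I) = y_n · (I / (I + I_sat))^n ,  n = 1, 2, 3.

Below ~0.01·I_sat the log–log slopes are 1/2/3 to better than 0.05; at
0.1·I_sat the saturating form already bends the slope by ~9%, which is why
slope tests fit deep in the asymptotic regime.

Undocumented parameters, chosen once and documented as assumptions:

| parameter | default | rationale |
| --- | --- | --- |
| spectral FWHM (MX/BX/TX) | 30 / 35 / 40 nm | typical CdSe/ZnS QD655 linewidths, broader for higher orders |
| relative yields y_n | 1 : 0.15 : 0.05 | calibrated so the ~610 nm shoulder emerges between low (~10%) and high (~50%) laser settings |
| I_sat | 1.0 (relative) | sets the unit of the relative intensity scale |

With this calibration the TX state appears as a *blue shoulder* on the BX
peak in the total spectrum — matching measured power series — rather than a
free-standing 590 nm maximum. The 590 nm claim is therefore tested on the
separable fitted component, not on a raw local maximum. The BX:TX photon
ratio inside the 580–610 nm detection band is physically unknown; the model
exposes it through the yields rather than asserting a value.

Organic fluorophores (DAPI, Atto488, Alexa700) use the same machinery with
order-1 components. DAPI carries a second broad component (540 nm, FWHM
90 nm, 10% yield) representing its long red emission tail, so its
bleed-through into a 405 nm-excited 580–610 nm channel is an emergent
prediction — and vanishes (<1%) when the TX scan uses 488 nm, reproducing
the published excitation-line workaround. Excitation curves are smooth
hand-written tables (monotone decreasing 400→600 nm for the QD), *not*
digitized vendor data; absolute cross-excitation percentages inherit that
uncertainty.

## Phantoms

Specimens are defined in continuous coordinates (nm) and rendered
analytically: each primitive's indicator function is convolved with an
isotropic Gaussian of σ = half the smallest voxel (25 nm at the default
grid). For spheres and shells the ball⊗Gaussian convolution has a closed
form; for filament tubes the disk⊗Gaussian cross-section is the Rice CDF.
Convolution with a unit-mass kernel preserves integrals, so each
primitive's total emitter count equals amplitude × labeled volume to <1%
regardless of orientation or grid phase (the axial direction is
sub-sampled at ≤1.5σ to keep the midpoint-rule quadrature error below
0.1%). The 25 nm smoothing also stands in for the physical width of an
antibody-decorated filament (~60 nm FWHM), which real immunolabeling adds.

What the phantoms do **not** emulate: realistic cell morphology, labeling
stochasticity (densities are continuous, not discrete emitters), refractive
heterogeneity, and depth-dependent aberrations. A green resolution test
therefore establishes that the *optical pipeline* produces the claimed
fold-gains under ideal specimen conditions — not that a given real sample
will.

Filament layouts use one shared base direction with jittered perpendicular
offsets (≥ min_separation apart) so each profile crosses exactly one
filament; pair layouts, sinusoidal bending and fragmentation (for
depolymerizing intermediate filaments) are options.

## Image formation

Expected photons are linear in emitter density; every phantom label is
driven by every laser line through its excitation table, so cross-talk is
emergent. Convolution uses FFTs with reflective padding. The detector is
Poisson photon noise × gain + offset + Gaussian read noise, clipped to the
bit depth (12 by default). Defaults: QE 0.3, gain 1, offset 10, read noise
2 counts — a plausible PMT regime that reproduces the photon-transfer
property var/mean ≈ gain.

Brightness in the end-to-end experiments is calibrated by a noiseless
render against an *unclipped* detector so the scale factor cannot be
corrupted by 12-bit saturation, then set to ~200 peak counts for cellular
channel images. Spectral scans of dried QD-antibody clusters are calibrated
to ~1500 peak counts (bright specimen, near the 12-bit range): at ~200
counts the TX component — 4% of the MX amplitude — cannot be located to
±2.5 nm from a single scan.

Multiplexing plans: the two three-color panels and the four-color panel are
reproduced exactly (laser lines, band edges, two-scan grouping,
unmix-required flag). Within "Scan 1" channels with non-overlapping bands
are treated as simultaneous; the published table is ambiguous on this and
nothing downstream depends on it. The four-color 430–610 nm spectral scan
has no published bandwidth; 10 nm is used (18 contiguous bands).

## Restoration

`cmle_deconvolve` is standard Richardson–Lucy with a constant background in
the forward model (`PSF ⊛ e + b`), a documented approximation of the
commercial "CMLE" implementations. Numerical choices:

* Circular (FFT) convolution, so forward and adjoint are an exact pair:
  with b = 0 the iteration conserves total intensity to FP precision and
  preserves non-negativity — properties the tests assert. Reflective
  padding (used on the acquisition side) would break exact adjointness;
  structures are kept away from volume borders in the experiments instead.
* Background default = mode of the intensity histogram.
* `snr` maps to damping: multiplicative corrections clipped to
  `[1/c, c]`, `c = 1 + 10/snr`. Undamped when unset.
* 40 iterations by default ("at least 40" in the source workflow).
* Default PSF for TX-band data: the **2-photon** model at the TX
  wavelengths. The 3-photon model is available; `periodicity_score` (the
  strongest non-DC peak of the radially averaged background power spectrum,
  normalized by the spectral median) quantifies the periodic background
  artifact that motivated the 2-photon choice, but no invariant asserts
  which model scores worse — that outcome depends on noise and background
  inhomogeneity this simulator does not fully reproduce.

Unmixing is per-voxel non-negative least squares on band-integrated,
norm-normalized reference signatures, with a collinearity check that names
the offending pair. Exact on noiseless data; the residual image flags model
misfit.

## Resolution metrics

Line profiles are sampled by spline interpolation with in-plane width
averaging. The default is bilinear at voxel-size spacing (what interactive
slicer tools do); the resolution experiments use cubic interpolation at
half-voxel spacing because deconvolved filaments approach the voxel pitch
(~60 nm on a 50 nm grid) and linear interpolation broadens such structures,
biasing the conventional and TX channels unequally and the fold ratio
downward. The choice is applied identically to all channels.

FWHM estimators: linear interpolation at half max above a local baseline
(mean of the outer 15% of samples), and a Gaussian + constant least-squares
fit (default for noisy data; reports R²). Both handle baselines explicitly;
they agree within 3% on noiseless Gaussians.

Enhancement reports store per-structure FWHMs per channel and recompute
fold ratios from those stored values on demand — there is no cached state
to drift.

## Why the absolute bench numbers are not reproduced

Measured structure widths on a real microscope (e.g. ~260 nm for a
microtubule in a conventional QD image) include specimen-induced
aberrations, detection inefficiency and out-of-focus haze that this
simulator deliberately idealizes; our theoretical conventional-channel
width for the same structure is ~150 nm. The *fold ratios* between channels
are robust to this idealization and are what the experiments reproduce
(≥1.4× for TX, ≥1.9× after deconvolution, √3 for the pure PSF narrowing).
Property-based checks (hollow-shell dip contrast, power-law exponents, RL
flux conservation, exact noiseless unmixing, bit-exact multiplexing plans,
spectral-scan additivity) substitute for the absolute values.
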