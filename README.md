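# qdti — quantum-dot tri-exciton confocal imaging, in silico

`qdti` is a simulation and analysis toolkit for **quantum-dot tri-exciton
imaging (QDTI)**, a sub-diffraction technique that runs on a standard
confocal microscope with continuous-wave lasers. Commercial QD655 quantum
dots can absorb up to three photons within one excited-state lifetime;
the mono- (MX), bi- (BX) and tri-exciton (TX) states emit at ~655, ~620 and
~590 nm. Because the TX generation rate scales with the **cube** of the
local excitation intensity, detecting only the blue-shifted TX band narrows
the effective excitation PSF by √3 ≈ 1.7× — no pulsed lasers, no special
hardware. Combined with maximum-likelihood deconvolution and spectral
multiplexing, filamentous and vesicular structures well below the
diffraction limit become resolvable.

The package lets microscopists and method developers reproduce and explore
those claims quantitatively: it models the n-exciton confocal PSF, the
power-dependent QD655 emission spectrum, synthesizes ground-truth specimens
(microtubule-like filaments, solid and hollow vesicles), simulates noisy
confocal acquisition including spectral scans and cross-excitation,
deconvolves with Richardson–Lucy (the "CMLE" family), unmixes spectra, and
measures resolution with FWHM line profiles.

## The model in brief

* n-exciton PSF: `PSF_n(r) = [h_exc(r)]ⁿ · h_det(r; λ_n)` with
  `h_exc` the excitation intensity distribution at 405 nm and `h_det` the
  emission PSF at the n-exciton wavelength convolved with a 0.7 AU pinhole
  disk (1 AU = 1.22 λ_em / NA). Cubing a Gaussian divides its FWHM by √3.
* Exciton populations: `w_n(I) ∝ y_n · (I / (I + I_sat))ⁿ`, giving the
  I¹ / I² / I³ power laws below saturation and bounded brightness above it.
* Image formation: expected photons = Σ_labels density × excitation
  efficiency at the laser line × photons emitted into the detection band,
  convolved with the channel PSF; counts = Poisson(QE·photons)·gain +
  offset + read noise, clipped to 12 bits.
* Restoration: Richardson–Lucy iterations
  `e ← e · [PSF* ⊛ (d / (PSF ⊛ e + b))]` (40 iterations by default), with
  the 2-photon-model PSF at the TX wavelengths — the model that proved
  robust for TX-band data.

## Worked example

```python
from qdti.experiments import filament_resolution_experiment, psf_narrowing_fold

print(round(psf_narrowing_fold(), 2))      # 1.73 — the √3 PSF narrowing

r = filament_resolution_experiment(seed=1)
print(r.n, round(r.fold_qdtx, 2), round(r.fold_decon, 2))
# 12 1.47 2.34
```

The second call builds a seeded phantom of six 25 nm filaments on a
50 nm / 150 nm voxel grid, renders the conventional QD channel
(405 nm → 635–675 nm) and the tri-exciton channel (405 nm³ → 580–610 nm)
with Poisson noise at ~200 peak counts, deconvolves the TX channel
(40 RL iterations, 2-photon-model PSF), and Gaussian-fits FWHMs across the
filaments in all three images. The printed numbers say: across 12 matched
profiles, the TX channel is 1.47× narrower than the conventional channel,
and 2.34× narrower after deconvolution — reproducing the ≥1.4× / ≥1.9×
resolution gains of the technique.

A thin CLI wraps the same library:

```sh
qdti simulate --phantom filaments --seed 1 --out stacks.tif
qdti plan --panel DAPI,QD655,Alexa700
qdti deconvolve stacks.tif decon.tif --psf-model 2p --iterations 40
qdti measure decon.tif --start 1500 3200 0 --end 1500 3200 6350
```

## Acceptance script

`scripts/acceptance.py` recomputes the package's headline quantities from
scratch — the √3 PSF narrowing fold, the filament-resolution folds before
and after deconvolution, and the recovered tri-exciton emission center from
a simulated 550–700 nm spectral scan — and writes them as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All simulations are seeded; the same seed reproduces the same numbers.

## Layout

| module | contents |
| --- | --- |
| `qdti.optics_psf` | optical configs, Gaussian & scalar-diffraction PSFs, pinhole, FWHM, Nyquist |
| `qdti.photophysics` | exciton ladder, emission spectra, detection bands, fluorophore library |
| `qdti.phantoms` | seeded filament / vesicle / test-pattern specimens with exact geometry |
| `qdti.acquisition` | channel & spectral-scan rendering, detector noise, multiplexing plans |
| `qdti.restore` | Richardson–Lucy deconvolution, NNLS spectral unmixing, artifact score |
| `qdti.metrics_io` | line profiles, FWHM estimators, enhancement reports, TIFF I/O |
| `qdti.experiments` | end-to-end seeded experiments used by tests and the acceptance script |

See `docs/methods.md` for the modeling assumptions, parameter defaults and
known limitations.
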