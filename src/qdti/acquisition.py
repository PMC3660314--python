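"""Confocal image formation: channel rendering, spectral scans, scan plans.

A channel render is the linear image-formation model

    expected photons = sum over labels [ density
                                         x excitation efficiency at the laser line
                                         x photons emitted into the detection band ]
                       convolved with the channel's n-exciton PSF,

followed by the detector: counts = clip(Poisson(photons * QE) * gain + offset
+ Gaussian read noise) at the configured bit depth.  Because every phantom
label is driven by every laser line through its excitation spectrum,
cross-excitation and bleed-through are emergent rather than assumed away
(e.g. DAPI excited by a strong 405 nm tri-exciton scan leaks into the
580-610 nm band).

Multiplexing plans reproduce the published acquisition scheme for panels of
QD655 with up to three organic dyes, including the four-color case that
requires a 430-610 nm spectral scan plus linear unmixing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import fftconvolve

from .optics_psf import OpticalConfig, PSF, make_nexciton_psf
from .photophysics import (
    Band,
    Fluorophore,
    FLUOROPHORES,
    Spectrum,
    band_flux,
    emission_spectrum,
)
from .phantoms import Phantom

__all__ = [
    "DetectorModel",
    "ChannelConfig",
    "SpectralScanDirective",
    "ScanPlan",
    "ImageStack",
    "SpectralStack",
    "render_channel",
    "spectral_scan",
    "plan_multiplex",
    "simulate_plan",
]


@dataclass(frozen=True)
class DetectorModel:
    """PMT-style detector: Poisson photon noise, gain, offset, read noise."""

    quantum_efficiency: float = 0.3
    gain: float = 1.0
    offset: float = 10.0
    read_noise_sd: float = 2.0
    bit_depth: int = 12

    def __post_init__(self) -> None:
        if not 0 < self.quantum_efficiency <= 1:
            raise ValueError("quantum_efficiency must be in (0, 1]")
        if self.gain <= 0 or self.read_noise_sd < 0 or self.offset < 0:
            raise ValueError("invalid detector parameters")

    @property
    def max_count(self) -> int:
        return 2**self.bit_depth - 1


@dataclass(frozen=True)
class ChannelConfig:
    """One acquisition channel: laser line + intensity, band, optics."""

    fluorophore: str
    excitation_wavelength: float
    laser_intensity: float
    emission_band: Band
    optical: OpticalConfig
    photon_order: int = 1
    name: str | None = None

    def __post_init__(self) -> None:
        if self.laser_intensity < 0:
            raise ValueError("laser_intensity must be non-negative")

    @property
    def channel_name(self) -> str:
        return self.name or f"{self.fluorophore}_{self.photon_order}x"

    def psf_config(self) -> OpticalConfig:
        return replace(
            self.optical,
            lambda_exc=self.excitation_wavelength,
            lambda_em=self.emission_band.center,
            photon_order=self.photon_order,
        )


@dataclass(frozen=True)
class SpectralScanDirective:
    """Spectral-scan entry of a plan: contiguous bands over a range."""

    excitation_wavelength: float
    range: Band
    bandwidth: float
    unmix_references: tuple[str, ...] = ()


@dataclass
class ScanPlan:
    """Ordered scans; each scan is a list of simultaneous channels or a
    spectral-scan directive.  ``unmix_required`` flags plans whose QDTX
    signal must be separated from a co-excited dye by linear unmixing."""

    scans: list
    unmix_required: bool = False

    def __post_init__(self) -> None:
        for scan in self.scans:
            if isinstance(scan, SpectralScanDirective):
                if not (400.0 <= scan.range.low and scan.range.high <= 750.0):
                    raise ValueError("spectral scan range must lie in [400, 750] nm")
                continue
            bands = [ch.emission_band for ch in scan]
            for i, b1 in enumerate(bands):
                for b2 in bands[i + 1:]:
                    if b1.low < b2.high and b2.low < b1.high:
                        raise ValueError(
                            f"simultaneous channels share emission band "
                            f"[{max(b1.low, b2.low)}, {min(b1.high, b2.high)}]"
                        )


@dataclass
class ImageStack:
    """Voxel data with physical pixel sizes and channel metadata.

    ``values`` is ``[z, y, x]`` for a single channel or ``[c, z, y, x]``
    for multi-channel data, in detector counts (float).
    """

    values: np.ndarray
    dx: float
    dy: float
    dz: float
    channel_names: list[str] = field(default_factory=list)
    bit_depth: int = 12
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (3, 4):
            raise ValueError("ImageStack must be 3D or 4D (c, z, y, x)")

    def channel(self, name: str) -> "ImageStack":
        if self.values.ndim == 3:
            raise ValueError("single-channel stack has no named channels")
        idx = self.channel_names.index(name)
        return ImageStack(self.values[idx], self.dx, self.dy, self.dz,
                          [name], self.bit_depth, dict(self.meta))


@dataclass
class SpectralStack:
    """One image per contiguous detection band of a spectral scan."""

    values: np.ndarray  # [band, z, y, x]
    band_edges: np.ndarray  # nm, length n_bands + 1
    dx: float
    dy: float
    dz: float
    meta: dict = field(default_factory=dict)

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]

    @property
    def band_centers(self) -> np.ndarray:
        return 0.5 * (self.band_edges[:-1] + self.band_edges[1:])

    def band(self, i: int) -> Band:
        return Band(float(self.band_edges[i]), float(self.band_edges[i + 1]))

    def summed_spectrum(self, mask: np.ndarray | None = None) -> Spectrum:
        """Per-band totals over ``mask`` as a spectrum vs band center."""
        vals = self.values if mask is None else self.values * mask[None]
        sums = vals.reshape(self.n_bands, -1).sum(axis=1)
        return Spectrum(self.band_centers, np.clip(sums, 0.0, None))


def _label_spectrum(label: str, excitation_wavelength: float,
                    laser_intensity: float) -> Spectrum:
    """Emission spectrum of a fluorophore under the given drive.

    The intensity driving the exciton ladder is the laser intensity scaled by
    the fluorophore's excitation efficiency at the laser line, so both the
    brightness and the MX/BX/TX balance respond to the excitation spectrum.
    """
    fluor = FLUOROPHORES[label] if isinstance(label, str) else label
    drive = laser_intensity * fluor.excitation_at(excitation_wavelength)
    return emission_spectrum(fluor.emission, drive)


def _convolve_reflect(density: np.ndarray, psf: np.ndarray) -> np.ndarray:
    """FFT convolution with reflective padding, cropped to the input shape."""
    pads = [min(p // 2, s) for p, s in zip(psf.shape, density.shape)]
    padded = np.pad(density, [(p, p) for p in pads], mode="reflect")
    out = fftconvolve(padded, psf, mode="same")
    sl = tuple(slice(p, p + s) for p, s in zip(pads, density.shape))
    return np.clip(out[sl], 0.0, None)


def _apply_detector(photons: np.ndarray, detector: DetectorModel,
                    rng: np.random.Generator | None) -> np.ndarray:
    if rng is None:
        counts = photons * detector.quantum_efficiency * detector.gain + detector.offset
    else:
        pe = rng.poisson(photons * detector.quantum_efficiency)
        counts = (pe * detector.gain + detector.offset
                  + rng.normal(0.0, detector.read_noise_sd, photons.shape))
    return np.clip(counts, 0.0, detector.max_count)


def render_channel(
    phantom: Phantom,
    channel: ChannelConfig,
    detector: DetectorModel = DetectorModel(),
    seed: int | None = 0,
    noise: bool = True,
    psf: PSF | None = None,
    psf_mode: str = "gaussian",
    photon_scale: float = 1.0,
) -> ImageStack:
    """Render one confocal channel of a phantom.

    ``photon_scale`` converts emitter density units to expected photons per
    voxel per unit spectral flux (an overall brightness knob).  ``seed=None``
    or ``noise=False`` disables the stochastic detector.
    """
    cfg = channel.psf_config()
    if not np.allclose([cfg.dx, cfg.dy, cfg.dz],
                       [phantom.dx, phantom.dy, phantom.dz]):
        raise ValueError(
            "channel optics voxel sizes do not match the phantom grid; "
            "resample the phantom or adjust OpticalConfig(dx, dy, dz)"
        )
    if psf is None:
        psf = make_nexciton_psf(cfg, mode=psf_mode)

    expected = np.zeros(phantom.shape)
    any_signal = False
    for label, density in phantom.density.items():
        spec = _label_spectrum(label, channel.excitation_wavelength,
                               channel.laser_intensity)
        flux = band_flux(spec, channel.emission_band)
        if flux > 1e-9 * max(spec.total(), 1e-300):
            any_signal = True
        expected += density * flux
    if not any_signal:
        import warnings

        warnings.warn(
            f"no fluorophore emits into band "
            f"[{channel.emission_band.low}, {channel.emission_band.high}] nm",
            stacklevel=2,
        )
    photons = _convolve_reflect(expected * photon_scale, psf.values)
    rng = np.random.default_rng(seed) if (noise and seed is not None) else None
    counts = _apply_detector(photons, detector, rng)
    return ImageStack(
        counts, phantom.dx, phantom.dy, phantom.dz,
        [channel.channel_name], detector.bit_depth,
        meta={"excitation_nm": channel.excitation_wavelength,
              "band_nm": [channel.emission_band.low, channel.emission_band.high],
              "photon_order": channel.photon_order,
              "psf_mode": psf.meta.get("mode", psf_mode),
              "laser_intensity": channel.laser_intensity},
    )


def spectral_scan(
    phantom: Phantom,
    excitation: ChannelConfig,
    scan_range: Band,
    bandwidth: float,
    detector: DetectorModel = DetectorModel(),
    seed: int | None = 0,
    noise: bool = True,
    psf: PSF | None = None,
    psf_mode: str = "gaussian",
    photon_scale: float = 1.0,
) -> SpectralStack:
    """Acquire contiguous narrow-band images across ``scan_range``.

    The band count is floor(range / bandwidth); ``bandwidth`` must divide the
    range width.  All bands share the PSF of ``excitation`` (one scan, one
    objective/pinhole state).
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    width = scan_range.width
    n_bands = int(round(width / bandwidth))
    if abs(n_bands * bandwidth - width) > 1e-9:
        raise ValueError(
            f"bandwidth {bandwidth} nm does not divide the {width} nm range"
        )
    edges = scan_range.low + bandwidth * np.arange(n_bands + 1)
    if psf is None:
        psf = make_nexciton_psf(excitation.psf_config(), mode=psf_mode)
    rng = np.random.default_rng(seed) if (noise and seed is not None) else None

    # convolve the per-label density once; per-band scaling is then linear
    convolved: dict[str, np.ndarray] = {
        label: _convolve_reflect(density * photon_scale, psf.values)
        for label, density in phantom.density.items()
    }
    spectra = {
        label: _label_spectrum(label, excitation.excitation_wavelength,
                               excitation.laser_intensity)
        for label in phantom.density
    }
    bands = np.empty((n_bands,) + phantom.shape)
    for i in range(n_bands):
        band = Band(float(edges[i]), float(edges[i + 1]))
        photons = np.zeros(phantom.shape)
        for label in phantom.density:
            photons += convolved[label] * band_flux(spectra[label], band)
        bands[i] = _apply_detector(photons, detector, rng)
    return SpectralStack(bands, edges, phantom.dx, phantom.dy, phantom.dz,
                         meta={"excitation_nm": excitation.excitation_wavelength,
                               "laser_intensity": excitation.laser_intensity,
                               "photon_order": excitation.photon_order})


def _optics(dx=50.0, dy=50.0, dz=150.0) -> OpticalConfig:
    return OpticalConfig(dx=dx, dy=dy, dz=dz)


def _channel(fluor: str, exc: float, band: tuple[float, float],
             order: int = 1, intensity: float = 0.05, name: str | None = None,
             optical: OpticalConfig | None = None) -> ChannelConfig:
    return ChannelConfig(fluor, exc, intensity, Band(*band),
                         optical or _optics(), order, name or fluor)


def plan_multiplex(panel: set[str] | frozenset[str],
                   optical: OpticalConfig | None = None,
                   qdtx_intensity: float = 5.0) -> ScanPlan:
    """Published two-scan multiplexing scheme for a fluorophore panel.

    Organic dyes are acquired first at low power; the tri-exciton QD655 scan
    runs second at high power.  The QDTX excitation line is chosen to avoid
    cross-exciting the panel's organics: 488 nm when DAPI is present (405 nm
    would co-excite it), 405 nm when Atto488 is present.  With all four
    fluorophores no clean line exists, so the plan switches to a 430-610 nm
    spectral scan with mandatory DAPI/QDTX unmixing.
    """
    panel = frozenset(panel)
    known = {"DAPI", "Atto488", "QD655", "Alexa700"}
    unknown = panel - known
    if unknown:
        raise ValueError(f"unknown fluorophores in panel: {sorted(unknown)}")
    if "QD655" not in panel:
        raise ValueError("multiplex planning requires QD655 in the panel")
    opt = optical or _optics()

    if panel == {"DAPI", "QD655", "Alexa700"}:
        return ScanPlan([
            [_channel("DAPI", 405.0, (415.0, 470.0), optical=opt),
             _channel("Alexa700", 633.0, (700.0, 750.0), optical=opt)],
            [_channel("QD655", 488.0, (560.0, 610.0), order=3,
                      intensity=qdtx_intensity, name="QDTX", optical=opt)],
        ])
    if panel == {"Atto488", "QD655", "Alexa700"}:
        return ScanPlan([
            [_channel("Atto488", 488.0, (500.0, 530.0), optical=opt),
             _channel("Alexa700", 633.0, (700.0, 750.0), optical=opt)],
            [_channel("QD655", 405.0, (580.0, 610.0), order=3,
                      intensity=qdtx_intensity, name="QDTX", optical=opt)],
        ])
    if panel == {"DAPI", "Atto488", "QD655", "Alexa700"}:
        return ScanPlan([
            [_channel("DAPI", 405.0, (415.0, 470.0), optical=opt),
             _channel("Atto488", 488.0, (500.0, 530.0), optical=opt),
             _channel("Alexa700", 633.0, (700.0, 750.0), optical=opt)],
            SpectralScanDirective(405.0, Band(430.0, 610.0), 10.0,
                                  unmix_references=("DAPI", "QD655")),
        ], unmix_required=True)
    raise ValueError(
        f"no published scheme for panel {sorted(panel)}; supported panels "
        "are {DAPI,QD655,Alexa700}, {Atto488,QD655,Alexa700} and all four"
    )


def simulate_plan(
    phantom: Phantom,
    plan: ScanPlan,
    detector: DetectorModel = DetectorModel(),
    seed: int | None = 0,
    noise: bool = True,
    psf_mode: str = "gaussian",
    photon_scale: float = 1.0,
) -> tuple[ImageStack | None, SpectralStack | None]:
    """Execute a scan plan on a phantom.

    Returns the stacked named channels and, if the plan contains a
    spectral-scan directive, the spectral stack.  Every phantom label is
    rendered into every channel (cross-excitation included), but all plan
    fluorophores must exist in the phantom.
    """
    wanted = set()
    for scan in plan.scans:
        if isinstance(scan, SpectralScanDirective):
            continue
        wanted.update(ch.fluorophore for ch in scan)
    missing = wanted - set(phantom.label_names)
    if missing:
        raise ValueError(f"phantom lacks labels for plan fluorophores: "
                         f"{sorted(missing)}")

    ss = np.random.SeedSequence(seed if seed is not None else None)
    images: list[np.ndarray] = []
    names: list[str] = []
    spectral: SpectralStack | None = None
    for scan, child in zip(plan.scans, ss.spawn(len(plan.scans))):
        sub = int(child.generate_state(1)[0] % (2**31))
        if isinstance(scan, SpectralScanDirective):
            exc = ChannelConfig("QD655", scan.excitation_wavelength, 5.0,
                                scan.range, _optics(phantom.dx, phantom.dy,
                                                    phantom.dz), 3, "QDTX_scan")
            spectral = spectral_scan(phantom, exc, scan.range, scan.bandwidth,
                                     detector, sub, noise,
                                     psf_mode=psf_mode,
                                     photon_scale=photon_scale)
            continue
        for ch in scan:
            img = render_channel(phantom, ch, detector, sub, noise,
                                 psf_mode=psf_mode, photon_scale=photon_scale)
            images.append(img.values)
            names.append(ch.channel_name)
            sub += 1
    stack = None
    if images:
        stack = ImageStack(np.stack(images), phantom.dx, phantom.dy,
                           phantom.dz, names, detector.bit_depth)
    return stack, spectral
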