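"""Multi-exciton QD655 emission spectra and their excitation-intensity dependence.

A quantum dot that absorbs one, two or three photons within one excited-state
lifetime populates the mono- (MX), bi- (BX) or tri-exciton (TX) state.  Each
state emits at a characteristic, progressively blue-shifted wavelength
(QD655: 655 / 620 / 590 nm), and the population of the n-exciton state scales
with the n-th power of the excitation intensity below saturation.  This
module models those spectra as sums of Gaussian components with a saturating
power-law intensity dependence, and integrates them over detection bands.

Component widths are not published for QD655; the defaults (30 / 35 / 40 nm
FWHM for MX / BX / TX) are typical for CdSe/ZnS dots and are configurable.

The same machinery describes ordinary organic fluorophores (DAPI, Atto488,
Alexa700) as single-component, order-1 emitters; see :data:`FLUOROPHORES`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import yaml

__all__ = [
    "SpectralComponent",
    "ExcitonModel",
    "Spectrum",
    "Band",
    "Fluorophore",
    "exciton_weights",
    "emission_spectrum",
    "band_integrate",
    "band_flux",
    "excitation_efficiency",
    "qd655_model",
    "FLUOROPHORES",
]

_DEFAULT_GRID = np.arange(400.0, 750.0 + 1e-9, 1.0)


@dataclass(frozen=True)
class SpectralComponent:
    """One Gaussian emission component.

    ``power_exponent`` is the number of photon absorptions required to
    populate the emitting state (MX: 1, BX: 2, TX: 3); ``relative_yield``
    scales its brightness at saturation.
    """

    label: str
    center: float  # nm
    fwhm: float  # nm
    power_exponent: int
    relative_yield: float

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("spectral FWHM must be positive")
        if self.power_exponent < 1:
            raise ValueError("power_exponent must be >= 1")
        if self.relative_yield < 0:
            raise ValueError("relative_yield must be >= 0")


@dataclass(frozen=True)
class ExcitonModel:
    """Emission model of a (multi-exciton capable) fluorophore."""

    components: tuple[SpectralComponent, ...]
    saturation_intensity: float = 1.0

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("at least one spectral component required")
        if self.saturation_intensity <= 0:
            raise ValueError("saturation_intensity must be positive")
        # higher-order states must be blue-shifted relative to lower orders
        for c1 in self.components:
            for c2 in self.components:
                if c2.power_exponent > c1.power_exponent and c2.center >= c1.center:
                    raise ValueError(
                        "component centers must decrease with exciton order: "
                        f"{c2.label} (order {c2.power_exponent}, {c2.center} nm) "
                        f"vs {c1.label} (order {c1.power_exponent}, {c1.center} nm)"
                    )

    def labels(self) -> list[str]:
        return [c.label for c in self.components]

    def to_yaml(self) -> str:
        payload = {
            "saturation_intensity": self.saturation_intensity,
            "components": [
                {"label": c.label, "center": c.center, "fwhm": c.fwhm,
                 "power_exponent": c.power_exponent,
                 "relative_yield": c.relative_yield}
                for c in self.components
            ],
        }
        return yaml.safe_dump(payload, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ExcitonModel":
        payload = yaml.safe_load(text)
        comps = tuple(SpectralComponent(**c) for c in payload["components"])
        return cls(comps, payload.get("saturation_intensity", 1.0))


@dataclass
class Spectrum:
    """Relative photon flux per nm on a strictly increasing wavelength grid."""

    wavelengths: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavelengths.shape != self.intensity.shape:
            raise ValueError("wavelength and intensity grids differ in length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("spectrum must be non-negative")

    def total(self) -> float:
        return float(np.trapezoid(self.intensity, self.wavelengths))

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.wavelengths, self.intensity]),
                   delimiter=",", header="wavelength_nm,intensity", comments="")


@dataclass(frozen=True)
class Band:
    """A detection band [low, high] in nm."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"band must have low < high, got [{self.low}, {self.high}]")

    @property
    def width(self) -> float:
        return self.high - self.low

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)


def exciton_weights(intensity: float, model: ExcitonModel) -> dict[str, float]:
    """Absolute (unnormalized) brightness of each component at ``intensity``.

    weight = relative_yield * (I / (I + I_sat))^power_exponent, a saturating
    power law: below saturation the n-exciton weight grows as I^n, above it
    the weights level off at the relative yields.
    """
    if intensity < 0:
        raise ValueError("intensity must be non-negative")
    s = intensity / (intensity + model.saturation_intensity)
    return {c.label: c.relative_yield * s**c.power_exponent for c in model.components}


def emission_spectrum(
    model: ExcitonModel,
    intensity: float,
    wavelengths: np.ndarray | None = None,
) -> Spectrum:
    """Summed Gaussian-component emission spectrum at the given intensity."""
    grid = _DEFAULT_GRID if wavelengths is None else np.asarray(wavelengths, float)
    weights = exciton_weights(intensity, model)
    out = np.zeros_like(grid)
    for comp in model.components:
        sigma = comp.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        out += weights[comp.label] * np.exp(-0.5 * ((grid - comp.center) / sigma) ** 2)
    return Spectrum(grid, out)


def band_integrate(spectrum: Spectrum, band: Band) -> float:
    """Fraction of the spectrum's photons falling inside ``band``.

    Trapezoidal integral over the band (edges interpolated) divided by the
    integral over the full grid.  Returns 0 for an all-zero spectrum.
    """
    wl, it = spectrum.wavelengths, spectrum.intensity
    if band.low < wl[0] or band.high > wl[-1]:
        raise ValueError(
            f"band [{band.low}, {band.high}] outside spectrum grid "
            f"[{wl[0]}, {wl[-1]}]"
        )
    total = np.trapezoid(it, wl)
    if total == 0:
        return 0.0
    inner = (wl > band.low) & (wl < band.high)
    xs = np.concatenate([[band.low], wl[inner], [band.high]])
    ys = np.concatenate([[np.interp(band.low, wl, it)], it[inner],
                         [np.interp(band.high, wl, it)]])
    return float(np.trapezoid(ys, xs) / total)


def band_flux(spectrum: Spectrum, band: Band) -> float:
    """Absolute photon flux inside ``band`` (band fraction times total)."""
    return band_integrate(spectrum, band) * spectrum.total()


def qd655_model(
    fwhms: tuple[float, float, float] = (30.0, 35.0, 40.0),
    yields: tuple[float, float, float] = (1.0, 0.15, 0.05),
    centers: tuple[float, float, float] = (655.0, 620.0, 590.0),
    saturation_intensity: float = 1.0,
) -> ExcitonModel:
    """QD655 three-component model (MX / BX / TX).

    Relative yields default to 1 : 0.15 : 0.05 at saturation — a calibration
    chosen so that the ~610 nm shoulder emerges between low (~10%) and high
    (~50%) laser settings, not a measured value.
    """
    mx, bx, tx = (
        SpectralComponent("MX", centers[0], fwhms[0], 1, yields[0]),
        SpectralComponent("BX", centers[1], fwhms[1], 2, yields[1]),
        SpectralComponent("TX", centers[2], fwhms[2], 3, yields[2]),
    )
    return ExcitonModel((mx, bx, tx), saturation_intensity)


@dataclass(frozen=True)
class Fluorophore:
    """A named fluorophore: emission model plus an excitation spectrum.

    The excitation spectrum is a coarse tabulated curve (relative absorption
    vs nm); intermediate wavelengths are linearly interpolated, and values
    outside the table are clamped to the end points.
    """

    name: str
    emission: ExcitonModel
    excitation_wavelengths: tuple[float, ...]
    excitation_values: tuple[float, ...]

    def excitation_at(self, wavelength: float) -> float:
        return float(np.interp(wavelength,
                               self.excitation_wavelengths,
                               self.excitation_values))


def _single_component(name: str, center: float, fwhm: float) -> ExcitonModel:
    return ExcitonModel((SpectralComponent(name, center, fwhm, 1, 1.0),))


# Excitation tables are smooth free-hand approximations of vendor curves
# (not digitized data): QD absorption rises steeply to the blue, organics
# have a single absorption band near their nominal excitation maximum.
FLUOROPHORES: dict[str, Fluorophore] = {
    "QD655": Fluorophore(
        "QD655",
        qd655_model(),
        (300, 350, 400, 405, 450, 488, 520, 561, 600, 620, 640),
        (3.0, 2.2, 1.55, 1.5, 1.0, 0.62, 0.42, 0.22, 0.08, 0.04, 0.01),
    ),
    "DAPI": Fluorophore(
        "DAPI",
        # main band plus the broad red tail that leaks into yellow channels
        ExcitonModel((
            SpectralComponent("DAPI", 461.0, 55.0, 1, 1.0),
            SpectralComponent("DAPI_tail", 540.0, 90.0, 1, 0.10),
        )),
        (300, 340, 358, 380, 405, 430, 460, 480, 488, 520),
        (0.25, 0.78, 1.0, 0.85, 0.45, 0.12, 0.012, 0.002, 0.001, 0.0),
    ),
    "Atto488": Fluorophore(
        "Atto488",
        _single_component("Atto488", 523.0, 35.0),
        (300, 400, 430, 460, 488, 501, 520, 540, 560, 600),
        (0.08, 0.05, 0.10, 0.35, 0.85, 1.0, 0.65, 0.18, 0.03, 0.0),
    ),
    "Alexa700": Fluorophore(
        "Alexa700",
        _single_component("Alexa700", 723.0, 40.0),
        (300, 400, 488, 550, 600, 633, 660, 680, 702, 720, 750),
        (0.12, 0.03, 0.02, 0.04, 0.12, 0.30, 0.60, 0.85, 1.0, 0.75, 0.15),
    ),
}


def excitation_efficiency(fluorophore: str | Fluorophore, wavelength: float) -> float:
    """Relative excitation efficiency of a fluorophore at a laser line."""
    if isinstance(fluorophore, str):
        try:
            fluorophore = FLUOROPHORES[fluorophore]
        except KeyError:
            raise KeyError(f"unknown fluorophore {fluorophore!r}; "
                           f"known: {sorted(FLUOROPHORES)}") from None
    return fluorophore.excitation_at(wavelength)
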