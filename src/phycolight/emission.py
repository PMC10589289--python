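"""Chlorophyll-a emission analysis: 685-nm peak / 730-nm shoulder summaries,
green:blue emission ratios, and the excitation-intensity adjustment used to
compare light-energy transfer to PS II versus PS I."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .spectrum import Spectrum
from .spectra import peak_in_window

__all__ = [
    "ExcitationSetting", "EmissionSummary", "BLUE", "GREEN",
    "summarize_emission", "green_blue_ratio", "adjust_for_excitation",
    "band_integral", "compare_psii_fraction_estimates",
]

PEAK_WINDOW = (670.0, 700.0)
VALID_PEAK_RANGE = (680.0, 690.0)


@dataclass(frozen=True)
class ExcitationSetting:
    """Excitation LED configuration of the emission spectrometer."""

    color: str  # "blue" | "green"
    peak: float  # nm
    intensity: float  # instrument relative units

    def __post_init__(self) -> None:
        if self.intensity <= 0:
            raise ValueError("excitation intensity must be positive")


BLUE = ExcitationSetting("blue", 452.0, 200.0)
GREEN = ExcitationSetting("green", 525.0, 600.0)


@dataclass
class EmissionSummary:
    peak685: float
    shoulder730: float
    peak_wavelength: float
    has_peak: bool
    excitation: Optional[ExcitationSetting] = None


def _excitation_from_meta(meta: dict) -> Optional[ExcitationSetting]:
    if "excitation_nm" not in meta or "excitation_ru" not in meta:
        return None
    nm = float(meta["excitation_nm"])
    color = str(meta.get("excitation_color", "blue" if nm < 500 else "green"))
    return ExcitationSetting(color, nm, float(meta["excitation_ru"]))


def summarize_emission(s: Spectrum,
                       peak_window: tuple[float, float] = PEAK_WINDOW) -> EmissionSummary:
    """Summarise a chlorophyll-a emission spectrum.

    The main emission peak is the quadratic-refined maximum inside
    ``peak_window``; a flat or absent band (no interior local maximum, or a
    refined position outside 680-690 nm) yields ``has_peak=False`` with the
    window maximum reported, never an error. The 730-nm shoulder value is
    read by linear interpolation.
    """
    if s.kind != "emission":
        raise ValueError(f"expected an emission spectrum, got kind={s.kind!r}")
    if s.wavelengths[0] > 670 or s.wavelengths[-1] < 730:
        raise ValueError("emission grid must cover at least 670-730 nm")
    try:
        pk = peak_in_window(s, peak_window)
        wl, value = pk.wavelength, pk.value
        has_peak = VALID_PEAK_RANGE[0] <= wl <= VALID_PEAK_RANGE[1]
    except ValueError:
        mask = (s.wavelengths >= peak_window[0]) & (s.wavelengths <= peak_window[1])
        i = int(np.argmax(s.values[mask]))
        wl = float(s.wavelengths[mask][i])
        value = float(s.values[mask][i])
        has_peak = False
    return EmissionSummary(
        peak685=float(value),
        shoulder730=s.value_at(730.0),
        peak_wavelength=float(wl),
        has_peak=has_peak,
        excitation=_excitation_from_meta(s.meta),
    )


def green_blue_ratio(green: EmissionSummary, blue: EmissionSummary) -> float:
    """Ratio of the green-excitation to blue-excitation emission peak values."""
    if blue.peak685 <= 0:
        raise ValueError("undefined ratio: blue emission peak is zero")
    return green.peak685 / blue.peak685


def adjust_for_excitation(raw_ratio: float,
                          green_setting: ExcitationSetting = GREEN,
                          blue_setting: ExcitationSetting = BLUE) -> float:
    """Correct a raw green:blue emission ratio for unequal excitation intensity.

    Divides by the green/blue intensity ratio so both channels are compared
    at equal excitation energy; with the default instrument settings
    (600 vs 200 relative units) this divides the raw ratio by 3.
    """
    return raw_ratio / (green_setting.intensity / blue_setting.intensity)


def band_integral(s: Spectrum, window: tuple[float, float] = (670.0, 750.0)) -> float:
    """Trapezoid integral of the emission band, for integral-based ratios."""
    mask = (s.wavelengths >= window[0]) & (s.wavelengths <= window[1])
    return float(np.trapezoid(s.values[mask], s.wavelengths[mask]))


@dataclass
class FractionComparison:
    absorbance_fraction: float
    emission_fraction: float
    difference_pp: float  # absorbance minus emission, percentage points


def compare_psii_fraction_estimates(absorbance_fraction: float,
                                    emission_fraction: float) -> FractionComparison:
    """Compare the absorbance-derived and emission-derived PS II Chl-a fractions.

    The emission-based fraction must be supplied by the caller (e.g. from an
    external calibration of the adjusted green:blue ratio); no default
    mapping from ratio to fraction is assumed.
    """
    for name, f in (("absorbance_fraction", absorbance_fraction),
                    ("emission_fraction", emission_fraction)):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    return FractionComparison(
        absorbance_fraction=absorbance_fraction,
        emission_fraction=emission_fraction,
        difference_pp=100.0 * (absorbance_fraction - emission_fraction),
    )
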