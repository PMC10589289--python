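"""Synthetic fixtures with known ground truth: Gaussian pigment-band
absorbance spectra, two-band chlorophyll emission spectra, Webb-consistent
rapid light curves, and replicated pigment concentration tables.

Every generator takes an explicit seed; no global random state is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .rlc import DarkReading, LightStep, RLCRecord
from .spectrum import Spectrum, default_grid

__all__ = [
    "Band", "SpeciesProfile", "RLCSimConfig", "PalmariaFixture",
    "DEFAULT_IRRADIANCES", "gaussian_band", "default_palmaria_profile",
    "make_palmaria_spectra", "make_emission_spectrum", "simulate_rlc",
    "make_pigment_table", "PIGMENT_MEANS",
]

# Actinic irradiance programme of the light-curve protocol (umol photons m-2 s-1);
# the 0 entry is the dark step.
DEFAULT_IRRADIANCES: tuple[float, ...] = (
    0, 7, 14, 20, 27, 38, 56, 85, 125, 186, 243, 341, 445,
)

_FOUR_LN2 = 4.0 * math.log(2.0)


@dataclass(frozen=True)
class Band:
    """A Gaussian pigment band: peak center (nm), FWHM (nm), peak amplitude."""

    center: float
    fwhm: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    def __call__(self, wavelengths: np.ndarray) -> np.ndarray:
        x = (np.asarray(wavelengths, dtype=float) - self.center) / self.fwhm
        return self.amplitude * np.exp(-_FOUR_LN2 * x * x)


def gaussian_band(band: Band, grid: np.ndarray, kind: str = "absorbance") -> Spectrum:
    """Evaluate a single Gaussian band on ``grid``.

    The value at the band center equals the amplitude and the value at
    center +/- fwhm/2 equals half the amplitude.
    """
    grid = np.asarray(grid, dtype=float)
    if not grid[0] <= band.center <= grid[-1]:
        raise ValueError(
            f"band center {band.center} nm outside grid [{grid[0]}, {grid[-1]}] nm")
    return Spectrum(grid, band(grid), kind)


@dataclass(frozen=True)
class SpeciesProfile:
    """Pigment-band composition of the fluorescent (LHC II + PS II) and
    non-fluorescent (LHC I + PS I) absorbance fractions.

    ``psII_red_fraction`` sets the share of the total red-peak absorbance
    contributed by the PS II chlorophyll-a band; the red-band amplitudes in
    the band lists are rescaled accordingly by the spectrum builder.
    """

    psII_bands: tuple[Band, ...]
    psI_bands: tuple[Band, ...]
    psII_red_fraction: float = 0.40
    red_window: tuple[float, float] = (640.0, 700.0)

    def __post_init__(self) -> None:
        if not self.psII_bands or not self.psI_bands:
            raise ValueError("both band lists must be non-empty")
        if not 0.0 <= self.psII_red_fraction <= 1.0:
            raise ValueError("psII_red_fraction must lie in [0, 1]")


def default_palmaria_profile(psII_red_fraction: float = 0.40,
                             pe_centers: tuple[float, float] = (495.0, 545.0),
                             red_centers: tuple[float, float] = (676.0, 681.0),
                             red_fwhm: float = 24.0) -> SpeciesProfile:
    """Red-algal profile: PE peak + shoulder and a blue Soret band feed PS II;
    a slightly red-shifted chlorophyll band plus Soret feed PS I."""
    psII = (
        Band(435.0, 40.0, 0.80),
        Band(pe_centers[0], 30.0, 1.00),
        Band(pe_centers[1], 40.0, 0.70),
        Band(red_centers[0], red_fwhm, psII_red_fraction),
    )
    psI = (
        Band(437.0, 40.0, 0.50),
        Band(red_centers[1], red_fwhm, 1.0 - psII_red_fraction),
    )
    return SpeciesProfile(psII, psI, psII_red_fraction)


@dataclass
class PalmariaFixture:
    total: Spectrum
    aPSII_true: Spectrum
    psI_true: Spectrum
    extract: Spectrum  # aPSII_true x dilution, exercises the normalization step
    truth: dict


def _split_red(bands: Sequence[Band], window: tuple[float, float]):
    red = [b for b in bands if window[0] <= b.center <= window[1]]
    other = [b for b in bands if not window[0] <= b.center <= window[1]]
    return red, other


def _solve_psii_red_amplitude(f: float, psii_red: Band, psi_red: list[Band],
                              total_red_amp: float) -> float:
    """Amplitude a such that a equals f times the red-peak value of the
    summed red bands (so the detected PS II fraction recovers f exactly)."""
    if f >= 1.0:
        return total_red_amp
    lo = min([psii_red.center] + [b.center for b in psi_red]) - 10
    hi = max([psii_red.center] + [b.center for b in psi_red]) + 10
    fine = np.linspace(lo, hi, int((hi - lo) * 100) + 1)
    psi_vals = sum(b(fine) for b in psi_red)
    shape = Band(psii_red.center, psii_red.fwhm, 1.0)(fine)
    a = f * total_red_amp
    for _ in range(100):
        a_new = f * float(np.max(a * shape + psi_vals))
        if abs(a_new - a) < 1e-14:
            a = a_new
            break
        a = a_new
    return a


def make_palmaria_spectra(profile: SpeciesProfile,
                          grid: Optional[np.ndarray] = None,
                          dilution: float = 0.5) -> PalmariaFixture:
    """Build a whole-tissue absorbance spectrum, its true PS II / PS I
    components, and a diluted extract, with a ground-truth sidecar.

    The total equals the sum of the two components at every grid point.
    Red-band amplitudes are rescaled so that the PS II band's peak value is
    ``psII_red_fraction`` of the summed red-peak absorbance; the PS I red
    amplitude is normalised to ``1 - psII_red_fraction``.
    """
    if grid is None:
        grid = default_grid(400.0, 800.0, 1.0)
    if dilution <= 0:
        raise ValueError("dilution must be positive")
    f = profile.psII_red_fraction
    psii_red, psii_other = _split_red(profile.psII_bands, profile.red_window)
    psi_red, psi_other = _split_red(profile.psI_bands, profile.red_window)
    if len(psii_red) != 1:
        raise ValueError("profile must contain exactly one PS II red band")

    total_red_amp = sum(b.amplitude for b in psii_red + psi_red)
    psi_red_scaled = []
    psi_amp_sum = sum(b.amplitude for b in psi_red)
    for b in psi_red:
        share = b.amplitude / psi_amp_sum if psi_amp_sum > 0 else 0.0
        psi_red_scaled.append(Band(b.center, b.fwhm, (1.0 - f) * total_red_amp * share))
    a_psii = _solve_psii_red_amplitude(f, psii_red[0], psi_red_scaled, total_red_amp)
    psii_red_scaled = [Band(psii_red[0].center, psii_red[0].fwhm, a_psii)]

    psii_bands = list(psii_other) + psii_red_scaled
    psi_bands = list(psi_other) + psi_red_scaled
    apsii_vals = sum(b(grid) for b in psii_bands)
    psi_vals = sum(b(grid) for b in psi_bands)

    apsii = Spectrum(grid, apsii_vals, "absorbance", {"component": "aPSII"})
    psi = Spectrum(grid, psi_vals, "absorbance", {"component": "psI"})
    total = Spectrum(grid, apsii_vals + psi_vals, "absorbance", {"component": "total"})
    extract = Spectrum(grid, apsii_vals * dilution, "absorbance",
                       {"component": "extract", "dilution": dilution})
    truth = {
        "psII_red_fraction": f,
        "psII_red_center": psii_red[0].center,
        "psI_red_centers": [b.center for b in psi_red],
        "dilution": dilution,
        "psII_red_amplitude": a_psii,
    }
    return PalmariaFixture(total=total, aPSII_true=apsii, psI_true=psi,
                           extract=extract, truth=truth)


_EXCITATION = {"blue": (452.0, 200.0), "green": (525.0, 600.0)}


def make_emission_spectrum(excitation: str, peak685: float,
                           shoulder_ratio: float = 0.4,
                           noise_sd: float = 0.0,
                           seed: Optional[int] = None,
                           grid: Optional[np.ndarray] = None) -> Spectrum:
    """Two-band chlorophyll-a emission spectrum: a 685-nm peak (FWHM 25 nm)
    and a 730-nm shoulder (FWHM 50 nm, amplitude ``shoulder_ratio x peak685``),
    tagged with the excitation LED metadata."""
    if excitation not in _EXCITATION:
        raise ValueError(f"excitation must be 'blue' or 'green', got {excitation!r}")
    if peak685 < 0:
        raise ValueError("peak685 must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if grid is None:
        grid = default_grid(600.0, 850.0, 1.0)
    values = Band(685.0, 25.0, peak685)(grid)
    if shoulder_ratio > 0:
        values = values + Band(730.0, 50.0, shoulder_ratio * peak685)(grid)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=grid.size)
    nm, ru = _EXCITATION[excitation]
    meta = {"excitation_color": excitation, "excitation_nm": nm, "excitation_ru": ru}
    return Spectrum(grid, values, "emission", meta)


@dataclass(frozen=True)
class RLCSimConfig:
    """Ground-truth configuration for a simulated rapid light curve."""

    alpha: float
    E_K: float
    irradiances: tuple[float, ...] = DEFAULT_IRRADIANCES
    F0_dark: float = 220.0
    Fm_dark: float = 580.0
    noise_sd: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.E_K <= 0:
            raise ValueError("alpha and E_K must be positive")
        es = self.irradiances
        if any(e < 0 for e in es) or any(b <= a for a, b in zip(es, es[1:])):
            raise ValueError("irradiances must be non-negative and strictly increasing")
        if not 0 < self.F0_dark < self.Fm_dark:
            raise ValueError("require 0 < F0_dark < Fm_dark")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def simulate_rlc(config: RLCSimConfig) -> RLCRecord:
    """Generate an RLC record whose noiseless yields are exactly consistent
    with the Webb model rETR(E) = alpha * E_K * (1 - exp(-E/E_K)).

    F'_m declines with irradiance as Fm_dark / (1 + E / (2 E_K)) — a
    quenching stand-in whose exact form never enters the fitted
    parameters, because F is chosen so that (F'_m - F)/F'_m = rETR(E)/E.
    """
    rng = np.random.default_rng(config.seed)
    steps: list[LightStep] = []
    for E in config.irradiances:
        if E == 0:
            steps.append(LightStep(0.0, config.F0_dark, config.Fm_dark))
            continue
        retr = config.alpha * config.E_K * (1.0 - math.exp(-E / config.E_K))
        phi = retr / E
        if phi > 1.0:
            raise ValueError(
                f"config implies operational yield {phi:.3f} > 1 at E={E}; reduce alpha")
        fm_prime = config.Fm_dark / (1.0 + E / (2.0 * config.E_K))
        f = fm_prime * (1.0 - phi)
        if config.noise_sd > 0:
            f += rng.normal(0.0, config.noise_sd)
            fm_prime += rng.normal(0.0, config.noise_sd)
            fm_prime = max(fm_prime, 1e-6)
        steps.append(LightStep(float(E), float(f), float(fm_prime)))
    dark = DarkReading(config.F0_dark, config.Fm_dark)
    meta = {"alpha_true": config.alpha, "E_K_true": config.E_K,
            "noise_sd": config.noise_sd, "seed": config.seed}
    return RLCRecord(dark=dark, steps=steps, meta=meta)


# Approximate per-cell mean concentrations (ug pigment per g wet weight)
# keyed by (species, tissue_age, season). Ulva is thallus-only ("new").
PIGMENT_MEANS: dict[tuple[str, str, str], dict[str, float]] = {
    ("Ulva", "new", "January"): {
        "Chl a": 2500.0, "Chl b": 1000.0, "lut": 350.0, "neo": 80.0, "viola": 112.0,
    },
    ("Ulva", "new", "October"): {
        "Chl a": 1000.0, "Chl b": 400.0, "lut": 150.0, "neo": 40.0, "viola": 50.0,
        "be-car": 50.0,
    },
    ("A. esculenta", "new", "January"): {"Chl a": 750.0},
    ("A. esculenta", "old", "January"): {"Chl a": 750.0},
    ("A. esculenta", "new", "October"): {"Chl a": 840.0},
    ("A. esculenta", "old", "October"): {"Chl a": 840.0},
    ("L. digitata", "new", "January"): {"Chl a": 175.0},
    ("L. digitata", "old", "January"): {"Chl a": 300.0},
    ("L. digitata", "new", "October"): {"Chl a": 160.0},
    ("L. digitata", "old", "October"): {"Chl a": 275.0},
    ("S. latissima", "new", "January"): {"Chl a": 130.0},
    ("S. latissima", "old", "January"): {"Chl a": 300.0},
    ("S. latissima", "new", "October"): {"Chl a": 340.0},
    ("S. latissima", "old", "October"): {"Chl a": 162.0},
}


def make_pigment_table(seed: Optional[int] = None,
                       cv: float = 0.15,
                       n_replicates: int = 3,
                       means: Optional[dict] = None) -> pd.DataFrame:
    """Long-format pigment concentration table with replicated cells.

    Each (species, tissue_age, season, pigment) cell receives
    ``n_replicates`` draws around the configured mean with multiplicative
    lognormal noise of coefficient of variation ``cv`` (mean-preserving).
    ``cv=0`` reproduces the means exactly.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    rng = np.random.default_rng(seed)
    sigma = math.sqrt(math.log1p(cv * cv))
    rows = []
    table = PIGMENT_MEANS if means is None else means
    for (species, tissue, season), pigments in table.items():
        for pigment, mean in pigments.items():
            for rep in range(1, n_replicates + 1):
                factor = 1.0 if sigma == 0 else rng.lognormal(-0.5 * sigma * sigma, sigma)
                rows.append({
                    "species": species, "tissue_age": tissue, "season": season,
                    "pigment": pigment, "replicate": rep,
                    "concentration": mean * factor,
                })
    return pd.DataFrame(rows)
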