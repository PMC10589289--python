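"""Core spectral container shared by every analysis stage."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

KINDS = ("absorbance", "reflectance", "emission")


@dataclass
class Spectrum:
    """A sampled optical spectrum on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths
        Grid in nanometres, strictly increasing, typically 1 nm spacing.
    values
        One value per grid point: dimensionless absorbance, reflectance
        fraction, or emission flux (nmol photons m^-2 s^-1).
    kind
        One of ``"absorbance"``, ``"reflectance"``, ``"emission"``.
    meta
        Free-form metadata (sample id, species, date, excitation info ...).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}; expected one of {KINDS}")
        if self.wavelengths.ndim != 1 or self.values.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D")
        if self.wavelengths.size != self.values.size:
            raise ValueError(
                f"grid/value length mismatch: {self.wavelengths.size} != {self.values.size}"
            )
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind in ("absorbance", "reflectance") and not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.kind} values must be finite")

    def __len__(self) -> int:
        return int(self.wavelengths.size)

    def value_at(self, wavelength: float) -> float:
        """Linearly interpolated value at ``wavelength`` (must lie on the grid span)."""
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if not (lo <= wavelength <= hi):
            raise ValueError(f"wavelength {wavelength} nm outside grid [{lo}, {hi}] nm")
        return float(np.interp(wavelength, self.wavelengths, self.values))

    def with_values(self, values: np.ndarray) -> "Spectrum":
        """Copy of this spectrum with replaced values (grid, kind and meta shared)."""
        return Spectrum(self.wavelengths.copy(), np.asarray(values, dtype=float),
                        self.kind, dict(self.meta))

    def same_grid(self, other: "Spectrum") -> bool:
        return (self.wavelengths.size == other.wavelengths.size
                and bool(np.array_equal(self.wavelengths, other.wavelengths)))


def require_common_grid(a: Spectrum, b: Spectrum) -> None:
    if not a.same_grid(b):
        raise ValueError("spectra are not on a common wavelength grid")


def default_grid(start: float = 400.0, stop: float = 800.0, step: float = 1.0) -> np.ndarray:
    """Inclusive wavelength grid in nm."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)
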