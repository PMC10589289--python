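"""Rapid light curves: fluorescence yields, rETR, and the Webb saturating-
exponential photosynthesis-irradiance fit.

The model fitted is ``rETR(E) = alpha * E_K * (1 - exp(-E / E_K))`` with the
light saturation parameter ``E_K = rETR_max / alpha``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "DarkReading", "LightStep", "RLCRecord", "StepResult", "PhotoParams",
    "QCReport", "max_quantum_yield", "operational_yield", "relative_etr",
    "webb_model", "fit_webb", "fit_record", "light_saturation",
    "step_results", "qc_fluorescence",
]


@dataclass(frozen=True)
class DarkReading:
    """Minimum (F0) and maximum (Fm) fluorescence after dark acclimation, mV."""

    F0: float
    Fm: float

    def __post_init__(self) -> None:
        if self.Fm <= 0:
            raise ValueError("Fm must be positive")
        if self.F0 < 0:
            raise ValueError("F0 must be non-negative")
        if self.F0 > self.Fm:
            raise ValueError("inverted dark reading: F0 > Fm")


@dataclass(frozen=True)
class LightStep:
    """One actinic-light step: irradiance E plus fluorescence F and F'_m, mV."""

    E: float
    F: float
    Fm_prime: float

    def __post_init__(self) -> None:
        if self.E < 0:
            raise ValueError("irradiance must be non-negative")
        if self.Fm_prime <= 0:
            raise ValueError("Fm_prime must be positive")


@dataclass
class RLCRecord:
    """A full rapid light curve: dark reading plus ordered light steps."""

    dark: DarkReading
    steps: list[LightStep]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        es = [s.E for s in self.steps]
        if any(b <= a for a, b in zip(es, es[1:])):
            raise ValueError("steps must be sorted by strictly ascending irradiance")


@dataclass(frozen=True)
class StepResult:
    E: float
    phi_prime: float
    rETR: float
    clipped: bool = False


@dataclass
class PhotoParams:
    """Fitted photosynthesis-irradiance parameters and fit diagnostics."""

    alpha: float
    rETR_max: float
    E_K: float
    Fv_Fm: float = float("nan")
    sse: float = float("nan")
    converged: bool = True
    n_points: int = 0


@dataclass
class QCReport:
    passed: bool
    flags: list[tuple[str, float]]
    bounds: tuple[float, float]


def max_quantum_yield(dark: DarkReading) -> float:
    """Maximum PS II quantum yield F_v/F_m = (Fm - F0)/Fm, in [0, 1]."""
    return (dark.Fm - dark.F0) / dark.Fm


def operational_yield(step: LightStep) -> float:
    """Operational PS II quantum yield (F'_m - F)/F'_m under actinic light.

    Negative values (measurement noise with F > F'_m) are clipped to 0 with
    a warning; use :func:`step_results` to retrieve the clip flag.
    """
    phi = (step.Fm_prime - step.F) / step.Fm_prime
    if phi < 0:
        warnings.warn(
            f"negative operational yield {phi:.4f} at E={step.E}; clipped to 0",
            stacklevel=2,
        )
        return 0.0
    return phi


def relative_etr(phi_prime: float, E: float) -> float:
    """Relative electron transport rate: phi'_PSII x E_PAR."""
    if not 0.0 <= phi_prime <= 1.0:
        raise ValueError("phi_prime must lie in [0, 1]")
    if E < 0:
        raise ValueError("irradiance must be non-negative")
    return phi_prime * E


def step_results(record: RLCRecord) -> list[StepResult]:
    """Per-step (E, phi', rETR) table; the E=0 step contributes rETR = 0."""
    out: list[StepResult] = []
    for step in record.steps:
        if step.E == 0:
            out.append(StepResult(0.0, max_quantum_yield(record.dark), 0.0))
            continue
        raw = (step.Fm_prime - step.F) / step.Fm_prime
        clipped = raw < 0
        phi = 0.0 if clipped else raw
        out.append(StepResult(step.E, phi, relative_etr(phi, step.E), clipped))
    return out


def webb_model(E: np.ndarray, alpha: float, E_K: float) -> np.ndarray:
    E = np.asarray(E, dtype=float)
    return alpha * E_K * (1.0 - np.exp(-E / E_K))


def light_saturation(rETR_max: float, alpha: float) -> float:
    """Light saturation parameter E_K = rETR_max / alpha."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return rETR_max / alpha


def _initial_guess(E: np.ndarray, r: np.ndarray) -> tuple[float, float]:
    order = np.argsort(E)
    E, r = E[order], r[order]
    # slope through the origin averaged over the two lowest irradiances
    slopes = r[:2] / E[:2]
    alpha0 = float(np.mean(slopes))
    if not alpha0 > 0:
        alpha0 = max(float(np.max(r)) / float(np.max(E)), 1e-6)
    sat = E[r >= 0.63 * np.max(r)]
    ek0 = float(sat[0]) if sat.size else float(np.median(E))
    if ek0 <= 0:
        ek0 = float(np.median(E))
    return alpha0, ek0


def fit_webb(curve: Sequence[tuple[float, float]]) -> PhotoParams:
    """Least-squares Webb fit of (E, rETR) pairs via Nelder-Mead.

    The search runs on (log alpha, log E_K) so both parameters stay
    positive; the origin (0, 0) is included as a fixed model point and
    any supplied E = 0 entries are dropped (rETR(0) = 0 identically).
    """
    arr = np.asarray(list(curve), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("curve must be a sequence of (E, rETR) pairs")
    E, r = arr[:, 0], arr[:, 1]
    mask = E > 0
    E, r = E[mask], r[mask]
    if E.size < 4:
        raise ValueError("need at least 4 points with E > 0")
    if np.all(r == 0):
        raise ValueError("no photosynthetic signal: all rETR are zero")

    Efit = np.concatenate([[0.0], E])
    rfit = np.concatenate([[0.0], r])

    def sse(logp: np.ndarray) -> float:
        a, ek = math.exp(logp[0]), math.exp(logp[1])
        resid = rfit - webb_model(Efit, a, ek)
        return float(resid @ resid)

    a0, ek0 = _initial_guess(E, r)
    x0 = np.log([a0, ek0])
    # fatol is absolute in scipy; scale it to the starting SSE so noisy fits
    # terminate instead of chasing sub-ulp improvements
    fatol = 1e-12 * (1.0 + sse(x0))
    res = minimize(
        sse,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": fatol, "maxiter": 10000, "maxfev": 10000},
    )
    alpha, ek = float(math.exp(res.x[0])), float(math.exp(res.x[1]))
    return PhotoParams(
        alpha=alpha,
        rETR_max=alpha * ek,
        E_K=ek,
        sse=float(res.fun),
        converged=bool(res.success),
        n_points=int(E.size),
    )


def fit_record(record: RLCRecord) -> PhotoParams:
    """Fit a full RLC record: Webb parameters plus F_v/F_m from the dark reading."""
    table = step_results(record)
    params = fit_webb([(s.E, s.rETR) for s in table if s.E > 0])
    params.Fv_Fm = max_quantum_yield(record.dark)
    return params


def qc_fluorescence(record: RLCRecord,
                    bounds: tuple[float, float] = (200.0, 600.0)) -> QCReport:
    """Flag fluorescence readings outside the signal-to-noise window (inclusive).

    QC failure never aborts processing; the report simply lists offenders.
    """
    lo, hi = bounds
    flags: list[tuple[str, float]] = []
    for label, value in (("F0", record.dark.F0), ("Fm", record.dark.Fm)):
        if not lo <= value <= hi:
            flags.append((label, value))
    for step in record.steps:
        if step.E == 0:
            continue
        if not lo <= step.F <= hi:
            flags.append((f"F@E={step.E:g}", step.F))
        if not lo <= step.Fm_prime <= hi:
            flags.append((f"Fm_prime@E={step.E:g}", step.Fm_prime))
    return QCReport(passed=not flags, flags=flags, bounds=bounds)
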