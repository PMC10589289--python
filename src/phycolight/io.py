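"""Delimited-text I/O for spectra, rapid-light-curve tables and pigment tables.

Spectrum files are two-column delimited text (wavelength_nm, value) with
``#``-prefixed ``key: value`` metadata header lines. RLC files carry the
columns ``step, E_PAR, F, Fm_prime`` with the dark reading on the E_PAR = 0
row. The comma is the default delimiter; tabs are accepted on read.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Union

import numpy as np
import pandas as pd

from .rlc import DarkReading, LightStep, RLCRecord
from .spectrum import Spectrum

__all__ = [
    "read_spectrum", "write_spectrum", "read_rlc", "write_rlc",
    "read_pigment_table", "write_pigment_table", "PIGMENT_VOCABULARY",
]

PIGMENT_VOCABULARY = (
    "Chl a", "Chl b", "Chl c1+c2", "fuco", "lut", "neo", "viola",
    "bb-car", "be-car", "fuco-der",
)

_REQUIRED_EMISSION_KEYS = ("excitation_nm", "excitation_ru")


class ParseError(ValueError):
    """Input file violates the expected delimited-text layout."""


def _coerce(text: str) -> Any:
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    return text


def _split_row(line: str) -> list[str]:
    if "," in line:
        return [c.strip() for c in line.split(",")]
    return line.split()


def read_spectrum(path: Union[str, Path]) -> Spectrum:
    """Read a spectrum file; see the module docstring for the layout.

    Raises :class:`ParseError` with the offending line number for
    non-monotone wavelengths, ragged rows, or missing required metadata.
    """
    path = Path(path)
    meta: dict[str, Any] = {}
    wavelengths: list[float] = []
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" not in body:
                    raise ParseError(f"{path}:{lineno}: malformed metadata line {line!r}")
                key, _, val = body.partition(":")
                meta[key.strip()] = _coerce(val.strip())
                continue
            cells = _split_row(line)
            if len(cells) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 columns, got {len(cells)}")
            try:
                wl, v = float(cells[0]), float(cells[1])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric row {line!r}") from None
            if wavelengths and wl <= wavelengths[-1]:
                raise ParseError(
                    f"{path}:{lineno}: wavelengths must be strictly increasing "
                    f"({wl} after {wavelengths[-1]})")
            wavelengths.append(wl)
            values.append(v)
    if "kind" not in meta:
        raise ParseError(f"{path}: missing required metadata key 'kind'")
    kind = str(meta.pop("kind"))
    if kind == "emission":
        for key in _REQUIRED_EMISSION_KEYS:
            if key not in meta:
                raise ParseError(
                    f"{path}: emission spectrum missing required metadata key {key!r}")
    if not wavelengths:
        raise ParseError(f"{path}: no data rows")
    return Spectrum(np.array(wavelengths), np.array(values), kind, meta)


def write_spectrum(s: Spectrum, path: Union[str, Path]) -> None:
    """Write a spectrum; numeric columns use repr-faithful formatting so a
    read/write round trip is bit-exact."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# kind: {s.kind}\n")
        for key, value in s.meta.items():
            fh.write(f"# {key}: {value}\n")
        for wl, v in zip(s.wavelengths, s.values):
            fh.write(f"{float(wl)!r},{float(v)!r}\n")


def read_rlc(path: Union[str, Path]) -> RLCRecord:
    """Read an RLC step table; the E_PAR = 0 row supplies the dark reading."""
    path = Path(path)
    meta: dict[str, Any] = {}
    rows: list[tuple[float, float, float]] = []
    header: list[str] | None = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                key, _, val = body.partition(":")
                meta[key.strip()] = _coerce(val.strip())
                continue
            cells = _split_row(line)
            if header is None:
                header = [c.strip() for c in cells]
                expected = ["step", "E_PAR", "F", "Fm_prime"]
                if header != expected:
                    raise ParseError(
                        f"{path}:{lineno}: expected header {expected}, got {header}")
                continue
            if len(cells) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(cells)}")
            try:
                _, e, f, fm = (float(c) for c in cells)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric row {line!r}") from None
            rows.append((e, f, fm))
    if header is None or not rows:
        raise ParseError(f"{path}: no data rows")
    es = [r[0] for r in rows]
    if len(set(es)) != len(es):
        raise ParseError(f"{path}: duplicate E_PAR values")
    rows.sort(key=lambda r: r[0])
    if rows[0][0] != 0:
        raise ParseError(f"{path}: no dark row (E_PAR = 0) found")
    dark = DarkReading(F0=rows[0][1], Fm=rows[0][2])
    steps = [LightStep(e, f, fm) for e, f, fm in rows]
    return RLCRecord(dark=dark, steps=steps, meta=meta)


def write_rlc(record: RLCRecord, path: Union[str, Path]) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in record.meta.items():
            fh.write(f"# {key}: {value}\n")
        fh.write("step,E_PAR,F,Fm_prime\n")
        for i, step in enumerate(record.steps, start=1):
            fh.write(f"{i},{float(step.E)!r},{float(step.F)!r},{float(step.Fm_prime)!r}\n")


_PIGMENT_COLUMNS = ["species", "tissue_age", "season", "pigment", "replicate",
                    "concentration"]


def read_pigment_table(path: Union[str, Path],
                       strict_vocabulary: bool = True) -> pd.DataFrame:
    """Read a long-format pigment concentration table (CSV or TSV)."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in _PIGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if (df["concentration"] < 0).any():
        raise ParseError(f"{path}: negative concentrations present")
    if strict_vocabulary:
        unknown = sorted(set(df["pigment"]) - set(PIGMENT_VOCABULARY))
        if unknown:
            raise ParseError(f"{path}: unknown pigment names {unknown}")
    return df[_PIGMENT_COLUMNS + [c for c in df.columns if c not in _PIGMENT_COLUMNS]]


def write_pigment_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, index=False)
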