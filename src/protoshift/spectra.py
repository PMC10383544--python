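"""Optical spectrum containers and their plain-text (CSV) serialization.

A spectrum is a strictly increasing wavelength axis (nm) plus values
(absorbance, dimensionless, or emission intensity, arbitrary units) and the
measurement metadata needed downstream: pH, temperature (degC), cosolvent
identity and mass fraction, optical path, spectrum kind and, for emission,
the excitation wavelength.

File dialect::

    # ph: 6.5
    # temperature_c: 25.0
    # cosolvent: glycerol
    # mass_fraction_percent: 40.0
    # path_cm: 1.0
    # kind: absorbance
    wavelength_nm,value
    400.0,0.0123
    ...
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

__all__ = [
    "SpectrumMeta",
    "Spectrum",
    "SpeciesReference",
    "read_spectrum",
    "write_spectrum",
    "read_species_reference",
    "write_species_reference",
]

#: metadata keys required in every spectrum file
REQUIRED_META = (
    "ph",
    "temperature_c",
    "cosolvent",
    "mass_fraction_percent",
    "path_cm",
    "kind",
)

#: absorbance dips below this (after blank subtraction) are rejected as
#: instrument artefacts rather than silently clipped
NEGATIVE_ABSORBANCE_FLOOR = -1e-3


@dataclass
class SpectrumMeta:
    ph: float
    temperature_c: float
    cosolvent: str = "none"
    mass_fraction_percent: float = 0.0
    path_cm: float = 1.0
    kind: str = "absorbance"  # {"absorbance", "emission"}
    excitation_nm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("absorbance", "emission"):
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        if self.kind == "emission" and self.excitation_nm is None:
            raise ValueError("emission spectra require excitation_nm metadata")
        if self.path_cm <= 0:
            raise ValueError("path_cm must be positive")

    @property
    def temperature_k(self) -> float:
        return self.temperature_c + 273.15


@dataclass
class Spectrum:
    wavelengths: np.ndarray  # nm, strictly increasing
    values: np.ndarray
    meta: SpectrumMeta

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.shape != self.values.shape:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if self.wavelengths.size < 2:
            raise ValueError("spectrum needs at least two samples")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelength axis must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum values must be finite")
        if self.meta.kind == "absorbance" and np.min(self.values) < NEGATIVE_ABSORBANCE_FLOOR:
            raise ValueError(
                f"absorbance dips below {NEGATIVE_ABSORBANCE_FLOOR} "
                f"(min {np.min(self.values):.3g}); blank subtraction suspect"
            )

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.wavelengths.copy(), self.values * factor, replace(self.meta))

    def restricted(self, lo_nm: float, hi_nm: float) -> "Spectrum":
        mask = (self.wavelengths >= lo_nm) & (self.wavelengths <= hi_nm)
        if mask.sum() < 2:
            raise ValueError(f"range {lo_nm}-{hi_nm} nm covers <2 samples")
        return Spectrum(self.wavelengths[mask], self.values[mask], replace(self.meta))

    def interpolate(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Linear interpolation of values onto a new axis (error outside range)."""
        w = np.asarray(wavelengths_nm, dtype=float)
        if w.min() < self.wavelengths[0] or w.max() > self.wavelengths[-1]:
            raise ValueError(
                f"requested range {w.min():.1f}-{w.max():.1f} nm outside "
                f"spectrum range {self.wavelengths[0]:.1f}-{self.wavelengths[-1]:.1f} nm"
            )
        return np.interp(w, self.wavelengths, self.values)


@dataclass
class SpeciesReference:
    """Per-species molar extinction curves on a shared wavelength grid.

    epsilon_* are in M^-1 cm^-1 for the monoanion (M), dianion (D) and the
    minor zwitterion (Z) of the dye.
    """

    wavelengths: np.ndarray  # nm
    epsilon_M: np.ndarray
    epsilon_D: np.ndarray
    epsilon_Z: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        for name in ("epsilon_M", "epsilon_D", "epsilon_Z"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.wavelengths.shape:
                raise ValueError(f"{name} not aligned with wavelength grid")
            if np.min(arr) < 0:
                raise ValueError(f"{name} has negative extinction values")
        if not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("reference wavelength grid must be strictly increasing")

    def epsilon(self, species: str) -> np.ndarray:
        return {"M": self.epsilon_M, "D": self.epsilon_D, "Z": self.epsilon_Z}[species]

    def epsilon_at(self, species: str, wavelength_nm: float) -> float:
        w = self.wavelengths
        if not (w[0] <= wavelength_nm <= w[-1]):
            raise ValueError(f"{wavelength_nm} nm outside reference grid {w[0]}-{w[-1]} nm")
        return float(np.interp(wavelength_nm, w, self.epsilon(species)))


# ---------------------------------------------------------------------------
# CSV round-trip

_FLOAT_META = {"ph", "temperature_c", "mass_fraction_percent", "path_cm", "excitation_nm"}


def _parse_header(lines: list[str], path: str) -> dict:
    meta: dict = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if not body or ":" not in body:
            continue
        key, _, value = body.partition(":")
        key = key.strip().lower()
        value = value.strip()
        meta[key] = float(value) if key in _FLOAT_META else value
    for key in REQUIRED_META:
        if key not in meta:
            raise ValueError(f"{path}: missing required metadata key '{key}'")
    if meta.get("kind") == "emission" and "excitation_nm" not in meta:
        raise ValueError(f"{path}: missing required metadata key 'excitation_nm'")
    return meta


def _split_file(path) -> tuple[list[str], list[str]]:
    header, body = [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                header.append(line)
            elif line.strip():
                body.append(line)
    return header, body


def read_spectrum(path) -> Spectrum:
    """Read a spectrum from the commented-CSV dialect written by this package."""
    header, body = _split_file(path)
    meta = _parse_header(header, str(path))
    data = np.loadtxt(io.StringIO("\n".join(body[1:])), delimiter=",", ndmin=2)
    w, v = data[:, 0], data[:, 1]
    if np.unique(w).size != w.size:
        raise ValueError(f"{path}: duplicated wavelength rows")
    spectrum_meta = SpectrumMeta(
        ph=meta["ph"],
        temperature_c=meta["temperature_c"],
        cosolvent=meta["cosolvent"],
        mass_fraction_percent=meta["mass_fraction_percent"],
        path_cm=meta["path_cm"],
        kind=meta["kind"],
        excitation_nm=meta.get("excitation_nm"),
    )
    return Spectrum(w, v, spectrum_meta)


def write_spectrum(spectrum: Spectrum, path) -> None:
    m = spectrum.meta
    lines = [
        f"# ph: {float(m.ph)!r}",
        f"# temperature_c: {float(m.temperature_c)!r}",
        f"# cosolvent: {m.cosolvent}",
        f"# mass_fraction_percent: {float(m.mass_fraction_percent)!r}",
        f"# path_cm: {float(m.path_cm)!r}",
        f"# kind: {m.kind}",
    ]
    if m.excitation_nm is not None:
        lines.append(f"# excitation_nm: {float(m.excitation_nm)!r}")
    lines.append("wavelength_nm,value")
    for w, v in zip(spectrum.wavelengths, spectrum.values):
        lines.append(f"{float(w)!r},{float(v)!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_species_reference(path) -> SpeciesReference:
    header, body = _split_file(path)
    provenance = ""
    for line in header:
        stripped = line.lstrip("#").strip()
        if stripped.lower().startswith("provenance:"):
            provenance = stripped.partition(":")[2].strip()
    data = np.loadtxt(io.StringIO("\n".join(body[1:])), delimiter=",", ndmin=2)
    return SpeciesReference(data[:, 0], data[:, 1], data[:, 2], data[:, 3], provenance)


def write_species_reference(ref: SpeciesReference, path) -> None:
    lines = [f"# provenance: {ref.provenance}", "wavelength_nm,epsilon_M,epsilon_D,epsilon_Z"]
    for row in zip(ref.wavelengths, ref.epsilon_M, ref.epsilon_D, ref.epsilon_Z):
        lines.append(",".join(repr(float(x)) for x in row))
    Path(path).write_text("\n".join(lines) + "\n")
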