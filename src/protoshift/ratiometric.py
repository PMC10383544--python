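"""Corrected ratiometric signal R = I488/I435 and its linear sensitivity.

The ratiometric readout of the probe is the ratio of integrated emission
intensities under dianion-selective (488 nm) and monoanion-selective
(435 nm) excitation, after putting both channels on a common
excitation-intensity scale (xenon-lamp ratio) and undoing inner-filter
reabsorption.  Sensitivity to temperature or viscosity is an ordinary
least-squares slope of R against the predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .spectra import Spectrum

__all__ = [
    "RatiometricPoint",
    "SensitivityFit",
    "lamp_correct",
    "reabsorption_correct",
    "ratiometric_signal",
    "sensitivity_fit",
]

DEFAULT_INTEGRATION_RANGE_NM = (500.0, 650.0)


@dataclass
class RatiometricPoint:
    I488: float
    I435: float
    R: float
    temperature_k: Optional[float] = None
    viscosity_cP: Optional[float] = None
    medium: str = ""

    def __post_init__(self) -> None:
        if self.I435 <= 0:
            raise ValueError("I435 must be positive")
        if abs(self.R - self.I488 / self.I435) > 1e-9 * max(abs(self.R), 1.0):
            raise ValueError("R must equal I488/I435")


@dataclass
class SensitivityFit:
    slope: float  # per degC or per cP
    intercept: float
    r_squared: float
    slope_stderr: float
    intercept_stderr: float


def lamp_correct(em435: Spectrum, lamp_ratio: float) -> Spectrum:
    """Rescale the 435 nm-excited channel by the lamp intensity ratio.

    lamp_ratio = I_lamp(488)/I_lamp(435); multiplying the 435-excited
    spectrum by it makes both channels comparable per unit excitation
    intensity.
    """
    if lamp_ratio <= 0:
        raise ValueError("lamp_ratio must be positive")
    return em435.scaled(lamp_ratio)


def reabsorption_correct(
    em: Spectrum,
    absorbance: Spectrum,
    d_ex_cm: float = 0.5,
    d_em_cm: float = 0.5,
) -> Spectrum:
    """Mean-path inner-filter correction of an emission spectrum.

    Each emission point is multiplied by 10^(A(lambda_ex) d_ex + A(lambda_em) d_em)
    to undo attenuation of the excitation beam on its way to the cuvette
    centre and of the emitted light on its way out; the 0.5 cm defaults are
    the half-paths of a 1 x 1 cm cuvette in L geometry.  A(lambda_em) beyond
    the red edge of the absorbance spectrum is an error only if the emission
    grid extends past it.
    """
    if em.meta.excitation_nm is None:
        raise ValueError("emission spectrum lacks excitation_nm metadata")
    a_ex = absorbance.interpolate(np.array([em.meta.excitation_nm]))[0]
    a_em = absorbance.interpolate(em.wavelengths)
    factor = 10.0 ** (a_ex * d_ex_cm + a_em * d_em_cm)
    return Spectrum(em.wavelengths.copy(), em.values * factor, replace(em.meta))


def ratiometric_signal(
    em488: Spectrum,
    em435: Spectrum,
    integration_range_nm: Sequence[float] = DEFAULT_INTEGRATION_RANGE_NM,
    temperature_k: Optional[float] = None,
    viscosity_cP: Optional[float] = None,
    medium: str = "",
) -> RatiometricPoint:
    """Trapezoid-integrated intensities and their ratio R = I488/I435."""
    lo, hi = integration_range_nm
    s488, s435 = em488.restricted(lo, hi), em435.restricted(lo, hi)
    I488 = float(np.trapezoid(s488.values, s488.wavelengths))
    I435 = float(np.trapezoid(s435.values, s435.wavelengths))
    if I435 <= 0:
        raise ValueError("I435 integrates to <= 0; ratio undefined")
    if temperature_k is None and em488.meta.temperature_c is not None:
        temperature_k = em488.meta.temperature_k
    return RatiometricPoint(
        I488=I488,
        I435=I435,
        R=I488 / I435,
        temperature_k=temperature_k,
        viscosity_cP=viscosity_cP,
        medium=medium or em488.meta.cosolvent,
    )


def sensitivity_fit(
    points: Sequence[RatiometricPoint], predictor: str = "temperature"
) -> SensitivityFit:
    """OLS line of R against temperature (degC) or viscosity (cP).

    The temperature predictor is in Celsius to match the conventional
    per-degC sensitivity quotation; presentation layers may rescale to
    1e-2 degC^-1.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 points for a sensitivity fit")
    if predictor == "temperature":
        x = np.array([p.temperature_k - 273.15 for p in points], dtype=float)
    elif predictor == "viscosity":
        x = np.array([p.viscosity_cP for p in points], dtype=float)
    else:
        raise ValueError(f"unknown predictor {predictor!r}")
    if np.unique(x).size < 2:
        raise ValueError("predictor values must not all coincide")
    y = np.array([p.R for p in points], dtype=float)
    res = stats.linregress(x, y)
    return SensitivityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_stderr=float(res.stderr),
        intercept_stderr=float(res.intercept_stderr),
    )
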