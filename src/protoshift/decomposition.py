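"""Decomposition of mixture absorption spectra into protolytic species.

The mixture spectrum of the probe near its pKa is modelled as a
non-negative linear combination of the monoanion and dianion extinction
curves, A(lambda) = l (c_M eps_M + c_D eps_D).  The fit is a non-negative
least-squares problem solved exactly; the apparent dissociation constant
follows by mass action, Ka_app = [D] [H+] / [M] with [H+] = 10^-pH.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import nnls

from .spectra import Spectrum, SpeciesReference

__all__ = [
    "DecompositionResult",
    "EquilibriumPoint",
    "correct_reference_pH5",
    "decompose",
    "compute_Ka",
    "pKa_from_series",
    "absorption_maximum",
]

log = logging.getLogger(__name__)

DEFAULT_FIT_RANGE_NM = (400.0, 540.0)


@dataclass
class DecompositionResult:
    c_M: float  # mol L^-1
    c_D: float  # mol L^-1
    r_squared: float
    residuals: np.ndarray  # absorbance, on the fitted grid
    wavelengths: np.ndarray  # nm, fitted grid
    covariance: np.ndarray  # 2x2, (c_M, c_D)

    def __post_init__(self) -> None:
        if self.c_M < 0 or self.c_D < 0:
            raise ValueError("species concentrations must be non-negative")
        if self.r_squared > 1 + 1e-12:
            raise ValueError("r_squared cannot exceed 1")


@dataclass
class EquilibriumPoint:
    temperature: float  # K
    pH: float
    Ka_app: float  # mol L^-1
    pKa_app: float

    def __post_init__(self) -> None:
        if self.Ka_app <= 0:
            raise ValueError("Ka_app must be positive")
        if abs(self.pKa_app + np.log10(self.Ka_app)) > 1e-9:
            raise ValueError("pKa_app must equal -log10(Ka_app)")


def correct_reference_pH5(
    raw: Spectrum,
    ref: SpeciesReference,
    c_total_M: float,
    f_D: float = 0.03,
    f_Z: float = 0.04,
) -> np.ndarray:
    """Monoanion extinction curve from a pH-5 spectrum contaminated by D and Z.

    At pH 5 the monoanion dominates but fractions f_D of dianion and f_Z of
    zwitterion persist; their extinction-weighted contributions are
    subtracted and the remainder rescaled:

        eps_M = (A_raw/(l c_tot) - f_D eps_D - f_Z eps_Z) / (1 - f_D - f_Z)

    Negative intermediate values (band edges, noise) are clipped to zero and
    the clip count logged.  Returns eps_M on the raw spectrum's grid.
    """
    if f_D < 0 or f_Z < 0 or f_D + f_Z >= 1.0:
        raise ValueError("require 0 <= f_D + f_Z < 1")
    w = raw.wavelengths
    eps_apparent = raw.values / (raw.meta.path_cm * c_total_M)
    eps_D = np.interp(w, ref.wavelengths, ref.epsilon_D)
    eps_Z = np.interp(w, ref.wavelengths, ref.epsilon_Z)
    eps_M = (eps_apparent - f_D * eps_D - f_Z * eps_Z) / (1.0 - f_D - f_Z)
    n_clip = int(np.sum(eps_M < 0))
    if n_clip:
        log.info("correct_reference_pH5: clipped %d negative points to zero", n_clip)
    return np.clip(eps_M, 0.0, None)


def decompose(
    mixture: Spectrum,
    ref: SpeciesReference,
    fit_range_nm: Sequence[float] = DEFAULT_FIT_RANGE_NM,
) -> DecompositionResult:
    """Non-negative least-squares split of a mixture spectrum into (c_M, c_D).

    References are linearly interpolated onto the mixture grid restricted to
    fit_range_nm; R^2 is reported over the fitted range only.  The
    covariance of (c_M, c_D) is the unconstrained-Gauss-Markov estimate
    sigma^2 (X^T X)^-1 with sigma^2 = SS_res/(n-2).
    """
    lo, hi = fit_range_nm
    sub = mixture.restricted(lo, hi)
    w, a = sub.wavelengths, sub.values
    if w[0] < ref.wavelengths[0] or w[-1] > ref.wavelengths[-1]:
        raise ValueError("fit range not covered by the reference grid")
    if not np.any(a > 0):
        raise ValueError("all-zero mixture spectrum; nothing to decompose")
    path = mixture.meta.path_cm
    X = np.column_stack(
        [
            path * np.interp(w, ref.wavelengths, ref.epsilon_M),
            path * np.interp(w, ref.wavelengths, ref.epsilon_D),
        ]
    )
    try:
        coef, _ = nnls(X, a, maxiter=10 * X.shape[1] * 100)
    except RuntimeError as exc:  # iteration cap
        raise RuntimeError(f"decomposition did not converge: {exc}") from exc
    # coefficients at round-off level relative to the dominant species are
    # the active constraint, not a real concentration
    coef[coef < 1e-12 * coef.max()] = 0.0
    fitted = X @ coef
    residuals = a - fitted
    ss_res = float(residuals @ residuals)
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    dof = max(a.size - 2, 1)
    sigma2 = ss_res / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return DecompositionResult(
        c_M=float(coef[0]),
        c_D=float(coef[1]),
        r_squared=r_squared,
        residuals=residuals,
        wavelengths=w,
        covariance=cov,
    )


def compute_Ka(dec: DecompositionResult, pH: float, temperature_k: float) -> EquilibriumPoint:
    """Apparent mass-action constant Ka = [D] 10^-pH / [M] from a decomposition."""
    if dec.c_M <= 0:
        raise ValueError("c_M = 0: equilibrium constant undefined on the boundary")
    if dec.c_D <= 0:
        raise ValueError("c_D = 0: Ka would be zero; spectrum carries no dianion")
    Ka = dec.c_D * 10.0 ** (-pH) / dec.c_M
    pKa = pH + np.log10(dec.c_M / dec.c_D)
    return EquilibriumPoint(temperature=temperature_k, pH=pH, Ka_app=Ka, pKa_app=float(pKa))


def pKa_from_series(points: Sequence[EquilibriumPoint]) -> float:
    """Aggregate pKa_app over a titration series by the median.

    The median is robust to edge-of-titration spectra where one species is
    nearly absent and its concentration poorly determined.
    """
    if not points:
        raise ValueError("empty series")
    return float(np.median([p.pKa_app for p in points]))


def absorption_maximum(s: Spectrum) -> float:
    """Wavenumber (cm^-1) of the spectrum maximum by parabolic interpolation.

    Fits a parabola through the top sample and its two neighbours in
    wavelength; the maximum must be interior to the grid.
    """
    i = int(np.argmax(s.values))
    if i == 0 or i == s.values.size - 1:
        raise ValueError("spectrum maximum lies on the grid boundary")
    w, v = s.wavelengths[i - 1 : i + 2], s.values[i - 1 : i + 2]
    # vertex of the exact parabola through the three points (centred for
    # conditioning); falls back to the grid point on a flat top
    a2, a1, _ = np.polyfit(w - w[1], v, 2)
    lam_max = w[1] if a2 == 0 else w[1] - a1 / (2.0 * a2)
    return float(1.0e7 / lam_max)
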