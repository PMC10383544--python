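"""Equilibrium thermodynamics and photophysical descriptors.

Covers the van't Hoff analysis of Ka(T), the implied linear pKa-vs-T
sensitivity, the Foerster-Weller excited-state pKa shift from 0-0 transition
energies, the Lippert-Mataga orientation-polarizability factor, binary
glycerol/sucrose-water viscosity correlations, and the cross-media
correlation of ratiometric temperature sensitivity with reaction enthalpy.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import yaml
from scipy import stats

from .constants import (
    BOLTZMANN_K,
    LN10,
    PLANCK_H,
    R_GAS,
    SPEED_OF_LIGHT_CM,
    T_REF_K,
)
from .decomposition import EquilibriumPoint
from .ratiometric import SensitivityFit

__all__ = [
    "VantHoffResult",
    "PhotoState",
    "PolarityDescriptor",
    "vant_hoff",
    "pKa_slope_from_enthalpy",
    "zero_zero_wavenumber",
    "forster_weller",
    "lippert_mataga_deltaf",
    "media_polarity",
    "viscosity_from_composition",
    "sensitivity_vs_enthalpy",
]


@dataclass
class VantHoffResult:
    dH: float  # J mol^-1
    intercept: float  # dimensionless, apparent -dS/R
    dH_stderr: float  # J mol^-1
    r_squared: float


@dataclass
class PhotoState:
    """0-0 transition wavenumbers of the two protolytic forms at temperature T."""

    nu00_D: float  # cm^-1
    nu00_M: float  # cm^-1
    temperature_k: float = T_REF_K

    def __post_init__(self) -> None:
        for name, nu in (("nu00_D", self.nu00_D), ("nu00_M", self.nu00_M)):
            if not (10_000.0 <= nu <= 40_000.0):
                raise ValueError(f"{name} = {nu} cm^-1 outside the 10000-40000 sanity window")
        if self.temperature_k <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class PolarityDescriptor:
    n: float  # refractive index
    eps: float  # static dielectric constant
    deltaf: float

    def __post_init__(self) -> None:
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")
        if self.eps <= 0:
            raise ValueError("dielectric constant must be positive")


def vant_hoff(points: Sequence[EquilibriumPoint]) -> VantHoffResult:
    """Reaction enthalpy from OLS of -ln Ka_app against 1/T.

    dH = slope * R_gas.  Unweighted, as is conventional when per-point
    uncertainties are not propagated.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 equilibrium points")
    T = np.array([p.temperature for p in points], dtype=float)
    if np.unique(T).size < 3:
        raise ValueError("need at least 3 distinct temperatures")
    x = 1.0 / T
    y = -np.log([p.Ka_app for p in points])
    res = stats.linregress(x, y)
    return VantHoffResult(
        dH=float(res.slope * R_GAS),
        intercept=float(res.intercept),
        dH_stderr=float(res.stderr * R_GAS),
        r_squared=float(res.rvalue**2),
    )


def pKa_slope_from_enthalpy(
    dH: float,
    pKa_ref: float = 6.45,
    t_range_c: Sequence[float] = (10.0, 80.0),
    n_points: int = 15,
) -> float:
    """Linear pKa-vs-temperature sensitivity implied by a van't Hoff enthalpy.

    Builds the exact curve pKa(T) = pKa_ref + (dH/(ln10 R))(1/T - 1/298.15 K)
    at n evenly spaced temperatures in t_range_c and returns the OLS slope of
    pKa against t (degC).  The mild 1/T curvature makes this slightly
    shallower than the point derivative at 25 degC.
    """
    if not np.isfinite(dH):
        raise ValueError("dH must be finite")
    if n_points < 3:
        raise ValueError("need at least 3 temperatures")
    lo, hi = t_range_c
    if not hi > lo:
        raise ValueError("degenerate temperature range")
    t_c = np.linspace(lo, hi, n_points)
    T = t_c + 273.15
    pKa = pKa_ref + (dH / (LN10 * R_GAS)) * (1.0 / T - 1.0 / T_REF_K)
    return float(stats.linregress(t_c, pKa).slope)


def zero_zero_wavenumber(nu_abs_max: float, nu_em_max: float) -> float:
    """Electronic 0-0 origin as the half-sum of absorption and emission maxima."""
    if nu_abs_max <= 0 or nu_em_max <= 0:
        raise ValueError("wavenumbers must be positive")
    return 0.5 * (nu_abs_max + nu_em_max)


def forster_weller(state: PhotoState) -> float:
    """Excited-state pKa shift from the Foerster-Weller cycle.

    dpKa* = h c (nu00_D - nu00_M) / (ln10 k T), with wavenumbers in cm^-1
    and c in cm s^-1.  Negative values mean the excited state favours the
    deprotonated (dianion) form.
    """
    return float(
        PLANCK_H
        * SPEED_OF_LIGHT_CM
        * (state.nu00_D - state.nu00_M)
        / (LN10 * BOLTZMANN_K * state.temperature_k)
    )


def lippert_mataga_deltaf(n: float, eps: float) -> PolarityDescriptor:
    """Orientation-polarizability factor deltaf = (eps-1)/(2eps+1) - (n^2-1)/(2n^2+1)."""
    if n < 1.0:
        raise ValueError("refractive index must be >= 1")
    if eps <= 0:
        raise ValueError("dielectric constant must be positive")
    deltaf = (eps - 1.0) / (2.0 * eps + 1.0) - (n**2 - 1.0) / (2.0 * n**2 + 1.0)
    return PolarityDescriptor(n=n, eps=eps, deltaf=float(deltaf))


def _load_yaml(name: str) -> dict:
    with resources.files("protoshift.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def media_polarity(cosolvent: str = "none", mass_fraction_percent: float = 0.0) -> PolarityDescriptor:
    """(n, eps, deltaf) for water or a listed cosolvent mixture at 25 degC.

    Values come from the shipped literature table (media.yaml), linearly
    interpolated in mass fraction between water and the tabulated points.
    """
    table = _load_yaml("media.yaml")
    water = table["water"]
    if cosolvent in ("none", "water", "") or mass_fraction_percent == 0:
        return lippert_mataga_deltaf(water["n"], water["eps"])
    if cosolvent not in table:
        raise ValueError(f"no polarity data for cosolvent {cosolvent!r}")
    entries = sorted((float(w), rec) for w, rec in table[cosolvent].items())
    ws = [0.0] + [w for w, _ in entries]
    ns = [water["n"]] + [rec["n"] for _, rec in entries]
    es = [water["eps"]] + [rec["eps"] for _, rec in entries]
    if mass_fraction_percent > ws[-1]:
        raise ValueError(
            f"mass fraction {mass_fraction_percent}% beyond tabulated range for {cosolvent}"
        )
    n = float(np.interp(mass_fraction_percent, ws, ns))
    eps = float(np.interp(mass_fraction_percent, ws, es))
    return lippert_mataga_deltaf(n, eps)


def _water_viscosity_cP(t_c: float, coeffs: dict) -> float:
    return coeffs["A"] * np.exp(
        (coeffs["B"] - t_c) * t_c / (coeffs["C"] + coeffs["D"] * t_c)
    )


def viscosity_from_composition(cosolvent: str, w_percent: float, T_k: float) -> float:
    """Dynamic viscosity (cP) of a binary water-cosolvent mixture.

    glycerol: Cheng's exponential mixing rule between the water and glycerol
    endmember curves.  sucrose: Genotelle's mole-fraction correlation,
    applied as a relative viscosity anchored to the same water curve.
    Strictly increasing in w at fixed T and decreasing in T at fixed w over
    the supported range (w <= 60% w/w, 273 < T < 373 K).
    """
    t_c = T_k - 273.15
    if not (0.0 < t_c + 273.15 and 273.0 < T_k < 373.0):
        raise ValueError(f"temperature {T_k} K outside correlation validity (273-373 K)")
    data = _load_yaml("viscosity.yaml")
    if cosolvent in ("none", "water", ""):
        w_percent = 0.0
        cosolvent = "glycerol"  # water limit of either correlation
    if cosolvent not in data:
        raise ValueError(f"no viscosity correlation for cosolvent {cosolvent!r}")
    spec = data[cosolvent]
    if not (0.0 <= w_percent <= spec["w_max_percent"]):
        raise ValueError(
            f"mass fraction {w_percent}% outside validity range 0-{spec['w_max_percent']}%"
        )
    if cosolvent == "glycerol":
        cm = w_percent / 100.0
        a = spec["a"]["c0"] + spec["a"]["c1"] * t_c
        b = (spec["b"]["c0"] + spec["b"]["c1"] * t_c) * a ** spec["b"]["exponent"]
        alpha = 1.0 - cm + a * b * cm * (1.0 - cm) / (a * cm + b * (1.0 - cm))
        eta_w = _water_viscosity_cP(t_c, spec["water_curve"])
        eta_g = spec["glycerol_curve"]["A"] * np.exp(
            (spec["glycerol_curve"]["B"] + t_c)
            * t_c
            / (spec["glycerol_curve"]["C"] + spec["glycerol_curve"]["D"] * t_c)
        )
        return float(eta_w**alpha * eta_g ** (1.0 - alpha))
    # sucrose
    c = spec["coeffs"]
    n_suc = w_percent / spec["molar_mass_sucrose"]
    n_wat = (100.0 - w_percent) / spec["molar_mass_water"]
    N = n_suc / (n_suc + n_wat)
    phi = (spec["phi"]["t0"] - t_c) / (spec["phi"]["t1"] + t_c)

    def log10_eta(N_: float) -> float:
        return c["c_N"] * N_ + c["c_0"] + phi * (c["c_phi0"] + c["c_phi1"] * N_ ** c["n_exp"])

    relative = 10.0 ** (log10_eta(N) - log10_eta(0.0))
    glycerol_water = _load_yaml("viscosity.yaml")["glycerol"]["water_curve"]
    return float(relative * _water_viscosity_cP(t_c, glycerol_water))


def sensitivity_vs_enthalpy(pairs: Sequence[tuple]) -> SensitivityFit:
    """OLS line of ratiometric temperature sensitivity against reaction enthalpy.

    pairs are (dH in kJ mol^-1, sensitivity in 1e-2 degC^-1) across media;
    a high r_squared indicates the cross-media linear coupling between the
    thermal response of the signal and the dissociation enthalpy.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 (dH, sensitivity) pairs")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    res = stats.linregress(x, y)
    return SensitivityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_stderr=float(res.stderr),
        intercept_stderr=float(res.intercept_stderr),
    )
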