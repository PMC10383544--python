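"""Synthetic spectra with known ground truth.

The generator emulates the optical signature of a two-species protolytic
probe (fluorescein monoanion M / dianion D, plus a minor zwitterion Z used
only for reference-contamination tests):

* each species' extinction curve is a sum of Gaussian bands in wavenumber;
* species fractions at a given (pH, T) follow mass action with a
  van't Hoff temperature dependence of the dissociation constant,
  pKa(T) = pKa(25 degC) + (dH / (ln10 R)) (1/T - 1/298.15);
* band centers shift linearly with temperature and with the medium's
  orientation-polarizability factor deltaf (bathochromic for heating and
  for less polar cosolvent media);
* measurement noise is multiplicative Gaussian per spectral point.

Every generated quantity is reproducible from (ground truth, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml

from .constants import LN10, R_GAS, T_REF_K, nm_to_wavenumber
from .spectra import Spectrum, SpectrumMeta, SpeciesReference

__all__ = [
    "SpectralGroundTruth",
    "load_default_ground_truth",
    "gaussian_bands",
    "generate_species_references",
    "generate_absorption_series",
    "generate_emission_pair",
    "generate_pure_species_spectra",
    "emission_ratio_closed_form",
    "DELTAF_WATER",
]

# deltaf of pure water at 25 degC, (eps-1)/(2eps+1) - (n^2-1)/(2n^2+1)
# with n = 1.3325, eps = 78.36 (media.yaml); the zero point of the
# polarity-driven band shift.
DELTAF_WATER = 0.3200792181862138


def _load_defaults() -> dict:
    with resources.files("protoshift.data").joinpath("defaults.yaml").open() as fh:
        return yaml.safe_load(fh)


@dataclass
class SpectralGroundTruth:
    """Generative parameters for the two-species band system.

    band and emission_band entries are per-species lists of
    (center cm^-1, width cm^-1, peak amplitude) triples; absorption peaks are
    molar extinctions in M^-1 cm^-1.
    """

    pKa_at_25C: float
    dH_true: float  # J mol^-1
    bands_cm: dict
    emission_bands_cm: dict
    shift_dnu_dT: float  # cm^-1 K^-1
    shift_dnu_ddeltaf: float  # cm^-1 per unit deltaf
    noise_rel: float = 0.005
    total_dye_M: float = 8.0e-6
    path_cm: float = 1.0
    phi_ratio_D_over_M: float = 2.5
    grid_nm: tuple = (400.0, 560.0, 0.5)
    emission_grid_nm: tuple = (480.0, 700.0, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_rel < 0:
            raise ValueError("noise_rel must be >= 0")
        if self.total_dye_M <= 0:
            raise ValueError("total dye concentration must be positive")
        for table in (self.bands_cm, self.emission_bands_cm):
            for species, bands in table.items():
                for center, width, peak in bands:
                    if width <= 0 or peak <= 0:
                        raise ValueError(
                            f"species {species}: band widths and peaks must be positive"
                        )

    # -- equilibrium ------------------------------------------------------

    def pKa_of_T(self, T_k: float) -> float:
        """Exact van't Hoff line through (25 degC, pKa_at_25C) with slope dH."""
        return self.pKa_at_25C + (self.dH_true / (LN10 * R_GAS)) * (1.0 / T_k - 1.0 / T_REF_K)

    def Ka_of_T(self, T_k: float) -> float:
        return 10.0 ** (-self.pKa_of_T(T_k))

    def fraction_D(self, pH: float, T_k: float) -> float:
        """Henderson-Hasselbalch dianion fraction 1/(1 + 10^(pKa - pH))."""
        return 1.0 / (1.0 + 10.0 ** (self.pKa_of_T(T_k) - pH))

    def wavelength_grid(self) -> np.ndarray:
        start, stop, step = self.grid_nm
        return np.arange(start, stop + 0.5 * step, step)

    def emission_wavelength_grid(self) -> np.ndarray:
        start, stop, step = self.emission_grid_nm
        return np.arange(start, stop + 0.5 * step, step)

    def band_shift(self, T_k: float, deltaf: float) -> float:
        """Common displacement (cm^-1) of all band centers at (T, deltaf)."""
        return self.shift_dnu_dT * (T_k - T_REF_K) + self.shift_dnu_ddeltaf * (
            deltaf - DELTAF_WATER
        )


def load_default_ground_truth(**overrides) -> SpectralGroundTruth:
    """Ground truth with the packaged default band model; fields overridable."""
    cfg = _load_defaults()["spectral"]
    kwargs = dict(
        pKa_at_25C=cfg["pKa_at_25C"],
        dH_true=cfg["dH_true"],
        bands_cm={k: [tuple(b) for b in v] for k, v in cfg["bands_cm"].items()},
        emission_bands_cm={
            k: [tuple(b) for b in v] for k, v in cfg["emission_bands_cm"].items()
        },
        shift_dnu_dT=cfg["shift_dnu_dT"],
        shift_dnu_ddeltaf=cfg["shift_dnu_ddeltaf"],
        noise_rel=cfg["noise_rel"],
        total_dye_M=cfg["total_dye_M"],
        path_cm=cfg["path_cm"],
        phi_ratio_D_over_M=cfg["phi_ratio_D_over_M"],
        grid_nm=tuple(cfg["grid_nm"]),
        emission_grid_nm=tuple(cfg["emission_grid_nm"]),
    )
    kwargs.update(overrides)
    return SpectralGroundTruth(**kwargs)


def gaussian_bands(nu_cm: np.ndarray, bands: Sequence[tuple], shift_cm: float = 0.0) -> np.ndarray:
    """Sum of Gaussian bands evaluated at wavenumbers nu_cm (cm^-1)."""
    nu = np.asarray(nu_cm, dtype=float)
    out = np.zeros_like(nu)
    for center, width, peak in bands:
        c = center + shift_cm
        out += peak * np.exp(-((nu - c) ** 2) / (2.0 * width**2))
    return out


def generate_species_references(
    gt: SpectralGroundTruth, T_k: float = T_REF_K, deltaf: float = DELTAF_WATER
) -> SpeciesReference:
    """Noise-free extinction curves of M, D and Z at (T, deltaf).

    Band centers are displaced by shift_dnu_dT*(T - 298.15 K) plus
    shift_dnu_ddeltaf*(deltaf - deltaf_water); widths and peak extinctions
    are condition-independent in this model.
    """
    if not (273.0 <= T_k <= 373.0):
        raise ValueError(f"temperature {T_k} K outside the 273-373 K model range")
    grid = gt.wavelength_grid()
    if not np.all(np.diff(grid) > 0):
        raise ValueError("wavelength grid must be strictly increasing")
    nu = nm_to_wavenumber(grid)
    shift = gt.band_shift(T_k, deltaf)
    return SpeciesReference(
        wavelengths=grid,
        epsilon_M=gaussian_bands(nu, gt.bands_cm["M"], shift),
        epsilon_D=gaussian_bands(nu, gt.bands_cm["D"], shift),
        epsilon_Z=gaussian_bands(nu, gt.bands_cm["Z"], shift),
        provenance=f"synthetic T={T_k:.2f}K deltaf={deltaf:.5f}",
    )


def _noise(rng: np.random.Generator, noise_rel: float, n: int) -> np.ndarray:
    return 1.0 + rng.normal(0.0, noise_rel, n) if noise_rel > 0 else np.ones(n)


def generate_absorption_series(
    gt: SpectralGroundTruth,
    pH_list: Sequence[float],
    T_list_k: Sequence[float],
    deltaf: float = DELTAF_WATER,
    cosolvent: str = "none",
    mass_fraction_percent: float = 0.0,
) -> list[Spectrum]:
    """Mixture absorption spectra for every (T, pH) combination.

    Each spectrum is A = l (c_M eps_M + c_D eps_D) with mass-action species
    fractions at (pH, T) and multiplicative Gaussian noise of s.d. noise_rel,
    seeded from gt.seed.  Spectra are ordered T-major, pH-minor.
    """
    if len(pH_list) == 0:
        raise ValueError("pH_list must be nonempty")
    rng = np.random.default_rng(gt.seed)
    out = []
    for T_k in T_list_k:
        ref = generate_species_references(gt, T_k, deltaf)
        for pH in pH_list:
            fD = gt.fraction_D(pH, T_k)
            c_D = gt.total_dye_M * fD
            c_M = gt.total_dye_M * (1.0 - fD)
            a = gt.path_cm * (c_M * ref.epsilon_M + c_D * ref.epsilon_D)
            a = a * _noise(rng, gt.noise_rel, a.size)
            meta = SpectrumMeta(
                ph=float(pH),
                temperature_c=T_k - 273.15,
                cosolvent=cosolvent,
                mass_fraction_percent=mass_fraction_percent,
                path_cm=gt.path_cm,
                kind="absorbance",
            )
            out.append(Spectrum(ref.wavelengths.copy(), np.clip(a, 0.0, None), meta))
    return out


def _emission_shapes(gt: SpectralGroundTruth, T_k: float, deltaf: float):
    grid = gt.emission_wavelength_grid()
    nu = nm_to_wavenumber(grid)
    shift = gt.band_shift(T_k, deltaf)
    shapes = {
        s: gaussian_bands(nu, gt.emission_bands_cm[s], shift) for s in ("M", "D")
    }
    return grid, shapes


def _species_weights(gt, pH, T_k, ref, lambda_ex):
    """Per-species emission amplitude eps(lambda_ex) * c * phi."""
    fD = gt.fraction_D(pH, T_k)
    conc = {"D": gt.total_dye_M * fD, "M": gt.total_dye_M * (1.0 - fD)}
    phi = {"D": gt.phi_ratio_D_over_M, "M": 1.0}
    return {s: ref.epsilon_at(s, lambda_ex) * conc[s] * phi[s] for s in ("M", "D")}


def generate_emission_pair(
    gt: SpectralGroundTruth,
    pH: float,
    T_k: float,
    lamp_ratio: float = 1.0,
    deltaf: float = DELTAF_WATER,
    cosolvent: str = "none",
    mass_fraction_percent: float = 0.0,
) -> tuple[Spectrum, Spectrum]:
    """(488 nm-excited, 435 nm-excited) emission spectra.

    Intensity per species is proportional to eps(lambda_ex) * c * phi times
    the species emission shape; lamp_ratio = I_lamp(488)/I_lamp(435) is the
    excitation-intensity asymmetry, applied so that the raw 435-excited
    channel is *weaker* by that factor (undone by ratiometric.lamp_correct).
    """
    if lamp_ratio <= 0:
        raise ValueError("lamp_ratio must be positive")
    ref = generate_species_references(gt, T_k, deltaf)
    for lam in (435.0, 488.0):
        if not (ref.wavelengths[0] <= lam <= ref.wavelengths[-1]):
            raise ValueError(f"excitation wavelength {lam} nm outside reference grid")
    grid, shapes = _emission_shapes(gt, T_k, deltaf)
    rng = np.random.default_rng(gt.seed)
    out = []
    for lambda_ex, lamp in ((488.0, 1.0), (435.0, 1.0 / lamp_ratio)):
        weights = _species_weights(gt, pH, T_k, ref, lambda_ex)
        intensity = lamp * sum(weights[s] * shapes[s] for s in ("M", "D"))
        intensity = intensity * _noise(rng, gt.noise_rel, intensity.size)
        meta = SpectrumMeta(
            ph=float(pH),
            temperature_c=T_k - 273.15,
            cosolvent=cosolvent,
            mass_fraction_percent=mass_fraction_percent,
            path_cm=gt.path_cm,
            kind="emission",
            excitation_nm=lambda_ex,
        )
        out.append(Spectrum(grid.copy(), intensity, meta))
    return out[0], out[1]


def generate_pure_species_spectra(
    gt: SpectralGroundTruth,
    species: str,
    T_k: float = T_REF_K,
    deltaf: float = DELTAF_WATER,
) -> tuple[Spectrum, Spectrum]:
    """Noise-free (absorption, emission) spectra of one pure protolytic form.

    Emulates the single-species reference measurements (monoanion at pH 5,
    dianion at pH 11) used to locate band maxima and 0-0 origins; the
    nominal pH recorded in the metadata is 5.0 for M and 11.0 for D.
    """
    if species not in ("M", "D"):
        raise ValueError("pure-species spectra exist for 'M' and 'D' only")
    ref = generate_species_references(gt, T_k, deltaf)
    ph = {"M": 5.0, "D": 11.0}[species]
    meta_abs = SpectrumMeta(
        ph=ph, temperature_c=T_k - 273.15, path_cm=gt.path_cm, kind="absorbance"
    )
    absorption = Spectrum(
        ref.wavelengths.copy(),
        gt.path_cm * gt.total_dye_M * ref.epsilon(species),
        meta_abs,
    )
    grid, shapes = _emission_shapes(gt, T_k, deltaf)
    meta_em = SpectrumMeta(
        ph=ph,
        temperature_c=T_k - 273.15,
        path_cm=gt.path_cm,
        kind="emission",
        excitation_nm=488.0 if species == "D" else 435.0,
    )
    emission = Spectrum(grid.copy(), shapes[species], meta_em)
    return absorption, emission


def emission_ratio_closed_form(
    gt: SpectralGroundTruth,
    pH: float,
    T_k: float,
    deltaf: float = DELTAF_WATER,
    integration_range_nm: tuple = (500.0, 650.0),
) -> float:
    """Analytic lamp-corrected ratio I488/I435 implied by the generator.

    R = sum_s eps_s(488) c_s phi_s S_s / sum_s eps_s(435) c_s phi_s S_s with
    S_s the integral of the species emission shape over the stated range.
    """
    ref = generate_species_references(gt, T_k, deltaf)
    grid, shapes = _emission_shapes(gt, T_k, deltaf)
    lo, hi = integration_range_nm
    mask = (grid >= lo) & (grid <= hi)
    integrals = {s: np.trapezoid(shapes[s][mask], grid[mask]) for s in ("M", "D")}
    num = sum(v * integrals[s] for s, v in _species_weights(gt, pH, T_k, ref, 488.0).items())
    den = sum(v * integrals[s] for s, v in _species_weights(gt, pH, T_k, ref, 435.0).items())
    return float(num / den)
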