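"""Physical constants (CODATA 2018) and unit conventions.

All internal temperatures are kelvin; file metadata carries Celsius with the
fixed conversion T/K = t/degC + 273.15.  Wavenumbers are cm^-1 throughout, so
the speed of light is kept in cm s^-1.
"""

import numpy as np

R_GAS = 8.314462618  # J mol^-1 K^-1
PLANCK_H = 6.62607015e-34  # J s
SPEED_OF_LIGHT_CM = 2.99792458e10  # cm s^-1
BOLTZMANN_K = 1.380649e-23  # J K^-1
LN10 = np.log(10.0)

T_REF_K = 298.15  # 25 degC reference for pKa and polarity defaults
CELSIUS_OFFSET = 273.15


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + CELSIUS_OFFSET


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - CELSIUS_OFFSET


def nm_to_wavenumber(lambda_nm):
    """Convert wavelength in nm to wavenumber in cm^-1 (1e7/lambda)."""
    return 1.0e7 / np.asarray(lambda_nm, dtype=float)


def wavenumber_to_nm(nu_cm):
    return 1.0e7 / np.asarray(nu_cm, dtype=float)
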