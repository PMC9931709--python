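"""Physical constants and unit conversions used throughout the package.

Unit policy: energies and couplings in cm^-1, dipoles in Debye, distances in
Angstrom (nm only inside the point-dipole formula), temperatures in K.
Wavelength -> wavenumber conversions use the vacuum convention (no air
refractive-index correction).
"""

from __future__ import annotations

import numpy as np

#: Coulomb coupling constant e^2/(4 pi eps0) in cm^-1 * Angstrom / e^2.
COULOMB_CM_ANGSTROM = 1.16141e5

#: hc/k_B in cm * K: converts an energy in cm^-1 to a temperature in K.
HC_OVER_KB_CM_K = 1.438777

#: Point-dipole coupling prefactor, cm^-1 * nm^3 / Debye^2.
DIPOLE_PREFACTOR_CM_NM3_D2 = 5.04

#: 1 e * Angstrom in Debye.
EA_TO_DEBYE = 4.803205


def nm_to_wavenumber(wavelength_nm):
    """Vacuum wavelength (nm) to wavenumber (cm^-1): E = 1e7 / lambda."""
    wavelength_nm = np.asarray(wavelength_nm, dtype=float)
    if np.any(wavelength_nm <= 0):
        raise ValueError("wavelength must be positive")
    return 1e7 / wavelength_nm


def wavenumber_to_nm(energy_cm):
    """Wavenumber (cm^-1) to vacuum wavelength (nm)."""
    energy_cm = np.asarray(energy_cm, dtype=float)
    if np.any(energy_cm <= 0):
        raise ValueError("wavenumber must be positive")
    return 1e7 / energy_cm


def thermal_wavenumber(temperature_k: float) -> float:
    """k_B T expressed in cm^-1."""
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    return temperature_k / HC_OVER_KB_CM_K
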