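"""Physical constants and unit conversions.

Working units throughout the package:

* energies in eV,
* time in fs,
* nuclear coordinates ``Q`` dimensionless (mass-frequency scaled),
* Cartesian geometries in Angstrom, masses in amu, frequencies in cm^-1,
* dipole moments in atomic units.

CODATA 2018 values.
"""

#: hbar in eV*fs
HBAR_EVFS = 0.6582119569509066

#: photon energy of a 1 cm^-1 line, in eV
EV_PER_CM1 = 1.2398419843320026e-4

#: 1 hartree in eV
HARTREE_TO_EV = 27.211386245988

#: 1 bohr in Angstrom
BOHR_TO_ANGSTROM = 0.529177210903

#: 1 amu in electron masses
AMU_TO_ME = 1822.888486209

#: h*c in eV*nm (photon wavelength-energy conversion)
HC_EV_NM = 1239.8419843320026

#: 1 cm^-1 in hartree
CM1_TO_HARTREE = EV_PER_CM1 / HARTREE_TO_EV


def photon_wavelength_nm(energy_ev: float) -> float:
    """Wavelength (nm) of a photon with the given energy (eV)."""
    if energy_ev <= 0:
        raise ValueError("photon energy must be positive")
    return HC_EV_NM / energy_ev


def photon_energy_ev(wavelength_nm: float) -> float:
    """Energy (eV) of a photon with the given wavelength (nm)."""
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    return HC_EV_NM / wavelength_nm
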