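"""Physical constants and unit conversions.

Internal unit system (everything in the package uses these unless a name
says otherwise):

========== =====================
length     nm
time       ps
energy     kcal/mol
mass       g/mol (amu)
charge     elementary charge e
========== =====================

A convenient identity: 1 g/mol * (nm/ps)^2 == 1 kJ/mol, so kinetic energy
in internal units is ``0.5*m*v**2 / KCAL`` with ``KCAL = 4.184`` kJ/kcal.
"""

import numpy as np

#: Avogadro constant, 1/mol
N_AVOGADRO = 6.02214076e23

#: kJ per kcal
KJ_PER_KCAL = 4.184

#: Boltzmann constant, kcal/(mol K)
KB = 0.00831446261815324 / KJ_PER_KCAL  # = 0.0019872043

#: Coulomb prefactor e^2/(4 pi eps0), kcal nm / (mol e^2)
COULOMB = 138.935458 / KJ_PER_KCAL  # = 33.2063712

#: 1 kcal/(mol nm^3) expressed in bar:
#: 4184 J/mol / (N_A * 1e-27 m^3) / 1e5 Pa/bar
PRESSURE_KCALNM3_TO_BAR = KJ_PER_KCAL * 1e30 / N_AVOGADRO / 1e5  # = 69.4769

#: 1 bar in kcal/(mol nm^3)
BAR = 1.0 / PRESSURE_KCALNM3_TO_BAR

#: conversion g/cm^3 -> (g/mol)/nm^3 (multiply mass density by this to get
#: amu per nm^3): rho[amu/nm^3] = rho[g/cm^3] * 1e-21 * N_A
GCM3_TO_AMU_NM3 = N_AVOGADRO * 1e-21  # = 602.214

#: nm^2/ps -> cm^2/s
NM2_PS_TO_CM2_S = 1e-2


def kinetic_energy(masses: np.ndarray, velocities: np.ndarray) -> float:
    """Total kinetic energy in kcal/mol for masses (N,) amu, velocities (N,3) nm/ps."""
    return 0.5 * float(np.sum(masses * np.sum(velocities**2, axis=1))) / KJ_PER_KCAL


def instantaneous_temperature(kinetic: float, n_dof: int) -> float:
    """Kinetic temperature (K) from kinetic energy (kcal/mol) and DOF count."""
    return 2.0 * kinetic / (n_dof * KB)


def mass_density_gcm3(total_mass_amu: float, volume_nm3: float) -> float:
    """Mass density in g/cm^3 of ``total_mass_amu`` amu in ``volume_nm3`` nm^3."""
    return total_mass_amu / volume_nm3 / GCM3_TO_AMU_NM3
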