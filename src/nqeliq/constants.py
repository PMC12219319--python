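"""Physical constants and unit conversions.

Internal unit system: energy kJ/mol, length Å, time ps, temperature K,
charge e, mass g/mol.  With these units a mass must be multiplied by
``MASS_SCALE`` before kinetic energies p²/2m come out in kJ/mol, because
1 (g/mol)·(Å/ps)² = 0.01 kJ/mol.  All dynamical code works with the scaled
("dynamical") masses; topologies store g/mol.
"""

import numpy as np

#: Boltzmann constant, kJ/(mol·K)  (CODATA, exact)
KB = 8.31446261815324e-3

#: Reduced Planck constant, kJ·ps/mol
HBAR = 1.054571817e-34 * 6.02214076e23 * 1e12 / 1e3  # ≈ 0.0635078

#: Coulomb prefactor e²/(4πε₀), kJ·Å/mol/e²
COULOMB = 1389.35457644382

#: 1 atm expressed in kJ/mol/Å³
ATM = 101325.0 * 6.02214076e23 * 1e-30 / 1e3  # ≈ 6.1019e-5

#: (g/mol)·(Å/ps)² → kJ/mol
MASS_SCALE = 0.01

#: Avogadro constant, 1/mol
NA = 6.02214076e23

#: Å³ → cm³ (per particle→per mole handled with NA where needed)
A3_TO_CM3 = 1e-24

#: Å³ → nm³
A3_TO_NM3 = 1e-3


def dynamical_masses(masses_amu: np.ndarray) -> np.ndarray:
    """Masses in units where m·v² (v in Å/ps) is kJ/mol."""
    return np.asarray(masses_amu, dtype=float) * MASS_SCALE
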