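"""Internal unit system and physical constants.

Everything inside the package works in Å (length), eV (energy), V Å⁻¹
(electric field), e·Å (dipole), e·Å² V⁻¹ (polarizability), fs (time) and
amu (mass).  With the elementary charge e = 1 in these units, the
dipole–field product e·Å × V Å⁻¹ is directly an energy in eV, so no
conversion constants appear in the model equations.
"""

import numpy as np

#: 1 e·Å expressed in Debye, for reporting only.
EA_TO_DEBYE = 4.803204

#: Boltzmann constant, eV / K.
KB = 8.617333262e-5

#: Converts (eV Å⁻¹) / amu into Å fs⁻²  (force / mass -> acceleration).
FORCE_TO_ACC = 9.648533212e-3

#: Speed of light in cm / fs, for converting 1/fs frequencies to cm⁻¹.
C_CM_PER_FS = 2.99792458e-5

#: Atomic masses (amu) for the handful of species the toys use; anything
#: unknown falls back to 12 amu, which only affects MD time scales.
MASSES = {
    "H": 1.00794, "D": 2.0141, "He": 4.0026, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998, "Na": 22.9898, "Cl": 35.453, "S": 32.06,
    "P": 30.974, "K": 39.098, "Ar": 39.948,
}


def mass_of(symbol: str) -> float:
    return MASSES.get(symbol, 12.0)


def masses_for(species) -> np.ndarray:
    return np.array([mass_of(s) for s in species], dtype=float)
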