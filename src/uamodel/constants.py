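"""Physical constants (CODATA 2018) and unit-conversion helpers.

Internal convention: lengths in nm, energies in units of k_BT at the medium
temperature. Conversions to kJ/mol happen only at I/O boundaries, using the
fixed constant ``KT_KJ_PER_MOL_300`` so that written files are reproducible
independent of the run's medium temperature.
"""

import math

E_CHARGE = 1.602176634e-19  # C
EPS0 = 8.8541878128e-12  # F/m
K_BOLTZMANN = 1.380649e-23  # J/K
N_AVOGADRO = 6.02214076e23  # 1/mol
PLANCK_H = 6.62607015e-34  # J s
R_GAS_KJ = 1e-3 * K_BOLTZMANN * N_AVOGADRO  # kJ/(mol K)

#: thermal energy at 300 K in kJ/mol, applied at file-format boundaries
KT_KJ_PER_MOL_300 = 2.494

DEFAULT_TEMPERATURE = 300.0  # K


def kT_joule(temperature: float) -> float:
    """Thermal energy k_BT in J at the given temperature (K)."""
    return K_BOLTZMANN * temperature


def kT_kj_per_mol(temperature: float) -> float:
    """Thermal energy in kJ/mol at the given temperature (K)."""
    return R_GAS_KJ * temperature


def bjerrum_length_nm(dielectric: float, temperature: float) -> float:
    """Bjerrum length e^2 / (4 pi eps0 eps k_BT), in nm."""
    lb_m = E_CHARGE**2 / (4.0 * math.pi * EPS0 * dielectric * K_BOLTZMANN * temperature)
    return lb_m * 1e9
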