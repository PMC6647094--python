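"""Physical constants used throughout the package.

Values are fixed here (CODATA via scipy.constants, plus the conventional
hartree->kcal/mol factor) so results are bit-reproducible.
"""

import scipy.constants as sc

HARTREE_TO_KCAL = 627.5095  # kcal/mol per hartree (conventional factor)
R_KCAL = 1.98720e-3  # gas constant, kcal/(mol K)
R_CAL = R_KCAL * 1000.0  # cal/(mol K)

KB = sc.k  # J/K
H_PLANCK = sc.h  # J s
C_LIGHT = sc.c  # m/s
N_A = sc.N_A  # 1/mol
AMU = sc.atomic_mass  # kg
P_STANDARD = sc.atm  # Pa (1 atm)
J_PER_KCAL = sc.calorie * 1000.0  # J per kcal

T_STANDARD = 298.15  # K
WATER_CONCENTRATION = 55.34  # mol/L, liquid water standard state
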