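"""Physical constants and unit-conversion factors used across the package.

Unit conventions (no unit library; every quantity carries its unit in the
variable or column name):

* activity: decays yr^-1 g^-1 solid (``A``); Bq kg^-1 offered as a convenience
* energy: eV internally (decay energies tabulated in MeV per parent decay)
* volumetric production: molecules cm^-3 sediment yr^-1, or mol / mol e-eq
* lengths: metres at module interfaces, centimetres inside solvers
"""

AVOGADRO = 6.02214076e23  # mol^-1
SECONDS_PER_YEAR = 3.1557600e7  # Julian year
EV_PER_MEV = 1.0e6
EARTH_RADIUS_KM = 6371.0  # authalic radius

# K2O -> K mass conversion: 2 M(K) / M(K2O)
MOLAR_MASS_K = 39.0983  # g/mol
MOLAR_MASS_K2O = 2 * MOLAR_MASS_K + 15.9994
K2O_TO_K = 2 * MOLAR_MASS_K / MOLAR_MASS_K2O  # 0.83015...

R_GAS_KJ = 8.314e-3  # kJ mol^-1 K^-1

# mol cm^-3 -> nmol L^-1 (nM): 1 mol/cm3 = 1e3 mol/L = 1e12 nM
MOL_CM3_TO_NM = 1.0e12
# uM -> mol cm^-3: 1 umol/L = 1e-6 mol / 1e3 cm3
UM_TO_MOL_CM3 = 1.0e-9
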