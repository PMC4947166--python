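"""Physical constants and unit conversions used across the package.

All mobility/CCS arithmetic funnels through the values here so that the
standard state (273.15 K, 760 torr) and the SI constants are defined in
exactly one place.
"""

# Charge carrier: proton (the [2M+nH]^n+ convention of native MS).
PROTON_MASS_DA = 1.007276

# SI constants (2019 redefinition).
ELEMENTARY_CHARGE_C = 1.602176634e-19
BOLTZMANN_J_PER_K = 1.380649e-23

# Gas number density at the mobility standard state (273.15 K, 760 torr),
# i.e. the Loschmidt constant, m^-3.
GAS_NUMBER_DENSITY_STP = 2.6868e25

DA_TO_KG = 1.66053906660e-27

# Buffer gas: helium.
HELIUM_MASS_DA = 4.002602

STANDARD_PRESSURE_TORR = 760.0
STANDARD_TEMPERATURE_K = 273.15

# Unit conversions.
MS_TO_S = 1e-3
CM2_TO_M2 = 1e-4
M2_TO_A2 = 1e20

# Monoisotopic neutral masses (Da) of adduct species commonly retained by
# native protein ions, with the number of protons each displaces when it
# binds as a charge-neutral salt adduct (e.g. K+ replaces one H+).
ADDUCT_SPECIES = {
    "Na": (22.98976928, 1),
    "K": (38.96370649, 1),
    "Mg": (23.98504170, 2),
    "Ca": (39.96259086, 2),
    "Mn": (54.93804391, 2),
    "Fe": (55.93493633, 2),
    "Zn": (63.92914201, 2),
    "H2O": (18.01056468, 0),
    "NH4": (18.03437413, 1),
}
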