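"""Physical constants and reference data used throughout the pipeline.

All enthalpies are in kJ mol^-1, temperatures in K, masses in g unless a
function documents otherwise.
"""

#: Molar gas constant, J mol^-1 K^-1.
GAS_CONSTANT = 8.3145

#: Thermochemical reference temperature, K.
T_REFERENCE = 298.15

#: IUPAC 2021 abridged standard atomic weights, g mol^-1 (CHO scope only).
ATOMIC_WEIGHTS = {"C": 12.011, "H": 1.008, "O": 15.999}

#: Standard molar enthalpy of formation of CO2(g) at 298.15 K, kJ mol^-1.
DFH_CO2_GAS = -393.51
#: Expanded uncertainty (k=2) of the CO2(g) reference, kJ mol^-1.
U_DFH_CO2_GAS = 0.13

#: Standard molar enthalpy of formation of H2O(l) at 298.15 K, kJ mol^-1.
DFH_H2O_LIQ = -285.83
#: Expanded uncertainty (k=2) of the H2O(l) reference, kJ mol^-1.
U_DFH_H2O_LIQ = 0.04

#: Default air density for buoyancy correction of weighed masses, g cm^-3.
AIR_DENSITY = 1.2e-3

#: Default density of calibration weights (stainless steel), g cm^-3.
WEIGHT_DENSITY = 8.0
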