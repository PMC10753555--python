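# Published values of the experimental chain, at their printed precision,
# used by the reproduce report for match/mismatch flagging.
quantity,printed_value,decimals
delta_U_IBP_kJ,-1.13938,5
massic_energy_run1_kJ_g,-27.6334,4
molar_mass_g_mol,190.198,3
molar_energy_kJ_mol,-5266.8,1
molar_enthalpy_kJ_mol,-5269.3,1
formation_cr_kJ_mol,-488.5,1
purity,0.9973,4
melting_temperature_K,431.9,1
fusion_enthalpy_Tfus_kJ_mol,30.6,1
fusion_298_kJ_mol,23.4,1
vaporization_298_kJ_mol,81.5,1
sublimation_298_kJ_mol,104.9,1
formation_gas_kJ_mol,-383.6,1
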