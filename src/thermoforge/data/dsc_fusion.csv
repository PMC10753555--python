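# DSC fusion replicates for 7M4MC (published experimental record).
# purity: mole fraction; melting_temperature_K: T_fus; fusion_enthalpy_kJ_mol:
# molar fusion enthalpy at T_fus.
purity,melting_temperature_K,fusion_enthalpy_kJ_mol
0.9987,432.9,31.7
0.9978,433.0,31.9
0.9976,430.6,29.4
0.9951,431.2,29.3
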