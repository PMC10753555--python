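# Gas-phase standard molar enthalpies of formation at 298.15 K, kJ mol^-1,
# for species used in homodesmic-reaction demonstrations (published
# experimental/literature values and the corresponding regression
# predictions).
species_id,formula,dfH_exp_kJ_mol,dfH_pred_kJ_mol
coumarin,C9H6O2,-176.8,-176.8
1-methoxy-2-methylbenzene,C8H10O,-106.6,-109.5
1-methoxy-3-methylbenzene,C8H10O,-102.6,-100.6
1-methoxy-4-methylbenzene,C8H10O,-99.0,-98.4
7-methoxycoumarin,C10H8O3,-321.6,-319.7
benzene,C6H6,82.9,83.5
toluene,C7H8,50.1,49.3
7M4MC,C11H10O3,-383.6,-384.9
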