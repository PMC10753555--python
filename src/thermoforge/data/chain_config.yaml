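# Scalar inputs for the 298.15 K enthalpy chain of 7M4MC.
compound: 7M4MC
formula: C11H10O3

# Six-run average massic combustion energy (only one run is printed in full
# in the public record; the average is carried as a constant, not recomputed).
mean_massic_energy_kJ_g: -27.6912
u_mean_massic_energy_kJ_g: 0.0162
# Expanded (k=2) uncertainty of the molar combustion energy including the
# benzoic-acid calibration and fuse contributions (not decomposable here).
u_molar_combustion_kJ_mol: 6.2

# Mean temperature of the TGA scan (midpoint of 438.15-488.15 K).
T_m_K: 463.15

# Liquid-phase heat capacities, J mol^-1 K^-1. Neither is measured: each is
# back-solved from the corresponding published 298.15 K enthalpy through the
# Chickos-Acree correction and is documented as such in every report.
cp_liquid_fusion_J_mol_K: 326.4
cp_liquid_vaporization_J_mol_K: 197.2

# Expanded (k=2) uncertainties of the adjusted phase-change enthalpies as
# published (they include rate/temperature components not printed).
u_fusion_298_kJ_mol: 1.4
u_vaporization_298_kJ_mol: 1.6
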