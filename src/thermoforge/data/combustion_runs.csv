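# Published bomb-combustion record for 7M4MC (one of six runs; the remaining
# five are available only in supplementary material and are represented by the
# six-run mean stored in chain_config.yaml).
# Masses in g (already buoyancy-corrected); delta_Tc_K: corrected temperature
# rise; calor_equiv_J_K: calorimeter energy equivalent; cont_term_kJ: printed
# eps(cont)*(-dTc) product; ignition_energy_kJ and standard_state_correction_kJ
# in kJ; fuse_massic_energy_kJ_g: cotton-fuse massic combustion energy.
sample_mass_g,fuse_mass_g,platinum_mass_g,delta_Tc_K,calor_equiv_J_K,cont_term_kJ,ignition_energy_kJ,standard_state_correction_kJ,fuse_massic_energy_kJ_g
0.0408401,0.0005911,0.2311213,0.891702,1281.2,-0.00111,0.00418,0.00081,-16.9452
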