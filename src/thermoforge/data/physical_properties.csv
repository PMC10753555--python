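# Physical properties at p0 = 0.1 MPa (published experimental record for the
# combustion sample, the calibrant and the fuse material).
# molar_mass_g_mol: IUPAC 2021 atomic weights; density_g_cm3: for buoyancy
# correction; minus_du_dp_J_g_MPa: -(du/dp)_T at 298.15 K (metadata only,
# consumed inside the supplied standard-state correction); cp_specific_J_g_K:
# specific heat capacity of the crystal at 298.15 K.
compound,molar_mass_g_mol,density_g_cm3,minus_du_dp_J_g_MPa,cp_specific_J_g_K
7M4MC,190.198,1.195,0.200,1.439
benzoic_acid,122.123,1.320,0.115,1.209
cotton,28.502,1.500,0.289,1.674
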