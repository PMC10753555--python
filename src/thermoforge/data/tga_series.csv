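# Published isothermal TGA mass-loss series for 7M4MC (438.15-488.15 K).
# rate_kg_per_s: dm/dt; nu: Langmuir flux, (kg K mol)^(1/2) m^-2 s^-1;
# ln_nu and thousand_over_T: the tabulated regression columns as printed.
# The crucible area is not part of the record; nu is ingested directly.
temperature_K,mass_mg,rate_kg_per_s,nu,ln_nu,thousand_over_T
438.15,1.174,3.630e-9,80.483e-3,-2.520,2.282
443.15,1.164,4.550e-9,101.455e-3,-2.288,2.257
448.15,1.149,5.700e-9,127.813e-3,-2.057,2.231
453.15,1.115,7.040e-9,158.738e-3,-1.840,2.207
458.15,1.109,8.640e-9,195.887e-3,-1.630,2.183
463.15,1.003,10.590e-9,241.404e-3,-1.421,2.159
468.15,0.999,12.800e-9,293.353e-3,-1.226,2.136
473.15,0.988,15.350e-9,353.668e-3,-1.039,2.113
478.15,0.973,18.300e-9,423.858e-3,-0.858,2.091
483.15,0.855,21.680e-9,504.763e-3,-0.684,2.070
488.15,0.723,25.320e-9,592.554e-3,-0.523,2.049
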