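# Demonstration exchange scheme, element-balanced and curator-authored:
#   coumarin + 1-methoxy-4-methylbenzene -> 7M4MC + benzene
# This is NOT one of the published reaction schemes (those are available only
# as a figure); the solved value is expected to differ from published results
# and is shipped purely to exercise the solver on real species data.
target: 7M4MC
enthalpy_column: dfH_pred_kJ_mol
stoichiometry:
  coumarin: -1
  1-methoxy-4-methylbenzene: -1
  7M4MC: 1
  benzene: 1
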