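# thermoforge

Thermochemical data reduction and additive prediction for organic CHO
compounds, built around the determination of the gas-phase standard
molar enthalpy of formation of 7-methoxy-4-methylcoumarin (7M4MC), a
pharmacologically interesting lactone.

It is aimed at experimental thermochemists and property-prediction
practitioners who need a tested, scriptable version of the classic
determination chain:

1. **Combustion calorimetry** — reduce static-bomb records to the massic
   energy Δ_c u°, the molar quantities Δ_c U_m° and
   Δ_c H_m° = Δ_c U_m° + Δn_g·R·T, and, by Hess's law against CO₂(g) and
   H₂O(l), the crystalline formation enthalpy Δ_f H_m°(cr).
2. **Thermogravimetry (Langmuir method)** — convert isothermal mass-loss
   rates to reduced fluxes ν = (1/A)(dm/dt)√(T/M) and fit
   ln ν = B − Δ_l^g H_m/(R·T) to extract the vaporization enthalpy.
3. **Enthalpy chain** — average DSC fusion replicates, adjust fusion and
   vaporization enthalpies to 298.15 K with the Chickos–Acree
   heat-capacity corrections, and compose
   Δ_f H_m°(g) = Δ_f H_m°(cr) + Δ_cr^l H_m(298) + Δ_l^g H_m(298).
4. **Prediction** — Benson group-additivity estimation over an updated
   coefficient table, from-scratch MLR and SGD refitting with seeded
   70/30 hold-out, a homodesmic-reaction solver, and a structural
   regression for crystalline coumarins.

The experimental tables behind the chain ship as plain-text fixtures; a
seeded synthetic-data module emulates the unpublished regression
training sets and raw instrument traces so every stage is testable
offline. See `docs/methods.md` for the models, conventions and
limitations.

## Worked example

Regenerate the experimental chain from the packaged fixtures and check
every value against the published record at printed precision:

```sh
thermoforge reproduce
```

Selected rows of the report (computed values, printed counterparts):

| quantity | computed | printed | match |
|---|---|---|---|
| ΔU_IBP / kJ | −1.13938 | −1.13938 | yes |
| Δ_c u° (run 1) / kJ g⁻¹ | −27.63344 | −27.6334 | yes |
| M / g mol⁻¹ | 190.198 | 190.198 | yes |
| Δ_c U_m° / kJ mol⁻¹ | −5266.81 | −5266.8 | yes |
| Δ_c H_m° / kJ mol⁻¹ | −5269.29 | −5269.3 | yes |
| Δ_f H_m°(cr) / kJ mol⁻¹ | −488.47 | −488.5 | yes |
| Δ_cr^l H_m(298.15 K) / kJ mol⁻¹ | 23.40 | 23.4 | yes |
| Δ_l^g H_m(298.15 K) / kJ mol⁻¹ | 81.50 | 81.5 | yes |
| Δ_cr^g H_m(298.15 K) / kJ mol⁻¹ | 104.90 | 104.9 | yes |
| Δ_f H_m°(g) / kJ mol⁻¹ | −383.57 | −383.6 | yes |

The bomb record reduces to an exothermic massic energy of −27.63 kJ per
gram of sample; scaled by the molar mass and corrected for the gas-mole
change (Δn_g = −1), Hess's law places the crystal 488.5 kJ mol⁻¹ below
its elements. Fusion (23.4) plus vaporization (81.5) gives a sublimation
enthalpy of 104.9 kJ mol⁻¹, and adding it to the crystal value yields
the gas-phase formation enthalpy −383.6 ± 6.7 kJ mol⁻¹. The report also
prints the two back-solved liquid heat capacities it consumed (326.4 and
197.2 J mol⁻¹ K⁻¹), which are documented inputs, not measurements.

The crystalline structural regression, with the validation compound held
out of training:

```sh
thermoforge crystal --predict 7M4MC
```

```json
{
  "train_r2": 0.9944,
  "predicted_minus_dfH_cr_kJ_mol": 491.73,
  "delta_vs_experiment_kJ_mol": 3.23
}
```

i.e. the four-descriptor model fits the eight training coumarins with
R² = 0.994 and predicts −Δ_f H°(cr) = 491.7 kJ mol⁻¹ for 7M4MC, 3.2
kJ mol⁻¹ away from the combustion-derived 488.5.

Other entry points: `thermoforge combustion | tga | chain | ga-predict |
train | homodesmic | simulate` (see `--help` on each). All I/O is plain
CSV/JSON/YAML with a strict dialect (UTF-8, comma, `.` decimals, `#`
comments).

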