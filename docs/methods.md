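# Methods

This note records the models implemented in `thermoforge`, the numerical
choices behind them, and what the packaged fixtures and synthetic
generators can and cannot establish.

## Combustion calorimetry reduction

A static-bomb experiment is reduced in three steps. The energy of the
isothermal bomb process is assembled from the calorimeter equivalent and
the corrected temperature rise,

    ΔU_IBP = ε(calor)·(−ΔT_c)/1000 + ε(cont)·(−ΔT_c) + ΔU_ign   [kJ],

with ε(calor) in J K⁻¹ and the contents term carried as the printed
product. The standard massic energy of combustion removes the
standard-state (Washburn) correction and the cotton-fuse credit:

    Δ_c u° = [ΔU_IBP + ΔU_corr − m_fuse·Δ_c u°(fuse)] / m_sample   [kJ g⁻¹].

ΔU_corr is an input per experiment, not recomputed: deriving it requires
the full bomb-state protocol (gas solubilities, pressure corrections,
(δu/δp)_T terms) whose inputs are not part of the packaged record. The
(δu/δp)_T value is retained as fixture metadata only.

Molar quantities follow from the molar mass under IUPAC 2021 abridged
atomic weights (C 12.011, H 1.008, O 15.999) and the balanced combustion
of CaHbOc with liquid water product,

    CaHbOc + (a + b/4 − c/2) O₂ → a CO₂(g) + (b/2) H₂O(l),
    Δn_g = c/2 − b/4,
    Δ_c H_m° = Δ_c U_m° + Δn_g·R·T/1000  (R = 8.3145 J mol⁻¹ K⁻¹, T = 298.15 K),

and Hess's law against Δ_f H°(CO₂, g) = −393.51 and Δ_f H°(H₂O, l) =
−285.83 kJ mol⁻¹ gives the crystalline-phase formation enthalpy. All
combustion energies are stored negative (exothermic); the packaged
record's printed chain sums exactly under this convention.

Uncertainties follow calorimetric convention: the expanded uncertainty of
a replicate mean is 2·s/√n, and independent expanded components combine
in quadrature (e.g. the formation-enthalpy uncertainty folds in
11·u(CO₂) and 5·u(H₂O)).

## Thermogravimetric vaporization enthalpy (Langmuir method)

Free evaporation relates the mass flux per unit area to the vapor
pressure. The reduced flux

    ν = (1/A)(dm/dt)·√(T/M)    [(kg K mol)^½ m⁻² s⁻¹]

is proportional to p; combined with Clausius–Clapeyron this yields the
working line ln ν = B − (Δ_l^g H_m / R)·(1/T). The Langmuir vaporization
coefficient γ and the pressure proportionality are absorbed into B, so
the method is relative and needs no pressure calibration for an enthalpy.

Fitting is unweighted ordinary least squares of ln ν on 1/T, computed in
closed form (S_xy/S_xx); the slope's standard error comes from the
residual variance with n−2 degrees of freedom, and the enthalpy
uncertainty reported by the fit is the slope component R·se(slope).
Components from the rate and temperature calibrations are accepted as
config when available and combined in quadrature. The mean temperature
T_m is defined as the midpoint of the scanned range (463.15 K for the
packaged 438.15–488.15 K series), not the mean of the sampled points.

The crucible area is not part of the packaged record. The module supports
three modes: explicit area, area calibrated from a single (rate, ν)
anchor row, or direct ingestion of a ν column. The packaged series is
fitted from its tabulated (ln ν, 10³/T) columns for bit-stable refits;
the implied area is constant across all 11 rows to ~10⁻⁵ relative, and
back-solves to ≈2.165×10⁻⁶ m².

## Temperature adjustment and the enthalpy chain

Fusion and vaporization enthalpies measured at T_fus and T_m are brought
to 298.15 K with the Chickos–Acree heat-capacity corrections,

    Δ_cr^l H(298) = Δ_cr^l H(T_fus) + [0.15·Cp(cr) − 0.26·Cp(l) − 9.83]·(T_fus − 298.15)/1000,
    Δ_l^g  H(298) = Δ_l^g H(T_m)   + [10.58 + 0.26·Cp(l)]·(T_m − 298.15)/1000,

with molar heat capacities in J mol⁻¹ K⁻¹. The crystal heat capacity at
298.15 K comes from the measured specific value (1.439 J g⁻¹ K⁻¹ ×
190.198 g mol⁻¹ = 273.7 J mol⁻¹ K⁻¹); a polynomial Cp(T) fit (default
degree 2, valid only over the fitted 273.15–388.15 K window) is provided
for temperature-resolved work.

The liquid-phase heat capacity of a compound that is crystalline at room
temperature is essentially never measured, and none is part of the
packaged record. Cp(l) is therefore an explicit input. The shipped config
carries two back-solved values — 326.4 J mol⁻¹ K⁻¹ for the fusion
adjustment and 197.2 J mol⁻¹ K⁻¹ for the vaporization adjustment — each
inverted from the corresponding published 298.15 K enthalpy, and every
report flags them as inputs rather than measurements. That the two
implied values disagree is a known tension in the published chain; both
are documented, and no test asserts one against the other.

The chain then composes by construction:

    Δ_cr^g H(298) = Δ_cr^l H(298) + Δ_l^g H(298),
    Δ_f H_m°(g)   = Δ_f H_m°(cr) + Δ_cr^g H(298),

with quadrature combination of the component expanded uncertainties.
Comparisons against published values use round-half-even at the printed
decimal places.

## Benson group additivity and regression refitting

Molecules are represented as count vectors over a closed vocabulary of
Benson groups (polyvalent atom + ligands), ring-strain and positional
corrections, and family indicators; the estimate is linear,
−Δ_f H°(g) = H₀ + Σ n_g·c_g. Coefficients are stored on the −Δ_f H°
scale (large positive numbers for these compound families); user-facing
reports print both signs. Group vectors are authored data: automatic
perception of Benson groups for fused-ring lactones involves judgment
calls that belong with a curator, so no SMILES parsing is attempted.
Fractional counts are allowed for symmetry-weighted decompositions, and
the "radical n" / positional-correction terms are ordinary counts (the
distinction between indicator and multiplicity semantics is not
resolvable from the available record; counts subsume both).

The regression module refits such tables from scratch. MLR is ordinary
least squares with intercept via an SVD-based least-squares solve;
rank-deficient designs return the minimum-norm solution with a warning.
SGD performs one squared-loss update per example with per-epoch
reshuffling from a fixed seed, an inverse-scaling learning rate
η_t = η₀/(1 + η₀·λ·t) (defaults η₀ = 0.01, λ = 10⁻⁴, 1000 epochs), and
feature/target standardization on by default — raw group counts are
badly conditioned for stochastic updates. Coefficients are mapped back
to original units after training; a 10× epoch-loss increase raises a
divergence error naming the learning rate. Hold-out evaluation uses a
seeded permutation with ceil(0.7·n) training rows (the rounding
convention is ours; for n = 84 this gives 59/25). External seeds quoted
with published splits index other tooling's generators and are accepted
as configuration without any claim of reproducing those exact splits.

## Homodesmic solver

A reaction is a signed stoichiometry map (reactants negative) with one
unknown species. Element balance is enforced before solving; under the
zero-reaction-enthalpy assumption the unknown is
Δ_f H(target) = −Σ_known ν_i·Δ_f H_i / ν_target. Solutions are invariant
under coefficient scaling and reaction reversal, and substituting back
gives a zero reaction enthalpy identically. A stricter group-conservation
check against Benson vectors is available, since group balance — not
mere atom balance — is what makes a reaction homodesmic. The published
reaction schemes for the title compound exist only as a figure and are
not machine-recoverable; the shipped demonstration scheme
(coumarin + 1-methoxy-4-methylbenzene → 7M4MC + benzene) is element-
balanced but explicitly non-canonical, and its solved value (−358.7
kJ mol⁻¹ from the shipped predicted enthalpies) is a solver exercise,
not a reproduction of published reaction results.

## Crystalline coumarin structural regression

For coumarins the available condensed-phase data are crystalline, so a
compact model −Δ_f H°(cr) = β₀ + β₁X₁ + β₂X₂ + β₃X₃ + β₄X₄ is fitted on
hydrogen count (X₁), oxygen count (X₂) and two substituent slots: X₃ the
substituent nearer the carbonyl (ring positions 3/4), X₄ the benzo-ring
substituent (positions 5–8). Carbon count is excluded — it adds no
information over this single-scaffold family. The numeric encoding of
the substituent slots is not specified by the source record; the shipped
default is an ordinal code {none: 0, OH: 1, OCH₃: 2, CH₃: 3}, kept in a
config table so alternatives can be compared. Under this encoding the
nine-compound fit reaches R² ≈ 0.994 (the published fit reports 0.9951
under its own, unstated encoding), and the leave-out prediction for the
title compound lands within a few kJ mol⁻¹ of its published counterpart;
the exact published prediction is encoding-dependent and is not asserted.
The validation compound is excluded from training by default when it is
the prediction target.

## Synthetic data

The generators emulate the statistical structure each stage assumes, at
realistic scales: group tables with integer counts on [0, 6],
coefficients on a ±100 kJ mol⁻¹ scale and Gaussian target noise
(default σ = 2 kJ mol⁻¹, n = 84); TGA traces on the 438.15–488.15 K,
11-point grid with generating enthalpies in the 60–100 kJ mol⁻¹ range
and log-normal flux noise (σ_ln ν = 0.01); six-run combustion sets whose
temperature rise is inverted from a known massic energy; and coumarin
descriptor sets from a known 5-parameter model. Each call uses its own
`numpy.random.default_rng(seed)` stream, so outputs are bit-reproducible
and generators never share state.

What they do not emulate: baseline drift, decomposition kinetics,
correlated instrument noise, non-integer or correlated group counts, and
the curatorial error of hand-assigned decompositions. Passing recovery
tests therefore demonstrates the estimators' correctness and calibration
under their stated assumptions, not robustness to real-instrument
artifacts.

## Problem sizes and statistical checks

Monte-Carlo checks use 500 replicates for TGA enthalpy recovery (3·SE
coverage ≥ 95 %) and 200 seeded replicates for MLR coefficient coverage
(all 11 parameters within 3 analytic SE in ≥ 95 % of replicates; the
per-parameter normal bound predicts ≈ 97 %). SGD–MLR agreement is
checked to 10⁻³ in standardized units on full-rank noiseless tables,
where the OLS solution interpolates and stochastic updates converge
cleanly; on noisy tables agreement is ~10⁻⁴ with the default schedule
but is not part of the guarantee. These sizes complete in seconds while
leaving the statistical bounds comfortably non-trivial.

## Known limitations

- The Washburn correction is consumed, never derived; records lacking it
  cannot be reduced to standard-state energies.
- Only C/H/O compounds are supported; nitric-acid, soot and platinum
  corrections are out of scope.
- The Langmuir method yields enthalpies, not absolute vapor pressures
  (γ·p is never separated from the intercept).
- The Chickos–Acree coefficients are the standard empirical ones; they
  carry their usual ~30 % correction-term uncertainty, which is why the
  back-solved Cp(l) inputs are flagged in every report.
- The group-additivity fixtures' decompositions are curator-authored and
  interpretive; no acceptance-level check depends on them.
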