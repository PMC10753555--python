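"""End-to-end regeneration of the experimental enthalpy chain.

:func:`reproduce` runs the full reduction from the packaged fixtures —
bomb-record reduction, DSC replicate summary, Clausius-Clapeyron refit of
the TGA columns, Chickos-Acree temperature adjustments, and the Hess
composition to the gas-phase formation enthalpy — and flags each computed
quantity against the published value at its printed precision
(round-half-even). The report also documents the back-solved liquid heat
capacities it consumed, which are inputs, not measurements.
"""

from __future__ import annotations

from decimal import ROUND_HALF_EVEN, Decimal

from . import combustion, enthalpy_chain, fixtures, tga

__all__ = ["reproduce", "round_printed", "ALL_STAGES"]

ALL_STAGES = ("combustion", "dsc", "tga", "chain")


def round_printed(value: float, decimals: int) -> float:
    """Round-half-even to the given number of printed decimal places."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_EVEN))


def _compute_quantities(stages: tuple[str, ...]) -> dict[str, float]:
    cfg = fixtures.load_chain_config()
    props = fixtures.load_physical_properties()
    formula = combustion.MolecularFormula.parse(cfg["formula"])
    out: dict[str, float] = {}

    molar = None
    if "combustion" in stages or "chain" in stages:
        run1 = fixtures.load_combustion_runs()[0]
        u_ibp = combustion.isothermal_bomb_energy(run1)
        out["delta_U_IBP_kJ"] = u_ibp
        out["massic_energy_run1_kJ_g"] = combustion.massic_combustion_energy(run1, u_ibp)
        molar = combustion.molar_combustion(
            cfg["mean_massic_energy_kJ_g"],
            formula,
            massic_uncertainty=cfg["u_mean_massic_energy_kJ_g"],
        )
        stoich = combustion.combustion_stoichiometry(formula)
        out["molar_mass_g_mol"] = molar.molar_mass
        out["molar_energy_kJ_mol"] = molar.molar_energy
        out["molar_enthalpy_kJ_mol"] = molar.molar_enthalpy
        out["formation_cr_kJ_mol"] = combustion.formation_enthalpy_crystal(
            molar.molar_enthalpy, stoich.co2_coeff, stoich.h2o_coeff
        )
        out["u_formation_cr_kJ_mol"] = combustion.formation_uncertainty(
            cfg["u_molar_combustion_kJ_mol"], stoich.co2_coeff, stoich.h2o_coeff
        )

    summary = None
    if "dsc" in stages or "chain" in stages:
        summary = enthalpy_chain.summarize_fusion(fixtures.load_fusion_records())
        out["purity"] = summary.purity
        out["melting_temperature_K"] = summary.melting_temperature
        out["fusion_enthalpy_Tfus_kJ_mol"] = summary.fusion_enthalpy
        out["u_fusion_enthalpy_Tfus_kJ_mol"] = summary.u_fusion_enthalpy

    fit = None
    if "tga" in stages or "chain" in stages:
        table = fixtures.load_tga_table()
        fit = tga.fit_vaporization(
            inv_temperature=table["thousand_over_T"].to_numpy() / 1000.0,
            ln_nu=table["ln_nu"].to_numpy(),
        )
        out["tga_slope_K"] = fit.slope
        out["tga_intercept"] = fit.intercept
        out["vaporization_Tm_kJ_mol"] = fit.enthalpy_at_Tm
        out["u_slope_K"] = fit.slope_standard_error

    if "chain" in stages:
        cp_cr = props.loc[cfg["compound"], "cp_specific_J_g_K"] * molar.molar_mass
        out["cp_crystal_molar_J_mol_K"] = cp_cr
        out["cp_liquid_fusion_J_mol_K"] = cfg["cp_liquid_fusion_J_mol_K"]
        out["cp_liquid_vaporization_J_mol_K"] = cfg["cp_liquid_vaporization_J_mol_K"]
        out["fusion_298_kJ_mol"] = enthalpy_chain.adjust_fusion_to_298(
            summary.fusion_enthalpy,
            summary.melting_temperature,
            cp_cr,
            cfg["cp_liquid_fusion_J_mol_K"],
        )
        out["vaporization_298_kJ_mol"] = enthalpy_chain.adjust_vaporization_to_298(
            fit.enthalpy_at_Tm, cfg["T_m_K"], cfg["cp_liquid_vaporization_J_mol_K"]
        )
        chain = enthalpy_chain.compose_chain(
            out["fusion_298_kJ_mol"],
            out["vaporization_298_kJ_mol"],
            out["formation_cr_kJ_mol"],
            u_fusion=cfg["u_fusion_298_kJ_mol"],
            u_vaporization=cfg["u_vaporization_298_kJ_mol"],
            u_formation_cr=out["u_formation_cr_kJ_mol"],
        )
        out["sublimation_298_kJ_mol"] = chain.sublimation_298
        out["u_sublimation_298_kJ_mol"] = chain.u_sublimation
        out["formation_gas_kJ_mol"] = chain.formation_gas
        out["u_formation_gas_kJ_mol"] = chain.u_formation_gas
    return out


def reproduce(stages: tuple[str, ...] | None = None) -> dict:
    """Recompute the chain and compare with published values.

    Returns a report dict with per-quantity rows (computed value, printed
    value, match flag at printed precision) plus the consumed fixture
    checksums. Quantities with no published counterpart (fit diagnostics,
    back-solved inputs) are reported without a match flag.
    """
    stages = ALL_STAGES if stages is None else tuple(stages)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    computed = _compute_quantities(stages)
    reference = fixtures.load_reference_chain()

    rows = []
    for name, value in computed.items():
        row: dict = {"quantity": name, "computed": value}
        if name in reference.index:
            printed = float(reference.loc[name, "printed_value"])
            decimals = int(reference.loc[name, "decimals"])
            rounded = round_printed(value, decimals)
            row.update(
                printed=printed,
                computed_at_printed_precision=rounded,
                match=bool(abs(rounded - printed) < 10.0**-decimals / 2),
            )
        rows.append(row)
    n_flagged = sum("match" in r for r in rows)
    n_matched = sum(r.get("match", False) for r in rows)
    return {
        "stages": list(stages),
        "rows": rows,
        "n_compared": n_flagged,
        "n_matched": n_matched,
        "all_match": n_matched == n_flagged,
        "fixture_checksums": fixtures.fixture_checksums(),
        "notes": [
            "cp_liquid_* inputs are back-solved from published 298.15 K values, "
            "not measured; see the chain_config fixture header.",
        ],
    }
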