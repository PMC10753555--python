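"""Bomb combustion calorimetry data reduction for CHO compounds.

The reduction chain turns a single static-bomb experiment record into the
standard massic energy of combustion, and a set (or mean) of massic
energies into the standard molar energy and enthalpy of combustion and,
via Hess's law against CO2(g) and H2O(l), the standard molar enthalpy of
formation in the crystalline phase at 298.15 K.

Sign convention: combustion energies are stored negative (exothermic).
The energy of the isothermal bomb process is

    dU_IBP = eps(calor) * (-dTc) / 1000 + eps(cont)*(-dTc) + dU_ign   [kJ]

and the massic combustion energy of the sample removes the standard-state
(Washburn) correction and the cotton-fuse contribution:

    dcu = [dU_IBP + dU_corr - m_fuse * dcu(fuse)] / m_sample          [kJ/g]

with ``dcu(fuse)`` itself negative, so the fuse term is a positive energy
credit. The standard-state correction is an input per experiment: it is a
measured/tabulated quantity in bomb calorimetry workflows and this module
does not re-derive it.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

from .constants import (
    AIR_DENSITY,
    ATOMIC_WEIGHTS,
    DFH_CO2_GAS,
    DFH_H2O_LIQ,
    GAS_CONSTANT,
    T_REFERENCE,
    U_DFH_CO2_GAS,
    U_DFH_H2O_LIQ,
    WEIGHT_DENSITY,
)
from .uncertainty import combine_quadrature

__all__ = [
    "CombustionExperiment",
    "MolecularFormula",
    "MolarCombustionResult",
    "Stoichiometry",
    "buoyancy_correct",
    "isothermal_bomb_energy",
    "massic_combustion_energy",
    "combustion_stoichiometry",
    "molar_mass",
    "molar_combustion",
    "formation_enthalpy_crystal",
    "formation_uncertainty",
]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class CombustionExperiment:
    """One bomb-calorimetry run.

    Masses are buoyancy-corrected grams; ``delta_Tc`` is the corrected
    temperature rise in K; ``calor_equiv`` is the calorimeter energy
    equivalent in J K^-1; ``cont_term`` is the printed eps(cont)*(-dTc)
    product in kJ; ``ignition_energy`` and ``standard_state_correction``
    are in kJ; ``fuse_massic_energy`` is the (negative) massic combustion
    energy of the cotton fuse in kJ g^-1.
    """

    sample_mass: float
    fuse_mass: float
    delta_Tc: float
    calor_equiv: float
    cont_term: float
    ignition_energy: float
    standard_state_correction: float
    fuse_massic_energy: float
    platinum_mass: float = 0.0

    def __post_init__(self) -> None:
        if self.sample_mass <= 0:
            raise ValueError("sample_mass must be positive")
        if self.delta_Tc <= 0:
            raise ValueError("delta_Tc must be positive")
        if self.fuse_mass < 0:
            raise ValueError("fuse_mass must be nonnegative")
        if self.fuse_massic_energy > 0:
            raise ValueError("fuse_massic_energy must be negative (exothermic)")


@dataclass(frozen=True)
class MolecularFormula:
    """Element counts of a CaHbOc compound."""

    element_counts: Mapping[str, int]

    def __post_init__(self) -> None:
        counts = dict(self.element_counts)
        unknown = set(counts) - {"C", "H", "O"}
        if unknown:
            raise ValueError(f"unsupported elements: {sorted(unknown)}")
        if any(v < 0 for v in counts.values()):
            raise ValueError("element counts must be nonnegative")
        if counts.get("C", 0) < 1:
            raise ValueError("formula must contain at least one carbon")
        object.__setattr__(self, "element_counts", counts)

    @classmethod
    def parse(cls, text: str) -> "MolecularFormula":
        """Parse a Hill-style CHO formula such as ``C11H10O3``."""
        counts: dict[str, int] = {}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(text):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
            pos = m.end()
        if pos != len(text) or not counts:
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(counts)

    def count(self, element: str) -> int:
        return self.element_counts.get(element, 0)


class Stoichiometry(NamedTuple):
    """Balanced combustion CaHbOc + nO2 O2 -> nCO2 CO2 + nH2O H2O(l)."""

    o2_coeff: float
    co2_coeff: float
    h2o_coeff: float
    delta_n_gas: float


@dataclass(frozen=True)
class MolarCombustionResult:
    massic_energy: float  # kJ g^-1
    molar_mass: float  # g mol^-1
    delta_n_gas: float
    molar_energy: float  # kJ mol^-1, dcUm
    molar_enthalpy: float  # kJ mol^-1, dcHm
    formation_enthalpy_cr: float | None = None  # kJ mol^-1
    expanded_uncertainty: float | None = None  # kJ mol^-1, k=2


def buoyancy_correct(
    apparent_mass: float,
    sample_density: float,
    weight_density: float = WEIGHT_DENSITY,
    air_density: float = AIR_DENSITY,
) -> float:
    """Air-buoyancy correction of a weighed mass (densities in g cm^-3).

    ``m_corr = m_app * (1 + rho_air * (1/rho_sample - 1/rho_weights))``.
    Fixture masses are already corrected; this is an optional
    pre-processing step for raw balance readings.
    """
    if sample_density <= 0 or weight_density <= 0:
        raise ValueError("densities must be positive")
    return apparent_mass * (1.0 + air_density * (1.0 / sample_density - 1.0 / weight_density))


def isothermal_bomb_energy(exp: CombustionExperiment) -> float:
    """Energy of the isothermal bomb process, kJ (negative, exothermic)."""
    return exp.calor_equiv * (-exp.delta_Tc) / 1000.0 + exp.cont_term + exp.ignition_energy


def massic_combustion_energy(exp: CombustionExperiment, u_ibp: float | None = None) -> float:
    """Standard massic energy of combustion of the sample, kJ g^-1.

    Removes the standard-state correction and the fuse's (negative)
    contribution from the bomb-process energy, then divides by the sample
    mass.
    """
    if u_ibp is None:
        u_ibp = isothermal_bomb_energy(exp)
    fuse_credit = exp.fuse_mass * (-exp.fuse_massic_energy)
    return (u_ibp + exp.standard_state_correction + fuse_credit) / exp.sample_mass


def combustion_stoichiometry(formula: MolecularFormula) -> Stoichiometry:
    """Balanced O2/CO2/H2O(l) coefficients and gas-mole change.

    Requires an even hydrogen count so the liquid-water product carries an
    integral or half-integral coefficient consistent with a per-mole
    balance; delta_n_gas = c/2 - b/4 counts gaseous products minus gaseous
    reactants (water is liquid).
    """
    a = formula.count("C")
    b = formula.count("H")
    c = formula.count("O")
    if b % 2 != 0:
        raise ValueError("odd hydrogen count is unsupported (liquid-water product convention)")
    o2 = a + b / 4.0 - c / 2.0
    return Stoichiometry(o2, float(a), b / 2.0, c / 2.0 - b / 4.0)


def molar_mass(formula: MolecularFormula, atomic_weights: Mapping[str, float] | None = None) -> float:
    """Molar mass in g mol^-1 from (by default IUPAC 2021) atomic weights."""
    weights = ATOMIC_WEIGHTS if atomic_weights is None else atomic_weights
    return sum(n * weights[el] for el, n in formula.element_counts.items())


def molar_combustion(
    massic: float,
    formula: MolecularFormula,
    atomic_weights: Mapping[str, float] | None = None,
    massic_uncertainty: float | None = None,
    gas_constant: float = GAS_CONSTANT,
    temperature: float = T_REFERENCE,
) -> MolarCombustionResult:
    """Molar combustion energy and enthalpy from the massic energy.

    ``dcUm = dcu * M``; ``dcHm = dcUm + dn_g * R * T / 1000``. The
    ``massic_uncertainty`` (expanded, kJ g^-1) is scaled by M when given.
    """
    if massic >= 0:
        raise ValueError("massic combustion energy must be negative (exothermic)")
    M = molar_mass(formula, atomic_weights)
    stoich = combustion_stoichiometry(formula)
    molar_energy = massic * M
    molar_enthalpy = molar_energy + stoich.delta_n_gas * gas_constant * temperature / 1000.0
    u = None if massic_uncertainty is None else abs(massic_uncertainty) * M
    return MolarCombustionResult(
        massic_energy=massic,
        molar_mass=M,
        delta_n_gas=stoich.delta_n_gas,
        molar_energy=molar_energy,
        molar_enthalpy=molar_enthalpy,
        expanded_uncertainty=u,
    )


def formation_enthalpy_crystal(
    molar_enthalpy: float,
    co2_coeff: float,
    h2o_coeff: float,
    ref_co2: float = DFH_CO2_GAS,
    ref_h2o: float = DFH_H2O_LIQ,
) -> float:
    """Hess's law: dfHm(cr) = nCO2*dfH(CO2,g) + nH2O*dfH(H2O,l) - dcHm."""
    return co2_coeff * ref_co2 + h2o_coeff * ref_h2o - molar_enthalpy


def formation_uncertainty(
    u_combustion: float,
    co2_coeff: float,
    h2o_coeff: float,
    u_co2: float = U_DFH_CO2_GAS,
    u_h2o: float = U_DFH_H2O_LIQ,
) -> float:
    """Quadrature propagation of the Hess chain's expanded uncertainties."""
    return combine_quadrature([u_combustion, co2_coeff * u_co2, h2o_coeff * u_h2o])
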