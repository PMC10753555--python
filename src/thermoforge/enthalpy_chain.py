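"""Phase-change enthalpy chain to the gas-phase formation enthalpy.

DSC fusion replicates are averaged; fusion and vaporization enthalpies
measured away from 298.15 K are brought to the reference temperature with
the Chickos-Acree empirical heat-capacity corrections; sublimation is the
sum of the adjusted fusion and vaporization terms; and the gas-phase
standard molar enthalpy of formation follows from the crystalline-phase
value plus sublimation:

    dcr^l H(298) = dcr^l H(Tfus) + [0.15 Cp(cr) - 0.26 Cp(l) - 9.83] (Tfus - 298.15)/1000
    dl^g  H(298) = dl^g  H(Tm)   + [10.58 + 0.26 Cp(l)] (Tm - 298.15)/1000
    dcr^g H(298) = dcr^l H(298) + dl^g H(298)
    dfH(g)       = dfH(cr) + dcr^g H(298)

Heat capacities are molar, J mol^-1 K^-1; enthalpies kJ mol^-1. The
liquid-phase heat capacity is rarely measured for crystalline solids and
is an explicit input here; helpers are provided to back-solve the value
implied by a published 298.15 K enthalpy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .constants import T_REFERENCE
from .uncertainty import combine_quadrature, expanded_uncertainty_of_mean

__all__ = [
    "FusionRecord",
    "FusionSummary",
    "CpPolynomial",
    "PhaseChainResult",
    "summarize_fusion",
    "fit_cp_polynomial",
    "adjust_fusion_to_298",
    "adjust_vaporization_to_298",
    "compose_chain",
    "cp_liquid_from_fusion",
    "cp_liquid_from_vaporization",
]


@dataclass(frozen=True)
class FusionRecord:
    """One DSC fusion experiment: mole-fraction purity, T_fus (K), and
    the fusion enthalpy at T_fus (kJ mol^-1)."""

    purity: float
    melting_temperature: float
    fusion_enthalpy: float

    def __post_init__(self) -> None:
        if not 0 < self.purity <= 1:
            raise ValueError("purity must be a mole fraction in (0, 1]")
        if self.melting_temperature <= T_REFERENCE:
            raise ValueError("melting temperature must exceed 298.15 K")


class FusionSummary(NamedTuple):
    purity: float
    melting_temperature: float
    fusion_enthalpy: float
    u_purity: float
    u_melting_temperature: float
    u_fusion_enthalpy: float


@dataclass(frozen=True)
class CpPolynomial:
    """Least-squares polynomial Cp(T), coefficients in ascending powers."""

    coefficients: np.ndarray
    valid_range: tuple[float, float]

    def evaluate(self, temperature) -> np.ndarray | float:
        t = np.asarray(temperature, dtype=float)
        lo, hi = self.valid_range
        if np.any((t < lo) | (t > hi)):
            raise ValueError(f"temperature outside fitted range [{lo}, {hi}] K")
        out = np.polynomial.polynomial.polyval(t, self.coefficients)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class PhaseChainResult:
    fusion_298: float
    vaporization_298: float
    sublimation_298: float
    formation_cr: float
    formation_gas: float
    u_fusion: float = 0.0
    u_vaporization: float = 0.0
    u_sublimation: float = 0.0
    u_formation_cr: float = 0.0
    u_formation_gas: float = 0.0


def summarize_fusion(
    records: Sequence[FusionRecord],
    calibration_uncertainties: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> FusionSummary:
    """Replicate means with expanded (k=2) uncertainties of the mean.

    ``calibration_uncertainties`` are optional expanded instrument
    contributions for (purity, T_fus, enthalpy), combined in quadrature
    with the replicate scatter.
    """
    if len(records) < 2:
        raise ValueError("need at least two fusion replicates")
    cols = {
        "purity": [r.purity for r in records],
        "t": [r.melting_temperature for r in records],
        "h": [r.fusion_enthalpy for r in records],
    }
    means = {k: sum(v) / len(v) for k, v in cols.items()}
    spread = {k: expanded_uncertainty_of_mean(v) for k, v in cols.items()}
    u = [
        combine_quadrature([spread[k], cal])
        for k, cal in zip(("purity", "t", "h"), calibration_uncertainties)
    ]
    return FusionSummary(means["purity"], means["t"], means["h"], u[0], u[1], u[2])


def fit_cp_polynomial(temperatures, heat_capacities, degree: int = 2) -> CpPolynomial:
    """Least-squares polynomial fit of molar heat capacity vs temperature."""
    t = np.asarray(temperatures, dtype=float)
    cp = np.asarray(heat_capacities, dtype=float)
    if t.size != cp.size:
        raise ValueError("mismatched lengths")
    if t.size <= degree:
        raise ValueError("underdetermined fit: need more samples than the degree")
    coeffs = np.polynomial.polynomial.polyfit(t, cp, degree)
    return CpPolynomial(coefficients=coeffs, valid_range=(float(t.min()), float(t.max())))


def adjust_fusion_to_298(
    fusion_at_Tfus: float,
    T_fus: float,
    cp_crystal: float,
    cp_liquid: float,
    t_ref: float = T_REFERENCE,
) -> float:
    """Chickos-Acree adjustment of a fusion enthalpy to 298.15 K."""
    if T_fus < t_ref:
        raise ValueError("T_fus must be at or above the reference temperature")
    bracket = 0.15 * cp_crystal - 0.26 * cp_liquid - 9.83
    return fusion_at_Tfus + bracket * (T_fus - t_ref) / 1000.0


def adjust_vaporization_to_298(
    vap_at_Tm: float,
    T_m: float,
    cp_liquid: float,
    t_ref: float = T_REFERENCE,
) -> float:
    """Chickos-Acree adjustment of a vaporization enthalpy to 298.15 K."""
    if T_m < t_ref:
        raise ValueError("T_m must be at or above the reference temperature")
    bracket = 10.58 + 0.26 * cp_liquid
    return vap_at_Tm + bracket * (T_m - t_ref) / 1000.0


def cp_liquid_from_fusion(
    fusion_298: float, fusion_at_Tfus: float, T_fus: float, cp_crystal: float
) -> float:
    """Liquid heat capacity implied by a known 298.15 K fusion enthalpy."""
    bracket = (fusion_298 - fusion_at_Tfus) * 1000.0 / (T_fus - T_REFERENCE)
    return (0.15 * cp_crystal - 9.83 - bracket) / 0.26


def cp_liquid_from_vaporization(vap_298: float, vap_at_Tm: float, T_m: float) -> float:
    """Liquid heat capacity implied by a known 298.15 K vaporization enthalpy."""
    bracket = (vap_298 - vap_at_Tm) * 1000.0 / (T_m - T_REFERENCE)
    return (bracket - 10.58) / 0.26


def compose_chain(
    fusion_298: float,
    vaporization_298: float,
    formation_cr: float,
    u_fusion: float = 0.0,
    u_vaporization: float = 0.0,
    u_formation_cr: float = 0.0,
) -> PhaseChainResult:
    """Sublimation and gas-phase formation enthalpies with quadrature
    combination of the (already expanded) component uncertainties."""
    sublimation = fusion_298 + vaporization_298
    u_subl = combine_quadrature([u_fusion, u_vaporization])
    return PhaseChainResult(
        fusion_298=fusion_298,
        vaporization_298=vaporization_298,
        sublimation_298=sublimation,
        formation_cr=formation_cr,
        formation_gas=formation_cr + sublimation,
        u_fusion=u_fusion,
        u_vaporization=u_vaporization,
        u_sublimation=u_subl,
        u_formation_cr=u_formation_cr,
        u_formation_gas=combine_quadrature([u_formation_cr, u_subl]),
    )
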