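"""Homodesmic-reaction solver for one unknown formation enthalpy.

A homodesmic reaction conserves bond and group types, so its reaction
enthalpy is assumed zero; with every species' formation enthalpy known
except one, the unknown follows from

    sum_i coeff_i * dfH_i = 0
    dfH(target) = -(sum_{known} coeff_i * dfH_i) / coeff(target)

Coefficients are signed: reactants negative, products positive. Reactions
are data (config files); element balance is always enforced before
solving, and a group-balance check against Benson group vectors is
available as the stricter homodesmic validity criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .combustion import MolecularFormula
from .group_additivity import GroupVector

__all__ = [
    "Species",
    "Reaction",
    "BalanceReport",
    "check_balance",
    "check_group_balance",
    "solve_target",
]


@dataclass(frozen=True)
class Species:
    """A reaction participant; ``formation_enthalpy`` is kJ mol^-1 or None
    when the species is the unknown."""

    id: str
    formula: MolecularFormula
    formation_enthalpy: float | None = None


@dataclass(frozen=True)
class Reaction:
    """Signed stoichiometry (reactants < 0, products > 0) with a single
    target species whose formation enthalpy is to be solved."""

    stoichiometry: Mapping[str, float]
    target: str

    def __post_init__(self) -> None:
        if self.target not in self.stoichiometry:
            raise ValueError(f"target {self.target!r} not in stoichiometry")
        if self.stoichiometry[self.target] == 0:
            raise ValueError("target coefficient must be nonzero")


@dataclass(frozen=True)
class BalanceReport:
    imbalances: Mapping[str, float]

    @property
    def balanced(self) -> bool:
        return all(abs(v) < 1e-9 for v in self.imbalances.values())


def _resolve(reaction: Reaction, species: Mapping[str, Species]) -> None:
    missing = sorted(set(reaction.stoichiometry) - set(species))
    if missing:
        raise KeyError(f"unresolvable species ids: {missing}")


def check_balance(reaction: Reaction, species: Mapping[str, Species]) -> BalanceReport:
    """Per-element signed atom totals; all zero iff the reaction balances."""
    _resolve(reaction, species)
    totals: dict[str, float] = {}
    for sid, coeff in reaction.stoichiometry.items():
        for el, n in species[sid].formula.element_counts.items():
            totals[el] = totals.get(el, 0.0) + coeff * n
    return BalanceReport(imbalances=totals)


def check_group_balance(
    reaction: Reaction, vectors: Mapping[str, GroupVector]
) -> BalanceReport:
    """Benson group conservation check (the strict homodesmic criterion):
    signed group-count totals over the reaction, zero when each group type
    is conserved between reactants and products."""
    missing = sorted(set(reaction.stoichiometry) - set(vectors))
    if missing:
        raise KeyError(f"no group vector for: {missing}")
    totals: dict[str, float] = {}
    for sid, coeff in reaction.stoichiometry.items():
        for g, c in vectors[sid].counts.items():
            totals[g] = totals.get(g, 0.0) + coeff * c
    return BalanceReport(imbalances={g: v for g, v in totals.items()})


def solve_target(reaction: Reaction, species: Mapping[str, Species]) -> float:
    """Solve the target's formation enthalpy under zero reaction enthalpy.

    Refuses unbalanced reactions (reporting the per-element imbalance) and
    reactions with more or fewer than one unknown enthalpy.
    """
    _resolve(reaction, species)
    balance = check_balance(reaction, species)
    if not balance.balanced:
        off = {el: v for el, v in balance.imbalances.items() if abs(v) >= 1e-9}
        raise ValueError(f"reaction is not element-balanced: {off}")
    unknown = [
        sid for sid in reaction.stoichiometry if species[sid].formation_enthalpy is None
    ]
    if unknown != [reaction.target]:
        if not unknown:
            raise ValueError("no unknown species: nothing to solve")
        raise ValueError(f"underdetermined: unknown enthalpies for {unknown}")
    known_sum = sum(
        coeff * species[sid].formation_enthalpy
        for sid, coeff in reaction.stoichiometry.items()
        if sid != reaction.target
    )
    return -known_sum / reaction.stoichiometry[reaction.target]
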