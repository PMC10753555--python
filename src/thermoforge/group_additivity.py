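"""Benson group additivity for gas-phase formation enthalpies.

A molecule is represented as a vector of counts over a closed vocabulary
of Benson groups (a polyvalent atom plus its ligands, e.g. ``C-(H)3(C)``),
ring-strain corrections, positional (ortho/meta/para) corrections and
family indicator terms. The estimate is linear:

    -dfH(g, 298.15 K) = H0 + sum_g count_g * value_g

The shipped coefficient table stores contributions to the *negated*
formation enthalpy (coumarin-scale values are large and positive under
this convention); :func:`estimate_formation` can return either sign.

Group vectors are authored data, not perceived from structures: assigning
Benson groups to fused-ring lactones involves judgment calls that belong
with the curator, not in code.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

__all__ = [
    "CoefficientTable",
    "GroupVector",
    "ValidationReport",
    "estimate_formation",
    "validate_vector",
]


@dataclass(frozen=True)
class CoefficientTable:
    """Additive coefficient vocabulary: intercept H0 plus one value per
    group label, all in kJ mol^-1 on the -dfH(g) scale."""

    intercept: float
    values: Mapping[str, float]

    @property
    def vocabulary(self) -> frozenset[str]:
        return frozenset(self.values)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CoefficientTable":
        """Read ``group,value`` rows; the intercept row is labelled H0."""
        intercept = None
        values: dict[str, float] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            rows = (r for r in csv.reader(fh) if r and not r[0].startswith("#"))
            header = next(rows)
            if [h.strip() for h in header[:2]] != ["group", "value"]:
                raise ValueError(f"unexpected coefficient CSV header: {header}")
            for row in rows:
                label, value = row[0].strip(), float(row[1])
                if label == "H0":
                    intercept = value
                elif label in values:
                    raise ValueError(f"duplicate group label {label!r}")
                else:
                    values[label] = value
        if intercept is None:
            raise ValueError("coefficient CSV lacks an H0 intercept row")
        return cls(intercept=intercept, values=values)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["group", "value"])
            writer.writerow(["H0", repr(self.intercept)])
            for label, value in self.values.items():
                writer.writerow([label, repr(value)])


@dataclass(frozen=True)
class GroupVector:
    """Group counts for one compound; fractional counts are permitted to
    support symmetry-weighted decompositions."""

    compound_id: str
    counts: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class ValidationReport:
    unknown_labels: tuple[str, ...]
    negative_labels: tuple[str, ...]

    @property
    def valid(self) -> bool:
        return not self.unknown_labels and not self.negative_labels


def validate_vector(vector: GroupVector, table: CoefficientTable) -> ValidationReport:
    """Check a group vector against the table's closed vocabulary."""
    unknown = tuple(sorted(g for g in vector.counts if g not in table.values))
    negative = tuple(sorted(g for g, c in vector.counts.items() if c < 0))
    return ValidationReport(unknown_labels=unknown, negative_labels=negative)


def estimate_formation(
    vector: GroupVector, table: CoefficientTable, negated: bool = True
) -> float:
    """Additive estimate for one compound, kJ mol^-1.

    Returns -dfH(g) under the table's storage convention, or dfH(g) when
    ``negated=False``. Unknown labels raise a ValueError naming them.
    """
    report = validate_vector(vector, table)
    if report.unknown_labels:
        raise ValueError(f"unknown group labels: {list(report.unknown_labels)}")
    if report.negative_labels:
        raise ValueError(f"negative counts for: {list(report.negative_labels)}")
    est = table.intercept + sum(c * table.values[g] for g, c in vector.counts.items())
    return est if negated else -est
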