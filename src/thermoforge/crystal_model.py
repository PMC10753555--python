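"""Structural regression for crystalline-phase coumarin enthalpies.

For coumarins, where the available condensed-phase data are all
crystalline, a compact linear model on atom counts and substituent
descriptors predicts -dfH(cr, 298.15 K):

    -dfH(cr) = b0 + b1*X1 + b2*X2 + b3*X3 + b4*X4

with X1 the hydrogen count, X2 the oxygen count, and X3/X4 integer codes
for the two substituent ("radical") slots — X3 the substituent nearer the
carbonyl (ring positions 3/4), X4 the benzo-ring substituent (positions
5-8). The carbon count adds no information over this coumarin scaffold
family and is deliberately excluded. The substituent encoding is a config
table so alternative encodings can be compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .regression import FeatureTable, RegressionFit, evaluate, fit_mlr

__all__ = [
    "CoumarinDescriptor",
    "DEFAULT_RADICAL_CODES",
    "fit_crystal_model",
    "predict_crystal",
]

#: Default integer codes for the substituent slots.
DEFAULT_RADICAL_CODES: Mapping[str, int] = {"none": 0, "OH": 1, "OCH3": 2, "CH3": 3}

_FEATURES = ("X1_H_count", "X2_O_count", "X3_radical_1", "X4_radical_2")


@dataclass(frozen=True)
class CoumarinDescriptor:
    """One coumarin's regressors; radicals are names resolved through an
    encoding table. ``target`` is -dfH(cr) in kJ mol^-1 when known."""

    compound_id: str
    h_count: int
    o_count: int
    radical_1: str = "none"
    radical_2: str = "none"
    target: float | None = None

    def __post_init__(self) -> None:
        if self.h_count < 0 or self.o_count < 0:
            raise ValueError("atom counts must be nonnegative")

    def encode(self, codes: Mapping[str, int] | None = None) -> np.ndarray:
        codes = DEFAULT_RADICAL_CODES if codes is None else codes
        for r in (self.radical_1, self.radical_2):
            if r not in codes:
                raise KeyError(f"radical {r!r} missing from the encoding table")
        return np.array(
            [self.h_count, self.o_count, codes[self.radical_1], codes[self.radical_2]],
            dtype=float,
        )


def _table(
    descriptors: Sequence[CoumarinDescriptor], codes: Mapping[str, int] | None
) -> FeatureTable:
    rows = [d for d in descriptors if d.target is not None]
    if len(rows) < 5:
        raise ValueError("need at least 5 compounds with known targets (5 parameters)")
    return FeatureTable(
        compound_ids=tuple(d.compound_id for d in rows),
        feature_names=_FEATURES,
        X=np.vstack([d.encode(codes) for d in rows]),
        y=np.array([d.target for d in rows]),
    )


def fit_crystal_model(
    descriptors: Sequence[CoumarinDescriptor],
    codes: Mapping[str, int] | None = None,
    exclude: str | None = None,
) -> RegressionFit:
    """OLS fit on all descriptors with known targets.

    ``exclude`` drops one compound from training (the usual pattern when
    that compound is the prediction target). Training metrics are attached
    to the returned fit.
    """
    kept = [d for d in descriptors if d.compound_id != exclude]
    table = _table(kept, codes)
    fit = fit_mlr(table)
    metrics = evaluate(table.y, fit.predict(table.X))
    return RegressionFit(
        method=fit.method,
        intercept=fit.intercept,
        coefficients=fit.coefficients,
        feature_names=fit.feature_names,
        rank_deficient=fit.rank_deficient,
        train_metrics=metrics,
    )


def predict_crystal(
    fit: RegressionFit,
    descriptor: CoumarinDescriptor,
    codes: Mapping[str, int] | None = None,
) -> tuple[float, float | None]:
    """Predict -dfH(cr) for one coumarin.

    Returns ``(predicted, delta)`` where ``delta = predicted - target``
    when the descriptor carries an experimental value, else None.
    """
    pred = float(fit.predict(descriptor.encode(codes)[None, :])[0])
    delta = None if descriptor.target is None else pred - descriptor.target
    return pred, delta
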