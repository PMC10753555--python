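"""Small helpers for expanded-uncertainty bookkeeping.

Conventions follow standard calorimetric practice: the expanded uncertainty
of a replicate mean is ``k * s / sqrt(n)`` with coverage factor ``k = 2``
(~95 % confidence), and independent expanded components combine in
quadrature (root-sum-square), the coverage factor already being common to
all components.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence


def expanded_uncertainty_of_mean(values: Sequence[float], k: float = 2.0) -> float:
    """Expanded uncertainty of the mean of replicate measurements.

    ``k * sd / sqrt(n)`` where ``sd`` is the sample standard deviation
    (ddof = 1). Requires at least two values.
    """
    n = len(values)
    if n < 2:
        raise ValueError("need at least two replicates for an uncertainty of the mean")
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return k * math.sqrt(var) / math.sqrt(n)


def combine_quadrature(components: Iterable[float]) -> float:
    """Root-sum-square combination of expanded uncertainty components."""
    return math.sqrt(sum(float(c) ** 2 for c in components))
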