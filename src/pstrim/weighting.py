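"""ATT odds weights and percentile weight trimming.

Weighting by the odds targets the average treatment effect among the
treated: exposed subjects keep weight 1 and unexposed subjects receive
p/(1-p), which reweights the unexposed group to resemble the exposed
group's covariate distribution. Trimming (truncation) replaces every
weight above a cutpoint w0 with w0, where w0 is a percentile of the
weight distribution; it is the ad-hoc variance-control device whose
costs and benefits this package measures.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .propensity import PropensityFit

#: the trim grid studied: 99th down to 50th percentile plus 100 (= no trim)
DEFAULT_TRIM_GRID = tuple(range(50, 101))

UNTRIMMED = 100


@dataclass(frozen=True)
class WeightSet:
    """Per-subject ATT odds weights at a given trim percentile."""

    weights: np.ndarray
    exposure: np.ndarray
    source_method: str
    trim_percentile: int = UNTRIMMED
    cutpoint_value: float = float("nan")

    def __post_init__(self):
        if len(self.weights) != len(self.exposure):
            raise ValueError("weights and exposure lengths differ")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if not 50 <= self.trim_percentile <= 100:
            raise ValueError("trim_percentile must lie in [50, 100]")
        if not np.all(self.weights[self.exposure == 1] == 1.0):
            raise ValueError("every exposed subject must have weight 1")

    @property
    def unexposed_weights(self) -> np.ndarray:
        return self.weights[self.exposure == 0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": np.arange(1, len(self.weights) + 1),
            "exposure": self.exposure,
            "weight": self.weights,
            "trim_percentile": self.trim_percentile,
        })


def odds_weights(fit: PropensityFit, exposure: np.ndarray) -> WeightSet:
    """Untrimmed ATT odds weights: exposed -> 1, unexposed -> p/(1-p)."""
    exposure = np.asarray(exposure)
    if len(fit.propensity) != len(exposure):
        raise ValueError("propensity and exposure lengths differ")
    p = fit.propensity
    w = np.where(exposure == 1, 1.0, p / (1.0 - p))
    return WeightSet(weights=w, exposure=exposure,
                     source_method=fit.method)


def trim_weights(ws: WeightSet, percentile: int,
                 reference: str = "unexposed") -> WeightSet:
    """Cap unexposed weights at the given percentile of the weight
    distribution.

    ``reference`` selects the population whose weights define the
    percentile: "unexposed" (default; exposed weights are identically 1
    and carry no information) or "all". Quantiles use linear
    interpolation between order statistics (type-7, the default of the
    common statistical software stacks). percentile=100 returns an
    unchanged copy.
    """
    percentile = int(percentile)
    if not 50 <= percentile <= 100:
        raise ValueError("trim percentile must lie in [50, 100]")
    if percentile == UNTRIMMED:
        return dataclasses.replace(ws)
    if percentile == ws.trim_percentile:
        # idempotence: the set already sits at this trim level (re-deriving
        # the cutpoint from capped weights would interpolate below it)
        return dataclasses.replace(ws)
    if reference == "unexposed":
        ref = ws.unexposed_weights
    elif reference == "all":
        ref = ws.weights
    else:
        raise ValueError("reference must be 'unexposed' or 'all'")
    if ref.size == 0:
        raise ValueError("reference group for trimming is empty")
    cut = float(np.quantile(ref, percentile / 100.0))  # type-7 interpolation
    w = np.where(ws.exposure == 0, np.minimum(ws.weights, cut), ws.weights)
    return WeightSet(weights=w, exposure=ws.exposure,
                     source_method=ws.source_method,
                     trim_percentile=percentile, cutpoint_value=cut)


def trim_grid(ws: WeightSet, percentiles: Sequence[int] = DEFAULT_TRIM_GRID,
              reference: str = "unexposed") -> list[WeightSet]:
    """Apply every trim level independently to the untrimmed weights."""
    return [trim_weights(ws, q, reference=reference) for q in percentiles]
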