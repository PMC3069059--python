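"""Weighted estimation of the treatment effect.

The estimator is the one used throughout the weighting literature for
this design: a weighted least-squares regression of the outcome on an
intercept and the exposure indicator only (no covariates, no
doubly-robust augmentation), with the propensity-score odds weights as
case weights. With a single binary regressor the slope is the weighted
mean outcome difference between exposed and unexposed.

Two variance estimators are available:

``model``
    The precision-weight (naive) WLS standard error that a standard
    weighted linear-model fit reports — the default, matching the usual
    software stack even though odds weights are not precision weights.
``sandwich``
    The HC0 robust (sandwich) standard error, offered as a sensitivity
    analysis.

Confidence intervals use Student-t critical values with n-2 degrees of
freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .dgp import SimulatedDataset
from .weighting import WeightSet

VARIANCE_ESTIMATORS = ("model", "sandwich")


@dataclass(frozen=True)
class EffectEstimate:
    """Results of one weighted effect estimation.

    Carries the point estimate, its standard error and confidence
    interval, plus the provenance keys (method, trim percentile,
    replicate seed) used by the Monte-Carlo aggregation layer.
    """

    estimate: float
    standard_error: float
    ci_low: float
    ci_high: float
    ci_level: float
    trim_percentile: int
    method: str
    replicate_seed: int
    variance: str = "model"
    intercept: float = float("nan")

    def __post_init__(self):
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0,1)")
        if self.standard_error < 0:
            raise ValueError("standard_error must be non-negative")
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise ValueError("estimate must lie inside its interval")

    def conf_int(self) -> tuple[float, float]:
        return (self.ci_low, self.ci_high)

    def covers(self, truth: float) -> bool:
        return covers_truth(self, truth)

    def summary(self) -> str:
        lines = [
            "Weighted ATT estimate",
            "=" * 53,
            f"propensity method:   {self.method}",
            f"trim percentile:     {self.trim_percentile}",
            f"variance estimator:  {self.variance}",
            "-" * 53,
            f"effect estimate:     {self.estimate: .4f}",
            f"standard error:      {self.standard_error: .4f}",
            (f"{self.ci_level * 100:.0f}% CI:              "
             f"[{self.ci_low: .4f}, {self.ci_high: .4f}]"),
            "=" * 53,
        ]
        return "\n".join(lines)


class AttWeightedOLS:
    """Weighted least squares of outcome on {intercept, exposure}.

    Model object in the fit()-returns-results style: construct from the
    raw arrays (or use :func:`estimate_effect` to construct from a
    simulated dataset and a weight set), call :meth:`fit` to obtain an
    :class:`EffectEstimate`.
    """

    def __init__(self, outcome: np.ndarray, exposure: np.ndarray,
                 weights: np.ndarray):
        self.outcome = np.asarray(outcome, dtype=float)
        self.exposure = np.asarray(exposure)
        self.weights = np.asarray(weights, dtype=float)
        if not (len(self.outcome) == len(self.exposure)
                == len(self.weights)):
            raise ValueError("outcome, exposure and weights lengths differ")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        self._wt = self.weights[self.exposure == 1].sum()
        self._wc = self.weights[self.exposure == 0].sum()
        if self._wt <= 0 or self._wc <= 0:
            bad = "exposed" if self._wt <= 0 else "unexposed"
            raise ValueError(f"{bad} group has zero total weight")

    def fit(self, ci_level: float = 0.95, variance: str = "model",
            trim_percentile: int = 100, method: str = "unknown",
            replicate_seed: int = -1) -> EffectEstimate:
        if variance not in VARIANCE_ESTIMATORS:
            raise ValueError(
                f"variance must be one of {VARIANCE_ESTIMATORS}")
        y, a, w = self.outcome, self.exposure, self.weights
        n = len(y)
        treated = a == 1
        mu1 = np.sum(w[treated] * y[treated]) / self._wt
        mu0 = np.sum(w[~treated] * y[~treated]) / self._wc
        slope = mu1 - mu0
        resid = y - np.where(treated, mu1, mu0)
        if variance == "model":
            sigma2 = np.sum(w * resid ** 2) / (n - 2)
            var = sigma2 * (1.0 / self._wt + 1.0 / self._wc)
        else:  # HC0 sandwich
            var = (np.sum((w[treated] * resid[treated]) ** 2) / self._wt ** 2
                   + np.sum((w[~treated] * resid[~treated]) ** 2)
                   / self._wc ** 2)
        se = float(np.sqrt(var))
        tcrit = stats.t.ppf(0.5 + ci_level / 2, df=n - 2)
        return EffectEstimate(
            estimate=float(slope),
            standard_error=se,
            ci_low=float(slope - tcrit * se),
            ci_high=float(slope + tcrit * se),
            ci_level=ci_level,
            trim_percentile=trim_percentile,
            method=method,
            replicate_seed=replicate_seed,
            variance=variance,
            intercept=float(mu0),
        )


def estimate_effect(dataset: SimulatedDataset, ws: WeightSet,
                    ci_level: float = 0.95,
                    variance: str = "model") -> EffectEstimate:
    """Fit the weighted outcome regression for one replicate/trim level."""
    if len(ws.weights) != dataset.n:
        raise ValueError("weight set does not match dataset")
    model = AttWeightedOLS(dataset.outcome, dataset.exposure, ws.weights)
    return model.fit(ci_level=ci_level, variance=variance,
                     trim_percentile=ws.trim_percentile,
                     method=ws.source_method,
                     replicate_seed=dataset.seed)


def covers_truth(est: EffectEstimate, truth: float) -> bool:
    """Closed-interval coverage: true iff ci_low <= truth <= ci_high."""
    return bool(est.ci_low <= truth <= est.ci_high)
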