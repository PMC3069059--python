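"""Monte-Carlo performance measures and weight diagnostics.

Aggregates per-replicate effect estimates into the three headline
performance curves — absolute percent bias, mean standard error, and 95%
confidence-interval coverage, each indexed by (scenario, method, trim
percentile) — plus diagnostics of the untrimmed weight distributions
(quartiles, extreme-weight proportions, top-5% weight mass) and
between-method Spearman correlations of the weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .inference import EffectEstimate
from .weighting import UNTRIMMED, WeightSet


def absolute_percent_bias(estimates: Sequence[float], truth: float) -> float:
    """100 * |mean(estimates) - truth| / |truth|.

    The absolute value of the mean relative deviation (not the mean of
    absolute deviations, which would conflate sampling noise with bias).
    """
    est = np.asarray(list(estimates), dtype=float)
    if est.size == 0:
        raise ValueError("estimates must be non-empty")
    if truth == 0:
        raise ValueError("relative bias is undefined for truth = 0")
    return float(100.0 * abs(est.mean() - truth) / abs(truth))


def mean_absolute_percent_error(estimates: Sequence[float],
                                truth: float) -> float:
    """Companion measure: mean of per-replicate absolute percent errors."""
    est = np.asarray(list(estimates), dtype=float)
    if est.size == 0:
        raise ValueError("estimates must be non-empty")
    if truth == 0:
        raise ValueError("relative error is undefined for truth = 0")
    return float(100.0 * np.mean(np.abs(est - truth)) / abs(truth))


def monte_carlo_se_of_bias(estimates: Sequence[float], truth: float) -> float:
    """Monte-Carlo standard error of the percent-bias estimate."""
    est = np.asarray(list(estimates), dtype=float)
    if truth == 0:
        raise ValueError("relative bias is undefined for truth = 0")
    if est.size < 2:
        return float("nan")
    return float(100.0 * est.std(ddof=1) / np.sqrt(est.size) / abs(truth))


def coverage_percent(records: Iterable[EffectEstimate],
                     truth: float) -> float:
    """Percent of replicates whose CI covers the truth (closed interval)."""
    records = list(records)
    if not records:
        raise ValueError("records must be non-empty")
    covered = sum(r.covers(truth) for r in records)
    return 100.0 * covered / len(records)


def mean_standard_error(records: Iterable[EffectEstimate]) -> float:
    """Arithmetic mean of per-replicate standard errors."""
    ses = [r.standard_error for r in records]
    if not ses:
        raise ValueError("records must be non-empty")
    return float(np.mean(ses))


@dataclass(frozen=True)
class PerformanceTable:
    """Bias / mean SE / coverage indexed by (scenario, method, trim
    percentile); thin wrapper around a long-format DataFrame."""

    table: pd.DataFrame

    KEY = ["scenario_id", "method", "trim_percentile"]
    COLUMNS = KEY + ["abs_percent_bias", "mean_abs_percent_error", "mean_se",
                     "coverage_percent", "n_reps", "mc_se_of_bias"]

    def __post_init__(self):
        missing = set(self.COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"performance table missing columns {missing}")
        if self.table.duplicated(self.KEY).any():
            raise ValueError("duplicate (scenario, method, trim) rows")

    def lookup(self, scenario_id: int, method: str,
               trim_percentile: int) -> pd.Series:
        t = self.table
        row = t[(t.scenario_id == scenario_id) & (t.method == method)
                & (t.trim_percentile == trim_percentile)]
        if row.empty:
            raise KeyError((scenario_id, method, trim_percentile))
        return row.iloc[0]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def performance_table(records: pd.DataFrame, truth: float) -> PerformanceTable:
    """Aggregate a long-format estimate record stream.

    ``records`` needs columns scenario_id, method, trim_percentile,
    estimate, se, ci_low, ci_high.
    """
    if records.empty:
        raise ValueError("no records to aggregate")
    if truth == 0:
        raise ValueError("relative bias is undefined for truth = 0")

    def agg(g: pd.DataFrame) -> pd.Series:
        est = g["estimate"].to_numpy()
        covered = ((g["ci_low"] <= truth) & (truth <= g["ci_high"])).mean()
        return pd.Series({
            "abs_percent_bias": 100.0 * abs(est.mean() - truth) / abs(truth),
            "mean_abs_percent_error":
                100.0 * np.mean(np.abs(est - truth)) / abs(truth),
            "mean_se": g["se"].mean(),
            "coverage_percent": 100.0 * covered,
            "n_reps": len(g),
            "mc_se_of_bias": monte_carlo_se_of_bias(est, truth),
        })

    out = (records.groupby(PerformanceTable.KEY, sort=True)
           .apply(agg, include_groups=False).reset_index())
    out["n_reps"] = out["n_reps"].astype(int)
    out["trim_percentile"] = out["trim_percentile"].astype(int)
    return PerformanceTable(out)


@dataclass(frozen=True)
class WeightDiagnostics:
    """Distribution summary of untrimmed unexposed weights for one
    (scenario, method) cell."""

    q1: float
    median: float
    q3: float
    max: float
    prop_ge_10: float
    prop_ge_20: float
    mean_top5_sum: float
    n_replicates: int

    def __post_init__(self):
        if not self.q1 <= self.median <= self.q3 <= self.max:
            raise ValueError("quartiles must be ordered")
        if not 0 <= self.prop_ge_20 <= self.prop_ge_10 <= 1:
            raise ValueError("proportions inconsistent")


def weight_diagnostics(weight_sets: Sequence[WeightSet]) -> WeightDiagnostics:
    """Summarize untrimmed unexposed weights across replicates.

    Quartiles, maximum, and the >=10 / >=20 proportions pool all
    unexposed weights across replicates; the top-5% weight mass (sum of
    unexposed weights above their replicate's 95th percentile) is
    computed per replicate and averaged.
    """
    if not weight_sets:
        raise ValueError("need at least one weight set")
    for ws in weight_sets:
        if ws.trim_percentile != UNTRIMMED:
            raise ValueError(
                "weight diagnostics are defined on untrimmed weights; got a "
                f"set trimmed at the {ws.trim_percentile}th percentile")
    pooled = np.concatenate([ws.unexposed_weights for ws in weight_sets])
    top5 = []
    for ws in weight_sets:
        u = ws.unexposed_weights
        q95 = np.quantile(u, 0.95)
        top5.append(u[u > q95].sum())
    q1, med, q3 = np.quantile(pooled, [0.25, 0.5, 0.75])
    return WeightDiagnostics(
        q1=float(q1), median=float(med), q3=float(q3),
        max=float(pooled.max()),
        prop_ge_10=float(np.mean(pooled >= 10)),
        prop_ge_20=float(np.mean(pooled >= 20)),
        mean_top5_sum=float(np.mean(top5)),
        n_replicates=len(weight_sets),
    )


def spearman_weight_correlations(
    weight_sets_by_method: Mapping[str, Sequence[WeightSet]],
    aggregation: str = "per_replicate",
) -> pd.DataFrame:
    """Method x method Spearman correlations of unexposed weights.

    Correlations are computed within each replicate on the unexposed
    subjects and averaged across replicates (default), or computed once
    on the pooled ranks (``aggregation='pooled'``).
    """
    methods = list(weight_sets_by_method)
    n_reps = {m: len(ws) for m, ws in weight_sets_by_method.items()}
    if len(set(n_reps.values())) != 1:
        raise ValueError(f"replicate counts differ across methods: {n_reps}")
    reps = next(iter(n_reps.values()))
    for k in range(reps):
        exps = [np.asarray(weight_sets_by_method[m][k].exposure)
                for m in methods]
        if any(not np.array_equal(exps[0], e) for e in exps[1:]):
            raise ValueError(
                f"replicate {k}: methods disagree on the exposure vector — "
                "weight sets must come from the same underlying datasets")
    out = pd.DataFrame(np.eye(len(methods)), index=methods, columns=methods)
    for i, mi in enumerate(methods):
        for j in range(i + 1, len(methods)):
            mj = methods[j]
            if aggregation == "per_replicate":
                rs = [
                    stats.spearmanr(
                        weight_sets_by_method[mi][k].unexposed_weights,
                        weight_sets_by_method[mj][k].unexposed_weights,
                    ).statistic
                    for k in range(reps)
                ]
                r = float(np.mean(rs))
            elif aggregation == "pooled":
                a = np.concatenate([
                    weight_sets_by_method[mi][k].unexposed_weights
                    for k in range(reps)])
                b = np.concatenate([
                    weight_sets_by_method[mj][k].unexposed_weights
                    for k in range(reps)])
                r = float(stats.spearmanr(a, b).statistic)
            else:
                raise ValueError(
                    "aggregation must be 'per_replicate' or 'pooled'")
            out.loc[mi, mj] = out.loc[mj, mi] = r
    return out


def optimal_trim_level(table: PerformanceTable, scenario_id: int,
                       method: str, criterion: str = "bias") -> int:
    """Trim percentile minimizing bias, or |coverage - 95|; ties go to the
    least-trimmed (largest) percentile."""
    t = table.table
    rows = t[(t.scenario_id == scenario_id) & (t.method == method)]
    if rows.empty:
        raise KeyError((scenario_id, method))
    if criterion == "bias":
        score = rows["abs_percent_bias"].to_numpy()
    elif criterion == "coverage":
        score = np.abs(rows["coverage_percent"].to_numpy() - 95.0)
    else:
        raise ValueError("criterion must be 'bias' or 'coverage'")
    q = rows["trim_percentile"].to_numpy()
    best = score.min()
    return int(q[np.isclose(score, best)].max())
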