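"""Experiment orchestration: scenario x method x trim level x replicate.

Runs the full factorial Monte-Carlo design — simulate a dataset, fit
each propensity method once, derive untrimmed odds weights, apply the
whole trim grid, estimate the effect at every trim level — and collects
a long-format record stream plus the untrimmed weight sets needed for
the weight diagnostics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from . import __version__
from .dgp import ScenarioSpec, default_scenario, simulate_dataset
from .inference import estimate_effect
from .metrics import (PerformanceTable, performance_table,
                      spearman_weight_correlations, weight_diagnostics)
from .propensity import (METHODS, BoostParams, CartParams, ForestParams,
                         fit_propensity)
from .weighting import DEFAULT_TRIM_GRID, WeightSet, odds_weights, trim_weights

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ["scenario_id", "method", "trim_percentile", "seed",
                  "estimate", "se", "ci_low", "ci_high", "covered"]

_PARAM_TYPES = {"cart": CartParams, "random_forest": ForestParams,
                "boosted_cart": BoostParams}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full experiment."""

    scenarios: tuple = (1, 2, 3)
    methods: tuple[str, ...] = METHODS
    trim_grid: tuple[int, ...] = DEFAULT_TRIM_GRID
    n: int = 500
    n_reps: int = 1000
    base_seed: int = 0
    ci_level: float = 0.95
    variance: str = "model"
    trim_reference: str = "unexposed"
    method_params: Mapping[str, Mapping] = field(default_factory=dict)
    out_dir: Optional[str] = None
    n_jobs: int = 1
    store_weights: bool = True

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not all(50 <= int(q) <= 100 for q in self.trim_grid):
            raise ValueError("trim grid must lie within [50, 100]")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")

    def resolved_scenarios(self) -> list[ScenarioSpec]:
        specs = []
        for s in self.scenarios:
            if isinstance(s, ScenarioSpec):
                specs.append(s)
            elif isinstance(s, (int, np.integer)):
                specs.append(default_scenario(int(s)))
            else:
                path = Path(s)
                if not path.exists():
                    raise FileNotFoundError(
                        f"scenario file not found: {path}")
                specs.append(ScenarioSpec.from_yaml(path))
        return specs

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenarios"] = [
            s if isinstance(s, (int, np.integer, str)) else s.scenario_id
            for s in self.scenarios
        ]
        d["method_params"] = {k: dict(v)
                              for k, v in self.method_params.items()}
        return d

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        for key in ("scenarios", "methods", "trim_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def method_seed(base_seed: int, scenario_id: int, rep: int,
                method: str) -> int:
    """Deterministic per-(replicate, method) seed below 2**31."""
    ss = np.random.SeedSequence(
        [int(base_seed), int(scenario_id), int(rep), METHODS.index(method)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _method_params(config: RunConfig, method: str, seed: int):
    cls = _PARAM_TYPES.get(method)
    if cls is None:  # logistic: deterministic, no settings
        return None
    overrides = dict(config.method_params.get(method, {}))
    overrides.setdefault("seed", seed)
    return cls(**overrides)


def _run_replicate(config: RunConfig, spec: ScenarioSpec, rep: int):
    ds = simulate_dataset(spec, config.n, config.base_seed + rep)
    records = []
    weight_sets = {}
    for m in config.methods:
        seed = method_seed(config.base_seed, spec.scenario_id, rep, m)
        fit = fit_propensity(ds, m, _method_params(config, m, seed))
        ws0 = odds_weights(fit, ds.exposure)
        if config.store_weights:
            weight_sets[m] = ws0
        for q in config.trim_grid:
            ws = trim_weights(ws0, int(q), reference=config.trim_reference)
            est = estimate_effect(ds, ws, ci_level=config.ci_level,
                                  variance=config.variance)
            records.append((
                spec.scenario_id, m, int(q), ds.seed, est.estimate,
                est.standard_error, est.ci_low, est.ci_high,
                est.covers(spec.treatment_effect),
            ))
    return records, weight_sets


@dataclass
class ExperimentResult:
    """In-memory result bundle of one experiment run."""

    config: RunConfig
    records: pd.DataFrame
    weight_sets: dict  # (scenario_id, method) -> list[WeightSet]
    truth: float
    manifest: dict

    def performance(self) -> PerformanceTable:
        return performance_table(self.records, self.truth)

    def weight_table(self) -> pd.DataFrame:
        """Untrimmed unexposed-weight distribution summary per
        (scenario, method) cell."""
        rows = []
        for (sid, m), sets in sorted(self.weight_sets.items()):
            d = weight_diagnostics(sets)
            rows.append({
                "scenario_id": sid, "method": m, "q1": d.q1,
                "median": d.median, "q3": d.q3, "max": d.max,
                "prop_ge_10": d.prop_ge_10, "prop_ge_20": d.prop_ge_20,
                "mean_top5_sum": d.mean_top5_sum,
            })
        return pd.DataFrame(rows)

    def correlation_table(self) -> pd.DataFrame:
        """Between-method Spearman weight correlations per scenario."""
        frames = []
        sids = sorted({sid for sid, _ in self.weight_sets})
        for sid in sids:
            by_method = {m: sets for (s, m), sets in self.weight_sets.items()
                         if s == sid}
            corr = spearman_weight_correlations(by_method)
            corr.insert(0, "scenario_id", sid)
            frames.append(corr.rename_axis("method").reset_index())
        return pd.concat(frames, ignore_index=True)


def run_experiment(config: RunConfig) -> ExperimentResult:
    """Execute the factorial experiment described by ``config``.

    Deterministic given the config: dataset k of a scenario uses seed
    base_seed + k, and every stochastic fitting method gets a seed
    derived from (base_seed, scenario, replicate, method).
    """
    t0 = time.time()
    specs = config.resolved_scenarios()
    truths = {s.treatment_effect for s in specs}
    if len(truths) != 1:
        raise ValueError("scenarios disagree on the true treatment effect")
    truth = truths.pop()

    all_records = []
    weight_sets: dict = {}
    timings = {}
    for spec in specs:
        ts = time.time()
        jobs = (delayed(_run_replicate)(config, spec, rep)
                for rep in range(config.n_reps))
        results = Parallel(n_jobs=config.n_jobs)(jobs)
        for rep, (records, ws) in enumerate(results):
            all_records.extend(records)
            for m, w in ws.items():
                weight_sets.setdefault((spec.scenario_id, m), []).append(w)
        timings[f"scenario_{spec.scenario_id}"] = time.time() - ts

    records = pd.DataFrame(all_records, columns=RECORD_COLUMNS)
    cfg_dict = config.to_dict()
    manifest = {
        "package_version": __version__,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()).hexdigest(),
        "n_records": len(records),
        "timings_sec": {k: round(v, 3) for k, v in timings.items()},
        "total_sec": round(time.time() - t0, 3),
    }
    result = ExperimentResult(config=config, records=records,
                              weight_sets=weight_sets, truth=truth,
                              manifest=manifest)
    if config.out_dir:
        save_results(result, config.out_dir)
    return result


def save_results(result: ExperimentResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.records.to_csv(out / "records.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)


def replicate_paper_config(reduced: bool = False, base_seed: int = 0,
                           out_dir: Optional[str] = None,
                           n_jobs: int = 1,
                           n_reps: Optional[int] = None) -> RunConfig:
    """The packaged full-study configuration: 3 scenarios x 4 methods x
    51 trim levels; 1000 replicates (250 with ``reduced``)."""
    if n_reps is None:
        n_reps = 250 if reduced else 1000
    return RunConfig(
        scenarios=(1, 2, 3), methods=METHODS, trim_grid=DEFAULT_TRIM_GRID,
        n=500, n_reps=n_reps, base_seed=base_seed, out_dir=out_dir,
        n_jobs=n_jobs,
    )


def summarize(result_or_records, out_dir: str | Path,
              truth: float = -0.4) -> PerformanceTable:
    """Aggregate a run into summary tables and figures on disk.

    Accepts an :class:`ExperimentResult` or a path to a ``records.csv``
    stream. Emits the performance table, weight-distribution and
    correlation replicas (when weights are available), and the bias /
    SE / coverage versus trim-percentile figures.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(result_or_records, ExperimentResult):
        result = result_or_records
        records = result.records
        truth = result.truth
    else:
        path = Path(result_or_records)
        if not path.exists():
            raise FileNotFoundError(f"record stream not found: {path}")
        records = pd.read_csv(path)
        if records.empty:
            raise ValueError(f"no records in {path}")
        result = None

    table = performance_table(records, truth)
    table.to_csv(out / "performance.csv")
    if result is not None and result.weight_sets:
        result.weight_table().to_csv(out / "weight_distribution.csv",
                                     index=False)
        result.correlation_table().to_csv(out / "weight_correlations.csv",
                                          index=False)
    for metric, fname in (("abs_percent_bias", "bias.png"),
                          ("mean_se", "standard_error.png"),
                          ("coverage_percent", "coverage.png")):
        fig = plot_performance(table, metric)
        fig.savefig(out / fname, dpi=150)
        import matplotlib.pyplot as plt
        plt.close(fig)
    return table


_METRIC_LABELS = {
    "abs_percent_bias": "absolute percent bias",
    "mean_se": "mean standard error",
    "coverage_percent": "95% CI coverage (%)",
}


def plot_performance(table: PerformanceTable, metric: str):
    """One panel per scenario, one line per method, metric vs trim
    percentile (x axis reversed: no trimming on the left)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if metric not in _METRIC_LABELS:
        raise ValueError(f"metric must be one of {sorted(_METRIC_LABELS)}")
    t = table.table
    sids = sorted(t.scenario_id.unique())
    fig, axes = plt.subplots(1, len(sids), figsize=(4.2 * len(sids), 3.6),
                             sharey=True, squeeze=False)
    for ax, sid in zip(axes[0], sids):
        for m in sorted(t.method.unique()):
            rows = t[(t.scenario_id == sid) & (t.method == m)].sort_values(
                "trim_percentile")
            ax.plot(rows.trim_percentile, rows[metric], label=m, marker=".",
                    markersize=3, linewidth=1)
        ax.set_title(f"scenario {sid}")
        ax.set_xlabel("trim percentile")
        ax.invert_xaxis()
        if metric == "coverage_percent":
            ax.axhline(95, color="grey", linestyle=":", linewidth=1)
    axes[0][0].set_ylabel(_METRIC_LABELS[metric])
    axes[0][-1].legend(fontsize=8)
    fig.tight_layout()
    return fig
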