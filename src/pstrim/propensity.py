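"""Propensity score estimators.

Four estimators of P(exposure=1 | covariates) are provided: main-effects
logistic regression (the field's default, deliberately misspecified when
the true model has interactions or curvature), a single classification
tree, a random forest, and gradient-boosted trees stopped at the
iteration that minimizes mean weighted Kolmogorov-Smirnov covariate
imbalance between the exposed group and the odds-weighted unexposed
group.

Raw probabilities from tree-based methods can hit exactly 0 or 1, which
odds weights p/(1-p) cannot tolerate; those fits are clipped to
[eps, 1-eps] (default eps=1e-3, capping any single weight at 999).
Logistic maximum-likelihood probabilities are interior and are not
clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import statsmodels.api as sm
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .dgp import SimulatedDataset

logger = logging.getLogger(__name__)

DEFAULT_CLIP_EPSILON = 1e-3
METHODS = ("logistic", "cart", "random_forest", "boosted_cart")


@dataclass(frozen=True)
class BalancePath:
    """Mean weighted-KS covariate imbalance along a boosting run."""

    iterations: np.ndarray
    mean_ks: np.ndarray
    chosen_iteration: int

    def __post_init__(self):
        if len(self.iterations) != len(self.mean_ks):
            raise ValueError("iterations and mean_ks lengths differ")
        if np.any(np.diff(self.iterations) <= 0):
            raise ValueError("iterations must be strictly increasing")
        best = self.iterations[np.argmin(self.mean_ks)]  # argmin -> first tie
        if self.chosen_iteration != best:
            raise ValueError(
                "chosen_iteration must be the first minimizer of mean_ks"
            )


@dataclass(frozen=True)
class PropensityFit:
    """A fitted propensity vector plus method metadata."""

    method: str
    propensity: np.ndarray
    raw_propensity: np.ndarray
    clip_epsilon: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.propensity) != len(self.raw_propensity):
            raise ValueError("propensity vectors have different lengths")
        if not ((self.propensity > 0) & (self.propensity < 1)).all():
            raise ValueError("clipped propensity must be strictly in (0,1)")


def clip_propensity(raw: np.ndarray, epsilon: float) -> np.ndarray:
    """Clamp raw probabilities into [epsilon, 1-epsilon]."""
    if not 0 < epsilon < 0.5:
        raise ValueError("epsilon must be in (0, 0.5)")
    raw = np.asarray(raw, dtype=float)
    clipped = np.clip(raw, epsilon, 1.0 - epsilon)
    n_clipped = int(np.sum(clipped != raw))
    if n_clipped:
        logger.debug("clipped %d propensity values to [%g, %g]",
                     n_clipped, epsilon, 1 - epsilon)
    return clipped


def _check_groups(dataset: SimulatedDataset) -> None:
    if dataset.exposure.sum() in (0, dataset.n):
        raise ValueError("both exposure groups must be non-empty")


def fit_logistic_main_effects(dataset: SimulatedDataset) -> PropensityFit:
    """Maximum-likelihood logistic regression on the 10 main effects only.

    Non-convergence or (near-)perfect separation does not raise; the fit
    is returned with ``metadata['converged'] = False`` so callers can
    decide how to treat the replicate.
    """
    _check_groups(dataset)
    x = sm.add_constant(dataset.covariates)
    converged = True
    try:
        res = sm.Logit(dataset.exposure, x).fit(disp=0, maxiter=100)
        converged = bool(res.mle_retvals.get("converged", True))
        fitted = np.asarray(res.predict(x))
        params = np.asarray(res.params)
        bse = np.asarray(res.bse)
    except Exception as exc:  # perfect separation, singular Hessian, ...
        logger.warning("logistic propensity fit failed (%s); falling back to "
                       "regularized fit", exc)
        res = sm.Logit(dataset.exposure, x).fit_regularized(disp=0, alpha=1e-6)
        converged = False
        fitted = np.asarray(res.predict(x))
        params = np.asarray(res.params)
        bse = np.full_like(params, np.nan)
    eps = np.finfo(float).tiny
    fitted = np.clip(fitted, eps, 1 - 1e-15)
    return PropensityFit(
        method="logistic",
        propensity=fitted,
        raw_propensity=fitted,
        clip_epsilon=0.0,
        metadata={"converged": converged, "params": params, "bse": bse},
    )


@dataclass(frozen=True)
class CartParams:
    """Single-tree settings (emulating recursive-partitioning defaults:
    minimum split size 20, minimum leaf size 7, pruning off)."""

    min_samples_split: int = 20
    min_samples_leaf: int = 7
    ccp_alpha: float = 0.0
    max_depth: Optional[int] = None
    seed: int = 0
    clip_epsilon: float = DEFAULT_CLIP_EPSILON


def fit_cart(dataset: SimulatedDataset,
             params: CartParams = CartParams()) -> PropensityFit:
    """Single classification tree; propensity = treated fraction per leaf."""
    _check_groups(dataset)
    tree = DecisionTreeClassifier(
        criterion="gini",
        min_samples_split=params.min_samples_split,
        min_samples_leaf=params.min_samples_leaf,
        ccp_alpha=params.ccp_alpha,
        max_depth=params.max_depth,
        random_state=params.seed,
    )
    tree.fit(dataset.covariates, dataset.exposure)
    raw = tree.predict_proba(dataset.covariates)[:, 1]
    if tree.get_n_leaves() == 1:
        logger.warning("CART produced no split; propensity is the sample "
                       "prevalence %.3f", dataset.exposure.mean())
    return PropensityFit(
        method="cart",
        propensity=clip_propensity(raw, params.clip_epsilon),
        raw_propensity=raw,
        clip_epsilon=params.clip_epsilon,
        metadata={"n_leaves": int(tree.get_n_leaves()),
                  "depth": int(tree.get_depth())},
    )


@dataclass(frozen=True)
class ForestParams:
    """Random-forest settings: 500 fully grown trees, 3 (= floor sqrt 10)
    candidate predictors per split, bootstrap resampling."""

    n_trees: int = 500
    max_features: int = 3
    bootstrap: bool = True
    min_samples_leaf: int = 1
    min_samples_split: int = 2
    seed: int = 0
    clip_epsilon: float = DEFAULT_CLIP_EPSILON


def fit_random_forest(dataset: SimulatedDataset,
                      params: ForestParams = ForestParams()) -> PropensityFit:
    """Bootstrap ensemble of trees with random predictor subsetting.

    With bootstrap resampling, in-sample probabilities come from the
    out-of-bag trees (fully grown trees memorize their in-bag samples, so
    OOB prediction is the meaningful training-set probability); without
    bootstrap the plain ensemble probability is used.
    """
    _check_groups(dataset)
    rf = RandomForestClassifier(
        n_estimators=params.n_trees,
        max_features=params.max_features,
        bootstrap=params.bootstrap,
        min_samples_leaf=params.min_samples_leaf,
        min_samples_split=params.min_samples_split,
        oob_score=params.bootstrap,
        random_state=params.seed,
        n_jobs=1,
    )
    import warnings

    with warnings.catch_warnings():
        # tiny forests can leave some rows with no OOB tree; handled below
        warnings.filterwarnings("ignore", message="Some inputs do not have OOB")
        rf.fit(dataset.covariates, dataset.exposure)
    if params.bootstrap:
        raw = rf.oob_decision_function_[:, 1].copy()
        missing = ~np.isfinite(raw)
        if missing.any():
            raw[missing] = rf.predict_proba(
                dataset.covariates[missing])[:, 1]
    else:
        raw = rf.predict_proba(dataset.covariates)[:, 1]
    return PropensityFit(
        method="random_forest",
        propensity=clip_propensity(raw, params.clip_epsilon),
        raw_propensity=raw,
        clip_epsilon=params.clip_epsilon,
        metadata={"n_trees": params.n_trees,
                  "max_features": params.max_features,
                  "bootstrap": params.bootstrap},
    )


def weighted_ks_statistic(x: np.ndarray, group: np.ndarray,
                          weights: np.ndarray) -> float:
    """Weighted two-sample Kolmogorov-Smirnov statistic.

    sup over observed values of |F1(x) - F0(x)| where F1, F0 are the
    weighted empirical CDFs of group 1 and group 0, each normalized by
    its group's total weight. With unit weights this is the classical
    two-sample KS statistic.
    """
    x = np.asarray(x, dtype=float)
    group = np.asarray(group)
    weights = np.asarray(weights, dtype=float)
    if not (len(x) == len(group) == len(weights)):
        raise ValueError("x, group and weights must have equal length")
    if np.any(weights < 0):
        raise ValueError("weights must be non-negative")
    w1 = weights[group == 1].sum()
    w0 = weights[group == 0].sum()
    if w1 <= 0 or w0 <= 0:
        bad = "treated" if w1 <= 0 else "control"
        raise ValueError(f"{bad} group has zero total weight")
    order = np.argsort(x, kind="mergesort")
    xs = x[order]
    gs = group[order]
    ws = weights[order]
    cdf1 = np.cumsum(np.where(gs == 1, ws, 0.0)) / w1
    cdf0 = np.cumsum(np.where(gs == 0, ws, 0.0)) / w0
    # evaluate only after the last entry of each tied block of x values
    last = np.ones(len(xs), dtype=bool)
    last[:-1] = xs[1:] != xs[:-1]
    return float(np.max(np.abs(cdf1[last] - cdf0[last])))


def mean_ks_balance(covariates: np.ndarray, exposure: np.ndarray,
                    propensity: np.ndarray) -> float:
    """Mean weighted-KS imbalance over all covariates under ATT odds
    weighting (exposed weight 1, unexposed weight p/(1-p))."""
    w = np.where(exposure == 1, 1.0, propensity / (1.0 - propensity))
    return float(np.mean([
        weighted_ks_statistic(covariates[:, k], exposure, w)
        for k in range(covariates.shape[1])
    ]))


@dataclass(frozen=True)
class BoostParams:
    """Gradient-boosting settings: shallow trees, strong shrinkage, and a
    balance-based stopping rule evaluated on a grid of iteration counts."""

    max_trees: int = 10_000
    learning_rate: float = 0.005
    max_depth: int = 3
    subsample: float = 0.5
    eval_every: int = 100
    grid: Optional[Sequence[int]] = None
    seed: int = 0
    clip_epsilon: float = DEFAULT_CLIP_EPSILON

    def iteration_grid(self) -> np.ndarray:
        if self.grid is not None:
            g = np.asarray(sorted(set(int(i) for i in self.grid)))
        else:
            g = np.arange(self.eval_every, self.max_trees + 1, self.eval_every)
        if g.size == 0:
            raise ValueError("boosting evaluation grid is empty")
        if g[0] < 1 or g[-1] > self.max_trees:
            raise ValueError(
                f"grid points must lie in [1, max_trees={self.max_trees}]"
            )
        return g


def fit_boosted_cart(dataset: SimulatedDataset,
                     params: BoostParams = BoostParams()) -> PropensityFit:
    """Gradient-boosted trees stopped at minimum mean-KS imbalance.

    Candidate propensities are extracted at each grid iteration from the
    staged predictions of a single boosting run; the returned fit is the
    stage whose ATT odds weights give the smallest mean weighted-KS
    statistic across all covariates (first minimizer on ties). The full
    balance path is stored in ``metadata['balance_path']``.
    """
    _check_groups(dataset)
    grid = params.iteration_grid()
    gbm = GradientBoostingClassifier(
        n_estimators=int(grid[-1]),
        learning_rate=params.learning_rate,
        max_depth=params.max_depth,
        subsample=params.subsample,
        random_state=params.seed,
    )
    gbm.fit(dataset.covariates, dataset.exposure)
    grid_set = set(int(i) for i in grid)
    mean_ks = np.empty(len(grid))
    probs = {}
    pos = 0
    for it, stage_prob in enumerate(
            gbm.staged_predict_proba(dataset.covariates), start=1):
        if it in grid_set:
            raw_p = stage_prob[:, 1]
            p = clip_propensity(raw_p, params.clip_epsilon)
            mean_ks[pos] = mean_ks_balance(
                dataset.covariates, dataset.exposure, p)
            probs[it] = raw_p
            pos += 1
    chosen = int(grid[np.argmin(mean_ks)])
    path = BalancePath(iterations=grid, mean_ks=mean_ks,
                       chosen_iteration=chosen)
    raw = probs[chosen]
    return PropensityFit(
        method="boosted_cart",
        propensity=clip_propensity(raw, params.clip_epsilon),
        raw_propensity=raw,
        clip_epsilon=params.clip_epsilon,
        metadata={"balance_path": path, "chosen_iteration": chosen},
    )


def fit_propensity(dataset: SimulatedDataset, method: str,
                   params=None) -> PropensityFit:
    """Dispatch to one of the four estimators by name."""
    if method == "logistic":
        return fit_logistic_main_effects(dataset)
    if method == "cart":
        return fit_cart(dataset, params or CartParams())
    if method == "random_forest":
        return fit_random_forest(dataset, params or ForestParams())
    if method == "boosted_cart":
        return fit_boosted_cart(dataset, params or BoostParams())
    raise ValueError(f"unknown propensity method {method!r}; "
                     f"choose from {METHODS}")
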