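"""Synthetic confounded exposure-outcome data generator.

Emulates a pharmacoepidemiologic simulation design: N subjects with 10
covariates (4 confounders, 3 exposure-only, 3 outcome-only), a binary
exposure drawn from a logistic model of the covariates, and a continuous
outcome linear in exposure and covariates with a known treatment effect.
Three scenarios of increasing propensity-model complexity are shipped as
config files: scenario 1 is additive and linear (main effects only),
scenario 2 adds three two-way interactions and one quadratic term, and
scenario 3 adds ten interactions and three quadratic terms.

Covariates are drawn from a correlated multivariate normal; a configured
subset is dichotomized at a threshold on the latent scale (Gaussian
copula), so the requested correlations hold on the latent variables.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

logger = logging.getLogger(__name__)

ROLES = ("confounder", "exposure_only", "outcome_only")
#: required number of covariates per role: 4 confounders, 3 exposure-only,
#: 3 outcome-only
ROLE_COUNTS = {"confounder": 4, "exposure_only": 3, "outcome_only": 3}
#: (n interaction terms, n quadratic terms) in the true propensity model
SCENARIO_TERM_COUNTS = {1: (0, 0), 2: (4, 1), 3: (10, 3)}

OUTCOME_BASES = ("latent", "observed")

_MAX_EXPOSURE_RETRIES = 10
_RETRY_SEED_STRIDE = 1_000_003  # prime stride keeps derived seeds distinct


class ScenarioConfigError(ValueError):
    """Raised when a scenario specification is internally inconsistent."""


@dataclass(frozen=True)
class ScenarioSpec:
    """Full generative specification for one simulation scenario.

    Covariate indices are 0-based throughout.  ``exposure_main_coefs`` and
    ``outcome_coefs`` are length-10; outcome coefficients must be zero for
    exposure-only covariates and exposure coefficients zero for
    outcome-only covariates (that is what the roles mean).
    """

    scenario_id: int
    covariate_roles: Mapping[int, str]
    exposure_intercept: float
    exposure_main_coefs: tuple[float, ...]
    outcome_intercept: float
    outcome_coefs: tuple[float, ...]
    n_covariates: int = 10
    correlation_pairs: tuple[tuple[int, int, float], ...] = ()
    dichotomize: tuple[int, ...] = ()
    dichotomize_cut: float = 0.0
    exposure_interaction_terms: tuple[tuple[int, int, float], ...] = ()
    exposure_quadratic_terms: tuple[tuple[int, float], ...] = ()
    treatment_effect: float = -0.4
    outcome_noise_sd: float = 0.0
    outcome_basis: str = "latent"

    def __post_init__(self):
        k = self.n_covariates
        if len(self.exposure_main_coefs) != k or len(self.outcome_coefs) != k:
            raise ScenarioConfigError(
                f"coefficient vectors must have length {k}"
            )
        counts = {r: 0 for r in ROLES}
        for idx, role in self.covariate_roles.items():
            if role not in ROLES:
                raise ScenarioConfigError(f"unknown covariate role {role!r}")
            if not 0 <= idx < k:
                raise ScenarioConfigError(f"covariate index {idx} out of range")
            counts[role] += 1
        if counts != ROLE_COUNTS:
            raise ScenarioConfigError(
                f"covariate roles must be {ROLE_COUNTS}, got {counts}"
            )
        expected = SCENARIO_TERM_COUNTS.get(self.scenario_id)
        if expected is None:
            raise ScenarioConfigError(
                f"scenario_id must be one of {sorted(SCENARIO_TERM_COUNTS)}"
            )
        n_int, n_quad = expected
        if len(self.exposure_interaction_terms) != n_int:
            raise ScenarioConfigError(
                f"scenario {self.scenario_id} requires {n_int} interaction "
                f"terms, got {len(self.exposure_interaction_terms)}"
            )
        if len(self.exposure_quadratic_terms) != n_quad:
            raise ScenarioConfigError(
                f"scenario {self.scenario_id} requires {n_quad} quadratic "
                f"terms, got {len(self.exposure_quadratic_terms)}"
            )
        for i, j, _ in self.exposure_interaction_terms:
            if not (0 <= i < k and 0 <= j < k):
                raise ScenarioConfigError(
                    f"interaction indices ({i},{j}) out of range"
                )
        for i, _ in self.exposure_quadratic_terms:
            if not 0 <= i < k:
                raise ScenarioConfigError(f"quadratic index {i} out of range")
        if self.outcome_noise_sd < 0:
            raise ScenarioConfigError("outcome_noise_sd must be >= 0")
        if self.outcome_basis not in OUTCOME_BASES:
            raise ScenarioConfigError(
                f"outcome_basis must be one of {OUTCOME_BASES}")
        # building the matrix validates positive definiteness eagerly
        self.correlation_matrix()

    def correlation_matrix(self) -> np.ndarray:
        """Latent covariate correlation matrix implied by correlation_pairs."""
        corr = np.eye(self.n_covariates)
        for i, j, rho in self.correlation_pairs:
            if not (0 <= i < self.n_covariates and 0 <= j < self.n_covariates):
                raise ScenarioConfigError(
                    f"correlation pair ({i},{j}) out of range"
                )
            if not -1.0 < rho < 1.0:
                raise ScenarioConfigError(
                    f"correlation for pair ({i},{j}) must be in (-1,1)"
                )
            corr[i, j] = corr[j, i] = rho
        try:
            np.linalg.cholesky(corr)
        except np.linalg.LinAlgError:
            pairs = [(i, j) for i, j, _ in self.correlation_pairs]
            raise ScenarioConfigError(
                "correlation_pairs imply a non-positive-definite matrix; "
                f"offending pairs among {pairs}"
            ) from None
        return corr

    @classmethod
    def from_dict(cls, raw: Mapping) -> "ScenarioSpec":
        """Build a spec from a parsed config mapping (1-based indices)."""
        roles = {}
        for role, idxs in raw["covariate_roles"].items():
            for i in idxs:
                roles[int(i) - 1] = role
        return cls(
            scenario_id=int(raw["scenario_id"]),
            n_covariates=int(raw.get("n_covariates", 10)),
            covariate_roles=roles,
            correlation_pairs=tuple(
                (int(i) - 1, int(j) - 1, float(r))
                for i, j, r in raw.get("correlation_pairs", [])
            ),
            dichotomize=tuple(int(i) - 1 for i in raw.get("dichotomize", [])),
            dichotomize_cut=float(raw.get("dichotomize_cut", 0.0)),
            exposure_intercept=float(raw["exposure_intercept"]),
            exposure_main_coefs=tuple(float(c) for c in raw["exposure_main_coefs"]),
            exposure_interaction_terms=tuple(
                (int(i) - 1, int(j) - 1, float(c))
                for i, j, c in raw.get("exposure_interaction_terms", [])
            ),
            exposure_quadratic_terms=tuple(
                (int(i) - 1, float(c))
                for i, c in raw.get("exposure_quadratic_terms", [])
            ),
            outcome_intercept=float(raw["outcome_intercept"]),
            outcome_coefs=tuple(float(c) for c in raw["outcome_coefs"]),
            treatment_effect=float(raw.get("treatment_effect", -0.4)),
            outcome_noise_sd=float(raw.get("outcome_noise_sd", 0.0)),
            outcome_basis=str(raw.get("outcome_basis", "latent")),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **changes) -> "ScenarioSpec":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class SimulatedDataset:
    """One simulated replicate."""

    covariates: np.ndarray
    exposure: np.ndarray
    outcome: np.ndarray
    true_propensity: np.ndarray
    seed: int
    scenario_id: int

    def __post_init__(self):
        n = self.covariates.shape[0]
        if not (len(self.exposure) == len(self.outcome)
                == len(self.true_propensity) == n):
            raise ValueError("field lengths disagree")
        if not np.isin(self.exposure, (0, 1)).all():
            raise ValueError("exposure must be binary 0/1")
        if not ((self.true_propensity > 0) & (self.true_propensity < 1)).all():
            raise ValueError("true_propensity must lie strictly in (0,1)")

    @property
    def n(self) -> int:
        return self.covariates.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        k = self.covariates.shape[1]
        df = pd.DataFrame(self.covariates,
                          columns=[f"w{i + 1}" for i in range(k)])
        df.insert(0, "id", np.arange(1, self.n + 1))
        df["exposure"] = self.exposure
        df["outcome"] = self.outcome
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def scenario_path(scenario_id: int) -> Path:
    """Filesystem path of a packaged scenario config."""
    res = resources.files("pstrim").joinpath(
        f"scenarios/scenario{scenario_id}.yaml"
    )
    return Path(str(res))


def default_scenario(scenario_id: int) -> ScenarioSpec:
    """Load one of the three packaged scenario specifications."""
    if scenario_id not in SCENARIO_TERM_COUNTS:
        raise ScenarioConfigError(
            f"no packaged scenario {scenario_id}; choose from 1, 2, 3"
        )
    return ScenarioSpec.from_yaml(scenario_path(scenario_id))


def _draw_latent(spec: ScenarioSpec, n: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Correlated multivariate standard-normal draws (pre-thresholding)."""
    if n < 2:
        raise ValueError("n must be at least 2")
    chol = np.linalg.cholesky(spec.correlation_matrix())
    return rng.standard_normal((n, spec.n_covariates)) @ chol.T


def _observe(spec: ScenarioSpec, latent: np.ndarray) -> np.ndarray:
    """Apply dichotomization to produce the analysis covariate matrix."""
    w = latent.copy()
    if spec.dichotomize:
        cols = list(spec.dichotomize)
        w[:, cols] = (w[:, cols] > spec.dichotomize_cut).astype(float)
    return w


def generate_covariates(
    spec: ScenarioSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw the n x 10 covariate matrix for one dataset.

    Latent draws are multivariate standard normal with the configured
    correlations; columns listed in ``spec.dichotomize`` are then
    thresholded at ``spec.dichotomize_cut`` to {0,1}.
    """
    return _observe(spec, _draw_latent(spec, n, rng))


def true_propensity(spec: ScenarioSpec, covariates: np.ndarray) -> np.ndarray:
    """True P(exposure=1 | covariates) under the scenario's logistic model."""
    w = np.asarray(covariates, dtype=float)
    if w.ndim != 2 or w.shape[1] != spec.n_covariates:
        raise ValueError(f"covariates must have {spec.n_covariates} columns")
    lin = spec.exposure_intercept + w @ np.asarray(spec.exposure_main_coefs)
    for i, j, c in spec.exposure_interaction_terms:
        lin = lin + c * w[:, i] * w[:, j]
    for i, c in spec.exposure_quadratic_terms:
        lin = lin + c * w[:, i] ** 2
    # keep probabilities strictly interior even for extreme linear scores
    return np.clip(expit(lin), 1e-12, 1.0 - 1e-12)


def simulate_dataset(spec: ScenarioSpec, n: int, seed: int) -> SimulatedDataset:
    """Simulate one replicate; deterministic given (spec, n, seed).

    The exposure is Bernoulli in the true propensity computed from the
    observed (post-dichotomization) covariates. The outcome is linear in
    exposure and covariates; with ``outcome_basis='latent'`` the outcome
    covariates are the continuous pre-dichotomization values, so the
    analyst's binary indicators are coarsened proxies of what actually
    drives the outcome.

    If an exposure draw is degenerate (all exposed or all unexposed) the
    whole dataset is redrawn from a derived seed, up to 10 times.
    """
    for attempt in range(_MAX_EXPOSURE_RETRIES + 1):
        draw_seed = seed + attempt * _RETRY_SEED_STRIDE
        rng = np.random.default_rng(draw_seed)
        z = _draw_latent(spec, n, rng)
        w = _observe(spec, z)
        p = true_propensity(spec, w)
        a = (rng.random(n) < p).astype(np.int64)
        if 0 < a.sum() < n:
            break
        logger.warning(
            "degenerate exposure draw (seed=%d, attempt=%d); retrying with "
            "seed %d", draw_seed, attempt, seed + (attempt + 1) * _RETRY_SEED_STRIDE,
        )
    else:
        raise RuntimeError(
            f"exposure degenerate after {_MAX_EXPOSURE_RETRIES} retries "
            f"(base seed {seed})"
        )
    basis = z if spec.outcome_basis == "latent" else w
    y = (
        spec.outcome_intercept
        + spec.treatment_effect * a
        + basis @ np.asarray(spec.outcome_coefs)
    )
    if spec.outcome_noise_sd > 0:
        y = y + rng.normal(0.0, spec.outcome_noise_sd, n)
    return SimulatedDataset(
        covariates=w, exposure=a, outcome=y, true_propensity=p,
        seed=seed, scenario_id=spec.scenario_id,
    )


def simulate_study(
    spec: ScenarioSpec, n: int, n_reps: int, base_seed: int
) -> list[SimulatedDataset]:
    """Simulate ``n_reps`` independent replicates; replicate k uses seed
    ``base_seed + k``."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    return [simulate_dataset(spec, n, base_seed + k) for k in range(n_reps)]
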