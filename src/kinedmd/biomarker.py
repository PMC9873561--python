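"""The KineDMD ethomic biomarker: a constrained monotone tanh progression
curve over age, selected by Bayesian optimization.

The biomarker family is

    Y(age) = (tanh(X) - tanh(Xmin)) / (tanh(Xmax) - tanh(Xmin)),
    X = alpha * age - beta,  Xmin = X(0),  Xmax = X(25),

with 0 < alpha <= 0.5 (per-year slope) and 0 <= beta <= 5 (offset). The
normalization pins Y(0) = 0 and Y(25) = 1 exactly, and Y is non-decreasing
in age for any valid parameters. A parameter pair is *clinically feasible*
when Y(5) lies in [0.01, 0.15] (few overt symptoms at age 5) and Y(15) in
[0.5, 0.8] (loss of ambulation through early upper-body decline by age 15).

The optimizer searches the (alpha, beta) box with expected-improvement
Bayesian optimization under a Gaussian-process surrogate; the objective is
the leave-one-subject-out error of GP regression of the candidate biomarker
values on the ethomic fingerprints — the best biomarker is the one the
behavioral data can predict most consistently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .gp import GPModel, pd_unique
from .prediction import (
    SELECTION_LS_FACTOR,
    SELECTION_NOISE,
    CohortDataset,
    select_features_floating,
)

ALPHA_MIN = 1e-6  # a zero slope degenerates the normalization
ALPHA_MAX = 0.5
BETA_MIN = 0.0
BETA_MAX = 5.0
AGE_MAX = 25.0
AGE5_BOX = (0.01, 0.15)
AGE15_BOX = (0.5, 0.8)
INFEASIBLE_PENALTY = 10.0


@dataclass(frozen=True)
class BiomarkerParams:
    """(alpha, beta) of the tanh progression curve, validated against bounds."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not ALPHA_MIN <= self.alpha <= ALPHA_MAX:
            raise ValueError(
                f"alpha must be in [{ALPHA_MIN}, {ALPHA_MAX}], got {self.alpha}"
            )
        if not BETA_MIN <= self.beta <= BETA_MAX:
            raise ValueError(
                f"beta must be in [{BETA_MIN}, {BETA_MAX}], got {self.beta}"
            )


def evaluate_biomarker(
    age: float | np.ndarray, params: BiomarkerParams
) -> float | np.ndarray:
    """Y(age) for ages in [0, 25]; exactly 0 at age 0 and 1 at age 25."""
    age_arr = np.asarray(age, dtype=float)
    if np.any(age_arr < 0) or np.any(age_arr > AGE_MAX):
        raise ValueError(f"age must lie in [0, {AGE_MAX}]")
    x = params.alpha * age_arr - params.beta
    x_min = -params.beta
    x_max = params.alpha * AGE_MAX - params.beta
    y = (np.tanh(x) - np.tanh(x_min)) / (np.tanh(x_max) - np.tanh(x_min))
    return float(y) if np.isscalar(age) else y


def check_feasibility(params: BiomarkerParams) -> tuple[bool, float, float]:
    """Clinical feasibility: Y(5) and Y(15) inside their closed boxes."""
    y5 = evaluate_biomarker(5.0, params)
    y15 = evaluate_biomarker(15.0, params)
    feasible = AGE5_BOX[0] <= y5 <= AGE5_BOX[1] and AGE15_BOX[0] <= y15 <= AGE15_BOX[1]
    return feasible, y5, y15


def biomarker_objective(
    params: BiomarkerParams,
    dataset: CohortDataset,
    *,
    max_subset: int = 10,
    normalize: bool = True,
    floating: bool = False,
) -> float:
    """LOSO regression error of fitting Y(age; params) from fingerprints.

    The candidate biomarker evaluated at each visit's age is the regression
    target; forward wrapper selection (floating optionally) chooses the
    fingerprint subset by inner-LOSO error, and the pooled LOSO RMSE of the
    selected subset is returned. Infeasible parameters receive a fixed
    penalty without touching the data. By default the target is z-scored
    first so the error is scale-free: a raw RMSE would trivially favor
    flatter curves (smaller target spread) over curves actually encoded in
    the data.
    """
    feasible, _, _ = check_feasibility(params)
    if not feasible:
        return INFEASIBLE_PENALTY
    ages = dataset.frame["age_years"].to_numpy(float)
    y = np.asarray(evaluate_biomarker(np.clip(ages, 0, AGE_MAX), params))
    if normalize:
        sd = y.std()
        y = (y - y.mean()) / (sd if sd > 0 else 1.0)
    X = dataset.features()
    groups = dataset.groups()
    subset = select_features_floating(
        X,
        y,
        groups,
        dataset.feature_columns,
        max_subset=max_subset,
        forward_only=not floating,
    )
    cols = [dataset.feature_columns.index(f) for f in subset]
    from .gp import grouped_loso_rmse

    return grouped_loso_rmse(X[:, cols], y, groups, SELECTION_LS_FACTOR, SELECTION_NOISE)


@dataclass
class BiomarkerCurve:
    """Fitted biomarker: parameters, trajectory and per-visit scores."""

    params: BiomarkerParams
    ages: np.ndarray
    curve: np.ndarray
    y_age5: float
    y_age15: float
    feasible: bool
    objective: float
    fitted_scores: pd.DataFrame  # per-visit out-of-fold predicted Y
    trace: list[dict] = field(default_factory=list)

    @property
    def x_min(self) -> float:
        return -self.params.beta

    @property
    def x_max(self) -> float:
        return AGE_MAX * self.params.alpha - self.params.beta


def _expected_improvement(
    mu: np.ndarray, sigma: np.ndarray, best_f: float, xi: float = 0.01
) -> np.ndarray:
    """EI for minimization under a GP posterior."""
    sigma = np.clip(sigma, 1e-12, None)
    imp = best_f - mu - xi
    z = imp / sigma
    return imp * norm.cdf(z) + sigma * norm.pdf(z)


def _sample_params(rng: np.random.Generator, size: int) -> np.ndarray:
    alpha = rng.uniform(ALPHA_MIN, ALPHA_MAX, size)
    beta = rng.uniform(BETA_MIN, BETA_MAX, size)
    return np.column_stack([alpha, beta])


def _feasible_mask(points: np.ndarray) -> np.ndarray:
    return np.array(
        [check_feasibility(BiomarkerParams(a, b))[0] for a, b in points]
    )


def optimize_biomarker(
    dataset: CohortDataset,
    budget: int = 100,
    seed: int | None = None,
    *,
    n_initial: int = 10,
    xi: float = 0.01,
    n_candidates: int = 2048,
    normalize_objective: bool = True,
    max_subset: int = 10,
) -> BiomarkerCurve:
    """Constrained EI Bayesian optimization of the biomarker parameters.

    The initial design is ``n_initial`` feasible points sampled uniformly
    from the (alpha, beta) box (feasibility is analytic, so infeasible
    draws are rejected before any data touch; 200 fruitless draws abort).
    Each subsequent proposal maximizes expected improvement, over feasible
    candidates only, under a GP surrogate fitted to the evaluated points.
    Returns the best feasible parameters with the fitted trajectory and
    per-visit out-of-fold predicted scores.
    """
    subjects = pd_unique(dataset.groups())
    if len(subjects) < 8:
        raise ValueError(f"need at least 8 subjects, got {len(subjects)}")
    if budget < n_initial:
        raise ValueError("budget smaller than the initial design")
    rng = np.random.default_rng(seed)

    initial: list[np.ndarray] = []
    draws = 0
    while len(initial) < n_initial:
        if draws >= 200 * n_initial:
            raise RuntimeError(
                "no feasible initial design found within 200 resamples per point"
            )
        point = _sample_params(rng, 1)[0]
        draws += 1
        if check_feasibility(BiomarkerParams(*point))[0]:
            initial.append(point)

    def objective(point: np.ndarray) -> float:
        return biomarker_objective(
            BiomarkerParams(*point),
            dataset,
            max_subset=max_subset,
            normalize=normalize_objective,
        )

    points = list(initial)
    values = [objective(p) for p in points]
    trace = [
        {"alpha": float(p[0]), "beta": float(p[1]), "objective": v,
         "feasible": True, "stage": "initial"}
        for p, v in zip(points, values)
    ]

    scale = np.array([ALPHA_MAX - ALPHA_MIN, BETA_MAX - BETA_MIN])
    kernel = (
        ConstantKernel(1.0, (1e-3, 1e3))
        * RBF([0.2, 0.2], (0.02, 5.0))
        + WhiteKernel(1e-4, (1e-9, 1.0))
    )
    while len(points) < budget:
        surrogate = GaussianProcessRegressor(
            kernel=kernel,
            normalize_y=True,
            n_restarts_optimizer=1,
            random_state=int(rng.integers(2**31 - 1)),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=ConvergenceWarning)
            surrogate.fit(np.array(points) / scale, np.array(values))
        candidates = _sample_params(rng, n_candidates)
        feasible = _feasible_mask(candidates)
        if not feasible.any():
            candidates = np.array(points)  # degenerate; fall back to known
            feasible = np.ones(len(candidates), dtype=bool)
        candidates = candidates[feasible]
        mu, sigma = surrogate.predict(candidates / scale, return_std=True)
        ei = _expected_improvement(mu, sigma, min(values), xi=xi)
        proposal = candidates[int(np.argmax(ei))]
        value = objective(proposal)
        points.append(proposal)
        values.append(value)
        trace.append(
            {"alpha": float(proposal[0]), "beta": float(proposal[1]),
             "objective": value, "feasible": True, "stage": "bo"}
        )

    best_idx = int(np.argmin(values))
    best = BiomarkerParams(*points[best_idx])
    feasible, y5, y15 = check_feasibility(best)
    ages = np.arange(0.0, AGE_MAX + 1e-9, 0.1)
    curve = np.asarray(evaluate_biomarker(ages, best))

    fitted = _loso_fitted_scores(dataset, best, max_subset=max_subset)
    return BiomarkerCurve(
        params=best,
        ages=ages,
        curve=curve,
        y_age5=y5,
        y_age15=y15,
        feasible=feasible,
        objective=float(values[best_idx]),
        fitted_scores=fitted,
        trace=trace,
    )


def _loso_fitted_scores(
    dataset: CohortDataset, params: BiomarkerParams, max_subset: int = 10
) -> pd.DataFrame:
    """Out-of-fold GP predictions of Y(age; params) per visit (the
    individual fingerprint-derived biomarker trajectories)."""
    ages = dataset.frame["age_years"].to_numpy(float)
    y = np.asarray(evaluate_biomarker(np.clip(ages, 0, AGE_MAX), params))
    X = dataset.features()
    groups = dataset.groups()
    subset = select_features_floating(
        X, y, groups, dataset.feature_columns,
        max_subset=max_subset, forward_only=True,
    )
    cols = [dataset.feature_columns.index(f) for f in subset]
    predicted = np.empty_like(y)
    for g in pd_unique(groups):
        test = groups == g
        model = GPModel(SELECTION_LS_FACTOR, SELECTION_NOISE).fit(
            X[np.ix_(~test, cols)], y[~test]
        )
        predicted[test] = model.predict(X[np.ix_(test, cols)])
    out = dataset.frame[[dataset.subject_column]].copy()
    out["age_years"] = ages
    out["target_Y"] = y
    out["predicted_Y"] = predicted
    return out
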