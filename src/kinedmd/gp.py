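"""Exact Gaussian-process regression with an RBF + white-noise kernel.

The wrapper-selection and biomarker-objective loops refit a GP thousands of
times on small training folds, so the core regressor is a minimal direct
implementation (kernel matrix, Cholesky solve) with no per-fit overhead.
Hyperparameters are never optimized inside a fit; they are chosen by grid
search on leave-one-subject-out error, as the evaluation protocol demands.

k(x, x') = exp(-||x - x'||^2 / (2 l^2)) + sigma_n^2 [x = x']

on z-scored features and target (unit signal variance), so ``l`` is in
units of standardized feature distance and ``sigma_n`` is relative to the
target's standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist

#: multiplicative length-scale grid (times sqrt(n_features)) and relative
#: noise grid searched by :func:`fit_gp`
LENGTH_SCALE_FACTORS = (0.5, 1.4, 4.0, 11.0, 32.0)
NOISE_LEVELS = (0.03, 0.08, 0.2, 0.5, 1.0)

_JITTERS = (0.0, 1e-10, 1e-8, 1e-6, 1e-4, 1e-2)


class GPRegressor:
    """Zero-mean exact GP with fixed RBF length-scale and noise level."""

    def __init__(self, length_scale: float, noise: float):
        if length_scale <= 0 or noise < 0:
            raise ValueError("length_scale must be > 0 and noise >= 0")
        self.length_scale = float(length_scale)
        self.noise = float(noise)

    def _kernel(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        d2 = cdist(a, b, "sqeuclidean")
        return np.exp(-0.5 * d2 / self.length_scale**2)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GPRegressor":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        K = self._kernel(X, X)
        n = len(X)
        diag = self.noise**2
        last_err: Exception | None = None
        for jitter in _JITTERS:
            try:
                self._chol = cho_factor(
                    K + (diag + jitter) * np.eye(n), lower=True, check_finite=False
                )
                break
            except np.linalg.LinAlgError as exc:
                last_err = exc
        else:
            raise np.linalg.LinAlgError(
                f"kernel matrix not positive definite after jitter escalation: {last_err}"
            )
        self._X = X
        self._alpha = cho_solve(self._chol, y, check_finite=False)
        return self

    def predict(
        self, X: np.ndarray, return_std: bool = False
    ) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        k_star = self._kernel(X, self._X)
        mean = k_star @ self._alpha
        if not return_std:
            return mean
        v = cho_solve(self._chol, k_star.T, check_finite=False)
        var = 1.0 + self.noise**2 - np.sum(k_star * v.T, axis=1)
        return mean, np.sqrt(np.clip(var, 0.0, None))


@dataclass
class Standardizer:
    """Column z-scoring with statistics frozen from the training rows only."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        std = X.std(axis=0)
        return cls(mean=X.mean(axis=0), std=np.where(std == 0.0, 1.0, std))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(np.asarray(X, dtype=float)) - self.mean) / self.std


class GPModel:
    """Standardizing front-end over :class:`GPRegressor`.

    Fits on raw features/target; predictions (and predictive standard
    deviations) are returned in the target's original units.
    """

    def __init__(self, length_scale_factor: float, noise: float):
        self.length_scale_factor = float(length_scale_factor)
        self.noise = float(noise)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GPModel":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        self._xscaler = Standardizer.fit(X)
        self._ymean = y.mean()
        ystd = y.std()
        self._ystd = ystd if ystd > 0 else 1.0
        ls = self.length_scale_factor * np.sqrt(X.shape[1])
        self._gp = GPRegressor(length_scale=ls, noise=self.noise).fit(
            self._xscaler.transform(X), (y - self._ymean) / self._ystd
        )
        return self

    def predict(
        self, X: np.ndarray, return_std: bool = False
    ) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
        Z = self._xscaler.transform(X)
        if not return_std:
            return self._gp.predict(Z) * self._ystd + self._ymean
        mean, std = self._gp.predict(Z, return_std=True)
        return mean * self._ystd + self._ymean, std * self._ystd


def grouped_loso_rmse(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    length_scale_factor: float,
    noise: float,
) -> float:
    """Pooled RMSE of leave-one-group-out GP predictions."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    residuals = np.empty_like(y)
    for g in pd_unique(groups):
        test = groups == g
        train = ~test
        model = GPModel(length_scale_factor, noise).fit(X[train], y[train])
        residuals[test] = model.predict(X[test]) - y[test]
    return float(np.sqrt(np.mean(residuals**2)))


def pd_unique(values: np.ndarray) -> np.ndarray:
    """Unique values in order of first appearance (stable fold order)."""
    _, idx = np.unique(values, return_index=True)
    return values[np.sort(idx)]


def fit_gp(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    length_scale_factors: tuple[float, ...] = LENGTH_SCALE_FACTORS,
    noise_levels: tuple[float, ...] = NOISE_LEVELS,
) -> GPModel:
    """Fit a GP with hyperparameters grid-searched by inner-LOSO RMSE.

    Every (length-scale, noise) grid point is scored by pooled
    leave-one-subject-out RMSE on the training data; the best point is
    refitted on all rows. Needs at least 4 rows and 2 distinct groups.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if len(X) < 4:
        raise ValueError("need at least 4 training rows")
    if len(pd_unique(groups)) < 2:
        raise ValueError("need at least 2 subjects for inner LOSO tuning")
    best = (np.inf, length_scale_factors[0], noise_levels[0])
    for ls in length_scale_factors:
        for noise in noise_levels:
            score = grouped_loso_rmse(X, y, groups, ls, noise)
            if score < best[0]:
                best = (score, ls, noise)
    _, ls, noise = best
    return GPModel(ls, noise).fit(X, y)
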