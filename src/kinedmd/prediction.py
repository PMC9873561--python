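"""Clinical-score prediction from fingerprints.

Protocol: Gaussian-process regression inside nested leave-one-subject-out
(LOSO) cross-validation. The outer loop holds out all visits of one subject
per fold; the inner loop (over the remaining subjects) drives both wrapper
feature selection and hyperparameter choice, so held-out subjects never
influence selection — the anti-leakage property the nested design exists
for. The per-fold selected subsets are reduced to the most frequent subset,
which is refitted per outer fold to produce pooled out-of-fold predictions;
aggregate RMSE and R^2 are computed on the pooled predictions.

Cross-sectional prediction targets a clinical scale at the same visit
(ambulant visits only for 6MWD and NSAA); longitudinal prediction targets
the scale roughly six months ahead, compared against predicting the scale
from its own baseline value.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .gp import GPModel, fit_gp, grouped_loso_rmse, pd_unique

TARGET_COLUMNS = {
    "6mwd": "sixmwd_m",
    "nsaa": "nsaa",
    "pul": "pul",
    "myogrip": "myogrip_pct",
}
#: scales administered only to ambulant participants
AMBULANT_ONLY_TARGETS = frozenset({"6mwd", "nsaa"})

MAX_SUBSET_SIZE = 10
IMPROVEMENT_TOL = 1e-6
#: fixed GP hyperparameters used to score candidate subsets during selection
SELECTION_LS_FACTOR = 3.0
SELECTION_NOISE = 0.1
LEARNING_CURVE_CAP = 1000


@dataclass
class CohortDataset:
    """Visit rows (one per subject-visit) with features and clinical scores."""

    frame: pd.DataFrame
    feature_columns: list[str]
    subject_column: str = "subject_id"

    def __post_init__(self) -> None:
        missing = [
            c
            for c in [self.subject_column, *self.feature_columns]
            if c not in self.frame.columns
        ]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        X = self.frame[self.feature_columns].to_numpy(float)
        if not np.isfinite(X).all():
            raise ValueError("non-finite feature values")

    @property
    def subjects(self) -> np.ndarray:
        return pd_unique(self.frame[self.subject_column].to_numpy())

    def features(self) -> np.ndarray:
        return self.frame[self.feature_columns].to_numpy(float)

    def groups(self) -> np.ndarray:
        return self.frame[self.subject_column].to_numpy()


@dataclass
class FoldPlan:
    """Ordered LOSO folds; fold i holds all row positions of subject i."""

    subjects: list
    folds: list[np.ndarray]


@dataclass
class SelectionResult:
    per_fold_subsets: list[tuple[str, ...]]
    final_subset: tuple[str, ...]
    frequencies: dict[tuple[str, ...], int]


@dataclass
class PredictionReport:
    predictions: pd.DataFrame  # subject_id, actual, predicted
    rmse: float
    r2: float
    selection: SelectionResult
    target: str
    mode: str = "cross_sectional"
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "mode": self.mode,
            "rmse": self.rmse,
            "r2": self.r2,
            "n_rows": int(len(self.predictions)),
            "final_subset": list(self.selection.final_subset),
            "per_fold_subsets": [list(s) for s in self.selection.per_fold_subsets],
            **self.extra,
        }


def make_loso_folds(dataset: CohortDataset) -> FoldPlan:
    """One fold per subject containing all and only that subject's rows."""
    groups = dataset.groups()
    subjects = list(pd_unique(groups))
    if len(subjects) < 3:
        raise ValueError(f"LOSO needs at least 3 subjects, got {len(subjects)}")
    folds = [np.flatnonzero(groups == s) for s in subjects]
    return FoldPlan(subjects=subjects, folds=folds)


def select_features_floating(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    feature_names: Sequence[str],
    *,
    max_subset: int = MAX_SUBSET_SIZE,
    tol: float = IMPROVEMENT_TOL,
    forward_only: bool = False,
) -> tuple[str, ...]:
    """Floating (forward + conditional backward) wrapper feature selection.

    Candidate subsets are scored by pooled leave-one-subject-out GP RMSE on
    the training data. Forward steps add the best-improving feature;
    after each addition, backward steps drop any feature whose removal
    improves the score. Stops when no step improves by more than ``tol`` or
    the subset cap is reached. Deterministic: ties resolve to the earliest
    feature in column order. Always returns at least one feature.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if len(pd_unique(groups)) < 4:
        raise ValueError("selection needs at least 4 subjects in the training fold")
    n_features = X.shape[1]

    def score(cols: list[int]) -> float:
        return grouped_loso_rmse(
            X[:, cols], y, groups, SELECTION_LS_FACTOR, SELECTION_NOISE
        )

    selected: list[int] = []
    best = np.inf
    while len(selected) < max_subset:
        # forward step
        candidates = [j for j in range(n_features) if j not in selected]
        if not candidates:
            break
        scores = [score(selected + [j]) for j in candidates]
        k = int(np.argmin(scores))
        if scores[k] >= best - tol and selected:
            break
        selected.append(candidates[k])
        best = scores[k]
        # conditional backward steps
        if not forward_only:
            improved = True
            while improved and len(selected) > 2:
                improved = False
                removal_scores = [
                    score([c for c in selected if c != j]) for j in selected
                ]
                k = int(np.argmin(removal_scores))
                if removal_scores[k] < best - tol:
                    del selected[k]
                    best = removal_scores[k]
                    improved = True
    return tuple(feature_names[j] for j in sorted(selected))


def most_frequent_subset(subsets: Sequence[Sequence[str]]) -> tuple[str, ...]:
    """Modal subset; ties broken by smaller cardinality, then lexicographic."""
    if not subsets:
        raise ValueError("no subsets given")
    canonical = [tuple(sorted(s)) for s in subsets]
    counts: dict[tuple[str, ...], int] = {}
    for s in canonical:
        counts[s] = counts.get(s, 0) + 1
    return min(counts, key=lambda s: (-counts[s], len(s), s))


def _pooled_metrics(actual: np.ndarray, predicted: np.ndarray) -> tuple[float, float]:
    rmse = float(np.sqrt(np.mean((actual - predicted) ** 2)))
    ss_tot = float(np.sum((actual - actual.mean()) ** 2))
    if ss_tot == 0.0:
        return rmse, 0.0
    r2 = 1.0 - float(np.sum((actual - predicted) ** 2)) / ss_tot
    return rmse, r2


def nested_cv_evaluate(
    dataset: CohortDataset,
    target: str,
    *,
    max_subset: int = MAX_SUBSET_SIZE,
    forward_only: bool = False,
    mode: str = "cross_sectional",
    subset_policy: str = "per_fold",
) -> PredictionReport:
    """Nested LOSO evaluation with wrapper feature selection.

    Rows missing the target are dropped (no imputation); more than 20%
    missing aborts. Per outer training fold, floating selection runs on the
    inner subjects; each held-out subject is then predicted with a GP
    refitted on its training fold (hyperparameters re-tuned by inner LOSO).
    Metrics are pooled over all out-of-fold predictions.

    ``subset_policy`` controls which subset predicts a fold. The default
    ``"per_fold"`` uses the subset selected on that fold's own training
    data, so no held-out subject can influence the features that predict
    it. ``"most_frequent"`` refits every fold with the modal subset across
    folds; since each fold's test subject took part in the other folds'
    selections, this variant carries a small selection optimism and is kept
    only for protocol comparison. The modal subset and the per-fold subsets
    are reported either way.
    """
    if subset_policy not in ("per_fold", "most_frequent"):
        raise ValueError(f"unknown subset_policy {subset_policy!r}")
    if target not in dataset.frame.columns:
        raise ValueError(f"target column {target!r} absent")
    missing = dataset.frame[target].isna()
    if missing.mean() > 0.2:
        raise ValueError(
            f"target {target!r} missing for {missing.mean():.0%} of rows (> 20%)"
        )
    frame = dataset.frame.loc[~missing].reset_index(drop=True)
    data = CohortDataset(frame, dataset.feature_columns, dataset.subject_column)
    plan = make_loso_folds(data)
    if len(plan.subjects) < 5:
        raise ValueError("nested evaluation needs at least 5 subjects")
    X = data.features()
    y = frame[target].to_numpy(float)
    groups = data.groups()

    per_fold_subsets = []
    for fold in plan.folds:
        train = np.setdiff1d(np.arange(len(frame)), fold)
        per_fold_subsets.append(
            select_features_floating(
                X[train],
                y[train],
                groups[train],
                data.feature_columns,
                max_subset=max_subset,
                forward_only=forward_only,
            )
        )
    final_subset = most_frequent_subset(per_fold_subsets)

    predicted = np.empty(len(frame))
    for fold, fold_subset in zip(plan.folds, per_fold_subsets):
        subset = fold_subset if subset_policy == "per_fold" else final_subset
        cols = [data.feature_columns.index(f) for f in subset]
        train = np.setdiff1d(np.arange(len(frame)), fold)
        model = fit_gp(X[np.ix_(train, cols)], y[train], groups[train])
        predicted[fold] = model.predict(X[np.ix_(fold, cols)])
    rmse, r2 = _pooled_metrics(y, predicted)
    frequencies: dict[tuple[str, ...], int] = {}
    for s in (tuple(sorted(s)) for s in per_fold_subsets):
        frequencies[s] = frequencies.get(s, 0) + 1
    out = frame[[data.subject_column]].copy()
    out["actual"] = y
    out["predicted"] = predicted
    return PredictionReport(
        predictions=out,
        rmse=rmse,
        r2=r2,
        selection=SelectionResult(per_fold_subsets, final_subset, frequencies),
        target=target,
        mode=mode,
    )


def cross_sectional_predict(
    dataset: CohortDataset, scale: str, **kwargs
) -> PredictionReport:
    """Cross-sectional prediction of one clinical scale from fingerprints.

    6MWD and NSAA are evaluated on ambulant visits only; PUL and MyoGrip on
    all visits.
    """
    scale = scale.lower()
    if scale not in TARGET_COLUMNS:
        raise ValueError(f"unknown scale {scale!r}; use one of {set(TARGET_COLUMNS)}")
    frame = dataset.frame
    if scale in AMBULANT_ONLY_TARGETS:
        frame = frame.loc[frame["ambulatory"].astype(bool)].reset_index(drop=True)
    data = CohortDataset(frame, dataset.feature_columns, dataset.subject_column)
    return nested_cv_evaluate(data, TARGET_COLUMNS[scale], **kwargs)


def build_longitudinal_pairs(
    dataset: CohortDataset,
    horizon_months: float = 6.0,
    tolerance_months: float = 2.0,
    score_columns: Sequence[str] = tuple(TARGET_COLUMNS.values()),
) -> pd.DataFrame:
    """Visit pairs (T, T+h) per subject with gap within the tolerance window.

    Each output row carries the predictors of the earlier visit (features
    and baseline scores, suffixed ``_t0``) and the later visit's scores as
    targets (suffixed ``_t1``).
    """
    frame = dataset.frame
    if "visit_month" not in frame.columns:
        raise ValueError("dataset lacks a visit_month column")
    lo = horizon_months - tolerance_months
    hi = horizon_months + tolerance_months
    rows = []
    for _, visits in frame.groupby(dataset.subject_column, sort=False):
        visits = visits.sort_values("visit_month")
        for i, j in itertools.combinations(range(len(visits)), 2):
            gap = visits.iloc[j]["visit_month"] - visits.iloc[i]["visit_month"]
            if lo <= gap <= hi:
                t0, t1 = visits.iloc[i], visits.iloc[j]
                row = {
                    dataset.subject_column: t0[dataset.subject_column],
                    "gap_months": gap,
                    "age_years": t0.get("age_years", np.nan),
                }
                for c in dataset.feature_columns:
                    row[c] = t0[c]
                for c in score_columns:
                    if c in frame.columns:
                        row[f"{c}_t0"] = t0[c]
                        row[f"{c}_t1"] = t1[c]
                rows.append(row)
    return pd.DataFrame(rows)


def longitudinal_compare(
    dataset: CohortDataset,
    scale: str,
    horizon_months: float = 6.0,
    tolerance_months: float = 2.0,
    **cv_kwargs,
) -> tuple[PredictionReport, PredictionReport]:
    """Score-only vs fingerprint-based prediction of a scale 6 months ahead.

    Report A predicts the scale at T+6 months from the scale itself at T;
    report B predicts it from the fingerprints at T. Both use the identical
    pair rows and the nested LOSO protocol.
    """
    scale = scale.lower()
    column = TARGET_COLUMNS[scale]
    pairs = build_longitudinal_pairs(
        dataset, horizon_months=horizon_months, tolerance_months=tolerance_months
    )
    if pairs.empty:
        raise ValueError("no longitudinal visit pairs in the dataset")
    target = f"{column}_t1"
    baseline = f"{column}_t0"
    report_a = nested_cv_evaluate(
        CohortDataset(pairs, [baseline], dataset.subject_column),
        target,
        mode="longitudinal_score_only",
        **cv_kwargs,
    )
    report_b = nested_cv_evaluate(
        CohortDataset(pairs, dataset.feature_columns, dataset.subject_column),
        target,
        mode="longitudinal_fingerprints",
        **cv_kwargs,
    )
    return report_a, report_b


def enumerate_subject_combinations(
    subjects: Sequence, k: int, cap: int = LEARNING_CURVE_CAP, seed: int | None = None
) -> list[tuple]:
    """All C(n, k) subject subsets, or ``cap`` distinct ones sampled
    uniformly without replacement when the count exceeds the cap."""
    subjects = list(subjects)
    n = len(subjects)
    if not 0 < k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    total = math.comb(n, k)
    if total <= cap:
        return [tuple(c) for c in itertools.combinations(subjects, k)]
    rng = np.random.default_rng(seed)
    seen: set[tuple[int, ...]] = set()
    while len(seen) < cap:
        pick = tuple(sorted(rng.choice(n, size=k, replace=False)))
        seen.add(pick)
    return [tuple(subjects[i] for i in pick) for pick in sorted(seen)]


def learning_curve(
    dataset: CohortDataset,
    target: str,
    k_values: Sequence[int],
    seed: int | None = None,
    cap: int = LEARNING_CURVE_CAP,
    **kwargs,
) -> pd.DataFrame:
    """Mean and s.d. of aggregate RMSE over subject subsets of each size k.

    For each k, nested LOSO evaluation runs on min(C(n, k), cap) seeded
    subject subsets.
    """
    subjects = list(dataset.subjects)
    rows = []
    for k in k_values:
        if k < 5:
            raise ValueError("learning-curve points need k >= 5 subjects")
        combos = enumerate_subject_combinations(subjects, k, cap=cap, seed=seed)
        rmses = []
        for combo in combos:
            mask = dataset.frame[dataset.subject_column].isin(combo)
            sub = CohortDataset(
                dataset.frame.loc[mask].reset_index(drop=True),
                dataset.feature_columns,
                dataset.subject_column,
            )
            rmses.append(nested_cv_evaluate(sub, target, **kwargs).rmse)
        rows.append(
            {
                "k": k,
                "n_combinations": len(combos),
                "rmse_mean": float(np.mean(rmses)),
                "rmse_sd": float(np.std(rmses)),
            }
        )
    return pd.DataFrame(rows)
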