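import math

import numpy as np
import pandas as pd
import pytest

import kinedmd.gp as gp_mod
from kinedmd.prediction import (
    CohortDataset,
    build_longitudinal_pairs,
    cross_sectional_predict,
    enumerate_subject_combinations,
    learning_curve,
    longitudinal_compare,
    make_loso_folds,
    most_frequent_subset,
    nested_cv_evaluate,
    select_features_floating,
)
from kinedmd.synthetic import generate_feature_cohort


def _toy_dataset(n_subjects=15, n_visits=2, n_features=10, seed=0, noise=0.0):
    """Target exactly linear in the first two features plus optional noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_subjects):
        for v in range(n_visits):
            feats = rng.normal(size=n_features)
            rows.append(
                {
                    "subject_id": f"S{i:02d}",
                    "visit_month": 6 * v,
                    **{f"x{j:02d}": feats[j] for j in range(n_features)},
                    "y": 2.0 * feats[0] - feats[1] + noise * rng.normal(),
                }
            )
    frame = pd.DataFrame(rows)
    return CohortDataset(frame, [f"x{j:02d}" for j in range(n_features)])


class TestLosoFolds:
    def test_three_subjects_two_visits(self):
        ds = _toy_dataset(n_subjects=3, n_visits=2)
        plan = make_loso_folds(ds)
        assert len(plan.folds) == 3
        assert all(len(f) == 2 for f in plan.folds)

    def test_folds_partition_rows(self):
        ds = _toy_dataset(n_subjects=6, n_visits=3)
        plan = make_loso_folds(ds)
        all_rows = np.sort(np.concatenate(plan.folds))
        np.testing.assert_array_equal(all_rows, np.arange(len(ds.frame)))
        for i, a in enumerate(plan.folds):
            for b in plan.folds[i + 1 :]:
                assert not set(a) & set(b)

    def test_unequal_visit_counts(self):
        frame = pd.DataFrame(
            {
                "subject_id": ["A", "B", "B", "B", "C"],
                "x00": np.arange(5.0),
                "y": np.arange(5.0),
            }
        )
        plan = make_loso_folds(CohortDataset(frame, ["x00"]))
        assert sorted(len(f) for f in plan.folds) == [1, 1, 3]

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="3 subjects"):
            make_loso_folds(_toy_dataset(n_subjects=2))


class TestFeatureSelection:
    def test_informative_feature_found_among_noise(self):
        rng = np.random.default_rng(7)
        n = 45  # 15 subjects x 3 visits
        X = rng.normal(size=(n, 10))
        y = 3.0 * X[:, 4]
        groups = np.repeat(np.arange(15), 3)
        subset = select_features_floating(
            X, y, groups, [f"x{j:02d}" for j in range(10)]
        )
        assert "x04" in subset

    def test_all_noise_returns_minimum_one_feature(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        subset = select_features_floating(
            X, y, np.repeat(np.arange(10), 2), list("abcde")
        )
        assert len(subset) >= 1

    def test_selection_is_deterministic(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(24, 6))
        y = X[:, 1] - X[:, 2] + 0.1 * rng.normal(size=24)
        groups = np.repeat(np.arange(8), 3)
        names = list("abcdef")
        assert select_features_floating(X, y, groups, names) == (
            select_features_floating(X, y, groups, names)
        )


class TestMostFrequentSubset:
    def test_modal_subset_wins(self):
        assert most_frequent_subset([("A", "B"), ("B", "A"), ("C",)]) == ("A", "B")

    def test_tie_breaks_to_smaller_then_lexicographic(self):
        assert most_frequent_subset([("B",), ("A",)]) == ("A",)
        assert most_frequent_subset([("A", "B"), ("C",)]) == ("C",)

    def test_single_subset_returned_as_is(self):
        assert most_frequent_subset([("Z", "A")]) == ("A", "Z")

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            most_frequent_subset([])


class TestNestedCV:
    def test_recoverable_linear_target(self):
        report = nested_cv_evaluate(_toy_dataset(seed=1), "y")
        assert report.r2 >= 0.99
        assert len(report.predictions) == 30

    def test_permuted_target_shows_no_optimism(self):
        ds = _toy_dataset(seed=2)
        rng = np.random.default_rng(0)
        frame = ds.frame.copy()
        for _ in range(3):
            subjects = frame["subject_id"].unique()
            mapping = dict(zip(subjects, rng.permutation(subjects)))
            # permute the target across subjects, keeping visits together
            per_subject = frame.groupby("subject_id")["y"].apply(list)
            frame["y"] = [
                y
                for s in subjects
                for y in per_subject[mapping[s]]
            ]
            report = nested_cv_evaluate(
                CohortDataset(frame, ds.feature_columns), "y"
            )
            assert report.r2 <= 0.1

    def test_missing_target_fraction_guard(self):
        ds = _toy_dataset()
        frame = ds.frame.copy()
        frame.loc[: len(frame) * 0.3, "y"] = np.nan
        with pytest.raises(ValueError, match="> 20%"):
            nested_cv_evaluate(CohortDataset(frame, ds.feature_columns), "y")

    def test_sparse_missing_rows_are_dropped(self):
        ds = _toy_dataset()
        frame = ds.frame.copy()
        frame.loc[0, "y"] = np.nan
        report = nested_cv_evaluate(CohortDataset(frame, ds.feature_columns), "y")
        assert len(report.predictions) == len(frame) - 1

    def test_standardization_never_sees_test_rows(self, monkeypatch):
        ds = _toy_dataset(n_subjects=6, n_features=3)
        n_rows = len(ds.frame)
        seen = []
        original = gp_mod.Standardizer.fit.__func__

        def spy(cls, X):
            seen.append(len(X))
            return original(cls, X)

        monkeypatch.setattr(
            gp_mod.Standardizer, "fit", classmethod(spy)
        )
        nested_cv_evaluate(ds, "y")
        assert seen and max(seen) < n_rows  # always a strict subset

    def test_rmse_invariant_to_subject_order(self):
        ds = _toy_dataset(seed=3, noise=0.3)
        shuffled = ds.frame.sample(frac=1.0, random_state=5).reset_index(drop=True)
        a = nested_cv_evaluate(ds, "y").rmse
        b = nested_cv_evaluate(CohortDataset(shuffled, ds.feature_columns), "y").rmse
        assert a == pytest.approx(b, rel=1e-9)


@pytest.fixture(scope="module")
def cohort():
    frame, cols = generate_feature_cohort(n_subjects=12, seed=6)
    return CohortDataset(frame, cols)


class TestCrossSectional:
    def test_ambulant_only_rule_for_walking_scales(self, cohort):
        report = cross_sectional_predict(cohort, "6mwd")
        ambulant_rows = int(cohort.frame["ambulatory"].astype(bool).sum())
        assert len(report.predictions) == ambulant_rows

    def test_upper_limb_scale_keeps_all_rows(self, cohort):
        report = cross_sectional_predict(cohort, "pul")
        assert len(report.predictions) == len(cohort.frame)

    def test_strong_severity_signal_is_predictive(self, cohort):
        report = cross_sectional_predict(cohort, "6mwd")
        assert report.r2 >= 0.7

    def test_unknown_scale_rejected(self, cohort):
        with pytest.raises(ValueError, match="unknown scale"):
            cross_sectional_predict(cohort, "grip-o-meter")


class TestLongitudinalPairs:
    def _dataset(self, months_by_subject):
        rows = []
        for sid, months in months_by_subject.items():
            for m in months:
                rows.append(
                    {
                        "subject_id": sid,
                        "visit_month": m,
                        "age_years": 8 + m / 12,
                        "x00": float(m),
                        "nsaa": 30.0 - m,
                    }
                )
        return CohortDataset(pd.DataFrame(rows), ["x00"])

    def test_standard_visit_grid_gives_adjacent_pairs(self):
        pairs = build_longitudinal_pairs(self._dataset({"A": [0, 6, 12]}))
        assert len(pairs) == 2
        assert sorted(pairs["gap_months"]) == [6, 6]

    def test_single_visit_subject_contributes_nothing(self):
        pairs = build_longitudinal_pairs(self._dataset({"A": [0]}))
        assert pairs.empty

    def test_gap_outside_tolerance_excluded(self):
        pairs = build_longitudinal_pairs(
            self._dataset({"A": [0, 9]}), horizon_months=6, tolerance_months=2
        )
        assert pairs.empty

    def test_compare_reports_share_pair_count(self):
        frame, cols = generate_feature_cohort(n_subjects=10, seed=8)
        a, b = longitudinal_compare(CohortDataset(frame, cols), "nsaa")
        assert len(a.predictions) == len(b.predictions)

    def test_degenerate_single_pair_input_rejected(self):
        with pytest.raises(ValueError):
            longitudinal_compare(self._dataset({"A": [0, 6]}), "nsaa")


class TestLearningCurve:
    def test_combination_counting(self):
        assert len(enumerate_subject_combinations(range(10), 8)) == math.comb(10, 8)
        assert len(enumerate_subject_combinations(range(20), 10, seed=0)) == 1000
        assert len(enumerate_subject_combinations(range(20), 20)) == 1

    def test_sampled_combinations_are_distinct_and_seeded(self):
        a = enumerate_subject_combinations(range(30), 10, cap=50, seed=1)
        b = enumerate_subject_combinations(range(30), 10, cap=50, seed=1)
        assert a == b
        assert len(set(a)) == 50

    def test_small_k_rejected(self):
        ds = _toy_dataset(n_subjects=8)
        with pytest.raises(ValueError, match="k >= 5"):
            learning_curve(ds, "y", [3])

    def test_full_cohort_point_has_zero_spread(self):
        ds = _toy_dataset(n_subjects=7, n_features=3, noise=0.3, seed=4)
        out = learning_curve(ds, "y", [7], max_subset=2)
        assert out.loc[0, "n_combinations"] == 1
        assert out.loc[0, "rmse_sd"] == 0.0
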