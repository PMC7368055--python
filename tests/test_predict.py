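"""kNN imputation, platelet-contribution regression, LOOCV classification
and FDR-corrected comparisons."""

import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeClassifier
from statsmodels.stats.multitest import multipletests

from thromboflow.predict import (
    FeatureTable,
    classify_conditions,
    compare_classifiers,
    default_roster,
    feature_table_from_records,
    impute_missing,
    platelet_contribution,
)
from thromboflow.registry import Condition
from thromboflow.synthetic import generate_parameter_cohort


def _table(features: np.ndarray, classes, surface="M6") -> FeatureTable:
    n = len(classes)
    return FeatureTable(
        pd.DataFrame(features, columns=[f"f{i}" for i in range(features.shape[1])]),
        pd.DataFrame(
            {"subject": [f"S{i}" for i in range(n)], "surface": surface,
             "condition_class": list(classes)}
        ),
    )


class TestImputeMissing:
    def test_no_missing_is_identity(self, rng):
        t = _table(rng.normal(0, 1, (6, 4)), [0, 0, 1, 1, 2, 2])
        out = impute_missing(t, k=3)
        assert out.features.equals(t.features)

    def test_duplicate_row_donates_exact_value(self):
        x = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [9.0, 9.0, 9.0]])
        x_missing = x.copy()
        x_missing[0, 2] = np.nan
        t = _table(x_missing, [0, 0, 1])
        out = impute_missing(t, k=1)
        assert out.features.iloc[0, 2] == 3.0

    def test_idempotent(self, rng):
        x = rng.normal(0, 1, (8, 5))
        x[rng.random((8, 5)) < 0.15] = np.nan
        if np.isnan(x).all(axis=1).any() or np.isnan(x).all(axis=0).any():
            x[0] = 1.0
        t = _table(x, [0] * 4 + [1] * 4)
        once = impute_missing(t, k=3)
        twice = impute_missing(once, k=3)
        assert once.features.equals(twice.features)

    def test_feature_missing_everywhere_raises(self):
        x = np.ones((4, 3))
        x[:, 1] = np.nan
        with pytest.raises(ValueError):
            impute_missing(_table(x, [0, 0, 1, 1]), k=2)

    def test_mask_and_recover_rmse_below_feature_sd(self, rng):
        # correlated features so neighbours are informative
        recs = generate_parameter_cohort(
            8, None, ["M2", "M6"], [Condition(), Condition(tf=True)], seed=3
        )
        table = feature_table_from_records(recs)
        x = table.features.to_numpy(float)
        rng_mask = np.random.default_rng(0)
        informative = np.where(x.std(axis=0) > 1e-9)[0]
        cells = [
            (i, j)
            for i in range(x.shape[0])
            for j in informative
            if rng_mask.random() < 0.1
        ]
        x_missing = x.copy()
        for i, j in cells:
            x_missing[i, j] = np.nan
        masked = FeatureTable(
            pd.DataFrame(x_missing, columns=table.features.columns), table.meta
        )
        out = impute_missing(masked, k=3).features.to_numpy(float)
        err = np.array([out[i, j] - x[i, j] for i, j in cells])
        sd = np.array([x[:, j].std() for _, j in cells])
        rmse = float(np.sqrt(np.mean(err**2)))
        assert rmse < float(np.mean(sd))


class TestPlateletContribution:
    @staticmethod
    def _frame(n, rng, make_target):
        p1 = rng.normal(50, 10, n)
        p2 = rng.normal(20, 5, n)
        data = {}
        for t in (0, 2, 4, 6, 8):
            data[f"P1_t{t}"] = p1
            data[f"P2_t{t}"] = p2
            data[f"P3_t{t}"] = make_target(p1, p2, rng)
        return pd.DataFrame(data)

    def test_target_copy_of_p1(self, rng):
        frame = self._frame(30, rng, lambda p1, p2, r: p1.copy())
        out = platelet_contribution(frame, targets=("P3",))
        assert (out["p1_pct"] > 99.0).all()
        assert (out["p2_pct"] < 20.0).all()

    def test_independent_target_flagged_unstable(self, rng):
        frame = self._frame(400, rng, lambda p1, p2, r: r.normal(0, 1, len(p1)))
        out = platelet_contribution(frame, targets=("P3",))
        assert out["unstable"].all()

    def test_zero_variance_target_missing(self, rng):
        frame = self._frame(20, rng, lambda p1, p2, r: np.zeros(len(p1)))
        out = platelet_contribution(frame, targets=("P3",))
        assert out["p1_pct"].isna().all()

    def test_dominant_p1_recovered(self):
        wins = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            frame = self._frame(
                40, r, lambda p1, p2, rr: 0.8 * p1 + 0.2 * p2 + rr.normal(0, 2, len(p1))
            )
            out = platelet_contribution(frame, targets=("P3",))
            wins += (out["p1_pct"] > out["p2_pct"]).all()
        assert wins >= 19  # >= 95% of seeds


class TestClassifyConditions:
    @staticmethod
    def _separable(n_per_class=4, n_classes=8, sep=50.0, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows, classes = [], []
        for c in range(n_classes):
            centre = np.zeros(5)
            centre[: 3] = [c % 2, (c // 2) % 2, (c // 4) % 2]
            for _ in range(n_per_class):
                jitter = rng.normal(0, noise, 5) if noise else np.zeros(5)
                rows.append(centre * sep + jitter)
                classes.append(c)
        return _table(np.asarray(rows), classes)

    def test_perfect_separation_reaches_full_accuracy(self):
        table = self._separable()
        roster = {
            "decision_tree": lambda: DecisionTreeClassifier(random_state=0),
            "knn": default_roster(0)["knn"],
        }
        report = classify_conditions(table, roster)
        assert (report.accuracies.loc["M6"] == 1.0).all()

    def test_zero_signal_near_chance_level(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (64, 5))
        classes = list(range(8)) * 8
        table = _table(x, classes)
        report = classify_conditions(table, default_roster(0))
        # chance is 1/8; binomial noise at n=64 keeps accuracies well below 0.35
        assert report.accuracies.to_numpy().mean() < 0.30

    def test_loocv_matches_fold_by_fold_oracle(self):
        # 16-run fixture, moderately noisy
        table = self._separable(n_per_class=2, sep=2.0, noise=1.0, seed=4)
        make_clf = lambda: DecisionTreeClassifier(random_state=0)
        report = classify_conditions(table, {"a": make_clf, "b": make_clf})
        x = table.features.to_numpy(float)
        y = table.meta["condition_class"].to_numpy()
        correct = 0
        for i in range(len(y)):  # independent explicit fold loop
            train = [j for j in range(len(y)) if j != i]
            clf = DecisionTreeClassifier(random_state=0)
            clf.fit(x[train], y[train])
            correct += int(clf.predict(x[i : i + 1])[0] == y[i])
        assert report.accuracies.loc["M6", "a"] == pytest.approx(correct / len(y))

    def test_no_leakage_on_random_labels(self):
        # a 1-NN memorizer would be perfect if its own row leaked into training
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (40, 5))
        classes = list(rng.integers(0, 8, 40))
        while len({c for c in classes if classes.count(c) >= 2}) < 2:
            classes = list(rng.integers(0, 8, 40))
        table = _table(x, classes)
        report = classify_conditions(table, {"knn": default_roster(0)["knn"],
                                             "tree": default_roster(0)["decision_tree"]})
        assert (report.accuracies.loc["M6"] < 0.9).all()

    def test_singleton_class_counted_unpredictable(self):
        x = np.vstack([np.zeros((2, 3)), np.ones((2, 3)), np.full((1, 3), 5.0)])
        table = _table(x, [0, 0, 1, 1, 2])
        report = classify_conditions(
            table, {"a": lambda: DecisionTreeClassifier(random_state=0),
                    "b": lambda: DecisionTreeClassifier(random_state=1)}
        )
        assert report.skipped_runs.get("M6") == 1
        assert (report.accuracies.loc["M6"] <= 4 / 5).all()

    def test_missing_values_rejected(self):
        x = np.ones((4, 3))
        x[0, 0] = np.nan
        with pytest.raises(ValueError):
            classify_conditions(_table(x, [0, 0, 1, 1]))


class TestCompareClassifiers:
    def _report(self, acc_by_surface):
        from thromboflow.predict import PredictionReport

        return PredictionReport(pd.DataFrame(acc_by_surface).T)

    def test_identical_vectors_give_p_one(self):
        report = self._report(
            {"M6": {"a": 0.5, "b": 0.6, "c": 0.7}, "M7": {"a": 0.5, "b": 0.6, "c": 0.7}}
        )
        out = compare_classifiers(report)
        assert out["p_raw"].iloc[0] == 1.0 and out["degenerate"].iloc[0]

    def test_adjusted_p_at_least_raw(self, rng):
        accs = {
            s: {c: float(rng.uniform(0.2, 0.9)) for c in "abcdef"}
            for s in ("M2", "M4", "M6", "M7")
        }
        out = compare_classifiers(self._report(accs))
        assert (out["p_fdr"] >= out["p_raw"] - 1e-12).all()

    def test_bh_closed_form_on_constructed_p_vector(self):
        # all m raw p equal alpha -> every BH-adjusted p equals alpha
        alpha = 0.03
        adj = multipletests([alpha] * 6, method="fdr_bh")[1]
        assert np.allclose(adj, alpha)
        # graded p-vector: adjusted p_i = min_{j>=i} p_j * m / j
        p = [0.01, 0.02, 0.03, 0.04]
        adj = multipletests(p, method="fdr_bh")[1]
        expect = [min(p[j] * 4 / (j + 1) for j in range(i, 4)) for i in range(4)]
        assert np.allclose(adj, expect)

    def test_null_simulation_false_positive_rate(self, rng):
        # random accuracies: BH at q=0.05 should reject rarely
        hits = 0
        n_sims = 100
        for _ in range(n_sims):
            accs = {
                s: {c: float(rng.uniform(0.4, 0.6)) for c in "abcdefgh"}
                for s in ("M2", "M6", "M7")
            }
            out = compare_classifiers(self._report(accs))
            hits += int((out["p_fdr"] < 0.05).any())
        assert hits / n_sims <= 0.12  # ~q plus simulation error


class TestFeatureTable:
    def test_records_flatten_to_41_features(self):
        recs = generate_parameter_cohort(2, None, ["M6"], [Condition()], seed=0,
                                         n_replicates=1)
        table = feature_table_from_records(recs)
        assert table.features.shape == (2, 41)
        assert (table.meta["condition_class"] == 0).all()

    def test_invalid_class_rejected(self):
        with pytest.raises(ValueError):
            FeatureTable(
                pd.DataFrame({"f0": [1.0]}),
                pd.DataFrame({"subject": ["S1"], "surface": ["M6"],
                              "condition_class": [9]}),
            )
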