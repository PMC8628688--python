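"""Tests for the ML stage: pruning, splitting, oversampling, SFFS, search,
training and the diagnostic metric panel."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nucleograde.mlpipe import (MetricPanel, SplitSpec, StandardizationParams,
                                cv_auc, evaluate, make_model, oversample,
                                point_biserial, prune_collinear, random_search,
                                sffs_select, split_cohort, train_model, _folds)


class TestPruning:
    def test_duplicated_column_keeps_one(self, rng):
        x = rng.normal(size=100)
        y = (x + rng.normal(size=100) > 0).astype(int)
        X = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=100)})
        retained, report = prune_collinear(X, y)
        assert "c" in retained
        assert sum(c in retained for c in ("a", "b")) == 1
        assert len(report) == 1

    def test_member_with_lower_point_biserial_dropped(self, rng):
        y = np.repeat([0, 1], 100)
        z = rng.normal(size=200)                  # shared latent
        a = z + 0.8 * y                           # stronger label loading
        b = z + 0.25 * y + rng.normal(0, 0.1, 200)
        X = pd.DataFrame({"a": a, "b": b})
        r2 = np.corrcoef(a, b)[0, 1] ** 2
        assert r2 >= 0.7, "fixture must be collinear"
        assert abs(point_biserial(a, y)) > abs(point_biserial(b, y))
        retained, _ = prune_collinear(X, y)
        assert retained == ["a"]

    def test_uncorrelated_input_unchanged(self, rng):
        X = pd.DataFrame(rng.normal(size=(200, 5)), columns=list("abcde"))
        y = rng.integers(0, 2, 200)
        retained, report = prune_collinear(X, y)
        assert retained == list("abcde")
        assert report.empty

    def test_pruned_representative_follows_merge_chain(self, rng):
        from nucleograde.mlpipe import pruned_representative

        z = rng.normal(size=300)
        y = rng.integers(0, 2, 300)
        X = pd.DataFrame({"a": z + 0.02 * rng.normal(size=300),
                          "b": z + 0.01 * rng.normal(size=300),
                          "c": rng.normal(size=300)})
        retained, report = prune_collinear(X, y)
        dropped = {"a", "b"} - set(retained)
        assert len(dropped) == 1
        rep = pruned_representative(report, dropped.pop())
        assert rep in retained
        assert pruned_representative(report, "c") == "c"

    def test_constant_feature_flagged_not_dropped(self, rng):
        X = pd.DataFrame({"k": np.ones(50), "a": rng.normal(size=50)})
        retained, report = prune_collinear(X, rng.integers(0, 2, 50))
        assert "k" in retained
        assert report.attrs["constant_features"] == ["k"]


class TestSplit:
    def test_study_cohort_arithmetic(self):
        """138 patients (80 pos / 58 neg) at 30%: ceil gives 24 + 18 = 42 test
        patients, prevalence 57.14%."""
        labels = pd.Series([1] * 80 + [0] * 58,
                           index=[f"P{i}" for i in range(138)])
        train, test = split_cohort(labels, SplitSpec(0.30, seed=0))
        assert len(test) == 42 and len(train) == 96
        test_labels = labels.loc[test]
        assert (test_labels == 1).sum() == 24
        assert (test_labels == 0).sum() == 18
        prev = 100 * (test_labels == 1).mean()
        assert prev == pytest.approx(57.14, abs=0.01)

    def test_half_split_of_two_plus_two(self):
        labels = pd.Series([0, 0, 1, 1], index=list("abcd"))
        train, test = split_cohort(labels, SplitSpec(0.5, seed=1))
        assert len(test) == 2 and len(train) == 2
        assert labels.loc[test].sum() == 1

    @pytest.mark.parametrize("seed", [0, 7, 123])
    def test_partition_contract(self, seed):
        labels = pd.Series(np.tile([0, 1], 20), index=range(40))
        train, test = split_cohort(labels, SplitSpec(0.3, seed=seed))
        assert set(train) | set(test) == set(labels.index)
        assert set(train) & set(test) == set()

    def test_tiny_class_rejected(self):
        labels = pd.Series([0, 1, 1, 1], index=range(4))
        with pytest.raises(ValueError):
            split_cohort(labels, SplitSpec(0.3))


class TestStandardization:
    def test_test_set_uses_training_parameters(self, rng):
        X_train = pd.DataFrame({"a": rng.normal(3, 2, 100), "k": np.ones(100)})
        params = StandardizationParams.fit(X_train)
        Z = params.transform(X_train)
        assert Z["a"].mean() == pytest.approx(0, abs=1e-12)
        assert Z["a"].std(ddof=0) == pytest.approx(1)
        assert params.constant_features == ["k"]
        X_test = pd.DataFrame({"a": [3.0], "k": [1.0]})
        Zt = params.transform(X_test)
        assert Zt["a"].iloc[0] == pytest.approx(
            (3.0 - X_train["a"].mean()) / X_train["a"].std(ddof=0))


class TestOversample:
    def test_balanced_input_unchanged(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.repeat([0, 1], 10)
        X2, y2 = oversample(X, y, "smote")
        assert np.array_equal(X2, X) and np.array_equal(y2, y)

    def test_synthetics_lie_on_minority_segment(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]] + [[10.0 + i, 0.0] for i in range(8)])
        y = np.array([1, 1] + [0] * 8)
        X2, y2 = oversample(X, y, "smote", k=1, seed=0)
        synth = X2[len(X):]
        assert len(synth) == 6
        # on the segment between (0,0) and (1,1): x == y and 0 <= x <= 1
        assert np.allclose(synth[:, 0], synth[:, 1])
        assert np.all((synth >= 0) & (synth <= 1))

    @pytest.mark.parametrize("variant", ["smote", "borderline"])
    def test_study_imbalance_balanced_to_majority(self, rng, variant):
        X = np.vstack([rng.normal(0, 1, (58, 4)), rng.normal(1, 1, (80, 4))])
        y = np.array([0] * 58 + [1] * 80)
        X2, y2 = oversample(X, y, variant, seed=1)
        assert (y2 == 0).sum() == 80 and (y2 == 1).sum() == 80
        assert len(X2) == 160

    def test_borderline_without_danger_points_falls_back(self, rng):
        # minority far from majority: no danger points
        X = np.vstack([rng.normal(0, 0.1, (10, 2)),
                       rng.normal(100, 0.1, (4, 2))])
        y = np.array([0] * 10 + [1] * 4)
        with pytest.warns(UserWarning, match="danger"):
            X2, y2 = oversample(X, y, "borderline", seed=2)
        assert (y2 == 1).sum() == 10


class TestSFFS:
    def _signal_problem(self, rng, n=120, noise_features=8):
        X = pd.DataFrame(rng.normal(size=(n, noise_features + 1)),
                         columns=["signal"] + [f"n{i}" for i in range(noise_features)])
        y = (X["signal"] + 0.3 * rng.normal(size=n) > 0).astype(int)
        return X, y

    def test_recovers_single_predictive_feature(self, rng):
        X, y = self._signal_problem(rng)
        res = sffs_select("logistic", X, y, iterations=20, folds=5, seed=0)
        assert "signal" in res.modal_subset
        hits = sum("signal" in s for s in res.subsets)
        assert hits >= 18  # >= 90% of iterations

    def test_all_noise_yields_chance_level(self, rng):
        X = pd.DataFrame(rng.normal(size=(100, 6)),
                         columns=[f"n{i}" for i in range(6)])
        y = pd.Series(np.tile([0, 1], 50))
        res = sffs_select("logistic", X, y, iterations=10, folds=5, seed=0)
        assert res.modal_auc < 0.75  # no real signal to find

    def test_cap_is_respected_and_deterministic(self, rng):
        X, y = self._signal_problem(rng)
        r1 = sffs_select("logistic", X, y, iterations=5, folds=4, cap=3, seed=3)
        r2 = sffs_select("logistic", X, y, iterations=5, folds=4, cap=3, seed=3)
        assert all(len(s) <= 3 for s in r1.subsets)
        assert r1.subsets == r2.subsets
        with pytest.raises(ValueError):
            sffs_select("logistic", X, y, cap=0)

    def test_grouped_folds_keep_patients_together(self):
        y = np.tile([0, 1], 20)
        groups = np.repeat(np.arange(10), 4)  # 4 sections per patient
        for tr, va in _folds(y, groups, 5, seed=0):
            assert set(groups[tr]) & set(groups[va]) == set()


class TestRandomSearch:
    def test_single_point_space_returned(self, rng):
        X = rng.normal(size=(60, 3))
        y = rng.integers(0, 2, 60)
        res = random_search("logistic", X, y, space={"C": [0.5]},
                            iterations=5, folds=3, seed=0)
        assert res.best_params == {"C": 0.5}

    def test_same_seed_same_selection(self, rng):
        X = rng.normal(size=(80, 4))
        y = (X[:, 0] > 0).astype(int)
        r1 = random_search("logistic", X, y, iterations=8, folds=4, seed=5)
        r2 = random_search("logistic", X, y, iterations=8, folds=4, seed=5)
        assert r1.best_params == r2.best_params
        assert r1.best_auc == r2.best_auc

    def test_search_beats_or_matches_defaults(self, rng):
        X = rng.normal(size=(150, 4))
        logits = 3.0 * X[:, 0]
        y = (rng.random(150) < 1 / (1 + np.exp(-logits))).astype(int)
        res = random_search("logistic", X, y, iterations=10, folds=5, seed=1)
        default_auc = cv_auc("logistic", None, X, y,
                             _folds(y, None, 5, 1), seed=1)
        assert res.best_auc >= default_auc - 0.05

    def test_empty_space_warns_and_uses_defaults(self, rng):
        X = rng.normal(size=(40, 2))
        y = np.tile([0, 1], 20)
        with pytest.warns(UserWarning, match="empty search space"):
            res = random_search("knn", X, y, space={}, folds=4)
        assert res.best_params == {}


class TestModels:
    def test_linearly_separable_logistic_is_perfect(self):
        X = np.array([[0.0], [1.0], [2.0], [10.0], [11.0], [12.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        m = train_model("logistic", X, y)
        assert (m.predict(X) == y).all()

    def test_constant_feature_gives_class_prior(self, rng):
        X = np.ones((100, 1))
        y = np.array([1] * 30 + [0] * 70)
        m = train_model("logistic", X, y, params={"C": 1e6})
        p = m.predict_proba(X)[:, 1]
        assert p == pytest.approx(np.full(100, 0.3), abs=1e-3)

    def test_naive_bayes_rejected_for_clinical_features(self):
        with pytest.raises(ValueError, match="clinical"):
            train_model("naive_bayes", np.ones((4, 2)), [0, 1, 0, 1],
                        feature_set="clinical")

    def test_unknown_model_lists_supported(self):
        with pytest.raises(ValueError, match="supported"):
            make_model("perceptron")

    @pytest.mark.parametrize("name", ["knn", "random_forest", "xgboost",
                                      "svm", "naive_bayes"])
    def test_probability_outputs_in_unit_interval(self, rng, name):
        X = rng.normal(size=(60, 3))
        y = (X[:, 0] > 0).astype(int)
        m = train_model(name, X, y, feature_set="spatial")
        p = m.predict_proba(X)[:, 1]
        assert np.all((p >= 0) & (p <= 1))


class TestMetricPanel:
    def test_clinical_lr_row_counts(self):
        """TP=18 FN=6 TN=13 FP=5: Sn 75.00, Sp 72.22, PPV 78.26, ACC 73.81,
        LR+ 2.70, LR- 0.35, DOR 7.80, f1 0.77."""
        p = MetricPanel.from_counts(tp=18, fn=6, tn=13, fp=5)
        assert p.sn == pytest.approx(75.00, abs=0.01)
        assert p.sp == pytest.approx(72.22, abs=0.01)
        assert p.ppv == pytest.approx(78.26, abs=0.01)
        assert p.acc == pytest.approx(73.81, abs=0.01)
        assert p.lr_pos == pytest.approx(2.70, abs=0.01)
        assert p.lr_neg == pytest.approx(0.35, abs=0.01)
        assert p.dor == pytest.approx(7.80, abs=0.01)
        assert p.f1 == pytest.approx(0.77, abs=0.01)

    def test_clinical_knn_row_counts(self):
        """TP=18 FN=6 TN=9 FP=9: Sn 75, Sp 50, LR+ 1.50, LR- 0.50, DOR 3.00."""
        p = MetricPanel.from_counts(tp=18, fn=6, tn=9, fp=9)
        assert (p.sn, p.sp) == (75.0, 50.0)
        assert p.lr_pos == pytest.approx(1.50)
        assert p.lr_neg == pytest.approx(0.50)
        assert p.dor == pytest.approx(3.00)

    def test_perfect_separation(self):
        probs = [0.9, 0.8, 0.95, 0.1, 0.2, 0.05]
        labels = [1, 1, 1, 0, 0, 0]
        p = evaluate(probs, labels)
        assert p.auc == 1.0
        assert p.fnr == 0.0 and p.fpr == 0.0 and p.acc == 100.0

    @settings(derandomize=True, max_examples=200)
    @given(tp=st.integers(1, 500), fn=st.integers(0, 500),
           tn=st.integers(1, 500), fp=st.integers(0, 500))
    def test_identities_hold_on_random_confusion_tables(self, tp, fn, tn, fp):
        p = MetricPanel.from_counts(tp, fn, tn, fp)
        assert p.sn + p.fnr == pytest.approx(100, abs=1e-9)
        assert p.sp + p.fpr == pytest.approx(100, abs=1e-9)
        assert p.ppv + p.fdr == pytest.approx(100, abs=1e-9)
        assert p.npv + p.f_or == pytest.approx(100, abs=1e-9)
        if p.sp < 100:
            assert p.lr_pos == pytest.approx(p.sn / (100 - p.sp), abs=1e-9)
        if p.sp > 0:
            assert p.lr_neg == pytest.approx((100 - p.sn) / p.sp, abs=1e-9)
        if np.isfinite(p.dor) and p.lr_neg > 0:
            assert p.dor == pytest.approx(p.lr_pos / p.lr_neg, rel=1e-9)
        assert p.f1 * 100 == pytest.approx(
            2 * p.ppv * p.sn / (p.ppv + p.sn), abs=1e-9)

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            evaluate([0.2, 0.8], [1, 1])

    def test_out_of_range_probabilities_rejected(self):
        with pytest.raises(ValueError):
            evaluate([0.2, 1.8], [1, 0])


def test_cv_auc_reapplies_oversampling_inside_folds(rng):
    X = np.vstack([rng.normal(0, 1, (30, 2)), rng.normal(2, 1, (12, 2))])
    y = np.array([0] * 30 + [1] * 12)
    folds = _folds(y, None, 4, 0)
    auc = cv_auc("logistic", None, X, y, folds, oversample_variant="smote")
    assert 0.5 < auc <= 1.0
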