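"""Split, preprocessing, SMOTE, mRMR, LASSO, and the two-step classifiers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from habicat import (
    ModelSettings,
    binary_labels,
    evaluate_two_step,
    generate_feature_table,
    lasso_select,
    make_split,
    mrmr_select,
    preprocess_fit,
    roc_auc,
    smote,
    train_classifier,
    train_two_step,
)

FAST = ModelSettings(lasso_cs=tuple(np.logspace(-1.5, 1.5, 6)),
                     lr_cs=(0.1, 1.0), mrmr_m=15)


class TestSplit:
    def test_stratification_arithmetic(self):
        labels = np.array([1] * 30 + [0] * 70)
        split = make_split(np.arange(100), labels, ratio=0.7, seed=0)
        test_pos = sum(labels[i] for i in split.test_ids)
        assert abs(test_pos - 9) <= 1
        assert len(split.test_ids) == 30

    def test_deterministic(self):
        labels = np.array([0, 1] * 20)
        a = make_split(np.arange(40), labels, seed=5)
        b = make_split(np.arange(40), labels, seed=5)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids

    def test_degenerate_ratios_rejected(self):
        labels = np.array([0, 1] * 10)
        with pytest.raises(ValueError):
            make_split(np.arange(20), labels, ratio=1.0)
        with pytest.raises(ValueError, match="2 members"):
            make_split(np.arange(3), np.array([0, 0, 1]))


class TestPreprocess:
    def test_outlier_clipped_to_fence(self, rng):
        vals = rng.normal(0, 1, 200)
        vals[0] = 1e6
        df = pd.DataFrame({"f": vals})
        pre = preprocess_fit(df, ["f"])
        q1, q3 = np.percentile(np.clip(vals, *np.percentile(vals, [0, 100])), [25, 75])
        assert pre.clip_high[0] < 1e6
        z = pre.transform(df)
        assert z["f"].iloc[0] == z["f"].max()

    def test_train_columns_standardized(self, rng):
        df = pd.DataFrame(rng.normal(3, 7, size=(300, 4)),
                          columns=list("abcd"))
        pre = preprocess_fit(df, list("abcd"))
        z = pre.transform(df)
        np.testing.assert_allclose(z.mean(), 0, atol=1e-10)
        np.testing.assert_allclose(z.std(ddof=0), 1, atol=1e-10)

    def test_test_rows_use_train_parameters(self, rng):
        train = pd.DataFrame({"f": rng.normal(0, 1, 100)})
        test = pd.DataFrame({"f": rng.normal(50, 1, 100)})
        pre = preprocess_fit(train, ["f"])
        z = pre.transform(test)
        # test rows clip to the TRAIN fence and z-score far above 0; had
        # the parameters been refitted on test, the mean would be ~0
        assert z["f"].mean() > 3
        assert z["f"].std() < 1e-6  # all clipped to the same train fence

    def test_constant_feature_dropped(self):
        df = pd.DataFrame({"f": np.ones(50), "g": np.arange(50.0)})
        pre = preprocess_fit(df, ["f", "g"])
        assert pre.dropped == ["f"]
        assert pre.features == ["g"]


class TestSmote:
    def test_balance_arithmetic(self, rng):
        x = rng.normal(size=(40, 3))
        y = np.array([0] * 30 + [1] * 10)
        xb, yb = smote(x, y, seed=0)
        assert len(xb) == 60
        assert (yb == 1).sum() == (yb == 0).sum() == 30

    def test_synthetics_on_segments(self, rng):
        # with exactly two minority points every synthetic lies on the
        # segment between them
        maj = rng.normal(10, 1, size=(8, 2))
        x = np.vstack([maj, [[0.0, 0.0], [1.0, 2.0]]])
        y = np.array([0] * 8 + [1] * 2)
        with pytest.warns(UserWarning, match="reducing k"):
            xb, yb = smote(x, y, k_neighbors=5, seed=1)
        synth = xb[10:]
        t = synth[:, 0]  # parameter along the segment x=(t, 2t)
        assert np.all((0 <= t) & (t <= 1))
        np.testing.assert_allclose(synth[:, 1], 2 * t, atol=1e-12)

    def test_one_dimensional_interval(self, rng):
        x = np.concatenate([rng.normal(5, 1, 20), [0.0, 1.0]])[:, None]
        y = np.array([0] * 20 + [1] * 2)
        xb, _ = smote(x, y, k_neighbors=1, seed=2)
        assert np.all((xb[22:] >= 0) & (xb[22:] <= 1))

    def test_minority_of_one_rejected(self, rng):
        x = rng.normal(size=(10, 2))
        y = np.array([0] * 9 + [1])
        with pytest.raises(ValueError), pytest.warns(UserWarning):
            smote(x, y, seed=0)


class TestMrmr:
    def test_duplicate_never_second(self, rng):
        n = 400
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        y = ((a + b + rng.normal(size=n)) > 0).astype(int)
        df = pd.DataFrame({"a": a, "a_dup": a.copy(), "b": b,
                           "noise": rng.normal(size=n)})
        ranked = mrmr_select(df, y, 4)
        assert ranked[1] != "a_dup" or ranked[0] != "a"
        assert set(ranked[:2]) == {"a", "b"}

    def test_informative_ranked_first(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            x = r.normal(size=(500, 10))
            y = (x[:, 0] + 0.7 * r.normal(size=500) > 0).astype(int)
            df = pd.DataFrame(x, columns=[f"f{i}" for i in range(10)])
            hits += mrmr_select(df, y, 1)[0] == "f0"
        assert hits >= 19

    def test_exhaustive_selection_is_permutation(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 6)),
                          columns=[f"f{i}" for i in range(6)])
        y = rng.integers(0, 2, 50)
        assert sorted(mrmr_select(df, y, 6)) == sorted(df.columns)

    def test_constant_feature_never_beats_informative(self, rng):
        x = rng.normal(size=(200, 2))
        y = (x[:, 0] > 0).astype(int)
        df = pd.DataFrame({"const": np.ones(200), "inf": x[:, 0],
                           "noise": x[:, 1]})
        assert mrmr_select(df, y, 1)[0] == "inf"


class TestLasso:
    def test_huge_penalty_selects_nothing_then_falls_back(self, rng):
        x = pd.DataFrame(rng.normal(size=(80, 5)),
                         columns=[f"f{i}" for i in range(5)])
        y = rng.integers(0, 2, 80)
        y[:3], y[-3:] = 0, 1
        with pytest.warns(UserWarning, match="falling back"):
            selected, c = lasso_select(x, y, cs=(1e-6,), seed=0)
        assert c == 1e-6

    def test_weak_penalty_matches_unpenalized_fit(self, rng):
        from sklearn.linear_model import LogisticRegression

        x = rng.normal(size=(500, 3))
        beta = np.array([1.0, -0.5, 0.25])
        y = (x @ beta + rng.normal(size=500) * 0.5 > 0).astype(int)
        l1 = LogisticRegression(l1_ratio=1.0, C=1e8, solver="liblinear",
                                max_iter=20000, tol=1e-10).fit(x, y)
        free = LogisticRegression(C=1e8, solver="lbfgs",
                                  max_iter=20000, tol=1e-10).fit(x, y)
        np.testing.assert_allclose(l1.coef_, free.coef_, atol=1e-4)

    def test_planted_signal_recovered(self):
        hits = 0
        for seed in range(5):
            r = np.random.default_rng(seed)
            x = r.normal(size=(400, 53))
            beta = np.zeros(53)
            beta[[3, 17, 40]] = 1.2
            y = (x @ beta + r.normal(size=400) > 0).astype(int)
            df = pd.DataFrame(x, columns=[f"f{i}" for i in range(53)])
            selected, _ = lasso_select(df, y, seed=seed)
            hits += {"f3", "f17", "f40"} <= set(selected)
        assert hits >= 4


class TestTrainedClassifier:
    @pytest.fixture(scope="class")
    def trained(self):
        tab = generate_feature_table(n_per_grade=40, signal="both", seed=3)
        y = binary_labels(tab["grade"], "model1").to_numpy()
        cols = [c for c in tab.columns if c.startswith(("WVOI__", "H1__"))]
        return tab, y, train_classifier(tab, y, cols, "clf", FAST, seed=0)

    def test_zero_features_give_intercept_probability(self, trained):
        tab, _, clf = trained
        row = tab.iloc[[0]].copy()
        # place the row exactly at the train feature means (z = 0)
        for f, m, s in zip(clf.preprocessor.features,
                           clf.preprocessor.mean, clf.preprocessor.sd):
            row[f] = m
        probs, _ = clf.predict(row)
        expected = 1 / (1 + np.exp(-clf.intercept))
        assert probs[0] == pytest.approx(expected, rel=1e-10)

    def test_probability_monotone_in_positive_coefficient(self, trained):
        tab, _, clf = trained
        j = int(np.argmax(np.abs(clf.coef)))
        feat = clf.selected_features[j]
        sign = np.sign(clf.coef[j])
        rows = pd.concat([tab.iloc[[0]]] * 5, ignore_index=True)
        base = float(tab[feat].median())
        spread = float(tab[feat].std())
        rows[feat] = base + sign * spread * np.arange(5) / 4
        probs, _ = clf.predict(rows)
        assert np.all(np.diff(probs) >= -1e-12)

    def test_hard_label_flips_at_threshold(self, trained):
        tab, y, clf = trained
        probs, labels = clf.predict(tab)
        np.testing.assert_array_equal(labels, probs >= clf.threshold)

    def test_missing_column_named_in_error(self, trained):
        tab, _, clf = trained
        with pytest.raises(ValueError, match="missing feature"):
            clf.predict(tab.drop(columns=clf.selected_features[:1]))


class TestTwoStep:
    @pytest.fixture(scope="class")
    def result(self):
        tab = generate_feature_table(n_per_grade=40, signal="habitat", seed=4)
        return tab, train_two_step(tab, FAST, seed=0)

    def test_total_pool_is_union_of_selections(self, result):
        _, res = result
        for model in ("model1", "model2"):
            clfs = res.classifiers[model]
            union = sorted(
                set(clfs["Clf_WVOI"].selected_features)
                | set(clfs["Clf_Habitats"].selected_features)
                | set(clfs["Clf_Clinical"].selected_features)
            )
            assert sorted(clfs["Clf_Total"].selected_features) == union

    def test_model2_uses_only_low_grades(self, result):
        tab, res = result
        split = res.splits["model2"]
        grades = tab.set_index("subject_id")["grade"]
        assert all(grades[list(split.train_ids)] < 3)
        assert all(grades[list(split.test_ids)] < 3)

    def test_training_ignores_test_rows(self):
        """Perturbing test-set feature values must not change the model."""
        tab = generate_feature_table(n_per_grade=25, signal="both", seed=6)
        res1 = train_two_step(tab, FAST, seed=1)
        tampered = tab.copy()
        test_ids = set(res1.splits["model1"].test_ids) & set(
            res1.splits["model2"].test_ids
        )
        rows = tampered["subject_id"].isin(test_ids)
        cols = [c for c in tab.columns if "__" in c]
        tampered.loc[rows, cols] += 1000.0
        res2 = train_two_step(tampered, FAST, seed=1)
        for model in ("model1", "model2"):
            for name in res1.classifiers[model]:
                np.testing.assert_array_equal(
                    res1.classifiers[model][name].coef,
                    res2.classifiers[model][name].coef,
                )

    def test_bit_reproducible_given_seed(self):
        tab = generate_feature_table(n_per_grade=20, signal="both", seed=8)
        r1 = train_two_step(tab, FAST, seed=9)
        r2 = train_two_step(tab, FAST, seed=9)
        for model in r1.classifiers:
            for name, clf in r1.classifiers[model].items():
                other = r2.classifiers[model][name]
                assert clf.selected_features == other.selected_features
                np.testing.assert_array_equal(clf.coef, other.coef)
                assert clf.threshold == other.threshold

    def test_null_labels_give_chance_auc(self):
        """With shuffled grades the test AUC stays near 0.5."""
        aucs = []
        for seed in range(5):
            tab = generate_feature_table(n_per_grade=50, signal="none",
                                         seed=seed)
            r = np.random.default_rng(seed)
            tab["grade"] = r.permutation(tab["grade"].to_numpy())
            tab[CLINICAL_NULL] = r.normal(size=(len(tab), len(CLINICAL_NULL)))
            res = train_two_step(tab, FAST, seed=seed)
            rep = evaluate_two_step(res, tab)
            m = rep.metrics
            aucs += list(
                m[(m.split == "test") & (m.model == "model1")]["AUC"]
            )
        assert 0.35 <= np.mean(aucs) <= 0.65


CLINICAL_NULL = list(
    generate_feature_table(n_per_grade=2, seed=0).columns[-13:]
)
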