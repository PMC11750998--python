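import numpy as np
import pandas as pd
import pytest

from nirscreen.connectivity import FCMatrixSet, fc_feature_names
from nirscreen.montage import N_ROIS
from nirscreen.rusboost import RUSBoostClassifier
from nirscreen.screening import (
    MODEL_NAMES,
    ReducerConfig,
    ScreeningModel,
    build_feature_table,
    delong_ci,
    evaluate_predictions,
    fit_fold,
    make_folds,
    permutation_eacc,
    run_task,
)
from nirscreen.synth import SCORE_COLUMNS, generate_scores


def _fc_set(rng, n_rois=N_ROIS):
    mats = {}
    for est in ("coh", "plv"):
        mats[est] = {}
        for ch in ("hbo", "hbr", "hbt"):
            a = rng.uniform(0, 1, size=(n_rois, n_rois))
            m = (a + a.T) / 2
            np.fill_diagonal(m, 1.0)
            mats[est][ch] = m
    return FCMatrixSet(matrices=mats)


def _scores_frame(ids, groups, rng):
    rows = []
    for sid, g in zip(ids, groups):
        row = generate_scores(g, 1, seed=rng.integers(2**31)).iloc[0].to_dict()
        row.update({"subject_id": sid, "group": g})
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def feature_table():
    rng = np.random.default_rng(0)
    groups = ["NC"] * 12 + ["SCD"] * 12 + ["MCI"] * 12
    ids = [f"S{i:03d}" for i in range(36)]
    fc = {sid: _fc_set(rng) for sid in ids}
    scores = _scores_frame(ids, groups, rng)
    return build_feature_table(fc, scores, include_scores=True)


class TestFeatureTable:
    def test_fc_only_has_270_columns(self):
        rng = np.random.default_rng(1)
        fc = {f"S{i}": _fc_set(rng) for i in range(4)}
        df = build_feature_table(fc)
        fc_cols = [c for c in df.columns if c != "subject_id"]
        assert len(fc_cols) == 270

    def test_with_scores_adds_six_columns(self, feature_table):
        fc_cols = [
            c for c in feature_table.columns
            if c not in {"subject_id", "group", *SCORE_COLUMNS}
        ]
        assert len(fc_cols) == 270
        assert all(c in feature_table.columns for c in SCORE_COLUMNS)

    def test_toy_three_roi_table(self):
        rng = np.random.default_rng(2)
        fc = {"A": _fc_set(rng, 3), "B": _fc_set(rng, 3)}
        df = build_feature_table(fc)
        assert df.shape == (2, 1 + 2 * 3 * 3)  # id + 2 est * 3 chrom * 3 pairs

    def test_misaligned_ids_rejected(self):
        rng = np.random.default_rng(3)
        fc = {"A": _fc_set(rng)}
        scores = _scores_frame(["B"], ["NC"], rng)
        with pytest.raises(ValueError, match="A"):
            build_feature_table(fc, scores, include_scores=True)


class TestFolds:
    def test_balanced_classes_split_evenly(self):
        labels = np.array(["a"] * 5 + ["b"] * 5)
        folds = make_folds(labels, 5, seed=0)
        for f in range(5):
            test = labels[folds == f]
            assert sorted(test) == ["a", "b"]

    def test_every_subject_tested_once(self):
        labels = np.repeat(["x", "y"], 13)
        folds = make_folds(labels, 5, seed=1)
        assert folds.shape == (26,)
        assert set(folds) == set(range(5))

    def test_deterministic_given_seed(self):
        labels = np.repeat(["x", "y"], 20)
        assert np.array_equal(
            make_folds(labels, 10, seed=5), make_folds(labels, 10, seed=5)
        )

    def test_k_larger_than_class_rejected(self):
        with pytest.raises(ValueError):
            make_folds(np.array(["a", "a", "b", "b", "b"]), 3, seed=0)


class TestFitFold:
    def test_transformed_features_standardized(self):
        rng = np.random.default_rng(4)
        X = rng.normal(5, 3, size=(40, 6))
        y = np.array(["p", "n"] * 20)
        pipe = fit_fold(X, y, "LDA", ReducerConfig(pca_variance=0.0))
        Z = (X[:, pipe.kept] - pipe.mean) / pipe.sd
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(Z.std(axis=0), 1, atol=1e-10)

    def test_variance_threshold_boundary(self):
        rng = np.random.default_rng(5)
        n = 400
        cols = {
            0.5: rng.normal(0, np.sqrt(0.5), n),
            1.0: rng.normal(0, 1.0, n),
            2.0: rng.normal(0, np.sqrt(2.0), n),
        }
        X = np.column_stack([v - v.mean() for v in cols.values()])
        # force exact sample variances
        X /= X.std(axis=0)
        X *= np.sqrt(np.array([0.5, 1.0, 2.0]))
        y = np.array(["p", "n"] * (n // 2))
        pipe = fit_fold(X, y, "LDA", ReducerConfig(pca_variance=0.0))
        assert pipe.kept.tolist() == [False, False, True]  # <=1 removed

    def test_all_removed_raises_by_default(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(0, 1, size=(30, 5))  # variance << 1
        y = np.array(["p", "n"] * 15)
        with pytest.raises(ValueError, match="variance"):
            fit_fold(X, y, "LDA")

    def test_all_removed_keep_all_fallback(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 1, size=(30, 5))
        y = np.array(["p", "n"] * 15)
        with pytest.warns(UserWarning):
            pipe = fit_fold(X, y, "LDA", ReducerConfig(on_empty="keep_all"))
        assert pipe.kept.all()

    def test_correlated_features_collapse_in_pca(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 3, size=200)
        X = np.column_stack([a, 2 * a + 1])
        y = np.array(["p", "n"] * 100)
        pipe = fit_fold(
            X, y, "LDA", ReducerConfig(variance_threshold=0.0, pca_variance=0.99)
        )
        assert pipe.pca.n_components_ == 1

    def test_no_leakage_transforms_depend_on_train_only(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0, 2, size=(60, 8))
        y = np.array(["p", "n"] * 30)
        pipe1 = fit_fold(X[:40], y[:40], "LDA", ReducerConfig(pca_variance=0.9))
        pipe2 = fit_fold(X[:40], y[:40], "LDA", ReducerConfig(pca_variance=0.9))
        assert np.array_equal(pipe1.kept, pipe2.kept)
        assert np.array_equal(pipe1.mean, pipe2.mean)
        # test rows never enter the transform: applying to wildly perturbed
        # test data uses identical statistics
        t1 = pipe1.transform(X[40:])
        t2 = pipe2.transform(X[40:])
        assert np.array_equal(t1, t2)
        perturbed = X[40:] * 100 + 7
        assert np.allclose(
            pipe1.transform(perturbed),
            (perturbed[:, pipe1.kept] - pipe1.mean) / pipe1.sd @ pipe1.pca.components_.T,
        )


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array(["p"] * 5 + ["n"] * 5)
        s = np.array([1.0] * 5 + [0.0] * 5)
        m = evaluate_predictions(y, y, s, "p")
        assert m["ACC"] == m["SEN"] == m["SPC"] == m["AUC"] == 1.0

    def test_confusion_arithmetic_example(self):
        # TP=3, FN=1, TN=2, FP=2
        y_true = np.array(["p", "p", "p", "p", "n", "n", "n", "n"])
        y_pred = np.array(["p", "p", "p", "n", "p", "p", "n", "n"])
        score = np.linspace(1, 0, 8)
        m = evaluate_predictions(y_true, y_pred, score, "p")
        assert m["ACC"] == pytest.approx(0.625)
        assert m["SEN"] == pytest.approx(0.75)
        assert m["SPC"] == pytest.approx(0.5)

    def test_all_positive_predictor(self):
        y_true = np.array(["p"] * 3 + ["n"] * 7)
        y_pred = np.array(["p"] * 10)
        m = evaluate_predictions(y_true, y_pred, np.linspace(0, 1, 10), "p")
        assert m["SEN"] == 1.0 and m["SPC"] == 0.0
        assert m["ACC"] == pytest.approx(0.3)

    def test_constant_scores_degenerate_auc(self):
        y = np.array(["p", "p", "n", "n"])
        with pytest.warns(UserWarning):
            m = evaluate_predictions(y, y, np.zeros(4), "p")
        assert m["AUC"] == 0.5

    def test_auc_matches_exhaustive_pairwise_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(1000):
            m = int(rng.integers(2, 7))
            n = int(rng.integers(2, 7))
            pos = rng.integers(0, 5, size=m).astype(float)  # ties likely
            neg = rng.integers(0, 5, size=n).astype(float)
            auc, lo, hi = delong_ci(pos, neg)
            wins = sum(
                1.0 if a > b else (0.5 if a == b else 0.0)
                for a in pos for b in neg
            )
            assert auc == pytest.approx(wins / (m * n), abs=1e-12)
            assert lo <= auc <= hi

    def test_ci_bounds_ordering(self):
        rng = np.random.default_rng(11)
        auc, lo, hi = delong_ci(rng.normal(1, 1, 40), rng.normal(0, 1, 40))
        assert 0 <= lo <= auc <= hi <= 1


class TestRunTask:
    def _separable(self, n=20):
        rng = np.random.default_rng(12)
        X = rng.normal(0, 0.3, size=(2 * n, 5))
        X[:n, 0] += 5.0
        df = pd.DataFrame(X, columns=[f"f{i}" for i in range(5)])
        df["group"] = ["MCI"] * n + ["NC"] * n
        df["subject_id"] = [f"S{i}" for i in range(2 * n)]
        return df

    def test_separable_data_perfect_accuracy(self):
        df = self._separable()
        red = ReducerConfig(variance_threshold=0.0)
        preds = run_task(df, ("MCI", "NC"), ("LDA", "LR", "SVM"), k=5,
                         seed=0, reducer=red)
        for name in ("LDA", "LR", "SVM"):
            r = preds[name]
            assert np.mean(r["y_true"] == r["y_pred"]) == 1.0

    def test_pooled_out_of_fold_coverage(self):
        df = self._separable()
        red = ReducerConfig(variance_threshold=0.0)
        preds = run_task(df, ("MCI", "NC"), ("LDA",), k=5, seed=0, reducer=red)
        r = preds["LDA"]
        assert len(r["y_true"]) == len(df)
        assert not np.isnan(r["y_score"]).any()

    def test_deterministic_given_seed(self):
        df = self._separable()
        red = ReducerConfig(variance_threshold=0.0)
        a = run_task(df, ("MCI", "NC"), ("RF",), k=5, seed=3, reducer=red)["RF"]
        b = run_task(df, ("MCI", "NC"), ("RF",), k=5, seed=3, reducer=red)["RF"]
        assert np.array_equal(a["y_pred"], b["y_pred"])
        assert np.array_equal(a["y_score"], b["y_score"])

    def test_uninformative_features_near_chance(self):
        rng = np.random.default_rng(13)
        accs = []
        red = ReducerConfig(variance_threshold=0.0)
        for s in range(20):
            X = rng.normal(size=(40, 6))
            df = pd.DataFrame(X, columns=[f"f{i}" for i in range(6)])
            df["group"] = ["MCI"] * 20 + ["NC"] * 20
            r = run_task(df, ("MCI", "NC"), ("LDA",), k=5, seed=s, reducer=red)["LDA"]
            accs.append(np.mean(r["y_true"] == r["y_pred"]))
        assert abs(np.mean(accs) - 0.5) < 0.07


class TestEacc:
    def test_balanced_uninformative_eacc_near_half(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(40, 5))
        df = pd.DataFrame(X, columns=[f"f{i}" for i in range(5)])
        df["group"] = ["MCI"] * 20 + ["NC"] * 20
        eacc = permutation_eacc(
            df, ("MCI", "NC"), "LDA", k=5, n_perm=200, seed=0,
            reducer=ReducerConfig(variance_threshold=0.0),
        )
        assert eacc == pytest.approx(0.5, abs=0.03)

    def test_imbalanced_majority_learner_eacc(self):
        from sklearn.dummy import DummyClassifier

        rng = np.random.default_rng(15)
        n_mci, n_nc = 90, 48
        X = rng.normal(size=(n_mci + n_nc, 4))
        df = pd.DataFrame(X, columns=[f"f{i}" for i in range(4)])
        df["group"] = ["MCI"] * n_mci + ["NC"] * n_nc
        eacc = permutation_eacc(
            df, ("MCI", "NC"), DummyClassifier(strategy="most_frequent"),
            k=5, n_perm=5, seed=1,
            reducer=ReducerConfig(variance_threshold=0.0),
        )
        assert eacc == pytest.approx(n_mci / (n_mci + n_nc), abs=0.02)

    def test_single_permutation_reproducible(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(20, 3))
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["group"] = ["MCI"] * 10 + ["NC"] * 10
        red = ReducerConfig(variance_threshold=0.0)
        e1 = permutation_eacc(df, ("MCI", "NC"), "LDA", k=5, n_perm=1,
                              seed=2, reducer=red)
        e2 = permutation_eacc(df, ("MCI", "NC"), "LDA", k=5, n_perm=1,
                              seed=2, reducer=red)
        assert e1 == e2


class TestRusboost:
    def test_learns_separable_data(self):
        rng = np.random.default_rng(17)
        X = np.vstack([rng.normal(-2, 1, (40, 3)), rng.normal(2, 1, (20, 3))])
        y = np.array(["a"] * 40 + ["b"] * 20)
        clf = RUSBoostClassifier(random_state=0).fit(X, y)
        assert (clf.predict(X) == y).mean() > 0.9

    def test_balanced_sensitivity_under_imbalance(self):
        rng = np.random.default_rng(18)
        X = np.vstack([rng.normal(-1, 1, (100, 2)), rng.normal(1, 1, (15, 2))])
        y = np.array(["maj"] * 100 + ["min"] * 15)
        clf = RUSBoostClassifier(random_state=1).fit(X, y)
        pred = clf.predict(X)
        minority_recall = (pred[y == "min"] == "min").mean()
        assert minority_recall > 0.6

    def test_proba_normalized(self):
        rng = np.random.default_rng(19)
        X = rng.normal(size=(30, 2))
        y = np.array(["a", "b"] * 15)
        clf = RUSBoostClassifier(random_state=2).fit(X, y)
        p = clf.predict_proba(X)
        assert np.allclose(p.sum(axis=1), 1.0)


class TestScreeningModel:
    def test_report_enumerates_tasks_and_models(self, feature_table):
        model = ScreeningModel(
            feature_table,
            models=MODEL_NAMES,
            fold_schemes=(5,),
            feature_sets=("fc_plus_neuro",),
        )
        res = model.fit(n_perm=1, seed=0)
        assert len(res.report) == 3 * 9
        assert set(res.report["model"]) == set(MODEL_NAMES)
        assert set(res.report["fold_scheme"]) == {5}
        metrics = res.report[["ACC", "EACC", "SPC", "SEN", "AUC"]]
        assert ((metrics >= 0) & (metrics <= 1)).all().all()
        assert (res.report["CI_low"] <= res.report["AUC"] + 1e-12).all()
        assert (res.report["AUC"] <= res.report["CI_high"] + 1e-12).all()
        assert "Cross-validated screening report" in res.summary()

    def test_scores_lift_auc_when_informative(self):
        # FC features weakly informative, neuropsych scores strongly so:
        # adding scores should raise AUC for the linear models in most seeds
        wins = {"LDA": 0, "LR": 0, "SVM": 0}
        n_seeds = 10
        for s in range(n_seeds):
            rng = np.random.default_rng(300 + s)
            n = 24
            groups = ["MCI"] * n + ["NC"] * n
            ids = [f"S{i}" for i in range(2 * n)]
            fc = {sid: _fc_set(rng) for sid in ids}
            scores = _scores_frame(ids, groups, rng)
            df = build_feature_table(fc, scores, include_scores=True)
            for name in wins:
                aucs = {}
                for fset, inc in (("fc_only", False), ("fc_plus_neuro", True)):
                    r = run_task(df, ("MCI", "NC"), (name,), k=5, seed=s,
                                 include_scores=inc,
                                 reducer=ReducerConfig(on_empty="keep_all"))[name]
                    aucs[fset] = evaluate_predictions(
                        r["y_true"], r["y_pred"], r["y_score"], "MCI"
                    )["AUC"]
                wins[name] += aucs["fc_plus_neuro"] >= aucs["fc_only"]
        for name, w in wins.items():
            assert w >= int(0.8 * n_seeds), (name, wins)
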