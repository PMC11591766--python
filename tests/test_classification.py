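"""Hold-out splitting, the seven-metric report and the experiment driver."""

import numpy as np
import pandas as pd
import pytest

from braintex.classification import (
    DEFAULT_PLANE_SETS,
    ExperimentConfig,
    FS_CLASSIFIERS,
    SplitError,
    SplitSpec,
    build_classifier_grid,
    compute_metrics,
    evaluate,
    holdout_split,
    multiclass_metrics,
    run_experiment,
)
from braintex.dataset_assembly import SliceFeatures, assemble


def separable_matrix(n_per_group=20, groups=("CN", "AD"), planes=("axial",),
                     shift=3.0, seed=0):
    """Assembled matrix whose group means differ by ``shift`` in many columns."""
    rng = np.random.default_rng(seed)
    feats = []
    for gi, g in enumerate(groups):
        for s in range(n_per_group):
            sid = f"{g}{s:02d}"
            for plane in planes:
                for k in range(8):
                    vals = rng.normal(size=(22, 4)) + gi * shift
                    feats.append(SliceFeatures(sid, g, plane, k, vals))
    return assemble(feats, plane_set=planes)


class TestHoldoutSplit:
    def test_80_20_counts(self):
        X = pd.DataFrame(np.arange(200).reshape(100, 2))
        y = ["a"] * 50 + ["b"] * 50
        Xtr, Xte, ytr, yte = holdout_split(X, y, SplitSpec(0.8, seed=0))
        assert len(Xtr) == 80 and len(Xte) == 20
        assert set(Xtr.index).isdisjoint(Xte.index)
        assert len(Xtr) + len(Xte) == 100

    def test_stratified_counting_oracle(self):
        X = pd.DataFrame(np.zeros((100, 1)))
        y = ["A"] * 60 + ["B"] * 40
        Xtr, Xte, ytr, yte = holdout_split(X, y, SplitSpec(0.8, seed=1))
        assert np.sum(np.asarray(ytr) == "A") == 48
        assert np.sum(np.asarray(ytr) == "B") == 32

    def test_same_seed_identical(self):
        X = pd.DataFrame(np.random.default_rng(2).normal(size=(50, 3)))
        y = ["a"] * 25 + ["b"] * 25
        s1 = holdout_split(X, y, SplitSpec(0.8, seed=5))
        s2 = holdout_split(X, y, SplitSpec(0.8, seed=5))
        assert list(s1[0].index) == list(s2[0].index)
        assert list(s1[1].index) == list(s2[1].index)

    def test_tiny_class_rejected(self):
        X = pd.DataFrame(np.zeros((3, 1)))
        with pytest.raises(SplitError):
            holdout_split(X, ["a", "a", "b"], SplitSpec(0.8, seed=0))

    def test_train_fraction_validated(self):
        with pytest.raises(ValueError):
            SplitSpec(train_fraction=1.0)


class TestComputeMetrics:
    def test_worked_example_counts_3_4_1_2(self):
        m = compute_metrics(tp=3, tn=4, fp=1, fn=2)
        assert round(m["accuracy"], 1) == 70.0
        assert round(m["precision"], 1) == 75.0
        assert round(m["recall"], 1) == 60.0
        assert round(m["specificity"], 1) == 80.0
        assert round(m["f1"], 1) == 66.7
        assert round(m["gmean"], 1) == 69.3

    def test_perfect_counts(self):
        m = compute_metrics(tp=10, tn=10, fp=0, fn=0)
        assert all(m[k] == 100.0 for k in m)

    def test_degenerate_majority_predictor(self):
        m = compute_metrics(tp=0, tn=10, fp=0, fn=10)
        assert m["accuracy"] == 50.0 and m["recall"] == 0.0
        assert m["gmean"] == 0.0 and m["precision"] == 0.0

    def test_gmean_precision_specificity_variant(self):
        m = compute_metrics(tp=16, tn=52, fp=0, fn=1,
                            gmean_variant="precision-specificity")
        # recall 94.1, specificity 100 -> the variant uses precision instead
        assert m["gmean"] == pytest.approx(100.0 * np.sqrt(1.0 * 1.0))
        m2 = compute_metrics(tp=16, tn=52, fp=0, fn=1)
        assert m2["gmean"] == pytest.approx(100.0 * np.sqrt((16 / 17) * 1.0))

    def test_identities_on_random_counts(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            tp, tn, fp, fn = rng.integers(0, 30, size=4)
            if tp + tn + fp + fn == 0:
                continue
            m = compute_metrics(tp, tn, fp, fn)
            assert m["accuracy"] == pytest.approx(
                100.0 * (tp + tn) / (tp + tn + fp + fn), abs=1e-9)
            p, r = m["precision"] / 100, m["recall"] / 100
            if p + r > 0:
                assert m["f1"] == pytest.approx(100.0 * 2 * p * r / (p + r), abs=1e-9)
            assert (m["gmean"] / 100) ** 2 == pytest.approx(
                (m["recall"] / 100) * (m["specificity"] / 100), abs=1e-9)


class TestMulticlassMetrics:
    def test_weighted_recall_equals_accuracy(self):
        y_true = ["a", "a", "b", "b", "c", "c"]
        y_pred = ["a", "a", "b", "c", "c", "a"]  # recalls 1.0, 0.5, 0.5
        m, counts = multiclass_metrics(y_true, y_pred, ["a", "b", "c"])
        assert m["recall"] == pytest.approx(m["accuracy"], abs=1e-9)
        assert m["accuracy"] == pytest.approx(100.0 * 4 / 6, abs=1e-9)
        assert counts["a"]["TP"] == 2

    def test_random_confusions_keep_identity(self):
        rng = np.random.default_rng(4)
        classes = ["CN", "MCI", "AD"]
        for _ in range(20):
            y_true = rng.choice(classes, size=30)
            y_pred = rng.choice(classes, size=30)
            m, _ = multiclass_metrics(y_true, y_pred, classes)
            assert m["recall"] == pytest.approx(m["accuracy"], abs=1e-9)


class TestClassifierGrid:
    def test_grid_membership_and_hyperparameters(self):
        grid = build_classifier_grid(seed=0)
        assert len(grid) == 17
        assert set(FS_CLASSIFIERS) <= set(grid)
        assert grid["ExTreeC"]().n_estimators == 300
        rf = grid["RF"]()
        assert (rf.max_depth, rf.n_estimators, rf.max_features) == (5, 300, 1)
        mlp = grid["MLP"]()
        assert mlp.alpha == 1.0 and mlp.max_iter == 1000
        sgd = grid["SGD"]()
        assert sgd.max_iter == 100 and sgd.tol == 1e-3
        assert grid["DeTreeC"]().max_depth == 5
        assert grid["LogRegCV"]().cv == 3
        assert grid["LogReg"]().solver == "lbfgs"


class TestEvaluate:
    def _split(self, m, seed=0):
        return holdout_split(m.data, m.groups, SplitSpec(0.8, seed))

    def test_perfect_classifier_on_separable_data(self):
        m = separable_matrix(shift=5.0, seed=5)
        Xtr, Xte, ytr, yte = self._split(m)
        grid = build_classifier_grid(0)
        rep = evaluate("LogReg", grid["LogReg"], Xtr, ytr, Xte, yte,
                       positive_label="AD", pair="CN_vs_AD", plane_set="axial")
        assert rep.metrics["accuracy"] == 100.0
        assert rep.metrics["f1"] == 100.0
        assert rep.metrics["auc"] == 100.0
        assert rep.counts["TP"] + rep.counts["FN"] == np.sum(np.asarray(yte) == "AD")

    def test_positive_class_is_second_named(self):
        m = separable_matrix(n_per_group=15, shift=5.0, seed=6)
        Xtr, Xte, ytr, yte = self._split(m)
        grid = build_classifier_grid(0)
        rep = evaluate("DeTreeC", grid["DeTreeC"], Xtr, ytr, Xte, yte,
                       positive_label="AD")
        n_pos = int(np.sum(np.asarray(yte) == "AD"))
        assert rep.counts["TP"] + rep.counts["FN"] == n_pos
        assert rep.counts["TN"] + rep.counts["FP"] == len(yte) - n_pos

    def test_feature_subset_restricts_columns(self):
        m = separable_matrix(seed=7)
        Xtr, Xte, ytr, yte = self._split(m)
        grid = build_classifier_grid(0)
        rep = evaluate("LogReg", grid["LogReg"], Xtr, ytr, Xte, yte,
                       subset=np.arange(10))
        assert rep.n_features_used == 10

    def test_single_class_training_fold_rejected(self):
        m = separable_matrix(seed=8)
        Xtr, Xte, ytr, yte = self._split(m)
        grid = build_classifier_grid(0)
        with pytest.raises(ValueError, match="single-class"):
            evaluate("LogReg", grid["LogReg"], Xtr, np.array(["CN"] * len(ytr)),
                     Xte, yte)


class TestRunExperiment:
    def test_no_fs_report_layout(self):
        m = separable_matrix(seed=9)
        ec = ExperimentConfig(pairs=(("CN", "AD"),), plane_sets=(("axial",),),
                              classifiers=("LogReg", "DeTreeC"), seed=1)
        best, sweep = run_experiment(m, ec)
        assert list(best.columns) == ["pair", "plane_set", "n_features",
                                      "classifier", "accuracy", "recall",
                                      "precision", "specificity", "f1", "auc",
                                      "gmean"]
        assert len(best) == 1 and len(sweep) == 2
        assert best["n_features"].iloc[0] == 704
        assert best["accuracy"].iloc[0] == sweep["accuracy"].max()

    def test_fs_mode_sweeps_and_includes_k_max(self):
        m = separable_matrix(n_per_group=15, seed=10)
        ec = ExperimentConfig(pairs=(("CN", "AD"),), plane_sets=(("axial",),),
                              feature_selection=True, classifiers=("LogReg",),
                              k_stride=100, seed=2)
        best, sweep = run_experiment(m, ec)
        assert sweep["n_features"].max() == 703  # k_max = columns - 1
        assert sweep["n_features"].min() == 2
        assert "n_features" in best.columns and len(best) == 1

    def test_multiclass_accuracy_equals_weighted_recall(self):
        m = separable_matrix(n_per_group=12, groups=("CN", "MCI", "AD"),
                             shift=2.0, seed=11)
        ec = ExperimentConfig(pairs=(("CN", "MCI", "AD"),),
                              plane_sets=(("axial",),),
                              classifiers=("DeTreeC",), seed=3)
        best, sweep = run_experiment(m, ec)
        assert best["pair"].iloc[0] == "all_vs_all"
        assert best["accuracy"].iloc[0] == pytest.approx(best["recall"].iloc[0],
                                                         abs=1e-9)

    def test_reproducible_given_seed(self):
        m = separable_matrix(seed=12)
        ec = ExperimentConfig(pairs=(("CN", "AD"),), plane_sets=(("axial",),),
                              classifiers=("LogReg", "DeTreeC"), seed=4)
        b1, s1 = run_experiment(m, ec)
        b2, s2 = run_experiment(m, ec)
        pd.testing.assert_frame_equal(b1, b2)
        pd.testing.assert_frame_equal(s1, s2)

    def test_nested_selection_variant_runs(self):
        m = separable_matrix(n_per_group=20, seed=13)
        ec = ExperimentConfig(pairs=(("CN", "AD"),), plane_sets=(("axial",),),
                              feature_selection=True, classifiers=("LogReg",),
                              k_stride=200, select_k_by="nested", seed=5)
        best, sweep = run_experiment(m, ec)
        assert len(best) == 1
        assert best["n_features"].iloc[0] in set(sweep["n_features"])

    def test_split_safe_scaling_variant_runs(self):
        m = separable_matrix(seed=14)
        ec = ExperimentConfig(pairs=(("CN", "AD"),), plane_sets=(("axial",),),
                              classifiers=("LogReg",), split_safe_scaling=True,
                              seed=6)
        best, _ = run_experiment(m, ec)
        assert best["accuracy"].iloc[0] == 100.0
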