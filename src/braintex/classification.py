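"""Hold-out classifier benchmarking with the seven-metric report.

The evaluation protocol is a single stratified 80/20 hold-out split per
comparison.  Binary comparisons treat the second-named group of the pair as
the positive class (AD in CN-vs-AD; MCI in AD-vs-MCI and CN-vs-MCI).  The
three-class "all-vs-all" task reports class-frequency-weighted one-vs-rest
metrics, under which weighted recall coincides with accuracy.

Metrics (reported as percentages): accuracy, precision, recall (sensitivity),
specificity TN/(TN+FP), F1, Gmean and ROC AUC.  The default Gmean is
sqrt(recall * specificity); a ``precision-specificity`` variant is available
because some published tables follow that convention instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.ensemble import (
    AdaBoostClassifier,
    BaggingClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.gaussian_process.kernels import RBF
from sklearn.linear_model import (
    LogisticRegression,
    LogisticRegressionCV,
    SGDClassifier,
)
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.multiclass import OneVsRestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import LinearSVC
from sklearn.tree import DecisionTreeClassifier

from braintex.dataset_assembly import (
    SubjectFeatureMatrix,
    fit_column_scaler,
    zscore_columns,
)
from braintex.feature_selection import fscore, incremental_subsets

METRIC_NAMES = ("accuracy", "recall", "precision", "specificity", "f1", "auc", "gmean")

#: classifiers retained for the feature-selection stage
FS_CLASSIFIERS = ("LinSVC", "OvsR", "ExTreeC", "LogRegCV", "LogReg", "BaggC", "DeTreeC")


class SplitError(ValueError):
    """The requested hold-out split leaves a class absent from one side."""


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class EvaluationReport:
    pair: str
    plane_set: str
    classifier: str
    n_features_used: int
    counts: dict
    metrics: dict  # percentage scale


def build_classifier_grid(seed: int = 0) -> dict[str, Callable[[], object]]:
    """Factories for the 17 scikit-learn/LightGBM classifier configurations.

    Hyperparameters beyond those listed are toolkit defaults.  Stochastic
    learners take ``seed``; the one-vs-rest linear SVM is pinned to state 0.
    """
    return {
        "GauPro": lambda: GaussianProcessClassifier(kernel=1.0 * RBF(1.0),
                                                    random_state=seed),
        "LinSVC": lambda: LinearSVC(random_state=seed),
        "SGD": lambda: SGDClassifier(max_iter=100, tol=1e-3, random_state=seed),
        "KNN": lambda: KNeighborsClassifier(),
        "LogReg": lambda: LogisticRegression(solver="lbfgs", random_state=seed),
        "LogRegCV": lambda: LogisticRegressionCV(cv=3, random_state=seed),
        "BaggC": lambda: BaggingClassifier(random_state=seed),
        "ExTreeC": lambda: ExtraTreesClassifier(n_estimators=300, random_state=seed,
                                                n_jobs=1),
        "RF": lambda: RandomForestClassifier(max_depth=5, n_estimators=300,
                                             max_features=1, random_state=seed,
                                             n_jobs=1),
        "GauNB": lambda: GaussianNB(),
        "DeTreeC": lambda: DecisionTreeClassifier(max_depth=5, random_state=seed),
        "MLP": lambda: MLPClassifier(alpha=1.0, max_iter=1000, random_state=seed),
        "AdaBoost": lambda: AdaBoostClassifier(random_state=seed),
        "QuaDis": lambda: QuadraticDiscriminantAnalysis(),
        "OvsR": lambda: OneVsRestClassifier(LinearSVC(random_state=0)),
        "GradBoost": lambda: GradientBoostingClassifier(random_state=seed),
        "LGBM": lambda: LGBMClassifier(random_state=seed, verbose=-1, n_jobs=1),
    }


def holdout_split(matrix: pd.DataFrame, labels, spec: SplitSpec):
    """Single stratified train/test partition; returns (Xtr, Xte, ytr, yte)."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < 2):
        raise SplitError("every class needs >= 2 rows to split")
    Xtr, Xte, ytr, yte = train_test_split(
        matrix, y, train_size=spec.train_fraction, random_state=spec.seed,
        stratify=y if spec.stratified else None)
    for side, name in ((ytr, "train"), (yte, "test")):
        if np.unique(side).size < classes.size:
            raise SplitError(f"a class is absent from the {name} fold")
    return Xtr, Xte, ytr, yte


def _rate(num: float, den: float) -> float:
    """num/den with the 0/0 := 0 convention."""
    return num / den if den > 0 else 0.0


def compute_metrics(tp: int, tn: int, fp: int, fn: int,
                    gmean_variant: str = "recall-specificity") -> dict:
    """Binary confusion-count metrics on the percentage scale (AUC excluded)."""
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    total = tp + tn + fp + fn
    accuracy = _rate(tp + tn, total)
    precision = _rate(tp, tp + fp)
    recall = _rate(tp, tp + fn)
    specificity = _rate(tn, tn + fp)
    f1 = _rate(2 * precision * recall, precision + recall)
    if gmean_variant == "precision-specificity":
        gmean = np.sqrt(precision * specificity)
    elif gmean_variant == "recall-specificity":
        gmean = np.sqrt(recall * specificity)
    else:
        raise ValueError(f"unknown gmean_variant {gmean_variant!r}")
    return {
        "accuracy": 100.0 * accuracy,
        "recall": 100.0 * recall,
        "precision": 100.0 * precision,
        "specificity": 100.0 * specificity,
        "f1": 100.0 * f1,
        "gmean": 100.0 * gmean,
    }


def multiclass_metrics(y_true, y_pred, classes: Sequence,
                       gmean_variant: str = "recall-specificity") -> tuple[dict, dict]:
    """Class-frequency-weighted one-vs-rest metrics from a confusion matrix.

    Returns (metrics, per_class_counts).  Weighted recall equals accuracy by
    construction.
    """
    cm = confusion_matrix(y_true, y_pred, labels=list(classes))
    n = cm.sum()
    support = cm.sum(axis=1)
    weights = support / n
    per_metric = {k: 0.0 for k in ("recall", "precision", "specificity", "f1", "gmean")}
    counts = {}
    for idx, cls in enumerate(classes):
        tp = cm[idx, idx]
        fn = support[idx] - tp
        fp = cm[:, idx].sum() - tp
        tn = n - tp - fn - fp
        counts[str(cls)] = {"TP": int(tp), "TN": int(tn), "FP": int(fp), "FN": int(fn)}
        mm = compute_metrics(tp, tn, fp, fn, gmean_variant)
        for k in per_metric:
            per_metric[k] += weights[idx] * mm[k]
    out = {"accuracy": 100.0 * np.trace(cm) / n, **per_metric}
    return out, counts


def _score_matrix(model, X: pd.DataFrame, classes: Sequence) -> np.ndarray:
    """Per-class continuous scores for AUC: probabilities, decision values,
    or one-hot predicted-class indicators as a last resort."""
    if hasattr(model, "predict_proba"):
        return np.asarray(model.predict_proba(X))
    if hasattr(model, "decision_function"):
        s = np.asarray(model.decision_function(X))
        if s.ndim == 1:  # binary: score of the second class in model.classes_
            return np.column_stack([-s, s])
        return s
    pred = model.predict(X)
    return np.array([[1.0 if p == c else 0.0 for c in classes] for p in pred])


def _weighted_ovr_auc(y_true, scores: np.ndarray, model_classes: Sequence,
                      classes: Sequence) -> float:
    y = np.asarray(y_true)
    col = {c: i for i, c in enumerate(model_classes)}
    aucs, weights = [], []
    for cls in classes:
        ind = (y == cls).astype(int)
        if ind.min() == ind.max():
            continue
        aucs.append(roc_auc_score(ind, scores[:, col[cls]]))
        weights.append(ind.sum())
    if not aucs:
        return 0.0
    return float(np.average(aucs, weights=weights))


def evaluate(classifier_name: str, make_model: Callable[[], object],
             Xtr: pd.DataFrame, ytr, Xte: pd.DataFrame, yte,
             subset: np.ndarray | None = None,
             positive_label=None, pair: str = "", plane_set: str = "",
             gmean_variant: str = "recall-specificity") -> EvaluationReport:
    """Fit one classifier on (a column subset of) the training fold and fill
    the confusion counts plus all seven metrics on the test fold."""
    ytr = np.asarray(ytr)
    yte = np.asarray(yte)
    if np.unique(ytr).size < 2:
        raise ValueError("degenerate single-class training fold")
    if subset is not None:
        Xtr = Xtr.iloc[:, subset]
        Xte = Xte.iloc[:, subset]
    model = make_model()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", FutureWarning)
        model.fit(Xtr, ytr)
        pred = model.predict(Xte)
        classes = sorted(np.unique(np.concatenate([ytr, yte])))
        scores = _score_matrix(model, Xte, classes)

    if len(classes) == 2:
        pos = positive_label if positive_label is not None else classes[1]
        neg = [c for c in classes if c != pos][0]
        tp = int(np.sum((yte == pos) & (pred == pos)))
        tn = int(np.sum((yte == neg) & (pred == neg)))
        fp = int(np.sum((yte == neg) & (pred == pos)))
        fn = int(np.sum((yte == pos) & (pred == neg)))
        metrics = compute_metrics(tp, tn, fp, fn, gmean_variant)
        pos_col = list(model.classes_).index(pos)
        ind = (yte == pos).astype(int)
        auc = roc_auc_score(ind, scores[:, pos_col]) if ind.min() != ind.max() else 0.0
        counts = {"TP": tp, "TN": tn, "FP": fp, "FN": fn}
    else:
        metrics, counts = multiclass_metrics(yte, pred, classes, gmean_variant)
        auc = _weighted_ovr_auc(yte, scores, list(model.classes_), classes)
    metrics["auc"] = 100.0 * auc
    return EvaluationReport(pair=pair, plane_set=plane_set,
                            classifier=classifier_name,
                            n_features_used=Xtr.shape[1],
                            counts=counts, metrics=metrics)


# --- experiment driver -------------------------------------------------------

DEFAULT_PAIRS = (("CN", "AD"), ("AD", "MCI"), ("CN", "MCI"), ("CN", "MCI", "AD"))
DEFAULT_PLANE_SETS = (("axial", "coronal", "sagittal"), ("axial",),
                      ("coronal",), ("sagittal",))


@dataclass
class ExperimentConfig:
    """Configuration of one full benchmarking run.

    ``feature_selection=False`` evaluates every classifier on the full column
    set; ``True`` sweeps F-score-ranked nested subsets (k_min .. k_max, thinned
    by ``k_stride``) for the feature-selection classifier subset.  ``k_max``
    defaults to columns-1.  ``select_k_by`` is "test" (best test accuracy per
    classifier — the published, optimistic protocol) or "nested" (k picked on
    an inner validation split of the training fold).
    """

    pairs: tuple = DEFAULT_PAIRS
    plane_sets: tuple = DEFAULT_PLANE_SETS
    feature_selection: bool = False
    classifiers: tuple | None = None
    k_min: int = 2
    k_max: int | None = None
    k_stride: int = 1
    seed: int = 0
    train_fraction: float = 0.8
    select_k_by: str = "test"
    split_safe_scaling: bool = False
    gmean_variant: str = "recall-specificity"


def _pair_label(pair: Sequence[str]) -> str:
    return "all_vs_all" if len(pair) > 2 else f"{pair[0]}_vs_{pair[1]}"


def _plane_label(plane_set: Sequence[str]) -> str:
    return "3planes" if len(plane_set) == 3 else plane_set[0]


def _report_row(rep: EvaluationReport) -> dict:
    row = {"pair": rep.pair, "plane_set": rep.plane_set,
           "n_features": rep.n_features_used, "classifier": rep.classifier}
    row.update({k: rep.metrics[k] for k in METRIC_NAMES})
    return row


def run_experiment(matrix: SubjectFeatureMatrix, config: ExperimentConfig,
                   out_dir: str | Path | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Benchmark the grid over pairs x plane-sets (x feature subsets).

    ``matrix`` is the assembled, *unscaled* feature matrix over all planes and
    subjects.  Returns ``(best, sweep)``: the per-(pair, plane-set) best-
    accuracy rows, and every evaluated cell.  With ``out_dir`` both tables are
    written as ``report_best.csv`` / ``report_sweep.csv`` with a fixed float
    format so identical configs yield byte-identical files.
    """
    grid = build_classifier_grid(config.seed)
    if config.classifiers is not None:
        names = list(config.classifiers)
    else:
        names = list(FS_CLASSIFIERS) if config.feature_selection else list(grid)
    unknown = [n for n in names if n not in grid]
    if unknown:
        raise ValueError(f"unknown classifiers: {unknown}")

    sweep_rows: list[dict] = []
    best_rows: list[dict] = []
    for pair in config.pairs:
        pair_lab = _pair_label(pair)
        positive = None if len(pair) > 2 else pair[1]
        for plane_set in config.plane_sets:
            plane_lab = _plane_label(plane_set)
            sub = matrix.subset_planes(plane_set).subset_groups(pair)
            spec = SplitSpec(config.train_fraction, config.seed)
            if config.split_safe_scaling:
                Xtr, Xte, ytr, yte = holdout_split(sub.data, sub.groups, spec)
                scale = fit_column_scaler(Xtr)
                Xtr, Xte = scale(Xtr), scale(Xte)
            else:
                scaled = zscore_columns(sub)
                Xtr, Xte, ytr, yte = holdout_split(scaled.data, scaled.groups, spec)

            cell_best: dict | None = None
            if not config.feature_selection:
                for name in names:
                    try:
                        rep = evaluate(name, grid[name], Xtr, ytr, Xte, yte,
                                       positive_label=positive, pair=pair_lab,
                                       plane_set=plane_lab,
                                       gmean_variant=config.gmean_variant)
                    except np.linalg.LinAlgError as exc:
                        # e.g. covariance-based models with features >> samples
                        warnings.warn(f"{name} failed on {pair_lab}/{plane_lab}: "
                                      f"{exc}; cell skipped")
                        continue
                    row = _report_row(rep)
                    sweep_rows.append(row)
                    if cell_best is None or row["accuracy"] > cell_best["accuracy"]:
                        cell_best = row
            else:
                ranking = fscore(Xtr, ytr)
                k_max = config.k_max if config.k_max is not None \
                    else Xtr.shape[1] - 1
                subsets = list(incremental_subsets(ranking, config.k_min,
                                                   k_max, config.k_stride))
                inner = None
                if config.select_k_by == "nested":
                    inner = holdout_split(Xtr, ytr,
                                          SplitSpec(0.75, config.seed))
                for name in names:
                    clf_rows = []
                    val_acc = []
                    for subset in subsets:
                        rep = evaluate(name, grid[name], Xtr, ytr, Xte, yte,
                                       subset=subset, positive_label=positive,
                                       pair=pair_lab, plane_set=plane_lab,
                                       gmean_variant=config.gmean_variant)
                        clf_rows.append(_report_row(rep))
                        if inner is not None:
                            iXtr, iXte, iytr, iyte = inner
                            irep = evaluate(name, grid[name], iXtr, iytr,
                                            iXte, iyte, subset=subset,
                                            positive_label=positive)
                            val_acc.append(irep.metrics["accuracy"])
                    sweep_rows.extend(clf_rows)
                    if config.select_k_by == "nested":
                        pick = clf_rows[int(np.argmax(val_acc))]
                    else:
                        pick = max(clf_rows, key=lambda r: r["accuracy"])
                    if cell_best is None or pick["accuracy"] > cell_best["accuracy"]:
                        cell_best = pick
            best_rows.append(cell_best)

    sweep = pd.DataFrame(sweep_rows)
    best = pd.DataFrame(best_rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        best.to_csv(out_dir / "report_best.csv", index=False, float_format="%.6f")
        sweep.to_csv(out_dir / "report_sweep.csv", index=False, float_format="%.6f")
    return best, sweep
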