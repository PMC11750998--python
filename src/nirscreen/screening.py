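"""Cross-validated multi-classifier screening of SCD/MCI.

Builds subject-level feature tables (270 FC features, optionally plus the
six neuropsychological scores), runs nine classifiers under stratified
5- and 10-fold cross-validation for the three pairwise diagnostic tasks,
and reports pooled out-of-fold accuracy (ACC), specificity, sensitivity
and AUC with a DeLong 95% CI, next to a permutation-derived empirical
chance accuracy (EACC).

Per training fold the pipeline is: variance filter on the raw training
features, z-score standardization with training statistics, PCA retaining
a configured variance fraction, then the classifier — every transform is
fitted on the training fold only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .connectivity import FCMatrixSet, fc_feature_names
from .rusboost import RUSBoostClassifier
from .synth import SCORE_COLUMNS

__all__ = [
    "MODEL_NAMES",
    "TASKS",
    "ReducerConfig",
    "build_feature_table",
    "make_folds",
    "fit_fold",
    "FoldPipeline",
    "run_task",
    "evaluate_predictions",
    "delong_ci",
    "permutation_eacc",
    "ScreeningModel",
    "ScreeningResults",
    "full_screen",
]

MODEL_NAMES = (
    "LDA", "LR", "GNB", "SVM", "KNN", "RF", "XGBoost", "GBDT", "RUSBoost",
)

# (positive class, negative class) per screening task
TASKS = (("SCD", "NC"), ("MCI", "NC"), ("MCI", "SCD"))


def make_classifier(name: str, seed: int | None = 0):
    """Instantiate one of the nine screening classifiers with library-typical
    defaults (no hyperparameter search)."""
    if name == "LDA":
        return LinearDiscriminantAnalysis()
    if name == "LR":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if name == "GNB":
        return GaussianNB()
    if name == "SVM":
        return SVC(kernel="rbf", random_state=seed)
    if name == "KNN":
        return KNeighborsClassifier()
    if name == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "XGBoost":
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=100,
            eval_metric="logloss",
            random_state=seed,
            verbosity=0,
        )
    if name == "GBDT":
        return GradientBoostingClassifier(random_state=seed)
    if name == "RUSBoost":
        return RUSBoostClassifier(random_state=seed)
    raise ValueError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")


@dataclass
class ReducerConfig:
    """Feature-reduction settings applied inside every training fold.

    ``variance_threshold`` drops features whose raw training variance is
    <= the threshold. ``on_empty`` controls the all-features-removed case:
    "raise" (strict) or "keep_all" (skip the filter with a warning), the
    latter is what the end-to-end screen uses so that low-variance feature
    sets (FC values live in [0, 1]) remain usable. ``strict_paper_order``
    applies the filter after z-scoring with a strictly-less-than rule
    (audit mode). ``pca_variance`` is the retained PCA variance fraction.
    """

    variance_threshold: float = 1.0
    on_empty: str = "raise"
    strict_paper_order: bool = False
    pca_variance: float = 0.95


@dataclass
class FoldPipeline:
    """Transforms + classifier fitted on one training fold only."""

    kept: np.ndarray  # boolean column support from the variance filter
    mean: np.ndarray
    sd: np.ndarray
    pca: PCA | None
    classifier: object
    classes_: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.classes_ = np.asarray(self.classifier.classes_)

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, float)[:, self.kept] - self.mean) / self.sd
        return self.pca.transform(Z) if self.pca is not None else Z

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classifier.predict(self.transform(X))

    def score_for(self, X: np.ndarray, positive_class) -> np.ndarray:
        """Continuous score increasing with the positive class."""
        Z = self.transform(X)
        clf = self.classifier
        if hasattr(clf, "predict_proba"):
            proba = clf.predict_proba(Z)
            col = int(np.nonzero(self.classes_ == positive_class)[0][0])
            return proba[:, col]
        s = clf.decision_function(Z)
        return s if self.classes_[1] == positive_class else -s


def build_feature_table(
    fc_by_subject: dict[str, FCMatrixSet],
    scores: pd.DataFrame | None = None,
    include_scores: bool = False,
) -> pd.DataFrame:
    """Assemble the subjects x features table.

    FC columns follow the fixed ordering estimator -> chromophore ->
    upper-triangle ROI pairs (270 columns for the full montage); the six
    neuropsychological score columns are appended when requested. The
    group label column is carried from ``scores`` when present.
    """
    if not fc_by_subject:
        raise ValueError("no subjects provided")
    first = next(iter(fc_by_subject.values()))
    names = fc_feature_names(first.n_rois)
    rows = {sid: fc.to_feature_vector() for sid, fc in fc_by_subject.items()}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    df.index.name = "subject_id"
    df = df.reset_index()
    if scores is not None:
        missing = set(df["subject_id"]) - set(scores["subject_id"])
        if missing:
            raise ValueError(
                f"subjects missing from the score table: {sorted(missing)}"
            )
        keep = ["subject_id"] + (
            [c for c in ("group",) if c in scores.columns]
        ) + (list(SCORE_COLUMNS) if include_scores else [])
        df = df.merge(scores[keep], on="subject_id", how="left")
    elif include_scores:
        raise ValueError("include_scores=True requires a score table")
    return df


def feature_columns(df: pd.DataFrame, include_scores: bool) -> list[str]:
    """Feature column names for a table built by :func:`build_feature_table`."""
    non_features = {"subject_id", "group"}
    score_set = set(SCORE_COLUMNS)
    cols = [c for c in df.columns if c not in non_features]
    if not include_scores:
        cols = [c for c in cols if c not in score_set]
    return cols


def make_folds(labels, k: int, seed: int = 0) -> np.ndarray:
    """Stratified k-fold assignment: fold index (0..k-1) per subject."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the smallest class count ({counts.min()})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[test_idx] = fold
    return assignment


def fit_fold(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    model: str | object = "LDA",
    reducer: ReducerConfig | None = None,
    seed: int | None = 0,
) -> FoldPipeline:
    """Fit the per-fold transform + classifier pipeline on training data only.

    Order: variance filter on raw training features, z-score with training
    mean/sd, PCA retaining ``reducer.pca_variance`` of the variance,
    classifier fit. All statistics are frozen for test application.
    """
    reducer = reducer or ReducerConfig()
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training fold must contain both classes")

    if reducer.strict_paper_order:
        # audit mode: z-score first, then filter with a strict < rule
        mu0 = X.mean(axis=0)
        sd0 = X.std(axis=0, ddof=0)
        sd0[sd0 == 0] = 1.0
        Z0 = (X - mu0) / sd0
        kept = Z0.var(axis=0, ddof=0) >= reducer.variance_threshold - 1e-12
    else:
        thr = reducer.variance_threshold
        # tolerance so a variance of exactly the threshold (up to float
        # rounding) sits on the "removed" side of the <= rule
        kept = X.var(axis=0, ddof=0) > thr + 1e-9 * max(1.0, abs(thr))
    if not kept.any():
        if reducer.on_empty == "keep_all":
            warnings.warn(
                "variance filter would remove every feature; keeping all "
                "(lower variance_threshold to silence)",
                stacklevel=2,
            )
            kept = np.ones(X.shape[1], dtype=bool)
        else:
            raise ValueError(
                "variance filter removed every feature; review "
                f"variance_threshold={reducer.variance_threshold}"
            )

    Xk = X[:, kept]
    mean = Xk.mean(axis=0)
    sd = Xk.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (Xk - mean) / sd

    pca: PCA | None = None
    if 0 < reducer.pca_variance < 1 and min(Z.shape) > 1:
        pca = PCA(n_components=reducer.pca_variance, svd_solver="full")
        Z = pca.fit_transform(Z)

    clf = make_classifier(model, seed) if isinstance(model, str) else model
    fit_y = y
    if hasattr(clf, "get_params") and clf.__class__.__name__ == "XGBClassifier":
        # xgboost needs integer labels; map back at predict time
        classes = np.unique(y)
        clf.fit(Z, np.searchsorted(classes, y))
        clf = _XGBWrapper(clf, classes)
    else:
        clf.fit(Z, fit_y)
    return FoldPipeline(kept=kept, mean=mean, sd=sd, pca=pca, classifier=clf)


class _XGBWrapper:
    """Adapts integer-label xgboost output back to string class labels."""

    def __init__(self, model, classes: np.ndarray) -> None:
        self._model = model
        self.classes_ = classes

    def predict(self, X):
        return self.classes_[self._model.predict(X).astype(int)]

    def predict_proba(self, X):
        return self._model.predict_proba(X)


def run_task(
    features: pd.DataFrame,
    task: tuple[str, str],
    models: tuple[str, ...] = MODEL_NAMES,
    k: int = 10,
    seed: int = 0,
    include_scores: bool = False,
    reducer: ReducerConfig | None = None,
    label_col: str = "group",
) -> dict[str, dict[str, np.ndarray]]:
    """Run one pairwise task: pooled out-of-fold predictions per model.

    Returns per model a dict with ``y_true``, ``y_pred``, ``y_score``
    (score increasing with the positive class). Every subject of the two
    task groups appears in the test set exactly once.
    """
    positive, negative = task
    cols = feature_columns(features, include_scores)
    mask = features[label_col].isin([positive, negative]).to_numpy()
    sub = features.loc[mask]
    X = sub[cols].to_numpy(dtype=float)
    y = sub[label_col].to_numpy()
    finite = np.all(np.isfinite(X), axis=1)
    if not finite.all():
        X, y = X[finite], y[finite]
    if len(np.unique(y)) < 2:
        raise ValueError(f"task {task} needs both groups present")

    folds = None
    for attempt in range(10):
        cand = make_folds(y, k, seed + attempt)
        ok = all(
            len(np.unique(y[cand != f])) == 2 for f in range(k)
        )
        if ok:
            folds = cand
            break
    if folds is None:
        raise ValueError("could not stratify folds with both classes in train")

    out: dict[str, dict[str, np.ndarray]] = {}
    for name in models:
        y_pred = np.empty(len(y), dtype=object)
        y_score = np.empty(len(y), dtype=float)
        for f in range(k):
            tr, te = folds != f, folds == f
            pipe = fit_fold(X[tr], y[tr], name, reducer, seed=seed)
            y_pred[te] = pipe.predict(X[te])
            y_score[te] = pipe.score_for(X[te], positive)
        out[name] = {
            "y_true": y.copy(),
            "y_pred": y_pred.astype(str),
            "y_score": y_score,
        }
    return out


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x)
    z = x[order]
    n = len(x)
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and z[j] == z[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n)
    out[order] = t
    return out


def delong_ci(
    scores_pos: np.ndarray, scores_neg: np.ndarray, level: float = 0.95
) -> tuple[float, float, float]:
    """AUC and DeLong confidence interval from class-wise score vectors."""
    x = np.asarray(scores_pos, float)
    y = np.asarray(scores_neg, float)
    m, n = len(x), len(y)
    tz = _midrank(np.concatenate([x, y]))
    tx = _midrank(x)
    ty = _midrank(y)
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    v01 = (tz[:m] - tx) / n
    v10 = 1.0 - (tz[m:] - ty) / m
    var = 0.0
    if m > 1:
        var += np.var(v01, ddof=1) / m
    if n > 1:
        var += np.var(v10, ddof=1) / n
    se = float(np.sqrt(var))
    z = stats.norm.ppf(0.5 + level / 2)
    lo = float(np.clip(auc - z * se, 0.0, 1.0))
    hi = float(np.clip(auc + z * se, 0.0, 1.0))
    return float(auc), lo, hi


def evaluate_predictions(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    y_score: np.ndarray,
    positive_class: str,
) -> dict[str, float]:
    """ACC / SPE / SEN / AUC (+95% DeLong CI) from pooled predictions."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    y_score = np.asarray(y_score, dtype=float)
    pos = y_true == positive_class
    if pos.all() or not pos.any():
        raise ValueError("both classes must be present in y_true")
    pred_pos = y_pred == positive_class
    tp = int((pos & pred_pos).sum())
    fn = int((pos & ~pred_pos).sum())
    tn = int((~pos & ~pred_pos).sum())
    fp = int((~pos & pred_pos).sum())
    acc = (tp + tn) / len(y_true)
    sen = tp / (tp + fn)
    spe = tn / (tn + fp)
    if np.ptp(y_score) == 0:
        warnings.warn("constant scores: AUC degenerate at 0.5", stacklevel=2)
        auc, lo, hi = 0.5, 0.5, 0.5
    else:
        auc, lo, hi = delong_ci(y_score[pos], y_score[~pos])
    return {
        "ACC": acc,
        "SPC": spe,
        "SEN": sen,
        "AUC": auc,
        "CI_low": lo,
        "CI_high": hi,
    }


def permutation_eacc(
    features: pd.DataFrame,
    task: tuple[str, str],
    model: str,
    k: int = 10,
    n_perm: int = 200,
    seed: int = 0,
    include_scores: bool = False,
    reducer: ReducerConfig | None = None,
    label_col: str = "group",
) -> float:
    """Empirical chance-level accuracy by label permutation.

    Repeats the identical cross-validation pipeline ``n_perm`` times with
    the task's labels randomly shuffled; EACC is the mean pooled accuracy
    over permutations.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    positive, negative = task
    rng = np.random.default_rng(seed)
    shuffled = features.copy()
    mask = shuffled[label_col].isin([positive, negative]).to_numpy()
    accs = []
    for p in range(n_perm):
        labs = shuffled.loc[mask, label_col].to_numpy().copy()
        rng.shuffle(labs)
        shuffled.loc[mask, label_col] = labs
        res = run_task(
            shuffled, task, (model,), k=k, seed=seed + p,
            include_scores=include_scores, reducer=reducer, label_col=label_col,
        )[model]
        accs.append(float(np.mean(res["y_true"] == res["y_pred"])))
    return float(np.mean(accs))


@dataclass
class ScreeningResults:
    """Per task x model x feature-set x fold-scheme screening metrics."""

    report: pd.DataFrame

    def summary(self) -> str:
        cols = [
            "task", "model", "feature_set", "fold_scheme",
            "ACC", "EACC", "SPC", "SEN", "AUC", "CI_low", "CI_high",
        ]
        return (
            "Cross-validated screening report (pooled out-of-fold metrics)\n"
            + self.report[cols].to_string(
                index=False, float_format=lambda v: f"{v:.3f}"
            )
        )

    def to_csv(self, path) -> None:
        self.report.to_csv(path, index=False)


class ScreeningModel:
    """Multi-classifier screening over the pairwise diagnostic tasks.

    Parameters
    ----------
    features : DataFrame from :func:`build_feature_table` (with a group
        column and, when scores are to be used, the six score columns).
    tasks, models, fold_schemes : which tasks / classifiers / k values to run.
    feature_sets : subset of {"fc_only", "fc_plus_neuro"}.
    reducer : per-fold reduction settings; defaults to the printed variance
        threshold with the keep-all fallback so FC-only runs are feasible.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        tasks: tuple = TASKS,
        models: tuple[str, ...] = MODEL_NAMES,
        fold_schemes: tuple[int, ...] = (5, 10),
        feature_sets: tuple[str, ...] = ("fc_only", "fc_plus_neuro"),
        reducer: ReducerConfig | None = None,
        label_col: str = "group",
    ) -> None:
        self.features = features
        self.tasks = tasks
        self.models = models
        self.fold_schemes = fold_schemes
        self.feature_sets = feature_sets
        self.reducer = reducer or ReducerConfig(on_empty="keep_all")
        self.label_col = label_col

    def fit(self, n_perm: int = 200, seed: int = 0) -> ScreeningResults:
        rows = []
        for fset in self.feature_sets:
            include_scores = fset == "fc_plus_neuro"
            if include_scores and not set(SCORE_COLUMNS) <= set(
                self.features.columns
            ):
                raise ValueError("fc_plus_neuro requires the six score columns")
            for task in self.tasks:
                for k in self.fold_schemes:
                    preds = run_task(
                        self.features, task, self.models, k=k, seed=seed,
                        include_scores=include_scores, reducer=self.reducer,
                        label_col=self.label_col,
                    )
                    for name in self.models:
                        r = preds[name]
                        metrics = evaluate_predictions(
                            r["y_true"], r["y_pred"], r["y_score"], task[0]
                        )
                        eacc = permutation_eacc(
                            self.features, task, name, k=k, n_perm=n_perm,
                            seed=seed, include_scores=include_scores,
                            reducer=self.reducer, label_col=self.label_col,
                        )
                        rows.append(
                            {
                                "task": f"{task[0]} vs {task[1]}",
                                "model": name,
                                "feature_set": fset,
                                "fold_scheme": k,
                                "ACC": metrics["ACC"],
                                "EACC": eacc,
                                "SPC": metrics["SPC"],
                                "SEN": metrics["SEN"],
                                "AUC": metrics["AUC"],
                                "CI_low": metrics["CI_low"],
                                "CI_high": metrics["CI_high"],
                                "seed": seed,
                                "n_perm": n_perm,
                            }
                        )
        return ScreeningResults(report=pd.DataFrame(rows))


def full_screen(
    features: pd.DataFrame,
    n_perm: int = 200,
    seed: int = 0,
    **kwargs,
) -> ScreeningResults:
    """Run the complete screen: all tasks x models x feature sets x fold
    schemes. Functional wrapper over :class:`ScreeningModel`."""
    return ScreeningModel(features, **kwargs).fit(n_perm=n_perm, seed=seed)
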