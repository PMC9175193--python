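"""Motor-status prediction: class-weighted linear SVM with recursive
feature elimination inside nested, stratified, bagged cross-validation.

The estimation surface follows the model/results convention:
:class:`MotorStatusSVM` is built from a :class:`~cstmotor.features.FeatureTable`
(or directly from a synthetic cohort) and a
:class:`~cstmotor.config.ModelConfig`; its :meth:`~MotorStatusSVM.fit` runs
the nested cross-validation and returns :class:`MotorStatusCVResults`
carrying pooled and per-fold metrics, selected-feature bookkeeping and a
``summary()`` table.

Pipeline per training set (outer-fold train or bootstrap resample):
impute -> standardise -> feature selection (SVM-RFE down to ``rfe_k``
features, or PCA to ``pca_components``) -> tune the penalty C on a
stratified inner CV -> fit the final class-weighted linear SVM.  All
statistics are derived from training rows only.  Within each outer fold,
``n_bootstrap`` stratified bootstrap resamples of the training set each
produce one model; the held-out prediction is the majority vote across
them (ties go to the deficit class) and the score for the ROC is the mean
signed decision value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from cstmotor.config import ModelConfig
from cstmotor.features import FeatureTable, impute_missing, pca_reduce, standardize


class ClassifierError(ValueError):
    """Raised for invalid classifier inputs or degenerate fits."""


@dataclass
class ClassWeights:
    """Class weights inversely proportional to class frequencies:
    w_j = n_samples / (n_classes * n_samples_j)."""

    w0: float
    w1: float

    def as_dict(self) -> dict[int, float]:
        return {0: self.w0, 1: self.w1}


def class_weights(labels) -> ClassWeights:
    y = np.asarray(labels).astype(int)
    n = y.size
    n1 = int(y.sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise ClassifierError("both classes must be present")
    return ClassWeights(w0=n / (2.0 * n0), w1=n / (2.0 * n1))


def _svc(C: float, weights: ClassWeights) -> SVC:
    return SVC(kernel="linear", C=C, class_weight=weights.as_dict())


@dataclass
class RFEResult:
    selected: list[int]            # surviving column indices, original order
    elimination_order: list[int]   # first-dropped first


def svm_rfe_rank(X: np.ndarray, y: np.ndarray, weights: ClassWeights,
                 k: int, C: float = 1.0) -> RFEResult:
    """Recursive feature elimination driven by linear-SVM coefficients.

    Repeatedly fits the class-weighted linear SVM and drops the single
    feature with the smallest absolute coefficient (ties: the highest
    column index is dropped) until ``k`` features remain.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if k < 1 or k > X.shape[1]:
        raise ClassifierError(f"k must lie in [1, {X.shape[1]}]")
    if np.all(X == X[0]):
        raise ClassifierError("degenerate training matrix (all rows identical)")
    active = list(range(X.shape[1]))
    order: list[int] = []
    while len(active) > k:
        clf = _svc(C, weights)
        clf.fit(X[:, active], y)
        coefs = np.abs(np.asarray(clf.coef_).ravel())
        worst_local = np.flatnonzero(coefs == coefs.min()).max()
        order.append(active.pop(worst_local))
    return RFEResult(selected=active, elimination_order=order)


def inner_cv_tune(X: np.ndarray, y: np.ndarray, config: ModelConfig,
                  seed: int = 0) -> float:
    """Pick C by stratified inner-fold CV on balanced accuracy; the
    smallest C attaining the maximum score wins."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < config.inner_folds:
        raise ClassifierError(
            f"class of size {counts.min()} cannot be stratified into "
            f"{config.inner_folds} inner folds")
    skf = StratifiedKFold(n_splits=config.inner_folds, shuffle=True,
                          random_state=seed % (2 ** 31))
    splits = list(skf.split(X, y))
    weights = class_weights(y)
    grid = list(config.C_grid)
    scores = np.zeros(len(grid))
    for ci, C in enumerate(grid):
        accs = []
        for tr, va in splits:
            clf = _svc(C, class_weights(y[tr]))
            clf.fit(X[tr], y[tr])
            pred = clf.predict(X[va])
            sens = _safe_rate(pred[y[va] == 1] == 1)
            spec = _safe_rate(pred[y[va] == 0] == 0)
            accs.append(0.5 * (sens + spec))
        scores[ci] = np.mean(accs)
    best = scores.max()
    for ci, C in enumerate(grid):
        if scores[ci] >= best - 1e-12:
            return float(C)
    return float(grid[0])


def _safe_rate(mask) -> float:
    mask = np.asarray(mask)
    return float(mask.mean()) if mask.size else 0.0


def compute_metrics(labels, predictions, scores=None) -> dict[str, float]:
    """Accuracy, sensitivity, specificity (deficit class 1 positive) and
    rank-based AUC (ties count one half)."""
    y = np.asarray(labels).astype(int)
    pred = np.asarray(predictions).astype(int)
    if y.size != pred.size:
        raise ClassifierError("labels and predictions must align")
    acc = float((y == pred).mean())
    pos = y == 1
    neg = y == 0
    sens = _safe_rate(pred[pos] == 1)
    spec = _safe_rate(pred[neg] == 0)
    out = {"accuracy": acc, "sensitivity": sens, "specificity": spec}
    if scores is not None:
        s = np.asarray(scores, dtype=float)
        if not (pos.any() and neg.any()):
            raise ClassifierError("AUC undefined for single-class labels")
        ranks = sps.rankdata(s)
        n1 = int(pos.sum())
        n0 = int(neg.sum())
        out["auc"] = float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1))
    return out


# ---------------------------------------------------------------------------
# Pipeline fitting (one training set)


@dataclass
class _PipelineState:
    train_raw: pd.DataFrame
    imputation: str
    knn_k: int
    std_params: object
    reducer: object            # None | list of column names | fitted PCA
    mode: str                  # "rfe" | "pca" | "none"
    model: SVC
    C: float
    selected: list[str]


def _transform(state: _PipelineState, X: pd.DataFrame) -> np.ndarray:
    _, Xi = impute_missing(state.train_raw, X, method=state.imputation,
                           k=state.knn_k)
    Z = (Xi.to_numpy(dtype=float) - state.std_params.mean) / state.std_params.scale
    Zdf = pd.DataFrame(Z, columns=X.columns)
    if state.mode == "rfe":
        return Zdf[state.reducer].to_numpy(dtype=float)
    if state.mode == "pca":
        return state.reducer.transform(Z)
    return Z


def _fit_pipeline(Xtr: pd.DataFrame, ytr: np.ndarray, config: ModelConfig,
                  seed: int) -> _PipelineState:
    Xi = impute_missing(Xtr, method=config.imputation, k=config.knn_k)
    Ztr, _, std_params = standardize(Xi)
    weights = class_weights(ytr)

    if config.feature_mode == "segments1000+pca":
        Ptr, _, pca = pca_reduce(Ztr, n_components=config.pca_components)
        Xfit = Ptr.to_numpy(dtype=float)
        mode, reducer = "pca", pca
        selected = list(Ptr.columns)
    elif config.use_rfe and config.rfe_k < Ztr.shape[1]:
        rfe = svm_rfe_rank(Ztr.to_numpy(dtype=float), ytr, weights, config.rfe_k)
        selected = [Ztr.columns[i] for i in rfe.selected]
        Xfit = Ztr[selected].to_numpy(dtype=float)
        mode, reducer = "rfe", selected
    else:
        selected = list(Ztr.columns)
        Xfit = Ztr.to_numpy(dtype=float)
        mode, reducer = "rfe", selected

    C = inner_cv_tune(Xfit, ytr, config, seed=seed)
    model = _svc(C, weights)
    model.fit(Xfit, ytr)
    return _PipelineState(train_raw=Xtr, imputation=config.imputation,
                          knn_k=config.knn_k, std_params=std_params,
                          reducer=reducer, mode=mode, model=model, C=C,
                          selected=selected)


def _stratified_bootstrap(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Bootstrap resample preserving per-class counts (so no resample can
    lose a class); indices into the training set."""
    idx = []
    for cls in (0, 1):
        members = np.flatnonzero(y == cls)
        idx.append(rng.choice(members, size=members.size, replace=True))
    return np.concatenate(idx)


@dataclass
class FoldResult:
    predictions: np.ndarray
    scores: np.ndarray
    vote_fraction: np.ndarray
    selected_counts: Counter
    n_models: int
    tuned_C: list[float]


def bagged_fold_fit_predict(train_X: pd.DataFrame, train_y: np.ndarray,
                            test_X: pd.DataFrame, config: ModelConfig,
                            seed: int = 0) -> FoldResult:
    """Fit ``n_bootstrap`` models on stratified bootstrap resamples of the
    training set and vote on the held-out rows.

    With ``tuning_scope="resample"`` the full pipeline (impute,
    standardise, RFE/PCA, inner-CV tuning) runs inside every resample;
    with ``"fold"`` the transforms and C are fitted once on the fold's
    training set and each resample only refits the final SVM.
    """
    train_y = np.asarray(train_y).astype(int)
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 23)))
    n_test = len(test_X)
    votes = np.zeros(n_test)
    scores = np.zeros(n_test)
    counts: Counter = Counter()
    tuned: list[float] = []

    # a single "resample" means no bagging: use the full training set, so
    # n_bootstrap=1 reduces exactly to the un-bagged pipeline
    def _draw():
        if config.n_bootstrap == 1:
            return np.arange(train_y.size)
        return _stratified_bootstrap(train_y, rng)

    if config.tuning_scope == "fold":
        state = _fit_pipeline(train_X, train_y, config, seed=seed)
        Ztr = _transform(state, train_X)   # same transforms, train rows
        Zte = _transform(state, test_X)
        for _ in range(config.n_bootstrap):
            bidx = _draw()
            clf = _svc(state.C, class_weights(train_y[bidx]))
            clf.fit(Ztr[bidx], train_y[bidx])
            votes += clf.predict(Zte)
            scores += clf.decision_function(Zte)
            counts.update(state.selected)
            tuned.append(state.C)
    else:
        for b in range(config.n_bootstrap):
            bidx = _draw()
            sub_seed = int(rng.integers(0, 2 ** 31))
            state = _fit_pipeline(train_X.iloc[bidx].reset_index(drop=True),
                                  train_y[bidx], config, seed=sub_seed)
            Zte = _transform(state, test_X)
            votes += state.model.predict(Zte)
            scores += state.model.decision_function(Zte)
            counts.update(state.selected)
            tuned.append(state.C)

    frac = votes / config.n_bootstrap
    preds = (frac >= 0.5).astype(int)      # ties -> deficit class
    mean_scores = scores / config.n_bootstrap
    return FoldResult(predictions=preds, scores=mean_scores,
                      vote_fraction=frac, selected_counts=counts,
                      n_models=config.n_bootstrap, tuned_C=tuned)


# ---------------------------------------------------------------------------
# Nested cross-validation


@dataclass
class CVReport:
    """Pooled and per-fold evaluation of one model configuration."""

    pooled: dict[str, float]
    fold_metrics: list[dict]
    selected_frequencies: dict[str, float]
    fold_selected: list[dict]
    tuned_C: list[list[float]]
    labels: np.ndarray
    predictions: np.ndarray
    scores: np.ndarray
    config: ModelConfig
    seed: int

    def to_dict(self) -> dict:
        return {
            "pooled": self.pooled,
            "fold_metrics": self.fold_metrics,
            "selected_frequencies": self.selected_frequencies,
            "tuned_C": self.tuned_C,
            "labels": self.labels.tolist(),
            "predictions": self.predictions.tolist(),
            "scores": self.scores.tolist(),
            "seed": self.seed,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def nested_cv_evaluate(table: FeatureTable, config: ModelConfig) -> CVReport:
    """Stratified nested CV with per-fold bagging.

    Outer folds estimate generalisation: each fold's held-out rows are
    predicted by the vote of ``n_bootstrap`` models fitted on bootstrap
    resamples of the fold's training rows, with imputation,
    standardisation, feature selection and C tuning all derived from
    training rows only.  Pooled accuracy/sensitivity/specificity come from
    the pooled confusion matrix; AUC from the pooled mean decision values.
    """
    y = table.y.to_numpy().astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < config.outer_folds:
        raise ClassifierError(
            f"need >= {config.outer_folds} samples per class for "
            f"{config.outer_folds} outer folds")
    skf = StratifiedKFold(n_splits=config.outer_folds, shuffle=True,
                          random_state=config.seed % (2 ** 31))
    X = table.X
    n = len(X)
    pooled_pred = np.zeros(n, dtype=int)
    pooled_score = np.zeros(n)
    fold_metrics = []
    fold_selected = []
    tuned = []
    total_counts: Counter = Counter()
    total_models = 0

    for fold_i, (tr, te) in enumerate(skf.split(X.to_numpy(), y)):
        assert np.intersect1d(tr, te).size == 0, "leakage guard: fold overlap"
        fold_seed = int(np.random.SeedSequence(
            (int(config.seed), fold_i)).generate_state(1)[0] % (2 ** 31))
        res = bagged_fold_fit_predict(
            X.iloc[tr].reset_index(drop=True), y[tr],
            X.iloc[te].reset_index(drop=True), config, seed=fold_seed)
        pooled_pred[te] = res.predictions
        pooled_score[te] = res.scores
        fm = compute_metrics(y[te], res.predictions,
                             res.scores if len(set(y[te])) == 2 else None)
        fm["fold"] = fold_i
        fold_metrics.append(fm)
        fold_selected.append(dict(res.selected_counts))
        tuned.append(res.tuned_C)
        total_counts.update(res.selected_counts)
        total_models += res.n_models

    pooled = compute_metrics(y, pooled_pred, pooled_score)
    freqs = {k: v / total_models for k, v in sorted(total_counts.items())}
    return CVReport(pooled=pooled, fold_metrics=fold_metrics,
                    selected_frequencies=freqs, fold_selected=fold_selected,
                    tuned_C=tuned, labels=y, predictions=pooled_pred,
                    scores=pooled_score, config=config, seed=config.seed)


# ---------------------------------------------------------------------------
# Model / Results surface


class MotorStatusSVM:
    """Motor-status classifier model bound to a feature table.

    Parameters
    ----------
    table
        Features and class labels (class 1 = motor deficit, MRC < 5).
    config
        Model variant; defaults to the histogram-feature, median-imputation
        configuration.

    Examples
    --------
    >>> model = MotorStatusSVM.from_cohort(cohort, preset_config("svm_2"))
    >>> results = model.fit()
    >>> print(results.summary())
    """

    def __init__(self, table: FeatureTable, config: ModelConfig | None = None):
        self.table = table
        self.config = config or ModelConfig()

    @classmethod
    def from_cohort(cls, cohort, config: ModelConfig | None = None) -> "MotorStatusSVM":
        """Assemble the feature table a config calls for from a generated
        cohort (profile estimator, feature mode, metric subset, clinical
        block) and bind the model to it."""
        from cstmotor.features import assemble_features
        config = config or ModelConfig()
        mode = {"histogram40": "histogram40",
                "segments1000+pca": "segments1000",
                "clinical": "clinical"}[config.feature_mode]
        profiles = {}
        if mode != "clinical":
            for p in cohort.patients:
                for hemi in ("left", "right"):
                    for metric in config.metrics:
                        profiles[(p.id, hemi, metric)] = cohort.profile(
                            p.id, hemi, metric, config.profile_method)
        table = assemble_features(profiles, cohort.patients, mode=mode,
                                  clinical=config.include_clinical or mode == "clinical",
                                  metrics=config.metrics)
        return cls(table, config)

    def fit(self) -> "MotorStatusCVResults":
        """Run the nested, bagged cross-validation and return results."""
        report = nested_cv_evaluate(self.table, self.config)
        return MotorStatusCVResults(self, report)


class MotorStatusCVResults:
    """Results of a fitted :class:`MotorStatusSVM`: pooled metrics,
    per-fold metrics, selected features and tuned penalties."""

    def __init__(self, model: MotorStatusSVM, report: CVReport):
        self.model = model
        self.report = report

    @property
    def accuracy(self) -> float:
        return self.report.pooled["accuracy"]

    @property
    def sensitivity(self) -> float:
        return self.report.pooled["sensitivity"]

    @property
    def specificity(self) -> float:
        return self.report.pooled["specificity"]

    @property
    def auc(self) -> float:
        return self.report.pooled["auc"]

    @property
    def selected_features(self) -> list[str]:
        freq = self.report.selected_frequencies
        return sorted(freq, key=lambda k: (-freq[k], k))

    def fold_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.report.fold_metrics)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Motor-status SVM - nested CV results",
            "=" * 52,
            f"profile method : {cfg.profile_method}",
            f"imputation     : {cfg.imputation}",
            f"feature mode   : {cfg.feature_mode}"
            + (" + clinical" if cfg.include_clinical else ""),
            f"outer/inner CV : {cfg.outer_folds}/{cfg.inner_folds} folds, "
            f"{cfg.n_bootstrap} bootstrap models per fold",
            "-" * 52,
            f"accuracy       : {self.accuracy:6.1%}",
            f"sensitivity    : {self.sensitivity:6.1%}",
            f"specificity    : {self.specificity:6.1%}",
            f"AUC            : {self.auc:6.1%}",
            "-" * 52,
            "top selected features (selection frequency):",
        ]
        freq = self.report.selected_frequencies
        for name in self.selected_features[:8]:
            lines.append(f"  {name:<20s} {freq[name]:5.1%}")
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<MotorStatusCVResults accuracy={self.accuracy:.3f} "
                f"auc={self.auc:.3f}>")
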