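"""Class weighting, SVM-RFE, inner tuning, bagging and the nested CV:
contracts, determinism, leakage freedom and power on planted effects."""

import numpy as np
import pandas as pd
import pytest

from cstmotor.classify import (
    ClassifierError,
    MotorStatusSVM,
    bagged_fold_fit_predict,
    class_weights,
    compute_metrics,
    inner_cv_tune,
    nested_cv_evaluate,
    svm_rfe_rank,
)
from cstmotor.config import ModelConfig, default_c_grid
from cstmotor.features import FeatureTable


def _fast_config(**kw):
    base = dict(outer_folds=4, inner_folds=3, n_bootstrap=3,
                tuning_scope="fold", C_grid=(0.1, 1.0, 10.0), seed=0)
    base.update(kw)
    return ModelConfig(**base)


def _planted_table(n=120, n_features=10, n_informative=2, effect=2.0, seed=0,
                   prevalence=0.4):
    rng = np.random.default_rng(seed)
    n1 = int(round(n * prevalence))
    y = np.array([1] * n1 + [0] * (n - n1))
    y = y[rng.permutation(n)]
    X = rng.normal(size=(n, n_features))
    X[:, :n_informative] += effect * y[:, None]
    cols = ([f"inf{i}" for i in range(n_informative)]
            + [f"noise{i}" for i in range(n_features - n_informative)])
    return FeatureTable(pd.DataFrame(X, columns=cols), pd.Series(y),
                        imaging_columns=cols)


# ---------------------------------------------------------------------------
# class_weights


def test_class_weights_cohort_counts():
    w = class_weights([0] * 71 + [1] * 45)
    assert w.w0 == pytest.approx(116 / 142)
    assert w.w1 == pytest.approx(116 / 90)


def test_class_weights_balanced_and_tiny():
    w = class_weights([0, 0, 1, 1])
    assert w.w0 == w.w1 == 1.0
    w = class_weights([0, 0, 0, 1])
    assert w.w1 == 2.0 and w.w0 == pytest.approx(2 / 3)


@pytest.mark.parametrize("seed", range(3))
def test_class_weights_invariant(seed):
    rng = np.random.default_rng(seed)
    y = (rng.random(rng.integers(10, 200)) < 0.37).astype(int)
    if y.sum() in (0, y.size):
        y[0] = 1 - y[0]
    w = class_weights(y)
    n1 = y.sum()
    n0 = y.size - n1
    assert n0 * w.w0 + n1 * w.w1 == pytest.approx(y.size)


def test_class_weights_single_class_raises():
    with pytest.raises(ClassifierError):
        class_weights([1, 1, 1])


# ---------------------------------------------------------------------------
# svm_rfe_rank


def test_rfe_k_equals_n_features_keeps_everything(rng):
    X = rng.normal(size=(30, 6))
    y = (rng.random(30) < 0.5).astype(int)
    res = svm_rfe_rank(X, y, class_weights(y), k=6)
    assert res.selected == list(range(6))
    assert res.elimination_order == []


def test_rfe_recovers_planted_informative_features():
    hits = 0
    runs = 100
    for seed in range(runs):
        t = _planted_table(n=200, n_features=40, n_informative=2,
                           effect=3.0, seed=seed)
        y = t.y.to_numpy()
        X = (t.X - t.X.mean()) / t.X.std()
        res = svm_rfe_rank(X.to_numpy(), y, class_weights(y), k=5)
        names = [t.X.columns[i] for i in res.selected]
        if "inf0" in names and "inf1" in names:
            hits += 1
    assert hits >= 95


def test_rfe_duplicate_columns_tie_rule_is_deterministic(rng):
    base = rng.normal(size=(40, 3))
    X = np.column_stack([base, base[:, 0]])  # col 3 duplicates col 0
    y = (base[:, 0] > 0).astype(int)
    runs = [svm_rfe_rank(X, y, class_weights(y), k=1) for _ in range(3)]
    for r in runs[1:]:
        assert r.elimination_order == runs[0].elimination_order
        assert r.selected == runs[0].selected


def test_rfe_matches_sklearn_reference(rng):
    # independent cross-check against sklearn's RFE with the same base SVM
    from sklearn.feature_selection import RFE
    from sklearn.svm import SVC
    t = _planted_table(n=80, n_features=12, n_informative=3, effect=1.5, seed=1)
    y = t.y.to_numpy()
    X = ((t.X - t.X.mean()) / t.X.std()).to_numpy()
    w = class_weights(y)
    ours = svm_rfe_rank(X, y, w, k=4)
    ref = RFE(SVC(kernel="linear", C=1.0, class_weight=w.as_dict()),
              n_features_to_select=4, step=1).fit(X, y)
    assert set(ours.selected) == set(np.flatnonzero(ref.support_))


def test_rfe_degenerate_matrix_raises(rng):
    X = np.ones((10, 4))
    y = np.array([0, 1] * 5)
    with pytest.raises(ClassifierError):
        svm_rfe_rank(X, y, class_weights(y), k=2)


# ---------------------------------------------------------------------------
# inner_cv_tune


def test_default_c_grid_has_100_values_excluding_zero():
    grid = default_c_grid()
    assert len(grid) == 100
    assert grid[0] == 0.1 and grid[-1] == 10.0
    assert all(c > 0 for c in grid)


def test_tuning_tie_returns_smallest_c():
    # widely separated classes: every C achieves a perfect score
    rng = np.random.default_rng(0)
    y = np.array([0, 1] * 20)
    X = rng.normal(size=(40, 2)) * 0.01 + 100.0 * y[:, None]
    cfg = _fast_config(C_grid=(0.1, 0.5, 2.0))
    assert inner_cv_tune(X, y, cfg, seed=0) == 0.1


def test_tuning_rejects_unstratifiable_class():
    X = np.random.default_rng(0).normal(size=(10, 2))
    y = np.array([1, 0, 0, 0, 0, 0, 0, 0, 0, 0])
    with pytest.raises(ClassifierError):
        inner_cv_tune(X, y, _fast_config(inner_folds=5), seed=0)


# ---------------------------------------------------------------------------
# compute_metrics


def test_metrics_perfect_prediction():
    out = compute_metrics([1, 0, 1, 0], [1, 0, 1, 0], [2.0, -1.0, 3.0, -2.0])
    assert out == {"accuracy": 1.0, "sensitivity": 1.0,
                   "specificity": 1.0, "auc": 1.0}


def test_metrics_tied_scores_auc_half():
    out = compute_metrics([1, 0, 1, 0], [1, 1, 1, 1], [0.3] * 4)
    assert out["auc"] == 0.5


def test_metrics_example_pair_count():
    out = compute_metrics([1, 1, 0, 0], [1, 0, 1, 0], [0.9, 0.4, 0.6, 0.1])
    assert out["auc"] == 0.75     # 3 of 4 (pos, neg) pairs correctly ordered


def test_metrics_match_sklearn_auc(rng):
    from sklearn.metrics import roc_auc_score
    y = (rng.random(60) < 0.4).astype(int)
    s = rng.normal(size=60)
    ours = compute_metrics(y, (s > 0).astype(int), s)["auc"]
    assert ours == pytest.approx(roc_auc_score(y, s))


def test_metrics_single_class_auc_raises():
    with pytest.raises(ClassifierError):
        compute_metrics([1, 1], [1, 0], [0.2, 0.3])


# ---------------------------------------------------------------------------
# bagging


def test_single_bootstrap_reduces_to_unbagged_fit():
    t = _planted_table(n=60, seed=2)
    tr = t.subset(range(40))
    te = t.subset(range(40, 60))
    cfg = _fast_config(n_bootstrap=1, tuning_scope="resample", use_rfe=True,
                       rfe_k=3)
    a = bagged_fold_fit_predict(tr.X, tr.y.to_numpy(), te.X, cfg, seed=5)
    b = bagged_fold_fit_predict(tr.X, tr.y.to_numpy(), te.X, cfg, seed=5)
    np.testing.assert_array_equal(a.predictions, b.predictions)
    # and the fold-scope path gives the same single fit
    c = bagged_fold_fit_predict(tr.X, tr.y.to_numpy(), te.X,
                                _fast_config(n_bootstrap=1, rfe_k=3), seed=5)
    np.testing.assert_array_equal(a.predictions, c.predictions)
    np.testing.assert_allclose(a.scores, c.scores, atol=1e-10)


def test_votes_unanimous_on_separable_duplicated_rows():
    rng = np.random.default_rng(3)
    y = np.repeat([0, 1], 15)
    X = pd.DataFrame({"a": 10.0 * y + rng.normal(0, 0.1, 30),
                      "b": rng.normal(size=30)})
    te = pd.DataFrame({"a": [0.0, 10.0], "b": [0.0, 0.0]})
    cfg = _fast_config(n_bootstrap=10, rfe_k=1)
    res = bagged_fold_fit_predict(X, y, te, cfg, seed=0)
    np.testing.assert_array_equal(res.vote_fraction, [0.0, 1.0])


def test_vote_fraction_tracks_true_class():
    t = _planted_table(n=200, n_features=10, effect=2.0, seed=4)
    tr = t.subset(range(150))
    te = t.subset(range(150, 200))
    cfg = _fast_config(n_bootstrap=20, rfe_k=5)
    res = bagged_fold_fit_predict(tr.X, tr.y.to_numpy(), te.X, cfg, seed=1)
    yte = te.y.to_numpy()
    frac = res.vote_fraction
    pb = np.corrcoef(frac, yte)[0, 1]
    assert pb > 0.5


def test_bagging_is_leakage_free():
    # replacing the held-out rows must not change the fold's fitted
    # transforms, selected features or tuned C
    t = _planted_table(n=80, seed=6)
    tr = t.subset(range(60))
    te1 = t.subset(range(60, 80))
    te2 = te1.X * 1e3
    cfg = _fast_config(n_bootstrap=4, rfe_k=3)
    a = bagged_fold_fit_predict(tr.X, tr.y.to_numpy(), te1.X, cfg, seed=2)
    b = bagged_fold_fit_predict(tr.X, tr.y.to_numpy(), te2, cfg, seed=2)
    assert a.selected_counts == b.selected_counts
    assert a.tuned_C == b.tuned_C


# ---------------------------------------------------------------------------
# nested_cv_evaluate


def test_report_contract_and_determinism():
    t = _planted_table(n=80, seed=8)
    cfg = _fast_config()
    r1 = nested_cv_evaluate(t, cfg)
    r2 = nested_cv_evaluate(t, cfg)
    assert set(r1.pooled) == {"accuracy", "sensitivity", "specificity", "auc"}
    assert len(r1.fold_metrics) == cfg.outer_folds
    assert all(0.0 <= v <= 1.0 for v in r1.pooled.values())
    assert r1.to_dict() == r2.to_dict()


def test_auc_increases_with_planted_effect():
    cfg = _fast_config(n_bootstrap=5)
    auc0 = nested_cv_evaluate(_planted_table(n=100, effect=0.0, seed=10),
                              cfg).pooled["auc"]
    auc2 = nested_cv_evaluate(_planted_table(n=100, effect=2.0, seed=10),
                              cfg).pooled["auc"]
    assert auc2 > auc0
    assert auc2 > 0.9


def test_nested_cv_needs_enough_samples_per_class():
    t = _planted_table(n=20, prevalence=0.15, seed=0)
    with pytest.raises(ClassifierError):
        nested_cv_evaluate(t, _fast_config(outer_folds=10))


def test_pca_variant_runs_and_reports(rng):
    n = 60
    y = (rng.random(n) < 0.4).astype(int)
    X = pd.DataFrame(rng.normal(size=(n, 30)),
                     columns=[f"s{i}" for i in range(30)])
    X.iloc[:, 0] += 2.0 * y
    t = FeatureTable(X, pd.Series(y), imaging_columns=list(X.columns))
    cfg = _fast_config(feature_mode="segments1000+pca", use_rfe=False,
                       pca_components=4, n_bootstrap=1)
    rep = nested_cv_evaluate(t, cfg)
    assert set(rep.selected_frequencies) == {"PC1", "PC2", "PC3", "PC4"}


# ---------------------------------------------------------------------------
# model / results surface


def test_model_results_surface(small_cohort):
    cfg = _fast_config(n_bootstrap=2, rfe_k=5)
    model = MotorStatusSVM.from_cohort(small_cohort, cfg)
    assert model.table.n_features == 40
    res = model.fit()
    txt = res.summary()
    assert "accuracy" in txt and "AUC" in txt
    assert 0.0 <= res.auc <= 1.0
    assert len(res.selected_features) >= cfg.rfe_k
    assert res.fold_frame().shape[0] == cfg.outer_folds


def test_presets_differ_only_in_documented_fields():
    from cstmotor.presets import preset_config
    a = preset_config("svm_1")
    b = preset_config("svm_3")
    diffs = {k for k in vars(a) if getattr(a, k) != getattr(b, k)}
    assert diffs == {"profile_method"}
    ad = preset_config("svm_ad")
    assert ad.metrics == ("AD",)
    clin = preset_config("svm_clinical")
    assert clin.feature_mode == "clinical" and clin.n_bootstrap == 1
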