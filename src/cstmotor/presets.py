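"""The eleven shipped model variants.

svm_1..svm_4 cross the two profile estimators (median vs Mahalanobis-
weighted mean) with the two imputation methods (median vs KNN, k=10) on
the 40 histogram features; svm_5 feeds the first four principal components
of the 1000 segment features to the linear SVM; svm_ad..svm_rd use the
histogram features of a single metric; svm_clinical uses demographic and
clinical variables only.  Bagging applies to svm_1-4 and the per-metric
models; svm_5 and svm_clinical fit a single model per fold.
"""

from __future__ import annotations

from cstmotor.config import ModelConfig

_METRIC_PRESETS = {f"svm_{m.lower()}": m for m in ("AD", "ADC", "FA", "FD", "RD")}

PRESETS: dict[str, dict] = {
    "svm_1": dict(profile_method="median", imputation="median"),
    "svm_2": dict(profile_method="median", imputation="knn"),
    "svm_3": dict(profile_method="weighted_mean", imputation="median"),
    "svm_4": dict(profile_method="weighted_mean", imputation="knn"),
    "svm_5": dict(profile_method="median", imputation="knn",
                  feature_mode="segments1000+pca", use_rfe=False,
                  n_bootstrap=1),
    "svm_clinical": dict(feature_mode="clinical", use_rfe=False,
                         n_bootstrap=1),
}
for name, metric in _METRIC_PRESETS.items():
    PRESETS[name] = dict(profile_method="median", imputation="knn",
                         metrics=(metric,))


def preset_config(name: str, **overrides) -> ModelConfig:
    """Instantiate a named preset, optionally overriding fields
    (e.g. ``n_bootstrap`` or ``tuning_scope`` for scaled-down runs)."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    return ModelConfig(**kwargs)
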