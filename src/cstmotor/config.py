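"""Configuration objects for simulation, modelling and pipeline runs.

All configs are plain dataclasses with validation in ``__post_init__`` and
YAML round-trip helpers, so an analysis is fully described by a single text
file plus a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path


import numpy as np
import yaml

#: Diffusion metrics handled throughout the package, in canonical order.
METRICS: tuple[str, ...] = ("AD", "ADC", "FA", "FD", "RD")

#: Number of along-tract segments per profile (index 0 = medulla oblongata,
#: index 99 = M1).
N_SEGMENTS: int = 100

#: Physiological baseline values inside the tract for each metric.
#: Diffusivities in mm^2/s; FA and FD are unitless.
BASELINES: dict[str, float] = {
    "AD": 1.4e-3,
    "ADC": 0.77e-3,
    "FA": 0.55,
    "FD": 0.45,
    "RD": 0.45e-3,
}

#: Sign of the planted lesion effect for the deficit class: FA and fibre
#: density decrease with tumour infiltration, the diffusivities increase.
EFFECT_SIGNS: dict[str, float] = {
    "AD": +1.0,
    "ADC": +1.0,
    "FA": -1.0,
    "FD": -1.0,
    "RD": +1.0,
}

_DEFAULT_NOISE_SD: dict[str, float] = {
    # Between-patient SD per metric; roughly 7-11% of the baseline value.
    "AD": 0.10e-3,
    "ADC": 0.06e-3,
    "FA": 0.04,
    "FD": 0.04,
    "RD": 0.05e-3,
}


class InvalidConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    The defaults describe the cohort the analysis was designed around:
    116 patients, 45 of them in the motor-deficit class, 5000 streamlines
    per hemisphere, per-class age distributions of 50.25 +/- 15.85 and
    58.64 +/- 15.45 years, and a lesion effect confined to the superior
    portion of the ipsilesional tract.

    Parameters
    ----------
    effect_size
        Planted between-class shift inside the lesion window, in units of
        the within-class (between-patient) SD of the affected metric.
    effect_metrics
        Metrics that carry the planted effect; all five by default.
    noise_sd_per_metric
        Between-patient SD per metric.  Voxel-level field noise is set to
        half of this value (it is strongly suppressed by averaging over
        streamlines).
    """

    n_patients: int = 116
    prevalence: float = 45 / 116
    n_streamlines: int = 5000
    n_points_raw: int = 40
    bundle_radius_mm: float = 2.0
    lesion_center_segment: int = 88
    lesion_halfwidth_segments: int = 10
    effect_size: float = 1.0
    effect_metrics: tuple[str, ...] = METRICS
    missing_fraction: float = 0.02
    noise_sd_per_metric: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_NOISE_SD))
    age_params: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {0: (50.25, 15.85), 1: (58.64, 15.45)})
    voxel_size_mm: float = 2.0
    grid_margin_mm: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise InvalidConfigError("prevalence must lie strictly in (0, 1)")
        if self.n_patients < 1:
            raise InvalidConfigError("n_patients must be positive")
        if self.n_streamlines < 1:
            raise InvalidConfigError("n_streamlines must be positive")
        if self.n_points_raw < 2:
            raise InvalidConfigError("n_points_raw must be >= 2")
        if self.bundle_radius_mm < 0:
            raise InvalidConfigError("bundle_radius_mm must be >= 0")
        lo = self.lesion_center_segment - self.lesion_halfwidth_segments
        hi = self.lesion_center_segment + self.lesion_halfwidth_segments
        if self.lesion_halfwidth_segments < 1:
            raise InvalidConfigError("lesion_halfwidth_segments must be >= 1")
        if not (0 <= self.lesion_center_segment <= N_SEGMENTS - 1):
            raise InvalidConfigError("lesion_center_segment outside [0, 99]")
        if lo < 0 or hi > N_SEGMENTS - 1:
            raise InvalidConfigError(
                f"lesion window [{lo}, {hi}] does not fit in [0, {N_SEGMENTS - 1}]")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise InvalidConfigError("missing_fraction must lie in [0, 1)")
        if self.effect_size < 0:
            raise InvalidConfigError("effect_size must be >= 0")
        unknown = set(self.effect_metrics) - set(METRICS)
        if unknown:
            raise InvalidConfigError(f"unknown effect metrics: {sorted(unknown)}")
        for m in METRICS:
            if m not in self.noise_sd_per_metric:
                raise InvalidConfigError(f"noise_sd_per_metric missing {m}")
            if self.noise_sd_per_metric[m] < 0:
                raise InvalidConfigError(f"noise SD for {m} must be >= 0")
        for cls in (0, 1):
            if cls not in self.age_params:
                raise InvalidConfigError(f"age_params missing class {cls}")

    @property
    def lesion_window(self) -> tuple[int, int]:
        """Inclusive segment range carrying the planted effect."""
        return (self.lesion_center_segment - self.lesion_halfwidth_segments,
                self.lesion_center_segment + self.lesion_halfwidth_segments)


def default_c_grid() -> tuple[float, ...]:
    """Penalty grid 0.1, 0.2, ..., 10.0 (zero is invalid for the SVM penalty)."""
    return tuple(np.round(np.arange(1, 101) * 0.1, 1))


@dataclass
class ModelConfig:
    """Configuration of one classifier variant.

    ``feature_mode`` selects the input representation: ``histogram40`` (the
    4 statistics x 5 metrics x 2 hemispheres histogram features),
    ``segments1000+pca`` (all segment values reduced to the first
    ``pca_components`` principal components) or ``clinical`` (demographic
    and clinical variables only).

    ``tuning_scope`` controls where feature selection and C tuning happen:
    ``"resample"`` runs RFE and the inner CV grid search inside every
    bootstrap resample (the default, faithful to tuning within the inner
    loop per synthetic training set), ``"fold"`` runs them once per outer
    fold and lets the bootstrap only refit the final SVM -- a much cheaper
    approximation used for large simulation studies.
    """

    profile_method: str = "median"            # median | weighted_mean
    imputation: str = "median"                # median | knn
    knn_k: int = 10
    feature_mode: str = "histogram40"         # histogram40 | segments1000+pca | clinical
    include_clinical: bool = False
    metrics: tuple[str, ...] = METRICS
    use_rfe: bool = True
    rfe_k: int = 5
    pca_components: int = 4
    C_grid: tuple[float, ...] = field(default_factory=default_c_grid)
    outer_folds: int = 10
    inner_folds: int = 5
    n_bootstrap: int = 1000
    tuning_scope: str = "resample"            # resample | fold
    seed: int = 0

    def __post_init__(self) -> None:
        if self.profile_method not in ("median", "weighted_mean"):
            raise InvalidConfigError(f"unknown profile_method {self.profile_method!r}")
        if self.imputation not in ("median", "knn"):
            raise InvalidConfigError(f"unknown imputation {self.imputation!r}")
        if self.feature_mode not in ("histogram40", "segments1000+pca", "clinical"):
            raise InvalidConfigError(f"unknown feature_mode {self.feature_mode!r}")
        if self.tuning_scope not in ("resample", "fold"):
            raise InvalidConfigError(f"unknown tuning_scope {self.tuning_scope!r}")
        if any(c <= 0 for c in self.C_grid):
            raise InvalidConfigError("all C values must be > 0")
        if self.rfe_k < 1:
            raise InvalidConfigError("rfe_k must be >= 1")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise InvalidConfigError("folds must be >= 2")
        if self.n_bootstrap < 1:
            raise InvalidConfigError("n_bootstrap must be >= 1")
        unknown = set(self.metrics) - set(METRICS)
        if unknown:
            raise InvalidConfigError(f"unknown metrics: {sorted(unknown)}")


@dataclass
class PipelineConfig:
    """End-to-end run description: either a simulation block or paths to
    real data, plus stage toggles and a model configuration."""

    sim: SimConfig | None = None
    tractogram_paths: dict | None = None
    scalar_map_paths: dict | None = None
    patient_table_path: str | None = None
    stages: tuple[str, ...] = ("simulate", "profile", "features", "stats", "classify")
    model: ModelConfig = field(default_factory=ModelConfig)
    output_dir: str = "cstmotor_out"
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self) -> None:
        has_paths = any(x is not None for x in (
            self.tractogram_paths, self.scalar_map_paths, self.patient_table_path))
        if self.sim is not None and has_paths:
            raise InvalidConfigError(
                "config mixes a simulation block with real-data paths; provide one")
        if self.sim is None and not has_paths:
            raise InvalidConfigError("provide either a simulation block or data paths")
        valid = {"simulate", "dti", "profile", "features", "stats", "classify"}
        unknown = set(self.stages) - valid
        if unknown:
            raise InvalidConfigError(f"unknown stages: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# YAML round trips


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def save_config(cfg, path: str | Path) -> None:
    """Write any config dataclass to YAML."""
    payload = {"kind": type(cfg).__name__, "config": _to_plain(cfg)}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


_KINDS = {"SimConfig": SimConfig, "ModelConfig": ModelConfig,
          "PipelineConfig": PipelineConfig}


def _build(kind: str, data: dict):
    cls = _KINDS[kind]
    if cls is SimConfig:
        if "effect_metrics" in data:
            data["effect_metrics"] = tuple(data["effect_metrics"])
        if "age_params" in data:
            data["age_params"] = {int(k): tuple(v) for k, v in data["age_params"].items()}
    if cls is ModelConfig:
        for key in ("C_grid", "metrics"):
            if key in data:
                data[key] = tuple(data[key])
    if cls is PipelineConfig:
        if data.get("sim") is not None:
            data["sim"] = _build("SimConfig", data["sim"])
        if data.get("model") is not None:
            data["model"] = _build("ModelConfig", data["model"])
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
    return cls(**data)


def load_config(path: str | Path):
    """Load a config dataclass previously written by :func:`save_config`."""
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict) or "kind" not in payload:
        raise InvalidConfigError(f"{path}: not a cstmotor config file")
    kind = payload["kind"]
    if kind not in _KINDS:
        raise InvalidConfigError(f"{path}: unknown config kind {kind!r}")
    return _build(kind, payload["config"])
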