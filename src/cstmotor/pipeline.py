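"""End-to-end orchestration: simulate (or load) -> profiles -> features ->
group statistics -> classification, with provenance.

Every run writes a provenance file (config, seeds, package versions) from
which the whole output bundle is reproducible.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

import cstmotor
from cstmotor import io as cio
from cstmotor.classify import MotorStatusSVM
from cstmotor.cohort import HEMISPHERES, generate_cohort, generate_dwi_phantom
from cstmotor.config import METRICS, PipelineConfig, save_config
from cstmotor.features import assemble_features
from cstmotor.stats import (
    categorical_association,
    cca_first_correlation,
    hedges_g,
    mannwhitney_r,
    results_to_frame,
    segmentwise_ttest_fdr,
)
from cstmotor.tensor import fit_tensor_irlls, make_scheme, tensor_to_scalars

log = logging.getLogger("cstmotor")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def _provenance(config: PipelineConfig, out: Path) -> None:
    import sklearn
    import scipy
    prov = {
        "cstmotor": cstmotor.__version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
    }
    (out / "provenance.json").write_text(json.dumps(prov, indent=1))
    save_config(config, out / "pipeline_config.yaml")


def _profiles_for_stats(cohort, method: str):
    """(pid, side, metric) -> profile with side relabelled ipsi/contra."""
    prof = {}
    for p in cohort.patients:
        sides = {"ipsi": p.ipsilesional_hemisphere,
                 "contra": p.contralesional_hemisphere}
        for side, hemi in sides.items():
            for metric in METRICS:
                prof[(p.id, side, metric)] = cohort.profile(p.id, hemi, metric, method)
    return prof


def run_experiment(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns a dict of output paths and
    key results.  Raises :class:`StageError` naming the failed stage."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    _provenance(config, out)
    results: dict = {"output_dir": str(out)}

    stage = "simulate"
    try:
        if config.sim is not None:
            cohort = generate_cohort(config.sim)
            if "simulate" in config.stages:
                cio.save_patient_table(cohort.patients, out / "patients.csv")
                save_config(config.sim, out / "sim_config.yaml")
                results["patients"] = str(out / "patients.csv")
            log.info("simulated cohort: %d patients, %d deficit",
                     len(cohort.patients), int(cohort.labels().sum()))
        else:
            cohort = _load_real_cohort(config)

        if "dti" in config.stages:
            stage = "dti"
            # self-check: fit the tensor estimator on a noiseless phantom and
            # write the recovered scalar maps
            scheme = make_scheme(40, 1000.0, 1)
            D = np.zeros((4, 4, 4, 3, 3))
            D[..., 0, 0], D[..., 1, 1], D[..., 2, 2] = 1.7e-3, 0.3e-3, 0.3e-3
            dwi = generate_dwi_phantom(D, scheme, s0=1000.0, noise_sd=0.0,
                                       seed=config.seed)
            field = fit_tensor_irlls(dwi, scheme)
            dti_dir = out / "dti"
            dti_dir.mkdir(exist_ok=True)
            for metric, smap in tensor_to_scalars(field).items():
                cio.save_scalar_map(smap, dti_dir / f"phantom_{metric}.nii")
            results["dti"] = str(dti_dir)

        if "profile" in config.stages:
            stage = "profile"
            cio.save_profiles(cohort.profiles, out / "profiles.csv")
            results["profiles"] = str(out / "profiles.csv")

        if "features" in config.stages:
            stage = "features"
            table = MotorStatusSVM.from_cohort(cohort, config.model).table
            table.to_csv(out / "features.csv")
            results["features"] = str(out / "features.csv")

        if "stats" in config.stages:
            stage = "stats"
            _run_stats(cohort, config, out, results)

        if "classify" in config.stages:
            stage = "classify"
            model = MotorStatusSVM.from_cohort(cohort, config.model)
            cv = model.fit()
            cv.report.to_json(out / "cv_report.json")
            pd.DataFrame({
                "patient": [p.id for p in cohort.patients],
                "label": cv.report.labels,
                "prediction": cv.report.predictions,
                "score": cv.report.scores,
            }).to_csv(out / "predictions.csv", index=False)
            (out / "summary.txt").write_text(cv.summary() + "\n")
            results["cv_report"] = str(out / "cv_report.json")
            results["pooled"] = cv.report.pooled
            log.info("classification done: %s", cv.report.pooled)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage '{stage}' failed: {exc}") from exc

    return results


def _run_stats(cohort, config: PipelineConfig, out: Path, results: dict) -> None:
    method = config.model.profile_method
    prof = _profiles_for_stats(cohort, method)
    labels = cohort.labels()
    ids = [p.id for p in cohort.patients]
    seg_rows = []
    for metric in METRICS:
        mat0 = np.stack([prof[(pid, "ipsi", metric)]
                         for pid, y in zip(ids, labels) if y == 0])
        mat1 = np.stack([prof[(pid, "ipsi", metric)]
                         for pid, y in zip(ids, labels) if y == 1])
        seg = segmentwise_ttest_fdr(mat0, mat1)
        df = seg.to_frame()
        df.insert(0, "metric", metric)
        seg_rows.append(df)
    pd.concat(seg_rows).to_csv(out / "segmentwise_stats.csv", index=False)

    ages = np.array([p.age for p in cohort.patients])
    tests = {}
    a1, a0 = ages[labels == 1], ages[labels == 0]
    tests["age_hedges_g"] = hedges_g(a1.mean(), a1.std(ddof=1), a1.size,
                                     a0.mean(), a0.std(ddof=1), a0.size)
    gender = np.array([p.gender == "female" for p in cohort.patients])
    tests["gender_assoc"] = categorical_association(
        [[int(np.sum(gender & (labels == c))), int(np.sum(~gender & (labels == c)))]
         for c in (0, 1)])
    left = np.array([p.ipsilesional_hemisphere == "left" for p in cohort.patients])
    tests["hemisphere_assoc"] = categorical_association(
        [[int(np.sum(left & (labels == c))), int(np.sum(~left & (labels == c)))]
         for c in (0, 1)])
    mean_ipsi_adc = np.array([np.nanmean(prof[(pid, "ipsi", "ADC")]) for pid in ids])
    tests["adc_mean_mwu"] = mannwhitney_r(mean_ipsi_adc[labels == 1],
                                          mean_ipsi_adc[labels == 0])
    df = results_to_frame(tests)
    df.to_csv(out / "group_stats.csv", index=False)

    # CCA between the 40 histogram features and age
    table = assemble_features(
        {(pid, h, m): cohort.profile(pid, h, m, method)
         for pid in ids for h in HEMISPHERES for m in METRICS},
        cohort.patients, mode="histogram40")
    X = table.X.to_numpy(dtype=float)
    X = np.where(np.isnan(X), np.nanmedian(X, axis=0), X)
    cca = cca_first_correlation(X, ages) if len(ids) > X.shape[1] + 1 else float("nan")
    summary = {"cca_features_age": cca,
               "tests": {k: {"stat": v.statistic, "p": v.p} for k, v in tests.items()}}
    (out / "stats_summary.json").write_text(json.dumps(summary, indent=1))
    results["stats"] = str(out / "group_stats.csv")
    results["cca_features_age"] = cca


def _load_real_cohort(config: PipelineConfig):
    """Minimal real-data path: load patient table, tractograms and maps,
    then compute profiles with both estimators."""
    from cstmotor.cohort import CohortData
    from cstmotor.tractometry import profile_median, profile_weighted_mean, sample_bundle
    from cstmotor.cohort import resample_bundle_fast

    if config.patient_table_path is None:
        raise StageError("stage 'load' failed: no patient table given")
    patients = cio.load_patient_table(config.patient_table_path)
    profiles: dict = {}
    for p in patients:
        for hemi in HEMISPHERES:
            t = cio.load_tractogram(config.tractogram_paths[p.id][hemi], hemi)
            lengths = {s.shape[0] for s in t.streamlines}
            if len(lengths) == 1:
                pts = resample_bundle_fast(np.stack(t.streamlines))
            else:
                from cstmotor.tractometry import resample_streamline
                pts = np.stack([resample_streamline(s) for s in t.streamlines])
            for metric in METRICS:
                m = cio.load_scalar_map(
                    config.scalar_map_paths[p.id][hemi][metric], metric)
                vals = sample_bundle(pts, m)
                profiles[(p.id, hemi, metric, "median")] = \
                    profile_median(vals, metric, hemi).values
                profiles[(p.id, hemi, metric, "weighted_mean")] = \
                    profile_weighted_mean(vals, pts, metric, hemi).values
    return CohortData(config=None, patients=patients, profiles=profiles,
                      ground_truth={}, missing_masks={})
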