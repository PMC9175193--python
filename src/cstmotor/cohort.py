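"""Synthetic cohort generator.

Because the clinical data the analysis was designed for are not public,
this module generates cohorts with the statistical structure the pipeline
assumes: per-hemisphere corticospinal-tract-like streamline bundles, scalar
metric fields (AD/ADC/FA/FD/RD) with a planted, class-dependent lesion
effect on the ipsilesional side, single-shell DWI phantoms for the tensor
fit, and a patient table with the demographic structure of a 116-patient
glioma cohort (45 with motor deficits, class-specific age distributions).

Everything is reproducible from a single seed: patient ``i`` receives
sub-seeds derived from ``numpy.random.SeedSequence((seed, i, stream))``
where ``stream`` enumerates the independent random draws (bundle left/right,
field noise per hemisphere, attributes, missingness), so any patient can be
regenerated in isolation.

The planted effect is expressed in SD units: inside the lesion window on
the ipsilesional side, deficit-class patients receive a shift of
``effect_size * noise_sd_per_metric[metric]``, where ``noise_sd_per_metric``
is the between-patient SD (a global per-patient field offset).  The ground
truth stored with the cohort suffices to recompute every expected segment
mean analytically, without re-simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from cstmotor.config import (
    BASELINES,
    EFFECT_SIGNS,
    METRICS,
    N_SEGMENTS,
    InvalidConfigError,
    SimConfig,
)
from cstmotor.tractometry import (
    ScalarMap,
    Tractogram,
    profile_median,
    profile_weighted_mean,
    sample_bundle,
)

HEMISPHERES = ("left", "right")

_GRADES = ("II", "III", "IV")
_LOCATIONS = ("frontal", "parietal", "insular", "temporal")

# Per-class categorical frequencies mirrored from the cohort the generator
# emulates (grade II/III/IV and tumour location counts per class).
_GRADE_P = {0: np.array([13, 18, 40]) / 71.0, 1: np.array([3, 5, 37]) / 45.0}
_LOC_P = {0: np.array([35, 19, 10, 7]) / 71.0, 1: np.array([25, 12, 5, 3]) / 45.0}
_P_FEMALE = 43 / 116.0
_P_LEFT = 47 / 116.0
_RMT = {  # (mean, sd) for (ipsi, contra) per class, V/m
    0: ((33.72, 7.2), (34.3, 6.05)),
    1: ((34.64, 9.15), (35.62, 8.64)),
}

# Amplitude of the smooth along-tract variation of the baseline profile,
# as a fraction of the baseline value.
_BASELINE_WOBBLE = 0.05
# Voxel-level field noise as a fraction of the between-patient SD.
_VOXEL_NOISE_FRACTION = 0.5


class CohortError(ValueError):
    """Raised when a cohort cannot be generated under the given config."""


@dataclass
class PatientRecord:
    """One synthetic patient; ``mrc_class`` is 1 iff the MRC muscle-power
    score is below 5 (motor deficit)."""

    id: str
    age: float
    gender: str                      # female | male
    who_grade: str                   # II | III | IV
    tumour_location: str             # frontal | parietal | insular | temporal
    ipsilesional_hemisphere: str     # left | right
    rmt_ipsi: float
    rmt_contra: float
    mrc_score: int
    mrc_class: int

    def __post_init__(self) -> None:
        if self.mrc_class != int(self.mrc_score < 5):
            raise CohortError("mrc_class must equal (mrc_score < 5)")

    @property
    def contralesional_hemisphere(self) -> str:
        return "right" if self.ipsilesional_hemisphere == "left" else "left"


# ---------------------------------------------------------------------------
# Geometry: centerline and hemisphere grid


def _base_curve(t: np.ndarray, hemisphere: str) -> np.ndarray:
    """Smooth curved CST-like centerline, inferior (t=0, medulla) to
    superior (t=1, M1), in mm.  Left hemisphere has negative x (RAS)."""
    sign = -1.0 if hemisphere == "left" else 1.0
    t = np.asarray(t, dtype=float)
    x = sign * (6.0 + 16.0 * t ** 2)
    y = 12.0 * t * (1.0 - t)
    z = 80.0 * t
    return np.stack([x, y, z], axis=-1)


def centerline(hemisphere: str, n: int = N_SEGMENTS) -> np.ndarray:
    """Centerline resampled to ``n`` points at equal arc length."""
    fine = _base_curve(np.linspace(0.0, 1.0, 512), hemisphere)
    seg = np.linalg.norm(np.diff(fine, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, arc[-1], n)
    out = np.empty((n, 3))
    for d in range(3):
        out[:, d] = np.interp(targets, arc, fine[:, d])
    return out


def anchors(hemisphere: str) -> tuple[np.ndarray, np.ndarray]:
    """(inferior, superior) anchor points for orientation checks."""
    c = centerline(hemisphere, 2)
    return c[0], c[-1]


@dataclass(frozen=True)
class _GeometryKey:
    hemisphere: str
    bundle_radius_mm: float
    voxel_size_mm: float
    grid_margin_mm: float


@lru_cache(maxsize=16)
def _hemisphere_grid(key: _GeometryKey):
    """Grid definition plus per-voxel (segment index, distance-to-core).

    Returns (affine, shape, seg_index, dist) where ``seg_index`` assigns
    each voxel the segment of the nearest centerline point and ``dist`` the
    distance to it (mm).
    """
    cl = centerline(key.hemisphere, N_SEGMENTS)
    pad = key.grid_margin_mm + 3.0 * key.bundle_radius_mm
    lo = cl.min(axis=0) - pad
    hi = cl.max(axis=0) + pad
    vox = key.voxel_size_mm
    shape = tuple(int(np.ceil((hi[d] - lo[d]) / vox)) + 1 for d in range(3))
    affine = np.eye(4)
    affine[:3, :3] *= vox
    affine[:3, 3] = lo
    idx = np.indices(shape).reshape(3, -1).T
    centers = idx * vox + lo
    d2 = ((centers[:, None, :] - cl[None, :, :]) ** 2).sum(axis=2)
    seg_index = np.argmin(d2, axis=1)
    dist = np.sqrt(d2[np.arange(d2.shape[0]), seg_index])
    return affine, shape, seg_index.reshape(shape), dist.reshape(shape)


def _grid_for(config: SimConfig, hemisphere: str):
    return _hemisphere_grid(_GeometryKey(
        hemisphere, float(config.bundle_radius_mm),
        float(config.voxel_size_mm), float(config.grid_margin_mm)))


# ---------------------------------------------------------------------------
# Bundle generation


def _frames(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-point orthonormal (normal, binormal) vectors perpendicular to the
    local tangent of a polyline."""
    tang = np.gradient(points, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    ref = np.array([1.0, 0.0, 0.0])
    if np.max(np.abs(tang @ ref)) > 0.99:
        ref = np.array([0.0, 1.0, 0.0])
    normal = ref - tang * (tang @ ref)[:, None]
    normal /= np.linalg.norm(normal, axis=1, keepdims=True)
    binormal = np.cross(tang, normal)
    return normal, binormal


def generate_bundle(config: SimConfig, hemisphere: str,
                    seed: int | None = None) -> Tractogram:
    """Scatter ``n_streamlines`` polylines around the hemisphere centerline.

    Each streamline is the centerline displaced by a constant random offset
    in the local perpendicular plane, drawn from an isotropic Gaussian with
    SD ``bundle_radius_mm`` per axis.  Streamlines run inferior->superior
    and the result is byte-identical for identical seeds.
    """
    if hemisphere not in HEMISPHERES:
        raise CohortError(f"unknown hemisphere {hemisphere!r}")
    if config.n_streamlines < 1 or config.bundle_radius_mm < 0:
        raise InvalidConfigError("invalid bundle configuration")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 7)))
    cl = centerline(hemisphere, config.n_points_raw)
    normal, binormal = _frames(cl)
    offsets = rng.normal(0.0, config.bundle_radius_mm,
                         size=(config.n_streamlines, 2))
    pts = (cl[None, :, :]
           + offsets[:, 0, None, None] * normal[None, :, :]
           + offsets[:, 1, None, None] * binormal[None, :, :])
    return Tractogram(list(pts), hemisphere=hemisphere)


def resample_bundle_fast(streamlines: np.ndarray, n: int = N_SEGMENTS) -> np.ndarray:
    """Vectorised equal-arc-length resampling of an (S, k, 3) bundle whose
    streamlines all have the same number of points.

    Equivalent to applying
    :func:`cstmotor.tractometry.resample_streamline` per streamline.
    """
    pts = np.asarray(streamlines, dtype=float)
    S, k, _ = pts.shape
    seg = np.linalg.norm(np.diff(pts, axis=1), axis=2)          # (S, k-1)
    arc = np.concatenate([np.zeros((S, 1)), np.cumsum(seg, axis=1)], axis=1)
    total = arc[:, -1]
    if np.any(total <= 0):
        raise CohortError("zero-length streamline in bundle")
    targets = np.linspace(0.0, 1.0, n)[None, :] * total[:, None]  # (S, n)
    # row-offset trick: make arcs globally increasing so one searchsorted
    # call resolves every row
    big = total.max() * 2.0 + 1.0
    off = np.arange(S)[:, None] * big
    idx = np.searchsorted(( arc + off).ravel(), (targets + off).ravel(),
                          side="right").reshape(S, n)
    idx -= np.arange(S)[:, None] * k          # back to per-row indices
    idx = np.clip(idx, 1, k - 1)
    i0 = idx - 1
    rows = np.arange(S)[:, None]
    a0 = arc[rows, i0]
    a1 = arc[rows, idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(a1 > a0, (targets - a0) / np.maximum(a1 - a0, 1e-300), 0.0)
    w = np.clip(w, 0.0, 1.0)
    out = pts[rows, i0] * (1.0 - w[..., None]) + pts[rows, idx] * w[..., None]
    out[:, 0] = pts[:, 0]
    out[:, -1] = pts[:, -1]
    return out


# ---------------------------------------------------------------------------
# Metric fields


def _baseline_profile(metric: str) -> np.ndarray:
    """Baseline metric value per segment: physiological tract value with a
    gentle smooth along-tract variation."""
    u = np.linspace(0.0, 1.0, N_SEGMENTS)
    return BASELINES[metric] * (1.0 + _BASELINE_WOBBLE * np.sin(2.0 * np.pi * u))


def lesion_segments(config: SimConfig) -> np.ndarray:
    lo, hi = config.lesion_window
    return np.arange(lo, hi + 1)


@dataclass
class GroundTruth:
    """Planted parameters for one patient, sufficient to recompute expected
    segment means analytically."""

    patient_offsets: dict      # (hemisphere, metric) -> float
    lesion_shift: dict         # metric -> float (0 for unaffected patients)
    lesion_window: tuple[int, int]
    ipsilesional_hemisphere: str

    def expected_profile(self, hemisphere: str, metric: str) -> np.ndarray:
        prof = _baseline_profile(metric) + self.patient_offsets[(hemisphere, metric)]
        if hemisphere == self.ipsilesional_hemisphere:
            lo, hi = self.lesion_window
            prof = prof.copy()
            prof[lo:hi + 1] += self.lesion_shift[metric]
        return prof


def _field_seed(config: SimConfig, patient_index: int, hemisphere: str) -> np.random.SeedSequence:
    h = HEMISPHERES.index(hemisphere)
    return np.random.SeedSequence((int(config.seed), int(patient_index), 11 + h))


def generate_metric_fields(config: SimConfig, patient: PatientRecord,
                           hemisphere: str, seed=None,
                           patient_index: int = 0) -> tuple[dict[str, ScalarMap], GroundTruth]:
    """Scalar metric fields for one (patient, hemisphere).

    The field equals the along-tract baseline (broadcast to each voxel via
    its nearest centerline segment), plus a per-(patient, hemisphere,
    metric) global offset with SD ``noise_sd_per_metric`` (between-patient
    variability), plus -- for deficit-class patients on the ipsilesional
    side -- the planted lesion shift inside the lesion window, plus voxel
    noise.  FA/FD shift downward, AD/ADC/RD upward.
    """
    if hemisphere not in HEMISPHERES:
        raise CohortError(f"unknown hemisphere {hemisphere!r}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else (
        np.random.SeedSequence(seed) if seed is not None
        else _field_seed(config, patient_index, hemisphere))
    rng = np.random.default_rng(ss)
    affine, shape, seg_index, dist = _grid_for(config, hemisphere)
    lesion_radius = 3.0 * config.bundle_radius_mm + config.voxel_size_mm
    lo, hi = config.lesion_window
    in_window = (seg_index >= lo) & (seg_index <= hi) & (dist <= lesion_radius)
    ipsi = hemisphere == patient.ipsilesional_hemisphere

    maps: dict[str, ScalarMap] = {}
    offsets: dict[tuple[str, str], float] = {}
    shifts: dict[str, float] = {}
    for metric in METRICS:
        sd = config.noise_sd_per_metric[metric]
        base = _baseline_profile(metric)[seg_index]
        offset = float(rng.normal(0.0, sd))
        shift = 0.0
        if patient.mrc_class == 1 and metric in config.effect_metrics:
            shift = EFFECT_SIGNS[metric] * config.effect_size * sd
        vals = base + offset
        if ipsi and shift != 0.0:
            vals = vals + shift * in_window
        vals = vals + rng.normal(0.0, _VOXEL_NOISE_FRACTION * sd, size=shape)
        maps[metric] = ScalarMap(vals, affine, metric=metric)
        offsets[(hemisphere, metric)] = offset
        shifts[metric] = shift  # applied only on the ipsilesional side
    gt = GroundTruth(patient_offsets=offsets, lesion_shift=shifts,
                     lesion_window=(lo, hi),
                     ipsilesional_hemisphere=patient.ipsilesional_hemisphere)
    return maps, gt


def generate_dwi_phantom(tensor_field: np.ndarray, scheme, s0: float = 1000.0,
                         noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """Single-shell DWI signal from a per-voxel tensor field.

    S(g, b) = S0 * exp(-b g^T D g) per voxel, with Rician noise of
    parameter ``noise_sd`` (magnitude of a complex Gaussian perturbation),
    as appropriate for magnitude MR data.  Deterministic per seed.
    """
    D = np.asarray(tensor_field, dtype=float)
    if D.shape[-2:] != (3, 3):
        raise CohortError("tensor field must have trailing (3, 3) axes")
    if not np.allclose(D, np.swapaxes(D, -1, -2), atol=1e-12):
        raise CohortError("tensors must be symmetric")
    ev = np.linalg.eigvalsh(D)
    if np.min(ev) < -1e-12:
        raise CohortError("tensors must be positive semidefinite")
    if scheme.n_b0 < 1 or scheme.n_dw < 6:
        raise CohortError("scheme needs >= 1 b=0 and >= 6 b>0 volumes")
    b = scheme.bvals
    g = scheme.bvecs
    # quadratic form g^T D g for every voxel x volume
    q = np.einsum("...ij,nj,ni->...n", D, g, g)
    S = s0 * np.exp(-b * q)
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence((int(seed), 13)))
        n1 = rng.normal(0.0, noise_sd, size=S.shape)
        n2 = rng.normal(0.0, noise_sd, size=S.shape)
        S = np.sqrt((S + n1) ** 2 + n2 ** 2)
    return S


# ---------------------------------------------------------------------------
# Whole cohort


@dataclass
class CohortData:
    """A generated cohort.

    Tract profiles (both estimators) are precomputed and stored; the
    volumetric maps and tractograms are regenerated deterministically on
    demand from the stored config and per-patient sub-seeds, keeping the
    object small even for large cohorts.
    """

    config: SimConfig
    patients: list[PatientRecord]
    profiles: dict      # (patient_id, hemisphere, metric, method) -> (100,) array
    ground_truth: dict  # patient_id -> GroundTruth
    missing_masks: dict  # (patient_id, hemisphere, metric) -> bool array (True=missing)

    def patient(self, patient_id: str) -> PatientRecord:
        for p in self.patients:
            if p.id == patient_id:
                return p
        raise KeyError(patient_id)

    def _index(self, patient_id: str) -> int:
        for i, p in enumerate(self.patients):
            if p.id == patient_id:
                return i
        raise KeyError(patient_id)

    def tractogram(self, patient_id: str, hemisphere: str) -> Tractogram:
        i = self._index(patient_id)
        seed = np.random.SeedSequence(
            (int(self.config.seed), i, 3 + HEMISPHERES.index(hemisphere)))
        return generate_bundle(self.config, hemisphere, seed=_ss_to_int(seed))

    def scalar_maps(self, patient_id: str, hemisphere: str) -> dict[str, ScalarMap]:
        i = self._index(patient_id)
        maps, _ = generate_metric_fields(
            self.config, self.patient(patient_id), hemisphere,
            seed=_field_seed(self.config, i, hemisphere))
        return maps

    def profile(self, patient_id: str, hemisphere: str, metric: str,
                method: str = "median") -> np.ndarray:
        return self.profiles[(patient_id, hemisphere, metric, method)]

    def labels(self) -> np.ndarray:
        return np.array([p.mrc_class for p in self.patients])

    def expected_profile(self, patient_id: str, hemisphere: str,
                         metric: str) -> np.ndarray:
        return self.ground_truth[patient_id].expected_profile(hemisphere, metric)


def _ss_to_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1, np.uint32)[0])


def _draw_patient(rng: np.random.Generator, i: int, cls: int,
                  config: SimConfig) -> PatientRecord:
    mean, sd = config.age_params[cls]
    age = float(np.clip(rng.normal(mean, sd), 18.0, 95.0))
    gender = "female" if rng.random() < _P_FEMALE else "male"
    grade = _GRADES[rng.choice(3, p=_GRADE_P[cls])]
    loc = _LOCATIONS[rng.choice(4, p=_LOC_P[cls])]
    hemi = "left" if rng.random() < _P_LEFT else "right"
    (mi, si), (mc, sc) = _RMT[cls]
    rmt_i = float(max(rng.normal(mi, si), 5.0))
    rmt_c = float(max(rng.normal(mc, sc), 5.0))
    mrc = 5 if cls == 0 else int(rng.integers(1, 5))
    return PatientRecord(
        id=f"sub-{i:04d}", age=age, gender=gender, who_grade=grade,
        tumour_location=loc, ipsilesional_hemisphere=hemi,
        rmt_ipsi=rmt_i, rmt_contra=rmt_c, mrc_score=mrc,
        mrc_class=int(mrc < 5))


def generate_cohort(config: SimConfig) -> CohortData:
    """Generate a full cohort: patients, planted fields, and precomputed
    median and weighted-mean tract profiles with missingness applied.

    Class labels are assigned by exact counts (``round(n * prevalence)``
    deficit patients), shuffled deterministically, so the realised
    prevalence matches the configured one.
    """
    n = config.n_patients
    n1 = int(round(n * config.prevalence))
    n0 = n - n1
    if n0 < 2 or n1 < 2:
        raise CohortError("need >= 2 patients per class for downstream statistics")

    label_rng = np.random.default_rng(np.random.SeedSequence((int(config.seed), 1)))
    labels = np.array([1] * n1 + [0] * n0)
    labels = labels[label_rng.permutation(n)]

    patients: list[PatientRecord] = []
    profiles: dict = {}
    ground_truth: dict = {}
    missing_masks: dict = {}

    for i in range(n):
        attr_rng = np.random.default_rng(
            np.random.SeedSequence((int(config.seed), i, 2)))
        p = _draw_patient(attr_rng, i, int(labels[i]), config)
        patients.append(p)

        gt_offsets: dict = {}
        gt_shift: dict = {}
        for hemisphere in HEMISPHERES:
            bundle_seed = np.random.SeedSequence(
                (int(config.seed), i, 3 + HEMISPHERES.index(hemisphere)))
            bundle = generate_bundle(config, hemisphere,
                                     seed=_ss_to_int(bundle_seed))
            pts = resample_bundle_fast(np.stack(bundle.streamlines), N_SEGMENTS)
            maps, gt = generate_metric_fields(
                config, p, hemisphere, seed=_field_seed(config, i, hemisphere))
            gt_offsets.update(gt.patient_offsets)
            if hemisphere == p.ipsilesional_hemisphere:
                gt_shift = gt.lesion_shift
            miss_rng = np.random.default_rng(
                np.random.SeedSequence((int(config.seed), i,
                                        17 + HEMISPHERES.index(hemisphere))))
            for metric in METRICS:
                vals = sample_bundle(pts, maps[metric])
                med = profile_median(vals, metric, hemisphere).values
                wm = profile_weighted_mean(vals, pts, metric, hemisphere).values
                mask = miss_rng.random(N_SEGMENTS) < config.missing_fraction
                med = med.copy()
                wm = wm.copy()
                med[mask] = np.nan
                wm[mask] = np.nan
                profiles[(p.id, hemisphere, metric, "median")] = med
                profiles[(p.id, hemisphere, metric, "weighted_mean")] = wm
                missing_masks[(p.id, hemisphere, metric)] = mask

        ground_truth[p.id] = GroundTruth(
            patient_offsets=gt_offsets,
            lesion_shift=gt_shift if gt_shift else {m: 0.0 for m in METRICS},
            lesion_window=config.lesion_window,
            ipsilesional_hemisphere=p.ipsilesional_hemisphere)

    return CohortData(config=config, patients=patients, profiles=profiles,
                      ground_truth=ground_truth, missing_masks=missing_masks)
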