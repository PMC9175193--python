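"""Tractometry: from streamline bundles and scalar maps to 100-segment
tract profiles.

The along-tract convention throughout the package is that segment 0 lies at
the medulla oblongata (inferior) and segment 99 at M1 (superior).  Two
profile estimators are provided: the per-segment median across streamlines,
and the per-segment mean weighted by the inverse Mahalanobis distance of
each streamline's point from the tract core, which down-weights streamlines
far from the bundle centre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from cstmotor.config import N_SEGMENTS


class TractometryError(ValueError):
    """Raised on invalid tractometry inputs (empty bundles, degenerate
    streamlines, non-invertible affines)."""


@dataclass
class Tractogram:
    """An ordered set of streamlines (3D polylines, mm coordinates) for one
    hemisphere."""

    streamlines: list[np.ndarray]
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        if len(self.streamlines) == 0:
            raise TractometryError("tractogram must contain at least one streamline")
        self.streamlines = [np.asarray(s, dtype=float) for s in self.streamlines]
        for s in self.streamlines:
            if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2:
                raise TractometryError("each streamline needs >= 2 points of 3 coords")
            if not np.all(np.isfinite(s)):
                raise TractometryError("streamline coordinates must be finite")

    def __len__(self) -> int:
        return len(self.streamlines)


@dataclass
class ScalarMap:
    """A 3D grid of one diffusion metric plus its voxel->mm affine."""

    values: np.ndarray
    affine: np.ndarray
    metric: str = "FA"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.values.ndim != 3:
            raise TractometryError("scalar map must be a 3D grid")
        if self.affine.shape != (4, 4):
            raise TractometryError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-15:
            raise TractometryError("affine is not invertible")


@dataclass
class TractProfile:
    """100 ordered per-segment values of one metric on one hemisphere.

    Missing segments are stored as NaN; the array always has exactly
    :data:`~cstmotor.config.N_SEGMENTS` entries.
    """

    values: np.ndarray
    metric: str = "FA"
    hemisphere: str = "left"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_SEGMENTS,):
            raise TractometryError(f"profile must have exactly {N_SEGMENTS} entries")

    @property
    def n_valid(self) -> int:
        return int(np.sum(~np.isnan(self.values)))


# ---------------------------------------------------------------------------
# Resampling and orientation


def _arc_lengths(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_streamline(points: np.ndarray, n: int = N_SEGMENTS) -> np.ndarray:
    """Resample a polyline to ``n`` points at equal arc-length spacing.

    Linear interpolation along the polyline; the first and last points are
    preserved exactly.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2:
        raise TractometryError("streamline needs at least 2 points")
    arc = _arc_lengths(points)
    total = arc[-1]
    if total <= 0:
        raise TractometryError("zero-length streamline cannot be resampled")
    targets = np.linspace(0.0, total, n)
    out = np.empty((n, points.shape[1]))
    for d in range(points.shape[1]):
        out[:, d] = np.interp(targets, arc, points[:, d])
    out[0] = points[0]
    out[-1] = points[-1]
    return out


def resample_tractogram(t: Tractogram, n: int = N_SEGMENTS) -> np.ndarray:
    """Resample every streamline; returns an (n_streamlines, n, 3) array."""
    return np.stack([resample_streamline(s, n) for s in t.streamlines])


def orient_streamlines(t: Tractogram, inferior_anchor, superior_anchor) -> Tractogram:
    """Flip streamlines so each runs inferior -> superior.

    A streamline is reversed iff its first point is closer to the superior
    anchor than its last point.  Idempotent.
    """
    inf = np.asarray(inferior_anchor, dtype=float)
    sup = np.asarray(superior_anchor, dtype=float)
    if np.allclose(inf, sup):
        raise TractometryError("anchors must be distinct")
    oriented = []
    for s in t.streamlines:
        if np.linalg.norm(s[0] - sup) < np.linalg.norm(s[-1] - sup):
            oriented.append(s[::-1].copy())
        else:
            oriented.append(s)
    return Tractogram(oriented, hemisphere=t.hemisphere)


# ---------------------------------------------------------------------------
# Scalar sampling


def sample_scalars(points: np.ndarray, m: ScalarMap) -> np.ndarray:
    """Trilinearly interpolate a scalar map at streamline points (mm).

    Points outside the grid yield NaN (missing) rather than zero, which
    would bias profiles toward the background.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    inv = np.linalg.inv(m.affine)
    vox = points @ inv[:3, :3].T + inv[:3, 3]
    out = ndimage.map_coordinates(m.values, vox.T, order=1,
                                  mode="constant", cval=np.nan)
    # map_coordinates treats the edge half-voxel as in-bounds only up to the
    # last grid point; anything beyond returns cval (NaN) as intended.
    return out


def sample_bundle(points: np.ndarray, m: ScalarMap) -> np.ndarray:
    """Sample a whole resampled bundle (n_streamlines, n_points, 3) at once;
    returns (n_streamlines, n_points)."""
    n_s, n_p, _ = points.shape
    flat = sample_scalars(points.reshape(-1, 3), m)
    return flat.reshape(n_s, n_p)


# ---------------------------------------------------------------------------
# Profile estimators


def profile_median(values: np.ndarray, metric: str = "FA",
                   hemisphere: str = "left") -> TractProfile:
    """Per-segment median across streamlines, ignoring missing samples.

    Segments where every streamline sample is missing come out missing.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.size == 0:
        raise TractometryError("need a non-empty (n_streamlines, n_segments) matrix")
    with warnings.catch_warnings():
        # all-NaN segments legitimately produce NaN; silence the warning
        warnings.simplefilter("ignore", category=RuntimeWarning)
        med = np.nanmedian(values, axis=0)
    return TractProfile(med, metric=metric, hemisphere=hemisphere)


def _segment_weights(points: np.ndarray) -> np.ndarray:
    """Inverse-Mahalanobis streamline weights per segment.

    ``points``: (n_streamlines, n_segments, 3).  For each segment the tract
    core is the mean point and the covariance is the 3x3 sample covariance
    across streamlines, regularised by eps = 1e-6 * trace/3 + 1e-12 on the
    diagonal; weights are 1/max(distance, 1e-8), unnormalised.
    """
    n, n_seg, _ = points.shape
    core = points.mean(axis=0)                         # (n_seg, 3)
    dev = points - core                                # (n, n_seg, 3)
    cov = np.einsum("isk,isl->skl", dev, dev) / (n - 1)  # (n_seg, 3, 3)
    trace = np.trace(cov, axis1=1, axis2=2)
    eps = 1e-6 * trace / 3.0 + 1e-12
    cov = cov + eps[:, None, None] * np.eye(3)
    inv = np.linalg.inv(cov)                           # (n_seg, 3, 3)
    d2 = np.einsum("isk,skl,isl->is", dev, inv, dev)
    d = np.sqrt(np.maximum(d2, 0.0))
    return 1.0 / np.maximum(d, 1e-8)


def profile_weighted_mean(values: np.ndarray, points: np.ndarray,
                          metric: str = "FA",
                          hemisphere: str = "left") -> TractProfile:
    """Per-segment mean weighted by inverse Mahalanobis distance from the
    tract core, so streamlines far from the bundle centre contribute less.

    Parameters
    ----------
    values
        (n_streamlines, n_segments) sampled metric values, NaN = missing.
    points
        (n_streamlines, n_segments, 3) the resampled coordinates the values
        were sampled at.
    """
    values = np.asarray(values, dtype=float)
    points = np.asarray(points, dtype=float)
    if values.ndim != 2:
        raise TractometryError("values must be (n_streamlines, n_segments)")
    n, n_seg = values.shape
    if n < 2:
        raise TractometryError("weighted mean needs >= 2 streamlines "
                               "(covariance undefined)")
    if points.shape != (n, n_seg, 3):
        raise TractometryError("points shape must match values with 3 coords")
    w = _segment_weights(points)                       # (n, n_seg)
    valid = ~np.isnan(values)
    w = np.where(valid, w, 0.0)
    wsum = w.sum(axis=0)
    vals = np.where(valid, values, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        prof = np.where(wsum > 0, (w * vals).sum(axis=0) / wsum, np.nan)
    return TractProfile(prof, metric=metric, hemisphere=hemisphere)


def bundle_profiles(tractogram: Tractogram, maps: dict[str, ScalarMap],
                    method: str = "median",
                    n_segments: int = N_SEGMENTS) -> dict[str, TractProfile]:
    """Resample a bundle once and profile every metric map along it."""
    pts = resample_tractogram(tractogram, n_segments)
    out = {}
    for metric, m in maps.items():
        vals = sample_bundle(pts, m)
        if method == "median":
            out[metric] = profile_median(vals, metric, tractogram.hemisphere)
        elif method == "weighted_mean":
            out[metric] = profile_weighted_mean(vals, pts, metric,
                                                tractogram.hemisphere)
        else:
            raise TractometryError(f"unknown profile method {method!r}")
    return out
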