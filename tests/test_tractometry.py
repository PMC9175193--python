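"""Resampling, orientation, scalar sampling and the two profile estimators,
each checked against independent brute-force computations."""

import numpy as np
import pytest

from cstmotor.tractometry import (
    ScalarMap,
    Tractogram,
    TractometryError,
    orient_streamlines,
    profile_median,
    profile_weighted_mean,
    resample_streamline,
    sample_bundle,
    sample_scalars,
)


# ---------------------------------------------------------------------------
# resample_streamline


def test_resample_straight_segment_gives_unit_spacing():
    s = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 99.0]])
    out = resample_streamline(s, 100)
    expected = np.stack([np.zeros(100), np.zeros(100), np.arange(100.0)], axis=1)
    np.testing.assert_allclose(out, expected, atol=1e-12)


def _walk_polyline(points, target):
    """Brute-force arc-length parameterisation: walk segments until the
    target arc distance falls inside one, then interpolate linearly."""
    acc = 0.0
    for a, b in zip(points[:-1], points[1:]):
        seg = np.linalg.norm(b - a)
        if acc + seg >= target - 1e-12:
            f = (target - acc) / seg
            return a + f * (b - a)
        acc += seg
    return points[-1]


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_resample_matches_exact_arclength_oracle(seed):
    rng = np.random.default_rng(seed)
    s = np.cumsum(rng.normal(size=(17, 3)), axis=0)
    out = resample_streamline(s, 100)
    total = np.sum(np.linalg.norm(np.diff(s, axis=0), axis=1))
    want = np.array([_walk_polyline(s, t)
                     for t in np.linspace(0.0, total, 100)])
    np.testing.assert_allclose(out, want, atol=1e-9)
    np.testing.assert_allclose(out[0], s[0])
    np.testing.assert_allclose(out[-1], s[-1])


def test_resample_semicircle_spacing_matches_arc_length():
    theta = np.linspace(0.0, np.pi, 5000)
    s = np.stack([np.cos(theta), np.sin(theta), np.zeros_like(theta)], axis=1)
    out = resample_streamline(s, 100)
    d = np.linalg.norm(np.diff(out, axis=0), axis=1)
    assert np.allclose(d, np.pi / 99.0, atol=1e-3)


def test_resample_zero_length_raises():
    with pytest.raises(TractometryError):
        resample_streamline(np.zeros((5, 3)))


# ---------------------------------------------------------------------------
# orient_streamlines


def _brute_orient(streamlines, inf, sup):
    """Assignment minimising summed endpoint-to-anchor distance."""
    out = []
    for s in streamlines:
        keep = (np.linalg.norm(s[0] - inf) + np.linalg.norm(s[-1] - sup))
        flip = (np.linalg.norm(s[-1] - inf) + np.linalg.norm(s[0] - sup))
        out.append(s if keep <= flip else s[::-1])
    return out


def test_orient_is_idempotent_and_fixes_reversals(rng):
    inf, sup = np.array([0.0, 0, 0]), np.array([0.0, 0, 80])
    base = [np.stack([rng.normal(size=12), rng.normal(size=12),
                      np.linspace(0, 80, 12)], axis=1) for _ in range(20)]
    flips = rng.random(20) < 0.5
    jumbled = Tractogram([s[::-1] if f else s for s, f in zip(base, flips)])
    fixed = orient_streamlines(jumbled, inf, sup)
    again = orient_streamlines(fixed, inf, sup)
    brute = _brute_orient(jumbled.streamlines, inf, sup)
    for a, b, c in zip(fixed.streamlines, again.streamlines, brute):
        np.testing.assert_array_equal(a, b)        # idempotent
        np.testing.assert_array_equal(a, c)        # matches brute force


def test_orient_all_reversed_bundle_flips_everything(rng):
    inf, sup = np.array([0.0, 0, 0]), np.array([0.0, 0, 80])
    base = [np.stack([rng.normal(size=9), rng.normal(size=9),
                      np.linspace(0, 80, 9)], axis=1) for _ in range(5)]
    reversed_all = Tractogram([s[::-1] for s in base])
    fixed = orient_streamlines(reversed_all, inf, sup)
    for a, b in zip(fixed.streamlines, base):
        np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------------------
# sample_scalars


def _brute_trilinear(grid, p):
    """Independent trilinear interpolation at one voxel-space point."""
    i0 = np.floor(p).astype(int)
    f = p - i0
    acc = 0.0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = ((f[0] if dx else 1 - f[0])
                     * (f[1] if dy else 1 - f[1])
                     * (f[2] if dz else 1 - f[2]))
                acc += w * grid[i0[0] + dx, i0[1] + dy, i0[2] + dz]
    return acc


def test_sample_constant_map_returns_constant():
    m = ScalarMap(np.full((6, 6, 6), 3.25), np.eye(4))
    pts = np.random.default_rng(0).uniform(0.5, 4.5, size=(100, 3))
    np.testing.assert_allclose(sample_scalars(pts, m), 3.25)


def test_sample_linear_field_is_exact():
    # f(z) = z_mm with a non-trivial affine: trilinear is exact on linear fields
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = [-5.0, 1.0, 7.0]
    k = np.arange(8)
    grid = np.broadcast_to(7.0 + 2.0 * k, (8, 8, 8)).astype(float)
    m = ScalarMap(grid, affine)
    rng = np.random.default_rng(1)
    pts_vox = rng.uniform(0.0, 7.0, size=(50, 3))
    pts_mm = pts_vox @ affine[:3, :3].T + affine[:3, 3]
    np.testing.assert_allclose(sample_scalars(pts_mm, m), pts_mm[:, 2], atol=1e-9)


def test_sample_matches_brute_force_oracle(rng):
    grid = rng.normal(size=(7, 8, 9))
    m = ScalarMap(grid, np.eye(4))
    pts = rng.uniform(0.0, 5.9, size=(40, 3))
    got = sample_scalars(pts, m)
    want = [_brute_trilinear(grid, p) for p in pts]
    np.testing.assert_allclose(got, want, atol=1e-10)


def test_sample_outside_grid_is_missing():
    m = ScalarMap(np.ones((4, 4, 4)), np.eye(4))
    out = sample_scalars(np.array([[10.0, 10.0, 10.0], [1.0, 1.0, 1.0]]), m)
    assert np.isnan(out[0]) and out[1] == 1.0


def test_sample_singular_affine_raises():
    aff = np.zeros((4, 4))
    aff[3, 3] = 1.0
    with pytest.raises(TractometryError):
        ScalarMap(np.ones((4, 4, 4)), aff)


# ---------------------------------------------------------------------------
# profile_median


def test_median_profile_of_identical_streamlines_is_that_streamline(rng):
    row = rng.normal(size=100)
    vals = np.tile(row, (7, 1))
    np.testing.assert_allclose(profile_median(vals).values, row)


def test_median_profile_matches_sorted_middle_oracle(rng):
    vals = rng.normal(size=(11, 100))
    vals[rng.random(vals.shape) < 0.1] = np.nan
    got = profile_median(vals).values
    for j in range(100):
        col = np.sort(vals[~np.isnan(vals[:, j]), j])
        want = np.nan if col.size == 0 else \
            (col[col.size // 2] if col.size % 2 else
             0.5 * (col[col.size // 2 - 1] + col[col.size // 2]))
        if np.isnan(want):
            assert np.isnan(got[j])
        else:
            assert got[j] == pytest.approx(want)


def test_median_profile_odd_count_and_empty_matrix():
    vals = np.tile(np.array([[1.0], [2.0], [10.0]]), (1, 100))
    assert profile_median(vals).values[0] == 2.0
    with pytest.raises(TractometryError):
        profile_median(np.empty((0, 100)))


# ---------------------------------------------------------------------------
# profile_weighted_mean


def _brute_weighted_mean(values, points):
    n, n_seg = values.shape
    out = np.empty(n_seg)
    for j in range(n_seg):
        pts = points[:, j, :]
        core = pts.mean(axis=0)
        dev = pts - core
        C = dev.T @ dev / (n - 1)
        C = C + (1e-6 * np.trace(C) / 3 + 1e-12) * np.eye(3)
        Cinv = np.linalg.inv(C)
        d = np.array([np.sqrt(max(v @ Cinv @ v, 0.0)) for v in dev])
        w = 1.0 / np.maximum(d, 1e-8)
        valid = ~np.isnan(values[:, j])
        if not valid.any():
            out[j] = np.nan
            continue
        w = np.where(valid, w, 0.0)
        out[j] = np.sum(w * np.nan_to_num(values[:, j])) / w.sum()
    return out


def test_weighted_mean_symmetric_pair_is_arithmetic_mean():
    # two streamlines mirrored about the core -> equal Mahalanobis weights
    z = np.linspace(0, 10, 100)
    a = np.stack([np.ones(100), np.zeros(100), z], axis=1)
    b = np.stack([-np.ones(100), np.zeros(100), z], axis=1)
    pts = np.stack([a, b])
    vals = np.stack([np.full(100, 2.0), np.full(100, 6.0)])
    np.testing.assert_allclose(profile_weighted_mean(vals, pts).values, 4.0)


def test_weighted_mean_identical_streamlines_returns_common_values(rng):
    row = rng.normal(size=100)
    pts = np.tile(rng.normal(size=(1, 100, 3)), (5, 1, 1))
    vals = np.tile(row, (5, 1))
    np.testing.assert_allclose(profile_weighted_mean(vals, pts).values, row)


def test_weighted_mean_matches_brute_force_oracle(rng):
    n = 9
    pts = rng.normal(size=(n, 100, 3))
    vals = rng.normal(size=(n, 100))
    vals[rng.random(vals.shape) < 0.07] = np.nan
    got = profile_weighted_mean(vals, pts).values
    np.testing.assert_allclose(got, _brute_weighted_mean(vals, pts), atol=1e-10)


def test_weighted_mean_three_streamline_toy_bundle():
    # hand-checkable toy: brute force at a single segment
    pts = np.zeros((3, 100, 3))
    pts[0, :, 0] = 1.0
    pts[1, :, 0] = -1.0
    pts[2, :, 1] = 2.0
    vals = np.stack([np.full(100, 1.0), np.full(100, 3.0), np.full(100, 8.0)])
    got = profile_weighted_mean(vals, pts).values
    np.testing.assert_allclose(got, _brute_weighted_mean(vals, pts), atol=1e-12)


def test_profile_estimators_are_order_invariant(rng):
    n = 8
    pts = rng.normal(size=(n, 100, 3))
    vals = rng.normal(size=(n, 100))
    perm = rng.permutation(n)
    np.testing.assert_allclose(profile_median(vals).values,
                               profile_median(vals[perm]).values)
    np.testing.assert_allclose(profile_weighted_mean(vals, pts).values,
                               profile_weighted_mean(vals[perm], pts[perm]).values,
                               atol=1e-12)


def test_weighted_mean_is_convex_combination(rng):
    n = 12
    pts = rng.normal(size=(n, 100, 3))
    vals = rng.normal(size=(n, 100))
    got = profile_weighted_mean(vals, pts).values
    assert np.all(got >= vals.min(axis=0) - 1e-12)
    assert np.all(got <= vals.max(axis=0) + 1e-12)


def test_weighted_mean_single_streamline_raises(rng):
    with pytest.raises(TractometryError):
        profile_weighted_mean(rng.normal(size=(1, 100)),
                              rng.normal(size=(1, 100, 3)))
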