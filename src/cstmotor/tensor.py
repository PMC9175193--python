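"""Diffusion tensor estimation and tensor-derived scalar maps.

The tensor is fitted per voxel from the log-linear signal model

    ln S(g, b) = ln S0 - b * g^T D g

by weighted least squares: an ordinary least-squares pass on the log
signals provides initial predicted signals, whose squares serve as weights;
the weights are then re-derived from the model-predicted signals for a
small number of reweighting iterations (iteratively reweighted linear
least squares).  Scalars follow the standard definitions

    AD  = l1,   RD = (l2 + l3) / 2,   ADC = (l1 + l2 + l3) / 3,
    FA  = sqrt(3/2) * sqrt(sum (li - lbar)^2) / sqrt(sum li^2),

with eigenvalues sorted descending and clamped at zero before the scalar
computation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from cstmotor.tractometry import ScalarMap


class TensorFitError(ValueError):
    """Raised for invalid gradient schemes or degenerate fits."""


@dataclass
class GradientScheme:
    """b-values (s/mm^2) and unit gradient directions."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (self.bvals.size, 3):
            raise TensorFitError("bvecs must be (n, 3) matching bvals")
        dw = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if dw.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise TensorFitError("b>0 gradient directions must be unit vectors")

    @property
    def n_dw(self) -> int:
        return int(np.sum(self.bvals > 0))

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.bvals == 0))


def make_scheme(n_dirs: int = 40, bval: float = 1000.0,
                n_b0: int = 1) -> GradientScheme:
    """Deterministic, approximately uniform single-shell scheme.

    Directions are placed by the golden-spiral (Fibonacci) construction,
    which distributes ``n_dirs`` points evenly over the sphere; ``n_b0``
    unweighted volumes are prepended.
    """
    if n_dirs < 6:
        raise TensorFitError("need >= 6 diffusion directions")
    i = np.arange(n_dirs)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n_dirs
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    dirs = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, float(bval))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return GradientScheme(bvals, bvecs)


def design_matrix(scheme: GradientScheme) -> np.ndarray:
    """Rows [-b gx^2, -b gy^2, -b gz^2, -2b gxgy, -2b gxgz, -2b gygz, 1]
    acting on [Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, ln S0]."""
    b = scheme.bvals
    g = scheme.bvecs
    B = np.column_stack([
        -b * g[:, 0] ** 2,
        -b * g[:, 1] ** 2,
        -b * g[:, 2] ** 2,
        -2 * b * g[:, 0] * g[:, 1],
        -2 * b * g[:, 0] * g[:, 2],
        -2 * b * g[:, 1] * g[:, 2],
        np.ones_like(b),
    ])
    return B


def _params_to_tensors(params: np.ndarray) -> np.ndarray:
    """(..., 7) fitted parameters -> (..., 3, 3) symmetric tensors."""
    dxx, dyy, dzz, dxy, dxz, dyz = (params[..., i] for i in range(6))
    T = np.empty(params.shape[:-1] + (3, 3))
    T[..., 0, 0] = dxx
    T[..., 1, 1] = dyy
    T[..., 2, 2] = dzz
    T[..., 0, 1] = T[..., 1, 0] = dxy
    T[..., 0, 2] = T[..., 2, 0] = dxz
    T[..., 1, 2] = T[..., 2, 1] = dyz
    return T


@dataclass
class TensorField:
    """Per-voxel tensor fit: sorted eigenvalues, eigenvectors and a
    fit-quality mask, in the spatial shape of the input volume."""

    evals: np.ndarray       # (..., 3) sorted descending
    evecs: np.ndarray       # (..., 3, 3) columns matching evals
    tensors: np.ndarray     # (..., 3, 3)
    s0: np.ndarray          # (...,)
    mask: np.ndarray        # (...,) bool, True where fitted

    @property
    def shape(self) -> tuple:
        return self.evals.shape[:-1]


def fit_tensor_irlls(dwi: np.ndarray, scheme: GradientScheme,
                     n_iter: int = 2) -> TensorField:
    """Iteratively reweighted linear least squares tensor fit.

    Parameters
    ----------
    dwi
        Signal array whose last axis enumerates the volumes of ``scheme``;
        any leading spatial shape is accepted.  Voxels with non-positive
        signal in any volume are excluded via the mask.
    n_iter
        Number of reweighting iterations after the initial weighted pass;
        ``n_iter=0`` reduces to ordinary log-linear least squares.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.shape[-1] != scheme.bvals.size:
        raise TensorFitError("last DWI axis must match the gradient scheme")
    if scheme.n_b0 < 1:
        raise TensorFitError("need at least one b=0 volume")
    if scheme.n_dw < 6:
        raise TensorFitError("need >= 6 diffusion-weighted directions")
    B = design_matrix(scheme)
    if np.linalg.matrix_rank(B) < 7:
        raise TensorFitError("rank-deficient design: gradient directions "
                             "are collinear or degenerate")

    spatial = dwi.shape[:-1]
    flat = dwi.reshape(-1, dwi.shape[-1])
    mask = np.all(flat > 0, axis=1) & np.all(np.isfinite(flat), axis=1)
    n_vox = flat.shape[0]
    params = np.zeros((n_vox, 7))
    if mask.any():
        S = flat[mask]
        y = np.log(S)
        # ordinary LS start
        p, *_ = np.linalg.lstsq(B, y.T, rcond=None)
        p = p.T                                          # (v, 7)
        # n_iter weighted solves: the first takes its weights from the
        # OLS-predicted signals, later ones from the current model
        # prediction; weights = squared predicted signals.  n_iter=0 keeps
        # the plain log-linear OLS solution.
        for _ in range(n_iter):
            pred = np.exp(p @ B.T)
            w = pred ** 2                                # (v, n)
            Bw = B[None, :, :] * w[:, :, None]           # (v, n, 7)
            lhs = np.einsum("vnp,nq->vpq", Bw, B)
            rhs = np.einsum("vnp,vn->vp", Bw, y)
            p = np.linalg.solve(lhs, rhs[..., None])[..., 0]
        params[mask] = p

    tensors = _params_to_tensors(params)
    evals, evecs = np.linalg.eigh(tensors)               # ascending
    evals = evals[..., ::-1]
    evecs = evecs[..., :, ::-1]
    s0 = np.exp(params[..., 6])
    return TensorField(
        evals=evals.reshape(spatial + (3,)),
        evecs=evecs.reshape(spatial + (3, 3)),
        tensors=tensors.reshape(spatial + (3, 3)),
        s0=s0.reshape(spatial),
        mask=mask.reshape(spatial),
    )


def scalars_from_evals(evals: np.ndarray) -> dict[str, np.ndarray]:
    """AD/RD/ADC/FA from (..., 3) eigenvalue arrays (sorted descending).

    Negative eigenvalues are clamped to zero first; FA is defined as 0
    where all eigenvalues vanish.
    """
    ev = np.maximum(np.asarray(evals, dtype=float), 0.0)
    l1, l2, l3 = ev[..., 0], ev[..., 1], ev[..., 2]
    ad = l1
    rd = (l2 + l3) / 2.0
    adc = (l1 + l2 + l3) / 3.0
    mean = adc
    num = ((l1 - mean) ** 2 + (l2 - mean) ** 2 + (l3 - mean) ** 2)
    den = l1 ** 2 + l2 ** 2 + l3 ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.sqrt(np.where(den > 0, num / np.maximum(den, 1e-300), 0.0))
    fa = np.where(den > 0, fa, 0.0)
    return {"AD": ad, "ADC": adc, "FA": fa, "RD": rd}


def tensor_to_scalars(field: TensorField,
                      affine: np.ndarray | None = None) -> dict[str, ScalarMap]:
    """Derive the AD/ADC/FA/RD scalar maps from a fitted tensor field.

    FD is never computed here: it is a spherical-deconvolution metric that
    the package consumes as a precomputed map.
    """
    if affine is None:
        affine = np.eye(4)
    scalars = scalars_from_evals(field.evals)
    out = {}
    for metric, vals in scalars.items():
        vals = np.where(field.mask, vals, 0.0)
        if vals.ndim != 3:
            vals = vals.reshape(vals.shape + (1,) * (3 - vals.ndim)) \
                if vals.ndim < 3 else vals
        out[metric] = ScalarMap(vals, affine, metric=metric)
    return out
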