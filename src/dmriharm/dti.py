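"""Diffusion tensor estimation (weighted linear least squares) and FA/MD maps.

The single-tensor model predicts ``S(b, g) = S0 exp(-b g^T D g)``.  Taking
logs gives a linear model in the 7 parameters ``(ln S0, Dxx, Dyy, Dzz, Dxy,
Dxz, Dyz)``.  Ordinary least squares on log-signals is heteroscedastic
(log-transformed Rician/Gaussian noise has variance ~ 1/S^2), so the
standard remedy is weighted linear least squares: fit OLS first, then
re-solve with per-measurement weights equal to the squared predicted
signals.  One re-weighting pass is the common choice and the default here.

Scalar maps are eigenvalue summaries of the fitted tensor:

    MD = (l1 + l2 + l3) / 3
    FA = sqrt(3/2) * ||l - mean(l)|| / ||l||

Negative eigenvalues from noisy fits are clamped to zero for the scalar
maps and counted in ``TensorField.n_negative_eig`` for QC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import B0_THRESHOLD, DWIStack

__all__ = ["TensorField", "design_matrix", "fit_wlls", "eigenvalues", "fa_map", "md_map"]

_LOG_EPS = 1e-10


@dataclass
class TensorField:
    """Per-voxel tensor parameters on a 3D grid.

    ``tensors`` stores the 6 unique elements (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)
    in mm^2/s; ``log_s0`` the fitted log-amplitude; ``mask`` marks fitted
    voxels.
    """

    tensors: np.ndarray  # (x, y, z, 6)
    log_s0: np.ndarray  # (x, y, z)
    mask: np.ndarray  # (x, y, z) bool
    n_negative_eig: int = 0


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows ``(1, -b gx^2, -b gy^2, -b gz^2, -2b gx gy, -2b gx gz, -2b gy gz)``."""
    b = np.asarray(bvals, dtype=float)
    g = np.asarray(bvecs, dtype=float)
    A = np.empty((len(b), 7))
    A[:, 0] = 1.0
    A[:, 1] = -b * g[:, 0] ** 2
    A[:, 2] = -b * g[:, 1] ** 2
    A[:, 3] = -b * g[:, 2] ** 2
    A[:, 4] = -2.0 * b * g[:, 0] * g[:, 1]
    A[:, 5] = -2.0 * b * g[:, 0] * g[:, 2]
    A[:, 6] = -2.0 * b * g[:, 1] * g[:, 2]
    return A


def fit_wlls(
    stack: DWIStack,
    mask: np.ndarray | None = None,
    n_reweight: int = 1,
    b0_threshold: float = B0_THRESHOLD,
) -> TensorField:
    """Weighted-linear-least-squares tensor fit.

    OLS on log-signals initialises; ``n_reweight`` passes (default 1)
    re-solve with weights equal to the squared predicted signals.
    Non-positive signals are clamped to a small epsilon before the log.
    """
    shape = stack.spatial_shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != shape:
        raise ValueError("mask shape does not match stack")

    A = design_matrix(stack.scheme.bvals, stack.scheme.bvecs)
    if len(stack.scheme) < 7 or np.linalg.matrix_rank(A) < 7:
        raise ValueError(
            "tensor fit needs >= 7 volumes spanning b=0 and one shell "
            "(rank-deficient design matrix)"
        )

    S = stack.data[mask]  # (n_vox, n_vol)
    S = np.clip(S, _LOG_EPS, None)
    y = np.log(S)

    # OLS initialisation (shared design matrix across voxels)
    beta, *_ = np.linalg.lstsq(A, y.T, rcond=None)
    beta = beta.T  # (n_vox, 7)

    for _ in range(n_reweight):
        w = np.exp(A @ beta.T).T ** 2  # squared predicted signals
        Aw = A[None, :, :] * w[:, :, None]
        lhs = np.einsum("nki,kj->nij", Aw, A)
        rhs = np.einsum("nki,nk->ni", Aw, y)
        beta = np.linalg.solve(lhs, rhs[..., None]).squeeze(-1)

    tensors = np.zeros(shape + (6,))
    log_s0 = np.zeros(shape)
    tensors[mask] = beta[:, 1:]
    log_s0[mask] = beta[:, 0]

    ev = eigenvalues(beta[:, 1:])
    n_neg = int(np.count_nonzero(ev < 0))
    return TensorField(tensors=tensors, log_s0=log_s0, mask=mask, n_negative_eig=n_neg)


def _tensor_matrices(six: np.ndarray) -> np.ndarray:
    """(…, 6) unique elements -> (…, 3, 3) symmetric matrices."""
    six = np.asarray(six, dtype=float)
    T = np.empty(six.shape[:-1] + (3, 3))
    T[..., 0, 0] = six[..., 0]
    T[..., 1, 1] = six[..., 1]
    T[..., 2, 2] = six[..., 2]
    T[..., 0, 1] = T[..., 1, 0] = six[..., 3]
    T[..., 0, 2] = T[..., 2, 0] = six[..., 4]
    T[..., 1, 2] = T[..., 2, 1] = six[..., 5]
    return T


def eigenvalues(six: np.ndarray) -> np.ndarray:
    """Tensor eigenvalues in descending order, shape (..., 3)."""
    ev = np.linalg.eigvalsh(_tensor_matrices(six))
    return ev[..., ::-1]


def _fa_from_eigenvalues(ev: np.ndarray) -> np.ndarray:
    ev = np.clip(ev, 0.0, None)
    mean = ev.mean(axis=-1, keepdims=True)
    num = np.sqrt((3.0 / 2.0) * ((ev - mean) ** 2).sum(axis=-1))
    den = np.sqrt((ev**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.where(den > 0, num / den, 0.0)
    return np.clip(fa, 0.0, 1.0)


def fa_map(t: TensorField) -> np.ndarray:
    """Fractional anisotropy, unitless in [0, 1]; 0 on the zero tensor."""
    fa = np.zeros(t.mask.shape)
    fa[t.mask] = _fa_from_eigenvalues(eigenvalues(t.tensors[t.mask]))
    return fa


def md_map(t: TensorField) -> np.ndarray:
    """Mean diffusivity (mm^2/s), eigenvalue mean with negatives clamped to 0."""
    md = np.zeros(t.mask.shape)
    ev = np.clip(eigenvalues(t.tensors[t.mask]), 0.0, None)
    md[t.mask] = ev.mean(axis=-1)
    return md
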