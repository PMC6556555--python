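"""Non-learning reference predictor: trilinear + SH interpolation.

The reference prediction of a target acquisition from a source acquisition
performs no harmonisation at all: b0-normalised source signals are
trilinearly resampled onto the target voxel grid in the spatial domain and
interpolated onto the target gradient directions with a spherical-harmonic
fit in the angular domain (order 6 for matched-resolution targets, order 8
for the high-angular-resolution ones).  Whatever systematic difference
exists between the scanners is carried through unchanged, which is exactly
what makes it the floor that learning methods must beat.

Interpolation operates on normalised signals and re-scales by the
trilinearly interpolated mean b0, so the spatial and angular steps commute
with any global gain.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from . import sh
from .io import B0_THRESHOLD, DWIStack, GradientScheme, mean_b0

__all__ = ["resample_trilinear", "predict_reference"]

_B0_EPS = 1e-8


def _target_coords(
    src_affine: np.ndarray, target_affine: np.ndarray, target_shape: tuple[int, int, int]
) -> np.ndarray:
    """Source voxel coordinates of every target voxel centre, shape (3, ...)."""
    idx = np.indices(target_shape).reshape(3, -1)
    homo = np.vstack([idx, np.ones((1, idx.shape[1]))])
    world = target_affine @ homo
    src = np.linalg.inv(src_affine) @ world
    return src[:3].reshape((3,) + tuple(target_shape))


def resample_trilinear(
    volume: np.ndarray,
    src_affine: np.ndarray,
    target_affine: np.ndarray,
    target_shape: tuple[int, int, int],
) -> np.ndarray:
    """Trilinear resampling of a 3D volume onto a target grid.

    Target centres outside the source bounding box take the edge value
    (nearest-neighbour extension).
    """
    coords = _target_coords(src_affine, target_affine, target_shape)
    return ndimage.map_coordinates(
        np.asarray(volume, dtype=float), coords, order=1, mode="nearest"
    )


def predict_reference(
    src: DWIStack,
    target_affine: np.ndarray,
    target_shape: tuple[int, int, int],
    target_scheme: GradientScheme,
    L: int = 6,
    lb_lambda: float = 0.006,
    b0_threshold: float = B0_THRESHOLD,
) -> DWIStack:
    """Reference prediction of a target acquisition from a source stack.

    ``L=6`` is the matched-resolution setting, ``L=8`` the high
    angular-resolution one.  An order-8 basis (45 coefficients) is
    under-determined from a 30-direction source, so ``lb_lambda`` must be
    positive on that path (the default 0.006 is).
    """
    sh.n_coeffs(L)  # validates evenness
    target_shape = tuple(int(s) for s in target_shape)
    b0 = mean_b0(src, b0_threshold)
    dwi = ~src.scheme.b0_mask(b0_threshold)
    src_dirs = src.scheme.bvecs[dwi]
    if L > 0 and np.count_nonzero(dwi) < sh.n_coeffs(L) and lb_lambda <= 0:
        raise ValueError(
            f"order-{L} fit from {np.count_nonzero(dwi)} directions needs "
            "lb_lambda > 0"
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        normalised = np.where(
            b0[..., None] > _B0_EPS, src.data[..., dwi] / b0[..., None], 0.0
        )

    # spatial step: trilinear onto the target grid, volume by volume
    res = np.stack(
        [
            resample_trilinear(normalised[..., k], src.affine, target_affine, target_shape)
            for k in range(normalised.shape[-1])
        ],
        axis=-1,
    )
    b0_res = resample_trilinear(b0, src.affine, target_affine, target_shape)

    # angular step: SH fit at source directions, evaluate at target directions
    field = sh.fit_sh(res, src_dirs, L, lb_lambda)
    tgt_dwi = ~target_scheme.b0_mask(b0_threshold)
    pred_dwi = sh.resample_sh(field, target_scheme.bvecs[tgt_dwi])

    out = np.empty(target_shape + (len(target_scheme),))
    out[..., tgt_dwi] = pred_dwi * b0_res[..., None]
    out[..., ~tgt_dwi] = b0_res[..., None]
    return DWIStack(data=out, affine=np.asarray(target_affine, dtype=float), scheme=target_scheme)
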