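"""Real symmetric spherical-harmonic (SH) representation of diffusion signals.

Single-shell diffusion signals are antipodally symmetric, so they are
represented in a real, even-order SH basis.  The basis used here is the
modified real basis common in diffusion MRI (Descoteaux-style): for even
order ``l`` and ``m = -l..l``

* ``m < 0``:  ``sqrt(2) * (-1)^m * Im(Y_l^{|m|})``
* ``m = 0``:  ``Y_l^0`` (real)
* ``m > 0``:  ``sqrt(2) * (-1)^m * Re(Y_l^{m})``

with coefficients stored in ``(l, m)`` order, ``l`` ascending and ``m``
ascending within each order.  The basis is orthonormal on the sphere.

Fitting is regularised least squares with the Laplace-Beltrami penalty
``diag(l^2 (l+1)^2)``, i.e. the coefficients solve

    min_c || B c - s ||^2 + lambda_lb * c^T L c

which smooths the angular profile without touching the order-0 term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import sph_harm_y

__all__ = [
    "n_coeffs",
    "sh_orders",
    "sh_basis",
    "lb_penalty",
    "SHField",
    "fit_sh",
    "resample_sh",
    "save_shfield",
    "load_shfield",
    "hemisphere_directions",
]


def n_coeffs(L: int) -> int:
    """Number of real even-order SH coefficients up to order ``L``.

    ``(L+1)(L+2)/2``; e.g. 15 for order 4, 28 for order 6, 45 for order 8.
    """
    if L < 0 or L % 2 != 0:
        raise ValueError(f"SH order must be even and non-negative, got {L}")
    return (L + 1) * (L + 2) // 2


def sh_orders(L: int) -> tuple[np.ndarray, np.ndarray]:
    """Arrays of (l, m) for each coefficient index, in storage order."""
    n_coeffs(L)  # validates
    ls, ms = [], []
    for l in range(0, L + 1, 2):
        for m in range(-l, l + 1):
            ls.append(l)
            ms.append(m)
    return np.asarray(ls), np.asarray(ms)


def _to_angles(directions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(directions, dtype=float)
    if d.ndim != 2 or d.shape[1] != 3:
        raise ValueError(f"directions must be (n, 3), got {d.shape}")
    norms = np.linalg.norm(d, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-3):
        raise ValueError("directions must be unit-norm")
    d = d / norms[:, None]
    theta = np.arccos(np.clip(d[:, 2], -1.0, 1.0))  # polar
    phi = np.arctan2(d[:, 1], d[:, 0])  # azimuth
    return theta, phi


def sh_basis(L: int, directions: np.ndarray) -> np.ndarray:
    """Evaluate the real even-order SH basis at unit ``directions``.

    Returns an ``(n_directions, n_coeffs(L))`` matrix.
    """
    theta, phi = _to_angles(directions)
    ls, ms = sh_orders(L)
    B = np.empty((len(theta), len(ls)))
    for j, (l, m) in enumerate(zip(ls, ms)):
        Y = sph_harm_y(int(l), int(abs(m)), theta, phi)
        sign = -1.0 if m % 2 else 1.0
        if m < 0:
            B[:, j] = np.sqrt(2.0) * sign * Y.imag
        elif m == 0:
            B[:, j] = Y.real
        else:
            B[:, j] = np.sqrt(2.0) * sign * Y.real
    return B


def lb_penalty(L: int) -> np.ndarray:
    """Diagonal of the Laplace-Beltrami penalty, ``l^2 (l+1)^2`` per coefficient."""
    ls, _ = sh_orders(L)
    return (ls * (ls + 1)) ** 2


@dataclass
class SHField:
    """Per-voxel real even-order SH coefficients.

    ``coeffs`` has shape ``(..., n_coeffs(order))`` — any leading spatial
    shape is allowed (a flat voxel list or a 3D grid).
    """

    coeffs: np.ndarray
    order: int
    lb_lambda: float = 0.0

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape[-1] != n_coeffs(self.order):
            raise ValueError(
                f"coefficient count {self.coeffs.shape[-1]} does not match "
                f"order {self.order} (expected {n_coeffs(self.order)})"
            )


def fit_sh(
    signals: np.ndarray,
    directions: np.ndarray,
    L: int,
    lb_lambda: float = 0.0,
) -> SHField:
    """Least-squares SH fit with Laplace-Beltrami regularisation.

    Parameters
    ----------
    signals : array, shape (..., n_directions)
        Signal values at each direction; callers normalise by the mean b=0
        signal beforehand where that is required.
    directions : array, shape (n_directions, 3)
    L : even SH order.
    lb_lambda : regularisation weight (0.006 is the conventional default
        for order-4 fits of 30-direction single-shell data).
    """
    signals = np.asarray(signals, dtype=float)
    B = sh_basis(L, directions)
    nc = B.shape[1]
    A = B.T @ B + lb_lambda * np.diag(lb_penalty(L).astype(float))
    # A guard for the genuinely under-determined, unregularised case.
    if lb_lambda == 0.0 and signals.shape[-1] < nc:
        raise np.linalg.LinAlgError(
            f"{signals.shape[-1]} directions cannot determine {nc} order-{L} "
            "coefficients without regularisation; pass lb_lambda > 0"
        )
    try:
        coeffs = np.linalg.solve(A, B.T @ signals[..., None]).squeeze(-1)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rank corner
        raise np.linalg.LinAlgError(
            f"singular SH normal matrix at lb_lambda={lb_lambda}; "
            "pass lb_lambda > 0"
        ) from exc
    return SHField(coeffs=coeffs, order=L, lb_lambda=lb_lambda)


def resample_sh(field: SHField, directions: np.ndarray) -> np.ndarray:
    """Evaluate an SH field at new unit directions: ``s(g) = sum c_lm Y_lm(g)``."""
    B = sh_basis(field.order, directions)
    return field.coeffs @ B.T


def save_shfield(field: SHField, path, affine: np.ndarray | None = None) -> None:
    """Write an SH field as a 4D NIfTI coefficient volume plus a sidecar.

    The sidecar (``<path>.json``) records the order, the Laplace-Beltrami
    weight and the (l, m) storage ordering, so the volume is
    self-describing.  Fields with flat (non-3D) leading shape are written
    as ``(n, 1, 1, n_coeffs)``.
    """
    import json
    from pathlib import Path

    import nibabel as nib

    coeffs = field.coeffs
    if coeffs.ndim != 4:
        coeffs = coeffs.reshape((-1, 1, 1, coeffs.shape[-1]))
    affine = np.eye(4) if affine is None else np.asarray(affine, dtype=float)
    nib.save(nib.Nifti1Image(coeffs.astype(np.float32), affine), str(path))
    ls, ms = sh_orders(field.order)
    sidecar = {
        "order": int(field.order),
        "lb_lambda": float(field.lb_lambda),
        "lm_ordering": [[int(l), int(m)] for l, m in zip(ls, ms)],
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_shfield(path) -> tuple[SHField, np.ndarray]:
    """Read a coefficient volume and its sidecar; returns (field, affine)."""
    import json
    from pathlib import Path

    import nibabel as nib

    img = nib.load(str(path))
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    ls, ms = sh_orders(sidecar["order"])
    stored = [tuple(x) for x in sidecar["lm_ordering"]]
    if stored != list(zip(ls.tolist(), ms.tolist())):
        raise ValueError("sidecar (l, m) ordering does not match this package's basis")
    field = SHField(
        coeffs=np.asarray(img.dataobj, dtype=float),
        order=sidecar["order"],
        lb_lambda=sidecar["lb_lambda"],
    )
    return field, np.asarray(img.affine)


def hemisphere_directions(n: int, seed: int = 0, n_iter: int = 500) -> np.ndarray:
    """Approximately uniform unit directions on the upper hemisphere.

    Electrostatic-repulsion optimisation with antipodal symmetry: points
    repel both each other and each other's antipodes, so the resulting set
    covers orientation space evenly (the standard construction for diffusion
    gradient schemes).  Deterministic for a given seed.
    """
    if n < 3:
        raise ValueError("need at least 3 directions")
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    step = 0.1
    for it in range(n_iter):
        diff = x[:, None, :] - x[None, :, :]
        summ = x[:, None, :] + x[None, :, :]
        d1 = np.linalg.norm(diff, axis=-1)
        d2 = np.linalg.norm(summ, axis=-1)
        np.fill_diagonal(d1, np.inf)
        np.fill_diagonal(d2, np.inf)
        d2[d2 < 1e-9] = np.inf
        force = (diff / d1[..., None] ** 3).sum(axis=1) + (
            summ / d2[..., None] ** 3
        ).sum(axis=1)
        # project onto tangent plane and take a bounded step
        force -= (force * x).sum(axis=1, keepdims=True) * x
        fmax = np.abs(force).max()
        if fmax < 1e-12:
            break
        x = x + step * force / fmax
        x /= np.linalg.norm(x, axis=1, keepdims=True)
        step *= 0.99
    # collapse to the z >= 0 hemisphere
    flip = x[:, 2] < 0
    x[flip] *= -1.0
    return x
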