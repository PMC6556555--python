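"""Diffusion volume containers and NIfTI / FSL gradient-table I/O.

The universal container is :class:`DWIStack`: a 4D intensity array with its
voxel-to-world affine and a :class:`GradientScheme` (per-volume b-value and
unit gradient direction).  Gradient tables follow the FSL dialect — one row
of b-values, three rows of direction cosines — with a flag for the
transposed (N-row) layout.

Volumes with b-value below ``B0_THRESHOLD`` (default 50 s/mm^2) are treated
as b=0 baselines throughout the package; the threshold is configurable on
every entry point that uses it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "B0_THRESHOLD",
    "GradientScheme",
    "DWIStack",
    "read_dwi",
    "write_dwi",
    "read_gradient_table",
    "write_gradient_table",
    "read_volume",
    "write_volume",
    "select_shell",
    "mean_b0",
]

B0_THRESHOLD = 50.0  # s/mm^2


@dataclass
class GradientScheme:
    """Per-volume diffusion weightings (s/mm^2) and unit gradient directions."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        self.bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.ndim != 2 or self.bvecs.shape[1] != 3:
            raise ValueError(f"bvecs must be (n, 3), got {self.bvecs.shape}")
        if len(self.bvals) != len(self.bvecs):
            raise ValueError(
                f"gradient table length mismatch: {len(self.bvals)} b-values "
                f"vs {len(self.bvecs)} directions"
            )
        if np.any(self.bvals < 0):
            raise ValueError("b-values must be non-negative")
        norms = np.linalg.norm(self.bvecs, axis=1)
        dwi = self.bvals > 0
        if np.any(np.abs(norms[dwi] - 1.0) > 1e-3):
            raise ValueError("bvecs for b > 0 volumes must be unit-norm")

    def __len__(self) -> int:
        return len(self.bvals)

    def b0_mask(self, b0_threshold: float = B0_THRESHOLD) -> np.ndarray:
        return self.bvals < b0_threshold

    def subset(self, index: np.ndarray) -> "GradientScheme":
        return GradientScheme(self.bvals[index], self.bvecs[index])


@dataclass
class DWIStack:
    """4D diffusion-weighted intensities plus geometry and gradient scheme."""

    data: np.ndarray
    affine: np.ndarray
    scheme: GradientScheme

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.data.shape[3] != len(self.scheme):
            raise ValueError(
                f"image has {self.data.shape[3]} volumes but the gradient "
                f"table has {len(self.scheme)} entries"
            )
        vs = self.voxel_size
        if np.any(vs <= 0):
            raise ValueError("voxel size entries must be strictly positive")

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths (mm), from the affine column norms."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


def read_gradient_table(
    bval_path: str | Path, bvec_path: str | Path, transposed: bool = False
) -> GradientScheme:
    """Read FSL-style bval/bvec text files.

    ``transposed=True`` accepts the N-row x 3-column bvec layout.
    """
    bvals = np.loadtxt(bval_path).ravel()
    bvecs = np.loadtxt(bvec_path)
    bvecs = np.atleast_2d(bvecs)
    if not transposed:
        bvecs = bvecs.T
    return GradientScheme(bvals=bvals, bvecs=bvecs)


def write_gradient_table(
    scheme: GradientScheme, bval_path: str | Path, bvec_path: str | Path
) -> None:
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.8f")


def read_dwi(
    image_path: str | Path,
    bval_path: str | Path,
    bvec_path: str | Path,
    transposed_bvecs: bool = False,
) -> DWIStack:
    """Read a 4D NIfTI plus its gradient table into a validated stack."""
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    scheme = read_gradient_table(bval_path, bvec_path, transposed=transposed_bvecs)
    return DWIStack(data=data, affine=np.asarray(img.affine), scheme=scheme)


def write_dwi(
    stack: DWIStack,
    image_path: str | Path,
    bval_path: str | Path | None = None,
    bvec_path: str | Path | None = None,
) -> None:
    img = nib.Nifti1Image(stack.data.astype(np.float32), stack.affine)
    nib.save(img, str(image_path))
    if bval_path is not None and bvec_path is not None:
        write_gradient_table(stack.scheme, bval_path, bvec_path)


def read_volume(path: str | Path, integer: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Read a 3D NIfTI (mask, label map or scalar map); returns (data, affine)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    data = np.rint(data).astype(int) if integer else data.astype(float)
    return data, np.asarray(img.affine)


def write_volume(data: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    dtype = np.int16 if np.issubdtype(np.asarray(data).dtype, np.integer) else np.float32
    nib.save(nib.Nifti1Image(np.asarray(data).astype(dtype), affine), str(path))


def select_shell(
    stack: DWIStack,
    b_target: float,
    tol: float = 100.0,
    include_b0: bool = True,
    b0_threshold: float = B0_THRESHOLD,
) -> DWIStack:
    """Sub-stack of volumes with ``|bval - b_target| <= tol``, order preserved.

    ``include_b0`` additionally keeps all b=0 volumes (the common case of
    working on one shell plus its baselines).
    """
    if tol < 0:
        raise ValueError("tol must be non-negative")
    bvals = stack.scheme.bvals
    keep = np.abs(bvals - b_target) <= tol
    if include_b0:
        keep |= stack.scheme.b0_mask(b0_threshold)
    if not np.any(np.abs(bvals[keep] - b_target) <= tol):
        raise ValueError(f"no volumes within {tol} of b={b_target}")
    idx = np.flatnonzero(keep)
    return DWIStack(
        data=stack.data[..., idx],
        affine=stack.affine,
        scheme=stack.scheme.subset(idx),
    )


def mean_b0(stack: DWIStack, b0_threshold: float = B0_THRESHOLD) -> np.ndarray:
    """Voxel-wise arithmetic mean over all b=0 volumes."""
    b0 = stack.scheme.b0_mask(b0_threshold)
    if not np.any(b0):
        raise ValueError("stack contains no b=0 volume")
    return stack.data[..., b0].mean(axis=-1)
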