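"""Synthetic travelling-subject phantom for cross-scanner harmonisation.

Real cross-scanner benchmark data of this kind is access-restricted, so the
package ships a generator that emulates its *structure*: a cohort of
subjects, each "scanned" under a source protocol and one or more target
protocols that differ in gradient directions, voxel size, a scanner-specific
signal transformation, and Rician noise.

Anatomy
    Each subject is a 3D grid of compartment mixtures: two crossing fibre
    populations plus an isotropic compartment.  The layout contains CSF
    (free isotropic diffusion), grey matter (slower isotropic), and white
    matter with both single-fibre and crossing-fibre regions, so that
    anisotropy-sensitive features (FA, R2) and isotropic ones (MD, R0) are
    all exercised.  Geometry and diffusivities are jittered per subject.

Signal model
    Noise-free multi-tensor signal ``S = S0 * sum_i f_i exp(-b g^T D_i g)``.

Scanner effect
    Applied in SH space: the normalised angular profile's order-l
    coefficients are multiplied by attenuation factors ``(a0, a2, a4)``
    (emulating TE/hardware-dependent contrast differences), the whole
    signal by a global gain, optionally followed by a spatial blur.  This
    is the minimal family that shifts FA, MD, R0 and R2 between scanners;
    the manifest records the parameters, so an oracle inverse transform is
    always available as a lower bound for harmonisers.

Noise
    Rician: magnitude of the noise-free signal plus complex Gaussian noise
    of standard deviation ``mean in-mask b0 signal / SNR``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import sh
from .io import DWIStack, GradientScheme, write_dwi, write_volume

__all__ = [
    "ScannerProtocol",
    "SubjectAnatomy",
    "make_subject",
    "render_acquisition",
    "anatomy_on_grid",
    "oracle_harmonise",
    "simulate_cohort",
    "make_benchmark",
    "DEFAULT_PROTOCOLS",
]

# label conventions of the generator
LABEL_CSF, LABEL_GM, LABEL_WM_SINGLE, LABEL_WM_CROSS = 1, 2, 3, 4
WM_LABELS = (LABEL_WM_SINGLE, LABEL_WM_CROSS)
TISSUE_CLASS = {LABEL_CSF: "CSF", LABEL_GM: "GM", LABEL_WM_SINGLE: "WM", LABEL_WM_CROSS: "WM"}


@dataclass
class ScannerProtocol:
    """Acquisition protocol plus the scanner's systematic signal effect."""

    name: str
    bval: float = 1200.0  # s/mm^2
    n_directions: int = 30
    voxel_size: float = 2.4  # mm, isotropic
    snr: float | None = 30.0  # b=0 SNR; None = noise-free
    gain: float = 1.0
    order_atten: tuple[float, float, float] = (1.0, 1.0, 1.0)  # a0, a2, a4
    blur_fwhm: float = 0.0  # mm
    dir_seed: int = 0  # seed of the gradient direction scheme
    n_b0: int = 1

    def __post_init__(self) -> None:
        if self.snr is not None and self.snr <= 0:
            raise ValueError("SNR must be positive")
        if self.n_directions < sh.n_coeffs(4):
            raise ValueError("matched-resolution protocols need >= 15 directions")

    def directions(self) -> np.ndarray:
        return sh.hemisphere_directions(self.n_directions, seed=self.dir_seed)

    def scheme(self) -> GradientScheme:
        dirs = self.directions()
        bvals = np.concatenate([np.zeros(self.n_b0), np.full(self.n_directions, self.bval)])
        bvecs = np.vstack([np.zeros((self.n_b0, 3)), dirs])
        return GradientScheme(bvals=bvals, bvecs=bvecs)


@dataclass
class SubjectAnatomy:
    """Per-voxel compartment mixtures on a fine reference grid."""

    fractions: np.ndarray  # (x, y, z, 3): fibre 1, fibre 2, isotropic
    tensors: np.ndarray  # (x, y, z, 3, 6) compartment tensors, mm^2/s
    s0: np.ndarray  # (x, y, z) proton-density-weighted baseline
    labels: np.ndarray  # 0 bg, 1 CSF, 2 GM, 3 WM single, 4 WM crossing
    affine: np.ndarray
    seed: int

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0


def _centered_affine(shape: tuple[int, int, int], voxel_size: float) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.eye(3) * voxel_size
    aff[:3, 3] = -(np.asarray(shape) - 1) * voxel_size / 2.0
    return aff


def _tensor6(evecs: np.ndarray, evals: np.ndarray) -> np.ndarray:
    D = evecs @ np.diag(evals) @ evecs.T
    return np.array([D[0, 0], D[1, 1], D[2, 2], D[0, 1], D[0, 2], D[1, 2]])


def _fibre_tensor(direction: np.ndarray, lam_par: float, lam_perp: float) -> np.ndarray:
    d = direction / np.linalg.norm(direction)
    # complete an orthonormal frame around the fibre direction
    ref = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e2 = np.cross(d, ref)
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(d, e2)
    return _tensor6(np.stack([d, e2, e3], axis=1), np.array([lam_par, lam_perp, lam_perp]))


def make_subject(
    seed: int, shape: tuple[int, int, int] = (24, 24, 24), voxel_size: float = 1.2
) -> SubjectAnatomy:
    """Deterministic per-seed anatomy with CSF, GM, single- and crossing-fibre WM."""
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)
    affine = _centered_affine(shape, voxel_size)

    ii = np.indices(shape).astype(float)
    centre = (np.asarray(shape) - 1) / 2.0
    # normalised coordinates in [-1, 1] per axis
    u = np.stack([(ii[k] - centre[k]) / centre[k] for k in range(3)], axis=-1)
    r_brain = 0.92 * (1.0 + 0.04 * rng.uniform(-1, 1, size=3))
    r_wm = 0.62 * (1.0 + 0.05 * rng.uniform(-1, 1, size=3))
    r_csf = 0.20 * (1.0 + 0.08 * rng.uniform(-1, 1, size=3))
    brain = ((u / r_brain) ** 2).sum(-1) <= 1.0
    wm = ((u / r_wm) ** 2).sum(-1) <= 1.0
    csf = ((u / r_csf) ** 2).sum(-1) <= 1.0
    cross_halfwidth = 0.28 * (1.0 + 0.1 * rng.uniform(-1, 1))
    crossing = wm & (np.abs(u[..., 0]) < cross_halfwidth) & (np.abs(u[..., 1]) < cross_halfwidth)

    labels = np.zeros(shape, dtype=int)
    labels[brain] = LABEL_GM
    labels[wm] = LABEL_WM_SINGLE
    labels[crossing] = LABEL_WM_CROSS
    labels[csf] = LABEL_CSF

    # per-subject diffusivity jitter (mm^2/s)
    lam_par = 1.7e-3 * (1 + 0.05 * rng.uniform(-1, 1))
    lam_perp = 0.30e-3 * (1 + 0.05 * rng.uniform(-1, 1))
    d_gm = 0.80e-3 * (1 + 0.05 * rng.uniform(-1, 1))
    d_csf = 2.8e-3 * (1 + 0.03 * rng.uniform(-1, 1))

    # fibre geometry: single-fibre WM follows a smoothly rotating in-plane
    # orientation; crossing region mixes two fixed oblique populations
    theta0 = rng.uniform(0, np.pi)
    phi = np.arctan2(u[..., 1], u[..., 0]) + theta0
    dir1_cross = np.array([np.cos(theta0), np.sin(theta0), 0.15])
    dir2_cross = np.array([-np.sin(theta0), np.cos(theta0), -0.15])
    t1_cross = _fibre_tensor(dir1_cross, lam_par, lam_perp)
    t2_cross = _fibre_tensor(dir2_cross, lam_par, lam_perp)

    fractions = np.zeros(shape + (3,))
    tensors = np.zeros(shape + (3, 6))
    iso = np.eye(3)
    tensors[..., 2, :3] = d_gm  # default isotropic compartment
    s0 = np.zeros(shape)

    gm = labels == LABEL_GM
    fractions[gm, 2] = 1.0
    s0[gm] = 900.0

    csf_m = labels == LABEL_CSF
    fractions[csf_m, 2] = 1.0
    tensors[csf_m, 2, :3] = d_csf
    s0[csf_m] = 1800.0

    sing = labels == LABEL_WM_SINGLE
    fractions[sing, 0] = 0.85
    fractions[sing, 2] = 0.15
    # tangential orientation field, voxel-wise
    for idx in np.argwhere(sing):
        p = phi[tuple(idx)]
        tensors[tuple(idx) + (0,)] = _fibre_tensor(
            np.array([np.cos(p), np.sin(p), 0.1]), lam_par, lam_perp
        )
    s0[sing] = 800.0

    cross_m = labels == LABEL_WM_CROSS
    fractions[cross_m, 0] = 0.425
    fractions[cross_m, 1] = 0.425
    fractions[cross_m, 2] = 0.15
    tensors[cross_m, 0, :] = t1_cross
    tensors[cross_m, 1, :] = t2_cross
    s0[cross_m] = 800.0

    return SubjectAnatomy(
        fractions=fractions, tensors=tensors, s0=s0, labels=labels, affine=affine, seed=seed
    )


def _resample_fields(anat: SubjectAnatomy, proto: ScannerProtocol):
    """Linearly sample anatomy fields at the protocol grid's voxel centres."""
    ref_vs = np.linalg.norm(anat.affine[:3, :3], axis=0)
    fov = np.asarray(anat.labels.shape) * ref_vs
    shape = tuple(int(round(f / proto.voxel_size)) for f in fov)
    affine = _centered_affine(shape, proto.voxel_size)

    idx = np.indices(shape).reshape(3, -1)
    homo = np.vstack([idx, np.ones((1, idx.shape[1]))])
    coords = (np.linalg.inv(anat.affine) @ affine @ homo)[:3].reshape((3,) + shape)

    def lin(v):
        return ndimage.map_coordinates(v, coords, order=1, mode="nearest")

    def nn(v):
        return ndimage.map_coordinates(v, coords, order=0, mode="nearest")

    fr = np.stack([lin(anat.fractions[..., i]) for i in range(3)], axis=-1)
    tn = np.stack(
        [np.stack([lin(anat.tensors[..., i, j]) for j in range(6)], axis=-1) for i in range(3)],
        axis=-2,
    )
    s0 = lin(anat.s0)
    labels = nn(anat.labels.astype(float)).astype(int)
    mask = nn(anat.mask.astype(float)) > 0.5
    return shape, affine, fr, tn, s0, labels, mask


def anatomy_on_grid(anat: SubjectAnatomy, proto: ScannerProtocol):
    """Mask, label map and affine of the anatomy on the protocol grid."""
    _, affine, _, _, _, labels, mask = _resample_fields(anat, proto)
    return mask, labels, affine


def _noise_free_attenuation(fr, tn, bval, dirs) -> np.ndarray:
    """Multi-tensor normalised signal E(g) at each voxel and direction."""
    # quadratic form g^T D g from the 6 unique elements
    g = dirs
    q = np.stack(
        [g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
         2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2]],
        axis=-1,
    )  # (n_dir, 6)
    # (..., 3, 6) x (n_dir, 6) -> (..., 3, n_dir)
    adc = np.einsum("...cj,dj->...cd", tn, q)
    E = (fr[..., :, None] * np.exp(-bval * adc)).sum(axis=-2)
    return E


def apply_order_attenuation(
    E: np.ndarray, dirs: np.ndarray, order_atten: tuple[float, float, float]
) -> np.ndarray:
    """Multiply the order-l SH content of an angular profile by (a0, a2, a4)."""
    if np.allclose(order_atten, 1.0):
        return E
    field = sh.fit_sh(E, dirs, L=4, lb_lambda=0.0)
    ls, _ = sh.sh_orders(4)
    scale = np.choose(ls // 2, np.asarray(order_atten, dtype=float))
    field.coeffs = field.coeffs * scale
    return sh.resample_sh(field, dirs)


def render_acquisition(
    anat: SubjectAnatomy, proto: ScannerProtocol, seed: int = 0
) -> DWIStack:
    """Simulate one acquisition of a subject under a protocol."""
    shape, affine, fr, tn, s0, labels, mask = _resample_fields(anat, proto)
    dirs = proto.directions()
    E = _noise_free_attenuation(fr, tn, proto.bval, dirs)
    E = apply_order_attenuation(E, dirs, proto.order_atten)

    S_dwi = proto.gain * s0[..., None] * E
    S_b0 = proto.gain * s0
    data = np.concatenate(
        [np.repeat(S_b0[..., None], proto.n_b0, axis=-1), S_dwi], axis=-1
    )

    if proto.blur_fwhm > 0:
        sigma_vox = proto.blur_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / proto.voxel_size
        for k in range(data.shape[-1]):
            data[..., k] = ndimage.gaussian_filter(data[..., k], sigma_vox)

    if proto.snr is not None:
        rng = np.random.default_rng(seed)
        sigma = float(S_b0[mask].mean()) / proto.snr
        n1 = rng.normal(scale=sigma, size=data.shape)
        n2 = rng.normal(scale=sigma, size=data.shape)
        data = np.sqrt((data + n1) ** 2 + n2**2)

    return DWIStack(data=data, affine=affine, scheme=proto.scheme())


def oracle_harmonise(
    src: DWIStack,
    src_proto: ScannerProtocol,
    tgt_proto: ScannerProtocol,
    L: int = 4,
    lb_lambda: float = 0.0,
) -> DWIStack:
    """Harmonisation with the recorded ground-truth scanner transform.

    Fits the b0-normalised source signal in SH space, rescales each order by
    ``a_l(target)/a_l(source)``, and evaluates at the target directions.
    Its residual error against the target acquisition is the noise +
    SH-truncation floor that no learned harmoniser can beat on average.
    Matched-resolution only (shared grid).
    """
    from .io import mean_b0

    b0 = mean_b0(src)
    dwi = ~src.scheme.b0_mask()
    with np.errstate(invalid="ignore", divide="ignore"):
        normalised = np.where(b0[..., None] > 1e-8, src.data[..., dwi] / b0[..., None], 0.0)
    field = sh.fit_sh(normalised, src.scheme.bvecs[dwi], L, lb_lambda)
    ls, _ = sh.sh_orders(L)
    a_src = np.choose(ls // 2, np.asarray(src_proto.order_atten, dtype=float))
    a_tgt = np.choose(ls // 2, np.asarray(tgt_proto.order_atten, dtype=float))
    field.coeffs = field.coeffs * (a_tgt / a_src)

    tgt_scheme = tgt_proto.scheme()
    tgt_dwi = ~tgt_scheme.b0_mask()
    pred = sh.resample_sh(field, tgt_scheme.bvecs[tgt_dwi])
    gain_ratio = tgt_proto.gain / src_proto.gain
    out = np.empty(src.spatial_shape + (len(tgt_scheme),))
    out[..., tgt_dwi] = pred * b0[..., None] * gain_ratio
    out[..., ~tgt_dwi] = b0[..., None] * gain_ratio
    return DWIStack(data=out, affine=src.affine, scheme=tgt_scheme)


# The two-scanner study conditions used throughout: a source scanner taken
# as the reference frame (identity effect) and a target scanner with a
# global gain and order-wise attenuation that shift MD/R0 (through a0, gain)
# as well as FA/R2 (through a2, a4).
DEFAULT_PROTOCOLS = {
    "source": ScannerProtocol(
        name="source", gain=1.0, order_atten=(1.0, 1.0, 1.0), dir_seed=101, snr=30.0
    ),
    "target": ScannerProtocol(
        name="target", gain=1.1, order_atten=(0.95, 0.75, 0.60), dir_seed=202, snr=30.0
    ),
}


def simulate_cohort(
    seed: int,
    n_subjects: int = 14,
    protocols: dict[str, ScannerProtocol] | None = None,
    shape: tuple[int, int, int] = (24, 24, 24),
) -> list[dict]:
    """In-memory travelling-subject cohort: every subject under every protocol."""
    protocols = protocols or DEFAULT_PROTOCOLS
    rng = np.random.default_rng(seed)
    subj_seeds = rng.integers(0, 2**31 - 1, size=n_subjects)
    noise_seeds = rng.integers(0, 2**31 - 1, size=(n_subjects, len(protocols)))
    cohort = []
    for i in range(n_subjects):
        anat = make_subject(int(subj_seeds[i]), shape=shape)
        entry = {"anatomy": anat, "seed": int(subj_seeds[i]), "acquisitions": {}, "grids": {}}
        for j, (name, proto) in enumerate(protocols.items()):
            stack = render_acquisition(anat, proto, seed=int(noise_seeds[i, j]))
            mask, labels, affine = anatomy_on_grid(anat, proto)
            entry["acquisitions"][name] = stack
            entry["grids"][name] = {"mask": mask, "labels": labels, "affine": affine}
        cohort.append(entry)
    return cohort


def make_benchmark(
    out_dir: str | Path,
    n_train: int = 10,
    n_test: int = 4,
    protocols: dict[str, ScannerProtocol] | None = None,
    seed: int = 0,
    shape: tuple[int, int, int] = (24, 24, 24),
) -> dict:
    """Write a benchmark dataset tree to disk and return its manifest.

    Layout: ``sub-XX/<protocol>/dwi.nii.gz + dwi.bval/.bvec + mask/labels``
    plus ``manifest.json`` recording every seed and scanner-effect
    parameter (the ground-truth transform), so the dataset regenerates
    bit-identically from the manifest alone.
    """
    protocols = protocols or DEFAULT_PROTOCOLS
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = n_train + n_test
    cohort = simulate_cohort(seed, n_subjects=n, protocols=protocols, shape=shape)

    subjects = []
    for i, entry in enumerate(cohort):
        sid = f"sub-{i:02d}"
        for name, stack in entry["acquisitions"].items():
            pdir = out / sid / name
            pdir.mkdir(parents=True, exist_ok=True)
            write_dwi(stack, pdir / "dwi.nii.gz", pdir / "dwi.bval", pdir / "dwi.bvec")
            g = entry["grids"][name]
            write_volume(g["mask"].astype(int), g["affine"], pdir / "mask.nii.gz")
            write_volume(g["labels"], g["affine"], pdir / "labels.nii.gz")
        subjects.append({"id": sid, "anatomy_seed": entry["seed"],
                         "split": "train" if i < n_train else "test"})

    manifest = {
        "seed": int(seed),
        "shape": list(shape),
        "n_train": n_train,
        "n_test": n_test,
        "protocols": {k: asdict(v) for k, v in protocols.items()},
        "subjects": subjects,
        "tissue_class": {str(k): v for k, v in TISSUE_CLASS.items()},
    }
    manifest = json.loads(json.dumps(manifest))  # canonical JSON types
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
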