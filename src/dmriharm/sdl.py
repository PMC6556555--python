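"""Sparse-dictionary-learning (SDL) harmonisation.

The target scanner's appearance is summarised by an over-complete
dictionary ``D`` (twice as many atoms as the patch dimension, unit-norm
columns) learned from vectorised spatio-angular patches ``X_n`` by
alternating minimisation of

    sum_n || X_n - D alpha_n ||_2^2 + lambda ||alpha_n||_1
    s.t. ||d_j||_2 = 1,  alpha_n >= 0

The alpha-step is non-negative lasso by coordinate descent at fixed ``D``;
the D-step minimises the residual column by column, each column solved
exactly on the unit sphere, which keeps the constraint satisfied after
every iteration and makes the full-batch objective non-increasing.
``lambda`` can be chosen by the Akaike information criterion with the
number of non-zero code elements as the degrees of freedom.

Harmonisation codes *source* patches on the *target* dictionary and
reconstructs them as ``D alpha``; because patches live in a standardised
per-image space and are un-standardised with the target statistics, the
reconstruction inherits the target scanner's intensity characteristics.
For resolution enhancement, codes are fitted on a spatially downsampled
copy of a high-resolution dictionary and the reconstruction uses the
original atoms.

Output gradient directions are matched in SH space with a residual
formulation: the harmonised channel values minus the source channel values
define a low-order correction field that is added to the source's SH
coefficients before resampling at the target directions.  The correction
carries the learned inter-scanner mapping; angular detail above the
correction order passes through from the source unchanged.

Angular channels: raw gradient schemes differ between scanners, so patches
are built not from raw volumes but from the b0-normalised signal resampled
(through an order-4 SH fit) at a small fixed set of representative
directions — 5 by default, giving the 3 x 3 x 3 x 5 patches used for
matched-resolution mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import sh
from .io import B0_THRESHOLD, DWIStack, GradientScheme, mean_b0

__all__ = [
    "CHANNEL_DIR_SEED",
    "angular_channels",
    "channel_stats",
    "PatchSet",
    "extract_patches",
    "reconstruct_from_patches",
    "nonneg_lasso",
    "SparseDictionary",
    "dictionary_objective",
    "learn_dictionary",
    "select_lambda_aic",
    "SDLModel",
    "save_model",
    "load_model",
    "train_sdl_matched",
    "harmonise_matched",
    "downsample_operator",
    "harmonise_superres",
]

CHANNEL_DIR_SEED = 77  # fixed: channel directions are part of the model space
_B0_EPS = 1e-8


def channel_directions(n_channels: int) -> np.ndarray:
    return sh.hemisphere_directions(n_channels, seed=CHANNEL_DIR_SEED)


def angular_channels(
    stack: DWIStack,
    mask: np.ndarray,
    n_channels: int = 5,
    L: int = 4,
    lb_lambda: float = 0.006,
    b0_threshold: float = B0_THRESHOLD,
    return_field: bool = False,
):
    """Scheme-independent angular channels of a stack.

    Returns ``(channels, b0, dirs)`` where ``channels`` is a 4D array of the
    b0-normalised signal SH-resampled at ``n_channels`` fixed directions
    (zero outside the mask).  With ``return_field=True`` the per-voxel
    order-``L`` coefficient image the channels were sampled from is appended
    to the tuple.
    """
    mask = np.asarray(mask).astype(bool)
    b0 = mean_b0(stack, b0_threshold)
    valid = mask & (b0 > _B0_EPS)
    dwi = ~stack.scheme.b0_mask(b0_threshold)
    signals = stack.data[valid][:, dwi] / b0[valid][:, None]
    field = sh.fit_sh(signals, stack.scheme.bvecs[dwi], L, lb_lambda)
    dirs = channel_directions(n_channels)
    vals = sh.resample_sh(field, dirs)
    channels = np.zeros(stack.spatial_shape + (n_channels,))
    channels[valid] = vals
    if return_field:
        coeffs_img = np.zeros(stack.spatial_shape + (sh.n_coeffs(L),))
        coeffs_img[valid] = field.coeffs
        return channels, b0, dirs, coeffs_img
    return channels, b0, dirs


def channel_stats(channels: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean and standard deviation over the mask (per-image)."""
    vox = channels[np.asarray(mask).astype(bool)]
    mean = vox.mean(axis=0)
    std = vox.std(axis=0)
    std = np.where(std > 1e-12, std, 1.0)
    return mean, std


@dataclass
class PatchSet:
    """Vectorised spatio-angular patches.

    ``X`` has one column per patch; a patch covering spatial block
    ``(a, b, c)`` with ``k`` channels is flattened in C order of
    ``(x, y, z, channel)``, so ``m = a*b*c*k``.
    """

    X: np.ndarray  # (m, N)
    positions: np.ndarray  # (N, 3) corner voxel indices
    spatial: tuple[int, int, int]
    n_channels: int
    image_shape: tuple[int, int, int]

    @property
    def m(self) -> int:
        return self.X.shape[0]

    @property
    def n_patches(self) -> int:
        return self.X.shape[1]


def extract_patches(
    channels: np.ndarray, mask: np.ndarray, spatial: tuple[int, int, int] = (3, 3, 3)
) -> PatchSet:
    """All fully-in-mask sliding-window patches (stride 1)."""
    channels = np.asarray(channels, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if channels.ndim != 4:
        raise ValueError("channels must be 4D (x, y, z, channel)")
    a, b, c = spatial
    sx, sy, sz, k = channels.shape
    if sx < a or sy < b or sz < c:
        raise ValueError("image smaller than one patch")
    # a patch is kept iff every voxel of its spatial block is in the mask
    from numpy.lib.stride_tricks import sliding_window_view

    win_mask = sliding_window_view(mask, (a, b, c)).reshape(-1, a * b * c).all(axis=1)
    positions = np.indices((sx - a + 1, sy - b + 1, sz - c + 1)).reshape(3, -1).T
    positions = positions[win_mask]
    if len(positions) == 0:
        raise ValueError("mask too small for a single patch")
    wins = sliding_window_view(channels, (a, b, c, k))  # (..., 1, a, b, c, k)
    wins = wins.reshape(sx - a + 1, sy - b + 1, sz - c + 1, a, b, c, k)
    X = wins.reshape(-1, a * b * c * k)[win_mask].T.copy()
    return PatchSet(
        X=X, positions=positions, spatial=(a, b, c), n_channels=k,
        image_shape=(sx, sy, sz),
    )


def reconstruct_from_patches(
    patch_matrix: np.ndarray,
    positions: np.ndarray,
    spatial: tuple[int, int, int],
    n_channels: int,
    image_shape: tuple[int, int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Overlap-average patches back into a channel image.

    Returns ``(image, coverage)`` where ``coverage`` counts contributing
    patches per voxel (0 = not covered).
    """
    a, b, c = spatial
    out = np.zeros(tuple(image_shape) + (n_channels,))
    cov = np.zeros(image_shape)
    P = patch_matrix.T.reshape(-1, a, b, c, n_channels)
    for p, (x, y, z) in zip(P, positions):
        out[x : x + a, y : y + b, z : z + c] += p
        cov[x : x + a, y : y + b, z : z + c] += 1.0
    nz = cov > 0
    out[nz] /= cov[nz][:, None]
    return out, cov


def nonneg_lasso(
    D: np.ndarray,
    X: np.ndarray,
    lam: float,
    max_sweeps: int = 200,
    tol: float = 1e-6,
    alpha0: np.ndarray | None = None,
) -> np.ndarray:
    """Non-negative lasso codes by coordinate descent.

    Minimises ``||x - D a||_2^2 + lam ||a||_1`` s.t. ``a >= 0`` for every
    column ``x`` of ``X`` simultaneously.  Columns of ``D`` need not be
    unit-norm (required for coding on a downsampled dictionary).  Stops
    when the largest coefficient update of a sweep falls below ``tol``
    (relative to the largest coefficient) or after ``max_sweeps``.
    """
    D = np.asarray(D, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != D.shape[0]:
        X = X.T  # accept (N, m) as well
    m, p = D.shape
    n = X.shape[1]
    norms2 = (D**2).sum(axis=0)
    alpha = np.zeros((p, n)) if alpha0 is None else np.array(alpha0, dtype=float)
    R = X - D @ alpha  # residuals
    usable = norms2 > 1e-12

    def sweep(cols) -> float:
        max_delta = 0.0
        for j in cols:
            rho = D[:, j] @ R + norms2[j] * alpha[j]
            new = np.maximum(0.0, (rho - lam / 2.0) / norms2[j])
            delta = new - alpha[j]
            nzd = np.abs(delta) > 0
            if np.any(nzd):
                R[:, nzd] -= np.outer(D[:, j], delta[nzd])
                alpha[j] = new
                max_delta = max(max_delta, np.abs(delta).max())
        return max_delta

    # active-set strategy: full sweeps establish which atoms are used at
    # all, cheaper sweeps iterate those to convergence, and a final full
    # sweep re-checks the optimality conditions of the excluded atoms
    all_cols = np.flatnonzero(usable)
    sweeps_left = max_sweeps
    while sweeps_left > 0:
        delta_full = sweep(all_cols)
        sweeps_left -= 1
        scale = max(np.abs(alpha).max(), 1.0)
        if delta_full / scale < tol:
            break
        while sweeps_left > 0:
            active = np.flatnonzero(usable & (alpha != 0).any(axis=1))
            if len(active) == 0:
                break
            d = sweep(active)
            sweeps_left -= 1
            if d / max(np.abs(alpha).max(), 1.0) < tol:
                break
    return alpha


@dataclass
class SparseDictionary:
    """Learned over-complete dictionary with its sparsity weight."""

    D: np.ndarray  # (m, p), unit-norm columns
    lam: float
    n_iterations: int
    batch_size: int
    seed: int
    objective_history: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_dead_reseeds: int = 0

    @property
    def m(self) -> int:
        return self.D.shape[0]

    @property
    def p(self) -> int:
        return self.D.shape[1]


def dictionary_objective(D: np.ndarray, X: np.ndarray, alpha: np.ndarray, lam: float) -> float:
    """``sum_n ||X_n - D a_n||^2 + lam ||a_n||_1`` (codes are non-negative)."""
    R = X - D @ alpha
    return float((R**2).sum() + lam * alpha.sum())


def learn_dictionary(
    X: np.ndarray,
    lam: float,
    n_iterations: int = 1000,
    batch_size: int = 128,
    seed: int = 0,
    p: int | None = None,
    code_sweeps: int = 5,
    code_tol: float = 1e-4,
    track_objective: bool = False,
) -> SparseDictionary:
    """Alternating sparse coding / dictionary update on random patch batches.

    The dictionary is initialised from randomly drawn patches and has
    ``p = 2m`` atoms by default.  Each iteration draws ``batch_size``
    patches, sparse-codes them (coordinate descent), and updates every used
    atom exactly on the unit sphere.  Atoms unused in a batch are re-seeded
    from a random patch.  With ``batch_size >= N`` the method becomes exact
    full-batch alternating minimisation with warm-started codes, whose
    objective is non-increasing.
    """
    X = np.asarray(X, dtype=float)
    m, N = X.shape
    if lam <= 0:
        raise ValueError("lam must be positive")
    p = 2 * m if p is None else p
    rng = np.random.default_rng(seed)
    if N < min(batch_size, N):
        raise ValueError("need at least one batch of patches")

    D = X[:, rng.integers(0, N, size=p)].astype(float).copy()
    cnorm = np.linalg.norm(D, axis=0)
    zero = cnorm < 1e-12
    if np.any(zero):  # all-zero init patches -> random unit atoms
        D[:, zero] = rng.normal(size=(m, int(zero.sum())))
        cnorm = np.linalg.norm(D, axis=0)
    D /= cnorm

    full_batch = batch_size >= N
    alpha_warm = np.zeros((p, N)) if full_batch else None
    history = [] if track_objective else None
    n_reseed = 0

    for it in range(n_iterations):
        if full_batch:
            idx = np.arange(N)
            alpha = nonneg_lasso(D, X, lam, max_sweeps=code_sweeps, tol=code_tol,
                                 alpha0=alpha_warm)
            alpha_warm = alpha
        else:
            idx = rng.integers(0, N, size=batch_size)
            alpha = nonneg_lasso(D, X[:, idx], lam, max_sweeps=code_sweeps, tol=code_tol)
        Xb = X[:, idx]
        A = alpha @ alpha.T
        Bm = Xb @ alpha.T
        used = np.diag(A) > 1e-12
        for j in range(p):
            if not used[j]:
                continue
            bj = Bm[:, j] - D @ A[:, j] + D[:, j] * A[j, j]
            nb = np.linalg.norm(bj)
            if nb > 1e-12:
                D[:, j] = bj / nb
        dead = ~used
        if np.any(dead) and not full_batch:
            # re-seed unused atoms from random patches (residual unchanged:
            # their codes are zero in this batch)
            ridx = rng.integers(0, N, size=int(dead.sum()))
            cand = X[:, ridx]
            cn = np.linalg.norm(cand, axis=0)
            ok = cn > 1e-12
            D[:, np.flatnonzero(dead)[ok]] = cand[:, ok] / cn[ok]
            n_reseed += int(ok.sum())
        if track_objective:
            history.append(dictionary_objective(D, Xb, alpha, lam))

    return SparseDictionary(
        D=D, lam=lam, n_iterations=n_iterations, batch_size=batch_size, seed=seed,
        objective_history=np.asarray(history) if track_objective else np.empty(0),
        n_dead_reseeds=n_reseed,
    )


def select_lambda_aic(
    X: np.ndarray,
    lam_grid: np.ndarray,
    n_iterations: int = 100,
    batch_size: int = 128,
    seed: int = 0,
    code_sweeps_final: int = 200,
) -> tuple[float, list[dict]]:
    """AIC-driven sparsity-weight selection.

    For each candidate ``lambda`` a dictionary is learned and the full
    patch set coded; the criterion is

        AIC = N m ln(RSS / (N m)) + 2 nnz

    with ``nnz`` the number of non-zero code elements (model degrees of
    freedom).  Ties break toward the larger (sparser) ``lambda``.
    Returns the winner and the per-candidate table.
    """
    lam_grid = np.asarray(lam_grid, dtype=float)
    if lam_grid.size == 0 or np.any(lam_grid <= 0):
        raise ValueError("lam_grid must be non-empty and positive")
    X = np.asarray(X, dtype=float)
    m, N = X.shape
    rows = []
    for lam in np.sort(lam_grid):
        model = learn_dictionary(
            X, lam, n_iterations=n_iterations, batch_size=batch_size, seed=seed
        )
        alpha = nonneg_lasso(model.D, X, lam, max_sweeps=code_sweeps_final)
        rss = float(((X - model.D @ alpha) ** 2).sum())
        nnz = int(np.count_nonzero(alpha))
        if rss <= 0:
            aic = -np.inf  # degenerate perfect fit; largest such lam wins
        else:
            aic = N * m * np.log(rss / (N * m)) + 2 * nnz
        rows.append({"lam": float(lam), "rss": rss, "nnz": nnz, "aic": float(aic)})
    best = min(rows, key=lambda r: (r["aic"], -r["lam"]))
    return best["lam"], rows


@dataclass
class SDLModel:
    """Trained matched-resolution SDL harmoniser (target-scanner dictionary)."""

    dictionary: SparseDictionary
    spatial: tuple[int, int, int]
    n_channels: int
    target_mean: np.ndarray  # per-channel, pooled over training images
    target_std: np.ndarray
    L: int = 4
    lb_lambda: float = 0.006
    recon_order: int = 2
    recon_lambda: float = 0.006
    version: str = "1"


def save_model(model: SDLModel, path) -> None:
    """Serialise a trained model to a single ``.npz`` archive."""
    d = model.dictionary
    np.savez(
        path,
        D=d.D, lam=d.lam, n_iterations=d.n_iterations, batch_size=d.batch_size,
        seed=d.seed, spatial=np.asarray(model.spatial), n_channels=model.n_channels,
        target_mean=model.target_mean, target_std=model.target_std,
        L=model.L, lb_lambda=model.lb_lambda, recon_order=model.recon_order,
        recon_lambda=model.recon_lambda, version=model.version,
    )


def load_model(path) -> SDLModel:
    with np.load(path, allow_pickle=False) as z:
        dictionary = SparseDictionary(
            D=z["D"], lam=float(z["lam"]), n_iterations=int(z["n_iterations"]),
            batch_size=int(z["batch_size"]), seed=int(z["seed"]),
        )
        return SDLModel(
            dictionary=dictionary,
            spatial=tuple(int(s) for s in z["spatial"]),
            n_channels=int(z["n_channels"]),
            target_mean=z["target_mean"], target_std=z["target_std"],
            L=int(z["L"]), lb_lambda=float(z["lb_lambda"]),
            recon_order=int(z["recon_order"]), recon_lambda=float(z["recon_lambda"]),
            version=str(z["version"]),
        )


def _standardised_channels(stack, mask, n_channels, L, lb):
    channels, b0, _, coeffs_img = angular_channels(
        stack, mask, n_channels, L, lb, return_field=True
    )
    mean, std = channel_stats(channels, mask)
    std_ch = np.where(mask[..., None], (channels - mean) / std, 0.0)
    return std_ch, channels, b0, mean, std, coeffs_img


def train_sdl_matched(
    target_stacks: list[DWIStack],
    target_masks: list[np.ndarray],
    lam: float | None = 0.1,
    lam_grid: np.ndarray | None = None,
    n_iterations: int = 1000,
    batch_size: int = 128,
    seed: int = 0,
    n_channels: int = 5,
    spatial: tuple[int, int, int] = (3, 3, 3),
    L: int = 4,
    lb_lambda: float = 0.006,
    recon_order: int = 2,
) -> SDLModel:
    """Learn the target-scanner dictionary from training subjects.

    If ``lam`` is None a grid search with :func:`select_lambda_aic` picks
    the sparsity weight first.
    """
    Xs, means, stds, weights = [], [], [], []
    for stack, mask in zip(target_stacks, target_masks):
        std_ch, _, _, mean, std, _ = _standardised_channels(stack, mask, n_channels, L, lb_lambda)
        ps = extract_patches(std_ch, mask, spatial)
        Xs.append(ps.X)
        means.append(mean)
        stds.append(std)
        weights.append(np.count_nonzero(mask))
    X = np.concatenate(Xs, axis=1)
    w = np.asarray(weights, dtype=float)
    w /= w.sum()
    target_mean = (np.stack(means) * w[:, None]).sum(axis=0)
    target_std = (np.stack(stds) * w[:, None]).sum(axis=0)

    if lam is None:
        if lam_grid is None:
            lam_grid = np.array([0.02, 0.05, 0.1, 0.2, 0.5])
        lam, _ = select_lambda_aic(X, lam_grid, seed=seed)
    dictionary = learn_dictionary(
        X, lam, n_iterations=n_iterations, batch_size=batch_size, seed=seed
    )
    return SDLModel(
        dictionary=dictionary, spatial=spatial, n_channels=n_channels,
        target_mean=target_mean, target_std=target_std, L=L, lb_lambda=lb_lambda,
        recon_order=recon_order,
    )


def _corrected_stack(
    coeffs_img: np.ndarray,
    corr_channels: np.ndarray,
    mask: np.ndarray,
    b0: np.ndarray,
    target_scheme: GradientScheme,
    affine: np.ndarray,
    L: int,
    recon_order: int,
    recon_lambda: float,
    n_channels: int,
) -> DWIStack:
    """Residual angular reconstruction.

    The harmonised signal is the source's order-``L`` SH field plus a
    low-order correction field fitted to the per-voxel channel-value
    differences — the correction carries the learned scanner mapping while
    the source field passes its full angular detail through.
    """
    dirs = channel_directions(n_channels)
    valid = np.asarray(mask).astype(bool)
    corr_field = sh.fit_sh(corr_channels[valid], dirs, recon_order, recon_lambda)
    coeffs = coeffs_img[valid].copy()
    nc_corr = sh.n_coeffs(recon_order)
    # low-order coefficients lead the (l, m) storage order, so the
    # correction pads in place
    coeffs[:, :nc_corr] += corr_field.coeffs
    field = sh.SHField(coeffs, order=L)
    tgt_dwi = ~target_scheme.b0_mask()
    pred = sh.resample_sh(field, target_scheme.bvecs[tgt_dwi])
    out = np.zeros(corr_channels.shape[:3] + (len(target_scheme),))
    dwi_img = np.zeros(corr_channels.shape[:3] + (int(tgt_dwi.sum()),))
    dwi_img[valid] = pred
    out[..., tgt_dwi] = dwi_img * b0[..., None]
    out[..., ~tgt_dwi] = b0[..., None]
    return DWIStack(data=out, affine=affine, scheme=target_scheme)


def harmonise_matched(
    src: DWIStack,
    src_mask: np.ndarray,
    model: SDLModel,
    target_scheme: GradientScheme,
) -> DWIStack:
    """Map a source acquisition onto the target scanner (shared grid).

    Source patches (standardised with the source image's own statistics)
    are sparse-coded on the target dictionary, reconstructed as ``D alpha``
    with overlapping predictions averaged per voxel, un-standardised with
    the *target* statistics, and resampled at the target directions.
    In-mask voxels not covered by any full patch fall back to the
    statistics-mapped source value.
    """
    if model.n_channels != model.dictionary.m // int(np.prod(model.spatial)):
        raise ValueError("model channel count inconsistent with dictionary size")
    mask = np.asarray(src_mask).astype(bool)
    std_ch, src_ch, b0, _, _, coeffs_img = _standardised_channels(
        src, mask, model.n_channels, model.L, model.lb_lambda
    )
    ps = extract_patches(std_ch, mask, model.spatial)
    if ps.m != model.dictionary.m:
        raise ValueError(
            f"patch dimension {ps.m} does not match dictionary rows {model.dictionary.m}"
        )
    alpha = nonneg_lasso(model.dictionary.D, ps.X, model.dictionary.lam)
    recon = model.dictionary.D @ alpha
    img, cov = reconstruct_from_patches(
        recon, ps.positions, ps.spatial, ps.n_channels, ps.image_shape
    )
    covered = cov > 0
    img = np.where(covered[..., None], img, std_ch)  # fallback: stats mapping only
    out_channels = np.where(
        mask[..., None], img * model.target_std + model.target_mean, 0.0
    )
    corr = np.where(mask[..., None], out_channels - src_ch, 0.0)
    return _corrected_stack(
        coeffs_img, corr, mask, b0, target_scheme, src.affine,
        model.L, model.recon_order, model.recon_lambda, model.n_channels,
    )


def downsample_operator(
    high_spatial: tuple[int, int, int],
    low_spatial: tuple[int, int, int],
    n_channels: int,
) -> np.ndarray:
    """Linear map from high-resolution to low-resolution patch space.

    Each low-resolution patch voxel is the (tri)linear average of the
    high-resolution block it covers: per axis, the low voxel centre
    ``(i + 1/2) * h / l - 1/2`` (in high index coordinates) is sampled with
    linear weights.  For integer ratios this reduces to exact
    block-averaging.  The channel dimension is preserved.
    """
    mats = []
    for h, l in zip(high_spatial, low_spatial):
        if h < l:
            raise ValueError(f"high patch extent {h} smaller than low extent {l}")
        W = np.zeros((l, h))
        for i in range(l):
            c = (i + 0.5) * h / l - 0.5
            f = int(np.floor(c))
            t = c - f
            if f < 0:
                W[i, 0] = 1.0
            elif f >= h - 1:
                W[i, h - 1] = 1.0
            else:
                W[i, f] = 1 - t
                W[i, f + 1] = t
        mats.append(W)
    Wsp = np.kron(np.kron(mats[0], mats[1]), mats[2])
    return np.kron(Wsp, np.eye(n_channels))


def harmonise_superres(
    src: DWIStack,
    src_mask: np.ndarray,
    high_model: SDLModel,
    low_spatial: tuple[int, int, int] = (3, 3, 3),
    target_scheme: GradientScheme | None = None,
    recon_order: int | None = None,
) -> DWIStack:
    """Resolution enhancement with a high-resolution dictionary.

    ``high_model`` holds a dictionary of high-resolution patches (e.g.
    6 x 6 x 6 spatial).  Source patches of ``low_spatial`` extent are coded
    on the *downsampled* dictionary and reconstructed with the original
    atoms onto a grid refined by the integer patch-size ratio; gradient
    directions are matched through a truncated SH basis on the channel
    values.  Requires the high/low patch extents to be integer multiples.
    """
    ratios = [h // l for h, l in zip(high_model.spatial, low_spatial)]
    if any(h != r * l for h, l, r in zip(high_model.spatial, low_spatial, ratios)) or min(ratios) < 1:
        raise ValueError(
            f"incompatible patch sizes {high_model.spatial} vs {low_spatial}: "
            "high extents must be integer multiples of low extents"
        )
    r = ratios[0]
    if any(rr != r for rr in ratios):
        raise ValueError("anisotropic refinement factors are not supported")

    mask = np.asarray(src_mask).astype(bool)
    std_ch, src_ch, b0, _, _, coeffs_img = _standardised_channels(
        src, mask, high_model.n_channels, high_model.L, high_model.lb_lambda
    )
    ps = extract_patches(std_ch, mask, low_spatial)
    W = downsample_operator(high_model.spatial, low_spatial, high_model.n_channels)
    D_low = W @ high_model.dictionary.D
    alpha = nonneg_lasso(D_low, ps.X, high_model.dictionary.lam)
    recon_high = high_model.dictionary.D @ alpha

    high_shape = tuple(int(s * r) for s in src.spatial_shape)
    high_positions = ps.positions * r
    img, cov = reconstruct_from_patches(
        recon_high, high_positions, high_model.spatial, high_model.n_channels, high_shape
    )

    # refined grid shares the source FOV; the affine scales accordingly
    high_affine = src.affine.copy()
    high_affine[:3, :3] /= r
    high_affine[:3, 3] = src.affine[:3, 3] - src.affine[:3, :3] @ np.full(3, (r - 1) / (2 * r))

    def up(v):
        return np.repeat(np.repeat(np.repeat(v, r, 0), r, 1), r, 2)

    mask_high = up(mask)
    b0_high = up(b0)
    covered = cov > 0
    std_high = up(std_ch)
    img = np.where(covered[..., None], img, std_high)
    out_channels = np.where(
        mask_high[..., None], img * high_model.target_std + high_model.target_mean, 0.0
    )
    corr = np.where(mask_high[..., None], out_channels - up(src_ch), 0.0)
    if target_scheme is None:
        target_scheme = src.scheme
    order = high_model.recon_order if recon_order is None else recon_order
    return _corrected_stack(
        up(coeffs_img), corr, mask_high, b0_high, target_scheme, high_affine,
        high_model.L, order, high_model.recon_lambda, high_model.n_channels,
    )
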