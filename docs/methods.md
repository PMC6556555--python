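# Methods

`dmriharm` implements cross-scanner/cross-protocol harmonisation of
single-shell diffusion-weighted MRI: given the same subjects imaged under a
"source" and a "target" acquisition, it learns mappings that make the source
data statistically comparable to the target, and quantifies the benefit with
a standard feature-error protocol.  This note records the models, the
numerical choices, and the reasoning behind the parameters that matter.

## Signal representation

Single-shell diffusion signals are antipodally symmetric functions on the
sphere, represented in the real, even-order ("modified") SH basis with
coefficients stored in `(l, m)` order, `l` ascending and `m` ascending
within each order — so the order-`L` vector always begins with the full
order-`(L-2)` vector, a property the residual reconstruction in the SDL
harmoniser relies on.  Fitting minimises

    ||B c - s||^2 + lambda_LB * c^T diag(l^2 (l+1)^2) c

the Laplace–Beltrami-regularised least-squares problem.  `lambda_LB = 0.006`
at order 4 is the conventional smoothing weight for ~30-direction shells and
is the package default wherever noisy signals are fitted; exact analyses
(round-trip identities, rotation-invariance checks) use `lambda_LB = 0`.
The penalty leaves the order-0 coefficient untouched, so the fitted mean
signal is unbiased.  The basis itself is orthonormal (checked by
Gauss–Legendre quadrature in the tests), which makes the per-order energies

    R_l = sum_m c_lm^2

rotation-invariant descriptors (RISH features).  R0 and R2 are computed on
signals normalised by the voxel-wise mean b=0 image; voxels whose mean b0 is
below 1e-8 are excluded (NaN) rather than producing unstable ratios.

Gradient direction sets are generated by electrostatic repulsion with
antipodal symmetry from a seeded random start: 500 bounded tangent-space
steps with a decaying step size.  This is deterministic per seed and yields
minimum pairwise angles within ~10% of the optimum for the set sizes used
here (30 directions: ~26 degrees).

## Tensor estimation

The diffusion tensor is fitted by weighted linear least squares: ordinary
least squares on log-signals initialises, then one re-weighted pass with
weights equal to the squared predicted signals (the standard correction for
the log-transform's heteroscedasticity).  One pass is the default because
further iterations change the estimate negligibly at the SNRs involved while
doubling cost; the count is configurable.  Non-positive signals are clamped
to 1e-10 before the log.  FA and MD are eigenvalue summaries; negative
eigenvalues from noisy fits are clamped to zero for the scalar maps and
counted in a QC field.  FA of the zero tensor is defined as 0.

## The reference predictor

The non-learning baseline resamples b0-normalised source signals trilinearly
onto the target voxel grid and interpolates onto the target directions with
an SH fit (order 6 for matched-resolution targets, order 8 for
high-angular-resolution ones).  Operating on normalised signals and
re-scaling by the trilinearly interpolated mean b0 makes the spatial and
angular steps commute with any global gain.  An order-8 basis (45
coefficients) from a 30-direction source is under-determined, so that path
requires `lambda_LB > 0` (default 0.006).  Note that with 30 directions and
28 order-6 coefficients the unregularised fit is least squares, *not* exact
interpolation; it reproduces the input exactly only on band-limited signals,
which is how the identity property is stated and tested.

## SDL: sparse dictionary learning

The target scanner's local signal structure is summarised by an
over-complete dictionary `D` (p = 2m atoms, unit-norm columns) over
vectorised spatio-angular patches, minimising

    sum_n ||X_n - D a_n||^2 + lambda ||a_n||_1,   a_n >= 0, ||d_j|| = 1.

*Angular channels.*  Raw gradient schemes differ between scanners, so
patches are built from the b0-normalised signal resampled (through the
order-4 SH fit) at 5 fixed representative directions, generated once from a
fixed seed — giving the 3x3x3x5 patches of the matched-resolution model.
Five channels observe the l=0 and l=2 content of the signal well, which is
where the kind of scanner effects modelled here live; the count is
configurable.

*Optimisation.*  The alpha-step is non-negative lasso by coordinate descent
(soft threshold lambda/2, active-set sweeps, stop at relative update < 1e-6
or 200 sweeps for final coding; 5 warm sweeps inside the learning loop).
The D-step updates each used atom by exact minimisation over the unit
sphere (`d_j <- b_j/||b_j||` with `b_j` the atom's residual correlation), so
the unit-norm constraint holds after every iteration and, in full-batch
mode with warm-started codes, the objective is monotonically
non-increasing.  Atoms unused in a batch are re-seeded from random patches
(their codes are zero, so the objective is unaffected).  Learning runs 1000
iterations on random 128-patch batches by default, with the dictionary
initialised from randomly drawn patches.  `lambda` can be chosen by AIC,
`N m ln(RSS/(N m)) + 2 nnz`, with the non-zero code count as the degrees of
freedom and ties broken toward the sparser grid point; the benchmark uses a
fixed `lambda = 0.1` on standardised patches (patch entries are ~unit
variance there, so the threshold `lambda/2` prunes sub-noise coefficients).

*Harmonisation.*  Source images are standardised per image and channel;
patches are coded on the target dictionary; overlapping reconstructions are
averaged; the result is un-standardised with the pooled target-cohort
statistics — mapping the source intensity distribution onto the target's.
The output stack is then reconstructed *residually*: harmonised minus
source channel values are fitted as an order-2 correction field (with the
Laplace–Beltrami penalty, which also resolves the 5-samples/6-coefficients
indeterminacy) and added onto the source's order-4 coefficients before
resampling at the target directions.  The correction carries the learned
inter-scanner mapping; source angular detail above order 2 passes through
unchanged.  Reconstructing absolute signals from the 5 channel values
instead loses ~5% RMS through the under-determined fit, which is why the
residual form is the default.  In-mask voxels not covered by any complete
patch fall back to the statistics mapping alone.

*Resolution enhancement.*  A dictionary of larger patches (6x6x6 by
default) is learned from high-resolution images; source patches are coded
on its spatially downsampled copy and reconstructed with the original
atoms on the refined grid.  The downsampling operator averages each
low-resolution patch voxel over the high-resolution block it covers
(exact block-averaging for integer size ratios, trilinear weights
otherwise), applied per channel.

## SHNet: the fully-connected coefficient harmoniser

A voxel-wise map on order-4 SH vectors (15 values) with the fixed topology
BatchNorm → FC(15→150)+ReLU → BatchNorm → FC(150→150)+ReLU → BatchNorm →
FC(150→150)+ReLU → BatchNorm → FC(150→15), trained on paired voxels from
co-registered acquisitions with mean-squared coefficient error (the loss
gradient is normalised per voxel, i.e. summed over the 15 coefficients —
this keeps the SGD phase's step sizes meaningful).  Training follows the
two-phase schedule: Adam (lr 0.001, batch 128) for the first five epochs,
then plain SGD (momentum 0) at the inherited rate, multiplied by 0.9
whenever the validation loss fails to improve for more than five epochs.
One training subject is held out for validation; the best-validation
snapshot is returned, its batch-norm population statistics recomputed
exactly over the training set (inference always uses population
statistics).  Early stopping after 20 non-improving epochs, 100 epochs
maximum.

An *epoch* draws a fixed number of voxel pairs (default 250k, with
replacement) rather than one pass over the data: schedules of this family
are calibrated against cohort-scale epochs of 10^5–10^6 voxels, and tying
the optimiser switch to five passes over a small synthetic cohort would
starve the Adam phase of steps.  With sample-count epochs the schedule
behaves identically at any cohort size; `samples_per_epoch=None` restores
plain passes.

The network predicts normalised signal shape only; output stacks re-use
the source mean b0 (interpolated for the super-resolution path), since all
evaluation features are invariant to that scale.  Matched-resolution
prediction is purely voxel-wise; resolution enhancement interpolates each
coefficient channel to the target grid with separable cubic splines before
applying the network, and target directions are resampled from the
predicted coefficients.  With fixed seeds, train→predict is
bit-reproducible.

## Evaluation protocol

Predicted FA/MD/R0/R2 maps are compared with maps from the acquired target
data via ME (predicted − acquired), MNE (ME/acquired) and MSE (ME²), at
three scales: global (mean over the brain mask), regional (per-ROI mean
within subject, then median across subjects) and local (means over sliding
3×3×3 fully-in-mask neighbourhoods, stride 1, pooled across subjects and
summarised by median and 95th percentile with linear-interpolation
quantiles).  Edge-of-brain voxels are removed by one-voxel morphological
erosion (width configurable); MNE excludes |acquired| < 1e-6; every
exclusion is counted so mask accounting closes.  Systematically poor ROIs
are those at or above the tissue-class-specific (WM/GM) 90th percentile of
regional median MSE for ≥ 3 algorithms in ≥ 1 feature — ties at the
threshold count as "at the percentile", but an ROI tied with the class
minimum is never flagged (so a degenerate all-equal class flags nothing).
Tissue classes are supplied as a label→WM/GM mapping; the package runs no
parcellation.

## The synthetic phantom

Each subject is a 3D mixture field of two crossing fibre compartments plus
an isotropic compartment on a 24³ grid of 1.2 mm voxels: a CSF core
(isotropic, ~2.8e-3 mm²/s), a GM shell (isotropic, ~0.8e-3), and a WM
region containing both a smoothly rotating single-fibre field
(λ∥ ≈ 1.7e-3, λ⊥ ≈ 0.3e-3, 15% isotropic volume fraction) and a
two-population crossing block — so anisotropy-sensitive features with sharp
edges (FA, R2) and smooth isotropic ones (MD, R0) are both exercised.
Geometry and diffusivities jitter per subject seed.  Signals follow the
multi-tensor model `S = S0 · Σ f_i exp(−b gᵀ D_i g)`.

Scanner effects are applied per SH order — the normalised angular profile's
orders are multiplied by `(a0, a2, a4)`, the whole signal by a global gain,
optionally followed by a spatial blur.  This is the minimal family that
shifts all four evaluation features, and its parameters are recorded in the
dataset manifest, so the inverse transform is always available.  Noise is
Rician (all protocols are magnitude data): the magnitude of the noise-free
signal plus complex Gaussian noise with σ = (mean in-mask b0)/SNR.

The benchmark conditions are fixed: 14 subjects (10 training / 4 test), a
b = 1200 s/mm², 30-direction, 2.4 mm protocol on both scanners (direction
schemes differ by seed, so angular resampling is always exercised), source
scanner at identity, target scanner with gain 1.1 and attenuations
(0.95, 0.75, 0.60), SNR 30.  At that SNR the induced feature shifts (≈6% in
MD, ≈10% in R0, ≈44% in R2) sit well above the single-scan noise floor, so
harmonisation benefit is measurable with four test subjects.

*The oracle.*  The benchmark also scores the inverse of the recorded
scanner transform applied to the *noise-free* source rendering.  Its error
against the acquired target is the irreducible noise + SH-truncation floor
and lower-bounds every method.  (Applying the inverse to the noisy source
is not a lower bound: learned voxel-wise maps approximate the conditional
mean and beat it by denoising.)

## What the phantom does and does not show

The generator emulates the *structure* of a travelling-subject study —
paired subjects, protocol differences, a systematic scanner effect,
magnitude noise — not real anatomy or real scanner physics.  Its scanner
effect is spatially uniform and order-diagonal by construction, which is
exactly the family the oracle can invert; real inter-scanner differences
include spatially varying, nonlinear components.  Passing benchmarks here
show the estimators are correct and the harmonisers learn the modelled
effect family through the full pipeline; they do not certify performance
on real multi-site data.  Geometry is simulated co-registered, mirroring
the assumption that registration happened upstream.

## Problem sizes and numerical conventions

Default experiment sizes (24³ anatomy at 1.2 mm → 12³ acquisition grids,
~600 brain voxels per subject; ~2.5k dictionary patches; ~5k network
training pairs) were chosen so the full benchmark with both harmonisers
trains and evaluates in minutes on one CPU while every effect of interest
remains well above its estimation noise.  All stochastic components take
explicit seeds (phantom geometry, noise draws, direction schemes, batch
sampling, network initialisation); a fixed top-level seed reproduces every
report bit-identically.  Voxel indices are 0-based; world coordinates come
from the stored NIfTI affine; no reorientation is performed — inputs are
assumed co-registered.  Volumes with b < 50 s/mm² count as b=0 baselines
(configurable); gradient tables use the FSL 3-row dialect with a flag for
the transposed layout.  Cross-terms of full b-matrices beyond bval/bvec are
not modelled.

## Serialisation

SH coefficient fields save as 4D NIfTI volumes with a JSON sidecar
recording order, `lambda_LB` and the `(l, m)` storage ordering (loading
refuses a sidecar whose ordering differs from the package's basis).
Trained harmonisers save as single `.npz` archives: the SDL model stores
the dictionary, `lambda`, patch geometry, channel statistics, seed and a
version tag; the network model stores all weights, the exact batch-norm
population statistics, the training configuration and seed.  Loading a
model reproduces its predictions bit-identically.

## Extension points and limitations

The harmoniser registry is the module surface: additional voxel-wise or
patch-based methods (residual networks, spherical convolutions,
fully-convolutional patch networks) can be added alongside `sdl` and
`shnet` by implementing the same train/predict contract.  Known
limitations: single-shell only (the multi-shell case needs a joint basis);
RISH evaluation stops at order 2; the SDL channel count bounds the angular
order the dictionary can correct; no statistical testing across algorithms
is performed.
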