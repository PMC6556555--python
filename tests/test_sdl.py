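import numpy as np
import pytest

from dmriharm import sdl, sh

from tests.conftest import make_stack


def sparse_generated(rng, m=60, p0=20, N=400, k=3):
    D0 = rng.normal(size=(m, p0))
    D0 /= np.linalg.norm(D0, axis=0)
    alpha = np.zeros((p0, N))
    for n in range(N):
        idx = rng.choice(p0, k, replace=False)
        alpha[idx, n] = rng.uniform(0.5, 2.0, k)
    return D0, alpha, D0 @ alpha


class TestPatches:
    def test_full_grid_patch_count(self):
        channels = np.random.default_rng(0).uniform(size=(9, 9, 9, 2))
        ps = sdl.extract_patches(channels, np.ones((9, 9, 9), bool), (3, 3, 3))
        assert ps.n_patches == 343  # (9-2)^3
        assert ps.m == 27 * 2

    def test_vectorise_restore_round_trip(self):
        rng = np.random.default_rng(1)
        channels = rng.uniform(size=(6, 6, 6, 3))
        mask = np.ones((6, 6, 6), bool)
        ps = sdl.extract_patches(channels, mask, (3, 3, 3))
        img, cov = sdl.reconstruct_from_patches(
            ps.X, ps.positions, ps.spatial, ps.n_channels, ps.image_shape
        )
        assert np.all(cov > 0)
        np.testing.assert_allclose(img, channels, atol=1e-12)

    def test_count_matches_sliding_window_enumeration(self):
        rng = np.random.default_rng(2)
        mask = rng.uniform(size=(7, 8, 6)) > 0.03
        channels = rng.uniform(size=mask.shape + (2,))
        ps = sdl.extract_patches(channels, mask, (3, 3, 3))
        count = 0
        for i in range(5):
            for j in range(6):
                for k in range(4):
                    if mask[i : i + 3, j : j + 3, k : k + 3].all():
                        count += 1
        assert ps.n_patches == count

    def test_mask_too_small_rejected(self):
        channels = np.zeros((5, 5, 5, 1))
        mask = np.zeros((5, 5, 5), bool)
        mask[0, 0, 0] = True
        with pytest.raises(ValueError, match="too small"):
            sdl.extract_patches(channels, mask, (3, 3, 3))

    def test_overlap_average_matches_accumulation_oracle(self):
        rng = np.random.default_rng(3)
        shape, spatial, k = (4, 4, 4), (3, 3, 3), 2
        positions = np.array([[0, 0, 0], [1, 1, 1], [0, 1, 0]])
        P = rng.uniform(size=(27 * k, len(positions)))
        img, cov = sdl.reconstruct_from_patches(P, positions, spatial, k, shape)
        acc = np.zeros(shape + (k,))
        cnt = np.zeros(shape)
        for col, (x, y, z) in enumerate(positions):
            block = P[:, col].reshape(3, 3, 3, k)
            acc[x : x + 3, y : y + 3, z : z + 3] += block
            cnt[x : x + 3, y : y + 3, z : z + 3] += 1
        exp = np.where(cnt[..., None] > 0, acc / np.maximum(cnt, 1)[..., None], 0)
        np.testing.assert_allclose(img, exp, atol=1e-12)
        np.testing.assert_array_equal(cov, cnt)


class TestNonnegLasso:
    def test_matches_sklearn_positive_lasso(self):
        sklearn = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(4)
        m, p, N = 30, 60, 10
        D = rng.normal(size=(m, p))
        D /= np.linalg.norm(D, axis=0)
        codes = np.abs(rng.normal(size=(p, N))) * (rng.uniform(size=(p, N)) < 0.1)
        X = D @ codes
        lam = 0.2
        ours = sdl.nonneg_lasso(D, X, lam, max_sweeps=2000, tol=1e-12)
        ref = sklearn.Lasso(
            alpha=lam / (2 * m), positive=True, fit_intercept=False,
            max_iter=50000, tol=1e-12,
        ).fit(D, X)
        np.testing.assert_allclose(ours, ref.coef_.T, atol=1e-6)

    def test_atom_self_coding_is_one_sparse(self):
        rng = np.random.default_rng(5)
        D = rng.normal(size=(40, 80))
        D /= np.linalg.norm(D, axis=0)
        alpha = sdl.nonneg_lasso(D, D[:, 7], lam=1e-4)
        assert alpha[7, 0] == pytest.approx(1.0, abs=1e-2)
        recon = D @ alpha[:, 0]
        assert np.linalg.norm(recon - D[:, 7]) < 1e-3

    def test_all_zero_input_gives_zero_codes(self):
        rng = np.random.default_rng(6)
        D = rng.normal(size=(20, 40))
        D /= np.linalg.norm(D, axis=0)
        alpha = sdl.nonneg_lasso(D, np.zeros((20, 5)), lam=0.1)
        assert np.all(alpha == 0)

    def test_codes_nonnegative(self):
        rng = np.random.default_rng(7)
        D = rng.normal(size=(20, 40))
        D /= np.linalg.norm(D, axis=0)
        alpha = sdl.nonneg_lasso(D, rng.normal(size=(20, 30)), lam=0.05)
        assert alpha.min() >= 0


class TestLearnDictionary:
    def test_generative_recovery(self):
        rng = np.random.default_rng(8)
        D0, alpha0, X = sparse_generated(rng)
        model = sdl.learn_dictionary(X, lam=0.01, n_iterations=150, batch_size=128, seed=3)
        codes = sdl.nonneg_lasso(model.D, X, 0.01)
        mse = ((X - model.D @ codes) ** 2).mean()
        assert mse <= 1e-3 * X.var()

    def test_unit_norm_columns_and_nonneg_codes(self):
        rng = np.random.default_rng(9)
        _, _, X = sparse_generated(rng, N=300)
        model = sdl.learn_dictionary(X, lam=0.05, n_iterations=30, batch_size=64, seed=1)
        np.testing.assert_allclose(np.linalg.norm(model.D, axis=0), 1.0, atol=1e-9)
        codes = sdl.nonneg_lasso(model.D, X, 0.05)
        assert codes.min() >= 0

    def test_full_batch_objective_non_increasing(self):
        rng = np.random.default_rng(10)
        _, _, X = sparse_generated(rng, m=30, p0=10, N=80)
        model = sdl.learn_dictionary(
            X, lam=0.1, n_iterations=25, batch_size=80, seed=2, track_objective=True
        )
        hist = model.objective_history
        assert len(hist) == 25
        assert np.all(np.diff(hist) <= 1e-9)

    def test_default_overcompleteness_factor_two(self):
        rng = np.random.default_rng(11)
        _, _, X = sparse_generated(rng, m=20, N=200)
        model = sdl.learn_dictionary(X, lam=0.1, n_iterations=5, batch_size=50, seed=0)
        assert model.p == 2 * model.m == 40

    def test_invalid_lambda_rejected(self):
        with pytest.raises(ValueError, match="lam"):
            sdl.learn_dictionary(np.ones((4, 10)), lam=0.0, n_iterations=1)


class TestAIC:
    def test_single_element_grid(self):
        rng = np.random.default_rng(12)
        _, _, X = sparse_generated(rng, m=20, N=100)
        lam, rows = sdl.select_lambda_aic(X, [0.1], n_iterations=10)
        assert lam == 0.1 and len(rows) == 1

    def test_aic_values_match_arithmetic_recomputation(self):
        rng = np.random.default_rng(13)
        _, _, X = sparse_generated(rng, m=20, N=100)
        m, N = X.shape
        _, rows = sdl.select_lambda_aic(X, [0.05, 0.3], n_iterations=10)
        for row in rows:
            expected = N * m * np.log(row["rss"] / (N * m)) + 2 * row["nnz"]
            assert row["aic"] == pytest.approx(expected)

    def test_winner_minimises_aic_with_sparse_tie_break(self):
        rng = np.random.default_rng(14)
        _, _, X = sparse_generated(rng, m=20, N=100)
        lam, rows = sdl.select_lambda_aic(X, [0.02, 0.1, 0.5], n_iterations=15)
        best = min(r["aic"] for r in rows)
        winners = [r["lam"] for r in rows if r["aic"] == pytest.approx(best)]
        assert lam == max(winners)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sdl.select_lambda_aic(np.ones((4, 10)), [])


def bandlimited_stack(rng, scheme, dirs30, shape=(7, 7, 7), order=2):
    """Smooth order-2 band-limited phantom stack with spatial structure."""
    nc = sh.n_coeffs(order)
    xx = np.linspace(0, 1, shape[0])
    base = 0.6 + 0.3 * np.sin(2 * np.pi * xx)[:, None, None]
    c = np.zeros(shape + (nc,))
    c[..., 0] = base * (2 * np.sqrt(np.pi))
    c[..., 3] = 0.3 * base  # anisotropic l=2 content
    sig = sh.resample_sh(sh.SHField(c, order), dirs30)
    b0 = np.full(shape, 500.0)
    data = np.concatenate([b0[..., None], sig * b0[..., None]], axis=-1)
    return make_stack(data, scheme)


class TestHarmoniseMatched:
    def test_self_reconstruction_close_to_input(self, shell_scheme, dirs30):
        rng = np.random.default_rng(15)
        stack = bandlimited_stack(rng, shell_scheme, dirs30)
        mask = np.ones((7, 7, 7), bool)
        model = sdl.train_sdl_matched(
            [stack], [mask], lam=0.005, n_iterations=150, seed=4
        )
        out = sdl.harmonise_matched(stack, mask, model, shell_scheme)
        dwi = stack.data[..., 1:]
        rms = np.sqrt(((out.data[..., 1:] - dwi) ** 2).mean()) / np.sqrt((dwi**2).mean())
        assert rms < 0.02

    def test_per_channel_offset_removed(self, shell_scheme, dirs30):
        # source differs from target by an angularly-uniform gain: the
        # statistics mapping built into the model must remove it
        rng = np.random.default_rng(16)
        target = bandlimited_stack(rng, shell_scheme, dirs30)
        source = make_stack(target.data.copy(), shell_scheme)
        source.data[..., 1:] *= 0.8
        mask = np.ones((7, 7, 7), bool)
        model = sdl.train_sdl_matched([target], [mask], lam=0.005, n_iterations=150, seed=5)
        out = sdl.harmonise_matched(source, mask, model, shell_scheme)
        raw_err = np.abs(source.data[..., 1:] - target.data[..., 1:]).mean()
        harm_err = np.abs(out.data[..., 1:] - target.data[..., 1:]).mean()
        assert harm_err < 0.25 * raw_err

    def test_patch_dimension_mismatch_rejected(self, shell_scheme, dirs30):
        rng = np.random.default_rng(17)
        stack = bandlimited_stack(rng, shell_scheme, dirs30)
        mask = np.ones((7, 7, 7), bool)
        model = sdl.train_sdl_matched([stack], [mask], lam=0.01, n_iterations=5, seed=0)
        model.n_channels = 4  # corrupt
        with pytest.raises(ValueError):
            sdl.harmonise_matched(stack, mask, model, shell_scheme)


class TestSuperres:
    def test_downsample_operator_block_average_for_integer_ratio(self):
        W = sdl.downsample_operator((6, 6, 6), (3, 3, 3), 1)
        assert W.shape == (27, 216)
        np.testing.assert_allclose(W.sum(axis=1), 1.0)
        # first low voxel averages the first 2x2x2 high block
        v = np.zeros((6, 6, 6))
        v[:2, :2, :2] = 1.0
        assert W @ v.ravel() == pytest.approx(np.eye(27)[0], abs=1e-12)

    def test_incompatible_patch_sizes_rejected(self, shell_scheme, dirs30):
        rng = np.random.default_rng(18)
        stack = bandlimited_stack(rng, shell_scheme, dirs30)
        mask = np.ones((7, 7, 7), bool)
        model = sdl.train_sdl_matched(
            [stack], [mask], lam=0.01, n_iterations=5, seed=0, spatial=(5, 5, 5)
        )
        with pytest.raises(ValueError, match="incompatible|multiple"):
            sdl.harmonise_superres(stack, mask, model, low_spatial=(3, 3, 3))

    def test_constant_image_maps_to_constant(self, shell_scheme):
        data = np.full((8, 8, 8, 31), 200.0)
        stack = make_stack(data, shell_scheme)
        mask = np.ones((8, 8, 8), bool)
        model = sdl.train_sdl_matched(
            [stack], [mask], lam=0.01, n_iterations=40, seed=1, spatial=(6, 6, 6)
        )
        out = sdl.harmonise_superres(stack, mask, model, low_spatial=(3, 3, 3))
        assert out.data.shape[:3] == (16, 16, 16)
        inner = out.data[2:-2, 2:-2, 2:-2, 1:]
        assert np.ptp(inner) / inner.mean() < 0.05

    def test_downsampled_reconstruction_consistent_with_input(self, shell_scheme, dirs30):
        rng = np.random.default_rng(19)
        high = bandlimited_stack(rng, shell_scheme, dirs30, shape=(12, 12, 12))
        mask_h = np.ones((12, 12, 12), bool)
        model = sdl.train_sdl_matched(
            [high], [mask_h], lam=0.005, n_iterations=100, seed=2, spatial=(6, 6, 6)
        )
        # a low-res source consistent with the high-res world
        low = bandlimited_stack(rng, shell_scheme, dirs30, shape=(6, 6, 6))
        low.affine[:3, :3] *= 2.0
        mask_l = np.ones((6, 6, 6), bool)
        out = sdl.harmonise_superres(low, mask_l, model, low_spatial=(3, 3, 3))
        # block-averaging the reconstruction back must stay near the input
        ch_low, _, _ = sdl.angular_channels(low, mask_l)
        ch_out, _, _ = sdl.angular_channels(out, np.ones(out.spatial_shape, bool))
        down = ch_out.reshape(6, 2, 6, 2, 6, 2, 5).mean(axis=(1, 3, 5))
        resid = np.sqrt(((down - ch_low) ** 2).mean())
        scale = np.sqrt((ch_low**2).mean())
        assert resid / scale < 0.1


class TestModelArchive:
    def test_save_load_round_trip_preserves_predictions(self, tmp_path, shell_scheme, dirs30):
        rng = np.random.default_rng(20)
        stack = bandlimited_stack(rng, shell_scheme, dirs30)
        mask = np.ones((7, 7, 7), bool)
        model = sdl.train_sdl_matched([stack], [mask], lam=0.01, n_iterations=20, seed=6)
        path = tmp_path / "model.npz"
        sdl.save_model(model, path)
        back = sdl.load_model(path)
        np.testing.assert_array_equal(back.dictionary.D, model.dictionary.D)
        assert back.spatial == model.spatial
        out_a = sdl.harmonise_matched(stack, mask, model, shell_scheme)
        out_b = sdl.harmonise_matched(stack, mask, back, shell_scheme)
        np.testing.assert_array_equal(out_a.data, out_b.data)
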