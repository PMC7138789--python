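"""Architecture grids, layer schedules, reshaping, the VAE objective,
autoencoder training contracts, and the PCA / random-projection baselines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.random_projection import johnson_lindenstrauss_min_dim

from microrep import (
    AEArchitecture,
    VAEOutputs,
    cae_filter_schedule,
    cae_geometry,
    dae_layer_schedule,
    encode,
    enumerate_ae_grid,
    pca_reduce,
    reshape_to_square,
    rp_reduce,
    square_side,
    train_autoencoder,
    vae_objective,
)
from microrep.representation import ArchitectureError, TrainedEncoder, flatten_from_square

FAST_TRAIN = dict(max_epochs=150, patience=20)


class TestArchitectureGrids:
    @pytest.mark.parametrize("kind,expected", [
        ("SAE", 5), ("DAE", 10), ("VAE", 15), ("CAE", 10),
    ])
    def test_grid_sizes(self, kind, expected):
        grid = enumerate_ae_grid(kind, 1000)
        assert len(grid) == expected
        assert len(set(grid)) == expected  # all distinct

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            enumerate_ae_grid("GAN", 100)

    def test_invalid_architectures_rejected(self):
        with pytest.raises(ArchitectureError):
            AEArchitecture("SAE", 100, latent_dim=32, n_added_layers=1)
        with pytest.raises(ArchitectureError):
            AEArchitecture("DAE", 100, latent_dim=32, n_added_layers=3)
        with pytest.raises(ArchitectureError):
            AEArchitecture("VAE", 100, latent_dim=32, intermediate_units=64)
        with pytest.raises(ArchitectureError):
            AEArchitecture("CAE", 100, n_conv_layers=4, first_filters=8)


class TestDAESchedule:
    def test_published_example(self):
        assert dae_layer_schedule(512, 2) == [2048, 1024, 512, 1024, 2048]

    def test_degenerate_and_single_insertion(self):
        assert dae_layer_schedule(32, 0) == [32]
        assert dae_layer_schedule(64, 1) == [128, 64, 128]

    @given(latent=st.integers(1, 512), added=st.integers(0, 4))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_palindromic_and_doubling(self, latent, added):
        widths = dae_layer_schedule(latent, added)
        assert len(widths) == 2 * added + 1
        assert widths == widths[::-1]
        mid = added
        assert widths[mid] == latent
        for k in range(mid):
            assert widths[k] == 2 * widths[k + 1]


class TestReshape:
    def test_square_side_examples(self):
        assert square_side(9) == 4
        assert square_side(91756) == 303  # strain-marker width of a real cohort

    def test_padding_count(self):
        grid = reshape_to_square(np.arange(1, 10))
        assert grid.shape == (4, 4)
        assert (grid.ravel()[9:] == 0).all()

    @given(n=st.integers(1, 1000))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_round_trip_and_capacity(self, n):
        rng = np.random.default_rng(n)
        x = rng.normal(size=n)
        grid = reshape_to_square(x)
        d = grid.shape[0]
        assert d == square_side(n) and d * d >= n
        np.testing.assert_array_equal(flatten_from_square(grid, n), x)


class TestCAEGeometry:
    def test_filter_schedule_halves(self):
        assert cae_filter_schedule(64, 3) == [64, 32, 16]
        assert cae_filter_schedule(4, 2) == [4, 2]

    def test_filter_schedule_reaching_zero_is_error(self):
        with pytest.raises(ArchitectureError):
            cae_filter_schedule(4, 4)

    def test_geometry_chains_percentage_rules(self):
        geometry = cae_geometry(100, 2)
        assert geometry[0] == (10, 2)          # 10% of 100, stride 25% of 10
        # layer 1 output: floor((100-10)/2)+1 = 46; layer 2: 10% of 46 -> 4, stride 2
        assert geometry[1] == (4, 2)

    def test_too_small_input_rejected(self):
        with pytest.raises(ArchitectureError):
            cae_geometry(9, 2)


class TestVAEObjective:
    def _outputs(self, mu, log_var, x=None):
        mu = np.asarray(mu, dtype=float)
        x = np.zeros(3) if x is None else x
        return VAEOutputs(mu=mu, log_var=np.asarray(log_var, dtype=float),
                          z_sample=mu, reconstruction=x)

    def test_posterior_equal_prior_has_zero_kl(self):
        _, _, kl = vae_objective(np.zeros(3), self._outputs([0, 0], [0, 0]))
        assert kl == 0.0

    def test_unit_mean_one_dimensional_kl(self):
        _, _, kl = vae_objective(np.zeros(3), self._outputs([1.0], [0.0]))
        assert kl == pytest.approx(0.5)

    def test_total_is_reconstruction_plus_kl(self):
        x = np.array([1.0, -1.0, 0.5])
        out = VAEOutputs(mu=np.array([0.3]), log_var=np.array([-0.2]),
                         z_sample=np.array([0.3]), reconstruction=np.zeros(3))
        total, recon, kl = vae_objective(x, out)
        assert recon == pytest.approx(np.sum(x**2))
        assert total == pytest.approx(recon + kl)

    def test_closed_form_matches_monte_carlo(self):
        # sampling oracle: KL(N(mu, sigma^2) || N(0, I)) from 2e5 draws
        rng = np.random.default_rng(0)
        for _ in range(10):
            mu = rng.normal(size=4)
            log_var = rng.uniform(-2, 2, size=4)
            _, _, kl = vae_objective(np.zeros(2), self._outputs(mu, log_var, np.zeros(2)))
            std = np.exp(0.5 * log_var)
            z = mu + std * rng.standard_normal((200_000, 4))
            log_q = -0.5 * (((z - mu) / std) ** 2 + log_var + np.log(2 * np.pi))
            log_p = -0.5 * (z**2 + np.log(2 * np.pi))
            mc = float(np.mean(np.sum(log_q - log_p, axis=1)))
            assert kl == pytest.approx(mc, rel=0.02)

    @given(st.lists(st.floats(-3, 3), min_size=1, max_size=6),
           st.lists(st.floats(-3, 3), min_size=1, max_size=6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_kl_non_negative(self, mu, log_var):
        k = min(len(mu), len(log_var))
        _, _, kl = vae_objective(
            np.zeros(1), self._outputs(mu[:k], log_var[:k], np.zeros(1))
        )
        assert kl >= -1e-12


class TestTraining:
    def test_linear_autoencoder_reaches_pca_subspace(self, rank_k_matrix):
        """A linear SAE with latent >= rank must reconstruct a rank-k
        matrix nearly perfectly (PCA top-k reconstruction is the oracle)."""
        x = rank_k_matrix
        arch = AEArchitecture("SAE", x.shape[1], latent_dim=8)
        enc = train_autoencoder(arch, x[:110], x[110:], seed=1, max_epochs=600)
        mse = enc.training_log.train_loss[-1]
        assert mse <= 0.05 * x[:110].var()

    def test_seeded_training_is_bit_reproducible(self, rank_k_matrix):
        x = rank_k_matrix
        arch = AEArchitecture("SAE", x.shape[1], latent_dim=4)
        e1 = train_autoencoder(arch, x[:100], x[100:], seed=9, **FAST_TRAIN)
        e2 = train_autoencoder(arch, x[:100], x[100:], seed=9, **FAST_TRAIN)
        assert e1.best_epoch == e2.best_epoch
        assert e1.training_log.val_loss == e2.training_log.val_loss
        assert np.array_equal(e1.transform(x[:7]), e2.transform(x[:7]))

    @pytest.mark.parametrize("kind,kwargs,out_dim", [
        ("DAE", dict(latent_dim=8, n_added_layers=1), 8),
        ("VAE", dict(latent_dim=4, intermediate_units=32), 4),
        ("CAE", dict(n_conv_layers=2, first_filters=4), None),
    ])
    def test_families_train_and_encode(self, small_marker, kind, kwargs, out_dim):
        profile, _ = small_marker
        x = profile.values
        arch = AEArchitecture(kind, x.shape[1], **kwargs)
        enc = train_autoencoder(arch, x[:90], x[90:], seed=2,
                                max_epochs=40, patience=10)
        z = enc.transform(x[:13])
        assert z.shape == (13, out_dim or enc.output_dim)
        assert enc.training_log.val_loss[enc.best_epoch] == min(enc.training_log.val_loss)
        # encoders are pure functions: repeated calls identical (VAE uses mu)
        assert np.array_equal(z, encode(enc, x[:13]))

    def test_mismatched_feature_space_rejected(self, rank_k_matrix):
        x = rank_k_matrix
        arch = AEArchitecture("SAE", x.shape[1], latent_dim=4)
        enc = train_autoencoder(arch, x[:100], x[100:], seed=0, max_epochs=5)
        with pytest.raises(ArchitectureError):
            enc.transform(x[:5, :10])

    def test_save_load_round_trip(self, rank_k_matrix, tmp_path):
        x = rank_k_matrix
        arch = AEArchitecture("SAE", x.shape[1], latent_dim=4)
        enc = train_autoencoder(arch, x[:100], x[100:], seed=0, **FAST_TRAIN)
        path = tmp_path / "encoder.npz"
        enc.save(path)
        back = TrainedEncoder.load(path)
        assert back.architecture == enc.architecture
        assert back.best_epoch == enc.best_epoch
        np.testing.assert_array_equal(back.transform(x[:9]), enc.transform(x[:9]))


class TestBaselines:
    def test_pca_rank_one_data_needs_one_component(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=(50, 1))
        x = u @ rng.normal(size=(1, 20))
        train_z, other_z = pca_reduce(x[:40], x[40:])
        assert train_z.shape[1] == 1

    def test_pca_component_count_definition(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(1)
        x = rng.normal(size=(80, 30)) * np.linspace(5, 0.1, 30)
        train_z, _ = pca_reduce(x, x[:5])
        k = train_z.shape[1]
        cumvar = np.cumsum(PCA(svd_solver="full").fit(x).explained_variance_ratio_)
        assert cumvar[k - 1] >= 0.99
        assert k == 1 or cumvar[k - 2] < 0.99

    def test_pca_axes_fitted_on_train_only(self):
        rng = np.random.default_rng(2)
        train = rng.normal(size=(60, 12))
        t1, _ = pca_reduce(train, rng.normal(size=(20, 12)))
        t2, _ = pca_reduce(train, 100.0 * rng.normal(size=(20, 12)))
        np.testing.assert_array_equal(t1, t2)  # held-out rows never move the axes

    def test_rp_target_dimension_follows_jl_bound(self):
        rng = np.random.default_rng(3)
        train = rng.normal(size=(100, 5000))
        t, o = rp_reduce(train, train[:10], eps=0.5, seed=0)
        expected = int(4 * np.log(100) / (0.5**2 / 2 - 0.5**3 / 3))
        assert t.shape[1] == expected
        assert expected == johnson_lindenstrauss_min_dim(100, eps=0.5)

    def test_rp_preserves_pairwise_distances(self):
        from scipy.spatial.distance import pdist

        rng = np.random.default_rng(4)
        x = rng.normal(size=(100, 10_000))
        z, _ = rp_reduce(x, x[:2], eps=0.5, seed=1)
        d2_orig = pdist(x) ** 2
        d2_proj = pdist(z) ** 2
        ratio = d2_proj / d2_orig
        ok = (ratio >= 0.5) & (ratio <= 1.5)
        assert ok.mean() >= 0.95

    def test_rp_seeded_determinism(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(60, 3000))
        z1, _ = rp_reduce(x, x[:3], seed=7)
        z2, _ = rp_reduce(x, x[:3], seed=7)
        np.testing.assert_array_equal(z1, z2)

    def test_rp_identity_pass_through_when_jl_dim_too_big(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(100, 50))  # JL dim (221) exceeds 50 features
        with pytest.warns(UserWarning, match="JL dimension"):
            z, o = rp_reduce(x, x[:4], eps=0.5, seed=0)
        np.testing.assert_array_equal(z, x)
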