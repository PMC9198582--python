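"""Model architecture contracts: shapes, determinism, latent sampling."""

import numpy as np
import pytest

from vitisvae import nn
from vitisvae.models import (FPLVAE, ConvAE, VAEConfig, AEConfig,
                             LatentDistribution, reparameterize, build_model,
                             save_checkpoint, load_checkpoint)

SMALL_VAE = VAEConfig(encoder_channels=(8, 8, 8, 8), latent_dim=12,
                      decoder_channels=(8, 8, 8, 8))
SMALL_AE = AEConfig(conv_channels=(4, 4, 4, 4), bottleneck_channels=2)


@pytest.fixture(scope="module")
def vae():
    return FPLVAE(SMALL_VAE, seed=0)


@pytest.fixture()
def batch(rng):
    return rng.uniform(0, 1, (2, 64, 64, 3)).astype(np.float32)


def test_encode_returns_one_distribution_per_sample(vae, batch):
    dist = vae.encode(batch)
    assert dist.mean.shape == (2, 12)
    assert dist.log_variance.shape == (2, 12)
    assert np.isfinite(dist.mean).all() and np.isfinite(dist.log_variance).all()


def test_encode_identical_inputs_identical_rows(vae, batch):
    dup = np.stack([batch[0], batch[0]])
    dist = vae.encode(dup)
    np.testing.assert_array_equal(dist.mean[0], dist.mean[1])
    np.testing.assert_array_equal(dist.log_variance[0], dist.log_variance[1])


def test_encode_all_zeros_is_finite(vae):
    dist = vae.encode(np.zeros((1, 64, 64, 3), dtype=np.float32))
    assert np.isfinite(dist.mean).all() and np.isfinite(dist.log_variance).all()


def test_encode_wrong_spatial_size_names_expected(vae):
    with pytest.raises(ValueError, match="64"):
        vae.encode(np.zeros((1, 32, 32, 3), dtype=np.float32))


def test_reparameterize_noise_free_returns_mean():
    dist = LatentDistribution(mean=np.array([1.0, -2.0]), log_variance=np.zeros(2))
    np.testing.assert_array_equal(reparameterize(dist, np.zeros(2)), dist.mean)


def test_reparameterize_unit_variance_unit_noise():
    dist = LatentDistribution(mean=np.array([0.5, 1.5]), log_variance=np.zeros(2))
    np.testing.assert_allclose(reparameterize(dist, np.ones(2)), dist.mean + 1.0)


def test_reparameterize_sample_mean_approaches_mu():
    rng = np.random.default_rng(0)
    mu = np.array([0.3, -1.2, 2.0])
    logvar = np.array([0.5, -0.5, 0.0])
    dist = LatentDistribution(mean=np.tile(mu, (10_000, 1)),
                              log_variance=np.tile(logvar, (10_000, 1)))
    z = reparameterize(dist, rng.standard_normal((10_000, 3)))
    se = np.exp(0.5 * logvar) / np.sqrt(10_000)
    assert np.all(np.abs(z.mean(axis=0) - mu) < 3 * se)


def test_reparameterize_length_mismatch_rejected():
    dist = LatentDistribution(mean=np.zeros(3), log_variance=np.zeros(3))
    with pytest.raises(ValueError, match="shape"):
        reparameterize(dist, np.zeros(4))


def test_decode_range_shape_and_determinism(vae, rng):
    z = rng.standard_normal((3, 12)).astype(np.float32)
    out = vae.decode(z)
    assert out.shape == (3, 64, 64, 3)
    assert out.min() >= 0.0 and out.max() <= 1.0
    np.testing.assert_array_equal(out, vae.decode(z))
    with pytest.raises(ValueError, match="latent"):
        vae.decode(np.zeros((1, 13), dtype=np.float32))


def test_forward_untrained_is_finite_and_shaped(vae, batch):
    recon, dist, eps = vae.forward(batch, eps=None)
    assert recon.shape == batch.shape
    assert np.isfinite(recon).all()
    np.testing.assert_array_equal(eps, 0.0)


def test_vae_stochastic_with_noise_frozen_without(vae, batch, rng):
    e1 = rng.standard_normal((2, 12)).astype(np.float32)
    e2 = rng.standard_normal((2, 12)).astype(np.float32)
    r1, _, _ = vae.forward(batch, eps=e1)
    r2, _, _ = vae.forward(batch, eps=e2)
    r1b, _, _ = vae.forward(batch, eps=e1)
    assert not np.array_equal(r1, r2)
    np.testing.assert_array_equal(r1, r1b)


def test_encoder_bottleneck_is_4x4_before_flatten():
    """Architecture audit: four stride-2 4x4 convs take 64 -> 4."""
    vae = FPLVAE(SMALL_VAE, seed=0)
    x = np.zeros((1, 64, 64, 3), dtype=np.float32)
    h = x
    spatial = [64]
    for layer in vae.encoder.layers:
        if isinstance(layer, nn.Flatten):
            break
        h = layer.forward(h, train=False)
        if isinstance(layer, nn.Conv2d):
            assert layer.k == 4 and layer.stride == 2
            spatial.append(h.shape[1])
    assert spatial == [64, 32, 16, 8, 4]
    assert h.shape[1:3] == (4, 4)


def test_parameter_count_is_a_pure_function_of_config():
    a = FPLVAE(SMALL_VAE, seed=0).parameter_count
    b = FPLVAE(SMALL_VAE, seed=123).parameter_count
    assert a == b
    # regression: the default config's exact parameter count
    assert FPLVAE(VAEConfig(), seed=0).parameter_count == 2_312_811


def test_baseline_ae_is_deterministic_and_shaped(batch):
    ae = ConvAE(SMALL_AE, variant="ssim_ae", seed=0)
    out = ae.forward(batch)
    assert out.shape == batch.shape
    np.testing.assert_array_equal(out, ae.forward(batch))
    assert np.isfinite(ae.forward(np.zeros_like(batch))).all()


def test_baseline_ae_keeps_spatial_resolution_throughout(batch):
    ae = ConvAE(SMALL_AE, variant="fpl_ae", seed=0)
    h = batch
    for layer in ae.net.layers:
        h = layer.forward(h, train=False)
        assert h.shape[1:3] == (64, 64)


def test_build_model_and_variant_validation():
    assert build_model("fpl_vae").kind == "fpl_vae"
    assert build_model("ssim_ae").variant == "ssim_ae"
    with pytest.raises(ValueError, match="unknown model kind"):
        build_model("pca")
    with pytest.raises(ValueError, match="variant"):
        ConvAE(SMALL_AE, variant="vae")


def test_checkpoint_round_trip_reproduces_scores(tmp_path, batch):
    vae = FPLVAE(SMALL_VAE, seed=3)
    ref = vae.reconstruct(batch)
    path = save_checkpoint(vae, tmp_path / "m.ckpt", extra={"note": "test"})
    loaded = load_checkpoint(path)
    assert loaded.kind == "fpl_vae"
    assert loaded.config == SMALL_VAE
    np.testing.assert_array_equal(loaded.reconstruct(batch), ref)


def test_missing_checkpoint_is_a_clear_error(tmp_path):
    with pytest.raises(FileNotFoundError, match="checkpoint"):
        load_checkpoint(tmp_path / "nope.ckpt")


def test_describe_lists_layers(vae):
    text = vae.describe()
    assert "Conv2d" in text and "Linear" in text
    assert "FPL-VAE" in text
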