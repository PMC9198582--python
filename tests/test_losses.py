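"""Loss functions against closed forms, sampling oracles, and skimage."""

import numpy as np
import pytest

from vitisvae.losses import (FeatureExtractorSpec, build_extractor,
                             feature_perceptual_loss, fpl_with_grad,
                             kl_divergence, total_loss, pixel_loss_map, ssim,
                             SSIMLoss, ExtractorConfigError, BCE_EPS)
from vitisvae.models import LatentDistribution


class IdentityExtractor:
    """Stub: the input itself is the single tapped feature map."""

    def features(self, x):
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        return [x]


# ---------------------------------------------------------------- FPL

def test_fpl_zero_on_identical_inputs():
    ex = build_extractor(FeatureExtractorSpec(seed=0))
    x = np.random.default_rng(0).uniform(0, 1, (2, 64, 64, 3)).astype(np.float32)
    total, per_layer = feature_perceptual_loss(x, x.copy(), ex)
    assert total == pytest.approx(0.0, abs=1e-6)
    assert all(abs(v) < 1e-6 for v in per_layer)


def test_fpl_hand_computed_on_stub_extractor():
    # one tap layer with a single 1x1x1 feature: L = 1/(2*1*1*1) * (3-1)^2 = 2
    x = np.full((1, 1, 1, 1), 3.0)
    x_hat = np.full((1, 1, 1, 1), 1.0)
    total, per_layer = feature_perceptual_loss(x, x_hat, IdentityExtractor())
    assert total == pytest.approx(2.0)
    assert per_layer == [pytest.approx(2.0)]


def test_fpl_quadruples_when_feature_gap_doubles():
    rng = np.random.default_rng(1)
    x = rng.uniform(0.4, 0.6, (1, 8, 8, 3))
    d = rng.uniform(-0.1, 0.1, x.shape)
    ex = IdentityExtractor()
    l1, _ = feature_perceptual_loss(x, x + d, ex)
    l2, _ = feature_perceptual_loss(x, x + 2 * d, ex)
    assert l2 == pytest.approx(4 * l1, rel=1e-9)


def test_fpl_shape_mismatch_and_unknown_tap_rejected():
    ex = build_extractor(FeatureExtractorSpec(seed=0))
    with pytest.raises(ValueError, match="shape mismatch"):
        feature_perceptual_loss(np.zeros((1, 64, 64, 3)), np.zeros((1, 32, 32, 3)), ex)
    with pytest.raises(ExtractorConfigError, match="unknown tap"):
        build_extractor(FeatureExtractorSpec(seed=0, layer_names=("feat9",)))


def test_fpl_bit_reproducible_across_extractor_builds():
    x = np.random.default_rng(2).uniform(0, 1, (2, 64, 64, 3)).astype(np.float32)
    y = np.random.default_rng(3).uniform(0, 1, (2, 64, 64, 3)).astype(np.float32)
    a = feature_perceptual_loss(x, y, build_extractor(FeatureExtractorSpec(seed=5)))
    b = feature_perceptual_loss(x, y, build_extractor(FeatureExtractorSpec(seed=5)))
    assert a == b
    fp1 = build_extractor(FeatureExtractorSpec(seed=5)).fingerprint
    fp2 = build_extractor(FeatureExtractorSpec(seed=6)).fingerprint
    assert fp1 != fp2


def test_fpl_gradient_matches_finite_differences():
    ex = build_extractor(FeatureExtractorSpec(seed=0))
    rng = np.random.default_rng(4)
    x = rng.uniform(0, 1, (1, 64, 64, 3)).astype(np.float64)
    y = rng.uniform(0, 1, (1, 64, 64, 3)).astype(np.float64)
    _, _, g = fpl_with_grad(x, y, ex)
    # directional derivative along the gradient: the float32 extractor makes
    # single-pixel finite differences too noisy, but the directional signal
    # eps*||g|| is orders of magnitude above the rounding floor
    g = np.asarray(g, dtype=np.float64)
    d = g / np.linalg.norm(g)
    eps = 1e-3
    num = (feature_perceptual_loss(x, y + eps * d, ex)[0]
           - feature_perceptual_loss(x, y - eps * d, ex)[0]) / (2 * eps)
    assert num == pytest.approx(np.linalg.norm(g), rel=1e-2)


def test_vgg_mode_without_weights_file_is_a_clear_error():
    with pytest.raises(ExtractorConfigError, match="weights"):
        build_extractor(FeatureExtractorSpec(mode="pretrained_vgg19"))
    with pytest.raises(ExtractorConfigError, match="unknown extractor mode"):
        build_extractor(FeatureExtractorSpec(mode="resnet"))


# ---------------------------------------------------------------- KL

def test_kl_closed_form_reference_points():
    assert kl_divergence((np.zeros(4), np.zeros(4))) == pytest.approx(0.0, abs=1e-9)
    # one dimension with mu=1, sigma=1: 0.5*(1 + 1 - 1 - 0) = 0.5
    assert kl_divergence((np.array([1.0]), np.array([0.0]))) == pytest.approx(0.5)


def test_kl_nonnegative_and_zero_only_at_prior():
    rng = np.random.default_rng(0)
    for _ in range(50):
        mu = rng.normal(0, 2, 8)
        logvar = rng.normal(0, 1, 8)
        kl = kl_divergence((mu, logvar))
        assert kl >= -1e-9
        if kl < 1e-9:
            assert np.allclose(mu, 0) and np.allclose(logvar, 0)


def test_kl_matches_monte_carlo_estimate():
    """Sampling oracle: E_q[log q(z) - log p(z)] over 1e5 draws."""
    rng = np.random.default_rng(42)
    for _ in range(5):
        d = 4
        mu = rng.normal(0, 1, d)
        logvar = rng.normal(0, 0.5, d)
        sigma = np.exp(0.5 * logvar)
        z = mu + sigma * rng.standard_normal((100_000, d))
        log_q = (-0.5 * ((z - mu) / sigma) ** 2 - 0.5 * np.log(2 * np.pi) - 0.5 * logvar).sum(axis=1)
        log_p = (-0.5 * z ** 2 - 0.5 * np.log(2 * np.pi)).sum(axis=1)
        samples = log_q - log_p
        se = samples.std(ddof=1) / np.sqrt(len(samples))
        assert kl_divergence((mu, logvar)) == pytest.approx(samples.mean(), abs=3 * se)


def test_kl_batch_input_gives_per_sample_values():
    mu = np.array([[0.0, 0.0], [1.0, 0.0]])
    logvar = np.zeros((2, 2))
    out = kl_divergence(LatentDistribution(mean=mu, log_variance=logvar))
    np.testing.assert_allclose(out, [0.0, 0.5])


def test_kl_rejects_non_finite():
    with pytest.raises(FloatingPointError):
        kl_divergence((np.array([np.nan]), np.array([0.0])))


# ---------------------------------------------------------------- total

def test_total_loss_weighting():
    assert total_loss(2.0, 3.0, alpha=1.0, lambda_=1.0) == pytest.approx(5.0)
    assert total_loss(2.0, 3.0, alpha=1.0, lambda_=0.0) == pytest.approx(3.0)
    assert total_loss(2.0, 3.0, alpha=0.5, lambda_=2.0) == pytest.approx(5.5)
    with pytest.raises(ValueError):
        total_loss(1.0, 1.0, alpha=-0.1, lambda_=1.0)


# ---------------------------------------------------------------- pixel maps

def test_pixel_maps_zero_on_identical_inputs():
    x = np.random.default_rng(0).uniform(0, 1, (8, 8, 3))
    for metric in ("l1", "mse"):
        m, score = pixel_loss_map(x, x, metric)
        assert m.shape == (8, 8)
        assert score == 0.0


def test_bce_at_half_is_ln2():
    x = np.full((4, 4, 3), 0.5)
    m, score = pixel_loss_map(x, x, "bce")
    np.testing.assert_allclose(m, np.log(2), atol=1e-9)
    assert score == pytest.approx(np.log(2))


def test_mse_single_pixel_arithmetic():
    x = np.ones((4, 4))
    y = np.ones((4, 4))
    y[2, 3] = 0.75
    m, _ = pixel_loss_map(x, y, "mse")
    assert m[2, 3] == pytest.approx(0.0625)
    assert m.sum() == pytest.approx(0.0625)


def test_bce_finite_at_saturated_values():
    x = np.zeros((3, 3))
    y = np.ones((3, 3))
    m, score = pixel_loss_map(x, y, "bce")
    assert np.isfinite(m).all()
    assert score == pytest.approx(-np.log(BCE_EPS), rel=1e-3)


def test_unknown_metric_rejected():
    with pytest.raises(ValueError, match="unknown metric"):
        pixel_loss_map(np.zeros((2, 2)), np.zeros((2, 2)), "psnr")


# ---------------------------------------------------------------- SSIM

def test_ssim_identity_and_symmetry():
    x = np.random.default_rng(1).uniform(0, 1, (32, 32, 3))
    y = np.clip(x + 0.05 * np.random.default_rng(2).standard_normal(x.shape), 0, 1)
    assert ssim(x, x) == pytest.approx(1.0, abs=1e-9)
    assert ssim(x, y) == pytest.approx(ssim(y, x), abs=1e-12)


def test_ssim_decreases_with_constant_gap():
    base = np.full((32, 32), 0.4)
    vals = [ssim(base, np.full((32, 32), 0.4 + gap)) for gap in (0.1, 0.2, 0.3)]
    assert all(v < 1.0 for v in vals)
    assert vals[0] > vals[1] > vals[2]


def test_ssim_window_larger_than_image_rejected():
    with pytest.raises(ValueError, match="window"):
        ssim(np.zeros((8, 8)), np.zeros((8, 8)), window=11)


def test_differentiable_ssim_agrees_with_skimage():
    rng = np.random.default_rng(3)
    x = rng.uniform(0, 1, (40, 40, 3))
    y = np.clip(x + 0.1 * rng.standard_normal(x.shape), 0, 1)
    loss = SSIMLoss()
    val, _ = loss.loss_and_grad(x[None], y[None])
    assert 1.0 - val == pytest.approx(ssim(x, y, window=11), abs=1e-10)


def test_differentiable_ssim_gradient_matches_finite_differences():
    rng = np.random.default_rng(6)
    x = rng.uniform(0.2, 0.8, (1, 24, 24, 1))
    y = rng.uniform(0.2, 0.8, (1, 24, 24, 1))
    loss = SSIMLoss()
    _, g = loss.loss_and_grad(x, y)
    eps = 1e-6
    for idx in [(0, 12, 12, 0), (0, 3, 20, 0)]:
        yp, ym = y.copy(), y.copy()
        yp[idx] += eps
        ym[idx] -= eps
        num = (loss.loss_and_grad(x, yp)[0] - loss.loss_and_grad(x, ym)[0]) / (2 * eps)
        assert g[idx] == pytest.approx(num, rel=1e-4, abs=1e-9)
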