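"""Loss functions: feature perceptual loss, KL divergence, pixel loss maps, SSIM.

The feature perceptual loss (FPL) compares input and reconstruction in the
hidden-layer feature space of a *frozen* convolutional extractor rather
than pixel space.  At tap layer ``l`` with feature maps of shape
``(C_l, H_l, W_l)``::

    L_rec^l = 1 / (2 C_l W_l H_l) * sum_{c,h,w} (f_l(x) - f_l(x_hat))^2

and the total reconstruction loss is the sum over tapped layers.  Two
extractor modes are provided: a VGG19-topology network loading pretrained
weights from a local ``.npz`` file, and a deterministic seeded random CNN
that needs no external weights and makes every result bit-reproducible.

KL divergence uses the closed form for a diagonal Gaussian against the
standard normal prior.  Pixel-wise l1 / MSE / BCE maps drive anomaly
scoring and heatmaps; SSIM (Gaussian-windowed, with a hand-derived
gradient for training) drives the SSIM-AE baseline.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi

from . import nn

__all__ = [
    "FeatureExtractorSpec",
    "FeatureExtractor",
    "LossBreakdown",
    "build_extractor",
    "feature_perceptual_loss",
    "kl_divergence",
    "total_loss",
    "pixel_loss_map",
    "ssim",
    "SSIMLoss",
    "BCE_EPS",
]

BCE_EPS = 1e-7

PIXEL_METRICS = ("l1", "mse", "bce")

_RANDOM_TAPS = ("feat1", "feat2", "feat3")
# VGG19 feature-section layout: (name, out_channels) per conv, 'M' = maxpool
_VGG19_LAYOUT = [
    ("conv1_1", 64), ("conv1_2", 64), "M",
    ("conv2_1", 128), ("conv2_2", 128), "M",
    ("conv3_1", 256), ("conv3_2", 256), ("conv3_3", 256), ("conv3_4", 256), "M",
    ("conv4_1", 512), ("conv4_2", 512), ("conv4_3", 512), ("conv4_4", 512), "M",
    ("conv5_1", 512), ("conv5_2", 512), ("conv5_3", 512), ("conv5_4", 512), "M",
]
_VGG_TAPS_DEFAULT = ("relu1_1", "relu2_1", "relu3_1")


class ExtractorConfigError(ValueError):
    """Raised for unknown modes, tap names, or missing weight files."""


@dataclass(frozen=True)
class FeatureExtractorSpec:
    """Configuration of the frozen feature extractor used by the FPL."""

    mode: str = "deterministic_random"          # or "pretrained_vgg19"
    layer_names: tuple[str, ...] = _RANDOM_TAPS
    weights_fingerprint: str = ""               # expected sha256, vgg mode
    seed: int = 0                               # random mode
    weights_path: str = ""                      # .npz with conv weights, vgg mode


@dataclass
class LossBreakdown:
    """Loss terms of one forward pass; total = alpha*kl + lambda_*rec."""

    reconstruction: float
    kl: float
    alpha: float
    lambda_: float
    per_layer: list[float] = field(default_factory=list)

    @property
    def total(self) -> float:
        return self.alpha * self.kl + self.lambda_ * self.reconstruction


class FeatureExtractor:
    """A frozen CNN with named tap points for the feature perceptual loss.

    ``features(x)`` returns the tapped activations for an (n, 64, 64, 3)
    batch in [0, 1]; ``backward_taps(tap_grads)`` backpropagates a
    gradient per tap down to the input (needed to train through the FPL).
    The extractor's own parameters are never updated.
    """

    def __init__(self, layers: list[nn.Layer], tap_points: dict[str, int],
                 layer_names: tuple[str, ...], mode: str,
                 normalize_mean: np.ndarray, normalize_std: np.ndarray,
                 fingerprint: str) -> None:
        unknown = [name for name in layer_names if name not in tap_points]
        if unknown:
            raise ExtractorConfigError(
                f"unknown tap layer(s) {unknown}; available: {sorted(tap_points)}")
        self.layers = layers
        self.tap_points = tap_points
        self.layer_names = tuple(layer_names)
        self.mode = mode
        self._mean = normalize_mean.reshape(1, 1, 1, 3)
        self._std = normalize_std.reshape(1, 1, 1, 3)
        self.fingerprint = fingerprint
        self._tap_index = {tap_points[n]: n for n in layer_names}
        self._depth = max(tap_points[n] for n in layer_names) + 1

    def _prepare(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        return (x - self._mean) / self._std

    def features(self, x: np.ndarray) -> list[np.ndarray]:
        """Tapped activations (NHWC), in the order of ``layer_names``."""
        h = self._prepare(x)
        taps: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers[:self._depth]):
            h = layer.forward(h, train=False)
            if i in self._tap_index:
                taps[self._tap_index[i]] = h
        return [taps[name] for name in self.layer_names]

    def backward_taps(self, tap_grads: list[np.ndarray]) -> np.ndarray:
        """Backpropagate per-tap gradients to the (normalized) input.

        Must follow a ``features`` call (layer caches are consumed).
        Returns the gradient w.r.t. the raw [0,1] NCHW input.
        """
        grads = {self.tap_points[n]: g for n, g in zip(self.layer_names, tap_grads)}
        g = None  # the deepest layer (depth-1) is always a tap
        for i in range(self._depth - 1, -1, -1):
            if i in grads:
                g = grads[i] if g is None else g + grads[i]
            g = self.layers[i].backward(g)
        return g / self._std


def _fingerprint_weights(arrays: dict[str, np.ndarray]) -> str:
    sha = hashlib.sha256()
    for key in sorted(arrays):
        sha.update(key.encode())
        sha.update(np.ascontiguousarray(arrays[key]).tobytes())
    return sha.hexdigest()


# random-extractor stages as (in_channels, out_channels, stride)
_RANDOM_CHANNELS = ((3, 16, 1), (16, 32, 2), (32, 64, 2))


def _build_random_extractor(spec: FeatureExtractorSpec) -> FeatureExtractor:
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0xFEA7]))
    layers: list[nn.Layer] = []
    tap_points: dict[str, int] = {}
    channels = _RANDOM_CHANNELS
    for i, (cin, cout, stride) in enumerate(channels):
        layers.append(nn.Conv2d(cin, cout, 3, stride=stride, padding=1, rng=rng))
        layers.append(nn.LeakyReLU(0.2))
        tap_points[f"feat{i + 1}"] = len(layers) - 1
    fp = _fingerprint_weights({f"w{i}": p.value for i, p in
                               enumerate(q for l in layers for q in l.params())})
    return FeatureExtractor(layers, tap_points, spec.layer_names, spec.mode,
                            normalize_mean=np.float32([0.5, 0.5, 0.5]),
                            normalize_std=np.float32([0.5, 0.5, 0.5]),
                            fingerprint=fp)


def _build_vgg19_extractor(spec: FeatureExtractorSpec) -> FeatureExtractor:
    path = Path(spec.weights_path) if spec.weights_path else None
    if path is None or not path.exists():
        raise ExtractorConfigError(
            "pretrained_vgg19 mode needs a local weights file: set "
            "FeatureExtractorSpec.weights_path to an .npz containing "
            "'convN_M.weight'/'convN_M.bias' arrays (torchvision layout, "
            "OIHW kernels). No weights ship with this package.")
    arrays = dict(np.load(path))
    fp = _fingerprint_weights(arrays)
    if spec.weights_fingerprint and fp != spec.weights_fingerprint:
        raise ExtractorConfigError(
            f"VGG19 weights fingerprint mismatch: expected "
            f"{spec.weights_fingerprint}, found {fp}")
    layers: list[nn.Layer] = []
    tap_points: dict[str, int] = {}
    cin = 3
    for item in _VGG19_LAYOUT:
        if item == "M":
            layers.append(nn.MaxPool2d())
            continue
        name, cout = item
        conv = nn.Conv2d(cin, cout, 3, stride=1, padding=1)
        w = np.asarray(arrays[f"{name}.weight"], dtype=np.float32)
        conv.weight.value = np.ascontiguousarray(w.transpose(2, 3, 1, 0))  # OIHW -> HWIO
        conv.bias.value = np.asarray(arrays[f"{name}.bias"], dtype=np.float32)
        layers.append(conv)
        layers.append(nn.LeakyReLU(0.0))     # plain ReLU
        tap_points[name.replace("conv", "relu")] = len(layers) - 1
        cin = cout
    return FeatureExtractor(layers, tap_points, spec.layer_names, spec.mode,
                            normalize_mean=np.float32([0.485, 0.456, 0.406]),
                            normalize_std=np.float32([0.229, 0.224, 0.225]),
                            fingerprint=fp)


def build_extractor(spec: FeatureExtractorSpec) -> FeatureExtractor:
    if not spec.layer_names:
        raise ExtractorConfigError("layer_names must be non-empty")
    if spec.mode == "deterministic_random":
        return _build_random_extractor(spec)
    if spec.mode == "pretrained_vgg19":
        if spec.layer_names == _RANDOM_TAPS:
            spec = FeatureExtractorSpec(mode=spec.mode, layer_names=_VGG_TAPS_DEFAULT,
                                        weights_fingerprint=spec.weights_fingerprint,
                                        seed=spec.seed, weights_path=spec.weights_path)
        return _build_vgg19_extractor(spec)
    raise ExtractorConfigError(f"unknown extractor mode {spec.mode!r}")


def feature_perceptual_loss(x: np.ndarray, x_hat: np.ndarray,
                            extractor) -> tuple[float, list[float]]:
    """FPL between a batch and its reconstruction (batch-mean).

    Returns ``(total, per_layer)`` where each per-layer term is
    ``1/(2 C W H) * sum((f(x) - f(x_hat))^2)`` averaged over the batch and
    ``total`` is their sum.  ``extractor`` is anything exposing
    ``features(batch) -> list of (n, C, H, W) arrays``.
    """
    x = np.asarray(x)
    x_hat = np.asarray(x_hat)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    fx = extractor.features(x)
    fxh = extractor.features(x_hat)
    per_layer = []
    for a, b in zip(fx, fxh):
        n, h, w, c = a.shape
        diff = a.astype(np.float64) - b.astype(np.float64)
        per_layer.append(float((diff ** 2).sum() / (2.0 * c * w * h) / n))
    return float(sum(per_layer)), per_layer


def fpl_with_grad(x: np.ndarray, x_hat: np.ndarray,
                  extractor: FeatureExtractor) -> tuple[float, list[float], np.ndarray]:
    """FPL plus its gradient w.r.t. ``x_hat`` (NHWC), for training.

    The extractor stays frozen: only the gradient to its *input* is used.
    """
    fx = [f.copy() for f in extractor.features(x)]
    fxh = extractor.features(x_hat)      # caches now belong to x_hat's pass
    n = x_hat.shape[0]
    per_layer, tap_grads = [], []
    for a, b in zip(fx, fxh):
        _, h, w, c = a.shape
        diff = b - a
        norm = 2.0 * c * w * h
        per_layer.append(float((diff.astype(np.float64) ** 2).sum() / norm / n))
        tap_grads.append((diff / (0.5 * norm) / n).astype(b.dtype))
    grad_input = extractor.backward_taps(tap_grads)
    return float(sum(per_layer)), per_layer, grad_input


def _dist_arrays(dist) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(dist, "mean") and hasattr(dist, "log_variance"):
        mu, logvar = dist.mean, dist.log_variance
    else:
        mu, logvar = dist
    mu = np.asarray(mu, dtype=np.float64)
    logvar = np.asarray(logvar, dtype=np.float64)
    if mu.shape != logvar.shape:
        raise ValueError(f"mean {mu.shape} and log_variance {logvar.shape} differ")
    if not (np.isfinite(mu).all() and np.isfinite(logvar).all()):
        raise FloatingPointError("non-finite latent distribution parameters")
    return mu, logvar


def kl_divergence(dist):
    """KL( N(mu, diag(sigma^2)) || N(0, I) ) in closed form.

    ``1/2 * sum_i (mu_i^2 + sigma_i^2 - 1 - log sigma_i^2)``; accepts a
    LatentDistribution or a ``(mean, log_variance)`` pair.  For 2-D inputs
    (batch) an array of per-sample divergences is returned.
    """
    mu, logvar = _dist_arrays(dist)
    var = np.exp(logvar)
    kl = 0.5 * (mu ** 2 + var - 1.0 - logvar)
    if kl.ndim <= 1:
        return float(kl.sum())
    return kl.sum(axis=tuple(range(1, kl.ndim)))


def kl_grads(mu: np.ndarray, logvar: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of the *batch-mean* KL w.r.t. mu and log-variance."""
    n = mu.shape[0]
    return mu / n, (0.5 * (np.exp(logvar) - 1.0)) / n


def total_loss(rec: float, kl: float, alpha: float, lambda_: float) -> float:
    """Weighted objective ``alpha * kl + lambda_ * rec``."""
    if alpha < 0 or lambda_ < 0:
        raise ValueError(f"loss weights must be >= 0, got alpha={alpha}, lambda_={lambda_}")
    return alpha * kl + lambda_ * rec


def pixel_loss_map(x: np.ndarray, x_hat: np.ndarray,
                   metric: str = "mse") -> tuple[np.ndarray, float]:
    """Per-pixel loss map (channel-averaged) and its spatial mean.

    Inputs are (H, W, C) or (H, W) arrays in [0, 1].  For ``bce`` both
    arguments are clamped to ``[BCE_EPS, 1 - BCE_EPS]``.
    """
    if metric not in PIXEL_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {PIXEL_METRICS}")
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    if metric == "l1":
        m = np.abs(x - x_hat)
    elif metric == "mse":
        m = (x - x_hat) ** 2
    else:
        xc = np.clip(x, BCE_EPS, 1.0 - BCE_EPS)
        xh = np.clip(x_hat, BCE_EPS, 1.0 - BCE_EPS)
        m = -(xc * np.log(xh) + (1.0 - xc) * np.log(1.0 - xh))
    if m.ndim == 3:
        m = m.mean(axis=-1)
    return m, float(m.mean())


def ssim(x: np.ndarray, x_hat: np.ndarray, window: int = 11,
         data_range: float = 1.0) -> float:
    """Structural similarity with a Gaussian window (sigma = 1.5).

    Channel-averaged for colour inputs; symmetric in its arguments.
    """
    x = np.asarray(x, dtype=np.float64)
    x_hat = np.asarray(x_hat, dtype=np.float64)
    if x.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_hat.shape}")
    if window > min(x.shape[0], x.shape[1]):
        raise ValueError(f"window {window} larger than image {x.shape[:2]}")
    from skimage.metrics import structural_similarity
    kwargs = dict(win_size=window, gaussian_weights=True, sigma=1.5,
                  use_sample_covariance=False, data_range=data_range)
    if x.ndim == 3:
        return float(structural_similarity(x, x_hat, channel_axis=-1, **kwargs))
    return float(structural_similarity(x, x_hat, **kwargs))


class SSIMLoss:
    """Differentiable ``1 - SSIM`` for training the SSIM-AE baseline.

    Works on NHWC batches; local statistics use a Gaussian window
    (sigma 1.5, zero-padded borders); the structural-similarity map is
    cropped by the window radius before averaging so the boundary handling
    never enters the loss, and the gradient (hand-derived via the chain
    rule through the window convolutions) is exact.
    """

    def __init__(self, sigma: float = 1.5, truncate: float = 3.5,
                 data_range: float = 1.0) -> None:
        self.sigma = sigma
        self.truncate = truncate
        self.pad = int(truncate * sigma + 0.5)
        self.c1 = (0.01 * data_range) ** 2
        self.c2 = (0.03 * data_range) ** 2

    def _blur(self, a: np.ndarray) -> np.ndarray:
        return ndi.gaussian_filter(a, sigma=(0, self.sigma, self.sigma, 0),
                                   truncate=self.truncate, mode="constant")

    def loss_and_grad(self, x: np.ndarray, x_hat: np.ndarray) -> tuple[float, np.ndarray]:
        """Return ``1 - mean SSIM`` and its gradient w.r.t. ``x_hat``."""
        x = x.astype(np.float64)
        y = x_hat.astype(np.float64)
        p = self.pad
        mx, my = self._blur(x), self._blur(y)
        mxx, myy, mxy = self._blur(x * x), self._blur(y * y), self._blur(x * y)
        vx = mxx - mx * mx
        vy = myy - my * my
        cxy = mxy - mx * my
        a1 = 2 * mx * my + self.c1
        a2 = 2 * cxy + self.c2
        b1 = mx * mx + my * my + self.c1
        b2 = vx + vy + self.c2
        s = (a1 * a2) / (b1 * b2)
        core = s[:, p:-p, p:-p, :]
        n_eff = core.size
        value = 1.0 - float(core.mean())
        # gradient of mean(S) over the cropped region w.r.t. y
        w = np.zeros_like(s)
        w[:, p:-p, p:-p, :] = 1.0 / n_eff
        ds_da1 = w * a2 / (b1 * b2)
        ds_da2 = w * a1 / (b1 * b2)
        ds_db1 = -w * s / b1
        ds_db2 = -w * s / b2
        g_my = ds_da1 * 2 * mx + ds_db1 * 2 * my
        g_vy = ds_db2
        g_cxy = ds_da2 * 2
        # back through vy = myy - my^2 and cxy = mxy - mx*my
        g_my = g_my - 2 * my * g_vy - mx * g_cxy
        g_myy = g_vy
        g_mxy = g_cxy
        # blur with zero boundary is self-adjoint
        grad_y = self._blur(g_my) + 2 * y * self._blur(g_myy) + x * self._blur(g_mxy)
        return value, -grad_y.astype(x_hat.dtype)
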