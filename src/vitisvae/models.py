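"""Autoencoder architectures: the FPL-VAE and the convolutional AE baseline.

FPL-VAE encoder: four 4x4 stride-2 convolutions (each followed by batch
normalization and LeakyReLU), taking a 64x64x3 patch down to a 4x4x256
map, then two fully connected heads for the latent mean and log-variance.
Decoder: a fully connected expansion back to 4x4x256 followed by four
stages of nearest-neighbour 2x upsampling + 3x3 stride-1 convolution with
replication padding (batch norm + LeakyReLU between stages) and a final
sigmoid so reconstructions live in [0, 1].

The baseline AE keeps the input resolution throughout (3x3 kernels,
padding 1, stride 1) and compresses by channel narrowing through a
bottleneck convolution; it is trained with either an SSIM loss (SSIM-AE)
or the feature perceptual loss (FPL-AE).
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn

__all__ = [
    "VAEConfig",
    "AEConfig",
    "LatentDistribution",
    "FPLVAE",
    "ConvAE",
    "reparameterize",
    "build_model",
    "save_checkpoint",
    "load_checkpoint",
    "validate_batch",
]

MODEL_KINDS = ("fpl_vae", "ssim_ae", "fpl_ae")


@dataclass(frozen=True)
class VAEConfig:
    input_size: int = 64
    input_channels: int = 3
    encoder_channels: tuple[int, int, int, int] = (32, 64, 128, 256)
    latent_dim: int = 100
    leaky_slope: float = 0.2
    decoder_channels: tuple[int, int, int, int] = (256, 128, 64, 32)

    def validate(self) -> None:
        if self.input_size != 64:
            # four stride-2 convs: 64 -> 32 -> 16 -> 8 -> 4
            raise ValueError(f"input_size must be 64 (four stride-2 stages), got {self.input_size}")
        if self.latent_dim < 1:
            raise ValueError(f"latent_dim must be >= 1, got {self.latent_dim}")
        if len(self.encoder_channels) != 4 or len(self.decoder_channels) != 4:
            raise ValueError("encoder_channels and decoder_channels must list 4 stages")

    @property
    def bottleneck_spatial(self) -> int:
        return self.input_size // 16


@dataclass(frozen=True)
class AEConfig:
    conv_channels: tuple[int, int, int, int] = (16, 16, 16, 16)
    kernel: int = 3
    padding: int = 1
    stride: int = 1
    bottleneck_channels: int = 8
    input_size: int = 64
    input_channels: int = 3
    leaky_slope: float = 0.2

    def validate(self) -> None:
        if len(self.conv_channels) != 4:
            raise ValueError("conv_channels must list 4 stages")
        if self.kernel != 3 or self.padding != 1 or self.stride != 1:
            raise ValueError("baseline AE uses 3x3 kernels, padding 1, stride 1")
        if self.bottleneck_channels < 1:
            raise ValueError("bottleneck_channels must be >= 1")


@dataclass
class LatentDistribution:
    """Per-sample diagonal Gaussian q(z|X): mean mu and log-variance."""

    mean: np.ndarray
    log_variance: np.ndarray

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean)
        self.log_variance = np.asarray(self.log_variance)
        if self.mean.shape != self.log_variance.shape:
            raise ValueError(
                f"mean {self.mean.shape} and log_variance {self.log_variance.shape} differ")
        if not np.isfinite(self.log_variance).all():
            raise FloatingPointError("log_variance contains non-finite values")


def reparameterize(dist: LatentDistribution, eps: np.ndarray) -> np.ndarray:
    """Sampling via ``z = mu + exp(log_var / 2) * eps`` with ``eps ~ N(0,1)``."""
    eps = np.asarray(eps)
    if eps.shape != dist.mean.shape:
        raise ValueError(f"noise shape {eps.shape} != latent shape {dist.mean.shape}")
    return dist.mean + np.exp(0.5 * dist.log_variance) * eps


def validate_batch(batch: np.ndarray, size: int, channels: int) -> np.ndarray:
    """Validate an (n, H, W, C) [0,1] batch and return it as float32."""
    batch = np.asarray(batch, dtype=np.float32)
    if batch.ndim == 3:
        batch = batch[None]
    if batch.ndim != 4 or batch.shape[1] != size or batch.shape[2] != size \
            or batch.shape[3] != channels:
        raise ValueError(
            f"expected batch shaped (n, {size}, {size}, {channels}), got {batch.shape}")
    return np.ascontiguousarray(batch)


class FPLVAE:
    """The variational autoencoder with feature-perceptual reconstruction loss."""

    kind = "fpl_vae"

    def __init__(self, config: VAEConfig = VAEConfig(), seed: int = 0) -> None:
        config.validate()
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0xAE]))
        c = config
        ec = c.encoder_channels
        s = c.leaky_slope
        enc: list[nn.Layer] = []
        cin = c.input_channels
        for cout in ec:
            enc += [nn.Conv2d(cin, cout, 4, stride=2, padding=1, rng=rng),
                    nn.BatchNorm2d(cout), nn.LeakyReLU(s)]
            cin = cout
        enc.append(nn.Flatten())
        self.encoder = nn.Sequential(*enc)
        feat = ec[-1] * c.bottleneck_spatial ** 2
        self.fc_mu = nn.Linear(feat, c.latent_dim, rng=rng)
        self.fc_logvar = nn.Linear(feat, c.latent_dim, rng=rng)
        dc = c.decoder_channels
        dec: list[nn.Layer] = [
            nn.Linear(c.latent_dim, dc[0] * c.bottleneck_spatial ** 2, rng=rng),
            nn.LeakyReLU(s),
            nn.Reshape((c.bottleneck_spatial, c.bottleneck_spatial, dc[0])),
        ]
        cin = dc[0]
        for cout in dc[1:]:
            dec += [nn.UpsampleNearest2x(),
                    nn.Conv2d(cin, cout, 3, stride=1, padding=1, pad_mode="replicate", rng=rng),
                    nn.BatchNorm2d(cout), nn.LeakyReLU(s)]
            cin = cout
        dec += [nn.UpsampleNearest2x(),
                nn.Conv2d(cin, c.input_channels, 3, stride=1, padding=1,
                          pad_mode="replicate", rng=rng),
                nn.Sigmoid()]
        self.decoder = nn.Sequential(*dec)
        self._modules = {"encoder": self.encoder, "fc_mu": self.fc_mu,
                         "fc_logvar": self.fc_logvar, "decoder": self.decoder}

    # -- public ops ---------------------------------------------------------
    def encode(self, batch: np.ndarray, train: bool = False) -> LatentDistribution:
        """Map an (n, 64, 64, 3) batch to per-sample (mu, log sigma^2)."""
        x = validate_batch(batch, self.config.input_size, self.config.input_channels)
        h = self.encoder.forward(x, train=train)
        mu = self.fc_mu.forward(h, train=train)
        logvar = self.fc_logvar.forward(h, train=train)
        return LatentDistribution(mean=mu, log_variance=logvar)

    def decode(self, z: np.ndarray, train: bool = False) -> np.ndarray:
        """Map latent vectors (n, latent_dim) to (n, 64, 64, 3) patches in [0,1]."""
        z = np.asarray(z, dtype=np.float32)
        if z.ndim == 1:
            z = z[None]
        if z.shape[1] != self.config.latent_dim:
            raise ValueError(
                f"latent vector length {z.shape[1]} != latent_dim {self.config.latent_dim}")
        return self.decoder.forward(z, train=train)

    def forward(self, batch: np.ndarray, eps: np.ndarray | None = None,
                train: bool = False) -> tuple[np.ndarray, LatentDistribution, np.ndarray]:
        """Full pass; ``eps=None`` means the deterministic ``eps = 0`` pass.

        Returns (reconstruction NHWC, latent distribution, eps used).
        """
        dist = self.encode(batch, train=train)
        if eps is None:
            eps = np.zeros_like(dist.mean)
        z = reparameterize(dist, eps)
        recon = self.decode(z, train=train)
        return recon, dist, eps

    def reconstruct(self, batch: np.ndarray) -> np.ndarray:
        """Deterministic eval-mode reconstruction (eps = 0) used for scoring."""
        recon, _, _ = self.forward(batch, eps=None, train=False)
        return recon

    def backward(self, grad_recon_nhwc: np.ndarray, dist: LatentDistribution,
                 eps: np.ndarray, grad_mu_extra: np.ndarray | None = None,
                 grad_logvar_extra: np.ndarray | None = None) -> None:
        """Accumulate parameter gradients for the last ``train=True`` forward.

        ``grad_recon_nhwc`` is dL/d(reconstruction); the extra latent grads
        carry the KL term's contribution.
        """
        g = np.asarray(grad_recon_nhwc, dtype=np.float32)
        gz = self.decoder.backward(g)
        gmu = gz.copy()
        glogvar = gz * eps * (0.5 * np.exp(0.5 * dist.log_variance))
        if grad_mu_extra is not None:
            gmu += grad_mu_extra.astype(gmu.dtype)
        if grad_logvar_extra is not None:
            glogvar += grad_logvar_extra.astype(glogvar.dtype)
        gh = self.fc_mu.backward(gmu) + self.fc_logvar.backward(glogvar)
        self.encoder.backward(gh)

    def params(self) -> list[nn.Param]:
        out = []
        for m in self._modules.values():
            out.extend(m.params())
        return out

    @property
    def parameter_count(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def describe(self) -> str:
        lines = [f"FPL-VAE (latent_dim={self.config.latent_dim}, "
                 f"params={self.parameter_count})"]
        for name, mod in self._modules.items():
            layers = mod.layers if isinstance(mod, nn.Sequential) else [mod]
            for layer in layers:
                lines.append(f"  {name}: {_layer_repr(layer)}")
        return "\n".join(lines)

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for name, mod in self._modules.items():
            for k, v in nn.state_dict(mod).items():
                state[f"{name}.{k}"] = v
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, mod in self._modules.items():
            sub = {k[len(name) + 1:]: v for k, v in state.items()
                   if k.startswith(name + ".")}
            nn.load_state_dict(mod, sub)


class ConvAE:
    """Baseline autoencoder: stride-1 3x3 stack with a channel bottleneck.

    ``variant`` selects the training loss only ('ssim_ae' or 'fpl_ae');
    the architecture is shared.
    """

    def __init__(self, config: AEConfig = AEConfig(), variant: str = "ssim_ae",
                 seed: int = 0) -> None:
        config.validate()
        if variant not in ("ssim_ae", "fpl_ae"):
            raise ValueError(f"variant must be 'ssim_ae' or 'fpl_ae', got {variant!r}")
        self.config = config
        self.variant = variant
        self.kind = variant
        self.seed = int(seed)
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0xCAE]))
        c = config
        s = c.leaky_slope
        layers: list[nn.Layer] = []
        cin = c.input_channels
        for cout in c.conv_channels:
            layers += [nn.Conv2d(cin, cout, 3, stride=1, padding=1, rng=rng),
                       nn.BatchNorm2d(cout), nn.LeakyReLU(s)]
            cin = cout
        layers += [nn.Conv2d(cin, c.bottleneck_channels, 3, stride=1, padding=1, rng=rng),
                   nn.BatchNorm2d(c.bottleneck_channels), nn.LeakyReLU(s)]
        cin = c.bottleneck_channels
        for cout in reversed(c.conv_channels[1:]):
            layers += [nn.Conv2d(cin, cout, 3, stride=1, padding=1, rng=rng),
                       nn.BatchNorm2d(cout), nn.LeakyReLU(s)]
            cin = cout
        layers += [nn.Conv2d(cin, c.input_channels, 3, stride=1, padding=1, rng=rng),
                   nn.Sigmoid()]
        self.net = nn.Sequential(*layers)

    def forward(self, batch: np.ndarray, train: bool = False) -> np.ndarray:
        x = validate_batch(batch, self.config.input_size, self.config.input_channels)
        return self.net.forward(x, train=train)

    def reconstruct(self, batch: np.ndarray) -> np.ndarray:
        return self.forward(batch, train=False)

    def backward(self, grad_recon_nhwc: np.ndarray) -> None:
        self.net.backward(np.asarray(grad_recon_nhwc, dtype=np.float32))

    def params(self) -> list[nn.Param]:
        return self.net.params()

    @property
    def parameter_count(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def describe(self) -> str:
        lines = [f"{self.variant.upper().replace('_', '-')} baseline AE "
                 f"(bottleneck={self.config.bottleneck_channels} ch, "
                 f"params={self.parameter_count})"]
        lines += [f"  net: {_layer_repr(l)}" for l in self.net.layers]
        return "\n".join(lines)

    def state_dict(self) -> dict[str, np.ndarray]:
        return nn.state_dict(self.net)

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        nn.load_state_dict(self.net, state)


def _layer_repr(layer: nn.Layer) -> str:
    if isinstance(layer, nn.Conv2d):
        return (f"Conv2d({layer.cin}->{layer.cout}, k={layer.k}, s={layer.stride}, "
                f"p={layer.pad}, {layer.pad_mode})")
    if isinstance(layer, nn.Linear):
        o, i = layer.weight.value.shape
        return f"Linear({i}->{o})"
    if isinstance(layer, nn.BatchNorm2d):
        return f"BatchNorm2d({layer.gamma.value.size})"
    if isinstance(layer, nn.LeakyReLU):
        return f"LeakyReLU({layer.slope})"
    return type(layer).__name__


def build_model(kind: str, seed: int = 0, vae_config: VAEConfig | None = None,
                ae_config: AEConfig | None = None):
    if kind == "fpl_vae":
        return FPLVAE(vae_config or VAEConfig(), seed=seed)
    if kind in ("ssim_ae", "fpl_ae"):
        return ConvAE(ae_config or AEConfig(), variant=kind, seed=seed)
    raise ValueError(f"unknown model kind {kind!r}; choose from {MODEL_KINDS}")


def save_checkpoint(model, path: str | Path, extra: dict | None = None) -> Path:
    """Serialize config + weights + seed into a single .npz-based file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "kind": model.kind,
        "seed": model.seed,
        "config": asdict(model.config),
        "extra": extra or {},
    }
    state = model.state_dict()
    buf = io.BytesIO()
    np.savez(buf, **state)
    with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
        # fixed timestamps keep checkpoints bit-reproducible across runs
        for name, payload in (("meta.json", json.dumps(meta, indent=2)),
                              ("state.npz", buf.getvalue())):
            info = zipfile.ZipInfo(name, date_time=(1980, 1, 1, 0, 0, 0))
            zf.writestr(info, payload)
    return path


def load_checkpoint(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checkpoint not found: {path}")
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        state = dict(np.load(io.BytesIO(zf.read("state.npz"))))
    kind = meta["kind"]
    cfg = meta["config"]
    if kind == "fpl_vae":
        cfg["encoder_channels"] = tuple(cfg["encoder_channels"])
        cfg["decoder_channels"] = tuple(cfg["decoder_channels"])
        model = FPLVAE(VAEConfig(**cfg), seed=meta["seed"])
    else:
        cfg["conv_channels"] = tuple(cfg["conv_channels"])
        model = ConvAE(AEConfig(**cfg), variant=kind, seed=meta["seed"])
    model.load_state_dict(state)
    return model
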