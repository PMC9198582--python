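"""One-class training on healthy patches only.

The method's premise is that a model trained exclusively on healthy
berries reconstructs healthy patches well and damaged ones poorly, so the
trainer *refuses* any patch labelled anomalous.  Training minimizes

* FPL-VAE : ``alpha * KL + lambda * FPL``
* FPL-AE  : ``lambda * FPL``
* SSIM-AE : ``1 - SSIM``

with Adam (initial learning rate 5e-4, batch size 64), validation on a
stage-stratified held-out fraction of the healthy patches (batch size 16),
and early stopping on the validation total loss with best-epoch weight
restoration.  All randomness derives from the config seed, so a
single-threaded run is bit-reproducible.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .losses import (FeatureExtractorSpec, FeatureExtractor, build_extractor,
                     fpl_with_grad, kl_divergence, kl_grads, total_loss, SSIMLoss)
from .models import FPLVAE, ConvAE
from .patches import Patch, PatchSet

__all__ = ["TrainConfig", "TrainReport", "OneClassViolation", "split_healthy", "train"]


class OneClassViolation(ValueError):
    """An anomalous-labelled patch reached the one-class trainer."""


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 64
    val_batch_size: int = 16
    learning_rate: float = 5e-4
    optimizer: str = "adam"
    max_epochs: int = 200
    early_stop_patience: int = 10
    early_stop_min_delta: float = 1e-4
    val_fraction: float = 0.2
    seed: int = 0
    alpha: float = 1e-5
    lambda_: float = 1.0

    def validate(self) -> None:
        if self.batch_size < 1 or self.val_batch_size < 1:
            raise ValueError("batch sizes must be >= 1")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError(f"val_fraction must lie in (0, 1), got {self.val_fraction}")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.alpha < 0 or self.lambda_ < 0:
            raise ValueError("loss weights must be >= 0")


@dataclass
class TrainReport:
    epochs_run: int
    best_epoch: int
    history: list[dict]
    stopped_early: bool
    checkpoint_path: str
    config_snapshot: dict

    def write_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(asdict(self), indent=2))
        return path

    def write_history_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        cols = ["epoch", "train_rec", "train_kl", "train_total",
                "val_rec", "val_kl", "val_total"]
        with path.open("w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=cols)
            w.writeheader()
            for row in self.history:
                w.writerow({k: row[k] for k in cols})
        return path


def _assert_one_class(patches: list[Patch], where: str) -> None:
    bad = [p.patch_id for p in patches if p.label == "anomalous"]
    if bad:
        raise OneClassViolation(
            f"{where} contains {len(bad)} anomalous patch(es) "
            f"(e.g. {bad[0]}); the model must be trained on healthy patches only")


def split_healthy(patch_set: PatchSet, val_fraction: float,
                  seed: int) -> tuple[PatchSet, PatchSet]:
    """Stage-stratified, seeded, disjoint and exhaustive train/val split."""
    if not 0.0 < val_fraction < 1.0:
        raise ValueError(f"val_fraction must lie in (0, 1), got {val_fraction}")
    patches = list(patch_set.patches)
    _assert_one_class(patches, "split input")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5BEE7]))
    by_stage: dict[str, list[int]] = {}
    for i, p in enumerate(patches):
        by_stage.setdefault(p.stage_tag, []).append(i)
    val_idx: set[int] = set()
    for stage in sorted(by_stage):
        idx = np.array(by_stage[stage])
        rng.shuffle(idx)
        n_val = int(round(val_fraction * len(idx)))
        val_idx.update(idx[:n_val].tolist())
    train_p = [p for i, p in enumerate(patches) if i not in val_idx]
    val_p = [p for i, p in enumerate(patches) if i in val_idx]
    mk = lambda ps: PatchSet(patches=ps, source_shape=patch_set.source_shape,
                             coverage_threshold=patch_set.coverage_threshold)
    return mk(train_p), mk(val_p)


def _batch_loss_and_grad(model, x: np.ndarray, cfg: TrainConfig,
                         extractor: FeatureExtractor | None,
                         ssim_loss: SSIMLoss | None,
                         rng: np.random.Generator, train: bool) -> tuple[float, float]:
    """One batch: returns (reconstruction_loss, kl_loss); accumulates grads
    into the model parameters when ``train`` is True.  Validation passes
    use the deterministic eps = 0 path."""
    if isinstance(model, FPLVAE):
        if train:
            eps = rng.standard_normal(
                (x.shape[0], model.config.latent_dim)).astype(np.float32)
        else:
            eps = None
        recon, dist, eps_used = model.forward(x, eps=eps, train=train)
        kl_arr = kl_divergence(dist)
        kl = float(np.mean(kl_arr))
        rec, _, grad_x = fpl_with_grad(x, recon, extractor) if train else \
            (fpl_value(x, recon, extractor), None, None)
        if train:
            grad_recon = cfg.lambda_ * grad_x
            gmu, glogvar = kl_grads(dist.mean.astype(np.float64),
                                    dist.log_variance.astype(np.float64))
            model.backward(grad_recon, dist, eps_used,
                           grad_mu_extra=cfg.alpha * gmu,
                           grad_logvar_extra=cfg.alpha * glogvar)
        return rec, kl
    # baseline AEs
    recon = model.forward(x, train=train)
    if model.variant == "fpl_ae":
        if train:
            rec, _, grad_x = fpl_with_grad(x, recon, extractor)
            model.backward(cfg.lambda_ * grad_x)
        else:
            rec = fpl_value(x, recon, extractor)
        return rec, 0.0
    # ssim_ae: loss = 1 - SSIM on the batch
    value, grad = ssim_loss.loss_and_grad(x.astype(np.float64),
                                          recon.astype(np.float64))
    if train:
        model.backward(grad)
    return value, 0.0


def fpl_value(x: np.ndarray, x_hat: np.ndarray, extractor) -> float:
    from .losses import feature_perceptual_loss
    total, _ = feature_perceptual_loss(x, x_hat, extractor)
    return total


def _epoch_pass(model, data: np.ndarray, cfg: TrainConfig, batch_size: int,
                extractor, ssim_loss, rng, train: bool,
                opt: nn.Adam | None, epoch: int) -> tuple[float, float]:
    n = data.shape[0]
    order = np.arange(n)
    if train:
        rng.shuffle(order)
    rec_sum = kl_sum = 0.0
    count = 0
    for start in range(0, n, batch_size):
        idx = order[start:start + batch_size]
        x = data[idx]
        if train:
            opt.zero_grad()
        rec, kl = _batch_loss_and_grad(model, x, cfg, extractor, ssim_loss,
                                       rng, train)
        if not (np.isfinite(rec) and np.isfinite(kl)):
            raise RuntimeError(
                f"non-finite loss at epoch {epoch}, batch {start // batch_size} "
                f"(rec={rec}, kl={kl}); aborting")
        if train:
            opt.step()
        rec_sum += rec * len(idx)
        kl_sum += kl * len(idx)
        count += len(idx)
    return rec_sum / count, kl_sum / count


def train(model, train_set: PatchSet, val_set: PatchSet, cfg: TrainConfig,
          extractor_spec: FeatureExtractorSpec | None = None,
          checkpoint_path: str | Path | None = None,
          verbose: bool = False) -> TrainReport:
    """Train a model on healthy patches with early stopping.

    ``extractor_spec`` configures the frozen feature extractor (needed for
    FPL-VAE and FPL-AE; ignored for SSIM-AE).  The best-validation-epoch
    weights are restored into ``model`` before returning.
    """
    cfg.validate()
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("train and validation sets must be non-empty")
    _assert_one_class(list(train_set.patches), "training set")
    _assert_one_class(list(val_set.patches), "validation set")

    needs_fpl = isinstance(model, FPLVAE) or getattr(model, "variant", "") == "fpl_ae"
    extractor = build_extractor(extractor_spec or FeatureExtractorSpec()) \
        if needs_fpl else None
    ssim_loss = SSIMLoss() if getattr(model, "variant", "") == "ssim_ae" else None

    x_train = train_set.stack().astype(np.float32)
    x_val = val_set.stack().astype(np.float32)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x7247]))
    opt = nn.Adam(model.params(), lr=cfg.learning_rate)

    history: list[dict] = []
    best_val = np.inf
    best_epoch = 0
    best_state = {k: v.copy() for k, v in model.state_dict().items()}
    bad_epochs = 0
    stopped_early = False
    epochs_run = 0

    for epoch in range(1, cfg.max_epochs + 1):
        tr_rec, tr_kl = _epoch_pass(model, x_train, cfg, cfg.batch_size,
                                    extractor, ssim_loss, rng, True, opt, epoch)
        va_rec, va_kl = _epoch_pass(model, x_val, cfg, cfg.val_batch_size,
                                    extractor, ssim_loss, rng, False, None, epoch)
        tr_total = total_loss(tr_rec, tr_kl, cfg.alpha, cfg.lambda_)
        va_total = total_loss(va_rec, va_kl, cfg.alpha, cfg.lambda_)
        history.append({"epoch": epoch,
                        "train_rec": tr_rec, "train_kl": tr_kl, "train_total": tr_total,
                        "val_rec": va_rec, "val_kl": va_kl, "val_total": va_total})
        epochs_run = epoch
        if verbose:
            print(f"epoch {epoch:3d}  train {tr_total:.5f}  val {va_total:.5f}")
        if va_total < best_val - cfg.early_stop_min_delta:
            best_val = va_total
            best_epoch = epoch
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.early_stop_patience:
                stopped_early = True
                break

    if best_epoch == 0:  # no epoch improved over +inf - delta edge case
        best_epoch = 1
    model.load_state_dict(best_state)

    ckpt = ""
    if checkpoint_path is not None:
        from .models import save_checkpoint
        save_checkpoint(model, checkpoint_path,
                        extra={"train_config": asdict(cfg), "best_epoch": best_epoch})
        ckpt = str(checkpoint_path)
    return TrainReport(epochs_run=epochs_run, best_epoch=best_epoch,
                       history=history, stopped_early=stopped_early,
                       checkpoint_path=ckpt, config_snapshot=asdict(cfg))
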