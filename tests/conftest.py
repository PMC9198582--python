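"""Shared fixtures.

The session-scoped ``trained_run`` fixture performs one real (scaled-down)
training of the FPL-VAE on synthetic healthy patches and is shared by all
end-to-end tests so the expensive part runs exactly once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from vitisvae.losses import FeatureExtractorSpec
from vitisvae.models import FPLVAE
from vitisvae.patches import PatchSet
from vitisvae.pipeline import PipelineConfig, prepare_patches
from vitisvae.synthetic import SceneSpec, generate_dataset, generate_scene
from vitisvae.training import TrainConfig, split_healthy, train

E2E_SEED = 1


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def tiny_pipeline_config(out_dir: str, seed: int = 11) -> PipelineConfig:
    """A minutes-to-seconds pipeline config for smoke/reproducibility tests."""
    from vitisvae.models import VAEConfig
    from vitisvae.training import TrainConfig as TC
    return PipelineConfig(
        seed=seed,
        out_dir=out_dir,
        n_healthy_scenes=12,
        n_anomalous_scenes=6,
        scene=SceneSpec(height=130, width=130, berry_count_range=(6, 10)),
        vae=VAEConfig(encoder_channels=(4, 4, 4, 4), latent_dim=8,
                      decoder_channels=(4, 4, 4, 4)),
        training=TC(batch_size=8, val_batch_size=8, max_epochs=2,
                    early_stop_patience=5, val_fraction=0.25),
        heatmap=dataclasses_replace_heatmap(max_scenes=2),
    )


def dataclasses_replace_heatmap(**kw):
    from vitisvae.pipeline import HeatmapBlock
    return HeatmapBlock(**kw)


@pytest.fixture(scope="session")
def tiny_run(tmp_path_factory):
    """One executed tiny pipeline run, shared across tests."""
    from vitisvae.pipeline import run_pipeline
    out = tmp_path_factory.mktemp("run") / "tiny"
    cfg = tiny_pipeline_config(str(out))
    run_dir = run_pipeline(cfg)
    return {"config": cfg, "run_dir": run_dir}


@pytest.fixture(scope="session")
def small_scene():
    """One healthy 192x192 scene with a handful of berries."""
    return generate_scene(SceneSpec(height=192, width=192,
                                    berry_count_range=(8, 12), seed=7))


@pytest.fixture(scope="session")
def trained_run():
    """A full scaled-down study: train the FPL-VAE on healthy patches only.

    Returns the trained model, an untrained twin, the balanced held-out
    test patches, and a fresh batch of damaged scenes for heatmap checks.
    """
    cfg = PipelineConfig(seed=E2E_SEED, n_healthy_scenes=160, n_anomalous_scenes=60)
    scenes = generate_dataset(cfg.n_healthy_scenes, cfg.n_anomalous_scenes,
                              cfg.scene, cfg.seed)
    train_pool, test_healthy, test_anomalous, per_scene = prepare_patches(cfg, scenes)
    assert len(train_pool) >= 400
    assert len(test_healthy) >= 100 and len(test_anomalous) >= 100
    train_set, val_set = split_healthy(PatchSet(patches=train_pool),
                                       cfg.training.val_fraction, cfg.seed)
    model = FPLVAE(seed=cfg.seed)
    tcfg = TrainConfig(max_epochs=20, seed=cfg.seed,
                       alpha=cfg.loss.alpha, lambda_=cfg.loss.lambda_)
    report = train(model, train_set, val_set, tcfg,
                   extractor_spec=FeatureExtractorSpec(seed=cfg.seed))
    damaged_scenes = generate_dataset(0, 20, cfg.scene, seed=E2E_SEED + 1000)
    return {
        "config": cfg,
        "model": model,
        "untrained_model": FPLVAE(seed=cfg.seed + 99),
        "report": report,
        "test_healthy": test_healthy,
        "test_anomalous": test_anomalous,
        "damaged_scenes": damaged_scenes,
    }
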