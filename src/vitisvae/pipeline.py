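"""End-to-end pipeline: synth -> patch -> train -> score -> eval -> heatmap.

A single :class:`PipelineConfig` (one YAML file) drives every stage; the
fully resolved config snapshot is written verbatim into the run directory
before any work starts, and a manifest records every artifact with its
sha256 checksum, so two runs with the same config and seed (random
extractor mode, single-threaded) are bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from contextlib import contextmanager
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .synthetic import SceneSpec, LabeledScene, generate_dataset, write_scenes, read_scenes
from .patches import (PatchSet, patches_from_scene, write_patch_manifest,
                      DEFAULT_COVERAGE_THRESHOLD, DEFAULT_MIN_ANOMALOUS_PIXELS,
                      PATCH_SOURCE_SIZE)
from .losses import FeatureExtractorSpec, build_extractor
from .models import VAEConfig, AEConfig, build_model, save_checkpoint, load_checkpoint
from .training import TrainConfig, split_healthy, train
from .scoring import (score_patches, optimize_threshold, evaluate_stratified,
                      score_histogram, write_scores)
from .heatmaps import patch_heatmap, assemble_image_heatmap, render_overlay

__all__ = ["PipelineConfig", "run_pipeline", "load_config",
           "PipelineStateError", "PipelineStageError"]

STAGES = ("synth", "patch", "train", "score", "eval", "heatmap")


class PipelineStateError(RuntimeError):
    """A stage was invoked without the outputs of its predecessor."""


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class PatchingBlock:
    patch_size: int = PATCH_SOURCE_SIZE
    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD
    min_anomalous_pixels: int = DEFAULT_MIN_ANOMALOUS_PIXELS
    use_ground_truth_mask: bool = True


@dataclass
class LossBlock:
    metric: str = "mse"
    alpha: float = 1e-5
    lambda_: float = 1.0
    extractor_mode: str = "deterministic_random"
    extractor_seed: int = 0
    extractor_layers: tuple[str, ...] = ("feat1", "feat2", "feat3")
    vgg_weights_path: str = ""

    def extractor_spec(self) -> FeatureExtractorSpec:
        return FeatureExtractorSpec(mode=self.extractor_mode,
                                    layer_names=tuple(self.extractor_layers),
                                    seed=self.extractor_seed,
                                    weights_path=self.vgg_weights_path)


@dataclass
class EvalBlock:
    test_fraction: float = 0.2     # healthy patches held out for the test set
    balance_test_set: bool = True
    histogram_bins: int = 30


@dataclass
class HeatmapBlock:
    metric: str = "mse"
    max_scenes: int = 8
    colormap: str = "jet"
    normalization: str = "minmax"
    suppress_min_area: int = 0     # 0 disables the small-blob post-filter


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "runs/run0"
    n_healthy_scenes: int = 60
    n_anomalous_scenes: int = 20
    model_kind: str = "fpl_vae"
    scene: SceneSpec = field(default_factory=lambda: SceneSpec(
        height=260, width=260, berry_count_range=(24, 40)))
    patching: PatchingBlock = field(default_factory=PatchingBlock)
    vae: VAEConfig = field(default_factory=VAEConfig)
    ae: AEConfig = field(default_factory=AEConfig)
    loss: LossBlock = field(default_factory=LossBlock)
    training: TrainConfig = field(default_factory=TrainConfig)
    eval: EvalBlock = field(default_factory=EvalBlock)
    heatmap: HeatmapBlock = field(default_factory=HeatmapBlock)

    def validate(self) -> None:
        self.scene.validate()
        self.vae.validate()
        self.ae.validate()
        self.training.validate()
        if self.model_kind not in ("fpl_vae", "ssim_ae", "fpl_ae"):
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if not 0.0 < self.eval.test_fraction < 1.0:
            raise ValueError("eval.test_fraction must lie in (0, 1)")
        # fail fast on a bad extractor config before any work starts
        if self.model_kind != "ssim_ae" and self.loss.extractor_mode == "pretrained_vgg19":
            build_extractor(self.loss.extractor_spec())


_NESTED = {"scene": SceneSpec, "patching": PatchingBlock, "vae": VAEConfig,
           "ae": AEConfig, "loss": LossBlock, "training": TrainConfig,
           "eval": EvalBlock, "heatmap": HeatmapBlock}
_TUPLE_FIELDS = {"berry_count_range", "berry_radius_range", "background_tone",
                 "anomaly_kinds", "encoder_channels", "decoder_channels",
                 "conv_channels", "extractor_layers"}


def _coerce(cls, data: dict):
    kwargs = {}
    for k, v in data.items():
        if k in _TUPLE_FIELDS and isinstance(v, (list, tuple)):
            v = tuple(v)
        kwargs[k] = v
    return cls(**kwargs)


def config_from_dict(data: dict) -> PipelineConfig:
    kwargs: dict = {}
    for k, v in data.items():
        if k in _NESTED:
            kwargs[k] = _coerce(_NESTED[k], v or {})
        else:
            kwargs[k] = v
    cfg = PipelineConfig(**kwargs)
    cfg.validate()
    return cfg


def load_config(path: str | Path, overrides: dict | None = None) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    for key, value in (overrides or {}).items():
        data[key] = value
    return config_from_dict(data)


def _sha256(path: Path) -> str:
    sha = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            sha.update(chunk)
    return sha.hexdigest()


class _Manifest:
    def __init__(self, run_dir: Path) -> None:
        self.run_dir = run_dir
        self.path = run_dir / "manifest.json"
        self.entries: dict[str, dict] = {}

    def add(self, stage: str, path: Path) -> None:
        rel = str(path.relative_to(self.run_dir))
        self.entries[rel] = {"stage": stage, "sha256": _sha256(path)}
        self.flush()

    def add_tree(self, stage: str, root: Path) -> None:
        for p in sorted(root.rglob("*")):
            if p.is_file():
                self.add(stage, p)

    def flush(self) -> None:
        self.path.write_text(json.dumps(self.entries, indent=2, sort_keys=True))


def _split_test_healthy(healthy: list, test_fraction: float, seed: int):
    """Deterministic stage-stratified holdout of healthy patches for testing."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7E57]))
    by_stage: dict[str, list[int]] = {}
    for i, p in enumerate(healthy):
        by_stage.setdefault(p.stage_tag, []).append(i)
    test_idx: set[int] = set()
    for stage in sorted(by_stage):
        idx = np.array(by_stage[stage])
        rng.shuffle(idx)
        test_idx.update(idx[:int(round(test_fraction * len(idx)))].tolist())
    pool = [p for i, p in enumerate(healthy) if i not in test_idx]
    test = [p for i, p in enumerate(healthy) if i in test_idx]
    return pool, test


def prepare_patches(cfg: PipelineConfig, scenes: list[LabeledScene]):
    """Patch all scenes and assemble the train pool and balanced test set."""
    pb = cfg.patching
    healthy_patches, anomalous_patches = [], []
    per_scene: dict[str, PatchSet] = {}
    for sc in scenes:
        ps = patches_from_scene(sc, patch_size=pb.patch_size,
                                coverage_threshold=pb.coverage_threshold,
                                min_anomalous_pixels=pb.min_anomalous_pixels,
                                use_ground_truth_mask=pb.use_ground_truth_mask)
        per_scene[sc.scene_id] = ps
        for p in ps:
            if sc.is_anomalous:
                # only confidently damaged windows from damaged scenes
                if p.label == "anomalous":
                    anomalous_patches.append(p)
            elif p.label == "healthy":
                healthy_patches.append(p)
    train_pool, test_healthy = _split_test_healthy(
        healthy_patches, cfg.eval.test_fraction, cfg.seed)
    if cfg.eval.balance_test_set:
        n = min(len(test_healthy), len(anomalous_patches))
        test_healthy, test_anomalous = test_healthy[:n], anomalous_patches[:n]
    else:
        test_anomalous = anomalous_patches
    return train_pool, test_healthy, test_anomalous, per_scene


def run_pipeline(cfg: PipelineConfig, verbose: bool = False) -> Path:
    """Execute all stages; returns the run directory.

    Any stage failure aborts with a :class:`PipelineStageError` naming the
    stage and cause, and the run's ``status.json`` marks it incomplete.
    """
    cfg.validate()
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.yaml").write_text(yaml.safe_dump(asdict(cfg), sort_keys=True))
    manifest = _Manifest(run_dir)
    manifest.add("config", run_dir / "config.yaml")
    status_path = run_dir / "status.json"

    def log(msg: str) -> None:
        if verbose:
            print(f"[vitisvae] {msg}")

    @contextmanager
    def stage(name: str):
        try:
            yield
        except Exception as exc:
            status_path.write_text(json.dumps(
                {"status": "incomplete", "failed_stage": name,
                 "error": str(exc)}, indent=2))
            manifest.add("status", status_path)
            raise PipelineStageError(f"stage '{name}' failed: {exc}") from exc

    fingerprint = ""
    if cfg.model_kind != "ssim_ae":
        fingerprint = build_extractor(cfg.loss.extractor_spec()).fingerprint[:16]
    log(f"seed={cfg.seed} model={cfg.model_kind} alpha={cfg.loss.alpha} "
        f"lambda={cfg.loss.lambda_} extractor={cfg.loss.extractor_mode} "
        f"fingerprint={fingerprint}")

    with stage("synth"):
        scenes = generate_dataset(cfg.n_healthy_scenes, cfg.n_anomalous_scenes,
                                  cfg.scene, cfg.seed)
        scene_dir = run_dir / "scenes"
        write_scenes(scenes, scene_dir)
        manifest.add_tree("synth", scene_dir)
        log(f"synth: {len(scenes)} scenes")

    with stage("patch"):
        train_pool, test_healthy, test_anomalous, per_scene = \
            prepare_patches(cfg, scenes)
        patch_dir = run_dir / "patches"
        patch_dir.mkdir(exist_ok=True)
        all_train = PatchSet(patches=train_pool)
        test_set = PatchSet(patches=test_healthy + test_anomalous)
        write_patch_manifest(all_train, patch_dir / "train.jsonl")
        write_patch_manifest(test_set, patch_dir / "test.jsonl")
        manifest.add_tree("patch", patch_dir)
        log(f"patch: {len(train_pool)} train / {len(test_set)} test "
            f"({len(test_anomalous)} anomalous)")
        if not train_pool:
            raise PipelineStateError("no healthy training patches produced")

    with stage("train"):
        train_set, val_set = split_healthy(all_train, cfg.training.val_fraction,
                                           cfg.seed)
        model = build_model(cfg.model_kind, seed=cfg.seed, vae_config=cfg.vae,
                            ae_config=cfg.ae)
        tcfg = dataclasses.replace(cfg.training, seed=cfg.seed,
                                   alpha=cfg.loss.alpha, lambda_=cfg.loss.lambda_)
        ckpt_path = run_dir / "model" / "checkpoint.vitis"
        report = train(model, train_set, val_set, tcfg,
                       extractor_spec=cfg.loss.extractor_spec(),
                       checkpoint_path=ckpt_path, verbose=verbose)
        # keep the report reproducible across run directories
        report.checkpoint_path = str(ckpt_path.relative_to(run_dir))
        report.write_json(run_dir / "model" / "train_report.json")
        report.write_history_csv(run_dir / "model" / "history.csv")
        manifest.add_tree("train", run_dir / "model")
        log(f"train: {report.epochs_run} epochs, best={report.best_epoch}, "
            f"early_stop={report.stopped_early}")

    with stage("score"):
        records = score_patches(model, test_set.patches, metric=cfg.loss.metric)
        score_dir = run_dir / "scores"
        write_scores(records, score_dir / "test_scores.jsonl")
        manifest.add_tree("score", score_dir)

    with stage("eval"):
        eval_dir = run_dir / "eval"
        eval_dir.mkdir(exist_ok=True)
        best = optimize_threshold(records)
        strat = evaluate_stratified(records, best.threshold)
        hist = score_histogram(records, bins=cfg.eval.histogram_bins)
        metrics = {
            "metric": cfg.loss.metric,
            "threshold": best.threshold,
            "joint_accuracy": best.accuracy,
            "counts": {"tp": best.tp, "tn": best.tn, "fp": best.fp, "fn": best.fn},
            "per_stage": {k: asdict(v) for k, v in strat.items()},
        }
        (eval_dir / "metrics.json").write_text(json.dumps(metrics, indent=2))
        with (eval_dir / "histogram.csv").open("w") as fh:
            labels = [k for k in hist if k != "edges"]
            fh.write("bin_lo,bin_hi," + ",".join(labels) + "\n")
            for i in range(len(hist["edges"]) - 1):
                row = [f"{hist['edges'][i]:.8g}", f"{hist['edges'][i + 1]:.8g}"]
                row += [str(int(hist[l][i])) for l in labels]
                fh.write(",".join(row) + "\n")
        manifest.add_tree("eval", eval_dir)
        log(f"eval: accuracy={best.accuracy:.3f} at threshold={best.threshold:.5g}")

    with stage("heatmap"):
        hm_dir = run_dir / "heatmaps"
        hm_dir.mkdir(exist_ok=True)
        done = 0
        for sc in scenes:
            if not sc.is_anomalous:
                continue
            if done >= cfg.heatmap.max_scenes:
                break
            hm = scene_heatmap(model, sc, per_scene[sc.scene_id],
                               cfg.heatmap.metric)
            np.savez_compressed(hm_dir / f"{sc.scene_id}.npz", values=hm.values,
                                valid_mask=hm.valid_mask)
            render_overlay(hm, sc.image, hm_dir / f"{sc.scene_id}.overlay.png",
                           colormap=cfg.heatmap.colormap,
                           normalization=cfg.heatmap.normalization)
            done += 1
        manifest.add_tree("heatmap", hm_dir)
        log(f"heatmap: {done} scenes rendered")

    status_path.write_text(json.dumps({"status": "complete"}, indent=2))
    manifest.add("status", status_path)
    return run_dir


def scene_heatmap(model, scene: LabeledScene, patch_set: PatchSet,
                  metric: str = "mse"):
    """Assemble the whole-scene reconstruction-error heatmap."""
    maps, origins = [], []
    if len(patch_set) == 0:
        return assemble_image_heatmap([], [], scene.image.shape[:2],
                                      scene_id=scene.scene_id, metric=metric)
    batch = patch_set.stack().astype(np.float32)
    recon = model.reconstruct(batch)
    for p, x, xh in zip(patch_set, batch, recon):
        maps.append(patch_heatmap(x, xh, metric))
        origins.append(p.origin)
    return assemble_image_heatmap(maps, origins, scene.image.shape[:2],
                                  source_size=patch_set.patches[0].source_size,
                                  scene_id=scene.scene_id, metric=metric)
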