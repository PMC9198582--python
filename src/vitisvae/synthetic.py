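"""Synthetic grapevine berry scenes with ground-truth berry and anomaly masks.

Real field imagery of grape bunches (with per-pixel damage annotation) is
hard to come by, so this module renders simplified but statistically
controlled stand-ins: clusters of quasi-circular green berries on a diffuse
background, under a smooth multiplicative illumination field, at a density
of roughly 6-10 berries per 130-px window.  Two colour/size regimes emulate
the pea-sized (early, BBCH75-like) and pre-harvest (late, BBCH89-like)
growth stages.  Anomalies — local discolouration, withered texture, and
thin stem-like artifacts — are injected into otherwise healthy scenes and
recorded pixel-exactly in an anomaly mask.

Everything is driven by a single integer seed through hierarchical
``numpy.random.SeedSequence`` spawning, so a (spec, seed) pair reproduces a
scene bit-for-bit regardless of generation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage as ndi

__all__ = [
    "SceneSpec",
    "LabeledScene",
    "SceneSpecError",
    "generate_scene",
    "inject_anomaly",
    "generate_dataset",
    "write_scenes",
    "read_scenes",
    "STAGE_TAGS",
    "ANOMALY_KINDS",
]

STAGE_TAGS = ("early", "late")
ANOMALY_KINDS = ("discolor", "wither", "stem")

# colour regimes: the expressed berry colour is the major stage cue the
# model has to learn, so the two stages get clearly separated green levels
_STAGE_COLOR = {
    "early": np.array([0.30, 0.52, 0.24]),   # deep pea-green
    "late": np.array([0.62, 0.74, 0.34]),    # light yellow-green, pre-harvest
}
_STAGE_RADIUS_SCALE = {"early": 0.85, "late": 1.15}


class SceneSpecError(ValueError):
    """Raised when a SceneSpec violates its invariants."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one rendered berry scene.

    ``anomaly_fraction`` is the probability that any given berry receives a
    discolor/wither lesion; if ``stem`` is among ``anomaly_kinds`` one stem
    artifact is added with the same probability.
    """

    height: int = 192
    width: int = 192
    berry_count_range: tuple[int, int] = (10, 16)
    berry_radius_range: tuple[int, int] = (13, 19)
    stage_tag: str = "early"
    background_tone: tuple[float, float, float] = (0.42, 0.38, 0.33)
    illumination_sigma: float = 0.12
    anomaly_fraction: float = 0.0
    anomaly_kinds: tuple[str, ...] = ("discolor", "wither", "stem")
    seed: int = 0

    def validate(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise SceneSpecError(f"height/width must be positive, got {self.height}x{self.width}")
        lo, hi = self.berry_count_range
        if lo < 0 or lo > hi:
            raise SceneSpecError(f"berry_count_range must satisfy 0 <= min <= max, got {(lo, hi)}")
        rlo, rhi = self.berry_radius_range
        if rlo <= 0 or rlo > rhi:
            raise SceneSpecError(f"berry_radius_range must be ordered and positive, got {(rlo, rhi)}")
        if self.stage_tag not in STAGE_TAGS:
            raise SceneSpecError(f"stage_tag must be one of {STAGE_TAGS}, got {self.stage_tag!r}")
        if not 0.0 <= self.anomaly_fraction <= 1.0:
            raise SceneSpecError(f"anomaly_fraction must lie in [0, 1], got {self.anomaly_fraction}")
        if self.illumination_sigma < 0:
            raise SceneSpecError(f"illumination_sigma must be >= 0, got {self.illumination_sigma}")
        unknown = set(self.anomaly_kinds) - set(ANOMALY_KINDS)
        if unknown:
            raise SceneSpecError(f"unknown anomaly kinds: {sorted(unknown)}")
        if not all(0.0 <= t <= 1.0 for t in self.background_tone):
            raise SceneSpecError(f"background_tone must lie in [0,1]^3, got {self.background_tone}")


@dataclass
class LabeledScene:
    """A rendered scene plus its ground truth.

    image : (H, W, 3) float array in [0, 1]
    berry_mask / anomaly_mask : (H, W) uint8 arrays in {0, 1}
    """

    image: np.ndarray
    berry_mask: np.ndarray
    anomaly_mask: np.ndarray
    stage_tag: str
    scene_id: str
    seed: int = 0

    @property
    def is_anomalous(self) -> bool:
        return bool(self.anomaly_mask.any())


def _illumination_field(rng: np.random.Generator, h: int, w: int, sigma: float) -> np.ndarray:
    """Smooth multiplicative illumination: blurred white noise, mean 1."""
    if sigma == 0:
        return np.ones((h, w))
    noise = rng.standard_normal((h, w))
    smooth = ndi.gaussian_filter(noise, sigma=min(h, w) / 6.0, mode="reflect")
    std = smooth.std()
    if std > 0:
        smooth = smooth / std
    return np.clip(1.0 + sigma * smooth, 0.3, 1.7)


def _render_berries(rng: np.random.Generator, spec: SceneSpec,
                    image: np.ndarray, berry_mask: np.ndarray) -> list[dict]:
    """Draw anti-aliased shaded ellipses clustered around a few centres."""
    h, w = berry_mask.shape
    n_berries = int(rng.integers(spec.berry_count_range[0], spec.berry_count_range[1] + 1))
    if n_berries == 0:
        return []
    base_color = _STAGE_COLOR[spec.stage_tag]
    rscale = _STAGE_RADIUS_SCALE[spec.stage_tag]
    n_clusters = max(1, int(np.ceil(n_berries / 9)))
    margin = spec.berry_radius_range[1] + 2
    centers = rng.uniform([margin, margin], [h - margin, w - margin], size=(n_clusters, 2))
    cluster_r = 0.35 * min(h, w)
    berries: list[dict] = []
    for i in range(n_berries):
        c = centers[i % n_clusters]
        for _ in range(20):  # rejection: stay in frame
            offset = rng.normal(0.0, cluster_r / 2.2, size=2)
            cy, cx = c + offset
            if margin <= cy < h - margin and margin <= cx < w - margin:
                break
        r = rng.uniform(*spec.berry_radius_range) * rscale
        aspect = rng.uniform(0.85, 1.0)
        theta = rng.uniform(0, np.pi)
        color = np.clip(base_color * rng.uniform(0.85, 1.15, size=3), 0, 1)
        # render only inside the berry's bounding box
        ext = int(np.ceil(r + 3))
        y0, y1 = max(0, int(cy) - ext), min(h, int(cy) + ext + 1)
        x0, x1 = max(0, int(cx) - ext), min(w, int(cx) + ext + 1)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        ct, st = np.cos(theta), np.sin(theta)
        dy, dx = yy - cy, xx - cx
        u = (ct * dx + st * dy) / r
        v = (-st * dx + ct * dy) / (r * aspect)
        dist = np.sqrt(u * u + v * v)
        # anti-aliased coverage: 1 inside, smooth ramp over ~1.5 px at the rim
        cov = np.clip((1.0 - dist) * r / 1.5 + 0.5, 0.0, 1.0)
        inside = cov > 0
        # radial shading with an off-centre specular-ish highlight
        shade = 1.0 - 0.45 * np.clip(dist, 0, 1) ** 2
        hl = np.exp(-((u + 0.35) ** 2 + (v + 0.35) ** 2) / 0.18)
        pix = color[None, None, :] * shade[..., None] + 0.25 * hl[..., None]
        pix = np.clip(pix, 0, 1)
        a = cov[..., None]
        sub = image[y0:y1, x0:x1]
        sub[inside] = (1 - a[inside]) * sub[inside] + a[inside] * pix[inside]
        berry_mask[y0:y1, x0:x1][cov > 0.5] = 1
        berries.append({"center": (cy, cx), "radius": r, "aspect": aspect, "theta": theta})
    return berries


def generate_scene(spec: SceneSpec) -> LabeledScene:
    """Render one scene; anomalies are injected per ``spec.anomaly_fraction``."""
    spec.validate()
    ss = np.random.SeedSequence([int(spec.seed), 0x5CE7E])
    rng = np.random.default_rng(ss)
    h, w = spec.height, spec.width
    image = np.empty((h, w, 3))
    image[:] = np.asarray(spec.background_tone)
    # low-amplitude background texture so the scene is not flat
    tex = ndi.gaussian_filter(rng.standard_normal((h, w)), sigma=2.5, mode="reflect")
    image += 0.03 * tex[..., None]
    berry_mask = np.zeros((h, w), dtype=np.uint8)
    berries = _render_berries(rng, spec, image, berry_mask)
    illum = _illumination_field(rng, h, w, spec.illumination_sigma)
    image = np.clip(image * illum[..., None], 0.0, 1.0)
    scene = LabeledScene(
        image=image,
        berry_mask=berry_mask,
        anomaly_mask=np.zeros((h, w), dtype=np.uint8),
        stage_tag=spec.stage_tag,
        scene_id=f"scene-{spec.stage_tag}-{spec.seed}",
        seed=int(spec.seed),
    )
    if spec.anomaly_fraction > 0 and spec.anomaly_kinds:
        lesion_kinds = [k for k in spec.anomaly_kinds if k != "stem"]
        for b in berries:
            if rng.random() < spec.anomaly_fraction and lesion_kinds:
                kind = lesion_kinds[int(rng.integers(len(lesion_kinds)))]
                scene = inject_anomaly(scene, kind, rng, berry=b)
        if "stem" in spec.anomaly_kinds and rng.random() < spec.anomaly_fraction:
            scene = inject_anomaly(scene, "stem", rng)
    return scene


def _pick_berry(scene: LabeledScene, rng: np.random.Generator) -> dict:
    labels, n = ndi.label(scene.berry_mask)
    if n == 0:
        raise ValueError("cannot inject a berry lesion into a berry-free scene")
    idx = int(rng.integers(1, n + 1))
    ys, xs = np.nonzero(labels == idx)
    cy, cx = ys.mean(), xs.mean()
    r = max(3.0, np.sqrt(len(ys) / np.pi))
    return {"center": (cy, cx), "radius": r}


def inject_anomaly(scene: LabeledScene, kind: str,
                   rng: np.random.Generator, berry: dict | None = None) -> LabeledScene:
    """Return a new scene with one injected anomaly of ``kind``.

    discolor : hue shift (green -> brown/red) on a connected sub-region of
        one berry, covering roughly 20-80 % of it.
    wither   : the same region geometry, darkened with added
        high-frequency texture (shrivelled skin).
    stem     : a thin (2-4 px) elongated brownish structure near the
        berries (or anywhere, on a berry-free scene).

    The returned anomaly_mask marks exactly the altered pixels.
    """
    if kind not in ANOMALY_KINDS:
        raise ValueError(f"unknown anomaly kind {kind!r}")
    image = scene.image.copy()
    anomaly_mask = scene.anomaly_mask.copy()
    h, w = anomaly_mask.shape
    yy, xx = np.mgrid[0:h, 0:w]

    if kind in ("discolor", "wither"):
        b = berry if berry is not None else _pick_berry(scene, rng)
        cy, cx = b["center"]
        r = b["radius"]
        frac = rng.uniform(0.2, 0.8)
        lr = r * np.sqrt(frac) * 1.15
        ang = rng.uniform(0, 2 * np.pi)
        off = r * (1 - np.sqrt(frac)) * 0.8
        ly, lx = cy + off * np.sin(ang), cx + off * np.cos(ang)
        region = ((yy - ly) ** 2 + (xx - lx) ** 2 <= lr ** 2) & (scene.berry_mask > 0)
        if not region.any():
            region = ((yy - cy) ** 2 + (xx - cx) ** 2 <= max(lr, 2.0) ** 2) & (scene.berry_mask > 0)
        if not region.any():
            raise ValueError("lesion region is empty; scene has no berry pixels near the target")
        if kind == "discolor":
            px = image[region]
            # rot/sunburn: strong shift to a saturated red-brown
            shifted = np.stack([
                0.70 * px[:, 0] + 0.55 * px[:, 1],
                0.30 * px[:, 1] + 0.08 * px[:, 0],
                0.20 * px[:, 2] + 0.05 * px[:, 1],
            ], axis=1)
            image[region] = np.clip(shifted, 0, 1)
        else:  # wither: shrivelled, dark, high-frequency texture
            noise = rng.standard_normal(int(region.sum()))
            px = image[region]
            dark = px * 0.35
            dark += 0.13 * noise[:, None]
            image[region] = np.clip(dark, 0, 1)
        changed = region & np.any(np.abs(image - scene.image) > 1e-9, axis=-1)
        anomaly_mask[changed] = 1
    else:  # stem
        if scene.berry_mask.any():
            ys, xs = np.nonzero(scene.berry_mask)
            i = int(rng.integers(len(ys)))
            sy, sx = float(ys[i]), float(xs[i])
        else:
            sy = float(rng.uniform(h * 0.2, h * 0.8))
            sx = float(rng.uniform(w * 0.2, w * 0.8))
        ang = rng.uniform(0, 2 * np.pi)
        length = rng.uniform(18, 30)
        width_px = rng.uniform(1.0, 2.0)  # half-width => 2-4 px wide
        t = np.linspace(0, 1, 80)
        curve = 6.0 * (rng.random() - 0.5)
        pys = sy + length * t * np.sin(ang) + curve * t * t * np.cos(ang)
        pxs = sx + length * t * np.cos(ang) - curve * t * t * np.sin(ang)
        keep = (pys >= 1) & (pys < h - 1) & (pxs >= 1) & (pxs < w - 1)
        pys, pxs = pys[keep], pxs[keep]
        if len(pys) < 10:
            pys = np.clip(pys, 1, h - 2)
            pxs = np.clip(pxs, 1, w - 2)
        pad = int(np.ceil(width_px)) + 2
        y0 = max(0, int(pys.min()) - pad); y1 = min(h, int(pys.max()) + pad + 1)
        x0 = max(0, int(pxs.min()) - pad); x1 = min(w, int(pxs.max()) + pad + 1)
        byy, bxx = np.mgrid[y0:y1, x0:x1]
        d2 = np.full((y1 - y0, x1 - x0), np.inf)
        for py, px_ in zip(pys, pxs):
            d2 = np.minimum(d2, (byy - py) ** 2 + (bxx - px_) ** 2)
        region = np.zeros((h, w), dtype=bool)
        region[y0:y1, x0:x1] = d2 <= width_px ** 2
        stem_color = np.array([0.36, 0.25, 0.12])
        image[region] = 0.15 * image[region] + 0.85 * stem_color
        anomaly_mask[region] = 1

    return replace(scene, image=image, anomaly_mask=anomaly_mask)


def generate_dataset(n_healthy: int, n_anomalous: int, spec: SceneSpec,
                     seed: int) -> list[LabeledScene]:
    """Generate ``n_healthy`` clean and ``n_anomalous`` damaged scenes.

    Stage tags alternate within each group so both groups are balanced
    across the two growth-stage regimes to within one scene.  Every
    anomalous scene is guaranteed a non-empty anomaly mask (a lesion is
    force-injected if the Bernoulli draws produced none).
    """
    if n_healthy < 0 or n_anomalous < 0:
        raise ValueError("scene counts must be non-negative")
    spec.validate()
    ss = np.random.SeedSequence(int(seed))
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n_healthy + n_anomalous)]
    scenes: list[LabeledScene] = []
    anomaly_fraction = spec.anomaly_fraction if spec.anomaly_fraction > 0 else 0.5
    for i in range(n_healthy):
        sub = replace(spec, seed=child_seeds[i], anomaly_fraction=0.0,
                      stage_tag=STAGE_TAGS[i % 2])
        sc = generate_scene(sub)
        sc.scene_id = f"healthy-{i:04d}-{sub.stage_tag}"
        scenes.append(sc)
    for j in range(n_anomalous):
        s = child_seeds[n_healthy + j]
        sub = replace(spec, seed=s, anomaly_fraction=anomaly_fraction,
                      stage_tag=STAGE_TAGS[j % 2])
        sc = generate_scene(sub)
        if not sc.is_anomalous:
            rng = np.random.default_rng(np.random.SeedSequence([s, 0xF0FCE]))
            kind = "stem" if not sc.berry_mask.any() else (
                [k for k in sub.anomaly_kinds if k != "stem"] or ["stem"])[0]
            sc = inject_anomaly(sc, kind, rng)
        sc.scene_id = f"anomalous-{j:04d}-{sub.stage_tag}"
        scenes.append(sc)
    return scenes


def write_scenes(scenes: list[LabeledScene], out_dir: str | Path) -> Path:
    """Write PNG triplets plus a JSON manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = []
    for sc in scenes:
        img8 = np.clip(np.round(sc.image * 255.0), 0, 255).astype(np.uint8)
        Image.fromarray(img8).save(out / f"{sc.scene_id}.png")
        Image.fromarray((sc.berry_mask * 255).astype(np.uint8)).save(out / f"{sc.scene_id}.berry.png")
        Image.fromarray((sc.anomaly_mask * 255).astype(np.uint8)).save(out / f"{sc.scene_id}.anomaly.png")
        records.append({
            "scene_id": sc.scene_id,
            "stage_tag": sc.stage_tag,
            "label": "anomalous" if sc.is_anomalous else "healthy",
            "seed": int(sc.seed),
        })
    manifest = out / "scenes.json"
    manifest.write_text(json.dumps(records, indent=2))
    return manifest


def read_scenes(manifest_path: str | Path) -> list[LabeledScene]:
    """Load scenes written by :func:`write_scenes`."""
    manifest_path = Path(manifest_path)
    out_dir = manifest_path.parent
    scenes = []
    for rec in json.loads(manifest_path.read_text()):
        sid = rec["scene_id"]
        image = np.asarray(Image.open(out_dir / f"{sid}.png"), dtype=np.float64) / 255.0
        berry = (np.asarray(Image.open(out_dir / f"{sid}.berry.png")) > 127).astype(np.uint8)
        anomaly = (np.asarray(Image.open(out_dir / f"{sid}.anomaly.png")) > 127).astype(np.uint8)
        scenes.append(LabeledScene(image=image, berry_mask=berry, anomaly_mask=anomaly,
                                   stage_tag=rec["stage_tag"], scene_id=sid,
                                   seed=int(rec.get("seed", 0))))
    return scenes
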