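"""ROI-guided patch extraction.

An image plus a binary berry mask is tiled on a regular, non-overlapping
grid of ``patch_size`` x ``patch_size`` windows (130 px by default)
anchored at the top-left corner; tiles whose berry-pixel coverage reaches
a threshold are kept and resized to the working resolution of 64 x 64.
Windows use 0-based, half-open, row-major coordinates throughout; the
residual right/bottom margins that do not fit a full window are discarded.

Downsampling uses exact local-mean (area) averaging, which is
anti-aliased and preserves the window mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize_local_mean

from .synthetic import LabeledScene

__all__ = [
    "Patch",
    "PatchSet",
    "extract_patches",
    "label_patch",
    "resize_patch",
    "color_threshold_segmenter",
    "patches_from_scene",
    "write_patch_manifest",
]

PATCH_SOURCE_SIZE = 130
PATCH_TARGET_SIZE = 64
DEFAULT_COVERAGE_THRESHOLD = 0.1
DEFAULT_MIN_ANOMALOUS_PIXELS = 30  # at source scale, ~0.18% of 130^2

LABELS = ("healthy", "anomalous", "unlabeled")


@dataclass
class Patch:
    """One 64x64 working tile with its provenance.

    origin is the (row, col) of the top-left corner of the source window
    in the original image; the window is half-open:
    ``[row, row+source_size) x [col, col+source_size)``.
    """

    pixels: np.ndarray
    origin: tuple[int, int]
    source_size: int = PATCH_SOURCE_SIZE
    scene_id: str = ""
    label: str = "unlabeled"
    stage_tag: str = "early"
    interpolation: str = "local_mean"

    @property
    def patch_id(self) -> str:
        return f"{self.scene_id}@{self.origin[0]}:{self.origin[1]}"


@dataclass
class PatchSet:
    patches: list[Patch] = field(default_factory=list)
    source_shape: tuple[int, int] = (0, 0)
    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD

    def __len__(self) -> int:
        return len(self.patches)

    def __iter__(self):
        return iter(self.patches)

    def stack(self) -> np.ndarray:
        """Return patches as an (n, 64, 64, 3) array."""
        return np.stack([p.pixels for p in self.patches]) if self.patches else \
            np.empty((0, PATCH_TARGET_SIZE, PATCH_TARGET_SIZE, 3))


def resize_patch(pixels: np.ndarray, target: int = PATCH_TARGET_SIZE) -> np.ndarray:
    """Resize a square tile by exact area averaging; output stays in [0, 1]."""
    if pixels.ndim not in (2, 3):
        raise ValueError("expected an HxW or HxWxC array")
    h, w = pixels.shape[:2]
    if h != w:
        raise ValueError(f"patch must be square, got {h}x{w}")
    if h == target:
        return pixels.astype(np.float64, copy=True)
    out_shape = (target, target) if pixels.ndim == 2 else (target, target, pixels.shape[2])
    out = resize_local_mean(pixels.astype(np.float64), out_shape)
    return np.clip(out, 0.0, 1.0)


def extract_patches(image: np.ndarray, roi_mask: np.ndarray,
                    patch_size: int = PATCH_SOURCE_SIZE,
                    coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
                    scene_id: str = "", stage_tag: str = "early",
                    target_size: int = PATCH_TARGET_SIZE) -> PatchSet:
    """Tile ``image`` and keep windows whose ROI coverage >= threshold.

    Grid cells are returned in row-major order of their origins.
    """
    image = np.asarray(image)
    roi_mask = np.asarray(roi_mask)
    if image.shape[:2] != roi_mask.shape[:2]:
        raise ValueError(
            f"image {image.shape[:2]} and roi_mask {roi_mask.shape[:2]} differ in size")
    h, w = image.shape[:2]
    if patch_size > min(h, w):
        raise ValueError(f"patch_size {patch_size} exceeds image size {h}x{w}")
    if not 0.0 <= coverage_threshold <= 1.0:
        raise ValueError(f"coverage_threshold must lie in [0, 1], got {coverage_threshold}")
    roi = roi_mask > 0
    kept: list[Patch] = []
    for r0 in range(0, h - patch_size + 1, patch_size):
        for c0 in range(0, w - patch_size + 1, patch_size):
            window_roi = roi[r0:r0 + patch_size, c0:c0 + patch_size]
            if window_roi.mean() >= coverage_threshold and window_roi.any():
                tile = image[r0:r0 + patch_size, c0:c0 + patch_size]
                kept.append(Patch(pixels=resize_patch(tile, target_size),
                                  origin=(r0, c0), source_size=patch_size,
                                  scene_id=scene_id, stage_tag=stage_tag))
    return PatchSet(patches=kept, source_shape=(h, w),
                    coverage_threshold=coverage_threshold)


def label_patch(patch: Patch, anomaly_mask: np.ndarray,
                min_anomalous_pixels: int = DEFAULT_MIN_ANOMALOUS_PIXELS) -> str:
    """Label a patch from the ground-truth anomaly mask of its source image."""
    r0, c0 = patch.origin
    s = patch.source_size
    h, w = anomaly_mask.shape[:2]
    if r0 < 0 or c0 < 0 or r0 + s > h or c0 + s > w:
        raise ValueError(
            f"patch window [{r0}:{r0 + s}, {c0}:{c0 + s}] outside mask bounds {h}x{w}")
    count = int((anomaly_mask[r0:r0 + s, c0:c0 + s] > 0).sum())
    return "anomalous" if count >= min_anomalous_pixels else "healthy"


def color_threshold_segmenter(image: np.ndarray,
                              green_margin: float = 0.04,
                              min_component_area: int = 40) -> np.ndarray:
    """Crude berry segmenter for synthetic scenes: green-dominant pixels.

    Keeps pixels whose green channel exceeds both red and blue by
    ``green_margin``, then removes connected components smaller than
    ``min_component_area`` and fills small holes.  This stands in for a
    learned segmentation model and is only meant for the synthetic scenes.
    """
    image = np.asarray(image, dtype=np.float64)
    r, g, b = image[..., 0], image[..., 1], image[..., 2]
    mask = (g > r + green_margin) & (g > b + green_margin)
    mask = ndi.binary_closing(mask, structure=np.ones((3, 3)))
    mask = ndi.binary_fill_holes(mask)
    labels, n = ndi.label(mask)
    if n:
        sizes = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        small = np.flatnonzero(sizes < min_component_area) + 1
        mask &= ~np.isin(labels, small)
    return mask.astype(np.uint8)


def patches_from_scene(scene: LabeledScene,
                       patch_size: int = PATCH_SOURCE_SIZE,
                       coverage_threshold: float = DEFAULT_COVERAGE_THRESHOLD,
                       min_anomalous_pixels: int = DEFAULT_MIN_ANOMALOUS_PIXELS,
                       use_ground_truth_mask: bool = True) -> PatchSet:
    """Extract labelled patches from a scene.

    Uses the scene's ground-truth berry mask as ROI by default; set
    ``use_ground_truth_mask=False`` to run the colour-threshold segmenter
    instead (the realistic pipeline path).
    """
    roi = scene.berry_mask if use_ground_truth_mask else color_threshold_segmenter(scene.image)
    ps = extract_patches(scene.image, roi, patch_size=patch_size,
                         coverage_threshold=coverage_threshold,
                         scene_id=scene.scene_id, stage_tag=scene.stage_tag)
    for p in ps.patches:
        p.label = label_patch(p, scene.anomaly_mask, min_anomalous_pixels)
    return ps


def write_patch_manifest(patch_set: PatchSet, path: str | Path,
                         dump_pngs: bool = False) -> Path:
    """Write a JSON-lines manifest (and optionally per-patch PNGs)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for p in patch_set:
            fh.write(json.dumps({
                "patch_id": p.patch_id, "scene_id": p.scene_id,
                "origin": list(p.origin), "source_size": p.source_size,
                "label": p.label, "stage_tag": p.stage_tag,
                "interpolation": p.interpolation,
            }) + "\n")
    if dump_pngs:
        from PIL import Image
        png_dir = path.parent / "patches"
        png_dir.mkdir(exist_ok=True)
        for p in patch_set:
            img8 = np.clip(np.round(p.pixels * 255.0), 0, 255).astype(np.uint8)
            Image.fromarray(img8).save(png_dir / f"{p.patch_id.replace(':', '_').replace('@', '_')}.png")
    return path
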