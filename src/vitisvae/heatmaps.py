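"""Pixel-wise anomaly heatmaps and whole-image reassembly.

Each scored patch yields a 64x64 channel-averaged loss map (MSE by
default, which penalizes strongly deviating pixels hardest); maps are
upscaled back to their 130x130 source windows by nearest-neighbour
interpolation and placed at their grid origins.  Because the patch grid is
non-overlapping no blending is needed; pixels not covered by any kept
patch carry a zero value and are flagged invalid.  Overlays render the
heatmap through a blue-to-red colormap on top of the source image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize

from .losses import pixel_loss_map

__all__ = [
    "ImageHeatmap",
    "patch_heatmap",
    "assemble_image_heatmap",
    "render_overlay",
    "suppress_small_blobs",
]


@dataclass
class ImageHeatmap:
    """Un-normalized per-pixel loss aligned to a source image."""

    values: np.ndarray        # (H, W) float, >= 0, zero outside valid_mask
    valid_mask: np.ndarray    # (H, W) uint8 in {0, 1}
    scene_id: str = ""
    metric: str = "mse"

    def __post_init__(self) -> None:
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask shapes differ")
        if not np.isfinite(self.values).all():
            raise ValueError("heatmap contains non-finite values")


def patch_heatmap(x: np.ndarray, x_hat: np.ndarray, metric: str = "mse") -> np.ndarray:
    """Channel-averaged pixel loss map for one patch (64x64, >= 0)."""
    m, _ = pixel_loss_map(x, x_hat, metric)
    return m


def assemble_image_heatmap(patch_maps: list[np.ndarray],
                           origins: list[tuple[int, int]],
                           source_shape: tuple[int, int],
                           source_size: int = 130,
                           scene_id: str = "", metric: str = "mse") -> ImageHeatmap:
    """Place upscaled patch loss maps back onto the source image grid."""
    if len(patch_maps) != len(origins):
        raise ValueError("patch_maps and origins length mismatch")
    h, w = source_shape
    values = np.zeros((h, w), dtype=np.float64)
    valid = np.zeros((h, w), dtype=np.uint8)
    seen: set[tuple[int, int]] = set()
    for m, (r0, c0) in zip(patch_maps, origins):
        if (r0, c0) in seen:
            raise ValueError(f"duplicate patch origin {(r0, c0)}")
        seen.add((r0, c0))
        if r0 < 0 or c0 < 0 or r0 + source_size > h or c0 + source_size > w:
            raise ValueError(f"origin {(r0, c0)} with size {source_size} "
                             f"outside image {h}x{w}")
        if valid[r0:r0 + source_size, c0:c0 + source_size].any():
            raise ValueError(f"patch window at {(r0, c0)} overlaps a previous window")
        up = resize(np.asarray(m, dtype=np.float64), (source_size, source_size),
                    order=0, preserve_range=True, anti_aliasing=False)
        values[r0:r0 + source_size, c0:c0 + source_size] = up
        valid[r0:r0 + source_size, c0:c0 + source_size] = 1
    return ImageHeatmap(values=values, valid_mask=valid, scene_id=scene_id,
                        metric=metric)


def suppress_small_blobs(heatmap: ImageHeatmap, threshold: float,
                         min_area: int) -> ImageHeatmap:
    """Zero out connected above-threshold components smaller than min_area.

    Optional post-filter against few-pixel false positives (specular
    highlights and mask-border slivers); off by default in the pipeline.
    """
    hot = heatmap.values > threshold
    labels, n = ndi.label(hot)
    values = heatmap.values.copy()
    if n:
        sizes = ndi.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
        small = np.flatnonzero(sizes < min_area) + 1
        values[np.isin(labels, small)] = 0.0
    return ImageHeatmap(values=values, valid_mask=heatmap.valid_mask,
                        scene_id=heatmap.scene_id, metric=heatmap.metric)


def render_overlay(heatmap: ImageHeatmap, image: np.ndarray,
                   out_path: str | Path | None = None, colormap: str = "jet",
                   normalization: str = "minmax", vmax: float | None = None,
                   alpha: float = 0.55) -> np.ndarray:
    """Blend the heatmap over the image; red = anomalous, dark blue = not.

    ``normalization`` is ``"minmax"`` (per image) or ``"absolute"`` (divide
    by ``vmax``).  Invalid pixels show the untouched image.  Returns the
    RGB overlay in [0, 1] and optionally writes it as PNG with a metadata
    sidecar recording the normalization.
    """
    import matplotlib
    image = np.asarray(image, dtype=np.float64)
    if image.shape[:2] != heatmap.values.shape:
        raise ValueError(f"image {image.shape[:2]} and heatmap "
                         f"{heatmap.values.shape} shapes differ")
    v = heatmap.values
    if normalization == "minmax":
        vmin, vtop = float(v.min()), float(v.max())
        scale = (vtop - vmin) or 1.0
        norm = (v - vmin) / scale
    elif normalization == "absolute":
        if vmax is None or vmax <= 0:
            raise ValueError("absolute normalization needs vmax > 0")
        norm = np.clip(v / vmax, 0.0, 1.0)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    cmap = matplotlib.colormaps[colormap]
    colored = np.asarray(cmap(norm))[..., :3]
    valid = heatmap.valid_mask.astype(bool)[..., None]
    overlay = np.where(valid, (1 - alpha) * image + alpha * colored, image)
    overlay = np.clip(overlay, 0.0, 1.0)
    if out_path is not None:
        from PIL import Image as PILImage
        out_path = Path(out_path)
        out_path.parent.mkdir(parents=True, exist_ok=True)
        PILImage.fromarray(
            np.clip(np.round(overlay * 255), 0, 255).astype(np.uint8)).save(out_path)
        meta = {"scene_id": heatmap.scene_id, "metric": heatmap.metric,
                "colormap": colormap, "normalization": normalization,
                "vmax": vmax, "alpha": alpha}
        out_path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return overlay
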