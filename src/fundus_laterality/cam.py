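"""Class activation maps for the GAP-headed laterality classifier.

Because the classifier ends in global average pooling followed by a
single affine layer, the spatial evidence for class ``c`` is the
weighted sum of the last convolutional layer's feature maps,

    R(x, y) = sum_k w_k^c * f_k(x, y),

with ``w^c`` the affine weights of class ``c`` (the bias is a constant
shift and is removed by normalization).  The raw map is bilinearly
upsampled to the input side and min-max normalized to [0, 1]; a constant
raw map carries no localization signal and maps to all zeros.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from skimage import transform

from .classifier import label_index
from .synth_fundus import FundusImage

__all__ = ["HeatMap", "compute_cam", "overlay", "roi_centroid", "cam_from_features"]


class UnsupportedArchitectureError(TypeError):
    """The model does not end in global average pooling + a single affine layer."""


@dataclass(frozen=True)
class HeatMap:
    values: np.ndarray  # (H, W), in [0, 1]
    target_class: str


def cam_from_features(feature_maps: np.ndarray, class_weights: np.ndarray) -> np.ndarray:
    """Raw activation map: per-pixel weighted sum over the K feature maps."""
    fmaps = np.asarray(feature_maps, dtype=np.float64)
    w = np.asarray(class_weights, dtype=np.float64)
    if fmaps.ndim != 3 or w.shape != (fmaps.shape[0],):
        raise ValueError("expected (K, H, W) feature maps and (K,) weights")
    return np.tensordot(w, fmaps, axes=(0, 0))


def normalize_map(raw: np.ndarray) -> np.ndarray:
    """Min-max normalization to [0, 1]; constant maps become all zeros."""
    lo, hi = float(raw.min()), float(raw.max())
    if hi <= lo:
        return np.zeros_like(raw, dtype=np.float64)
    return (raw - lo) / (hi - lo)


def compute_cam(model, image: FundusImage | np.ndarray, target_class: str) -> HeatMap:
    """CAM for ``target_class``, upsampled to the model's input side."""
    if not getattr(model, "gap_head", False):
        raise UnsupportedArchitectureError(
            "CAM requires a network ending in GAP + a single affine layer"
        )
    pixels = image.pixels if isinstance(image, FundusImage) else np.asarray(image)
    side = model.input_side
    if pixels.shape[:2] != (side, side):
        raise ValueError("image does not match the model input side")
    x = np.ascontiguousarray(pixels.transpose(2, 0, 1), dtype=np.float32)[None] / 255.0
    fmaps = model.feature_maps(x)[0]
    weights = model.head.w.value[label_index(target_class)]
    raw = cam_from_features(fmaps, weights)
    up = transform.resize(raw, (side, side), order=1, anti_aliasing=False)
    return HeatMap(values=normalize_map(up), target_class=target_class)


def overlay(heat: HeatMap, image: FundusImage, opacity: float) -> FundusImage:
    """Jet-pseudocolor blend of the heat map over the image."""
    if heat.values.shape != image.pixels.shape[:2]:
        raise ValueError("heat map and image dimensions must match")
    if not (0.0 <= opacity <= 1.0):
        raise ValueError("opacity must lie in [0, 1]")
    cmap = colormaps["jet"]
    colored = cmap(heat.values)[..., :3] * 255.0
    out = (1.0 - opacity) * image.pixels.astype(np.float64) + opacity * colored
    return FundusImage(
        pixels=np.clip(np.round(out), 0, 255).astype(np.uint8), meta=image.meta
    )


def roi_centroid(heat: HeatMap, threshold: float) -> tuple[float, float] | None:
    """Intensity-weighted centroid (x, y) over pixels >= threshold; None if empty."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    mask = heat.values >= threshold
    if not mask.any():
        return None
    ys, xs = np.nonzero(mask)
    w = heat.values[ys, xs]
    total = w.sum()
    return (float((xs * w).sum() / total), float((ys * w).sum() / total))
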