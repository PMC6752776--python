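"""Size normalization and enhancement of fundus photographs.

The normalization chain brings every camera format to the classifier's
input geometry: crop the black border (detected by per-line pixel
summation), center-crop to a square, bilinearly rescale to
``target_side`` (299 px by default), and zero everything outside a
circle of ``mask_ratio`` (95%) of the fundus radius to strip the
overexposed rim.

Four enhancement methods are provided for comparison:

ORIGINAL
    identity.
CLAHE
    contrast-limited adaptive histogram equalization applied to the
    CIELAB luminance channel, chroma untouched.
LSACR
    local-space-average-color removal: ``clip(a*I - b*G_sigma(I) + c)``
    per channel, with a Gaussian estimate of the local average color.
GRAY
    Rec.601 luma replicated to all three channels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import color as skcolor
from skimage import transform

from .synth_fundus import FundusImage

METHODS = ("original", "clahe", "lsacr", "gray")

_CLAHE_NBINS = 256


class DegenerateImageError(ValueError):
    """Raised when an image carries no usable content (e.g., entirely dark)."""


@dataclass(frozen=True)
class PreprocessConfig:
    target_side: int = 299
    mask_ratio: float = 0.95
    border_threshold: float = 0.02   # fraction of the peak per-line sum
    method: str = "original"
    clahe_clip: float = 2.0          # multiples of the uniform tile-histogram level
    clahe_tiles: int = 8             # tiles per image side
    lsacr_alpha: float = 4.0
    lsacr_beta: float = 4.0
    lsacr_gamma: float = 128.0
    lsacr_sigma_frac: float = 1.0 / 30.0

    def __post_init__(self):
        if self.target_side < 32:
            raise ValueError("target_side must be >= 32")
        if not (0.0 < self.mask_ratio <= 1.0):
            raise ValueError("mask_ratio must lie in (0, 1]")
        if not (0.0 <= self.border_threshold < 1.0):
            raise ValueError("border_threshold must lie in [0, 1)")
        if self.method.lower() not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")


def _replace_pixels(image: FundusImage, pixels: np.ndarray) -> FundusImage:
    return FundusImage(pixels=pixels, meta=image.meta)


def crop_dark_border(image: FundusImage, border_threshold: float = 0.02) -> FundusImage:
    """Cut off the dark border by per-line pixel summation.

    A row/column is content if the sum (over the line) of the per-pixel
    maximum channel exceeds ``border_threshold`` times the peak line sum.
    """
    stat = image.pixels.max(axis=2).astype(np.int64)
    row_sums = stat.sum(axis=1)
    col_sums = stat.sum(axis=0)
    rows = np.where(row_sums > border_threshold * row_sums.max())[0]
    cols = np.where(col_sums > border_threshold * col_sums.max())[0]
    if rows.size == 0 or cols.size == 0:
        raise DegenerateImageError("image is entirely dark; no content to crop to")
    out = image.pixels[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    return _replace_pixels(image, out.copy())


def to_square(image: FundusImage) -> FundusImage:
    """Center-crop the longer dimension; the odd extra pixel comes off the trailing side."""
    h, w = image.pixels.shape[:2]
    if h == w:
        return _replace_pixels(image, image.pixels.copy())
    if w > h:
        cut = w - h
        lead = cut // 2
        out = image.pixels[:, lead : lead + h]
    else:
        cut = h - w
        lead = cut // 2
        out = image.pixels[lead : lead + w, :]
    return _replace_pixels(image, out.copy())


def resize(image: FundusImage, target_side: int) -> FundusImage:
    """Bilinear resample of a square image to ``target_side`` squared."""
    h, w = image.pixels.shape[:2]
    if h != w:
        raise ValueError("resize expects a square image; run to_square first")
    out = transform.resize(
        image.pixels.astype(np.float64),
        (target_side, target_side, 3),
        order=1,
        anti_aliasing=False,
        preserve_range=True,
    )
    return _replace_pixels(image, np.clip(np.round(out), 0, 255).astype(np.uint8))


def circular_mask(image: FundusImage, mask_ratio: float = 0.95) -> FundusImage:
    """Zero pixels farther than ``mask_ratio`` x half-side from the image center."""
    h, w = image.pixels.shape[:2]
    if h != w:
        raise ValueError("circular_mask expects a square image")
    c = (h - 1) / 2.0
    ys = np.arange(h, dtype=np.float64) - c
    r2 = ys[:, None] ** 2 + ys[None, :] ** 2
    out = image.pixels.copy()
    out[r2 > (mask_ratio * h / 2.0) ** 2] = 0
    return _replace_pixels(image, out)


def normalize(image: FundusImage, config: PreprocessConfig | None = None) -> FundusImage:
    """crop_dark_border -> to_square -> resize -> circular_mask."""
    cfg = config or PreprocessConfig()
    out = crop_dark_border(image, cfg.border_threshold)
    out = to_square(out)
    out = resize(out, cfg.target_side)
    return circular_mask(out, cfg.mask_ratio)


def _enhance_gray(pixels: np.ndarray) -> np.ndarray:
    luma = (
        0.299 * pixels[..., 0].astype(np.float64)
        + 0.587 * pixels[..., 1]
        + 0.114 * pixels[..., 2]
    )
    luma = np.clip(np.round(luma), 0, 255).astype(np.uint8)
    return np.repeat(luma[:, :, None], 3, axis=2)


def _enhance_lsacr(pixels: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    f = pixels.astype(np.float64)
    sigma = cfg.lsacr_sigma_frac * pixels.shape[0]
    background = gaussian_filter(f, sigma=(sigma, sigma, 0))
    out = cfg.lsacr_alpha * f - cfg.lsacr_beta * background + cfg.lsacr_gamma
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def clahe_channel(
    channel: np.ndarray, tiles: int = 8, clip: float = 2.0, nbins: int = _CLAHE_NBINS
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization of one [0, 1] channel.

    Canonical CLAHE: per-tile histograms clipped at ``clip`` times the
    uniform level (excess redistributed equally), per-tile CDF mappings,
    and bilinear interpolation between the four surrounding tile centers.
    The tile grid is laid out symmetrically, so the operator commutes with
    horizontal mirroring up to floating-point rounding at any image size.
    """
    h, w = channel.shape
    tiles = max(1, min(tiles, h, w))
    vals = np.clip(np.round(channel * (nbins - 1)), 0, nbins - 1).astype(np.intp)

    yb = np.floor(np.arange(tiles + 1) * h / tiles + 0.5).astype(int)
    xb = np.floor(np.arange(tiles + 1) * w / tiles + 0.5).astype(int)
    maps = np.empty((tiles, tiles, nbins))
    for ti in range(tiles):
        for tj in range(tiles):
            tile = vals[yb[ti] : yb[ti + 1], xb[tj] : xb[tj + 1]]
            hist = np.bincount(tile.ravel(), minlength=nbins).astype(float)
            limit = max(clip * tile.size / nbins, 1.0)
            excess = np.clip(hist - limit, 0.0, None).sum()
            hist = np.minimum(hist, limit) + excess / nbins
            cdf = np.cumsum(hist)
            maps[ti, tj] = cdf / cdf[-1]

    ycent = (yb[:-1] + yb[1:] - 1) / 2.0
    xcent = (xb[:-1] + xb[1:] - 1) / 2.0
    fy = np.interp(np.arange(h), ycent, np.arange(tiles, dtype=float))
    fx = np.interp(np.arange(w), xcent, np.arange(tiles, dtype=float))
    y0 = np.floor(fy).astype(int)
    x0 = np.floor(fx).astype(int)
    y1 = np.minimum(y0 + 1, tiles - 1)
    x1 = np.minimum(x0 + 1, tiles - 1)
    wy = (fy - y0)[:, None]
    wx = (fx - x0)[None, :]

    m00 = maps[y0[:, None], x0[None, :], vals]
    m01 = maps[y0[:, None], x1[None, :], vals]
    m10 = maps[y1[:, None], x0[None, :], vals]
    m11 = maps[y1[:, None], x1[None, :], vals]
    return (1 - wy) * ((1 - wx) * m00 + wx * m01) + wy * ((1 - wx) * m10 + wx * m11)


def _enhance_clahe(pixels: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    lab = skcolor.rgb2lab(pixels)
    lab[..., 0] = clahe_channel(
        lab[..., 0] / 100.0, cfg.clahe_tiles, cfg.clahe_clip
    ) * 100.0
    rgb = skcolor.lab2rgb(lab)
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def enhance(image: FundusImage, config: PreprocessConfig) -> FundusImage:
    """Apply the configured enhancement method to a normalized image."""
    method = config.method.lower()
    if method == "original":
        out = image.pixels.copy()
    elif method == "gray":
        out = _enhance_gray(image.pixels)
    elif method == "lsacr":
        out = _enhance_lsacr(image.pixels, config)
    elif method == "clahe":
        out = _enhance_clahe(image.pixels, config)
    else:
        raise ValueError(f"unknown method {config.method!r}; expected one of {METHODS}")
    return _replace_pixels(image, out)


def preprocess(image: FundusImage, config: PreprocessConfig) -> FundusImage:
    """Full chain: size normalization followed by the configured enhancement."""
    return enhance(normalize(image, config), config)


def with_method(config: PreprocessConfig, method: str) -> PreprocessConfig:
    return dataclasses.replace(config, method=method.lower())
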