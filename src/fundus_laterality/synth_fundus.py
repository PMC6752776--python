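"""Synthetic color fundus photographs with known laterality ground truth.

Real macula-centered fundus photographs show a bright optic disc displaced
nasally — to the left of the image midline in left eyes and to the right in
right eyes — a darker macula at the image center, vessel arcades leaving the
disc, an overexposed rim at the edge of the circular fundus field, and black
side bars where the circular field does not fill the landscape sensor.  The
generator reproduces exactly that geometry (plus an optional poor-quality
subpopulation with occlusions or a partially visible disc) so that every
downstream stage — preprocessing, training, CAM, evaluation — can be
exercised without clinical data.

Right-eye images are rendered by horizontally mirroring the left-eye
rendering for the same seed, so the two classes are exact mirror
populations by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

LEFT = "left"
RIGHT = "right"

#: canvas sizes of the three camera formats the pipeline must accept
DEFAULT_CANVAS_SIZES: tuple[tuple[int, int], ...] = (
    (2560, 1920),
    (3280, 2480),
    (4700, 3100),
)

_FUNDUS_BASE = np.array([200.0, 90.0, 40.0])  # orange-red fundus background
_DISC_COLOR = np.array([238.0, 208.0, 150.0])
_VESSEL_COLOR = np.array([128.0, 34.0, 28.0])
_NOISE_SIGMA = 8.0
_RIM_GAIN = 1.2          # overexposed edge: +20% brightness in the outer annulus
_RIM_INNER_FRAC = 0.955  # annulus spans [_RIM_INNER_FRAC * R, R]

MANIFEST_COLUMNS = [
    "filename",
    "laterality",
    "obscured_fraction",
    "disc_visible_fraction",
    "width",
    "height",
    "seed",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; defaults emulate macula-centered 45° photographs."""

    n_images: int = 100
    left_fraction: float = 0.5
    canvas_sizes: tuple[tuple[int, int], ...] = DEFAULT_CANVAS_SIZES
    disc_offset: float = 0.55        # horizontal disc displacement, fraction of fundus radius
    disc_radius_frac: float = 0.18
    macula_radius_frac: float = 0.12
    vessel_count: int = 6
    poor_quality_fraction: float = 0.0
    border_bar_frac: float = 0.125   # black side-bar width as fraction of canvas width
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.left_fraction <= 1.0):
            raise ValueError("left_fraction must lie in [0, 1]")
        if not (0.0 <= self.poor_quality_fraction <= 1.0):
            raise ValueError("poor_quality_fraction must lie in [0, 1]")
        for name in ("disc_offset", "disc_radius_frac", "macula_radius_frac", "border_bar_frac"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.n_images < 0 or self.vessel_count < 0:
            raise ValueError("counts must be nonnegative")
        for w, h in self.canvas_sizes:
            if w <= 0 or h <= 0:
                raise ValueError("canvas dimensions must be positive")
            if w < h:
                raise ValueError("canvas must be landscape (width >= height)")


@dataclass(frozen=True)
class ImageMeta:
    laterality: str
    obscured_fraction: float
    disc_visible_fraction: float
    canvas_size: tuple[int, int]
    disc_center: tuple[float, float]
    seed: int

    def __post_init__(self):
        if self.laterality not in (LEFT, RIGHT):
            raise ValueError(f"laterality must be {LEFT!r} or {RIGHT!r}")
        if not (0.0 <= self.obscured_fraction <= 1.0):
            raise ValueError("obscured_fraction must lie in [0, 1]")
        if not (0.0 <= self.disc_visible_fraction <= 1.0):
            raise ValueError("disc_visible_fraction must lie in [0, 1]")


@dataclass
class FundusImage:
    """8-bit RGB raster plus (optional) generator ground truth."""

    pixels: np.ndarray
    meta: ImageMeta | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 array")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit unsigned")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def disc_center_for(
    laterality: str, canvas_size: tuple[int, int], config: SynthConfig | None = None
) -> tuple[float, float]:
    """Ground-truth disc center (x, y) for a rendered image, without rendering.

    The disc sits on the horizontal midline, displaced ``disc_offset`` fundus
    radii toward the laterality side of the canvas center.
    """
    cfg = config or SynthConfig()
    w, h = int(canvas_size[0]), int(canvas_size[1])
    radius = min(w, h) / 2.0
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    dx = cx - cfg.disc_offset * radius
    if laterality == RIGHT:
        dx = (w - 1) - dx
    return (dx, cy)


def _stamp_disks(img: np.ndarray, centers: np.ndarray, radius: int, color: np.ndarray,
                 clip_mask: np.ndarray) -> None:
    """Paint filled disks at integer centers, restricted to clip_mask."""
    h, w = img.shape[:2]
    dy, dx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    offs = np.argwhere(dy**2 + dx**2 <= radius**2) - radius
    for cy, cx in centers:
        ys = offs[:, 0] + cy
        xs = offs[:, 1] + cx
        ok = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
        ys, xs = ys[ok], xs[ok]
        ok2 = clip_mask[ys, xs]
        img[ys[ok2], xs[ok2]] = color


def generate_image(
    seed: int,
    laterality: str,
    canvas_size: tuple[int, int],
    quality: str = "good",
    config: SynthConfig | None = None,
) -> tuple[FundusImage, ImageMeta]:
    """Render one synthetic fundus photograph.

    Deterministic in its arguments.  A right-eye image is the exact
    horizontal mirror of the left-eye image rendered from the same seed.
    """
    cfg = config or SynthConfig()
    w, h = int(canvas_size[0]), int(canvas_size[1])
    if w <= 0 or h <= 0:
        raise ValueError("canvas dimensions must be positive")
    if laterality not in (LEFT, RIGHT):
        raise ValueError(f"laterality must be {LEFT!r} or {RIGHT!r}")
    if quality not in ("good", "poor"):
        raise ValueError("quality must be 'good' or 'poor'")

    rng = np.random.default_rng(seed)
    # fundus circle spans the full canvas height, centered on the canvas
    radius = min(w, h) / 2.0
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0

    xs = np.arange(w, dtype=np.float32) - cx
    ys = np.arange(h, dtype=np.float32) - cy
    r2 = ys[:, None] ** 2 + xs[None, :] ** 2
    fundus = r2 <= radius**2

    img = np.zeros((h, w, 3), dtype=np.float32)
    img[fundus] = _FUNDUS_BASE

    # overexposed rim annulus
    rim = fundus & (r2 >= (_RIM_INNER_FRAC * radius) ** 2)
    img[rim] *= _RIM_GAIN

    # macula: smooth dark blob at the canvas center
    mac_r = cfg.macula_radius_frac * radius
    darken = 1.0 - 0.5 * np.exp(-r2 / (2.0 * mac_r**2))
    img *= darken[:, :, None]

    # optic disc: bright ellipse displaced toward the left for LEFT eyes
    disc_cx, disc_cy = disc_center_for(LEFT, (w, h), cfg)
    disc_a = cfg.disc_radius_frac * radius          # horizontal semi-axis
    disc_b = 1.15 * disc_a                          # slightly taller than wide
    disc = ((xs[None, :] - (disc_cx - cx)) / disc_a) ** 2 + (
        (ys[:, None] - (disc_cy - cy)) / disc_b
    ) ** 2 <= 1.0

    # vessel arcades: quadratic Bezier arcs from the disc toward the periphery
    thick = max(1, int(round(0.012 * radius)))
    n_samp = max(32, int(round(1.5 * radius)) // max(1, thick // 2 + 1) * 4)
    for _ in range(cfg.vessel_count):
        ang = rng.uniform(0, 2 * np.pi)
        end = np.array(
            [disc_cx + 0.9 * radius * np.cos(ang), disc_cy + 0.9 * radius * np.sin(ang)]
        )
        ctrl = np.array(
            [
                disc_cx + rng.uniform(0.2, 0.6) * radius * np.cos(ang + rng.uniform(-0.9, 0.9)),
                disc_cy + rng.uniform(0.2, 0.6) * radius * np.sin(ang + rng.uniform(-0.9, 0.9)),
            ]
        )
        start = np.array([disc_cx, disc_cy])
        t = np.linspace(0.0, 1.0, n_samp)[:, None]
        pts = (1 - t) ** 2 * start + 2 * t * (1 - t) * ctrl + t**2 * end
        centers = np.round(pts[:, ::-1]).astype(int)  # (y, x)
        _stamp_disks(img, centers, thick, _VESSEL_COLOR, fundus)

    img[disc] = _DISC_COLOR

    # pixel noise inside the fundus field
    idx = np.where(fundus)
    img[idx] += rng.normal(0.0, _NOISE_SIGMA, size=(idx[0].size, 3)).astype(np.float32)

    obscured_fraction = 0.0
    disc_visible_fraction = 1.0
    if quality == "poor":
        style = int(rng.integers(2))
        if style == 0:
            # black half-plane through (just past) the center: obscures > 50%
            side = 1 if rng.random() < 0.5 else -1
            occl = (side * (xs[None, :])) >= -0.1 * radius
            occl = np.broadcast_to(occl, (h, w))
        else:
            # strip over the disc: disc only partially visible
            occl = np.broadcast_to(xs[None, :] <= (disc_cx - cx), (h, w))
        img[occl] = 0.0
        n_fundus = int(fundus.sum())
        obscured_fraction = float((occl & fundus).sum() / n_fundus)
        disc_visible_fraction = float((disc & ~occl).sum() / max(1, int(disc.sum())))

    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    disc_center = (disc_cx, disc_cy)
    if laterality == RIGHT:
        pixels = pixels[:, ::-1].copy()
        disc_center = ((w - 1) - disc_cx, disc_cy)

    meta = ImageMeta(
        laterality=laterality,
        obscured_fraction=obscured_fraction,
        disc_visible_fraction=disc_visible_fraction,
        canvas_size=(w, h),
        disc_center=disc_center,
        seed=int(seed),
    )
    return FundusImage(pixels=pixels, meta=meta), meta


def mirror(image: FundusImage) -> FundusImage:
    """Horizontal reflection; swaps the laterality label when metadata is present."""
    pixels = image.pixels[:, ::-1].copy()
    meta = image.meta
    if meta is not None:
        w = image.width
        meta = dataclasses.replace(
            meta,
            laterality=RIGHT if meta.laterality == LEFT else LEFT,
            disc_center=((w - 1) - meta.disc_center[0], meta.disc_center[1]),
        )
    return FundusImage(pixels=pixels, meta=meta)


def is_poor_quality(meta: ImageMeta) -> bool:
    """Exclusion rule: >= 50% of the field obscured, or the disc only partly visible."""
    if meta.obscured_fraction is None or meta.disc_visible_fraction is None:
        raise ValueError("metadata quality fields are required")
    return meta.obscured_fraction >= 0.5 or meta.disc_visible_fraction < 1.0


def generate_dataset(config: SynthConfig, output: str | Path) -> pd.DataFrame:
    """Write ``n_images`` PNGs plus ``manifest.csv`` to ``output``; return the manifest.

    Class counts follow ``left_fraction`` within rounding; exactly
    ``round(poor_quality_fraction * n)`` images are rendered poor quality.
    Everything is a pure function of the config (per-image seeds derive from
    ``config.seed``).
    """
    out = Path(output)
    out.mkdir(parents=True, exist_ok=True)
    n = config.n_images
    rng = np.random.default_rng(config.seed)

    n_left = int(round(config.left_fraction * n))
    labels = np.array([LEFT] * n_left + [RIGHT] * (n - n_left))
    rng.shuffle(labels)
    n_poor = int(round(config.poor_quality_fraction * n))
    poor = np.zeros(n, dtype=bool)
    if n_poor:
        poor[rng.choice(n, size=n_poor, replace=False)] = True

    rows = []
    for i in range(n):
        canvas = config.canvas_sizes[i % len(config.canvas_sizes)]
        seed_i = (config.seed * 1_000_003 + i) % (2**31)
        quality = "poor" if poor[i] else "good"
        image, meta = generate_image(seed_i, labels[i], canvas, quality, config)
        fname = f"fundus_{i:05d}.png"
        Image.fromarray(image.pixels).save(out / fname)
        rows.append(
            {
                "filename": fname,
                "laterality": meta.laterality,
                "obscured_fraction": meta.obscured_fraction,
                "disc_visible_fraction": meta.disc_visible_fraction,
                "width": canvas[0],
                "height": canvas[1],
                "seed": seed_i,
            }
        )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def load_image(path: str | Path, meta: ImageMeta | None = None) -> FundusImage:
    """Read a PNG/JPEG as an 8-bit RGB :class:`FundusImage`."""
    with Image.open(path) as im:
        pixels = np.asarray(im.convert("RGB"), dtype=np.uint8)
    return FundusImage(pixels=pixels, meta=meta)
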