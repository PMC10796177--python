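"""Foreground gating and invertible sliding-window patch extraction.

The sliding window is ``n x n`` with stride ``n/2``.  Defaults follow the
pipeline contract: n = 700 / target 768 at 10x, n = 2800 / target 1024 at
40x.  Each extracted patch records a :class:`PatchTransform` so detections
can be mapped back to slide coordinates exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace

import numpy as np
from PIL import Image

from .slideio import Instance, SlideImage, polygon_bounds

__all__ = [
    "TileConfig",
    "PatchTransform",
    "luminance",
    "otsu_threshold",
    "foreground_mask",
    "plan_tiles",
    "extract_patch",
    "to_slide_coords",
    "to_patch_coords",
    "DEFAULT_TILE_CONFIGS",
]


@dataclass(frozen=True)
class TileConfig:
    """Window geometry for one magnification."""

    n: int = 700
    stride: int = 350
    target_size: int = 768
    pad_value: int = 255

    def __post_init__(self) -> None:
        if self.n < 2 or self.n % 2 != 0:
            raise ValueError("n must be an even integer >= 2")
        if self.stride * 2 != self.n:
            raise ValueError("stride must equal n / 2")
        if self.target_size < 1:
            raise ValueError("target_size must be >= 1")


#: Contract defaults per magnification.
DEFAULT_TILE_CONFIGS = {
    "10x": TileConfig(n=700, stride=350, target_size=768),
    "40x": TileConfig(n=2800, stride=1400, target_size=1024),
}


@dataclass(frozen=True)
class PatchTransform:
    """Exact record of crop origin, padding, and rescale for one patch.

    Patch coordinates relate to slide coordinates by
    ``x_patch = (x_slide - x0 + pad_left) * scale`` and the inverse
    ``x_slide = x_patch / scale - pad_left + x0`` (same for y).
    """

    x0: int
    y0: int
    n: int
    pad_left: int = 0
    pad_top: int = 0
    scale: float = 1.0
    valid_width: int = 0   # unpadded crop extent actually read from the slide
    valid_height: int = 0

    def to_slide(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        out = xy / self.scale
        out[..., 0] += self.x0 - self.pad_left
        out[..., 1] += self.y0 - self.pad_top
        return out

    def to_patch(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        out = xy.copy()
        out[..., 0] += self.pad_left - self.x0
        out[..., 1] += self.pad_top - self.y0
        return out * self.scale


# ---------------------------------------------------------------------------
# foreground gating
# ---------------------------------------------------------------------------

_LUMA = np.array([0.2125, 0.7154, 0.0721])


def luminance(pixels: np.ndarray) -> np.ndarray:
    """8-bit luminance raster (Rec. 709 weights, rounded)."""
    return np.round(np.asarray(pixels, dtype=float) @ _LUMA).astype(np.uint8)


def otsu_threshold(lum: np.ndarray) -> int | None:
    """Gray level maximizing between-class variance over all 256 cuts.

    Returns ``None`` when the histogram is single-valued (no foreground).
    Threshold ``t`` splits into background ``>= t`` vs foreground ``< t``.
    """
    hist = np.bincount(lum.ravel(), minlength=256).astype(float)
    total = hist.sum()
    w0 = np.cumsum(hist)            # weight of classes {0..t}
    mu = np.cumsum(hist * np.arange(256))
    mu_total = mu[-1]
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = mu / w0
        m1 = (mu_total - mu) / w1
        var_between = w0 * w1 * (m0 - m1) ** 2
    var_between = np.nan_to_num(var_between[:-1], nan=0.0)
    if var_between.max() <= 0.0:
        return None
    # threshold = first gray level above the optimal cut
    return int(var_between.argmax()) + 1


def foreground_mask(slide: SlideImage) -> np.ndarray:
    """Boolean tissue mask: luminance strictly below the Otsu threshold."""
    lum = luminance(slide.pixels)
    t = otsu_threshold(lum)
    if t is None:
        return np.zeros(lum.shape, dtype=bool)
    return lum < t


# ---------------------------------------------------------------------------
# tile planning and extraction
# ---------------------------------------------------------------------------


def _axis_origins(extent: int, config: TileConfig) -> list[int]:
    if extent <= config.n:
        return [0]
    origins = list(range(0, extent - config.n + 1, config.stride))
    if origins[-1] != extent - config.n:
        origins.append(extent - config.n)  # clamp so last tile ends at edge
    return origins


def plan_tiles(mask: np.ndarray, config: TileConfig) -> list[tuple[int, int]]:
    """Tile origins on the stride lattice whose window contains foreground.

    Every foreground pixel is covered by at least one kept tile; tiles with
    no foreground are dropped entirely.
    """
    mask = np.asarray(mask, dtype=bool)
    height, width = mask.shape
    origins = []
    # summed-area table for O(1) window occupancy queries
    integral = np.pad(np.cumsum(np.cumsum(mask, axis=0), axis=1), ((1, 0), (1, 0)))
    for y0 in _axis_origins(height, config):
        y1 = min(y0 + config.n, height)
        for x0 in _axis_origins(width, config):
            x1 = min(x0 + config.n, width)
            count = (integral[y1, x1] - integral[y0, x1]
                     - integral[y1, x0] + integral[y0, x0])
            if count > 0:
                origins.append((x0, y0))
    return origins


def extract_patch(
    slide: SlideImage, origin: tuple[int, int], config: TileConfig
) -> tuple[np.ndarray, PatchTransform]:
    """Crop, pad to ``n x n`` and bilinearly rescale to the target size."""
    x0, y0 = origin
    height, width = slide.shape
    valid_x = x0 in _axis_origins(width, config)
    valid_y = y0 in _axis_origins(height, config)
    if not (valid_x and valid_y):
        raise ValueError(f"origin {origin} is not on the tile lattice")
    crop = slide.pixels[y0:y0 + config.n, x0:x0 + config.n]
    ch, cw = crop.shape[:2]
    if (ch, cw) != (config.n, config.n):
        padded = np.full((config.n, config.n, 3), config.pad_value,
                         dtype=slide.pixels.dtype)
        padded[:ch, :cw] = crop
        crop = padded
    scale = config.target_size / config.n
    if config.target_size == config.n:
        patch = crop.copy()
    else:
        # PIL's bilinear resampler; grid alignment x_target = x_source * s
        image = Image.fromarray(np.ascontiguousarray(crop))
        patch = np.asarray(image.resize(
            (config.target_size, config.target_size), Image.BILINEAR))
    transform = PatchTransform(x0=x0, y0=y0, n=config.n, pad_left=0,
                               pad_top=0, scale=scale,
                               valid_width=cw, valid_height=ch)
    return patch, transform


def to_slide_coords(instance: Instance, transform: PatchTransform) -> Instance:
    """Map a patch-space instance back to slide coordinates."""
    poly = transform.to_slide(np.asarray(instance.polygon, dtype=float))
    return dc_replace(instance, polygon=poly, bbox=polygon_bounds(poly))


def to_patch_coords(instance: Instance, transform: PatchTransform) -> Instance:
    """Map a slide-space instance into patch coordinates."""
    poly = transform.to_patch(np.asarray(instance.polygon, dtype=float))
    return dc_replace(instance, polygon=poly, bbox=polygon_bounds(poly))
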