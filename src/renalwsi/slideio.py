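"""Core data model and I/O: slides, instance annotations, GeoJSON interchange.

Coordinate conventions shared by every module:

* All coordinates are 0-based pixel indices, ``x`` rightward, ``y`` downward.
* A pixel with index ``(x, y)`` covers the continuous square
  ``[x, x+1) x [y, y+1)``; its center is at ``(x + 0.5, y + 0.5)``.
* A bounding box ``(x, y, w, h)`` covers the half-open range
  ``[x, x+w) x [y, y+h)`` and is always the tight axis-aligned bound of the
  instance polygon.
* Rasterization uses pixel-center inclusion: a pixel is inside a polygon iff
  its center is.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from shapely import intersects_xy, prepare
from shapely.geometry import Polygon as ShapelyPolygon
from skimage import measure
import tifffile

__all__ = [
    "ALLOWED_LABELS",
    "STRUCTURE_LABELS",
    "GLOMERULUS_LABELS",
    "MPP_BY_MAGNIFICATION",
    "SlideImage",
    "Instance",
    "AnnotationSet",
    "read_annotations",
    "write_annotations",
    "polygon_bounds",
    "polygon_to_mask",
    "mask_to_polygon",
    "read_slide_image",
    "write_slide_image",
]

#: The nine instance labels understood by every stage of the pipeline.
ALLOWED_LABELS = (
    "artery",
    "distal_tubule",
    "proximal_tubule",
    "glomerulus_crescent",
    "glomerulus_no_crescent",
    "glomerular_tuft",
    "mesangial_hyper",
    "endocap_hyper",
    "nucleus",
)

#: Kidney-structure labels detected on H&E at 10x.
STRUCTURE_LABELS = (
    "artery",
    "distal_tubule",
    "proximal_tubule",
    "glomerulus_crescent",
    "glomerulus_no_crescent",
    "glomerular_tuft",
)

GLOMERULUS_LABELS = ("glomerulus_crescent", "glomerulus_no_crescent")

#: Microns per pixel at each supported magnification.
MPP_BY_MAGNIFICATION = {"10x": 1.0, "40x": 0.25}


def polygon_bounds(polygon: np.ndarray) -> tuple[float, float, float, float]:
    """Tight axis-aligned ``(x, y, w, h)`` bounds of a polygon vertex array."""
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise ValueError("polygon must be an (N, 2) array with N >= 3")
    x0, y0 = poly.min(axis=0)
    x1, y1 = poly.max(axis=0)
    return (float(x0), float(y0), float(x1 - x0), float(y1 - y0))


@dataclass(frozen=True)
class SlideImage:
    """A single-resolution RGB slide raster with physical pixel size."""

    pixels: np.ndarray
    stain: str
    magnification: str
    mpp: float
    slide_id: str

    def __post_init__(self) -> None:
        if self.stain not in ("HE", "PAS"):
            raise ValueError(f"stain must be 'HE' or 'PAS', got {self.stain!r}")
        if self.magnification not in MPP_BY_MAGNIFICATION:
            raise ValueError(
                f"magnification must be one of {sorted(MPP_BY_MAGNIFICATION)}, "
                f"got {self.magnification!r}"
            )
        expected = MPP_BY_MAGNIFICATION[self.magnification]
        if abs(self.mpp - expected) > 1e-9:
            raise ValueError(
                f"mpp {self.mpp} inconsistent with magnification "
                f"{self.magnification} (expected {expected})"
            )
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("pixels must be an HxWx3 raster with H, W >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) in pixels."""
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class Instance:
    """One annotated or detected object in a fixed slide coordinate space.

    ``score`` is ``None`` for ground truth; detections carry a score in
    ``(0, 1]``.  ``bbox`` is derived from the polygon and is always tight.
    """

    label: str
    polygon: np.ndarray
    bbox: tuple[float, float, float, float]
    score: float | None = None
    slide_id: str = ""
    magnification: str = "10x"

    def __post_init__(self) -> None:
        if self.label not in ALLOWED_LABELS:
            raise ValueError(
                f"unknown label {self.label!r}; allowed labels are "
                f"{list(ALLOWED_LABELS)}"
            )
        x, y, w, h = self.bbox
        if w <= 0 or h <= 0:
            raise ValueError(f"bbox must have positive extent, got {self.bbox}")
        if self.score is not None and not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score must lie in [0, 1], got {self.score}")

    @classmethod
    def from_polygon(
        cls,
        label: str,
        polygon: np.ndarray,
        score: float | None = None,
        slide_id: str = "",
        magnification: str = "10x",
    ) -> "Instance":
        poly = np.asarray(polygon, dtype=float)
        return cls(
            label=label,
            polygon=poly,
            bbox=polygon_bounds(poly),
            score=score,
            slide_id=slide_id,
            magnification=magnification,
        )

    def scaled(self, factor: float) -> "Instance":
        """Return a copy with all coordinates multiplied by ``factor``."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        poly = np.asarray(self.polygon, dtype=float) * factor
        return replace(self, polygon=poly, bbox=polygon_bounds(poly))

    def centroid(self) -> tuple[float, float]:
        """Area centroid of the polygon (shoelace-weighted)."""
        c = ShapelyPolygon(np.asarray(self.polygon, dtype=float)).centroid
        return (c.x, c.y)


@dataclass
class AnnotationSet:
    """A bag of instances sharing one (slide, magnification, stain) space."""

    instances: list[Instance] = field(default_factory=list)
    slide_id: str = ""
    magnification: str = "10x"
    stain: str = "HE"

    def __post_init__(self) -> None:
        for inst in self.instances:
            if inst.slide_id and inst.slide_id != self.slide_id:
                raise ValueError(
                    f"instance slide_id {inst.slide_id!r} does not match set "
                    f"space {self.slide_id!r}"
                )
            if inst.magnification != self.magnification:
                raise ValueError(
                    f"instance magnification {inst.magnification!r} does not "
                    f"match set space {self.magnification!r}"
                )

    def __len__(self) -> int:
        return len(self.instances)

    def by_label(self, label: str) -> list[Instance]:
        return [i for i in self.instances if i.label == label]


# ---------------------------------------------------------------------------
# GeoJSON interchange
# ---------------------------------------------------------------------------


def write_annotations(annotations: AnnotationSet, path: str | Path) -> None:
    """Serialize an :class:`AnnotationSet` to a GeoJSON FeatureCollection."""
    features = []
    for inst in annotations.instances:
        ring = np.asarray(inst.polygon, dtype=float)
        coords = ring.tolist()
        if coords[0] != coords[-1]:
            coords.append(coords[0])  # GeoJSON rings are explicitly closed
        props: dict = {
            "label": inst.label,
            "magnification": inst.magnification,
            "slide_id": inst.slide_id or annotations.slide_id,
        }
        if inst.score is not None:
            props["score"] = float(inst.score)
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [coords]},
                "properties": props,
            }
        )
    doc = {
        "type": "FeatureCollection",
        "properties": {
            "slide_id": annotations.slide_id,
            "magnification": annotations.magnification,
            "stain": annotations.stain,
        },
        "features": features,
    }
    Path(path).write_text(json.dumps(doc))


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read a GeoJSON FeatureCollection written by :func:`write_annotations`.

    Unknown labels and non-polygon geometries are rejected with a message
    naming the offending value.
    """
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValueError("annotation file must be a GeoJSON FeatureCollection")
    meta = doc.get("properties", {})
    instances = []
    for feat in doc.get("features", []):
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon":
            raise ValueError(
                f"only Polygon geometries are supported, got {geom.get('type')!r}"
            )
        props = feat.get("properties", {})
        label = props.get("label")
        if label not in ALLOWED_LABELS:
            raise ValueError(
                f"unknown label {label!r}; allowed labels are {list(ALLOWED_LABELS)}"
            )
        ring = np.asarray(geom["coordinates"][0], dtype=float)
        if len(ring) >= 2 and np.allclose(ring[0], ring[-1]):
            ring = ring[:-1]  # drop the closing vertex
        instances.append(
            Instance.from_polygon(
                label=label,
                polygon=ring,
                score=props.get("score"),
                slide_id=props.get("slide_id", meta.get("slide_id", "")),
                magnification=props.get(
                    "magnification", meta.get("magnification", "10x")
                ),
            )
        )
    return AnnotationSet(
        instances=instances,
        slide_id=meta.get("slide_id", ""),
        magnification=meta.get("magnification", "10x"),
        stain=meta.get("stain", "HE"),
    )


# ---------------------------------------------------------------------------
# Polygon <-> mask
# ---------------------------------------------------------------------------


def _rasterize_window(
    polygon: np.ndarray,
) -> tuple[int, int, np.ndarray]:
    """Rasterize a polygon within its bounding window.

    Returns ``(col0, row0, submask)`` where ``submask[r, c]`` is True iff the
    center of pixel ``(col0 + c, row0 + r)`` lies in the polygon's closure.
    """
    poly = np.asarray(polygon, dtype=float)
    x0, y0, w, h = polygon_bounds(poly)
    cx0, cy0 = int(np.floor(x0)), int(np.floor(y0))
    cx1, cy1 = int(np.ceil(x0 + w)), int(np.ceil(y0 + h))
    xs = np.arange(cx0, cx1) + 0.5
    ys = np.arange(cy0, cy1) + 0.5
    gx, gy = np.meshgrid(xs, ys)
    shape = ShapelyPolygon(poly)
    prepare(shape)
    inside = intersects_xy(shape, gx.ravel(), gy.ravel())  # closure inclusion
    return cx0, cy0, inside.reshape(gy.shape)


def polygon_to_mask(
    polygon: np.ndarray, extent: tuple[int, int]
) -> np.ndarray:
    """Rasterize a polygon into a boolean ``(height, width)`` mask.

    A pixel is on iff its center ``(x + 0.5, y + 0.5)`` lies inside the
    polygon (boundary centers count as inside).
    """
    height, width = extent
    poly = np.asarray(polygon, dtype=float)
    x0, y0, w, h = polygon_bounds(poly)
    if x0 < 0 or y0 < 0 or x0 + w > width or y0 + h > height:
        raise ValueError(
            f"polygon bounds ({x0}, {y0}, {w}, {h}) exceed raster extent "
            f"{extent}"
        )
    mask = np.zeros((height, width), dtype=bool)
    cx0, cy0, sub = _rasterize_window(poly)
    mask[cy0:cy0 + sub.shape[0], cx0:cx0 + sub.shape[1]] = sub
    return mask


def mask_to_polygon(mask: np.ndarray) -> np.ndarray:
    """Trace the largest connected region of a boolean mask as a polygon.

    The contour runs along the midlines between on and off pixel centers and
    is shifted by +0.5 so that re-rasterizing with pixel-center inclusion is
    idempotent for axis-aligned shapes.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    contour = max(contours, key=len)
    # (row, col) in padded frame -> (x, y) continuous slide frame
    poly = np.column_stack([contour[:, 1], contour[:, 0]]) - 1.0 + 0.5
    if np.allclose(poly[0], poly[-1]):
        poly = poly[:-1]
    return poly


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill interior holes of a boolean mask (e.g. tubule lumens)."""
    return ndimage.binary_fill_holes(np.asarray(mask, dtype=bool))


# ---------------------------------------------------------------------------
# Raster I/O
# ---------------------------------------------------------------------------


def write_slide_image(slide: SlideImage, path: str | Path) -> None:
    """Write a slide raster as TIFF or PNG depending on the suffix."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, slide.pixels)
    else:
        Image.fromarray(slide.pixels).save(path)


def read_slide_image(
    path: str | Path, stain: str, magnification: str, slide_id: str = ""
) -> SlideImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
    else:
        pixels = np.asarray(Image.open(path).convert("RGB"))
    return SlideImage(
        pixels=pixels,
        stain=stain,
        magnification=magnification,
        mpp=MPP_BY_MAGNIFICATION[magnification],
        slide_id=slide_id or path.stem,
    )
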