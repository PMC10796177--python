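"""Morphometric and hypercellularity quantification.

Pixel geometry is converted to physical units through the microns-per-pixel
of the instance's coordinate space.  Definitions:

* ``area`` — signed polygon (shoelace) area, in um^2.
* ``perimeter`` — polygon boundary length, in um.
* ``roundness`` — isoperimetric ratio ``4*pi*A / P^2`` (1 for a disk).
* ``major_axis_length`` — major axis of the second-moment-equivalent
  ellipse (``4 * sqrt(lambda_max)`` of the polygon covariance), in um.
* hypercellularity — a glomerulus is mesangial-hypercellular when >= 4
  nucleus centroids fall inside one of its detected mesangial regions, and
  endocapillary-hypercellular when >= 2 fall inside an endocapillary region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.geometry import Polygon as ShapelyPolygon

from .slideio import GLOMERULUS_LABELS, Instance
from .fuse import WholeSlideResult

__all__ = [
    "MorphometricRecord",
    "MESANGIAL_MIN_NUCLEI",
    "ENDOCAP_MIN_NUCLEI",
    "AGE_BINS",
    "polygon_moments",
    "morphometry",
    "count_glomeruli",
    "hypercellularity_flags",
    "age_group",
    "morphometry_table",
    "cohort_table",
]

#: Operational hypercellularity thresholds (nucleus centroids per region).
MESANGIAL_MIN_NUCLEI = 4
ENDOCAP_MIN_NUCLEI = 2

#: Cohort age bins (inclusive bounds).
AGE_BINS = (("1-5", 1, 5), ("6-10", 6, 10), ("11-15", 11, 15),
            ("16-20", 16, 20))


@dataclass(frozen=True)
class MorphometricRecord:
    label: str
    area_um2: float
    perimeter_um: float
    major_axis_um: float
    roundness: float
    equivalent_diameter_um: float
    nuclei_count: int | None = None
    crescent: bool | None = None
    mesangial_hyper: bool | None = None
    endocap_hyper: bool | None = None


def polygon_moments(polygon: np.ndarray) -> tuple[float, tuple[float, float],
                                                  np.ndarray]:
    """Exact area, centroid and central covariance of a simple polygon.

    Green's-theorem closed forms; the covariance matches the normalized
    second central moments of the uniformly filled region.
    """
    poly = np.asarray(polygon, dtype=float)
    x, y = poly[:, 0], poly[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = 0.5 * cross.sum()
    if area == 0:
        raise ValueError("degenerate polygon with zero area")
    cx = ((x + x1) * cross).sum() / (6.0 * area)
    cy = ((y + y1) * cross).sum() / (6.0 * area)
    mxx = ((x * x + x * x1 + x1 * x1) * cross).sum() / 12.0
    myy = ((y * y + y * y1 + y1 * y1) * cross).sum() / 12.0
    mxy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / 24.0
    cov = np.array([
        [mxx / area - cx * cx, mxy / area - cx * cy],
        [mxy / area - cx * cy, myy / area - cy * cy],
    ])
    return abs(area), (cx, cy), cov


def morphometry(instance: Instance, mpp: float) -> MorphometricRecord:
    """Compute the per-instance morphometric record in physical units."""
    if mpp <= 0:
        raise ValueError("mpp must be positive")
    area_px, _centroid, cov = polygon_moments(instance.polygon)
    shape = ShapelyPolygon(np.asarray(instance.polygon, dtype=float))
    perimeter_px = shape.exterior.length
    eigvals = np.linalg.eigvalsh(cov)
    major_px = 4.0 * math.sqrt(max(eigvals[-1], 0.0))
    area = area_px * mpp * mpp
    perimeter = perimeter_px * mpp
    roundness = 4.0 * math.pi * area / (perimeter * perimeter)
    return MorphometricRecord(
        label=instance.label,
        area_um2=area,
        perimeter_um=perimeter,
        major_axis_um=major_px * mpp,
        roundness=roundness,
        equivalent_diameter_um=2.0 * math.sqrt(area / math.pi),
        crescent=(instance.label == "glomerulus_crescent"
                  if instance.label in GLOMERULUS_LABELS else None),
    )


def count_glomeruli(result: WholeSlideResult) -> int:
    """Number of detected glomeruli (with or without crescent)."""
    return len(result.glomeruli())


def hypercellularity_flags(
    glomerulus: Instance,
    nuclei: list[Instance],
    regions: list[Instance],
) -> tuple[bool, bool]:
    """(mesangial, endocapillary) flags for one glomerulus.

    ``glomerulus`` and ``nuclei`` are in 10x space, ``regions`` in 40x space;
    nucleus centroids are multiplied by 4 before the containment test.
    Regions not belonging to this glomerulus (centroid outside its polygon,
    tested at 40x) are ignored.
    """
    glom40 = ShapelyPolygon(np.asarray(glomerulus.polygon, dtype=float) * 4.0)
    centroids40 = [tuple(4.0 * c for c in n.centroid()) for n in nuclei]
    counts = {"mesangial_hyper": 0, "endocap_hyper": 0}
    for region in regions:
        shape = ShapelyPolygon(np.asarray(region.polygon, dtype=float))
        if not contains_xy(glom40, shape.centroid.x, shape.centroid.y):
            continue
        inside = sum(bool(contains_xy(shape, cx, cy))
                     for (cx, cy) in centroids40)
        counts[region.label] = max(counts[region.label], inside)
    return (counts["mesangial_hyper"] >= MESANGIAL_MIN_NUCLEI,
            counts["endocap_hyper"] >= ENDOCAP_MIN_NUCLEI)


def age_group(age: int) -> str:
    for (name, lo, hi) in AGE_BINS:
        if lo <= age <= hi:
            return name
    raise ValueError(f"age {age} outside the supported bins 1-20")


def morphometry_table(result: WholeSlideResult, mpp_10x: float = 1.0) -> pd.DataFrame:
    """Per-instance morphometry for all structures of one assembled slide.

    Glomerulus rows carry nuclei counts of their tuft (nuclei assigned by
    centroid containment) and hypercellularity flags from the detected PAS
    regions.
    """
    # nuclei per structure index
    nuclei_by_structure: dict[int, list[Instance]] = {}
    for nucleus, assigned in zip(result.nuclei, result.nucleus_assignment):
        if assigned is not None:
            nuclei_by_structure.setdefault(assigned, []).append(nucleus)

    # map each tuft to its enclosing glomerulus (centroid containment)
    glom_indices = [i for i, s in enumerate(result.structures)
                    if s.label in GLOMERULUS_LABELS]
    glom_shapes = {i: ShapelyPolygon(np.asarray(result.structures[i].polygon))
                   for i in glom_indices}

    rows = []
    for i, inst in enumerate(result.structures):
        record = morphometry(inst, mpp=mpp_10x)
        nuclei_count = len(nuclei_by_structure.get(i, []))
        mes = endo = None
        if inst.label in GLOMERULUS_LABELS:
            # count tuft nuclei: nuclei assigned to any tuft whose centroid
            # lies inside this glomerulus
            tuft_nuclei = []
            for j, s in enumerate(result.structures):
                if s.label != "glomerular_tuft":
                    continue
                cx, cy = s.centroid()
                if contains_xy(glom_shapes[i], cx, cy):
                    tuft_nuclei.extend(nuclei_by_structure.get(j, []))
            nuclei_count = len(tuft_nuclei)
            mes, endo = hypercellularity_flags(
                inst, tuft_nuclei, result.hyper_regions)
        rows.append({
            "slide_id": result.slide_id,
            "index": i,
            "label": inst.label,
            "area_um2": record.area_um2,
            "perimeter_um": record.perimeter_um,
            "major_axis_um": record.major_axis_um,
            "roundness": record.roundness,
            "equivalent_diameter_um": record.equivalent_diameter_um,
            "nuclei_count": nuclei_count,
            "crescent": record.crescent,
            "mesangial_hyper": mes,
            "endocap_hyper": endo,
        })
    return pd.DataFrame(rows)


def cohort_table(
    results: list[WholeSlideResult],
    metadata: pd.DataFrame,
    mpp_10x: float = 1.0,
) -> pd.DataFrame:
    """One row per slide: glomerulus count and mean area joined to metadata.

    ``metadata`` must contain ``slide_id``, ``age``, ``sex`` and
    ``diagnosis`` columns and cover every assembled slide.
    """
    meta = metadata.set_index("slide_id")
    rows = []
    for result in results:
        if result.slide_id not in meta.index:
            raise ValueError(
                f"metadata has no row for slide_id {result.slide_id!r}"
            )
        info = meta.loc[result.slide_id]
        gloms = result.glomeruli()
        areas = [morphometry(g, mpp=mpp_10x).area_um2 for g in gloms]
        rows.append({
            "slide_id": result.slide_id,
            "glomerulus_count": len(gloms),
            "mean_glomerular_area_um2": float(np.mean(areas)) if areas
            else float("nan"),
            "age": int(info["age"]),
            "age_group": age_group(int(info["age"])),
            "sex": info["sex"],
            "diagnosis": info["diagnosis"],
        })
    return pd.DataFrame(rows)
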