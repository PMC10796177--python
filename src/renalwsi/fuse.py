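"""Whole-slide fusion: coordinate mapping, per-class NMS, nuclei integration.

Per-tile detections are mapped to slide coordinates through their
:class:`~renalwsi.tiler.PatchTransform`, deduplicated with greedy per-class
non-maximum suppression at IoU 0.5, nuclei are rescaled from 40x to 10x by a
factor of 1/4 and assigned to structures by centroid containment (tuft takes
precedence over the enclosing glomerulus), and glomerulus boxes are
transferred to the 40x PAS slide by multiplying coordinates by 4.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from shapely import contains_xy
from shapely.geometry import Polygon as ShapelyPolygon

from .slideio import GLOMERULUS_LABELS, Instance, SlideImage
from .tiler import (
    DEFAULT_TILE_CONFIGS,
    PatchTransform,
    TileConfig,
    extract_patch,
    foreground_mask,
    plan_tiles,
    to_slide_coords,
)

__all__ = [
    "FuseConfig",
    "WholeSlideResult",
    "iou",
    "nms",
    "rescale_instances",
    "assemble_slide",
    "transfer_to_pas",
    "run_pipeline",
]


@dataclass(frozen=True)
class FuseConfig:
    """Fusion parameters; NMS for nuclei runs at 40x before rescaling."""

    iou_threshold: float = 0.5
    score_threshold: float = 0.05


@dataclass
class WholeSlideResult:
    """Assembled per-slide detections across all coordinate spaces."""

    slide_id: str
    structures: list[Instance] = field(default_factory=list)  # 10x space
    nuclei: list[Instance] = field(default_factory=list)      # 10x space
    nuclei_40x: list[Instance] = field(default_factory=list)
    hyper_regions: list[Instance] = field(default_factory=list)  # 40x space
    #: per-nucleus index into ``structures`` or None (interstitial)
    nucleus_assignment: list[int | None] = field(default_factory=list)

    def glomeruli(self) -> list[Instance]:
        return [s for s in self.structures if s.label in GLOMERULUS_LABELS]

    def by_label(self, label: str) -> list[Instance]:
        pool = self.hyper_regions if label.endswith("_hyper") else (
            self.nuclei_40x if label == "nucleus" else self.structures)
        return [i for i in pool if i.label == label]


# ---------------------------------------------------------------------------
# box arithmetic
# ---------------------------------------------------------------------------


def iou(box_a: tuple[float, float, float, float],
        box_b: tuple[float, float, float, float]) -> float:
    """Intersection-over-union of two half-open ``(x, y, w, h)`` boxes."""
    ax, ay, aw, ah = box_a
    bx, by, bw, bh = box_b
    if aw <= 0 or ah <= 0 or bw <= 0 or bh <= 0:
        raise ValueError("boxes must have positive width and height")
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union


def nms(instances: list[Instance], iou_threshold: float = 0.5) -> list[Instance]:
    """Greedy non-maximum suppression over same-class scored instances.

    Sort by score descending (ties: larger box area first, then input
    order); keep the head and suppress everything with IoU strictly greater
    than the threshold against a kept box.
    """
    if not instances:
        return []
    labels = {i.label for i in instances}
    if len(labels) > 1:
        raise ValueError(f"nms expects a single class, got {sorted(labels)}")
    for inst in instances:
        if inst.score is None:
            raise ValueError("all instances must carry a score for NMS")
    order = sorted(
        range(len(instances)),
        key=lambda i: (-instances[i].score,
                       -(instances[i].bbox[2] * instances[i].bbox[3]), i),
    )
    kept: list[int] = []
    for i in order:
        if all(iou(instances[i].bbox, instances[j].bbox) <= iou_threshold
               for j in kept):
            kept.append(i)
    return [instances[i] for i in sorted(kept)]


def rescale_instances(instances: list[Instance], factor: float,
                      magnification: str | None = None) -> list[Instance]:
    """Multiply all coordinates by ``factor`` (areas scale by ``factor**2``)."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    out = [inst.scaled(factor) for inst in instances]
    if magnification is not None:
        out = [replace(i, magnification=magnification) for i in out]
    return out


def transfer_to_pas(
    glomeruli: list[Instance],
) -> list[tuple[float, float, float, float]]:
    """10x glomerulus boxes -> 40x PAS boxes: (x, y, w, h) multiplied by 4."""
    return [tuple(4.0 * v for v in inst.bbox) for inst in glomeruli]


# ---------------------------------------------------------------------------
# whole-slide assembly
# ---------------------------------------------------------------------------


def _nms_per_class(instances: list[Instance], threshold: float) -> list[Instance]:
    out: list[Instance] = []
    for label in sorted({i.label for i in instances}):
        out.extend(nms([i for i in instances if i.label == label], threshold))
    return out


def _check_space(instances, slide_id):
    for inst in instances:
        if inst.slide_id and inst.slide_id != slide_id:
            raise ValueError(
                f"instance from slide {inst.slide_id!r} cannot be assembled "
                f"into {slide_id!r}"
            )


def assign_nuclei(structures: list[Instance],
                  nuclei: list[Instance]) -> list[int | None]:
    """Assign each nucleus to the structure containing its centroid.

    Tuft polygons are tried before all other structures so nuclei in a tuft
    are not claimed by the enclosing glomerulus.  Unassigned nuclei map to
    ``None`` (interstitial).
    """
    order = sorted(
        range(len(structures)),
        key=lambda i: 0 if structures[i].label == "glomerular_tuft" else 1,
    )
    shapes = [ShapelyPolygon(np.asarray(structures[i].polygon)) for i in order]
    assignment: list[int | None] = []
    for nucleus in nuclei:
        cx, cy = nucleus.centroid()
        hit = None
        for pos, shape in enumerate(shapes):
            if contains_xy(shape, cx, cy):
                hit = order[pos]
                break
        assignment.append(hit)
    return assignment


def assemble_slide(
    slide_id: str,
    structure_tiles: list[tuple[list[Instance], PatchTransform]],
    nucleus_tiles: list[tuple[list[Instance], PatchTransform]] = (),
    hyper_instances: list[Instance] = (),
    config: FuseConfig = FuseConfig(),
) -> WholeSlideResult:
    """Fuse per-tile detections into one :class:`WholeSlideResult`.

    Steps: map tile instances to slide coordinates; per-class NMS at the IoU
    threshold; NMS nuclei at 40x then rescale by 1/4; assign each nucleus to
    the structure containing its centroid.
    """
    structures: list[Instance] = []
    for instances, transform in structure_tiles:
        _check_space(instances, slide_id)
        for inst in instances:
            if inst.score is not None and inst.score < config.score_threshold:
                continue
            mapped = to_slide_coords(inst, transform)
            structures.append(replace(mapped, slide_id=slide_id,
                                      magnification="10x"))
    structures = _nms_per_class(structures, config.iou_threshold)

    nuclei_40x: list[Instance] = []
    for instances, transform in nucleus_tiles:
        _check_space(instances, slide_id)
        for inst in instances:
            if inst.score is not None and inst.score < config.score_threshold:
                continue
            mapped = to_slide_coords(inst, transform)
            nuclei_40x.append(replace(mapped, slide_id=slide_id,
                                      magnification="40x"))
    nuclei_40x = _nms_per_class(nuclei_40x, config.iou_threshold)
    nuclei_10x = rescale_instances(nuclei_40x, 0.25, magnification="10x")

    hyper = _nms_per_class(
        [replace(i, slide_id=slide_id, magnification="40x")
         for i in hyper_instances],
        config.iou_threshold)

    return WholeSlideResult(
        slide_id=slide_id,
        structures=structures,
        nuclei=nuclei_10x,
        nuclei_40x=nuclei_40x,
        hyper_regions=hyper,
        nucleus_assignment=assign_nuclei(structures, nuclei_10x),
    )


# ---------------------------------------------------------------------------
# end-to-end pipeline
# ---------------------------------------------------------------------------


def _segment_slide(slide: SlideImage, backend, tile_config: TileConfig):
    from .segment import segment_patch

    mask = foreground_mask(slide)
    tiles = []
    for origin in plan_tiles(mask, tile_config):
        patch, transform = extract_patch(slide, origin, tile_config)
        valid = (int(np.ceil(transform.valid_height * transform.scale)),
                 int(np.ceil(transform.valid_width * transform.scale)))
        instances = segment_patch(patch, slide.stain, slide.magnification,
                                  backend, valid=valid)
        tiles.append((instances, transform))
    return tiles


def run_pipeline(
    he10: SlideImage,
    he40: SlideImage,
    pas40: SlideImage | None = None,
    *,
    structure_backend=None,
    nucleus_backend=None,
    pas_backend=None,
    crescent_classifier=None,
    tile_config_10x: TileConfig | None = None,
    tile_config_40x: TileConfig | None = None,
    fuse_config: FuseConfig = FuseConfig(),
) -> WholeSlideResult:
    """Tile -> segment -> assemble a slide triple with pluggable backends.

    Glomerulus labels from the structure backend are overridden by the
    crescent classifier; PAS hypercellularity regions are segmented inside
    transferred (x4) glomerulus boxes.
    """
    from .segment import (
        ReferenceNucleusBackend,
        ReferencePASBackend,
        ReferenceStructureBackend,
        classify_crescent,
        crop_for_classification,
    )

    structure_backend = structure_backend or ReferenceStructureBackend()
    nucleus_backend = nucleus_backend or ReferenceNucleusBackend()
    pas_backend = pas_backend or ReferencePASBackend()
    tile10 = tile_config_10x or DEFAULT_TILE_CONFIGS["10x"]
    tile40 = tile_config_40x or DEFAULT_TILE_CONFIGS["40x"]

    structure_tiles = _segment_slide(he10, structure_backend, tile10)
    nucleus_tiles = _segment_slide(he40, nucleus_backend, tile40)

    # PAS hypercellularity inside transferred glomerulus boxes
    hyper: list[Instance] = []
    interim = assemble_slide("", structure_tiles, nucleus_tiles,
                             config=fuse_config)
    if pas40 is not None:
        from .segment import segment_patch

        height40, width40 = pas40.shape
        for box in transfer_to_pas(interim.glomeruli()):
            x0 = max(int(np.floor(box[0])), 0)
            y0 = max(int(np.floor(box[1])), 0)
            x1 = min(int(np.ceil(box[0] + box[2])), width40)
            y1 = min(int(np.ceil(box[1] + box[3])), height40)
            if x1 <= x0 or y1 <= y0:
                continue
            crop = pas40.pixels[y0:y1, x0:x1]
            for inst in segment_patch(crop, "PAS", "40x", pas_backend):
                poly = np.asarray(inst.polygon) + (x0, y0)
                hyper.append(Instance.from_polygon(
                    inst.label, poly, score=inst.score,
                    magnification="40x"))

    result = assemble_slide(he10.slide_id, structure_tiles, nucleus_tiles,
                            hyper_instances=hyper, config=fuse_config)

    # crescent classification overrides the structure backend's glom label
    relabeled = []
    for inst in result.structures:
        if inst.label in GLOMERULUS_LABELS:
            crop = crop_for_classification(he10, inst)
            call = classify_crescent(crop, crescent_classifier)
            label = ("glomerulus_crescent" if call.label == "crescentic"
                     else "glomerulus_no_crescent")
            inst = replace(inst, label=label)
        relabeled.append(inst)
    result.structures = relabeled
    return result
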