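"""Synthetic paired pseudo-histology slides with exhaustive ground truth.

A generated "slide triple" consists of an H&E raster at 10x (1 um/pixel), an
H&E raster at 40x (0.25 um/pixel) and a PAS raster at 40x, all rendering the
same planted scene.  Geometry is generated on the 40x integer pixel grid and
divided by 4 for the 10x representation, so cross-magnification coordinate
checks are exact.

Every structure class is rendered with a fixed, documented flat RGB color
(:data:`PALETTE`), which is what makes the deterministic reference
segmentation backend possible:

==================  =================  =========================================
class               color              shape
==================  =================  =========================================
tissue              (210, 160, 185)    single irregular connected polygon
glomerulus          (159, 164, 250)    disk (Bowman space) with inner tuft
glomerular tuft     (128, 88, 173)     concentric disk, 0.62 x glomerulus radius
crescent            (120, 60, 60)      partial annulus between tuft and capsule
proximal tubule     (250, 87, 91)      thick-walled ring (lumen = tissue color)
distal tubule       (225, 180, 80)     thin-walled ring
artery              (205, 20, 141)     very thick concentric ring
nucleus (40x H&E)   (40, 40, 120)      small dark ellipse
mesangial region    (170, 40, 170)     hue-shifted blob inside tuft (PAS only)
endocapillary       (60, 150, 70)      hue-shifted blob inside tuft (PAS only)
==================  =================  =========================================

Background is white (255).  Nuclei are drawn only on the 40x H&E raster;
hypercellularity blobs only on the 40x PAS raster.  The palette was chosen
so that bilinear blends of every pair of colors that can touch in a rendered
H&E scene stay at Euclidean RGB distance >= 80 from every third color whose
misassignment could change a detection, which is what makes nearest-color
classification in the reference backends immune to resampling artifacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from .slideio import (
    MPP_BY_MAGNIFICATION,
    Instance,
    SlideImage,
    _rasterize_window,
)

__all__ = [
    "PALETTE",
    "SynthConfig",
    "CohortSpec",
    "GlomerulusRecord",
    "GroundTruth",
    "generate_slide_pair",
    "generate_cohort",
]

#: Fixed color signatures (RGB, 8-bit) keyed by scene element.
PALETTE = {
    "background": (255, 255, 255),
    "tissue": (210, 160, 185),
    "glomerulus_space": (159, 164, 250),
    "glomerular_tuft": (128, 88, 173),
    "crescent": (120, 60, 60),
    "proximal_tubule": (250, 87, 91),
    "distal_tubule": (225, 180, 80),
    "artery": (205, 20, 141),
    "nucleus": (40, 40, 120),
    "mesangial_hyper": (170, 40, 170),
    "endocap_hyper": (60, 150, 70),
}

_TUFT_RADIUS_FRACTION = 0.62
_CRESCENT_SPAN_DEG = 150.0


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of one synthetic slide triple.

    All pixel quantities are expressed on the 10x grid; the 40x rasters have
    exactly 4x the linear dimensions.
    """

    seed: int = 0
    slide_width_10x: int = 640
    slide_height_10x: int = 640
    n_glomeruli: int = 5
    crescent_fraction: float = 0.4
    n_proximal: int = 10
    n_distal: int = 10
    n_arteries: int = 3
    nuclei_per_tuft_range: tuple[int, int] = (5, 9)
    mesangial_hyper_fraction: float = 0.4
    endocap_hyper_fraction: float = 0.4
    glomerulus_radius_range_10x: tuple[int, int] = (26, 40)
    n_interstitial_nuclei: int = 8

    def validate(self) -> None:
        for name in ("n_glomeruli", "n_proximal", "n_distal", "n_arteries",
                     "n_interstitial_nuclei"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("crescent_fraction", "mesangial_hyper_fraction",
                     "endocap_hyper_fraction"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        lo, hi = self.nuclei_per_tuft_range
        if lo < 0 or hi < lo:
            raise ValueError("nuclei_per_tuft_range must be 0 <= lo <= hi")
        rlo, rhi = self.glomerulus_radius_range_10x
        if rlo < 8 or rhi < rlo:
            raise ValueError(
                "glomerulus_radius_range_10x must satisfy 8 <= lo <= hi"
            )
        if min(self.slide_width_10x, self.slide_height_10x) < 4 * rhi:
            raise ValueError(
                "slide_width_10x/slide_height_10x must be at least twice the "
                "maximum glomerulus diameter (4 x max radius)"
            )


@dataclass
class GlomerulusRecord:
    """Planted per-glomerulus ground truth used by recovery tests."""

    index: int
    center_10x: tuple[float, float]
    radius_10x: int
    tuft_radius_10x: float
    crescent: bool
    mesangial_hyper: bool
    endocap_hyper: bool
    n_nuclei_tuft: int = 0


@dataclass
class GroundTruth:
    """All planted instances of one slide triple.

    Structure instances live in 10x space; nucleus and hypercellularity
    instances live in 40x space.  ``structures_at_40x`` rescales exactly.
    """

    slide_id: str
    structures: list[Instance] = field(default_factory=list)
    nuclei: list[Instance] = field(default_factory=list)
    hyper_regions: list[Instance] = field(default_factory=list)
    per_glomerulus: list[GlomerulusRecord] = field(default_factory=list)
    nucleus_params: list[dict] = field(default_factory=list)
    tissue_polygon_10x: np.ndarray | None = None

    @property
    def instances(self) -> list[Instance]:
        return [*self.structures, *self.nuclei, *self.hyper_regions]

    def structures_at_40x(self) -> list[Instance]:
        return [
            replace(inst.scaled(4.0), magnification="40x")
            for inst in self.structures
        ]

    def by_label(self, label: str) -> list[Instance]:
        return [i for i in self.instances if i.label == label]


# ---------------------------------------------------------------------------
# geometry primitives (40x integer grid)
# ---------------------------------------------------------------------------


def _circle40(cx10: float, cy10: float, r10: float, n: int = 64) -> np.ndarray:
    """64-gon approximating a circle, vertices rounded on the 40x grid."""
    theta = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    xs = np.round(4.0 * cx10 + 4.0 * r10 * np.cos(theta))
    ys = np.round(4.0 * cy10 + 4.0 * r10 * np.sin(theta))
    return np.column_stack([xs, ys]).astype(float)


def _ellipse40(cx40: float, cy40: float, a: float, b: float, angle: float,
               n: int = 32) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    ex = a * np.cos(theta)
    ey = b * np.sin(theta)
    ca, sa = math.cos(angle), math.sin(angle)
    xs = np.round(cx40 + ca * ex - sa * ey)
    ys = np.round(cy40 + sa * ex + ca * ey)
    return np.column_stack([xs, ys]).astype(float)


def _arc40(cx10: float, cy10: float, r_in10: float, r_out10: float,
           theta0: float, span: float, n: int = 48) -> np.ndarray:
    """Partial annulus (crescent) polygon on the 40x grid."""
    theta = np.linspace(theta0, theta0 + span, n)
    outer = np.column_stack([
        np.round(4.0 * cx10 + 4.0 * r_out10 * np.cos(theta)),
        np.round(4.0 * cy10 + 4.0 * r_out10 * np.sin(theta)),
    ])
    inner = np.column_stack([
        np.round(4.0 * cx10 + 4.0 * r_in10 * np.cos(theta[::-1])),
        np.round(4.0 * cy10 + 4.0 * r_in10 * np.sin(theta[::-1])),
    ])
    return np.vstack([outer, inner]).astype(float)


def _tissue_polygon40(rng: np.random.Generator, width10: int, height10: int,
                      margin10: int) -> np.ndarray:
    """Wiggly rectangle on the 40x grid containing [margin, dim - margin]."""
    m = margin10 / 2.0
    jitter = max(m / 2.0 - 2.0, 1.0)
    pts: list[tuple[float, float]] = []

    def edge(p0, p1, n=14):
        for t in np.linspace(0.0, 1.0, n, endpoint=False):
            x = p0[0] + t * (p1[0] - p0[0])
            y = p0[1] + t * (p1[1] - p0[1])
            pts.append((x + rng.uniform(-jitter, jitter),
                        y + rng.uniform(-jitter, jitter)))

    w, h = width10, height10
    edge((m, m), (w - m, m))
    edge((w - m, m), (w - m, h - m))
    edge((w - m, h - m), (m, h - m))
    edge((m, h - m), (m, m))
    poly10 = np.asarray(pts)
    return np.round(poly10 * 4.0)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _paint_polygon(raster: np.ndarray, poly: np.ndarray,
                   color: tuple[int, int, int]) -> None:
    x0, y0, sub = _rasterize_window(poly)
    window = raster[y0:y0 + sub.shape[0], x0:x0 + sub.shape[1]]
    window[sub] = color


def _paint_ring(raster: np.ndarray, outer: np.ndarray, inner: np.ndarray,
                color: tuple[int, int, int]) -> None:
    x0, y0, sub = _rasterize_window(outer)
    ix0, iy0, isub = _rasterize_window(inner)
    ring = sub.copy()
    ring[iy0 - y0:iy0 - y0 + isub.shape[0],
         ix0 - x0:ix0 - x0 + isub.shape[1]] &= ~isub
    window = raster[y0:y0 + sub.shape[0], x0:x0 + sub.shape[1]]
    window[ring] = color


def _paint_tissue(raster: np.ndarray, poly: np.ndarray) -> None:
    # PIL's C scanline fill; sub-pixel fidelity is irrelevant for the blob
    stencil = Image.new("L", (raster.shape[1], raster.shape[0]), 0)
    ImageDraw.Draw(stencil).polygon(
        [(float(x), float(y)) for x, y in poly], fill=1)
    raster[np.asarray(stencil, dtype=bool)] = PALETTE["tissue"]


# ---------------------------------------------------------------------------
# scene construction
# ---------------------------------------------------------------------------


def _sample_center(rng, width, height, margin, radius, placed, gap, tries=400):
    """Rejection-sample a circle center not colliding with placed circles."""
    for _ in range(tries):
        cx = int(rng.integers(margin, width - margin))
        cy = int(rng.integers(margin, height - margin))
        ok = True
        for (px, py, pr) in placed:
            if (cx - px) ** 2 + (cy - py) ** 2 < (radius + pr + gap) ** 2:
                ok = False
                break
        if ok:
            return cx, cy
    return None


def _place_nuclei(rng, centers40, n_target, center40, max_dist, axes_range,
                  min_extra_checks=(), tries=300):
    """Sample nucleus (center, a, b, angle) tuples at 40x inside a disk.

    ``min_extra_checks`` is a sequence of (cx, cy, max_r) constraints the
    nucleus center must additionally satisfy.  Returns the achieved list,
    which may be shorter than ``n_target`` if space runs out.
    """
    (a_lo, a_hi), (b_lo, b_hi) = axes_range
    placed = []
    for _ in range(n_target):
        for _ in range(tries):
            a = int(rng.integers(a_lo, a_hi + 1))
            b = int(rng.integers(b_lo, b_hi + 1))
            angle = float(rng.uniform(0.0, math.pi))
            limit = max_dist(a)
            if limit <= 0:
                continue
            rho = limit * math.sqrt(rng.uniform())
            phi = rng.uniform(0.0, 2.0 * math.pi)
            cx = center40[0] + rho * math.cos(phi)
            cy = center40[1] + rho * math.sin(phi)
            ok = all(
                (cx - ex) ** 2 + (cy - ey) ** 2 <= er ** 2
                for (ex, ey, er) in min_extra_checks
            )
            if ok:
                for (ox, oy, oa, _ob, _ang) in [*centers40, *placed]:
                    if (cx - ox) ** 2 + (cy - oy) ** 2 < (a + oa + 3) ** 2:
                        ok = False
                        break
            if ok:
                placed.append((cx, cy, a, b, angle))
                break
        else:
            break  # ran out of room; record the achieved count
    return placed


def generate_slide_pair(
    config: SynthConfig,
) -> tuple[SlideImage, SlideImage, SlideImage, GroundTruth]:
    """Render one slide triple (H&E 10x, H&E 40x, PAS 40x) plus ground truth.

    Deterministic in ``config.seed``: the same config yields byte-identical
    rasters and an identical :class:`GroundTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    w10, h10 = config.slide_width_10x, config.slide_height_10x
    r_lo, r_hi = config.glomerulus_radius_range_10x
    margin = r_hi + 8
    slide_id = f"synth-{config.seed}"

    gt = GroundTruth(slide_id=slide_id)
    gt.tissue_polygon_10x = _tissue_polygon40(rng, w10, h10, margin) / 4.0

    placed: list[tuple[int, int, int]] = []  # (cx, cy, outer_r) at 10x

    # --- glomeruli ---------------------------------------------------------
    glom_geom = []
    for i in range(config.n_glomeruli):
        r = int(rng.integers(r_lo, r_hi + 1))
        pos = _sample_center(rng, w10, h10, margin, r, placed, gap=10)
        if pos is None:
            raise ValueError(
                "could not place all glomeruli; reduce counts or enlarge the "
                "slide (n_glomeruli)"
            )
        placed.append((*pos, r))
        glom_geom.append((pos[0], pos[1], r))

    n_crescent = int(round(config.crescent_fraction * config.n_glomeruli))
    order = rng.permutation(config.n_glomeruli)
    crescent_set = set(order[:n_crescent].tolist())
    n_mes = int(round(config.mesangial_hyper_fraction * config.n_glomeruli))
    n_endo = int(round(config.endocap_hyper_fraction * config.n_glomeruli))
    mes_set = set(rng.permutation(config.n_glomeruli)[:n_mes].tolist())
    endo_set = set(rng.permutation(config.n_glomeruli)[:n_endo].tolist())

    # --- tubules and arteries ---------------------------------------------
    def place_rings(count, outer_range, inner_fn, label):
        rings = []
        for _ in range(count):
            r = int(rng.integers(*outer_range))
            pos = _sample_center(rng, w10, h10, margin, r, placed, gap=6)
            if pos is None:
                raise ValueError(
                    f"could not place all structures ({label}); reduce counts "
                    "or enlarge the slide"
                )
            placed.append((*pos, r))
            rings.append((pos[0], pos[1], r, inner_fn(r)))
        return rings

    prox = place_rings(config.n_proximal, (10, 15),
                       lambda r: max(int(round(0.5 * r)), 3), "n_proximal")
    dist = place_rings(config.n_distal, (9, 13), lambda r: r - 3, "n_distal")
    art = place_rings(config.n_arteries, (13, 19),
                      lambda r: max(int(round(0.35 * r)), 3), "n_arteries")

    # --- rasters -----------------------------------------------------------
    he10 = np.full((h10, w10, 3), 255, dtype=np.uint8)
    he40 = np.full((4 * h10, 4 * w10, 3), 255, dtype=np.uint8)
    pas40 = np.full((4 * h10, 4 * w10, 3), 255, dtype=np.uint8)
    tissue40 = np.asarray(gt.tissue_polygon_10x) * 4.0
    _paint_tissue(he10, np.asarray(gt.tissue_polygon_10x))
    _paint_tissue(he40, tissue40)
    _paint_tissue(pas40, tissue40)

    def paint_all(poly40, color):
        _paint_polygon(he10, poly40 / 4.0, color)
        _paint_polygon(he40, poly40, color)
        _paint_polygon(pas40, poly40, color)

    def paint_ring_all(outer40, inner40, color):
        _paint_ring(he10, outer40 / 4.0, inner40 / 4.0, color)
        _paint_ring(he40, outer40, inner40, color)
        _paint_ring(pas40, outer40, inner40, color)

    for (cx, cy, r, ri) in prox:
        outer = _circle40(cx, cy, r)
        paint_ring_all(outer, _circle40(cx, cy, ri), PALETTE["proximal_tubule"])
        gt.structures.append(Instance.from_polygon(
            "proximal_tubule", outer / 4.0, slide_id=slide_id))
    for (cx, cy, r, ri) in dist:
        outer = _circle40(cx, cy, r)
        paint_ring_all(outer, _circle40(cx, cy, ri), PALETTE["distal_tubule"])
        gt.structures.append(Instance.from_polygon(
            "distal_tubule", outer / 4.0, slide_id=slide_id))
    for (cx, cy, r, ri) in art:
        outer = _circle40(cx, cy, r)
        paint_ring_all(outer, _circle40(cx, cy, ri), PALETTE["artery"])
        gt.structures.append(Instance.from_polygon(
            "artery", outer / 4.0, slide_id=slide_id))

    # --- glomerular interiors ---------------------------------------------
    nucleus_axes = ((12, 16), (9, 12))
    region_nucleus_axes = ((10, 12), (7, 9))
    all_nuclei40: list[tuple[float, float, int, int, float]] = []

    for i, (cx, cy, r) in enumerate(glom_geom):
        tuft_r = round(_TUFT_RADIUS_FRACTION * r, 2)
        outer = _circle40(cx, cy, r)
        tuft = _circle40(cx, cy, tuft_r)
        paint_all(outer, PALETTE["glomerulus_space"])
        paint_all(tuft, PALETTE["glomerular_tuft"])

        is_crescent = i in crescent_set
        if is_crescent:
            theta0 = float(rng.uniform(0.0, 2.0 * math.pi))
            cres = _arc40(cx, cy, tuft_r + 1, r - 2, theta0,
                          math.radians(_CRESCENT_SPAN_DEG))
            paint_all(cres, PALETTE["crescent"])

        label = "glomerulus_crescent" if is_crescent else "glomerulus_no_crescent"
        gt.structures.append(
            Instance.from_polygon(label, outer / 4.0, slide_id=slide_id))
        gt.structures.append(
            Instance.from_polygon("glomerular_tuft", tuft / 4.0,
                                  slide_id=slide_id))

        # hypercellularity regions (PAS 40x) and their guaranteed nuclei
        c40 = (4.0 * cx, 4.0 * cy)
        tuft_r40 = 4.0 * tuft_r
        glom_nuclei: list[tuple[float, float, int, int, float]] = []
        regions = []
        if i in mes_set:
            rr = round(0.45 * tuft_r40)
            off = tuft_r40 - rr - 6
            regions.append(("mesangial_hyper", (c40[0] - off, c40[1]), rr, 4))
        if i in endo_set:
            rr = round(0.38 * tuft_r40)
            off = tuft_r40 - rr - 6
            regions.append(("endocap_hyper", (c40[0] + off, c40[1]), rr, 2))
        placed_regions = {"mesangial_hyper": False, "endocap_hyper": False}
        for (rlabel, rcenter, rr, n_required) in regions:
            nuc = _place_nuclei(
                rng, glom_nuclei, n_required, rcenter,
                max_dist=lambda a, rr=rr: rr - 2,
                axes_range=region_nucleus_axes,
                min_extra_checks=[(c40[0], c40[1], tuft_r40 - 14)],
            )
            if len(nuc) < n_required:
                continue  # region does not fit with its nuclei; skip it
            region_poly = _circle40(rcenter[0] / 4.0, rcenter[1] / 4.0, rr / 4.0)
            _paint_polygon(pas40, region_poly, PALETTE[rlabel])
            gt.hyper_regions.append(Instance.from_polygon(
                rlabel, region_poly, slide_id=slide_id, magnification="40x"))
            glom_nuclei.extend(nuc)
            placed_regions[rlabel] = True

        n_target = int(rng.integers(config.nuclei_per_tuft_range[0],
                                    config.nuclei_per_tuft_range[1] + 1))
        n_free = max(n_target - len(glom_nuclei), 0)
        free = _place_nuclei(
            rng, glom_nuclei, n_free, c40,
            max_dist=lambda a, R=tuft_r40: R - a - 3,
            axes_range=nucleus_axes,
        )
        glom_nuclei.extend(free)

        for (nx, ny, a, b, angle) in glom_nuclei:
            poly = _ellipse40(nx, ny, a, b, angle)
            _paint_polygon(he40, poly, PALETTE["nucleus"])
            gt.nuclei.append(Instance.from_polygon(
                "nucleus", poly, slide_id=slide_id, magnification="40x"))
            gt.nucleus_params.append(
                {"center_40x": (nx, ny), "a": a, "b": b, "angle": angle,
                 "glomerulus_index": i})
        all_nuclei40.extend(glom_nuclei)

        gt.per_glomerulus.append(GlomerulusRecord(
            index=i, center_10x=(float(cx), float(cy)), radius_10x=r,
            tuft_radius_10x=tuft_r, crescent=is_crescent,
            mesangial_hyper=placed_regions["mesangial_hyper"],
            endocap_hyper=placed_regions["endocap_hyper"],
            n_nuclei_tuft=len(glom_nuclei)))

    # --- interstitial nuclei (40x H&E, outside every planted structure) ----
    inter_margin40 = 4 * margin
    for _ in range(config.n_interstitial_nuclei):
        for _ in range(300):
            a = int(rng.integers(*nucleus_axes[0]))
            b = int(rng.integers(*nucleus_axes[1]))
            angle = float(rng.uniform(0.0, math.pi))
            nx = float(rng.uniform(inter_margin40, 4 * w10 - inter_margin40))
            ny = float(rng.uniform(inter_margin40, 4 * h10 - inter_margin40))
            ok = all(
                (nx - 4 * px) ** 2 + (ny - 4 * py) ** 2
                > (4 * pr + a + 10) ** 2
                for (px, py, pr) in placed
            )
            if ok:
                for (ox, oy, oa, _ob, _ang) in all_nuclei40:
                    if (nx - ox) ** 2 + (ny - oy) ** 2 < (a + oa + 3) ** 2:
                        ok = False
                        break
            if ok:
                poly = _ellipse40(nx, ny, a, b, angle)
                _paint_polygon(he40, poly, PALETTE["nucleus"])
                gt.nuclei.append(Instance.from_polygon(
                    "nucleus", poly, slide_id=slide_id, magnification="40x"))
                gt.nucleus_params.append(
                    {"center_40x": (nx, ny), "a": a, "b": b, "angle": angle,
                     "glomerulus_index": None})
                all_nuclei40.append((nx, ny, a, b, angle))
                break

    mk = lambda px, stain, mag: SlideImage(
        pixels=px, stain=stain, magnification=mag,
        mpp=MPP_BY_MAGNIFICATION[mag], slide_id=slide_id)
    return (mk(he10, "HE", "10x"), mk(he40, "HE", "40x"),
            mk(pas40, "PAS", "40x"), gt)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """How per-slide metadata and scene scaling are sampled for a cohort."""

    age_groups: tuple[str, ...] = ("1-5", "6-10", "11-15", "16-20")
    age_bounds: tuple[tuple[int, int], ...] = ((1, 5), (6, 10), (11, 15),
                                               (16, 20))
    radius_scale: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)
    diagnoses: tuple[str, ...] = ("MCG", "IgAN", "HSPN", "MsPGN")
    male_fraction: float = 0.55
    n_glomeruli_range: tuple[int, int] = (3, 8)


def generate_cohort(
    config: SynthConfig,
    n_slides: int,
    metadata_spec: CohortSpec | None = None,
) -> tuple[list[tuple[SlideImage, SlideImage, SlideImage, GroundTruth]],
           pd.DataFrame]:
    """Generate ``n_slides`` reproducible slide triples plus a metadata table.

    Age groups are assigned round-robin so every group is populated; when
    ``radius_scale`` differs across groups, planted mean glomerular areas are
    monotone in the group ordering (recovery tests rely on this).
    """
    if n_slides < 1:
        raise ValueError("n_slides must be >= 1")
    spec = metadata_spec or CohortSpec()
    if len(spec.radius_scale) != len(spec.age_groups):
        raise ValueError("radius_scale must have one entry per age group")

    triples = []
    rows = []
    for i in range(n_slides):
        child_seed = int(np.random.SeedSequence([config.seed, i]).generate_state(1)[0])
        meta_rng = np.random.default_rng(child_seed)
        g = i % len(spec.age_groups)
        lo, hi = spec.age_bounds[g]
        age = int(meta_rng.integers(lo, hi + 1))
        sex = "M" if meta_rng.uniform() < spec.male_fraction else "F"
        diagnosis = str(meta_rng.choice(list(spec.diagnoses)))
        scale = spec.radius_scale[g]
        r_lo, r_hi = config.glomerulus_radius_range_10x
        n_glom = int(meta_rng.integers(spec.n_glomeruli_range[0],
                                       spec.n_glomeruli_range[1] + 1))
        slide_config = replace(
            config,
            seed=child_seed,
            n_glomeruli=n_glom,
            glomerulus_radius_range_10x=(int(round(r_lo * scale)),
                                         int(round(r_hi * scale))),
        )
        he10, he40, pas40, gt = generate_slide_pair(slide_config)
        slide_id = f"synth-{config.seed}-{i:03d}"
        gt.slide_id = slide_id
        gt.structures = [replace(s, slide_id=slide_id) for s in gt.structures]
        gt.nuclei = [replace(s, slide_id=slide_id) for s in gt.nuclei]
        gt.hyper_regions = [replace(s, slide_id=slide_id)
                            for s in gt.hyper_regions]
        he10 = replace(he10, slide_id=slide_id)
        he40 = replace(he40, slide_id=slide_id)
        pas40 = replace(pas40, slide_id=slide_id)
        triples.append((he10, he40, pas40, gt))
        rows.append({"slide_id": slide_id, "age": age,
                     "age_group": spec.age_groups[g], "sex": sex,
                     "diagnosis": diagnosis})
    return triples, pd.DataFrame(rows)


def write_cohort(triples, metadata: pd.DataFrame, out_dir: str | Path) -> None:
    """Write rasters (TIFF), ground truth (GeoJSON) and metadata (CSV)."""
    from .slideio import AnnotationSet, write_annotations, write_slide_image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (he10, he40, pas40, gt) in triples:
        sid = gt.slide_id
        write_slide_image(he10, out / f"{sid}_HE_10x.tiff")
        write_slide_image(he40, out / f"{sid}_HE_40x.tiff")
        write_slide_image(pas40, out / f"{sid}_PAS_40x.tiff")
        write_annotations(
            AnnotationSet(instances=gt.structures, slide_id=sid,
                          magnification="10x", stain="HE"),
            out / f"{sid}_structures_10x.geojson")
        write_annotations(
            AnnotationSet(instances=[*gt.nuclei], slide_id=sid,
                          magnification="40x", stain="HE"),
            out / f"{sid}_nuclei_40x.geojson")
        write_annotations(
            AnnotationSet(instances=[*gt.hyper_regions], slide_id=sid,
                          magnification="40x", stain="PAS"),
            out / f"{sid}_hyper_40x.geojson")
    metadata.to_csv(out / "cohort.csv", index=False)
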