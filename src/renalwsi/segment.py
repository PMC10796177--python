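"""Pluggable per-patch detection contract plus deterministic reference backends.

Deep-learning backends are an adapter interface only; the reference backends
are rule systems tied to the fixed color signatures of
:mod:`renalwsi.synthdata`:

1. nearest-color pixel classification against the documented palette,
2. connected components,
3. shape/area rules (hole filling for ring-shaped tubules and arteries,
   minimum component area, truncation rejection at patch borders),
4. score = fraction of component pixels within a color-rule tolerance of the
   class's canonical color.

Components touching the border of the valid (unpadded) patch area are
rejected as truncated; with stride n/2 every object of diameter < stride is
fully contained in at least one tile, so whole-slide fusion still recovers
each object exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .slideio import Instance, SlideImage, mask_to_polygon, polygon_bounds
from .synthdata import PALETTE

__all__ = [
    "BackendSpec",
    "CrescentCall",
    "ReferenceStructureBackend",
    "ReferenceNucleusBackend",
    "ReferencePASBackend",
    "ReferenceCrescentClassifier",
    "ExternalBackend",
    "DropoutBackend",
    "segment_patch",
    "classify_crescent",
    "crop_for_classification",
]


@dataclass(frozen=True)
class BackendSpec:
    """What a detection backend accepts and emits."""

    name: str
    accepts: frozenset  # of (stain, magnification) pairs
    emits: frozenset    # subset of the nine allowed labels


@dataclass(frozen=True)
class CrescentCall:
    """Binary crescent decision; ``score`` is the crescentic probability."""

    label: str
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("score must lie in [0, 1]")
        expected = "crescentic" if self.score >= 0.5 else "non_crescentic"
        if self.label != expected:
            raise ValueError("label must be crescentic iff score >= 0.5")


#: scene colors per stain/magnification; each backend classifies pixels only
#: against the colors that can occur in its input
_SCENE_KEYS = {
    ("HE", "10x"): ("background", "tissue", "glomerulus_space",
                    "glomerular_tuft", "crescent", "proximal_tubule",
                    "distal_tubule", "artery"),
    ("HE", "40x"): ("background", "tissue", "glomerulus_space",
                    "glomerular_tuft", "crescent", "proximal_tubule",
                    "distal_tubule", "artery", "nucleus"),
    ("PAS", "40x"): ("background", "tissue", "glomerulus_space",
                     "glomerular_tuft", "crescent", "proximal_tubule",
                     "distal_tubule", "artery", "mesangial_hyper",
                     "endocap_hyper"),
}

#: color-rule tolerance (Euclidean RGB) used for scoring
_SCORE_TOL = 30.0


def _nearest_color(
    patch: np.ndarray, keys: tuple[str, ...]
) -> tuple[dict[str, int], np.ndarray, np.ndarray]:
    """Per-pixel nearest color among ``keys``.

    Returns ``(key->index map, index raster, squared-distance raster)``.
    """
    px = np.asarray(patch, dtype=np.float32)
    best_d2 = np.full(px.shape[:2], np.inf, dtype=np.float32)
    idx = np.zeros(px.shape[:2], dtype=np.uint8)
    for i, key in enumerate(keys):
        diff = px - np.asarray(PALETTE[key], dtype=np.float32)
        d2 = np.einsum("...c,...c->...", diff, diff)
        closer = d2 < best_d2
        idx[closer] = i
        np.minimum(best_d2, d2, out=best_d2)
    return {k: i for i, k in enumerate(keys)}, idx, best_d2


def _components_to_instances(
    class_mask: np.ndarray,
    d2: np.ndarray,
    label: str,
    *,
    valid: tuple[int, int],
    min_area: int,
    fill: bool,
    crescent_mask: np.ndarray | None = None,
    crescent_min: int = 10,
) -> list[Instance]:
    out = []
    labeled = measure.label(class_mask, connectivity=2)
    for region in measure.regionprops(labeled):
        if region.area < min_area:
            continue
        r0, c0, r1, c1 = region.bbox
        if r0 <= 0 or c0 <= 0 or r1 >= valid[0] or c1 >= valid[1]:
            continue  # truncated at the valid patch border
        sub = region.image  # component mask within its own bbox
        window = (slice(r0, r1), slice(c0, c1))
        final_label = label
        if crescent_mask is not None:
            n_crescent = int((sub & crescent_mask[window]).sum())
            final_label = ("glomerulus_crescent" if n_crescent >= crescent_min
                           else "glomerulus_no_crescent")
        score = float((d2[window][sub] <= _SCORE_TOL ** 2).mean())
        score = max(min(score, 1.0), 1e-6)
        if fill:
            sub = ndimage.binary_fill_holes(sub)
        poly = mask_to_polygon(sub) + (c0, r0)
        out.append(Instance.from_polygon(final_label, poly, score=score))
    return out


class ReferenceStructureBackend:
    """Kidney-structure detector for H&E patches at 10x."""

    spec = BackendSpec(
        name="reference-structure",
        accepts=frozenset({("HE", "10x")}),
        emits=frozenset({
            "artery", "distal_tubule", "proximal_tubule",
            "glomerulus_crescent", "glomerulus_no_crescent",
            "glomerular_tuft",
        }),
    )
    min_area = 50

    def detect(self, patch: np.ndarray,
               valid: tuple[int, int] | None = None) -> list[Instance]:
        valid = valid or patch.shape[:2]
        key_index, idx, dist = _nearest_color(patch, _SCENE_KEYS[("HE", "10x")])
        space = idx == key_index["glomerulus_space"]
        tuft = idx == key_index["glomerular_tuft"]
        crescent = idx == key_index["crescent"]
        instances = _components_to_instances(
            space | tuft | crescent, dist, "glomerulus_no_crescent",
            valid=valid, min_area=self.min_area, fill=True,
            crescent_mask=crescent)
        instances += _components_to_instances(
            tuft, dist, "glomerular_tuft", valid=valid,
            min_area=self.min_area, fill=True)
        for key, label in (("proximal_tubule", "proximal_tubule"),
                           ("distal_tubule", "distal_tubule"),
                           ("artery", "artery")):
            instances += _components_to_instances(
                idx == key_index[key], dist, label, valid=valid,
                min_area=self.min_area, fill=True)
        return instances


class ReferenceNucleusBackend:
    """Nucleus detector for H&E patches at 40x."""

    spec = BackendSpec(
        name="reference-nucleus",
        accepts=frozenset({("HE", "40x")}),
        emits=frozenset({"nucleus"}),
    )
    min_area = 8

    def detect(self, patch: np.ndarray,
               valid: tuple[int, int] | None = None) -> list[Instance]:
        valid = valid or patch.shape[:2]
        key_index, idx, dist = _nearest_color(patch, _SCENE_KEYS[("HE", "40x")])
        return _components_to_instances(
            idx == key_index["nucleus"], dist, "nucleus", valid=valid,
            min_area=self.min_area, fill=True)


class ReferencePASBackend:
    """Hypercellularity-region detector for PAS crops at 40x."""

    spec = BackendSpec(
        name="reference-pas",
        accepts=frozenset({("PAS", "40x")}),
        emits=frozenset({"mesangial_hyper", "endocap_hyper"}),
    )
    min_area = 40

    def detect(self, patch: np.ndarray,
               valid: tuple[int, int] | None = None) -> list[Instance]:
        valid = valid or patch.shape[:2]
        key_index, idx, dist = _nearest_color(patch, _SCENE_KEYS[("PAS", "40x")])
        out = _components_to_instances(
            idx == key_index["mesangial_hyper"], dist, "mesangial_hyper",
            valid=valid, min_area=self.min_area, fill=True)
        out += _components_to_instances(
            idx == key_index["endocap_hyper"], dist, "endocap_hyper",
            valid=valid, min_area=self.min_area, fill=True)
        return out


class ExternalBackend:
    """Adapter invoking an external per-patch detector via JSON.

    Protocol: the patch is written as a PNG to a temporary file and the
    configured command is run with that path appended as its last argument.
    The command must print a JSON array to stdout, one object per instance::

        [{"label": "...", "polygon": [[x, y], ...], "score": 0.93}, ...]

    Coordinates are patch-space pixels; ``score`` defaults to 1.0.
    This is the slot a trained deep-learning model plugs into.
    """

    def __init__(self, command: list[str], accepts, emits,
                 name: str = "external"):
        self.spec = BackendSpec(name=name, accepts=frozenset(accepts),
                                emits=frozenset(emits))
        self.command = list(command)

    def detect(self, patch: np.ndarray,
               valid: tuple[int, int] | None = None) -> list[Instance]:
        import json
        import subprocess
        import tempfile

        from PIL import Image

        with tempfile.NamedTemporaryFile(suffix=".png") as handle:
            Image.fromarray(np.ascontiguousarray(patch)).save(handle.name)
            proc = subprocess.run(
                [*self.command, handle.name], capture_output=True,
                text=True, check=True)
        instances = []
        for obj in json.loads(proc.stdout):
            label = obj["label"]
            if label not in self.spec.emits:
                raise ValueError(
                    f"external backend emitted label {label!r} outside its "
                    f"declared set {sorted(self.spec.emits)}")
            instances.append(Instance.from_polygon(
                label, np.asarray(obj["polygon"], dtype=float),
                score=float(obj.get("score", 1.0))))
        return instances


class DropoutBackend:
    """Wrap a backend and drop each detection with a fixed probability.

    A degradation harness for agreement experiments: the wrapped backend is
    deterministic given the construction seed but, unlike the reference
    backends, is stateful across patches (each call advances the RNG).
    """

    def __init__(self, base, drop_rate: float, seed: int = 0):
        if not (0.0 <= drop_rate < 1.0):
            raise ValueError("drop_rate must lie in [0, 1)")
        self.base = base
        self.spec = base.spec
        self.drop_rate = drop_rate
        self._rng = np.random.default_rng(seed)

    def detect(self, patch: np.ndarray,
               valid: tuple[int, int] | None = None) -> list[Instance]:
        kept = []
        for inst in self.base.detect(patch, valid):
            if self._rng.uniform() >= self.drop_rate:
                kept.append(inst)
        return kept


def segment_patch(
    patch: np.ndarray,
    stain: str,
    magnification: str,
    backend,
    valid: tuple[int, int] | None = None,
) -> list[Instance]:
    """Run a backend on one patch, enforcing its (stain, magnification) spec.

    ``valid`` is the (height, width) of the unpadded patch area; components
    touching its border are treated as truncated and dropped.
    """
    if (stain, magnification) not in backend.spec.accepts:
        raise ValueError(
            f"backend {backend.spec.name!r} does not accept "
            f"({stain!r}, {magnification!r}); accepted pairs: "
            f"{sorted(backend.spec.accepts)}"
        )
    return backend.detect(patch, valid)


# ---------------------------------------------------------------------------
# crescent classification
# ---------------------------------------------------------------------------


class ReferenceCrescentClassifier:
    """Rule-based crescent scorer on 224x224 glomerulus crops.

    Let ``f`` be the fraction of Bowman-space pixels (space + crescent color
    classes) carrying the crescent signature.  The crescentic score is
    ``min(1, f / f0)`` with ``f0 = 0.25``.
    """

    f0 = 0.25

    def score(self, patch: np.ndarray) -> float:
        key_index, idx, _ = _nearest_color(patch, _SCENE_KEYS[("HE", "10x")])
        crescent = int((idx == key_index["crescent"]).sum())
        space = int((idx == key_index["glomerulus_space"]).sum())
        annulus = crescent + space
        if annulus == 0:
            return 0.0
        return float(min(1.0, (crescent / annulus) / self.f0))


def classify_crescent(patch: np.ndarray, classifier=None) -> CrescentCall:
    """Classify a 224x224 glomerulus crop as crescentic / non-crescentic."""
    patch = np.asarray(patch)
    if patch.shape[:2] != (224, 224):
        raise ValueError(
            f"crescent classification expects a 224x224 crop, got "
            f"{patch.shape[:2]}"
        )
    classifier = classifier or ReferenceCrescentClassifier()
    score = float(classifier.score(patch))
    label = "crescentic" if score >= 0.5 else "non_crescentic"
    return CrescentCall(label=label, score=score)


def crop_for_classification(
    slide: SlideImage, instance: Instance, pad_value: int = 255
) -> np.ndarray:
    """Square-pad the glomerulus bbox crop and resize it to 224x224."""
    if instance.label not in ("glomerulus_crescent", "glomerulus_no_crescent"):
        raise ValueError(
            f"expected a glomerulus instance, got label {instance.label!r}"
        )
    x, y, w, h = instance.bbox
    height, width = slide.shape
    x0 = max(int(np.floor(x)), 0)
    y0 = max(int(np.floor(y)), 0)
    x1 = min(int(np.ceil(x + w)), width)
    y1 = min(int(np.ceil(y + h)), height)
    if x1 <= x0 or y1 <= y0:
        raise ValueError("glomerulus bbox does not intersect the slide")
    crop = slide.pixels[y0:y1, x0:x1]
    side = max(crop.shape[0], crop.shape[1])
    padded = np.full((side, side, 3), pad_value, dtype=crop.dtype)
    padded[:crop.shape[0], :crop.shape[1]] = crop
    if side == 224:
        return padded
    from PIL import Image

    image = Image.fromarray(np.ascontiguousarray(padded))
    return np.asarray(image.resize((224, 224), Image.BILINEAR))


def polygon_pixels_covered(instance: Instance, x0: int, y0: int,
                           x1: int, y1: int) -> float:
    """Fraction of the instance's rasterized pixels inside a crop window."""
    from .slideio import polygon_to_mask

    bx, by, bw, bh = polygon_bounds(instance.polygon)
    extent = (int(np.ceil(by + bh)) + 2, int(np.ceil(bx + bw)) + 2)
    mask = polygon_to_mask(instance.polygon, extent)
    total = mask.sum()
    window = mask[y0:min(y1, extent[0]), x0:min(x1, extent[1])]
    return float(window.sum() / total) if total else 0.0
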