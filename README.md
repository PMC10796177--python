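# renalwsi

A whole-slide renal-biopsy analysis toolkit: sliding-window tiling of paired
H&E/PAS slides at two magnifications, pluggable per-patch instance
segmentation, fusion of patch detections into whole-slide results via exact
coordinate transforms and per-class non-maximum suppression, crescent
classification, morphometric and hypercellularity quantification, and
evaluation against annotations with VOC 11-point average precision and
agreement statistics.  A synthetic-slide generator makes every stage
testable offline, with exhaustive ground truth and a deterministic
rule-based reference segmentation backend.

## Modules

| module      | role |
|-------------|------|
| `synthdata` | paired pseudo-histology slides (H&E 10x, H&E 40x, PAS 40x) with ground truth; cohorts with age/sex/diagnosis metadata |
| `slideio`   | data model (slides, instances, annotation sets), GeoJSON/TIFF/PNG/CSV I/O, polygon/mask round trips |
| `tiler`     | Otsu foreground gating, overlapping n-by-n windows (stride n/2), pad/resize to model input size, invertible patch-to-slide transforms |
| `segment`   | backend contract plus deterministic nearest-color reference backends (structures at 10x, nuclei at 40x, PAS hypercellularity regions) and the 224x224 crescent classifier |
| `fuse`      | IoU, greedy per-class NMS at 0.5, 40x-to-10x nuclei rescale (factor 1/4), nucleus-to-structure assignment, x4 H&E-to-PAS box transfer, end-to-end `run_pipeline` |
| `quant`     | per-instance morphometry (area, perimeter, roundness, major axis in physical units), glomerulus counting, >=4 / >=2 nucleus hypercellularity flags, cohort tables |
| `evalstats` | VOC 11-point AP50 / mAP, confusion metrics, ROC AUC, Spearman, two-way absolute-agreement single-measure ICC with 95% CI, one-way ANOVA + Tukey-Kramer, lowest-20%-mAP annotation triage |

## CLI

```bash
renalwsi synth --seed 0 --n-slides 2 --out-dir cohort/   # slides + GT + CSV
renalwsi validate cohort/<id>_structures_10x.geojson
renalwsi tile cohort/<id>_HE_10x.tiff --magnification 10x --out-dir tiles/
renalwsi run --he10 <he10.tiff> --he40 <he40.tiff> --pas40 <pas40.tiff> \
             --out-dir out/
renalwsi quant --structures out/structures_10x.geojson --out morphometry.csv
renalwsi eval --detections dets.geojson --ground-truth gt.geojson \
              --out report.json
renalwsi stats --csv counts.csv --x manual --y model --group age_group \
               --out stats.json
```

Annotations are interchanged as GeoJSON FeatureCollections (QuPath-style
polygons with `label`, optional `score`, `magnification` and `slide_id`
properties).  All coordinates are 0-based pixel indices with half-open
`(x, y, w, h)` boxes; 10x pixels are 1 um, 40x pixels 0.25 um, and 40x
coordinates are exactly 4x their 10x counterparts.

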