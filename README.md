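# brightmorph

Automated morphometry of microscopic model organisms from plain bright-field
images: marker-controlled watershed segmentation of **fission yeast**,
**budding yeast**, and ***C. elegans*** micrographs, followed by per-object
shape measurement, worm skeleton-length extraction, and bud–mother lineage
assignment. It is aimed at labs that measure hundreds to thousands of cells
per condition (strain panels, starve/release time courses, worm staging) and
want those measurements without fluorescent reporters, z-stacks, manual
annotation, or machine-learning training sets.

## The method

Cell walls image as dark outlines in bright-field. After selecting the
highest-contrast channel (blue for yeasts) the image is inverted so walls
are bright, contrast-stretched between its 1st and 99th percentiles, and
denoised (Gaussian σ = 0.5 px for fission yeast; total-variation for the
smaller budding yeast; worms additionally get a white-tophat to flatten
uneven illumination). Binarization is Bradley–Roth adaptive thresholding: a
pixel *I(x, y)* is wall iff

    I(x, y) > μ_w(x, y) · (1 + (0.5 − s)),        s = 0.35,

where *μ_w* is the local mean over a window (≈ min(H, W)/8) computed with an
integral image. Components below 150 px are removed and a 2 px disk closing
seals wall breaks. Foreground markers are the enclosed holes of the wall
mask, `fill(wall) ∧ ¬wall` — one per cell interior; background markers are
the SKIZ (skeleton by influence zones) of the wall components. Watershed
flooding of the preprocessed image with minima imposed at all markers then
yields exactly one region per foreground marker; border-touching objects are
dropped.

Per object, the morphometry module reports the moment-ellipse major/minor
axes as length and width (in µm via the pixel calibration), eccentricity
√(1 − (b/a)²), solidity (area / convex area), areas, centroid, and mean raw
intensity. Worm length is measured on the object's skeleton: thinned to one
pixel, minimally thickened to 4-connectivity, split into end- and
branch-segments, and searched exhaustively for the longest
endpoint-to-endpoint path (diagonal steps weighted √2, the winning path
re-measured on a smoothed polyline, tips extended by the local medial
radius). Buds are split from mothers by an area threshold and each bud is
assigned the mother with the smallest boundary-to-boundary distance.

A synthetic-scene generator renders bright-field-like images (dark wall
band, bright interior and background, illumination gradient, blur, noise)
with exact ground truth for all three organism classes, so the entire
pipeline is testable end-to-end without any real data.

## Worked example

```python
from brightmorph import (FISSION_YEAST, generate_rod_scene, run_pipeline,
                         measure_regions, select_channel, summarize)

scene = generate_rod_scene(10, seed=42)              # truth known exactly
labels = run_pipeline(scene.raw, FISSION_YEAST, pixel_size_um=0.1)
records = measure_regions(labels, select_channel(scene.raw, "blue", 0.1))
print(summarize(records).loc[["length_um", "eccentricity", "solidity"]])
```

Running `python examples/segment_fission_yeast.py` (this scene) prints:

```
segmented 10 cells (commanded: 10)

cell  commanded_len_um  measured_len_um  eccentricity  solidity
   1             13.47            13.39         0.947     0.976
   2             13.63            13.54         0.956     0.974
   ...
population summary (mean / sd / n):
                   mean        sd   n
length_um     11.014537  2.125509  10
eccentricity   0.919602  0.030704  10
solidity       0.977319  0.002579  10
```

All ten commanded cells are recovered and measured lengths track the
commanded geometry to ≈ 0.1 µm — well inside the ±0.85/−0.46 µm band that
separates automated from manual measurement on real data. The other
examples show worm-length extraction (`examples/measure_worm_length.py`:
straight and curved 600 µm worms both measured within ~1%, separated by
solidity 0.96 vs 0.35) and bud–parent assignment
(`examples/bud_lineage.py`).

## Command line

The same pipeline runs as a batch tool:

```bash
brightmorph synth --kind rod --n 10 --seed 1 --outdir scenes/
brightmorph segment scenes/rod_1.tif --species fission_yeast \
    --pixel-size-um 0.1 --outdir out/
brightmorph worms  worm_images/*.tif --pixel-size-um 1.0 --outdir out/
brightmorph buds   budding/*.tif --pixel-size-um 0.1 --outdir out/
```

Each run writes per-image label TIFFs, colored overlays, morphometry CSVs,
a combined CSV across images (one `image_id` column — suited to time-course
batches), the resolved configuration, and a `run.log`. Unreadable images
are logged and skipped. Profiles are YAML-serializable
(`--profile-config`); individual fields can be overridden with
`--set key=value`.

## Scope

No time-lapse tracking or pedigrees, no fluorescence-marker augmentation,
no focus-quality estimation, no untangling of overlapping worms. See
`docs/methods.md` for model details, parameter defaults, and limitations.
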