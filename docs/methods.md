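# Methods

## Segmentation model and its assumptions

The pipeline assumes bright-field optics in which the cell wall images as a
thin dark band against a brighter background, with the cytoplasm at a
brightness comparable to (here: slightly above) the background. Everything
downstream follows from that premise: after inversion the wall is the
*bright* structure, each cell interior is a *hole* enclosed by wall pixels,
and the watershed treats the wall as the ridge between catchment basins.
The method therefore makes no convexity assumption about cell shape — bent
tea1Δ-like rods, round wee1Δ-like cells, and noodle-shaped worms all
segment through the same operator chain; only size parameters change per
organism.

Stages, in order:

1. **Channel selection** — one plane of the RGB raster, rescaled by the
   container bit depth (255 or 65535), never by the observed maximum, so
   absolute intensity is comparable across images. Blue carries the highest
   wall contrast for yeasts; worms use grayscale input.
2. **Inversion + robust stretch** — `1 − I`, then a linear stretch mapping
   the 1st percentile to 0 and the 99th to 1 (clipping outside). Percentile
   anchoring makes the stretch immune to hot pixels. If the robust range is
   below 0.15 of full scale the image carries no wall contrast — an empty
   or grossly defocused field — and stretching would only amplify noise
   into spurious wall components, so the image is passed through inverted
   but unstretched with a warning; a blank image then correctly yields zero
   objects.
3. **Denoising** — Gaussian σ = 0.5 px (fission yeast), or total-variation
   (Chambolle, weight 0.1) for budding yeast where the thinner walls
   benefit from edge-preserving smoothing. Worms first get a white tophat
   (disk radius 25 px, decomposed footprint) that subtracts any background
   structure wider than the disk — the illumination ramps of large fields
   of view vanish while the thin bright walls survive.
4. **Bradley–Roth binarization** — foreground iff
   `I > μ_w · (1 + (0.5 − s))` with sensitivity s = 0.35 and the local mean
   μ_w computed via an integral image (replicate padding) over a square
   window of about min(H, W)/8 (odd, floor 15 px) — large enough to span a
   cell plus local background. At s = 0.5 the rule degenerates to plain
   local-mean thresholding; s > 0.5 admits pixels below their local mean.
5. **Wall cleanup** — 8-connected components strictly below the minimum
   area (150 px fission / 100 budding / 300 worm) are removed *before*
   closing, so noise speckle cannot be welded into larger structures; a
   disk closing (radius 2–3 px) then seals wall breaks.
6. **Markers** — foreground: `fill_holes(wall) ∧ ¬wall`, one 8-connected
   component per enclosed interior; regions open to the border are not
   holes, so markers cannot touch the frame. Budding yeast builds markers
   on green and blue independently and ORs them (component count after the
   union is the marker count). Markers smaller than a per-species floor
   (half the wall minimum area; 1000 px for worms, since even an L1 larva
   encloses more than that at ~1 µm/px) are discarded as artifact loops.
   Background: the SKIZ of the wall components, computed as the boundary of
   the nearest-component partition of the Euclidean distance transform
   (transition pixels marked on one side only → a ~1 px network). A single
   wall component has no internal zone boundary, so its SKIZ is empty;
   image-border equidistance artifacts never arise by construction. The
   pipeline additionally seeds the background flood from the image frame
   (minus any wall pixels): the frame is provably background once
   border-touching objects are removed, and without it a single-cell image
   would flood entirely from its one foreground marker.
7. **Watershed** — skimage's priority-flood watershed on the preprocessed
   intensity image with the markers imposed as the only minima and
   `watershed_line=True`, so ridge pixels and all background catchments map
   to label 0 and each foreground marker yields exactly one connected
   region (checked on every run: region count before border clearing must
   equal the marker count). A `zero_markers` flag reproduces the literal
   "zero the elevation under the markers" convention for comparison.
8. **Border clearing** — objects touching the outermost row/column are
   deleted and labels renumbered consecutively. Enforcing this once on the
   final labels is equivalent to also pruning border-cut wall components
   earlier, and simpler.

## Morphometry conventions

Length and width are the major and minor axes of the ellipse with the same
second central moments as the pixel set, times the pixel size. This is a
*convention*, and it matters for rods: the moment ellipse of an ideal
capsule (tip-to-tip length L, width W) has major axis noticeably longer
than L — e.g. 10.70 µm for a 10 × 4 µm capsule, 16.63 µm for 15 × 3 (closed
form in `capsule_moment_axes`, verified against a high-resolution raster
oracle). Users comparing against pole-to-pole manual measurements should
expect that offset; the synthetic truth tables store both the tip-to-tip
and the analytic moment-ellipse values so accuracy is always assessed
like-for-like. For strongly bent cells the skeleton-path length of the
worm module is the appropriate length measure instead.

Eccentricity is √(1 − (minor/major)²); solidity is pixel area over convex
hull area; mean intensity is taken on the raw, non-inverted, non-stretched
channel so it does not depend on per-image contrast. Coordinates are
0-based with x = column, y = row; centroids are real-valued. Degenerate
(single-pixel or collinear) objects get their minor axis floored at one
pixel with a warning. Table summaries use the sample standard deviation
(ddof = 1), reported as 0 for a single record.

## Worm length

The skeleton (topology-preserving thinning) is minimally thickened to
4-connectivity — for every diagonal-only adjacency exactly one of the two
completing axial pixels is inserted, deterministically the one with the
smaller raster index — so the curve splits unambiguously at its nodes:
pixels with one neighbor are endpoints, three or more are branch points.
Segment lengths are measured on the *pre-thickening* chain geometry: steps
routed through an inserted pixel contribute √2 in total, axial steps 1
(unit-weighting the thickened path would overestimate diagonal runs by up
to 41%). The worm length is the maximum over all endpoint-to-endpoint paths
that never reuse a segment, found by exhaustive depth-first search — which
also makes explicit spur pruning unnecessary, since a short spur simply
loses the maximization. The search is capped at 32 segments (real worm
skeletons have far fewer); cyclic skeletons (no endpoints) return the
longest simple cycle with a warning.

Two digitization corrections are applied to the *reported* length, both on
the winning path only:

* the √2-weighted chain systematically overestimates smooth oblique curves
  (up to ~8% at 22.5°), so the selected path is re-measured as the chord
  length of its coordinate sequence smoothed with a 7-sample moving
  average;
* thinning retracts the skeleton about half a body-width from each tip, so
  the distance-transform value (local medial radius) at the two terminal
  skeleton pixels is added back (`extend_tips=True`, the default).

With both corrections, sinusoidal synthetic worms of commanded 600 µm body
length measure within ~1.5% across seeds; without them the errors are −4%
(tips) and +3…+8% (chain bias) and partially cancel only by luck.
`alive_hint` is solidity < 0.5 (configurable): curved, living worms have
low solidity, straight dead ones approach 1.

## Bud lineage

Objects are split at an area threshold (default 40% of the median object
area, recomputed per image — with buds in the minority the median sits in
the mother class); an object exactly at the threshold is a mother. Each
bud's parent is the mother minimizing the minimum boundary-to-boundary
pixel distance (computed from the distance transform of the bud's
complement), a metric chosen over centroid distance because buds physically
touch their mothers and centroid distance misassigns elongated mothers.
Ties break to the smaller label; two or more mothers within 2 px flag the
assignment ambiguous — the known failure mode of buds emerging in crowded
neighborhoods. The size ratio uses equivalent-circle diameters
(2·√(area/π)·pixel size), rotation-invariant and well defined for round
buds; the major-axis-length ratio is emitted alongside.

## Synthetic scenes: what they emulate, and what they do not

The generator renders the premise the segmentation relies on: background
0.78, interior 0.88, a dark wall band (0.30) of 3–4 px straddling each
cell outline, an optional multiplicative linear illumination ramp
(amplitude 0.1 for yeast fields, 0.3 for worm fields), Gaussian blur as a
defocus proxy (σ 0.7 px yeast / 1.0 px worm), and additive Gaussian noise
(σ 0.01) drawn independently per channel. Calibration is fixed at
0.1 µm/px for yeast (≈ 60× objective on a CCD) and 1 µm/px for worms.
Geometry: capsules with optional arc bending for fission yeast (lengths
7–14 µm default, widths 3.5–4.5 µm); ellipse mothers (equivalent radius
2.2–2.8 µm, axis ratio 1.25–1.5) with tangent circular buds at 0.35–0.55
of the mother equivalent diameter; constant-width sinusoidal tubes for
worms (600 µm long, 25 µm wide by default — an aspect ratio typical of
late-larval animals). "Touching" crowding packs rods into cliques of up to
four laterally tangent cells; if a clique cannot be placed late in the
packing it shrinks rather than failing, and mothers are packed
largest-first. Placement, geometry and noise all derive from one seeded
generator, so a scene is a pure function of (parameters, seed).

Deliberately absent: optical point-spread physics and defocus asymmetry,
camera fixed-pattern noise, debris and dirty-slide artifacts, cytoplasmic
texture (the structured cytoplasm that over-segments some real long-cell
strains), overlapping worms, and out-of-focus cells. Passing the synthetic
suite therefore demonstrates the correctness of the operator chain and its
measurements under the stated image model — not performance on degraded
real-world acquisitions, which the underlying approach handles only up to
the documented failure modes (focus sensitivity, low wall contrast).

## Numerical choices and edge cases

* Boundary handling is reflective for all convolutions and morphology, so
  the frame cannot manufacture wall pixels; the adaptive threshold uses
  replicate padding in its integral image.
* Strict `>` in the threshold: a constant image is all-background for any
  s < 0.5. Images engineered so that pixel equals local mean exactly (pure
  linear ramps at s = 0.5) sit on a knife edge where float associativity
  decides the side; generic images are unaffected.
* The tophat uses skimage's decomposed ("sequence") disk footprint — an
  approximation of the exact disk that changes nothing about ramp removal
  and is much faster at radius 25.
* Watershed flooding, EDT nearest-site attribution, component labeling and
  the path search are all deterministic; two runs on identical input
  produce byte-identical label maps and CSVs.
* Thinning tie-breaks are not perfectly 4-fold symmetric, so a 90°-rotated
  mask can skeletonize to a marginally different path; measured worm
  lengths agree to a fraction of a percent rather than bit-exactly.
* Zero foreground markers (blank image) yield an empty label map with
  warnings, never an exception; a mask with multiple components is
  rejected by `skeletonize_object` with instructions to process per label;
  buds without any mother raise an error listing the unassignable labels.

## Parameter defaults

| Parameter | fission | budding | worm | Why |
|---|---|---|---|---|
| channels | blue | green+blue | gray | wall contrast / published choice |
| denoiser | Gaussian 0.5 px | TV, weight 0.1 | Gaussian 1.0 px | organism scale |
| sensitivity | 0.35 | 0.35 | 0.35 | published operating point |
| window | min(H,W)/8, ≥15 odd | same | same | spans a cell |
| min wall area (px) | 150 | 100 | 300 | published (fission); rescaled |
| closing radius (px) | 2 | 2 | 3 | published (fission); rescaled |
| tophat radius (px) | — | — | 25 | exceeds wall-band width by far |
| min marker area (px) | 75 | 50 | 1000 | smallest plausible interior |
| bud threshold | — | 40% of median area | — | sits between size classes |

All are fields of `SpeciesProfile`, overridable per run and serializable to
YAML.

## Known limitations

Cells whose wall never closes in the mask produce no marker and are
absorbed into the background (the under-segmentation failure mode); heavily
textured interiors could in principle split a hole in two and over-segment,
though the marker-area floor suppresses the small fragment. The worm module
does not untangle touching or self-overlapping worms — a self-contact turns
the skeleton cyclic and the reported length becomes the longest simple
cycle. Lineage assignment is geometric only; it cannot distinguish a
detached daughter lying next to an unrelated cell from a true bud.
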