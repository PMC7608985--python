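# Methods

This note documents the models, conventions and numerical choices behind
`cystquant`, the assumptions they rest on, and what the synthetic test
conditions do and do not establish about real histology.

## Recognition pipeline

The pipeline assumes H&E appearance: cyst lumens are near-white (high green
channel), stained tissue is substantially darker, and the section fills the
frame.  All steps are deterministic; repeated runs on the same image give
bit-identical results.

**Mean threshold.** The global mean `μ_G` is computed over the whole frame
(no tissue masking) and kept as a real number; foreground is *strictly*
brighter than `μ_G`, so a constant image yields an empty mask rather than an
arbitrary half-split.

**k-means refinement.** One-dimensional two-cluster Lloyd iteration on the
pixel intensities, initialised with the threshold labels.  The schedule is:
recompute the two centroid means, reassign each pixel to the nearer
centroid (ties to the brighter cluster), stop when both centroids move less
than 0.5 grey levels or after 10 iterations.  Foreground is the cluster
with the higher final centroid.  Degenerate initialisations (all pixels one
label) are returned unchanged, and an assignment step that would empty a
cluster keeps the previous stable assignment — blank slides must not crash
a batch.  On bimodal images this converges to the same partition as an
exhaustive search over all 255 cut points (tested).

**Opening.** Disk structuring elements only (isotropic).  `skimage`'s
`disk(r)` has odd diameter `2r+1`, so the element is the odd-diameter disk
nearest the nominal size: diameter 3 for liver; `max(3, round(d_min))` for
kidney, i.e. `disk(max(1, round(d_min)//2))`.  The kidney choice reads the
size filter literally — remove objects smaller than the smallest cyst of
interest; an area-opening at `π·d_min²/4` would be a defensible
alternative but couples the filter to area rather than width.

**Contours.** Components are 8-connected; only the outer border is traced
(Moore-neighbour border following, the outer-border case of the classical
border-following family).  Holes inside a cyst count as cyst area: debris
floating in a lumen should not shrink the cyst.  The tracer's stopping rule
is state repetition of the (pixel, backtrack-direction) pair, which is
robust to borders that pass through a pixel twice.  Polygons are the
ordered border pixels, 0-based, `x` = column; rasterising the closed chain
and filling enclosed background reconstructs the filled component
pixel-for-pixel, so polygon-derived areas equal mask areas exactly (this
round trip is property-tested on random masks).

**Diameter.** Always the equivalent-circle diameter `2√(A/π)` of the filled
area; the range filter is inclusive at both ends.  Ranges can be given in
µm and are converted once through the calibration (µm/pixel) at
construction.

## LBP texture descriptor

Rotation-invariant *uniform* mapping ("riu2"): at scale `(R, P)` a pattern
with at most two circular 0/1 transitions is coded by its number of set
bits (0..P), all other patterns share one non-uniform bin — `P+2` bins per
scale, hence 54 features for `(1,8),(2,16),(3,24)`.  Neighbour comparison
is `≥` (ties set the bit); non-integer neighbour positions use bilinear
interpolation, with sampling offsets snapped to integers when within 1e-8
(so axis-aligned neighbours are read exactly).  The luminance conversion is
the standard `0.299R + 0.587G + 0.114B`, rounded.  Each scale's histogram
is accumulated over the region pixels whose full neighbourhood lies inside
the image and normalised to sum 1, making the descriptor region-size
invariant — a requirement for comparing cysts of different sizes in one
SVM.  A region with no valid pixel at some scale raises a
region-unsupported error; during candidate classification such candidates
are routed to the rejected set.  Internally the computation is cropped to
the region's bounding box padded by the largest radius, which is provably
identical to a whole-image computation (and tested to be bit-identical).

## Small-cyst classifier

RBF-SVM with hyper-parameters from a power-of-two grid, `C = 2^i` for
`i = −5..15` step 2 and `γ = 2^i` for `i = −13..3` step 2.  The data is
split 50/25/25 into train/validation/test by a seeded stratified shuffle;
the grid is scored by mean Cohen kappa under stratified 4-fold
cross-validation over the pooled 75% (train+validation), the winner is
refit on the pool, and the untouched 25% provides the reported held-out
kappa and accuracy.  Ties prefer smaller `C`, then smaller `γ` (smoother
models).  Cohen's kappa is `(p_o − p_e)/(1 − p_e)` from the 2×2 confusion
table, defined as 0 when `p_e = 1`.

## Supervision and accounting

Edits are recorded in an ordered log; each record stores the polygons it
created, so replaying a log from the initial set reproduces the final set
exactly without the image or the classifier, and undo/redo only move a
cursor.  Conventions:

* *split*: the drawn polyline is rasterised 1 px wide and excluded from
  both children; the cut must yield exactly two components.
* *merge*: the union of the parts is morphologically closed with a disk of
  radius equal to the gap tolerance (default 8 px) so visually separated
  fragments can bridge; the result must be a single component.
* *remove inner cysts*: "falling into" a manually drawn container means
  full pixel containment — overlapping the boundary keeps the cyst.
* *complete*: the old detection is retired and a fresh derived cyst takes
  its place, even if the geometry is unchanged.
* *add smaller cysts*: re-segments with the fine 3-px opening regardless of
  organ, keeps candidates in the small-diameter range that do not overlap
  existing cysts, and appends those the classifier accepts.  Overlap
  exclusion makes the operation idempotent.

Error accounting is identity-based: TP = automatic cysts surviving the log
untouched, FP = automatic cysts retired by any edit, FN = surviving cysts
the supervision created.  This reproduces the per-edit rules (split = 1 FP
+ 2 FN, merge of k = k FP + 1 FN, complete = 1 FP + 1 FN, …) and makes
NA = TP+FP the automatic count and NS = TP+FN the supervised count by
construction.  Cysts accepted by the small-cyst tool count as FN by
default; `add_smaller_counts_as="fp"` switches to the alternative reading.
Multi-image aggregation sums counts before computing Se/Sp (micro-average);
per-image macro-averaging can be done by the caller from the per-image
counts.

Quantification: the cystic index uses the pixel **union** of the filled
cyst regions (overlaps counted once, so CI ≤ 100) over the whole frame, or
over a tissue mask when one is supplied.  The size profile uses half-open
100-px diameter bins `[0,100), …, [400,500)` plus an overflow bin
`≥ 500 px`.  Severity bands close the inner interval: kidney mild < 35 ≤
cystic ≤ 55 < severe; liver mild < 5 ≤ cystic ≤ 15 < severe.

## Synthetic study conditions

The generator emulates what the pipeline keys on, not photorealism:
eosin-pink tissue (`RGB (200,120,165)`) with Gaussian speckle (σ = 11) and
3% scattered dark nuclei; smooth near-white lumens (`RGB (243,240,246)`,
green margin 120 ≥ 60 grey levels over tissue); global Gaussian noise
σ = 5.  Cysts are random ellipses (aspect 0.75–1, area-preserving
parametrisation so the sampled equivalent diameter is exact), placed by
rejection sampling with 12 px minimum separation and a budget of
`10 × n_objects` attempts per object; exhausting the budget raises an
infeasible-packing error.  Distractors (tubules below `d_min`, ducts/
vessels inside the cyst range) share lumen brightness but carry 2-px-block
speckle (amplitude 42) and a darker 2-px rim — texture at the 1–3 px scale
the LBP resolves.  Training patches for the classifier take their
descriptor region from the segmentation itself (threshold → k-means → fine
opening), mirroring how false-positive examples arise in practice as
recogniser proposals.

Default image size is 1020×768 — quarter-scale of the 4080×3072 microscope
frames the tool targets — with 10–50 cysts per image in the "easy" suite;
these sizes keep the full 50-image recovery battery plus all oracle suites
within a few minutes on one CPU while leaving dozens of cysts per frame.

What passing the synthetic suites shows: the pipeline recovers known
objects and their areas under realistic contrast and noise, the accounting
and formulas are exact, the classifier separates texture classes the
generator renders, and the global-threshold baseline over-counts in the
presence of distractors exactly as it does on real tissue.  What it does
not show: robustness to stain variability, uneven illumination, sectioning
artefacts, touching/confluent cysts, or real tubule morphology — the
synthetic texture dichotomy (smooth vs speckled) is cleaner than real
tubules, so synthetic classifier kappas overstate real-world performance
and are stand-ins, not benchmarks.

## Known limitations

* `μ_G` over the whole frame assumes organ-filling sections; sections on
  large empty backgrounds need the tissue-mask denominator and would also
  bias the threshold.
* The k-means schedule (0.5-grey-level tolerance, 10 iterations) is a
  package choice; other convergence settings can flip borderline pixels.
* Equivalent diameter under-represents elongated cysts; strongly
  non-convex "cysts" (fused lumens) are better handled by the split tool
  than by the filter.
* No colour deconvolution or stain normalisation: images from markedly
  different staining protocols may need their own diameter range and may
  shift the threshold.
* Whole-slide formats (SVS/NDPI) are out of scope; inputs are 8-bit RGB
  PNG/TIFF/JPEG.
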