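# Methods

This note records the models, conventions and numerical choices behind
`shredmetric`, and what the synthetic validation does and does not
establish about real scans.

## Acquisition model and units

All geometry is in millimetres.  A scan is a rectangular grid of
height counts at fixed x/y pitch; the count→mm factor of the scanner
head is not standardised, so it is a config value (default 1e-3 mm per
count, under which the canonical shred-surface band of 26 000–28 000
counts spans 26–28 mm).  The synthetic stage top sits at z = 26.5 mm
and the background plane at 20 mm — outside the band — so z-window ROI
cropping behaves as it does on real scans.  Grid indices are 0-based
with the origin at the grid corner; a height map converts to one point
per valid pixel.

The two surfaces are scanned independently.  A real lower scanner has
an arbitrary z origin, so the *scene generator* emits the lower cloud
in a frame calibrated such that the gauge block's reference points
coincide with the upper ones when no misalignment is injected, then
subtracts the configured misalignment.  Registration must therefore
recover exactly the injected offset, and every thickness quantity uses
only within-surface z differences, which are invariant to this
convention.  The *standalone* gauge-block generator, by contrast, emits
geometric surfaces (upper − lower = thickness over the footprint),
which is the natural contract for single-object fixtures.

Sensor noise is independent Gaussian: σ_z = 0.5 µm on heights and
σ_x = 2.5 µm along the profile axis — the static precisions of the
scanner class being emulated.

## Preprocessing

Chain order is fixed: z-crop → radius filter → Gaussian smoothing →
voxel downsampling.  The radius filter counts *other* points within
the radius (the point itself is excluded).  Smoothing acts on z only,
with neighbourhoods taken in the scan plane (scans are single-valued
height fields); the kernel radius defaults to 3σ.  Downsampling is
voxel-centroid with a majority label vote, ties broken toward the
smaller class code.  With the documented defaults (crop to the object
band, 0.2 mm/4-neighbour density test, σ = 0.05 mm, 0.15 mm voxel) a
dense synthetic scene reduces to roughly a tenth of its raw size.

## Augmentation

Global displacement draws one (Δx, Δy, Δz), each uniform in
[−0.1, 0.1] mm, per cloud; global rotation draws one angle in [0, 2π]
about a fixed axis (Y by default).  Label rotation pivots the selected
class about that subset's own centroid so the shred stays in-scene; the
pivot choice is a design decision, as is treating the displacement as
three independent draws.  All are label-preserving isometries, so
pooling originals with k enabled methods yields a (1 + k)-fold dataset
with intact ground truth.

## Segmentation network

The encoder applies two set-abstraction levels (default 512 then 128
centroids).  Centroids come from farthest point sampling with a
geometric start rule (the point farthest from the centroid,
lexicographic tie-breaks), which makes the selected *set* — and hence
the prediction — independent of input point order.  Grouping is
KNN-based: a fixed neighbour count is better conditioned than a radius
ball query when filament features are thin and densities uniform.
Each level groups at several k values and concatenates the pooled
per-scale features ("multi-scale grouping"); the combo naming
`R1-a-R2-b` selects the first a/b entries of each level's configured k
list (default list 16, 32, 48, …, so the default `R1-2-R2-1` uses
k = {16, 32} and k = {16}).  The decoder is standard feature
propagation: inverse-distance interpolation over 3 coarse neighbours
plus skip concatenation and a shared MLP; the head emits 5-class
logits per point.

Training minimises class-weighted cross-entropy (default weights
[4, 4, 4, 4, 1]: background is both over-represented and easy) with
Adam under a cosine-annealed learning rate (defaults η_max = 1e-3,
η_min = 1e-5, one period over all epochs; warm restarts when
`T_restart` is set).  Inputs are resampled to `n_input_points`
(default 4096; sampling with replacement and a warning when a cloud is
smaller), centered and scaled to the unit sphere per sample.  The
optimizer, normalisation and width choices are this package's own
defaults — they are exposed in `NetworkConfig`, not hard-coded.

The network and its autodiff run on NumPy in float64.  Desk-scale
configurations (≈512 points, 64/16 centroids, 32–64-wide MLPs) train in
seconds on one CPU and reach mIoU > 0.7 on held-out spatially-separable
toy scenes within 20 epochs; full-scale defaults are provided but are a
GPU-scale undertaking.  Metrics macro-average over the four shred
classes only, because background points would otherwise dominate every
mean; classes absent from both prediction and truth are excluded and
logged.

## Registration

Reference points are the oriented-bounding-rectangle center and four
edge midpoints of the gauge footprint (PCA axes with deterministic
sign conventions so the five pairs match across surfaces); each
reference z is the mean surface height within a disk of three grid
pitches (the paper-style prescription gives no neighbourhood, so this
is a documented choice).  The correction is the per-axis mean of the
five upper − lower differences — a translation only.  Rotational
misalignment of the rig is *not* modelled; the validation scenes
therefore only inject translations.  Noiseless recovery is exact;
with zero-mean noise on the references the residual scales as σ/√5.

## DTC measurement

Per instance (8-connected component of same-label pixels):

* the instance is rotated in-plane so its PCA major axis is vertical,
  then rasterised at the grid pitch.  Re-binning rotated grid samples
  aliases single-pixel holes into the mask, so a 3×3 morphological
  closing (on a padded copy, to protect the true boundary) is applied;
* the mask is cut into 5-pixel bands (configurable); each connected
  run of at least 3 pixels in a band contributes its centroid as a
  center (smaller runs are sub-resolution corner fragments of the
  filament's oblique cut end); centers are chained greedy
  nearest-neighbour from the minimal-y (then minimal-x) center;
* terminal chain segments that advance mostly sideways
  (|Δx| > 1.5 |Δy|) are pruned: bands advance along y, so such a step
  can only come from an end-face wedge centroid, not from centerline
  curvature at band spacing;
* centers lift to 3-D by inverse-distance-weighted z of the 4 nearest
  cloud points in x,y (exact hits return that z; queries farther than
  5 pitches from any point are flagged unmapped);
* length is the 3-D polyline sum; the 2-D baseline drops the z term
  and can only under-report;
* width profiles are cast perpendicular to each segment through its
  midpoint and marched at quarter-pixel steps until they exit the
  instance mask; the flip point overshoots the true edge by half a
  pixel on average, which is subtracted.  End-band segments are
  excluded (cut-end contamination) and profiles wider than 2.5× the
  median are dropped as along-trunk traverses; the average and maximum
  of the surviving profiles are reported.  A fixed two intersections
  per perpendicular are assumed;
* thickness compares mean surface heights against the gauge reference:
  T = H − H₁ − H₂ when the shred's upper surface is below the gauge
  top, T = H + H₁ − H₂ otherwise.  Non-positive T is flagged invalid,
  not clamped.  Note the mean-height-difference definition measures
  the *vertical* extent: for a ribbon tilted by τ it reads
  ≈ thickness/cos τ; the validation therefore uses untilted slabs for
  thickness, matching how a gauge validation is performed physically.

Grid quantisation bounds the attainable accuracy: at 0.05 mm pitch the
skeleton truncates about half a band at each filament end
(≈ 0.25 mm total) and widths carry ≈ ±half-pixel edge noise per side,
averaged down across segments.

## Synthetic generator

Filament centerlines are circular arcs (exact arc length rφ) or planar
sinusoids (arc length enforced by dense quadrature of the speed, then
even resampling); ribbons have rectangular width × thickness
cross-sections, optionally tilted about the long axis, and are swept as
dense face samples rasterised to the scan grid keeping the topmost
(upper scan) or bottommost (lower scan) height per pixel.  Defaults
emulate the study conditions: 0.05 mm pitch, widths ≈ 1 mm, thickness
0.1 mm (a realistic cut-lamina thickness), tilts up to 45°, sinusoid
steepness capped near 45° from the trunk axis, and the σ_z/σ_x noise
above.  Scenes reject overlapping x,y footprints.  What the generator
does *not* model: leaf-vein texture, scanner occlusion/shadowing,
partially transparent or frayed edges, and non-rectangular
cross-sections — so passing parameter-recovery tests demonstrates the
geometry pipeline, not robustness to real-material appearance.  The
`toy_segmentation_scenes` fixture generator (well-separated class
clusters) plays the same role for the network: it shows the
training/prediction machinery learns, not that real shred classes are
separable.

## Validation experiments

`scripts/acceptance.py` (and the mirror tests) recompute, from
scratch, at 0.05 mm pitch:

* length and average width of the noiseless reference gauge scan
  (nominal 30 and 9 mm);
* thickness of a noiseless 0.5 mm slab measured against the registered
  gauge (nominal 0.5 mm);
* maximum relative length and width errors over 20 noisy curved
  filaments (arc lengths 10–40 mm, widths 0.8–1.2 mm, tilts ≤ 45°,
  alternating arc/sinusoid centerlines);
* mean relative thickness error over 10 noisy slab repeats.

Problem sizes (20 filaments, 10 repeats, single scenes of ≈3×10⁵
points per surface) keep the whole script under a minute on one CPU
while leaving every stage — generation, projection, skeletonisation,
lifting, registration, thickness — exercised end to end.  Child seeds
derive from the single `--seed` via `numpy.random.SeedSequence`.

## Known limitations

* Translation-only registration (no rotation term).
* Thickness reads vertical extent; tilted filaments are over-read by
  1/cos τ.
* Greedy nearest-neighbour chaining assumes the lowest-y center is a
  filament end; strongly U-shaped shreds whose principal axis is
  ambiguous may chain across arms.
* Overlapping shreds are separated only by label + connected
  components; touching same-class shreds merge into one instance.
* The NumPy network is desk-scale; the full 4096-point default
  configuration trains, but slowly.
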