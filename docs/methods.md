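# Methods

This note documents the models, parameters, numerical choices, and known
limitations of `fishtrack`. Coordinates everywhere are 0-based pixels with
x = column, y = row and the origin at the top-left; angles are degrees in
[0, 360) measured in image coordinates, so 0° points right and 90° points
*down* the image.

## Segmentation

The background model is the per-pixel median over the first
`n_background_frames` frames (default 100; the `SYNTH` profile uses 200).
The median rejects a moving fish at a pixel as long as the fish covers that
pixel in fewer than half of the model frames; with fish of length ~60 px
moving ~3 px/frame, a pixel stays covered for ~20 frames, so 100–200 model
frames give a comfortable margin. Short clips violate this: a sequence must
be long enough (or the fish fast enough) that no pixel is occupied half the
time, otherwise the background absorbs the fish. For even `n` the lower of
the two middle order statistics is used so the background remains an
attainable gray level.

Thresholding is strict (`|background − frame| > T_g`) and symmetric in
contrast polarity. Cleaning is fill → remove-small → median-smooth, in that
order:

* hole filling floods the background phase from the image border, so
  foreground touching the border is preserved;
* components with area < `min_blob_area` (default 30 px) are removed;
* a boolean median filter of size `median_kernel` (default 3) smooths
  ragged edges.

The paper-derived profiles name these cleaning steps without values;
`min_blob_area` and `median_kernel` defaults are ours.

## Centerline (augmented fast marching)

Boundary parameterization uses Moore-neighbor contour following, clockwise,
starting at the row-major smallest boundary pixel of each component. A
deterministic start replaces "choose a random edge point": after wrap
correction the centerline is invariant to the start choice, and
deterministic runs make outputs reproducible byte-for-byte. On traced
boundaries `U` takes each value 1..L exactly once (revisited pixels on 1-px
protrusions keep their first value). Components are processed
independently; `U` is never compared across components.

Propagation solves the Eikonal equation with a first-order upwind scheme on
the 4-neighborhood (heap-ordered fast marching). Each boundary pixel is its
own *origin*; a pixel being frozen inherits the origin — and hence `U` — of
whichever frozen 4-neighbor's origin is Euclidean-nearest to it. This
origin-tracking rule keeps the inherited boundary point within a fraction
of a pixel of the true nearest boundary point on convex shapes (the naive
"inherit from the smallest-arrival neighbor" rule drifts by >1.5 px on a
disk).

The centerline detector marks pixel (x, y) when
`max(|ux|, |uy|) > T_u` with forward differences `ux = U(x+1,y) − U(x,y)`,
`uy = U(x,y+1) − U(x,y)`. Every absolute difference `d` is wrap-corrected
to `min(d, L − d)`: without this, the seam where `U` jumps from L back to 1
paints a spurious centerline from the start point. A consequence is that
`T_u ≥ L/2` yields an empty centerline, which bounds the usable `T_u` by
the component's boundary length — the reason small rendered fish need a
smaller `T_u` than large recorded ones. The raw detector corresponds to
the minimal threshold of 2; only the thresholded form is implemented. The
raw ridge can be 2 px thick, so it is morphologically thinned to unit width
before graph analysis (endpoint/junction counting needs unit-width curves).

The skeleton graph classifies pixels by 8-neighbor count (1 = endpoint,
≥3 = junction; isolated pixels count as endpoints) and traces maximal
simple paths between nodes. Orthogonal meetings can produce small junction
*clusters* (several adjacent junction pixels); branch distances are
measured to the nearest junction pixel, which is what "distance to the
nearest intersection point" means on a raster curve.

`skimage.morphology.medial_axis` / `skeletonize` are deliberately *not*
used in the pipeline; they serve only as independent oracles in the tests.

## Head detection

Endpoint filtering uses along-skeleton arc length (1 per axial step, √2 per
diagonal) to the nearest junction, strict `> T_l`; endpoints on
junction-free skeletons are always kept, since a lone fish body has no
junction anywhere. Width is `2 ×` the exact Euclidean distance transform at
the endpoint (the largest inscribed circle's diameter); heads are endpoints
with width strictly `> T_w`. If one component yields several
super-threshold endpoints (overlapping fish) all are emitted; if it yields
none (head branch pruned during a deep occlusion) the frame simply lacks
that detection and the tracker copes.

## Head direction

`L_xx, L_xy, L_yy` are second-order Gaussian-derivative responses computed
by separable correlation over a patch of radius 4s around the endpoint
(replicate padding near borders, flagged). The patch mean is subtracted
first: a derivative operator must annihilate constants, and the truncated
kernel would otherwise leak a small DC response. Scale selection maximizes
|DoH| = |(L_xx·L_yy − L_xy²)·s⁴| over `scales` (default {2, 3, 4, 6, 8} px,
spanning the head sizes the default profiles expect); ties go to the
smaller scale.

The direction is the angle of the eigenvector belonging to the
smaller-magnitude eigenvalue (along the body axis, where curvature is
least). Two degenerate cases are flagged rather than silently numeric:
|DoH| = 0 at every scale, and eigenvalue ratio |λ₁|/|λ₂| below
`anisotropy_min` (default 1.2, an isotropic patch has no axis). The
eigenvector's 180° ambiguity is resolved by a hint vector from the 5th
skeleton pixel back toward the endpoint — the direction pointing out of the
body through the head. Estimation runs on the foreground-bright image;
frames of dark fish are inverted first (`polarity = dark`, the default) so
eigenvalue signs are consistent.

## Tracking

The cost is `cv = ω·pc/pc_max + (1−ω)·dc/dc_max`; values above 1 are legal
when `pc > pc_max` — exclusion is the gate's job, and the gate compares the
positional Euclidean distance alone against `T_o`. A detection or track
without a usable direction contributes the uninformative midpoint
`dc_max/2` to the direction term instead of being excluded. A matched
detection with no direction leaves the track's previous heading in place.

The assignment is solved by the Hungarian method
(`scipy.optimize.linear_sum_assignment`) after replacing +∞ by a finite
constant larger than any feasible total and padding rectangular matrices
square; matches through gated or dummy entries are undone afterwards, so
fully gated rows/columns stay unmatched. Tests cross-check the solver
against exhaustive permutation search up to 7×7.

Initialization starts at the first frame with exactly `N` detections
(forward scan); if none exists the run fails explicitly with per-frame
counts. After initialization every frame holds exactly `N` states:
unmatched tracks receive a verbatim copy of their previous state flagged
`propagated`, and surplus detections are dropped. A propagated track's
stored heading participates in gating on re-acquisition as-is. Ties among
equal-cost assignments resolve deterministically (row order).

## Parameter profiles

| profile | T_g | T_u | T_l | T_w | ω | pc_max | dc_max | T_o | N |
|---------|-----|-----|-----|-----|-----|--------|--------|-----|----|
| D1 | 75 | 70 | 9 | 16 | 0.5 | 60 | 180 | 300 | 20 |
| D2 | 40 | 40 | 7 | 9 | 0.4 | 80 | 180 | 350 | 40 |
| SYNTH | 60 | 30 | 9 | 11 | 0.5 | 60 | 180 | 150 | 10 |

D1/D2 are the published settings for the two zebrafish groups (2048×2040 px
video, fish spanning 150–300 px). The renderer draws 60-px fish whose body
boundary is only ~130 px long, so `T_u = 70` is outside the usable range
(≥ L/2 empties the centerline); `SYNTH` derives its thresholds from the
renderer geometry by the same rules the original settings followed: `T_g`
well inside the 130-gray-level contrast, `T_u` large enough to prune burrs
yet below L/2, `T_w = 11` midway between the rendered head (~16 px) and
tail (~6–7 px) endpoint widths, and `T_o` scaled to the arena.

## Synthetic data

A fish is a rigid tapered capsule: midline segment from head center H to
tail center T (length 60 px tip-to-tip by default), radius tapering
linearly from 8 px at H to 2 px at T, drawn at gray 70 on background 200
with additive Gaussian noise (σ = 3) and optional inversion. Ground-truth
position is H and ground-truth heading the midline direction; the AFMM
endpoint sits within a few pixels of H at the `SYNTH` thresholds.

Motion is a bounded random walk: per-frame turn ~ N(0, max_turn/2) clipped
to ±max_turn (default 15°), speed ~ N(3, 1) px/frame clipped to
[0.3, 6] — comfortably inside the tracker's pc_max/dc_max envelopes — with
reflection at walls (a reflection itself may exceed the turn bound, as a
wall bounce does). Each fish draws from its own child stream of one seed,
so in free motion adding a fish never perturbs the others; everything is
bit-exactly reproducible from the seed.

Three benchmark profiles fix the study conditions: *easy* (10 fish,
600×600, mutual avoidance plus a hard minimum body separation of 24 px
against an occlusion envelope of 16 px, guaranteeing zero occlusions by
construction), *occluding* (20 fish, 700×700, scheduled pairs steered
toward each other until their bodies overlap, then released), and *dense*
(40 fish, 900×900, crossings). The occluded flag is geometric: two body
segments closer than the sum of their head half-widths.

What the generator does **not** emulate: body bending and tail-beat
deformation, perspective and lens distortion, shadows and reflections at
the water surface, illumination drift, and appearance differences between
individuals. Passing the synthetic benchmarks therefore demonstrates the
correctness of the algorithmic chain (segmentation → skeleton → width →
direction → association) under the stated geometry and noise, not
field-ready performance on arbitrary footage; on real video the published
D1/D2-style threshold calibration against a few annotated frames is still
required.

## Benchmark sizes and determinism

The shipped tests and `scripts/acceptance.py` run the easy and occluding
benchmarks at 200 frames (10 and 20 fish), sizes at which the full pipeline
completes in a few minutes on one CPU while every claimed property (ACDR ≥
0.95, AEDR ≤ 0.01, TIS = 0 and MTT = 10 on easy; conservation, propagation
events and ≥ 80 % mostly-tracked on occluding) is exercised. All
randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`; two runs with the same seed and config produce
byte-identical CSVs.

## Known limitations

* Heads of fish occluded so deeply that their branch is pruned are simply
  propagated; a long occlusion therefore freezes the track until the head
  re-emerges within `T_o`.
* Identity switches can still occur when two fish emerge from a crossing
  in near-symmetric states; the occluding benchmark reports a nonzero TIS.
* The AFMM runs per frame in pure Python over each component's pixels;
  throughput is roughly 3–5 frames/s at 700×700 with 20 fish. Larger
  frames scale linearly in foreground area.
* `N` is fixed for a run; fish entering or leaving the arena are out of
  scope, as is appearance-based re-identification.
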