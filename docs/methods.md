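# Methods

This note documents the models, numerical choices and known limitations of
`angiotrack`. Units are pixels and frames throughout; coordinates are
(x, y) = (column, row), 0-based, origin at the top-left, with y increasing
downward (image convention).

## Scope and assumptions

The pipeline starts at *segmented* angiography frames: binary masks whose
foreground is the contrast-filled coronary tree (plus the catheter). It
assumes

- vessels are locally tube-like, 3–15 px wide, with at most three branches
  at a bifurcation (the tree degree is capped at 3);
- the catheter enters near the upper-left image corner, so the
  catheter-proximal segment is the one starting closest (city-block) to
  the origin;
- between adjacent frames the vessels translate and fold but do not change
  topology or length appreciably — the basis of the matching thresholds;
- overlapping or crossing vessels in projection are *not* disambiguated;
  a crossing produces a spurious 4-way junction and wrong segment
  decomposition. This is an acknowledged limitation, not a failure mode
  the tests exercise.

## Centerline extraction

**Thinning.** Two-subiteration (Zhang–Suen) thinning; a pixel with
2 ≤ N(p1) ≤ 6 foreground neighbors and exactly one 0→1 transition S(p1)
around its 8-neighborhood is deleted when the direction products
(p2·p4·p6, p4·p6·p8 in the first subiteration; p2·p4·p8, p2·p6·p8 in the
second) vanish. Deletions within a subiteration are simultaneous; the loop
stops when a full pass deletes nothing. The vectorized implementation is
tested for exact equality against a naive per-pixel re-implementation.

*Known degeneracy:* on a perfectly straight band running at exactly 45° to
the pixel grid, this scheme can erode the whole band at unlucky sub-pixel
phases (2-px-wide diagonal staircases satisfy the deletion conditions
everywhere at once). Real vessels are never ideal diagonals; the phantom
layout helper keeps generated branch directions ≥ 4° away from the exact
diagonals so that phantom studies measure the pipeline, not this
well-known thinning artifact.

**Staircase smoothing.** Thinning leaves two-pixel staircase steps on
shallow diagonals, which corrupt junction detection (the step pixels have
three neighbors). A single deterministic pass deletes a pixel whose two
path neighbors match either staircase coordinate pattern (predecessor
left / successor above, or predecessor above / successor right, checked
in both walk directions), skipping any deletion that would disconnect the
local neighborhood.

**Keypoints.** Endpoints have exactly one skeleton neighbor. An
intersection pixel must have N(p1) ≥ 3 *and* every clockwise triple
p3+p4+p5, p5+p6+p7, p7+p8+p9, p9+p2+p3 at most 1 — this rejects pixels
merely adjacent to a junction. Adjacent qualifying pixels are merged to
the one nearest the cluster centroid. Note the triple conditions miss some
symmetric Y-junctions (two arms falling into the same triple); therefore
the *splitting* step below cuts at all junction clusters, while the
reported intersection set stays as defined.

**Splitting, burrs, repair.** The skeleton is cut at junction pixels
(≥ 3 neighbors). Junction clusters a few pixels apart joined by a
connector chain shorter than the burr length are one anatomical
bifurcation split in two by thinning; such connectors are absorbed into a
single cluster instead of being reported as vessels. Each remaining chain
becomes one ordered path; incident paths share the junction cluster's
representative pixel, which is excluded from a path's own length. Paths
shorter than 6 own pixels with a free end are burrs and removed (a path
of exactly 6 px is kept). The deburred skeleton is the original minus the
burrs' own pixels, with junction remnants of a dissolved spur pruned when
their removal keeps the neighborhood connected; repair then restores a
deleted pixel that would rejoin two endpoints of different components
lying within 2 px of a former junction — re-joining vessels wrongly cut by
burr removal. Keypoints are recomputed and the skeleton re-split, so a
junction whose spur vanished no longer splits the through-vessel.

## Segment description

A segment's start/end are its terminal skeleton pixels (oriented so the
start is city-block-closer to the origin; the tree may re-orient a child
so its start sits at the junction it attaches by). Length is the own-pixel
count of the path.

**Diameter.** At each centerline pixel a straight line is fitted by least
squares (minimizing Σ(ax+b−y)²) to a window of N = 5 path pixels centered
on it (truncated at path ends; axes swapped when the x-spread is < 1e-6,
i.e. a vertical window). The normal through the pixel is marched in both
directions in 0.25-px steps with bilinear mask interpolation; the exit is
the sub-pixel 0.5-crossing, capped at 50 px per side. The diameter is the
distance between the two exits. Samples are dropped when

- they lie within 2 px (Euclidean) of a split point, or
- the measured diameter d exceeds twice the sample's distance to the
  nearest split point — there the chord still spans the bifurcation blob
  and is not a lumen diameter. Without this guard the junction bulge at a
  child vessel's origin fabricates ~50 % stenosis candidates.

On phantom bars of width 3–11 px at 0–90°, the mean absolute diameter
error is ≈ 0.1 px and > 99 % of samples agree with a 2×distance-transform
oracle within 1.5 px.

## Vessel tree

Breadth-first from the root: an unassigned segment whose nearer endpoint
lies within city-block distance 10 (inclusive) of the node's end becomes a
child (the three nearest win if more qualify) and is oriented to start at
the junction. Siblings are ordered by the sign of the cross product
V = (x2−x1)(y3−y2) − (y2−y1)(x3−x2), evaluated in image coordinates,
pairwise for three children; since incident paths share the junction pixel
as start, the ordering uses a *departure point* ~5 px into each child,
which carries the branch direction. Collinear ties order by ascending
(x, y). Unreachable segments become roots of additional trees of a forest
(segmentation dropouts should not abort the frame). IDs are rewritten in
level order across the forest: the root gets the smallest ID and IDs grow
with depth, mirroring the order in which vessels fill with contrast.

## Sequence fusion

For segments of two frames, d_s and d_e are the city-block distances of
their start and end points and rate = min(L1,L2)/max(L1,L2). A pair
matches iff d_s < 65, d_e < 65, rate > 0.80, all strict, thresholds tied
to the acquisition frame rate (config-overridable). All candidate pairs
are collected and assigned greedily by ascending d_s + d_e, so ambiguity
resolution is deterministic and independent of input order. Tracks extend
frame-by-frame; a track ending at frame t tries frames t+1, t+2, t+3, and
a segment already in a track is never re-matched. Per member the track
stores the frame's most-severe stenosis degree (0 when the vessel has no
candidate minimum, missing when the profile is too short to assess) and
the mean smoothed diameter.

## Stenosis and myocardial bridge

The diameter curve is smoothed by a trailing moving average
y(k) = mean(x(k−N_w+1..k)) with the window shrinking at the left edge.
N_w defaults to 5 (odd, matching the line-fit scale; the value is a
package choice and config-overridable).

A stenosis candidate is a local minimum of the smoothed curve; the
expected healthy diameter is the mean of the nearest local maxima on
either side (a curve endpoint counts as a maximum when the curve runs
monotonically into it), giving P = (1 − 2·D_min/(D_f + D_b))·100. For a
non-peripheral (non-leaf) vessel the single candidate is the global
minimum of the whole curve; a peripheral vessel uses its interior local
minima excluding the distal 20 % of the path, where distal tapering is
physiological. Findings below 30 % are normal vessels and not reported.
Grades are half-open, lower-inclusive: [30, 50) mild (label 0), [50, 70)
moderate (1), ≥ 70 severe (2).

A track with ≥ 4 members is screened with two independent rules, A first:

- **A (stenosis variation):** some pair of frames at least 3 apart whose
  stenosis degrees differ by ≥ 0.25;
- **B (diameter ratio):** some pair of frames at least 3 apart whose mean
  diameters have ratio min/max ≤ 0.75 — covering long lesions where no
  discrete stenosis can be quantified.

A rule's reported extrema are the qualifying pair with the largest swing
(smallest ratio). Evaluating pairs rather than single max/min occurrences
keeps the frame-gap requirement meaningful when a periodic signal attains
its extremes repeatedly.

Internally stenosis degrees are fractions (0–1); reports print percent.

## Phantom generator

The phantom emulates exactly what the pipeline assumes: branching trees
(widths ~3–15 px, bi-/trifurcations only — a junction with a single
continuing child is the same vessel and is not generated), rigid per-frame
translation, and lesions as raised-cosine width dips
w(s) = base·(1 − degree·(1+cos(2π(s−s0)/extent))/2) over a finite extent.
A periodic lesion's degree oscillates as severity·(1+cos(2πt/period))/2 —
the milking effect — while a static lesion keeps its severity. Rendering
stamps a disc of diameter equal to the local width at centerline samples
spaced 0.5 px, so the rendered width is analytically known; vessels are
clipped at the image border and the truth sidecar marks clipped segments.
Everything is a pure function of the spec (bit-exact reproducibility);
the seed only drives the layout helpers.

What the phantom does *not* emulate: X-ray background anatomy, contrast
diffusion and noise, segmentation errors, vessel overlap/crossing, and
non-rigid cardiac deformation. Passing phantom suites therefore validates
the geometry and logic of the pipeline under its stated assumptions, not
its robustness to imperfect segmentations.

Default study sizes keep suites fast while exercising every code path:
256×256 frames, trees of 3–7 segments, sequences of 4–12 frames, motion
up to ~±12 px/frame (well inside the 65-px matching bound), lesion
severities 0.45–0.6 (periodic) and 0.35–0.5 (static) with period 6
frames over 12-frame sequences, so rule A's 0.25 swing and 3-frame gap
are genuinely probed.

## Evaluation metrics

Dice = 2|A∩B|/(|A|+|B|) (1.0 for two empty masks); ASD averages the
symmetric nearest-boundary distances over both 4-connectivity boundaries
(error on empty masks); accuracy = (TP+TN)/total and recall = TP/(TP+FN),
NaN when undefined. ASD is validated against a brute-force double-loop
oracle.

## Determinism

There is no hidden randomness: thinning, splitting, tree construction,
matching (global greedy with total tie-breaks) and the clinical rules are
deterministic, so identical masks and config produce byte-identical
reports, and identical phantom specs produce bit-identical masks and
truth.
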