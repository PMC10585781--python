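# angiotrack

Post-segmentation analytics for coronary X-ray angiography sequences.

Conventional coronary angiography records a few seconds of contrast-filled
coronaries at ~15 fps. Once the vessels have been segmented into binary
masks, the clinically interesting questions are quantitative: where is the
lumen narrowed and by how much, and does the narrowing of a vessel *pulse*
with the cardiac cycle — the "milking effect" of a **myocardial bridge**,
a band of myocardium overlying a coronary segment and squeezing it during
systole. `angiotrack` answers these questions from the masks alone:

1. **Centerlines** — Zhang–Suen thinning with a staircase-smoothing pass,
   endpoint/intersection detection on the single-pixel skeleton, splitting
   into per-vessel paths, burr (< 6 px spur) removal and skeleton repair.
2. **Segment description** — per-vessel diameter profile `d = |A − B|`,
   where A and B are the exits of the mask along the normal of a local
   least-squares line (window N = 5) through each centerline pixel; plus
   length and start/end coordinates.
3. **Vessel tree** — a per-frame ternary tree rooted at the
   catheter-proximal segment (nearest the upper-left image origin); a
   segment with start within city-block distance d_n ≤ 10 of a node's end
   becomes its child, siblings ordered by the cross product
   `V = (x2−x1)(y3−y2) − (y2−y1)(x3−x2)`.
4. **Sequence fusion** — the same physical vessel is linked across frames
   when `d_s < 65`, `d_e < 65` and `rate = min(L1,L2)/max(L1,L2) > 0.80`
   (city-block distances of start and end points); ambiguities resolve to
   the smallest `d_s + d_e`, and gaps of up to three frames are bridged.
5. **Clinical findings** — percent diameter stenosis
   `P = (1 − 2·D_min/(D_f + D_b)) · 100` from the smoothed diameter curve
   (local minimum vs. flanking local maxima), graded mild [30, 50) /
   moderate [50, 70) / severe ≥ 70; a myocardial bridge is called on a
   track when the per-frame stenosis degree swings by ≥ 0.25, or the
   per-frame mean diameter ratio min/max drops to ≤ 0.75, with the
   extreme frames at least 3 frames apart.

A deterministic phantom generator (`angiotrack.phantom`) renders branching
vessel trees with known widths, rigid inter-frame motion, and focal or
periodic narrowings, each with a ground-truth JSON sidecar — so the whole
pipeline is testable without clinical data. An evaluation module provides
Dice, average symmetric surface distance (ASD), accuracy and recall.

## Worked example

```python
import numpy as np
from angiotrack import phantom, pipeline

# a proximal vessel with a periodic (bridge-like) lesion, drifting rigidly
spec = phantom.lesion_sequence_spec(seed=7, periodic=True, n_frames=12)
masks, truth = phantom.make_sequence(spec)

report = pipeline.run_pipeline(masks)
print("frames:  ", report["metadata"]["n_frames"])
print("segments:", len(report["frames"][0]["segments"]))
print("tracks:  ", len(report["tracks"]))
b = report["bridges"][0]
print("bridge:  rule=%s  swing %.2f -> %.2f  frames %d/%d" % (
    b["rule"], b["stenosis_min"], b["stenosis_max"],
    b["stenosis_min_frame"], b["stenosis_max_frame"]))
```

prints

```
frames:   12
segments: 3
tracks:   3
bridge:  rule=stenosis_variation  swing 0.02 -> 0.47  frames 3/6
```

i.e. each frame decomposes into the three phantom vessels, each vessel is
followed through all twelve frames, and the lesioned track is flagged as a
myocardial bridge by the stenosis-variation rule: its measured stenosis
degree oscillates between ~0.02 (frame 3, fully open) and ~0.47 (frame 6,
peak compression), far beyond the 0.25 threshold, with the extrema three
frames apart.

The same pipeline is available from the shell:

```sh
angiotrack simulate --spec spec.yaml --out seq/ --seed 7
angiotrack analyze  --masks seq/ --out report.json --qc qc/
angiotrack evaluate --ref seq/ --seg seq/ --out metrics.json
```

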